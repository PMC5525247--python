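"""Preferred-cage dynamics: blocks, stability, and chance-match tests.

At each 10-minute grid point the preferred cage is the argmax of the
cumulative satellite dwell durations. A maximal run of grid points with a
constant preferred cage is a "preference block"; few long blocks indicate a
stable choice, many short ones an unstable one. Whether the early
preference (after 10 min, 90 min, 24 h) already matches the final
preference is compared against the 1-in-4 chance expectation with a 1-df
chi-square goodness-of-fit test (Yates continuity correction on by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rfid import Occupancy, compute_durations
from .selectivity import DEFAULT_STEP_S, cumulative_cage_durations, grid_times

UNDEFINED = -1  # preference code before any satellite visit
DEFAULT_CHECKPOINTS_H = (10.0 / 60.0, 1.5, 24.0)


@dataclass
class PreferenceSeries:
    """Preferred cage (1..4, or −1 while undefined) on the 10-minute grid."""

    times_h: np.ndarray
    cage: np.ndarray  # int codes

    @property
    def defined(self) -> np.ndarray:
        return self.cage != UNDEFINED


def preferred_cage_series(
    occupancy: Occupancy, step_s: float = DEFAULT_STEP_S
) -> PreferenceSeries:
    """Argmax of cumulative satellite dwell at each grid point.

    Ties keep the previous defined point's preference when it is among the
    tied maxima, else take the lowest cage index; the series is undefined
    until the first satellite visit.
    """
    times = grid_times(occupancy.layout.span_hours, step_s)
    cum = cumulative_cage_durations(occupancy, times)
    totals = cum.sum(axis=1)
    cage = np.full(len(times), UNDEFINED, dtype=int)
    defined = totals > 0
    base = np.argmax(cum, axis=1) + 1  # lowest index on ties
    is_tie = np.sum(cum == cum.max(axis=1, keepdims=True), axis=1) > 1
    prev = UNDEFINED
    for i in np.flatnonzero(defined):
        if is_tie[i] and prev != UNDEFINED and cum[i, prev - 1] == cum[i].max():
            cage[i] = prev
        else:
            cage[i] = base[i]
        prev = cage[i]
    return PreferenceSeries(times_h=times, cage=cage)


@dataclass
class BlockSummary:
    """Stability summary of one preference series."""

    n_blocks: int
    last_block_fraction: float  # % of defined grid points in the final run
    stabilization_time_h: float  # grid time at which the final block starts


def segment_blocks(series: PreferenceSeries) -> BlockSummary | None:
    """Count preference blocks and measure the final block.

    n_blocks = 1 + number of changes between consecutive defined points
    (4 changes = 5 blocks). Returns None for an all-undefined series.
    """
    idx = np.flatnonzero(series.defined)
    if idx.size == 0:
        return None
    vals = series.cage[idx]
    changes = np.flatnonzero(np.diff(vals) != 0)
    n_blocks = 1 + len(changes)
    last_start_pos = changes[-1] + 1 if len(changes) else 0
    run_len = len(vals) - last_start_pos
    return BlockSummary(
        n_blocks=int(n_blocks),
        last_block_fraction=100.0 * run_len / len(vals),
        stabilization_time_h=float(series.times_h[idx[last_start_pos]]),
    )


@dataclass
class FinalPreference:
    cage: int  # 1..4
    tie: bool


def final_preference(occupancy: Occupancy) -> FinalPreference | None:
    """Cage with the largest total dwell over the whole run.

    Ties resolve to the lowest index with a flag; None if the mouse never
    entered a satellite cage.
    """
    d = compute_durations(occupancy).satellite_totals_h
    if d.sum() == 0:
        return None
    best = int(np.argmax(d)) + 1
    tie = int(np.sum(d == d.max())) > 1
    return FinalPreference(cage=best, tie=tie)


@dataclass
class CheckpointMatch:
    checkpoint_h: float
    matched: bool
    undefined_at_checkpoint: bool


def match_at(
    series: PreferenceSeries,
    occupancy: Occupancy,
    checkpoints_h: tuple[float, ...] = DEFAULT_CHECKPOINTS_H,
) -> list[CheckpointMatch]:
    """Does the early preference match the final one?

    For each checkpoint, the preferred cage at the last grid point at or
    before the checkpoint is compared to the full-run final preference; an
    undefined preference at the checkpoint counts as a non-match, flagged
    separately.
    """
    final = final_preference(occupancy)
    out = []
    for cp in checkpoints_h:
        if cp <= 0 or cp > occupancy.layout.span_hours:
            raise ValueError(f"checkpoint {cp} h outside the run window")
        i = int(np.searchsorted(series.times_h, cp + 1e-9) - 1)
        pref = series.cage[i] if i >= 0 else UNDEFINED
        undefined = pref == UNDEFINED or final is None
        out.append(
            CheckpointMatch(
                checkpoint_h=cp,
                matched=bool(not undefined and pref == final.cage),
                undefined_at_checkpoint=bool(undefined),
            )
        )
    return out


@dataclass
class MatchTestResult:
    n_matched: int
    n_total: int
    expected: float
    statistic: float
    p: float
    yates: bool


def chance_match_test(
    n_matched: int, n_total: int, k_options: int = 4, yates: bool = True
) -> MatchTestResult:
    """Goodness-of-fit of observed matches against the 1/k chance rate.

    Observed (matched, unmatched) counts are compared with expectations
    (n/k, n·(k−1)/k) in a 1-df chi-square test. With the Yates continuity
    correction (default), |O−E| is reduced by 0.5 (floored at 0) before
    squaring; the corrected statistic never exceeds the uncorrected one.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_matched <= n_total:
        raise ValueError("n_matched must lie in [0, n_total]")
    expected = n_total / k_options
    obs = np.array([n_matched, n_total - n_matched], dtype=float)
    exp = np.array([expected, n_total - expected])
    dev = np.abs(obs - exp)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float(np.sum(dev**2 / exp))
    p = float(stats.chi2.sf(statistic, df=1))
    return MatchTestResult(
        n_matched=int(n_matched),
        n_total=int(n_total),
        expected=expected,
        statistic=statistic,
        p=p,
        yates=yates,
    )
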