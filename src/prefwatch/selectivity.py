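"""Selectivity index (SI) and its temporal dynamics.

SI = SD / SD_max, where SD is the sample standard deviation (n−1
denominator) of the four percentage dwell shares across the satellite
cages and SD_max = 50 is the largest standard deviation attainable with
four shares (realised by 100/0/0/0). SI is 0 for a mouse dividing its
social time evenly and 1 for a mouse that visits a single satellite cage
only. The temporal series evaluates SI on cumulative (expanding) windows
anchored at the run start, on a 10-minute grid: the first window is 10
minutes long, the second 20, and so forth. Before the first satellite
visit SI is undefined and propagated as NaN, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .rfid import Occupancy

SD_MAX = 50.0
DEFAULT_STEP_S = 600.0


def grid_times(span_h: float, step_s: float = DEFAULT_STEP_S) -> np.ndarray:
    """Evaluation grid t_i = i·step from the run start (i ≥ 1)."""
    step_h = step_s / 3600.0
    n = int(np.floor(span_h / step_h + 1e-9))
    return np.arange(1, n + 1) * step_h


def cumulative_cage_durations(occupancy: Occupancy, times_h: np.ndarray) -> np.ndarray:
    """Cumulative dwell per satellite cage at each grid time.

    Returns an array of shape (len(times_h), 4): column k is the total time
    spent in satellite cage k+1 on [0, t]. Each cage's cumulative dwell is
    piecewise linear (slope 1 inside its own intervals), so evaluation
    interpolates between interval boundaries.
    """
    out = np.zeros((len(times_h), 4))
    for cage in range(1, 5):
        sel = occupancy.cages == cage
        if not sel.any():
            continue
        s = occupancy.start_h[sel]
        e = occupancy.end_h[sel]
        d = np.cumsum(e - s)
        xs = np.empty(2 * len(s))
        ys = np.empty(2 * len(s))
        xs[0::2], xs[1::2] = s, e
        ys[0::2] = d - (e - s)
        ys[1::2] = d
        out[:, cage - 1] = np.interp(times_h, xs, ys, left=0.0, right=ys[-1])
    return out


def proportional_durations(d: np.ndarray) -> np.ndarray:
    """Percentage shares p_k = 100·d_k/Σd of the four satellite dwells.

    All-zero input (no social time) yields an all-NaN vector — the
    undefined marker — rather than an exception.
    """
    d = np.asarray(d, dtype=float)
    if d.shape != (4,):
        raise ValueError("expected four satellite dwell totals")
    if np.any(d < 0):
        raise ValueError("durations must be nonnegative")
    total = d.sum()
    if total == 0:
        return np.full(4, np.nan)
    return 100.0 * d / total


def selectivity_index(p: np.ndarray) -> float:
    """SI of a percentage vector: sample SD of the four shares over 50."""
    p = np.asarray(p, dtype=float)
    if p.shape != (4,):
        raise ValueError("expected four percentages")
    if np.isnan(p).all():
        return float("nan")
    if np.any(p < -1e-9) or abs(p.sum() - 100.0) > 1e-6:
        raise ValueError("percentages must be nonnegative and sum to 100")
    return float(np.std(p, ddof=1) / SD_MAX)


@dataclass
class SelectivitySeries:
    """Cumulative SI on the 10-minute grid for one focal mouse."""

    times_h: np.ndarray
    si: np.ndarray  # NaN where undefined (no satellite time yet)
    cumulative_h: np.ndarray  # (n_grid, 4) cumulative satellite dwells
    mouse_id: str | None = None

    def to_frame(self) -> pd.DataFrame:
        totals = self.cumulative_h.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals[:, None] > 0, 100.0 * self.cumulative_h / totals[:, None], np.nan)
        df = pd.DataFrame(
            {
                "t_h": self.times_h,
                **{f"S{k}_h": self.cumulative_h[:, k - 1] for k in range(1, 5)},
                **{f"S{k}_pct": pct[:, k - 1] for k in range(1, 5)},
                "si": self.si,
            }
        )
        if self.mouse_id is not None:
            df.insert(0, "mouse_id", self.mouse_id)
        return df


def si_series(
    occupancy: Occupancy, step_s: float = DEFAULT_STEP_S, mouse_id: str | None = None
) -> SelectivitySeries:
    """Cumulative-window SI at every grid point of the run."""
    times = grid_times(occupancy.layout.span_hours, step_s)
    cum = cumulative_cage_durations(occupancy, times)
    totals = cum.sum(axis=1)
    si = np.full(len(times), np.nan)
    defined = totals > 0
    if defined.any():
        pct = 100.0 * cum[defined] / totals[defined, None]
        si[defined] = np.std(pct, axis=1, ddof=1) / SD_MAX
    return SelectivitySeries(times_h=times, si=si, cumulative_h=cum, mouse_id=mouse_id)


def overall_si(occupancy: Occupancy) -> float:
    """SI of the full-run satellite dwell totals (one value per mouse)."""
    from .rfid import compute_durations

    d = compute_durations(occupancy).satellite_totals_h
    return selectivity_index(proportional_durations(d))


def group_mean_si(series: list[SelectivitySeries]) -> pd.DataFrame:
    """Pointwise mean SI with a t-based symmetric 95% confidence band.

    Undefined values are excluded pointwise; the per-point n is reported.
    The band is NaN where fewer than two values are defined.
    """
    if not series:
        raise ValueError("need at least one series")
    times = series[0].times_h
    for s in series[1:]:
        if not np.array_equal(s.times_h, times):
            raise ValueError("series are on different grids")
    mat = np.vstack([s.si for s in series])
    n = np.sum(~np.isnan(mat), axis=0)
    mean = np.full(len(times), np.nan)
    sd = np.full(len(times), np.nan)
    if (n > 0).any():
        mean[n > 0] = np.nanmean(mat[:, n > 0], axis=0)
    if (n > 1).any():
        sd[n > 1] = np.nanstd(mat[:, n > 1], axis=0, ddof=1)
    se = sd / np.sqrt(np.maximum(n, 1))
    tcrit = np.where(n > 1, stats.t.ppf(0.975, np.maximum(n - 1, 1)), np.nan)
    half = tcrit * se
    return pd.DataFrame(
        {"t_h": times, "mean_si": mean, "ci_lo": mean - half, "ci_hi": mean + half, "n": n}
    )
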