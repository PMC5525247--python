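"""Antenna-read logs, occupancy reconstruction, dwell durations, activity.

The arena is a star: one central cage joined to four satellite cages by
tubes, each tube carrying two ring antennae (one at the central end, one at
the satellite end). A read therefore places the mouse at a known tube end.
Occupancy is reconstructed with a nearest-side rule: after a read at the
satellite end of tube k the mouse is in satellite cage Sk, after a read at
the central end it is in the central cage, and the location changes at the
read's timestamp. The rule needs no lookahead, is robust to missed reads,
and attributes tube transit time to the origin cage.

All within-run times are expressed as float hours from the run start; the
run window (default: Thursday 16:00 to the following Wednesday 08:00,
136 h) is carried by the :class:`AntennaLayout`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

#: cage codes: 0 = central, 1..4 = S1..S4
CENTRAL = 0
CAGE_NAMES = ("central", "S1", "S2", "S3", "S4")

DEFAULT_START = datetime(2014, 3, 6, 16, 0, 0)  # a Thursday, 16:00
DEFAULT_END = datetime(2014, 3, 12, 8, 0, 0)  # the following Wednesday, 08:00
NOMINAL_SPAN_H = 136.0


@dataclass(frozen=True)
class AntennaRead:
    """One detection: a timestamp (ms resolution) and an antenna id."""

    timestamp: datetime
    antenna_id: int


def default_antenna_map() -> dict[int, tuple[int, str]]:
    """Antenna 2k−1 sits at the central end of tube k, antenna 2k at the
    satellite end."""
    m: dict[int, tuple[int, str]] = {}
    for k in range(1, 5):
        m[2 * k - 1] = (k, "central")
        m[2 * k] = (k, "satellite")
    return m


@dataclass
class AntennaLayout:
    """Arena wiring plus the run window for one focal mouse.

    ``antennae`` maps antenna id → (tube 1..4, side ∈ {central, satellite});
    exactly eight antennae, each (tube, side) pair once.
    """

    antennae: dict[int, tuple[int, str]] = field(default_factory=default_antenna_map)
    start: datetime = DEFAULT_START
    end: datetime = DEFAULT_END
    focal_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.antennae) != 8:
            raise ValueError(f"expected 8 antennae, got {len(self.antennae)}")
        pairs = set()
        for aid, (tube, side) in self.antennae.items():
            if tube not in (1, 2, 3, 4) or side not in ("central", "satellite"):
                raise ValueError(f"bad (tube, side) for antenna {aid}: ({tube}, {side})")
            pairs.add((tube, side))
        if len(pairs) != 8:
            raise ValueError("each (tube, side) pair must appear exactly once")
        if self.end <= self.start:
            raise ValueError("run end must follow run start")

    @property
    def span_hours(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    def cage_of(self, antenna_id: int) -> int:
        """Location implied by a read at this antenna under the nearest-side
        rule: satellite end → that tube's satellite cage, central end →
        central."""
        tube, side = self.antennae[antenna_id]
        return tube if side == "satellite" else CENTRAL

    def antenna_for(self, tube: int, side: str) -> int:
        for aid, ts in self.antennae.items():
            if ts == (tube, side):
                return aid
        raise KeyError((tube, side))

    def hours_from_start(self, ts: datetime) -> float:
        return (ts - self.start).total_seconds() / 3600.0


# ---------------------------------------------------------------------------
# event-log I/O
# ---------------------------------------------------------------------------

@dataclass
class LogAnomalies:
    unknown_antenna: int = 0
    duplicates_collapsed: int = 0
    truncated_recording: bool = False


def write_event_log(reads: list[AntennaRead], path) -> None:
    """Two-column TSV: ISO-8601 timestamp with milliseconds, antenna id."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.timestamp.isoformat(timespec='milliseconds')}\t{r.antenna_id}\n")


def read_event_log(
    path, layout: AntennaLayout, min_span_fraction: float = 0.9
) -> tuple[list[AntennaRead], LogAnomalies]:
    """Parse an event-log TSV into time-sorted reads.

    Unknown antenna ids are dropped and counted; exact duplicates (same
    timestamp and antenna) are collapsed and counted; a recording whose
    first-to-last read span is below ``min_span_fraction`` of the nominal
    run window is flagged as truncated (never silently dropped). An empty
    file is valid and yields an empty list. Unparseable timestamps raise
    with the offending line number.
    """
    anomalies = LogAnomalies()
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["timestamp", "antenna_id"], dtype=str)
    except pd.errors.EmptyDataError:
        return [], anomalies
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    bad = np.flatnonzero(ts.isna().to_numpy())
    if bad.size:
        raise ValueError(f"unparseable timestamp at line {bad[0] + 1}: {df['timestamp'].iloc[bad[0]]!r}")
    aid = pd.to_numeric(df["antenna_id"], errors="coerce")
    if aid.isna().any():
        line = int(np.flatnonzero(aid.isna().to_numpy())[0])
        raise ValueError(f"unparseable antenna id at line {line + 1}")
    df = pd.DataFrame({"timestamp": ts, "antenna_id": aid.astype(int)})
    known = df["antenna_id"].isin(layout.antennae.keys())
    anomalies.unknown_antenna = int((~known).sum())
    df = df[known]
    before = len(df)
    df = df.drop_duplicates(subset=["timestamp", "antenna_id"], keep="first")
    anomalies.duplicates_collapsed = before - len(df)
    df = df.sort_values("timestamp", kind="stable")
    reads = [
        AntennaRead(timestamp=t.to_pydatetime(), antenna_id=int(a))
        for t, a in zip(df["timestamp"], df["antenna_id"])
    ]
    if reads:
        span = (reads[-1].timestamp - reads[0].timestamp).total_seconds() / 3600.0
        if span < min_span_fraction * layout.span_hours:
            anomalies.truncated_recording = True
    return reads, anomalies


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OccupancyInterval:
    cage: str
    t_start: datetime
    t_end: datetime


@dataclass
class Occupancy:
    """Tiling of the run window into cage stays.

    ``cages`` holds integer cage codes, ``start_h``/``end_h`` hours from the
    run start; successive intervals abut exactly and cover the whole window.
    """

    cages: np.ndarray
    start_h: np.ndarray
    end_h: np.ndarray
    layout: AntennaLayout
    anomalies: dict = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.cages) == 0:
            raise ValueError("occupancy must cover the run window")
        if not np.all(self.end_h > self.start_h):
            raise ValueError("empty or inverted interval")
        if self.start_h[0] != 0.0 or not np.isclose(self.end_h[-1], self.layout.span_hours):
            raise ValueError("occupancy does not cover the run window")
        if len(self.cages) > 1 and not np.array_equal(self.end_h[:-1], self.start_h[1:]):
            raise ValueError("intervals do not abut")

    def intervals(self) -> list[OccupancyInterval]:
        out = []
        for c, s, e in zip(self.cages, self.start_h, self.end_h):
            out.append(
                OccupancyInterval(
                    cage=CAGE_NAMES[int(c)],
                    t_start=self.layout.start + timedelta(hours=float(s)),
                    t_end=self.layout.start + timedelta(hours=float(e)),
                )
            )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cage": [CAGE_NAMES[int(c)] for c in self.cages],
                "start_h": self.start_h,
                "end_h": self.end_h,
            }
        )


def reconstruct_occupancy(reads: list[AntennaRead], layout: AntennaLayout) -> Occupancy:
    """Apply the nearest-side rule to a sorted read sequence.

    The mouse starts in the central cage (where it was placed); each read
    moves it to the cage implied by the antenna's side, at the read's
    timestamp; the final interval extends to the run end. Reads outside the
    run window are rejected and counted. The anomaly report additionally
    counts physically impossible jumps — a satellite-end read in tube j
    while the current location is a different satellite cage, with no
    intervening central-end read (the star topology forbids direct
    satellite→satellite moves).
    """
    span = layout.span_hours
    if reads:
        t = np.array([layout.hours_from_start(r.timestamp) for r in reads])
        codes = np.array([layout.cage_of(r.antenna_id) for r in reads])
        inside = (t >= 0.0) & (t <= span)
        out_of_window = int((~inside).sum())
        t, codes = t[inside], codes[inside]
    else:
        t = np.empty(0)
        codes = np.empty(0, dtype=int)
        out_of_window = 0

    # location after each read is fully determined by that read
    prev_loc = np.concatenate(([CENTRAL], codes[:-1])) if codes.size else codes
    jumps = int(np.sum((codes > 0) & (prev_loc > 0) & (codes != prev_loc)))

    # collapse runs: a read only opens a new interval when it changes location
    change = codes != prev_loc
    ct = t[change]
    cc = codes[change]
    starts = np.concatenate(([0.0], ct))
    cages = np.concatenate(([CENTRAL], cc)).astype(int)
    ends = np.concatenate((starts[1:], [span]))
    keep = ends > starts  # a change exactly at t=0 or t=end leaves a void stub
    occ = Occupancy(
        cages=cages[keep],
        start_h=starts[keep],
        end_h=ends[keep],
        layout=layout,
        anomalies={"out_of_window": out_of_window, "impossible_jumps": jumps},
    )
    occ.validate()
    return occ


@dataclass
class DurationSummary:
    """Per-cage total dwell (hours) and the share of time spent social."""

    totals_h: np.ndarray  # length 5, index = cage code
    social_share: float
    span_h: float

    @property
    def satellite_totals_h(self) -> np.ndarray:
        return self.totals_h[1:]


def compute_durations(occupancy: Occupancy) -> DurationSummary:
    """Total time per cage and the fraction of the run spent in any
    satellite cage (time "close to another mouse")."""
    dur = occupancy.end_h - occupancy.start_h
    totals = np.bincount(occupancy.cages, weights=dur, minlength=5)
    span = occupancy.layout.span_hours
    return DurationSummary(
        totals_h=totals,
        social_share=float(totals[1:].sum() / span),
        span_h=span,
    )


def activity_per_hour(
    reads: list[AntennaRead], window: tuple[datetime, datetime]
) -> pd.Series:
    """Antenna reads per clock hour over half-open bins [h, h+1).

    A read exactly on an hour boundary counts in the later bin; hours with
    no reads are 0. The sum over bins equals the number of reads inside the
    window.
    """
    start, end = window
    idx = pd.date_range(start.replace(minute=0, second=0, microsecond=0), end, freq="h")
    if len(idx) and idx[-1] >= end:
        idx = idx[:-1]
    counts = pd.Series(0, index=idx, dtype=int)
    if reads:
        ts = pd.Series([r.timestamp for r in reads])
        ts = ts[(ts >= start) & (ts < end)]
        binned = ts.dt.floor("h").value_counts()
        counts = counts.add(binned, fill_value=0).astype(int)
    counts.index.name = "hour"
    counts.name = "reads"
    return counts
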