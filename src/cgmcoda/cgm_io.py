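"""Reading CGM series and cutting anchored 24-h / 6-h windows.

CGM devices record glucose nominally every 5 minutes; real exports contain
gaps, jitter and occasional bad rows.  This module parses a timestamped CSV
into a :class:`CGMSeries`, extracts half-open windows starting at the four
anchor clock times (00:00, 06:00, 12:00, 18:00) and applies the validity
rule: a 24-h window is usable only if each of its four 6-h sub-blocks
contains at least 70% of the expected samples.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: anchor clock times at which windows start or end
ANCHORS = (dt.time(0), dt.time(6), dt.time(12), dt.time(18))
DAY_MINUTES = 1440
BLOCK_MINUTES = 360
VALID_DURATIONS = (DAY_MINUTES, BLOCK_MINUTES)


class FormatError(ValueError):
    """The input file does not have the expected columns."""


class DataError(ValueError):
    """The input violates a data invariant (e.g. duplicate timestamps)."""


@dataclass(frozen=True)
class CGMSeries:
    """An ordered CGM record for one patient.

    ``times`` is a ``datetime64[ns]`` array aligned on the cadence grid,
    strictly increasing; ``glucose`` holds positive mg/dL values.
    """

    patient_id: str
    times: np.ndarray
    glucose: np.ndarray
    cadence: int = 5

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype="datetime64[ns]")
        g = np.asarray(self.glucose, dtype=float)
        if t.shape != g.shape or t.ndim != 1:
            raise ValueError("times and glucose must be 1-D arrays of equal length")
        if len(t) > 1 and np.any(np.diff(t) <= np.timedelta64(0, "ns")):
            raise DataError("timestamps must be strictly increasing and unique")
        if np.any(g <= 0) or not np.all(np.isfinite(g)):
            raise DataError("glucose values must be positive and finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "glucose", g)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def start(self) -> dt.datetime:
        return pd.Timestamp(self.times[0]).to_pydatetime()

    @property
    def end(self) -> dt.datetime:
        return pd.Timestamp(self.times[-1]).to_pydatetime()


@dataclass(frozen=True)
class PeriodWindow:
    """One 24-h or 6-h window of a series, anchored at a clock time.

    ``n_valid`` holds the observed sample count per 6-h sub-block (four
    entries for 24-h windows, one for 6-h windows).
    """

    start: dt.datetime
    duration: int
    cadence: int
    times: np.ndarray
    glucose: np.ndarray
    n_valid: tuple[int, ...]

    @property
    def anchor(self) -> dt.time:
        return self.start.time()

    @property
    def end(self) -> dt.datetime:
        return self.start + dt.timedelta(minutes=self.duration)

    @property
    def n_expected(self) -> int:
        return self.duration // self.cadence

    @property
    def n_observed(self) -> int:
        return len(self.times)


def _snap_to_grid(times: pd.Series, cadence: int) -> pd.Series:
    """Snap timestamps to the nearest multiple of the cadence from midnight."""
    return times.dt.round(f"{cadence}min")


def read_cgm_csv(path, cadence: int = 5, patient_id: str | None = None) -> CGMSeries:
    """Parse a CGM CSV with columns ``timestamp`` (ISO 8601) and ``glucose``.

    Rows with unparseable timestamps or non-numeric / non-positive glucose
    are dropped with a logged count.  Timestamps are snapped to the nearest
    cadence grid slot; when two rows snap to the same slot the first is kept
    and a warning is logged.  Exact duplicate timestamps in the input are a
    data error.
    """
    df = pd.read_csv(path)
    missing = {"timestamp", "glucose"} - set(df.columns)
    if missing:
        raise FormatError(f"missing required column(s): {sorted(missing)}")

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    glucose = pd.to_numeric(df["glucose"], errors="coerce")
    bad = ts.isna() | glucose.isna() | (glucose <= 0)
    if bad.any():
        logger.warning("dropped %d invalid row(s) from %s", int(bad.sum()), path)
    ts, glucose = ts[~bad], glucose[~bad]

    if ts.duplicated().any():
        raise DataError(f"duplicate timestamps in {path}")

    order = ts.argsort(kind="stable").to_numpy()
    ts = ts.iloc[order].reset_index(drop=True)
    glucose = glucose.iloc[order].reset_index(drop=True)

    snapped = _snap_to_grid(ts, cadence)
    clash = snapped.duplicated(keep="first")
    if clash.any():
        logger.warning(
            "%d sample(s) snapped onto an occupied %d-min slot; keeping first",
            int(clash.sum()), cadence,
        )
        snapped, glucose = snapped[~clash], glucose[~clash]

    pid = patient_id if patient_id is not None else str(path)
    return CGMSeries(pid, snapped.to_numpy(), glucose.to_numpy(), cadence)


def extract_window(series: CGMSeries, start: dt.datetime, duration: int) -> PeriodWindow:
    """Cut the half-open window ``[start, start + duration)`` from a series.

    ``duration`` must be 1440 or 360 minutes and ``start`` must fall on an
    anchor clock time.  Sample counts are tallied per 6-h sub-block.
    """
    if duration not in VALID_DURATIONS:
        raise ValueError(f"duration must be one of {VALID_DURATIONS}, got {duration}")
    if start.time() not in ANCHORS:
        raise ValueError(
            f"window start {start} is not at an anchor time "
            f"{[a.strftime('%H:%M') for a in ANCHORS]}"
        )
    t0 = np.datetime64(start, "ns")
    t1 = t0 + np.timedelta64(duration * 60_000_000_000, "ns")
    mask = (series.times >= t0) & (series.times < t1)
    times, glucose = series.times[mask], series.glucose[mask]

    n_blocks = duration // BLOCK_MINUTES
    block = np.timedelta64(BLOCK_MINUTES * 60_000_000_000, "ns")
    counts = tuple(
        int(((times >= t0 + i * block) & (times < t0 + (i + 1) * block)).sum())
        for i in range(n_blocks)
    )
    return PeriodWindow(start, duration, series.cadence, times, glucose, counts)


def is_valid(window: PeriodWindow, threshold: float = 0.70) -> bool:
    """Apply the per-6-h-block validity rule.

    Every 6-h sub-block must contain at least ``ceil(threshold * expected)``
    samples (51 of 72 at a 5-min cadence with the default 70% threshold);
    "at least 70%" is an inclusive bound on an integer count, hence the
    ceiling.  Standalone 6-h windows are held to the same rule on their
    single block.
    """
    expected = BLOCK_MINUTES // window.cadence
    need = math.ceil(threshold * expected)
    return all(n >= need for n in window.n_valid)


def iter_windows(series: CGMSeries, anchor: dt.time, duration: int):
    """Yield consecutive windows of ``duration`` starting at ``anchor``.

    Windows are generated for every calendar day the series touches; empty
    windows are skipped.  Consecutive same-anchor 24-h windows tile the
    timeline, so each sample lands in exactly one of them.
    """
    if anchor not in ANCHORS:
        raise ValueError(f"anchor must be one of {ANCHORS}")
    if len(series) == 0:
        return
    first = pd.Timestamp(series.times[0])
    last = pd.Timestamp(series.times[-1])
    day = (first.normalize() - pd.Timedelta(days=1)).to_pydatetime()
    stop = (last.normalize() + pd.Timedelta(days=1)).to_pydatetime()
    while day <= stop:
        start = dt.datetime.combine(day.date(), anchor)
        w = extract_window(series, start, duration)
        if w.n_observed > 0:
            yield w
        day += dt.timedelta(days=1)


def valid_windows(
    series: CGMSeries, anchor: dt.time, duration: int, threshold: float = 0.70
) -> list[PeriodWindow]:
    """All valid windows of the given duration starting at ``anchor``."""
    return [w for w in iter_windows(series, anchor, duration) if is_valid(w, threshold)]


def pair_24h_with_next_6h(
    series: CGMSeries, anchor: dt.time, threshold: float = 0.70
) -> list[tuple[PeriodWindow, PeriodWindow]]:
    """Pair each valid 24-h window ending at ``anchor`` with the valid 6-h
    window starting at that same instant.

    Pairs where either member fails the validity rule are excluded; the
    result may be empty.  This is the sampling unit of the transition
    model: the category of the past day conditions the category of the
    following 6 hours.
    """
    if anchor not in ANCHORS:
        raise ValueError(f"anchor must be one of {ANCHORS}")
    pairs = []
    if len(series) == 0:
        return pairs
    first = pd.Timestamp(series.times[0]).normalize()
    last = pd.Timestamp(series.times[-1]).normalize()
    day = first
    while day <= last + pd.Timedelta(days=1):
        t = dt.datetime.combine(day.date(), anchor)
        w24 = extract_window(series, t - dt.timedelta(minutes=DAY_MINUTES), DAY_MINUTES)
        if is_valid(w24, threshold):
            w6 = extract_window(series, t, BLOCK_MINUTES)
            if is_valid(w6, threshold):
                pairs.append((w24, w6))
        day += pd.Timedelta(days=1)
    return pairs
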