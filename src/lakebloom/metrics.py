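"""Bloom statistics from daily detections: weighted daily frequency,
15-day smoothing, onset, persistence and annual frequency.

The daily frequency weights the raw bloom fraction by the squared valid
observation fraction, so low-cloud (high-coverage) days dominate the
time series:

    frequency = (A_Bloom / A_valid) * (A_valid / A_Lake)**2
              = A_Bloom * A_valid / A_Lake**2

Phenology is extracted inside a per-lake "bloom year" window that absorbs
hemisphere and ice-season differences: calendar year for Northern lakes,
the ice-free melt-to-freeze span for frozen lakes, and a July-June window
for non-frozen Southern lakes.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .detection import LakeGeometry

__all__ = [
    "DailyBloomRecord",
    "AnnualMetrics",
    "BloomYearWindow",
    "daily_frequency",
    "smooth_daily",
    "bloom_year_window",
    "phenology",
]

#: Column names of the canonical daily detection table.
DAILY_COLUMNS = ("date", "A_Bloom", "A_valid", "A_Lake")

SMOOTH_WINDOW_DAYS = 15


@dataclass(frozen=True)
class DailyBloomRecord:
    """One lake-day observation: areas in km2 plus the weighted frequency."""

    date: dt.date
    a_bloom: float
    a_valid: float
    a_lake: float

    @property
    def frequency(self) -> float:
        return daily_frequency(self.a_bloom, self.a_valid, self.a_lake)


@dataclass(frozen=True)
class AnnualMetrics:
    """Per-lake-year phenology summary.

    ``onset``, ``persistence`` and ``annual_frequency`` are all present or
    all absent (None) depending on whether any bloom day fell in the
    window.  ``onset`` is a 1-based day within the window's calendar: the
    ordinary day-of-year for windows contained in one calendar year, and
    days since the window start for windows that wrap the new year.
    """

    lake_id: str
    bloom_year: int
    onset: Optional[int]
    persistence: Optional[int]
    annual_frequency: Optional[float]
    n_observations: int

    def __post_init__(self) -> None:
        present = [self.onset is None, self.persistence is None,
                   self.annual_frequency is None]
        if len(set(present)) != 1:
            raise ValueError("onset, persistence and annual_frequency must be "
                             "jointly present or jointly absent")


@dataclass(frozen=True)
class BloomYearWindow:
    """Date span over which one bloom year's phenology is extracted."""

    start: dt.date
    end: dt.date
    bloom_year: int
    #: True when onset is counted from the window start (windows that
    #: wrap the calendar year); False when onset is a calendar day-of-year.
    relative: bool

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def day_number(self, date: dt.date) -> int:
        """1-based day label for ``date`` under this window's convention."""
        if self.relative:
            return (date - self.start).days + 1
        return date.timetuple().tm_yday


def daily_frequency(a_bloom: float, a_valid: float, a_lake: float) -> float:
    """Cloud-weighted daily bloom frequency.

    Equals ``(A_Bloom/A_valid) * (A_valid/A_Lake)**2`` and hence
    ``A_Bloom*A_valid/A_Lake**2``; returns 0 for days with no valid
    observation.  Raises ``ValueError`` if the area ordering
    ``0 <= A_Bloom <= A_valid <= A_Lake`` (with ``A_Lake > 0``) is violated.
    """
    if a_lake <= 0:
        raise ValueError("A_Lake must be positive")
    if not (0 <= a_bloom <= a_valid * (1 + 1e-12) + 1e-12):
        raise ValueError("require 0 <= A_Bloom <= A_valid")
    if a_valid > a_lake * (1 + 1e-12) + 1e-12:
        raise ValueError("require A_valid <= A_Lake")
    if a_valid == 0:
        return 0.0
    return (a_bloom / a_valid) * (a_valid / a_lake) ** 2


def smooth_daily(
    frequency: pd.Series, window: Optional[BloomYearWindow] = None
) -> pd.Series:
    """Centered 15-day running mean over observed days only.

    ``frequency`` is indexed by the dates of days with a valid observation
    (``A_valid > 0``); unobserved days are simply absent and are excluded
    from each window's averaging set rather than zero-filled.  The window
    is truncated at the edges of the bloom-year window (or of the observed
    span when no window is given).  Returns a series on the same index.
    """
    if len(frequency) == 0:
        return frequency.copy()
    idx = pd.DatetimeIndex(frequency.index)
    if window is not None:
        full = pd.date_range(window.start, window.end, freq="D")
    else:
        full = pd.date_range(idx.min(), idx.max(), freq="D")
    dense = frequency.set_axis(idx).reindex(full)
    smoothed = dense.rolling(SMOOTH_WINDOW_DAYS, center=True, min_periods=1).mean()
    out = smoothed.loc[idx]
    out.index = frequency.index
    return out


def bloom_year_window(geometry: LakeGeometry, calendar_year: int) -> BloomYearWindow:
    """Bloom-year date window for one lake and calendar year.

    * Frozen lakes (either hemisphere): the ice-free span from the melt day
      of ``calendar_year`` to the next freeze day.  When the freeze day-of-
      year precedes the melt day-of-year the span runs into the following
      calendar year (austral summer).
    * Non-frozen Northern lakes: Jan 1 .. Dec 31 of ``calendar_year``.
    * Non-frozen Southern lakes: Jul 1 of ``calendar_year`` .. Jun 30 of the
      next year, labelled ``bloom_year = calendar_year``.
    """
    if geometry.frozen and geometry.ice_cover is not None:
        freeze, melt = geometry.ice_cover
        start = _from_doy(calendar_year, melt)
        end_year = calendar_year + (1 if freeze < melt else 0)
        end = _from_doy(end_year, freeze)
        return BloomYearWindow(start, end, calendar_year, relative=freeze < melt)
    if geometry.hemisphere == "N":
        return BloomYearWindow(
            dt.date(calendar_year, 1, 1),
            dt.date(calendar_year, 12, 31),
            calendar_year,
            relative=False,
        )
    return BloomYearWindow(
        dt.date(calendar_year, 7, 1),
        dt.date(calendar_year + 1, 6, 30),
        calendar_year,
        relative=True,
    )


def _from_doy(year: int, doy: int) -> dt.date:
    return dt.date(year, 1, 1) + dt.timedelta(days=int(doy) - 1)


def phenology(
    records: pd.DataFrame, window: BloomYearWindow, lake_id: str = "lake"
) -> AnnualMetrics:
    """Extract onset, persistence and annual frequency for one bloom year.

    ``records`` must carry columns ``date``, ``A_Bloom``, ``A_valid`` and
    ``A_Lake``; rows outside the window are ignored.  Onset is the first
    day with a detected bloom, persistence the inclusive span from first to
    last bloom day, and the annual frequency the median of the smoothed
    daily frequencies over that span.  All three are absent when the window
    holds no bloom day.
    """
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    in_win = (df["date"] >= window.start) & (df["date"] <= window.end)
    df = df.loc[in_win].sort_values("date")
    observed = df[df["A_valid"] > 0]
    n_obs = int(len(observed))
    bloom_days = observed[observed["A_Bloom"] > 0]
    if bloom_days.empty:
        return AnnualMetrics(lake_id, window.bloom_year, None, None, None, n_obs)

    first = bloom_days["date"].iloc[0]
    last = bloom_days["date"].iloc[-1]
    onset = window.day_number(first)
    persistence = (last - first).days + 1

    freq = pd.Series(
        [
            daily_frequency(r.A_Bloom, r.A_valid, r.A_Lake)
            for r in observed.itertuples()
        ],
        index=pd.DatetimeIndex(pd.to_datetime(observed["date"])),
    )
    smoothed = smooth_daily(freq, window)
    span = (smoothed.index >= pd.Timestamp(first)) & (
        smoothed.index <= pd.Timestamp(last)
    )
    annual = float(np.median(smoothed[span]))
    return AnnualMetrics(lake_id, window.bloom_year, onset, persistence, annual, n_obs)
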