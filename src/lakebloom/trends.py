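"""Per-lake and global trend estimation for annual bloom metrics.

Lakes qualify for trend analysis when blooms occurred in at least half of
their observed years.  Trends are ordinary least-squares slopes of annual
values on year, classified into four classes by sign and significance
(p < 0.05): Sig. Inc., Inc., Sig. Dec., Dec.  The global series is the
per-year median of annual frequency across bloom-affected lakes; its
relative rate is the OLS slope expressed as a percentage of the long-term
mean per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendResult",
    "RelativeRate",
    "PeriodComparison",
    "TREND_CLASSES",
    "eligible_lakes",
    "lake_trend",
    "global_median_series",
    "global_relative_rate",
    "period_comparison",
]

TREND_CLASSES = ("Sig. Inc.", "Inc.", "Sig. Dec.", "Dec.")

DEFAULT_ALPHA = 0.05
DEFAULT_PERIOD_A = (2003, 2015)
DEFAULT_PERIOD_B = (2016, 2022)


@dataclass(frozen=True)
class TrendResult:
    lake_id: str
    metric: str
    slope: float
    p_value: float
    n_years: int
    trend_class: str


@dataclass(frozen=True)
class RelativeRate:
    """OLS slope of a yearly series as % of its long-term mean per year."""

    rate_pct_per_yr: float
    slope: float
    p_value: float
    mean: float
    n_years: int


@dataclass(frozen=True)
class PeriodComparison:
    """Paired per-lake relative growth rates in two periods."""

    per_lake: pd.DataFrame  # columns: lake, rate_a, rate_b
    median_rate_a: float
    median_rate_b: float
    t_statistic: Optional[float]
    p_value: Optional[float]
    n_lakes: int
    #: Optional contrast: lakes split by period-A mean frequency; period-B
    #: rates of the high-frequency half vs the low-frequency half.
    split: Optional[dict] = None


def eligible_lakes(annual: pd.DataFrame) -> set[str]:
    """Lakes with blooms in at least half of their observed years.

    ``annual`` holds one row per lake-year with columns ``lake``,
    ``bloom_year``, ``annual_frequency`` (NaN when no bloom that year) and
    ``n_observations``.  A year counts as observed when it has at least one
    valid observation; it counts as a bloom year when ``annual_frequency``
    is defined.  With 20 observed years the cutoff is 10 bloom years.
    """
    if annual.empty:
        return set()
    out: set[str] = set()
    for lake, grp in annual.groupby("lake"):
        observed = int((grp["n_observations"] > 0).sum())
        bloom_years = int(grp["annual_frequency"].notna().sum())
        if observed > 0 and bloom_years >= observed / 2 and bloom_years > 0:
            out.add(str(lake))
    return out


def lake_trend(
    years,
    values,
    *,
    lake_id: str = "lake",
    metric: str = "frequency",
    alpha: float = DEFAULT_ALPHA,
) -> Optional[TrendResult]:
    """OLS trend of annual values on year with a four-way classification.

    Returns None for fewer than 3 pairs.  Zero variance in ``years`` is a
    hard error.  A slope of exactly zero (e.g. constant values) falls in
    the non-significant increase class by the tie rule.
    """
    years = np.asarray(years, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(years) & np.isfinite(values)
    years, values = years[keep], values[keep]
    if len(years) < 3:
        return None
    if np.ptp(years) == 0:
        raise ValueError("years have zero variance; cannot fit a trend")
    res = stats.linregress(years, values)
    slope = float(res.slope)
    p = float(res.pvalue)
    if not np.isfinite(p):  # constant values: no evidence of any trend
        p = 1.0
    if slope >= 0:
        cls = "Sig. Inc." if p < alpha else "Inc."
    else:
        cls = "Sig. Dec." if p < alpha else "Dec."
    return TrendResult(lake_id, metric, slope, p, int(len(years)), cls)


def global_median_series(annual: pd.DataFrame) -> pd.Series:
    """Per-year median annual frequency across lakes with a defined value."""
    df = annual.dropna(subset=["annual_frequency"])
    if df.empty:
        return pd.Series(dtype=float)
    return df.groupby("bloom_year")["annual_frequency"].median().sort_index()


def global_relative_rate(medians: pd.Series) -> RelativeRate:
    """Relative growth rate of the global median series, %/yr.

    Convention: OLS slope divided by the long-term mean of the series,
    times 100.  Scale-invariant by construction.  Raises ``ValueError``
    for fewer than 3 years or a zero mean.
    """
    medians = medians.dropna().sort_index()
    if len(medians) < 3:
        raise ValueError("need at least 3 yearly medians")
    mean = float(medians.mean())
    if mean == 0:
        raise ValueError("relative rate undefined: series mean is zero")
    res = stats.linregress(medians.index.values.astype(float), medians.values)
    p = float(res.pvalue)
    if not np.isfinite(p):
        p = 1.0
    return RelativeRate(
        rate_pct_per_yr=float(res.slope) / mean * 100.0,
        slope=float(res.slope),
        p_value=p,
        mean=mean,
        n_years=int(len(medians)),
    )


def _period_rate(grp: pd.DataFrame, lo: int, hi: int, min_years: int):
    sel = grp[(grp["bloom_year"] >= lo) & (grp["bloom_year"] <= hi)].dropna(
        subset=["annual_frequency"]
    )
    if len(sel) < min_years:
        return None, None
    mean = float(sel["annual_frequency"].mean())
    if mean == 0:
        return None, None
    res = stats.linregress(
        sel["bloom_year"].values.astype(float), sel["annual_frequency"].values
    )
    return float(res.slope) / mean * 100.0, mean


def period_comparison(
    annual: pd.DataFrame,
    period_a: tuple[int, int] = DEFAULT_PERIOD_A,
    period_b: tuple[int, int] = DEFAULT_PERIOD_B,
    *,
    min_years: int = 3,
) -> Optional[PeriodComparison]:
    """Compare per-lake relative growth rates between two periods.

    Each qualifying lake (>= ``min_years`` annual values in each period)
    contributes one (rate_a, rate_b) pair; the matched-pair t-test runs
    across lakes.  With fewer than 2 qualifying lakes the t-test is refused
    (statistics set to None); with no qualifying lake the whole comparison
    returns None.  The ``split`` field contrasts period-B rates between
    lakes above and below the median period-A mean frequency.
    """
    rows = []
    for lake, grp in annual.groupby("lake"):
        rate_a, mean_a = _period_rate(grp, *period_a, min_years)
        rate_b, _ = _period_rate(grp, *period_b, min_years)
        if rate_a is None or rate_b is None:
            continue
        rows.append({"lake": lake, "rate_a": rate_a, "rate_b": rate_b,
                     "mean_freq_a": mean_a})
    if not rows:
        return None
    per_lake = pd.DataFrame(rows)
    t_stat = p_val = None
    if len(per_lake) >= 2:
        t, p = stats.ttest_rel(per_lake["rate_b"], per_lake["rate_a"])
        if np.isfinite(t):
            t_stat, p_val = float(t), float(p)
        else:  # all paired differences identical (e.g. all zero)
            t_stat, p_val = 0.0, 1.0

    split = None
    if len(per_lake) >= 4:
        cutoff = per_lake["mean_freq_a"].median()
        hi = per_lake[per_lake["mean_freq_a"] > cutoff]["rate_b"]
        lo = per_lake[per_lake["mean_freq_a"] <= cutoff]["rate_b"]
        if len(hi) >= 2 and len(lo) >= 2:
            t, p = stats.ttest_ind(hi, lo, equal_var=False)
            split = {
                "median_rate_b_high_freq": float(hi.median()),
                "median_rate_b_low_freq": float(lo.median()),
                "t_statistic": float(t) if np.isfinite(t) else 0.0,
                "p_value": float(p) if np.isfinite(p) else 1.0,
                "n_high": int(len(hi)),
                "n_low": int(len(lo)),
            }
    return PeriodComparison(
        per_lake=per_lake,
        median_rate_a=float(per_lake["rate_a"].median()),
        median_rate_b=float(per_lake["rate_b"].median()),
        t_statistic=t_stat,
        p_value=p_val,
        n_lakes=int(len(per_lake)),
        split=split,
    )
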