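"""Correlation of bloom frequency with candidate drivers and best-factor
attribution.

Daily meteorological drivers (air temperature, precipitation, wind speed)
are correlated against same-day bloom frequency over days with at least
one valid observation.  Nutrient drivers (annual N and P fertilizer usage
and ten anthropogenic-N input categories plus their subset sums) are
correlated against annual bloom frequency over the overlapping years.
Each lake is then labelled with the factor holding the highest significant
(p < alpha) absolute correlation, or "others" when none qualifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MET_COLUMNS",
    "N_CATEGORIES",
    "N_SUBSETS",
    "FACTOR_ORDER",
    "DriverAttribution",
    "ThresholdStats",
    "daily_driver_correlation",
    "annual_nutrient_correlation",
    "assign_best_factor",
    "temperature_threshold_stats",
]

#: Canonical column names of a daily meteorological table.
MET_COLUMNS = ("date", "air_temperature", "wind_speed", "precipitation")

#: The ten anthropogenic-N input categories, in canonical order
#: (i .. x): NH4/NO3 fertilizer on cropland and pasture, manure applied to
#: cropland/pasture, manure deposited on pasture/rangeland, NHx and NOy
#: atmospheric deposition.
N_CATEGORIES = (
    "nh4_fertilizer_cropland",      # i
    "no3_fertilizer_cropland",      # ii
    "nh4_fertilizer_pasture",       # iii
    "no3_fertilizer_pasture",       # iv
    "manure_applied_cropland",      # v
    "manure_applied_pasture",       # vi
    "manure_deposited_pasture",     # vii
    "manure_deposited_rangeland",   # viii
    "nhx_deposition",               # ix
    "noy_deposition",               # x
)

#: Subset aggregations of the ten categories (by canonical index).
N_SUBSETS: dict[str, tuple[int, ...]] = {
    "fertilizer_n_input": (0, 1, 2, 3),
    "manure_n_input": (4, 5, 6, 7),
    "atmospheric_n_input": (8, 9),
    "cropland_n_input": (0, 1, 4),
    "pasture_n_input": (2, 3, 5, 6),
}

#: Fixed tie-breaking order for best-factor assignment.
FACTOR_ORDER = (
    "temperature",
    "precipitation",
    "wind",
    "fertilizer_N",
    "fertilizer_P",
)

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class DriverAttribution:
    """Per-lake correlation table and the winning factor label."""

    lake_id: str
    factors: Mapping[str, Optional[tuple[float, float]]]
    best_factor: str


@dataclass(frozen=True)
class ThresholdStats:
    """Fractions of bloom events above / below air-temperature thresholds."""

    frac_above_upper: float
    frac_at_or_below_lower: float
    upper_c: float
    lower_c: float
    n_events: int


def _pearson(x: np.ndarray, y: np.ndarray) -> Optional[tuple[float, float]]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = stats.pearsonr(x, y)
    if not np.isfinite(r):
        return None
    return float(r), float(p)


def _spearman(x: np.ndarray, y: np.ndarray) -> Optional[tuple[float, float]]:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r, p = stats.spearmanr(x, y)
    if not np.isfinite(r):
        return None
    return float(r), float(p)


def daily_driver_correlation(
    daily: pd.DataFrame,
    met: pd.DataFrame,
    *,
    min_days: int = 10,
    lag_days: int = 0,
    method: str = "pearson",
) -> dict[str, Optional[tuple[float, float]]]:
    """Correlate same-day bloom frequency with daily meteorology.

    ``daily`` needs columns ``date``, ``frequency`` and ``A_valid``; days
    with ``A_valid == 0`` carry no bloom information and are dropped (not
    treated as zero frequency).  ``met`` follows :data:`MET_COLUMNS`.  A
    positive ``lag_days`` correlates frequency with meteorology from
    ``lag_days`` earlier.  Factors with zero variance are returned as None
    (incomputable).
    """
    corr = _pearson if method == "pearson" else _spearman
    d = daily[daily["A_valid"] > 0][["date", "frequency"]].copy()
    d["date"] = pd.to_datetime(d["date"])
    m = met.copy()
    m["date"] = pd.to_datetime(m["date"]) + pd.Timedelta(days=lag_days)
    merged = d.merge(m, on="date", how="inner").dropna()
    if len(merged) < min_days:
        raise ValueError(
            f"need >= {min_days} matched observed days, got {len(merged)}"
        )
    freq = merged["frequency"].to_numpy()
    return {
        "temperature": corr(merged["air_temperature"].to_numpy(), freq),
        "precipitation": corr(merged["precipitation"].to_numpy(), freq),
        "wind": corr(merged["wind_speed"].to_numpy(), freq),
    }


def annual_nutrient_correlation(
    annual_frequency: pd.Series,
    nutrients: pd.DataFrame,
    *,
    min_years: int = 5,
    method: str = "pearson",
) -> Optional[dict[str, Optional[tuple[float, float]]]]:
    """Correlate annual bloom frequency with nutrient quantities.

    ``annual_frequency`` is indexed by year.  ``nutrients`` holds one row
    per year with ``year``, ``fertilizer_N``, ``fertilizer_P``, the ten
    :data:`N_CATEGORIES` columns and optionally ``total_n_input``.  Total N
    is verified to equal the category sum (conservation gate) before any
    correlation.  Returns None when fewer than ``min_years`` overlapping
    years exist; flat series come back as None entries.
    """
    corr = _pearson if method == "pearson" else _spearman
    nut = nutrients.set_index("year")
    cat = nut[list(N_CATEGORIES)]
    total = cat.sum(axis=1)
    if "total_n_input" in nut.columns and not np.allclose(
        nut["total_n_input"].to_numpy(), total.to_numpy(), rtol=1e-9, atol=1e-9
    ):
        raise ValueError("total_n_input does not equal the sum of the 10 "
                         "N input categories")
    years = annual_frequency.dropna().index.intersection(nut.index)
    if len(years) < min_years:
        return None
    freq = annual_frequency.loc[years].to_numpy(dtype=float)

    out: dict[str, Optional[tuple[float, float]]] = {}
    out["fertilizer_N"] = corr(nut.loc[years, "fertilizer_N"].to_numpy(), freq)
    out["fertilizer_P"] = corr(nut.loc[years, "fertilizer_P"].to_numpy(), freq)
    out["total_n_input"] = corr(total.loc[years].to_numpy(), freq)
    for name, idxs in N_SUBSETS.items():
        subset = cat.iloc[:, list(idxs)].sum(axis=1)
        out[name] = corr(subset.loc[years].to_numpy(), freq)
    return out


def assign_best_factor(
    lake_id: str,
    factors: Mapping[str, Optional[tuple[float, float]]],
    *,
    alpha: float = DEFAULT_ALPHA,
    order: Sequence[str] = FACTOR_ORDER,
) -> DriverAttribution:
    """Label a lake with its best-explaining factor.

    Among factors with p < ``alpha``, the one with maximal \\|r\\| wins;
    ties break by the fixed ``order``.  When no factor is significant (or
    all are incomputable) the label is ``"others"``.
    """
    best = "others"
    best_abs_r = -1.0
    for name in order:
        rp = factors.get(name)
        if rp is None:
            continue
        r, p = rp
        if p < alpha and abs(r) > best_abs_r:
            best = name
            best_abs_r = abs(r)
    return DriverAttribution(lake_id, dict(factors), best)


def temperature_threshold_stats(
    temperatures,
    *,
    upper_c: float = 20.0,
    lower_c: float = 16.0,
) -> Optional[ThresholdStats]:
    """Fractions of bloom events warmer than ``upper_c`` / at or below
    ``lower_c``.

    ``temperatures`` are the same-day air temperatures of every bloom event
    (lake-day with detected bloom area).  The two fractions need not sum
    to 1.  Returns None for an empty event set.
    """
    t = np.asarray(list(temperatures), dtype=float)
    if t.size == 0:
        return None
    return ThresholdStats(
        frac_above_upper=float(np.mean(t > upper_c)),
        frac_at_or_below_lower=float(np.mean(t <= lower_c)),
        upper_c=upper_c,
        lower_c=lower_c,
        n_events=int(t.size),
    )
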