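"""Synthetic lakes, scenes, meteorology and nutrients with known truth.

Everything downstream (detection, metrics, trends, drivers) is exercised
against scenes generated here, where the true bloom mask, the true bloom
season, the true frequency trend and the true driving factor are known by
construction.

Generative model, in brief:

* Lake rasters are square grids, fully water, with a low water-presence
  fringe strip emulating floating-leaved vegetation zones.
* Daily air temperature is a sinusoidal seasonal cycle (phase-shifted six
  months in the Southern Hemisphere) plus an optional linear warming trend
  and Gaussian noise; wind and precipitation are independent positive
  noise series.
* Each day a bloom occurs with probability given either by a logistic
  model in air temperature (plus a per-lake linear year trend on the logit
  scale) or, for designed-season experiments, a fixed in-season
  probability.  Bloom days get a connected patch of pixels whose spectra
  have positive nFAI and green chromaticity; open water has negative nFAI;
  cloud pixels are white and invalid; iced days are entirely invalid.
* Annual nutrient series are smooth trends plus noise across ten
  anthropogenic-N input categories (plus N and P fertilizer totals).

Randomness derives from per-lake, per-purpose child streams of the master
seed, so any lake can be regenerated independently and the whole artifact
is byte-reproducible for a fixed config.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .detection import BANDS_NM, LakeGeometry
from .drivers import N_CATEGORIES

__all__ = [
    "BloomModel",
    "SimulationConfig",
    "SceneStack",
    "GroundTruth",
    "generate_lake_geometry",
    "generate_met_series",
    "generate_scene_series",
    "generate_nutrient_series",
]

# Reference spectra (reflectance per band 443/555/645/859/1240 nm), chosen
# to sit firmly on the detector's decision variables rather than to be
# radiometrically realistic: water has negative FAI and bluish chromaticity,
# bloom has strongly positive nFAI and green chromaticity, cloud and ice are
# bright and white.
WATER_SPECTRUM = np.array([0.060, 0.050, 0.040, 0.020, 0.010])
BLOOM_SPECTRUM = np.array([0.020, 0.120, 0.050, 0.150, 0.030])
CLOUD_SPECTRUM = np.array([0.300, 0.300, 0.300, 0.300, 0.300])
ICE_SPECTRUM = np.array([0.400, 0.400, 0.400, 0.350, 0.300])


@dataclass(frozen=True)
class BloomModel:
    """Daily bloom-occurrence model.

    With ``season`` unset the per-day bloom probability is
    ``expit(intercept + temp_coef * T + year_trend * year_index)``.  With
    ``season = (d1, d2)`` (1-based days within the lake's bloom-year
    window) the probability is ``p_in_season`` inside the span and
    ``p_off_season`` outside, ignoring temperature — the designed-season
    mode used by phenology-recovery experiments.
    """

    intercept: float = -8.0
    temp_coef: float = 0.35
    year_trend: float = 0.0
    season: Optional[tuple[int, int]] = None
    p_in_season: float = 0.9
    p_off_season: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    n_lakes: int = 20
    year_start: int = 2003
    year_end: int = 2022
    grid_size: int = 16
    bloom_model: BloomModel = field(default_factory=BloomModel)
    #: Mean per-day fraction of pixels censored by cloud.  The realized
    #: fraction is drawn each day from Uniform(0, 2*cloud_prob) clipped to
    #: [0, 1], then applied as i.i.d. per-pixel Bernoulli censoring.
    cloud_prob: float = 0.2
    #: Fraction of lakes given a winter ice season (Northern lakes first).
    ice_fraction: float = 0.25
    #: Fraction of lakes in the Southern Hemisphere (lowest indices).
    southern_fraction: float = 0.25
    #: NH freeze/melt days of year; mirrored by ~6 months for SH ice lakes.
    freeze_doy: int = 330
    melt_doy: int = 120
    fringe_width: int = 2
    pixel_area_km2: float = 1.0
    temp_mean_c: float = 12.0
    temp_amplitude_c: float = 12.0
    warming_trend_c_per_yr: float = 0.0
    temp_noise_sd: float = 1.5
    reflectance_noise_sd: float = 0.0
    max_patch_radius: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")
        if self.year_end - self.year_start + 1 < 2:
            raise ValueError("the year range must span at least 2 years")
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ValueError("cloud_prob must be in [0, 1]")
        if self.n_lakes < 1:
            raise ValueError("n_lakes must be >= 1")

    @property
    def n_years(self) -> int:
        return self.year_end - self.year_start + 1

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(
            dt.date(self.year_start, 1, 1), dt.date(self.year_end, 12, 31), freq="D"
        )


@dataclass
class SceneStack:
    """All scenes of one lake as dense arrays: reflectance ``(day, band,
    y, x)`` and validity ``(day, y, x)``."""

    dates: pd.DatetimeIndex
    reflectance: np.ndarray
    valid: np.ndarray
    bands: tuple[int, ...] = BANDS_NM

    def scene(self, i: int):
        from .detection import Scene

        return Scene(
            date=self.dates[i].date(),
            reflectance=self.reflectance[i],
            valid_mask=self.valid[i],
            bands=self.bands,
        )

    def __len__(self) -> int:
        return len(self.dates)


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring the pipeline against.

    ``true_bloom`` keeps the bloom label even on pixels later censored by
    cloud (detection cannot see those; scoring can).
    """

    dates: pd.DatetimeIndex
    true_bloom: np.ndarray  # (day, y, x) bool
    bloom_probability: np.ndarray  # (day,)
    true_driver: str
    true_year_trend: float

    def true_daily_areas(self, geometry: LakeGeometry) -> pd.DataFrame:
        """True per-day bloom area (km2) regardless of cloud censoring."""
        px = geometry.pixel_area_km2
        return pd.DataFrame(
            {
                "date": self.dates,
                "A_Bloom": self.true_bloom.sum(axis=(1, 2)) * px,
                "A_Lake": geometry.area_km2,
            }
        )


def _lake_rng(config: SimulationConfig, lake_index: int, purpose: int):
    """Independent child stream per (lake, purpose); regenerating one
    artifact never perturbs another."""
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, lake_index, purpose])
    )


def _hemisphere(config: SimulationConfig, lake_index: int) -> str:
    n_south = int(round(config.southern_fraction * config.n_lakes))
    return "S" if lake_index < n_south else "N"


def _is_frozen(config: SimulationConfig, lake_index: int) -> bool:
    n_south = int(round(config.southern_fraction * config.n_lakes))
    n_ice = int(round(config.ice_fraction * config.n_lakes))
    return n_south <= lake_index < n_south + n_ice


def generate_lake_geometry(
    config: SimulationConfig, lake_index: int
) -> LakeGeometry:
    """Build one lake's static geometry.

    The mask covers the full grid (trivially connected); the water-presence
    raster is 0.95 over open water and 0.30 on a fringe strip of
    ``fringe_width`` pixels along the border, emulating floating-leaved
    vegetation zones that detection must exclude.
    """
    if lake_index >= config.n_lakes:
        raise ValueError("lake_index out of range")
    n = config.grid_size
    if n * n < 25:
        raise ValueError(
            f"grid of {n}x{n} yields a lake mask of {n * n} < 25 pixels"
        )
    mask = np.ones((n, n), dtype=bool)
    wp = np.full((n, n), 0.95)
    w = config.fringe_width
    if w > 0:
        fringe = np.zeros((n, n), dtype=bool)
        fringe[:w, :] = fringe[-w:, :] = True
        fringe[:, :w] = fringe[:, -w:] = True
        wp[fringe] = 0.30
    hemi = _hemisphere(config, lake_index)
    frozen = _is_frozen(config, lake_index)
    ice = None
    if frozen:
        if hemi == "N":
            ice = (config.freeze_doy, config.melt_doy)
        else:  # shift the ice season by ~6 months for the austral winter
            ice = (
                (config.freeze_doy + 182 - 1) % 365 + 1,
                (config.melt_doy + 182 - 1) % 365 + 1,
            )
    return LakeGeometry(
        lake_id=f"lake{lake_index:04d}",
        lake_mask=mask,
        area_km2=float(mask.sum()) * config.pixel_area_km2,
        water_presence=wp,
        hemisphere=hemi,
        ice_cover=ice,
        frozen=frozen,
    )


def generate_met_series(config: SimulationConfig, lake_index: int) -> pd.DataFrame:
    """Daily meteorology for one lake (columns per drivers.MET_COLUMNS).

    Temperature: sinusoid peaking near day 200 (shifted six months for
    Southern lakes) plus the configured linear warming trend and Gaussian
    noise.  Wind is gamma-distributed, precipitation an exponential amount
    on ~40% wet days; both strictly non-negative and independent of
    everything else.
    """
    rng = _lake_rng(config, lake_index, 1)
    dates = config.dates()
    doy = dates.dayofyear.to_numpy(dtype=float)
    years = dates.year.to_numpy(dtype=float) - config.year_start
    peak = 200.0 if _hemisphere(config, lake_index) == "N" else 200.0 - 182.5
    temp = (
        config.temp_mean_c
        + config.temp_amplitude_c * np.cos(2 * np.pi * (doy - peak) / 365.25)
        + config.warming_trend_c_per_yr * years
        + rng.normal(0.0, config.temp_noise_sd, size=len(dates))
    )
    wind = rng.gamma(shape=2.0, scale=1.5, size=len(dates))
    wet = rng.random(len(dates)) < 0.4
    precip = np.where(wet, rng.exponential(4.0, size=len(dates)), 0.0)
    return pd.DataFrame(
        {
            "date": dates,
            "air_temperature": temp,
            "wind_speed": wind,
            "precipitation": precip,
        }
    )


def _window_day_numbers(
    dates: pd.DatetimeIndex, geometry: LakeGeometry
) -> np.ndarray:
    """1-based day position of each date inside its bloom-year window,
    matching metrics.bloom_year_window labelling (calendar DOY for
    Northern/frozen-NH lakes, days since Jul 1 for shifted SH windows)."""
    if geometry.hemisphere == "N" or geometry.frozen:
        return dates.dayofyear.to_numpy()
    # non-frozen SH: window starts Jul 1
    starts = np.where(
        dates.month >= 7,
        pd.to_datetime({"year": dates.year, "month": 7, "day": 1}),
        pd.to_datetime({"year": dates.year - 1, "month": 7, "day": 1}),
    )
    return (dates.to_numpy() - starts).astype("timedelta64[D]").astype(int) + 1


def _disk_patch(
    center: tuple[int, int], radius: int, allowed: np.ndarray
) -> np.ndarray:
    ny, nx = allowed.shape
    yy, xx = np.ogrid[:ny, :nx]
    disk = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
    return disk & allowed


def generate_scene_series(
    geometry: LakeGeometry,
    met: pd.DataFrame,
    config: SimulationConfig,
    lake_index: int = 0,
) -> tuple[SceneStack, GroundTruth]:
    """Simulate every daily scene of one lake plus its ground truth.

    Requires ``met`` to cover every simulated day (hard error otherwise).
    Bloom patches are connected disks placed in the high water-presence
    interior; clouds censor pixels i.i.d. at a per-day drawn fraction; iced
    days are fully invalid.  Cloud/ice pixels never expose a bloom spectrum
    to detection, but the true bloom label is retained in the truth.
    """
    from scipy.special import expit

    rng = _lake_rng(config, lake_index, 2)
    dates = config.dates()
    met_idx = pd.DatetimeIndex(pd.to_datetime(met["date"]))
    if not dates.isin(met_idx).all():
        raise ValueError("met series does not cover every simulated day")
    temp = (
        met.set_index(met_idx)["air_temperature"].reindex(dates).to_numpy()
    )

    n_days = len(dates)
    ny = nx = config.grid_size
    model = config.bloom_model
    years = dates.year.to_numpy() - config.year_start

    if model.season is not None:
        d1, d2 = model.season
        wday = _window_day_numbers(dates, geometry)
        prob = np.where(
            (wday >= d1) & (wday <= d2), model.p_in_season, model.p_off_season
        )
    else:
        logit = model.intercept + model.temp_coef * temp + model.year_trend * years
        prob = expit(logit)

    iced = np.array([geometry.is_iced(d.date()) for d in dates])
    bloom_day = (rng.random(n_days) < prob) & ~iced

    interior = geometry.lake_mask & (geometry.water_presence >= 0.9)
    interior_coords = np.argwhere(interior)
    max_r = config.max_patch_radius or max(2, config.grid_size // 4)

    true_bloom = np.zeros((n_days, ny, nx), dtype=bool)
    for d in np.flatnonzero(bloom_day):
        center = interior_coords[rng.integers(len(interior_coords))]
        radius = int(rng.integers(1, max_r + 1))
        patch = _disk_patch((center[0], center[1]), radius, interior)
        if not patch.any():  # pragma: no cover - interior centers always hit
            patch = np.zeros((ny, nx), dtype=bool)
            patch[center[0], center[1]] = True
        true_bloom[d] = patch

    refl = np.empty((n_days, len(BANDS_NM), ny, nx), dtype=np.float32)
    refl[:] = WATER_SPECTRUM[None, :, None, None]
    refl_px = refl.transpose(0, 2, 3, 1)  # (day, y, x, band) view
    refl_px[true_bloom] = BLOOM_SPECTRUM
    if config.reflectance_noise_sd > 0:
        refl += rng.normal(
            0.0, config.reflectance_noise_sd, size=refl.shape
        ).astype(np.float32)

    # cloud censoring: per-day fraction draw, then i.i.d. per-pixel Bernoulli
    if config.cloud_prob > 0:
        frac = np.clip(
            rng.uniform(0.0, 2.0 * config.cloud_prob, size=n_days), 0.0, 1.0
        )
        cloud = rng.random((n_days, ny, nx)) < frac[:, None, None]
    else:
        cloud = np.zeros((n_days, ny, nx), dtype=bool)
    refl_px[cloud] = CLOUD_SPECTRUM

    valid = ~cloud
    if iced.any():
        refl[iced] = ICE_SPECTRUM[None, :, None, None].astype(np.float32)
        valid[iced] = False

    stack = SceneStack(dates=dates, reflectance=refl, valid=valid)
    truth = GroundTruth(
        dates=dates,
        true_bloom=true_bloom,
        bloom_probability=prob,
        true_driver=(
            "season"
            if model.season is not None
            else ("temperature" if model.temp_coef != 0 else "none")
        ),
        true_year_trend=model.year_trend,
    )
    return stack, truth


def generate_nutrient_series(
    config: SimulationConfig, lake_index: int
) -> pd.DataFrame:
    """Annual nutrient series for one lake.

    Ten non-negative N-input categories, each a smooth linear trend plus
    noise, together with N and P fertilizer totals; ``total_n_input`` is
    the exact sum of the ten categories (conservation by construction).
    """
    rng = _lake_rng(config, lake_index, 3)
    years = np.arange(config.year_start, config.year_end + 1)
    t = years - config.year_start
    data: dict[str, np.ndarray] = {"year": years}
    cats = []
    for name in N_CATEGORIES:
        base = rng.uniform(0.5, 5.0)
        slope = rng.normal(0.0, 0.05)
        series = np.maximum(
            0.0, base + slope * t + rng.normal(0.0, 0.1, size=len(t))
        )
        data[name] = series
        cats.append(series)
    data["total_n_input"] = np.sum(cats, axis=0)
    data["fertilizer_N"] = np.maximum(
        0.0,
        rng.uniform(5, 50) + rng.normal(0, 0.3) * t + rng.normal(0, 1.0, len(t)),
    )
    data["fertilizer_P"] = np.maximum(
        0.0,
        rng.uniform(1, 10) + rng.normal(0, 0.1) * t + rng.normal(0, 0.3, len(t)),
    )
    return pd.DataFrame(data)
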