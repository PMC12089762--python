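"""Per-scene algal bloom classification from multi-band lake reflectance.

A daily :class:`Scene` carries Rayleigh-corrected-style reflectance in five
bands (443, 555, 645, 859 and 1240 nm) plus a validity mask.  A pixel is
flagged as bloom when all of the following hold:

1. it is a valid (observed, cloud/ice-free) pixel inside the lake mask,
2. its normalized floating-algae index (nFAI) exceeds a threshold,
3. its CIE (x, y) chromaticity falls inside a configurable green region
   (screens out clouds, shadows and other non-green features), and
4. its historical open-water presence probability is high enough (screens
   out floating-leaved vegetation fringes).

The floating-algae index is the excess of near-infrared reflectance over a
linear baseline between the red (645 nm) and shortwave-infrared (1240 nm)
bands; nFAI divides it by the 555+645+859 nm brightness so that the sign is
preserved while bright and dark targets become comparable.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from matplotlib.path import Path as _MplPath

__all__ = [
    "BANDS_NM",
    "Scene",
    "LakeGeometry",
    "DetectionParams",
    "BloomMask",
    "ExcludedLakeError",
    "MissingBandError",
    "fai_index",
    "nfai_index",
    "compute_nfai",
    "chromaticity",
    "in_green_region",
    "detect_bloom",
    "detect_stack",
]

#: Nominal band centres, nm, in storage order.
BANDS_NM: tuple[int, ...] = (443, 555, 645, 859, 1240)

#: Linear sRGB -> XYZ (D65) matrix, applied to (R645, R555, R443) as (R, G, B).
RGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

#: Default green chromaticity polygon: the region x < 0.35, y > 0.35, y > x
#: clipped to the chromaticity simplex, as (x, y) vertices.
DEFAULT_GREEN_REGION: tuple[tuple[float, float], ...] = (
    (0.0, 0.35),
    (0.35, 0.35),
    (0.35, 0.65),
    (0.0, 1.0),
)


class ExcludedLakeError(ValueError):
    """Raised when detection is requested on a lake flagged for exclusion."""


class MissingBandError(ValueError):
    """Raised when a scene lacks a band required by an index."""


@dataclass
class Scene:
    """One lake-day of multi-band reflectance.

    Parameters
    ----------
    date
        Calendar day of the observation.
    reflectance
        Array of shape ``(n_bands, ny, nx)`` with dimensionless reflectance.
    valid_mask
        Boolean array of shape ``(ny, nx)``; True where the pixel was
        observed and is cloud/ice-free.
    bands
        Band centres in nm matching the leading axis of ``reflectance``.
    """

    date: dt.date
    reflectance: np.ndarray
    valid_mask: np.ndarray
    bands: tuple[int, ...] = BANDS_NM

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.reflectance.ndim != 3:
            raise ValueError("reflectance must be (band, y, x)")
        if self.reflectance.shape[0] != len(self.bands):
            raise ValueError(
                f"reflectance has {self.reflectance.shape[0]} bands, "
                f"expected {len(self.bands)}"
            )
        if self.valid_mask.shape != self.reflectance.shape[1:]:
            raise ValueError("valid_mask shape does not match reflectance grid")
        if not np.all(np.isfinite(self.reflectance[:, self.valid_mask])):
            raise ValueError("reflectance must be finite on valid pixels")

    def band(self, nm: int) -> np.ndarray:
        """Return the reflectance plane for the band centred at ``nm``."""
        try:
            idx = self.bands.index(nm)
        except ValueError:
            raise MissingBandError(f"scene is missing the {nm} nm band") from None
        return self.reflectance[idx]


@dataclass
class LakeGeometry:
    """Static per-lake descriptors conditioning every pipeline stage.

    ``ice_cover`` is a ``(freeze_doy, melt_doy)`` pair of 1-based days of
    year.  The ice-free season runs cyclically from melt to freeze, so a
    Southern-Hemisphere lake freezing mid-year is expressed with
    ``freeze < melt``.
    """

    lake_id: str
    lake_mask: np.ndarray
    area_km2: float
    water_presence: np.ndarray
    hemisphere: str = "N"
    ice_cover: Optional[tuple[int, int]] = None
    frozen: bool = False
    include: bool = True

    def __post_init__(self) -> None:
        self.lake_mask = np.asarray(self.lake_mask, dtype=bool)
        self.water_presence = np.asarray(self.water_presence, dtype=float)
        if self.area_km2 <= 0:
            raise ValueError("area_km2 must be positive")
        if self.hemisphere not in ("N", "S"):
            raise ValueError("hemisphere must be 'N' or 'S'")
        if self.water_presence.shape != self.lake_mask.shape:
            raise ValueError("water_presence shape does not match lake_mask")
        wp = self.water_presence[self.lake_mask]
        if wp.size and (wp.min() < 0 or wp.max() > 1):
            raise ValueError("water_presence must lie in [0, 1]")
        if self.frozen and self.ice_cover is None:
            raise ValueError("frozen lake requires ice_cover dates")
        if self.ice_cover is not None:
            freeze, melt = self.ice_cover
            if freeze == melt:
                raise ValueError("ice_cover freeze and melt days must differ")

    @property
    def pixel_area_km2(self) -> float:
        """Uniform pixel area implied by lake area and mask pixel count."""
        n = int(self.lake_mask.sum())
        if n == 0:
            raise ValueError("lake_mask is empty")
        return self.area_km2 / n

    def is_iced(self, date: dt.date) -> bool:
        """True when ``date`` falls inside the lake's ice-cover season."""
        if not self.frozen or self.ice_cover is None:
            return False
        freeze, melt = self.ice_cover
        doy = date.timetuple().tm_yday
        if melt <= freeze:  # ice-free season within one calendar year (NH)
            return not (melt <= doy <= freeze)
        # ice-free season wraps the new year (austral summer)
        return not (doy >= melt or doy <= freeze)


@dataclass
class DetectionParams:
    """Thresholds and regions for the per-pixel bloom classifier."""

    nfai_threshold: float = 0.02
    green_region: Sequence[tuple[float, float]] = DEFAULT_GREEN_REGION
    water_presence_min: float = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.water_presence_min <= 1.0:
            raise ValueError("water_presence_min must be in [0, 1]")
        verts = np.asarray(self.green_region, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise ValueError("green_region must be a polygon of (x, y) vertices")
        self._green_path = _MplPath(verts)


@dataclass
class BloomMask:
    """Per-scene detection result: pixel flags and Eq-style areas."""

    bloom: np.ndarray
    bloom_area_km2: float
    valid_area_km2: float
    lake_area_km2: float

    def __post_init__(self) -> None:
        if not (
            -1e-9 <= self.bloom_area_km2
            <= self.valid_area_km2 + 1e-9
            <= self.lake_area_km2 + 2e-9
        ):
            raise ValueError("areas must satisfy 0 <= A_Bloom <= A_valid <= A_Lake")


def fai_index(
    r645: np.ndarray, r859: np.ndarray, r1240: np.ndarray
) -> np.ndarray:
    """Floating-algae index: NIR excess over the 645-1240 nm linear baseline."""
    w = (859.0 - 645.0) / (1240.0 - 645.0)
    baseline = r645 + (r1240 - r645) * w
    return np.asarray(r859, dtype=float) - baseline


def nfai_index(
    r555: np.ndarray, r645: np.ndarray, r859: np.ndarray, r1240: np.ndarray
) -> np.ndarray:
    """Normalized FAI: FAI divided by the 555+645+859 nm brightness.

    The denominator is strictly positive over water/bloom targets, so the
    normalization preserves the sign of FAI.  Pixels with non-positive
    brightness yield NaN.
    """
    fai = fai_index(r645, r859, r1240)
    denom = np.asarray(r555, dtype=float) + r645 + r859
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, fai / np.where(denom > 0, denom, 1.0), np.nan)
    return out


def compute_nfai(scene: Scene) -> np.ndarray:
    """Per-pixel nFAI for a scene; raises :class:`MissingBandError` if a
    required band (555, 645, 859 or 1240 nm) is absent."""
    return nfai_index(
        scene.band(555), scene.band(645), scene.band(859), scene.band(1240)
    )


def chromaticity(scene: Scene) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel CIE (x, y) chromaticity from the 645/555/443 nm bands.

    The (R, G, B) triple (R645, R555, R443) is mapped to XYZ tristimulus
    values with the linear sRGB D65 matrix and normalized.  Pixels with
    X+Y+Z == 0 are unclassifiable and returned as NaN (treated downstream
    as non-green).
    """
    return _chromaticity_from_rgb(scene.band(645), scene.band(555), scene.band(443))


def _chromaticity_from_rgb(
    r: np.ndarray, g: np.ndarray, b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    rgb = np.stack([np.asarray(r, float), np.asarray(g, float), np.asarray(b, float)])
    xyz = np.tensordot(RGB_TO_XYZ, rgb, axes=(1, 0))
    total = xyz.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(total != 0, xyz[0] / np.where(total != 0, total, 1.0), np.nan)
        y = np.where(total != 0, xyz[1] / np.where(total != 0, total, 1.0), np.nan)
    return x, y


def in_green_region(
    x: np.ndarray, y: np.ndarray, params: DetectionParams
) -> np.ndarray:
    """Boolean mask of chromaticity points inside the green polygon.

    NaN (unclassifiable) points are never green.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pts = np.column_stack([x.ravel(), y.ravel()])
    ok = np.isfinite(pts).all(axis=1)
    inside = np.zeros(len(pts), dtype=bool)
    if ok.any():
        inside[ok] = params._green_path.contains_points(pts[ok])
    return inside.reshape(x.shape)


def detect_bloom(
    scene: Scene, geometry: LakeGeometry, params: DetectionParams
) -> BloomMask:
    """Classify a scene's valid lake pixels as bloom / non-bloom.

    Returns a :class:`BloomMask` with the bloom flag raster and the areas
    ``A_Bloom`` and ``A_valid`` (pixel counts times the uniform pixel area).
    An all-censored scene yields ``A_valid = 0`` and no bloom pixels; a lake
    with ``include=False`` is refused with :class:`ExcludedLakeError`.
    """
    if not geometry.include:
        raise ExcludedLakeError(
            f"lake {geometry.lake_id} is flagged for exclusion from analysis"
        )
    valid = scene.valid_mask & geometry.lake_mask
    if geometry.is_iced(scene.date):
        valid = np.zeros_like(valid)
    nfai = compute_nfai(scene)
    cx, cy = chromaticity(scene)
    green = in_green_region(cx, cy, params)
    with np.errstate(invalid="ignore"):
        bloom = (
            valid
            & (nfai > params.nfai_threshold)
            & green
            & (geometry.water_presence >= params.water_presence_min)
        )
    px = geometry.pixel_area_km2
    return BloomMask(
        bloom=bloom,
        bloom_area_km2=float(bloom.sum()) * px,
        valid_area_km2=float(valid.sum()) * px,
        lake_area_km2=geometry.area_km2,
    )


def detect_stack(
    reflectance: np.ndarray,
    valid: np.ndarray,
    geometry: LakeGeometry,
    params: DetectionParams,
    *,
    return_masks: bool = False,
) -> dict:
    """Vectorized detection over a ``(day, band, y, x)`` reflectance stack.

    ``valid`` is ``(day, y, x)``; ice handling is the caller's concern (the
    synthetic generator invalidates iced days already).  Returns a dict with
    ``bloom_area_km2`` and ``valid_area_km2`` arrays of length n_days, and
    the boolean bloom masks when ``return_masks`` is set.

    Semantically equivalent to mapping :func:`detect_bloom` over days; kept
    separate because the per-day path is the reference implementation used
    by the brute-force equivalence tests.
    """
    if not geometry.include:
        raise ExcludedLakeError(
            f"lake {geometry.lake_id} is flagged for exclusion from analysis"
        )
    bands = BANDS_NM
    idx = {nm: bands.index(nm) for nm in (443, 555, 645, 859, 1240)}
    r = reflectance
    nfai = nfai_index(r[:, idx[555]], r[:, idx[645]], r[:, idx[859]], r[:, idx[1240]])
    cx, cy = _chromaticity_from_rgb(r[:, idx[645]], r[:, idx[555]], r[:, idx[443]])
    green = in_green_region(cx, cy, params)
    lake_valid = valid & geometry.lake_mask
    with np.errstate(invalid="ignore"):
        bloom = (
            lake_valid
            & (nfai > params.nfai_threshold)
            & green
            & (geometry.water_presence >= params.water_presence_min)
        )
    px = geometry.pixel_area_km2
    out = {
        "bloom_area_km2": bloom.sum(axis=(1, 2)) * px,
        "valid_area_km2": lake_valid.sum(axis=(1, 2)) * px,
    }
    if return_masks:
        out["bloom_masks"] = bloom
    return out
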