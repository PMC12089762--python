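"""Readers/writers for scene stacks and tabular artifacts.

Scene stacks are stored one file per lake in a self-describing gridded
format (NetCDF): dimensions ``day x band x y x x``, a ``band`` coordinate
in nm, reflectance as float32 and validity as a byte mask.  CSV tables use
ISO-8601 dates throughout.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import xarray as xr

from .detection import BANDS_NM, LakeGeometry, Scene
from .synthetic import SceneStack

__all__ = [
    "FormatError",
    "write_scene_stack",
    "read_scene_stack",
    "read_scene_tiff",
    "write_geometry",
    "read_geometry",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


def write_scene_stack(path: Union[str, Path], stack: SceneStack) -> None:
    """Write a lake's scene stack to NetCDF (day, band, y, x)."""
    ds = xr.Dataset(
        {
            "reflectance": (
                ("day", "band", "y", "x"),
                stack.reflectance.astype(np.float32),
            ),
            "valid": (("day", "y", "x"), stack.valid.astype(np.int8)),
        },
        coords={
            "day": stack.dates,
            "band": np.array(stack.bands, dtype=np.int32),
        },
        attrs={"band_units": "nm", "conventions": "lakebloom-scene-stack-v1"},
    )
    ds.to_netcdf(path)
    ds.close()


def read_scene_stack(path: Union[str, Path]) -> SceneStack:
    """Read a scene stack; validates bands and mask, sorts unordered days.

    Raises :class:`FormatError` naming the missing field when a required
    band or the validity mask is absent.  Write-then-read round-trips are
    value-identical.
    """
    with xr.open_dataset(path) as ds:
        if "band" not in ds.coords:
            raise FormatError("scene stack is missing the 'band' coordinate")
        if "valid" not in ds.variables:
            raise FormatError("scene stack is missing the 'valid' mask variable")
        if "reflectance" not in ds.variables:
            raise FormatError("scene stack is missing 'reflectance'")
        bands = tuple(int(b) for b in ds["band"].values)
        for nm in BANDS_NM:
            if nm not in bands:
                raise FormatError(f"scene stack is missing the {nm} nm band")
        days = pd.DatetimeIndex(ds["day"].values)
        if not days.is_monotonic_increasing:
            warnings.warn("scene stack days were unordered; sorting", stacklevel=2)
            logger.warning("scene stack %s had unordered days; sorted", path)
            ds = ds.sortby("day")
            days = pd.DatetimeIndex(ds["day"].values)
        # normalize band order to the canonical one
        ds = ds.sel(band=list(BANDS_NM))
        refl = np.asarray(ds["reflectance"].values, dtype=np.float32)
        valid = np.asarray(ds["valid"].values).astype(bool)
    return SceneStack(dates=days, reflectance=refl, valid=valid, bands=BANDS_NM)


def read_scene_tiff(
    path: Union[str, Path], date: dt.date, valid_mask: Optional[np.ndarray] = None
) -> Scene:
    """Read a single-day scene from a (band, y, x) TIFF raster.

    A GeoTIFF written band-interleaved reads fine; georeferencing tags are
    ignored.  ``valid_mask`` defaults to all-valid.
    """
    import tifffile

    arr = np.asarray(tifffile.imread(str(path)), dtype=float)
    if arr.ndim != 3 or arr.shape[0] != len(BANDS_NM):
        raise FormatError(
            f"expected a ({len(BANDS_NM)}, y, x) raster, got shape {arr.shape}"
        )
    if valid_mask is None:
        valid_mask = np.ones(arr.shape[1:], dtype=bool)
    return Scene(date=date, reflectance=arr, valid_mask=valid_mask, bands=BANDS_NM)


def write_geometry(path: Union[str, Path], geometry: LakeGeometry) -> None:
    """Persist lake geometry as a small NetCDF (masks + scalar attrs)."""
    attrs = {
        "lake_id": geometry.lake_id,
        "area_km2": geometry.area_km2,
        "hemisphere": geometry.hemisphere,
        "frozen": int(geometry.frozen),
        "include": int(geometry.include),
    }
    if geometry.ice_cover is not None:
        attrs["freeze_doy"], attrs["melt_doy"] = geometry.ice_cover
    ds = xr.Dataset(
        {
            "lake_mask": (("y", "x"), geometry.lake_mask.astype(np.int8)),
            "water_presence": (("y", "x"), geometry.water_presence),
        },
        attrs=attrs,
    )
    ds.to_netcdf(path)
    ds.close()


def read_geometry(path: Union[str, Path]) -> LakeGeometry:
    with xr.open_dataset(path) as ds:
        for var in ("lake_mask", "water_presence"):
            if var not in ds.variables:
                raise FormatError(f"geometry file is missing '{var}'")
        ice = None
        if "freeze_doy" in ds.attrs:
            ice = (int(ds.attrs["freeze_doy"]), int(ds.attrs["melt_doy"]))
        return LakeGeometry(
            lake_id=str(ds.attrs["lake_id"]),
            lake_mask=ds["lake_mask"].values.astype(bool),
            area_km2=float(ds.attrs["area_km2"]),
            water_presence=ds["water_presence"].values,
            hemisphere=str(ds.attrs["hemisphere"]),
            ice_cover=ice,
            frozen=bool(int(ds.attrs["frozen"])),
            include=bool(int(ds.attrs["include"])),
        )
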