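"""NDVI from NIR/RED reflectance and yearly percent vegetation cover.

NDVI = (NIR - RED) / (NIR + RED), in [-1, 1]. Pixels with NDVI strictly
above a threshold (default 0.2) are classified as vegetation, and cover is
the percentage of classified pixels among the wetland-interior pixels with
a defined NDVI.

Band semantics depend on the sensor: NIR/RED are bands 4/3 on Landsat 7
ETM+ and bands 5/4 on Landsat 8 OLI. The mapping is configuration of input
channel names, never hardcoded; this module only ever sees "nir" and "red"
arrays.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import numpy as np

from .errors import NoResultError

NDVI_THRESHOLD = 0.2

#: Sensor name -> (NIR band, RED band) for documentation/configuration.
SENSOR_BANDS = {"landsat7": (4, 3), "landsat8": (5, 4)}


@dataclass(frozen=True)
class ReflectanceRaster:
    """Paired NIR/RED reflectance with a wetland-interior mask."""

    nir: np.ndarray
    red: np.ndarray
    mask: np.ndarray
    year: int

    def __post_init__(self):
        if self.nir.shape != self.red.shape or self.nir.shape != self.mask.shape:
            raise ValueError("nir, red and mask must share a shape")
        if not self.mask.any():
            raise ValueError("mask selects no interior pixel")
        for name, band in (("nir", self.nir), ("red", self.red)):
            finite = band[np.isfinite(band)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                import warnings

                warnings.warn(
                    f"{name} reflectance outside [0, 1]", stacklevel=2
                )


@dataclass(frozen=True)
class VegetationCover:
    year: int
    percent_cover: float

    def __post_init__(self):
        if not 0.0 <= self.percent_cover <= 100.0:
            raise ValueError("percent_cover outside [0, 100]")


def ndvi(nir, red) -> np.ndarray:
    """Normalized difference vegetation index per pixel.

    Pixels where both bands are zero (or either is missing) are NaN.
    Reflectance outside [0, 1] is tolerated but flagged with a warning by
    callers that validate rasters; here the arithmetic is applied as-is.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if nir.shape != red.shape:
        raise ValueError(f"shape mismatch: {nir.shape} vs {red.shape}")
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (nir - red) / denom, np.nan)
    out = np.where(np.isnan(nir) | np.isnan(red), np.nan, out)
    return out


def vegetation_percent(
    ndvi_array,
    mask=None,
    threshold: float = NDVI_THRESHOLD,
    year: int | None = None,
) -> VegetationCover:
    """Percent of interior pixels classified as vegetation.

    A pixel counts as vegetation when its NDVI is strictly greater than
    ``threshold``; pixels with undefined NDVI are excluded from both the
    numerator and the denominator.
    """
    arr = np.asarray(ndvi_array, dtype=float)
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError("mask shape does not match NDVI array")
    vals = arr[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise NoResultError("no masked pixel with a defined NDVI")
    pct = 100.0 * np.count_nonzero(vals > threshold) / vals.size
    return VegetationCover(year=int(year) if year is not None else -1, percent_cover=pct)


def read_band(path: str | PathLike) -> np.ndarray:
    """Read a single-band GeoTIFF (or plain TIFF) as a float array."""
    import tifffile

    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a single-band raster, got shape {arr.shape}")
    return arr


def cover_from_rasters(
    nir_path,
    red_path,
    mask_path=None,
    threshold: float = NDVI_THRESHOLD,
    year: int | None = None,
) -> VegetationCover:
    """End-to-end cover for one year from NIR/RED (and optional mask) files."""
    nir = read_band(nir_path)
    red = read_band(red_path)
    mask = read_band(mask_path).astype(bool) if mask_path is not None else None
    return vegetation_percent(ndvi(nir, red), mask, threshold, year)


def require_supported_index(index: str) -> None:
    """Reject unsupported spectral indices loudly.

    Only NDVI is implemented; NDWI is accepted in configuration for
    forward compatibility but has no defined computation here.
    """
    if index.lower() == "ndvi":
        return
    if index.lower() == "ndwi":
        raise NotImplementedError(
            "NDWI is recognized but not implemented; only NDVI is available"
        )
    raise ValueError(f"unknown spectral index {index!r}")
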