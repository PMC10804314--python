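"""Image-quality metrics for processed/reference mosaic pairs.

Two complementary families:

* content retention away from the artifact — RMSE (and its expression as a
  percentage of the 16-bit range, %RMSE = RMSE/65535 x 100) and SSIM with
  Gaussian spatial weighting (sigma 1.5), both computed on "ROI mosaics"
  assembled from the central crop of every tile footprint so the overlap
  zones targeted by the corrections are excluded;
* brightness-uniformity improvement — sample skewness and excess kurtosis
  of the zero-ignoring X/Y axis-mean profiles, which exaggerate the
  tile-pitch-periodic brightness modulation a tiling artifact produces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.metrics import structural_similarity

from .errors import (
    DegenerateInputError,
    GeometryError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "RoiMosaic",
    "AxisProfile",
    "MetricsReport",
    "extract_roi_mosaic",
    "rmse",
    "ssim",
    "axis_profile",
    "profile_moments",
    "otsu_threshold_nonzero",
]

U16_MAX = 65535


@dataclass
class RoiMosaic:
    """Contiguous grid of per-tile central crops (grid order preserved)."""

    pixels: np.ndarray
    roi_size: int


@dataclass
class AxisProfile:
    """Per-line means ignoring background; absent lines are NaN, not zero.

    ``axis='x'`` averages each row along x (profile indexed by row), the
    direction in which a top-to-bottom intra-tile gradient shows up as a
    tile-pitch-periodic profile; ``axis='y'`` averages each column.
    """

    axis: str
    values: np.ndarray
    mask_threshold: float

    @property
    def present(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]


@dataclass
class MetricsReport:
    """All metrics for one processed/reference pair under one condition."""

    rmse: float
    pct_rmse: float
    ssim: float
    skew_x: float
    kurt_x: float
    skew_y: float
    kurt_y: float
    condition: tuple | None = None


def extract_roi_mosaic(image: np.ndarray, geometry, roi_size: int = 100,
                       offset=(0, 0)) -> RoiMosaic:
    """Assemble the central roi_size x roi_size crop of every tile footprint.

    Crops are taken at the *nominal* tile centers (image coordinates shifted
    by ``offset``) and tiled contiguously in grid order.  ``roi_size`` must
    not intrude into the nominal overlap zones.
    """
    image = np.asarray(image)
    g = geometry
    if roi_size <= 0:
        raise InvalidParameterError("roi_size must be positive")
    if roi_size > g.tile_size - g.overlap_px:
        raise GeometryError(
            f"roi_size {roi_size} intrudes into the {g.overlap_px}-px overlap zone "
            f"of {g.tile_size}-px tiles"
        )
    margin = (g.tile_size - roi_size) // 2
    out = np.zeros((g.grid_rows * roi_size, g.grid_cols * roi_size), dtype=image.dtype)
    oy, ox = int(offset[0]), int(offset[1])
    for r in range(g.grid_rows):
        for c in range(g.grid_cols):
            y0 = oy + r * g.pitch + margin
            x0 = ox + c * g.pitch + margin
            if y0 < 0 or x0 < 0 or y0 + roi_size > image.shape[0] or x0 + roi_size > image.shape[1]:
                raise GeometryError(f"ROI for tile {(r, c)} falls outside the image")
            out[r * roi_size : (r + 1) * roi_size, c * roi_size : (c + 1) * roi_size] = image[
                y0 : y0 + roi_size, x0 : x0 + roi_size
            ]
    return RoiMosaic(pixels=out, roi_size=roi_size)


def rmse(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Root-mean-square pixel difference and its percentage of 65535."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise GeometryError(f"shape mismatch {x.shape} vs {y.shape}")
    value = float(np.sqrt(np.mean((x - y) ** 2)))
    return value, value / U16_MAX * 100.0


def ssim(x: np.ndarray, y: np.ndarray, sigma: float = 1.5,
         data_range: float | None = None) -> float:
    """Mean SSIM with Gaussian spatial weighting (Wang et al. formulation).

    Local means/variances/covariance are weighted by a Gaussian of width
    ``sigma``; luminance, contrast and structure terms enter with unit
    exponents and the standard stabilizing constants scaled by the data
    range (65535 for 16-bit input unless overridden).
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise GeometryError(f"shape mismatch {x.shape} vs {y.shape}")
    if data_range is None:
        if np.issubdtype(x.dtype, np.integer):
            data_range = float(np.iinfo(x.dtype).max)
        else:
            data_range = float(max(x.max(), y.max()) - min(x.min(), y.min()))
    if data_range <= 0:
        raise DegenerateInputError("data range is zero")
    return float(
        structural_similarity(
            x,
            y,
            gaussian_weights=True,
            sigma=sigma,
            use_sample_covariance=False,
            data_range=data_range,
        )
    )


def otsu_threshold_nonzero(image: np.ndarray) -> float:
    """Otsu threshold computed on the nonzero pixels (background suppressor)."""
    nz = np.asarray(image)[np.asarray(image) > 0]
    if nz.size < 2 or nz.min() == nz.max():
        return 0.0
    return float(threshold_otsu(nz))


def axis_profile(image: np.ndarray, axis: str = "x",
                 mask_threshold: float = 0.0) -> AxisProfile:
    """Per-line mean over pixels above max(0, mask_threshold).

    Zeros (background) are always ignored; a positive threshold suppresses
    dim background further.  Lines with no qualifying pixels are NaN.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise GeometryError("image must be 2-D")
    if axis not in ("x", "y"):
        raise InvalidParameterError("axis must be 'x' or 'y'")
    thr = max(0.0, float(mask_threshold))
    reduce_axis = 1 if axis == "x" else 0
    qualifying = image > thr
    count = qualifying.sum(axis=reduce_axis)
    total = np.where(qualifying, image, 0.0).sum(axis=reduce_axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return AxisProfile(axis=axis, values=values, mask_threshold=thr)


def profile_moments(profile: AxisProfile) -> tuple[float, float]:
    """Sample skewness and excess kurtosis of the present profile values.

    Excess kurtosis (normal distribution -> 0) is used throughout.
    """
    vals = profile.present
    if vals.size < 4:
        raise InsufficientDataError(
            f"need >= 4 present profile entries, got {vals.size}"
        )
    return float(stats.skew(vals)), float(stats.kurtosis(vals, fisher=True))
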