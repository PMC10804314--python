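"""Retrospective (calibration-free) flat-field estimation and correction.

Per-tile vignetting — the radial/directional brightness falloff toward tile
edges — is the dominant cause of grid-like tiling artifacts in stitched
mosaics.  This module estimates a multiplicative gain field ("mesh") from
the tile statistics themselves: all tiles are pixelwise averaged (pooled
over every z-slice in *cumulative* mode, or per z-slice in *individual*
mode), straight lines are least-squares fitted to the row- and column-mean
profiles of the normalized mean tile, and the mesh is the max-normalized
outer product of the two fitted lines.  Each tile is then corrected by
pixelwise division by the mesh.

The mesh is separable and linear by construction; curvature of the true
vignette (e.g. a radial component) is only partially captured, which is
why a frequency-domain destriping step is still useful downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .errors import (
    DegenerateInputError,
    EmptyInputError,
    GeometryError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "MeanTile",
    "FlatFieldMesh",
    "accumulate_mean_tile",
    "estimate_flatfield",
    "apply_flatfield",
    "estimate_mesh",
    "correct_scan",
    "save_mesh",
    "load_mesh",
]

U16_MAX = 65535


@dataclass
class MeanTile:
    """Pixelwise mean over contributing tiles, rescaled so max = 1."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("mean tile contains non-finite values")


@dataclass
class FlatFieldMesh:
    """Strictly positive multiplicative gain field, max-normalized to 1.

    ``mode`` records provenance: ``cumulative`` (pooled over z),
    ``individual`` (one z-slice, ``z_index`` set), or ``synthetic``
    (a simulator ground-truth vignette field).
    """

    gain: np.ndarray
    mode: str = "cumulative"
    z_index: int | None = None
    clip_floor: float = 0.0

    def __post_init__(self):
        self.gain = np.asarray(self.gain, dtype=float)
        if self.gain.ndim != 2:
            raise GeometryError("gain field must be 2-D")
        if not np.all(np.isfinite(self.gain)) or np.any(self.gain <= 0):
            raise InvalidParameterError("gain field must be finite and strictly positive")
        if self.mode == "individual" and self.z_index is None:
            raise InvalidParameterError("individual mode requires z_index")

    @property
    def shape(self):
        return self.gain.shape


def accumulate_mean_tile(scan, mode: str = "cumulative", z: int | None = None) -> MeanTile:
    """Average tiles pixelwise and normalize the result to max 1.

    ``mode='cumulative'`` pools every tile of every z-slice;
    ``mode='individual'`` uses only the tiles of slice ``z``.
    """
    if mode not in ("cumulative", "individual"):
        raise InvalidParameterError(f"unknown flat-field mode {mode!r}")
    if mode == "individual":
        if z is None:
            raise InvalidParameterError("individual mode requires z")
        selected = [t for (r, c, zz), t in scan.tiles.items() if zz == z]
    else:
        if z is not None:
            raise InvalidParameterError("z is only meaningful in individual mode")
        selected = list(scan.tiles.values())
    if not selected:
        raise EmptyInputError("no tiles selected for mean-tile accumulation")
    acc = np.zeros(selected[0].shape, dtype=np.float64)
    for t in selected:
        if t.shape != acc.shape:
            raise GeometryError("tiles have inconsistent shapes")
        acc += t
    acc /= len(selected)
    peak = acc.max()
    if peak <= 0:
        raise DegenerateInputError("mean tile is identically zero")
    return MeanTile(acc / peak)


def _axis_mean_profile(values: np.ndarray, axis: int) -> np.ndarray:
    """Per-line mean along ``axis``, ignoring zeros in lines that are >50% zero.

    Lines that are entirely zero fall back to the profile's overall mean so
    the subsequent line fit stays finite.
    """
    plain = values.mean(axis=axis)
    nz = values != 0
    count = nz.sum(axis=axis)
    n = values.shape[axis]
    with np.errstate(invalid="ignore", divide="ignore"):
        nonzero_mean = np.where(count > 0, values.sum(axis=axis) / np.maximum(count, 1), np.nan)
    prof = np.where(count < 0.5 * n, nonzero_mean, plain)
    if np.any(~np.isfinite(prof)):
        fill = np.nanmean(prof) if np.any(np.isfinite(prof)) else 1.0
        prof = np.where(np.isfinite(prof), prof, fill)
    return prof


def estimate_flatfield(
    mean_tile: MeanTile,
    clip_floor: float = 0.05,
    *,
    mode: str = "cumulative",
    z_index: int | None = None,
) -> FlatFieldMesh:
    """Build the separable line-fit mesh from a mean tile.

    Row profile r(i) and column profile c(j) of the mean tile each get a
    least-squares straight-line fit against pixel index; the mesh is
    ``outer(r_fit, c_fit)`` normalized to max 1 and clipped below at
    ``clip_floor`` (bounding the correction gain at 1/clip_floor).
    """
    values = np.asarray(mean_tile.values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InvalidInputError("mean tile contains NaN/Inf")
    if values.max() <= 0:
        raise DegenerateInputError("mean tile is all zero")
    if not (0.0 < clip_floor < 1.0):
        raise InvalidParameterError("clip_floor must lie in (0, 1)")

    n_rows, n_cols = values.shape
    row_profile = _axis_mean_profile(values, axis=1)   # length n_rows
    col_profile = _axis_mean_profile(values, axis=0)   # length n_cols

    i = np.arange(n_rows, dtype=float)
    j = np.arange(n_cols, dtype=float)
    row_fit = np.polyval(np.polyfit(i, row_profile, 1), i)
    col_fit = np.polyval(np.polyfit(j, col_profile, 1), j)

    mesh = np.outer(row_fit, col_fit)
    if np.any(mesh <= 0):
        warnings.warn(
            "fitted flat-field line non-positive; clipping at floor",
            RuntimeWarning,
            stacklevel=2,
        )
        mesh = np.clip(mesh, np.finfo(float).tiny, None)
    mesh = mesh / mesh.max()
    mesh = np.clip(mesh, clip_floor, None)
    return FlatFieldMesh(gain=mesh, mode=mode, z_index=z_index, clip_floor=clip_floor)


def apply_flatfield(tile: np.ndarray, mesh: FlatFieldMesh) -> np.ndarray:
    """Divide a 16-bit tile pixelwise by the mesh gain.

    Output is rounded and clipped to [0, 65535]; zero pixels stay zero.
    """
    tile = np.asarray(tile)
    if tile.shape != mesh.gain.shape:
        raise GeometryError(f"tile shape {tile.shape} != mesh shape {mesh.gain.shape}")
    out = np.rint(tile.astype(np.float64) / mesh.gain)
    return np.clip(out, 0, U16_MAX).astype(np.uint16)


def estimate_mesh(scan, mode: str = "cumulative", z: int | None = None,
                  clip_floor: float = 0.05) -> FlatFieldMesh:
    """Convenience: accumulate the mean tile and fit the mesh in one call."""
    mt = accumulate_mean_tile(scan, mode=mode, z=z)
    return estimate_flatfield(mt, clip_floor=clip_floor, mode=mode, z_index=z)


def correct_scan(scan, mode: str = "cumulative", clip_floor: float = 0.05):
    """Flat-field-correct every tile of a scan, returning a new scan.

    Cumulative mode estimates one mesh from all z-slices and applies it to
    every tile; individual mode estimates one mesh per z-slice and applies
    it only to the tiles of that slice.
    """
    from .synthetic_scan import TileScan  # local import avoids a cycle

    if mode == "cumulative":
        mesh = estimate_mesh(scan, mode="cumulative", clip_floor=clip_floor)
        meshes = {z: mesh for z in range(scan.geometry.n_z)}
    elif mode == "individual":
        meshes = {
            z: estimate_mesh(scan, mode="individual", z=z, clip_floor=clip_floor)
            for z in range(scan.geometry.n_z)
        }
    else:
        raise InvalidParameterError(f"unknown flat-field mode {mode!r}")
    tiles = {key: apply_flatfield(t, meshes[key[2]]) for key, t in scan.tiles.items()}
    return TileScan(
        tiles=tiles,
        geometry=scan.geometry,
        channel=scan.channel,
        true_positions=scan.true_positions,
    )


def save_mesh(mesh: FlatFieldMesh, path) -> None:
    """Write the mesh as a 32-bit float TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, mesh.gain.astype(np.float32))
    meta = {"mode": mesh.mode, "z_index": mesh.z_index, "clip_floor": mesh.clip_floor}
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_mesh(path) -> FlatFieldMesh:
    path = Path(path)
    gain = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    return FlatFieldMesh(gain=gain, **meta)
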