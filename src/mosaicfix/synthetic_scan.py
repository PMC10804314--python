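"""Synthetic tile-scan simulator with known ground truth.

Real whole-slide multiphoton mosaics have no per-pixel ground truth, so
correction quality can only be judged indirectly.  This module generates a
band-limited "tissue" specimen, then renders it into the tile scan a
motorized-stage microscope would acquire: overlapping crops at jittered
stage positions, per-tile multiplicative vignetting (directional ramps plus
an optionally off-center radial falloff), z-dependent defocus blur,
signal-dependent photon-like noise with a constant read-noise floor, and
16-bit quantization.  Every corruption is parameterized and seeded, so
downstream correction stages can be scored against exact truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .errors import GeometryError, InvalidParameterError
from .flatfield import FlatFieldMesh

__all__ = [
    "ScanGeometry",
    "GroundTruthImage",
    "VignetteParams",
    "TileScan",
    "generate_specimen",
    "make_vignette_field",
    "render_tilescan",
    "write_tilescan",
    "read_tilescan",
]

U16_MAX = 65535


@dataclass(frozen=True)
class ScanGeometry:
    """Rectangular tile grid with nominal overlap and z-stack depth.

    ``overlap_fraction`` is the fraction of the tile width shared with each
    neighbor (default 10%); the nominal grid pitch is therefore
    ``tile_size - round(tile_size * overlap_fraction)`` pixels.
    """

    grid_rows: int
    grid_cols: int
    tile_size: int = 256
    overlap_fraction: float = 0.10
    n_z: int = 5
    jitter_sd: float = 0.0

    def __post_init__(self):
        if self.tile_size < 16:
            raise InvalidParameterError("tile_size must be >= 16")
        if not (0.0 < self.overlap_fraction < 0.5):
            raise InvalidParameterError("overlap_fraction must lie in (0, 0.5)")
        if self.grid_rows < 2 or self.grid_cols < 2:
            raise InvalidParameterError("grid must be at least 2x2")
        if self.n_z < 1:
            raise InvalidParameterError("n_z must be >= 1")
        if self.jitter_sd < 0:
            raise InvalidParameterError("jitter_sd must be >= 0")

    @property
    def overlap_px(self) -> int:
        return int(round(self.tile_size * self.overlap_fraction))

    @property
    def pitch(self) -> int:
        """Nominal tile-to-tile spacing in pixels."""
        return self.tile_size - self.overlap_px

    @property
    def mosaic_shape(self) -> tuple[int, int]:
        return (
            self.pitch * (self.grid_rows - 1) + self.tile_size,
            self.pitch * (self.grid_cols - 1) + self.tile_size,
        )

    @property
    def z_focus(self) -> int:
        """Index of the in-focus (middle) z-slice."""
        return (self.n_z - 1) // 2

    def nominal_position(self, row: int, col: int) -> np.ndarray:
        return np.array([row * self.pitch, col * self.pitch], dtype=float)

    def grid_keys(self):
        for r in range(self.grid_rows):
            for c in range(self.grid_cols):
                yield (r, c)

    def to_dict(self) -> dict:
        return {
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "tile_size": self.tile_size,
            "overlap_fraction": self.overlap_fraction,
            "n_z": self.n_z,
            "jitter_sd": self.jitter_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(**d)


@dataclass
class GroundTruthImage:
    """Noise- and vignette-free specimen: intensities plus a tissue mask.

    Pixels are nonnegative and exactly zero outside the tissue mask, so the
    zero-ignoring background conventions of the metrics stage are exercised.
    """

    pixels: np.ndarray
    tissue_mask: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.pixels.shape != self.tissue_mask.shape:
            raise GeometryError("pixels and tissue_mask shapes differ")
        if np.any(self.pixels < 0):
            raise InvalidParameterError("ground-truth pixels must be nonnegative")
        if np.any(self.pixels[~self.tissue_mask] != 0):
            raise InvalidParameterError("pixels outside the tissue mask must be zero")


@dataclass(frozen=True)
class VignetteParams:
    """Forward model of per-tile vignetting.

    ``axial_slope_rows``/``axial_slope_cols`` are fractional brightness
    drops across one tile (top-to-bottom / left-to-right linear ramps);
    ``radial_strength`` is the peak-to-farthest-corner falloff of a radial
    component whose maximum sits at the tile center offset by ``asymmetry``
    (pixels, (row, col)).
    """

    axial_slope_rows: float = 0.0
    axial_slope_cols: float = 0.0
    radial_strength: float = 0.0
    asymmetry: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        vals = (self.axial_slope_rows, self.axial_slope_cols, self.radial_strength,
                *self.asymmetry)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError("vignette parameters must be finite")


@dataclass
class TileScan:
    """Indexed 16-bit tiles keyed by (row, col, z) plus grid geometry."""

    tiles: dict
    geometry: ScanGeometry
    channel: str = "chan0"
    true_positions: dict | None = None

    def __post_init__(self):
        g = self.geometry
        shape = None
        for r in range(g.grid_rows):
            for c in range(g.grid_cols):
                for z in range(g.n_z):
                    if (r, c, z) not in self.tiles:
                        raise GeometryError(f"missing tile {(r, c, z)}")
        for t in self.tiles.values():
            if shape is None:
                shape = t.shape
            elif t.shape != shape:
                raise GeometryError("tiles have inconsistent shapes")

    def tiles_at_z(self, z: int) -> dict:
        """Map (row, col) -> tile for one z-slice."""
        return {(r, c): t for (r, c, zz), t in self.tiles.items() if zz == z}


def generate_specimen(
    geometry: ScanGeometry,
    texture_scale: float = 4.0,
    seed: int = 0,
    *,
    mask_fraction: float = 0.6,
    peak_intensity: float = 3000.0,
) -> GroundTruthImage:
    """Band-limited random texture inside an irregular tissue mask.

    The texture is Gaussian-smoothed white noise (correlation length set by
    ``texture_scale``); the mask is a smooth random field thresholded at the
    quantile that makes the tissue occupy exactly ``mask_fraction`` of the
    extent, which must lie in [0.4, 0.8].
    """
    if texture_scale <= 0:
        raise InvalidParameterError("texture_scale must be positive")
    if not (0.4 <= mask_fraction <= 0.8):
        raise InvalidParameterError("mask_fraction must lie in [0.4, 0.8]")
    if peak_intensity <= 0:
        raise InvalidParameterError("peak_intensity must be positive")
    rng = np.random.default_rng(seed)
    shape = geometry.mosaic_shape

    tex = ndimage.gaussian_filter(rng.standard_normal(shape), texture_scale)
    lo, hi = tex.min(), tex.max()
    if hi <= lo:  # pragma: no cover - degenerate only for absurd scales
        raise InvalidParameterError("texture is constant; texture_scale too large")
    tex = (tex - lo) / (hi - lo)

    # Irregular tissue blob: very-low-frequency random field, quantile cut.
    blob = ndimage.gaussian_filter(rng.standard_normal(shape), min(shape) / 8.0)
    mask = blob >= np.quantile(blob, 1.0 - mask_fraction)

    pixels = peak_intensity * (0.2 + 0.8 * tex) * mask
    return GroundTruthImage(pixels=pixels, tissue_mask=mask)


def make_vignette_field(tile_size: int, params: VignetteParams) -> FlatFieldMesh:
    """Construct the multiplicative vignette gain field for one tile.

    Combines separable linear ramps with a radial falloff centered at the
    tile center plus ``params.asymmetry``; the result is max-normalized and
    must be strictly positive.
    """
    if tile_size < 16:
        raise InvalidParameterError("tile_size must be >= 16")
    n = tile_size
    i = np.arange(n, dtype=float)[:, None]
    j = np.arange(n, dtype=float)[None, :]
    ramp = (1.0 - params.axial_slope_rows * i / (n - 1)) * (
        1.0 - params.axial_slope_cols * j / (n - 1)
    )
    cy = (n - 1) / 2.0 + params.asymmetry[0]
    cx = (n - 1) / 2.0 + params.asymmetry[1]
    r2 = (i - cy) ** 2 + (j - cx) ** 2
    corners = [(0.0, 0.0), (0.0, n - 1.0), (n - 1.0, 0.0), (n - 1.0, n - 1.0)]
    r2_max = max((y - cy) ** 2 + (x - cx) ** 2 for y, x in corners)
    radial = 1.0 - params.radial_strength * r2 / r2_max
    fld = ramp * radial
    if np.any(fld <= 0):
        raise InvalidParameterError("vignette parameters yield a non-positive field")
    fld = fld / fld.max()
    return FlatFieldMesh(gain=fld, mode="synthetic", clip_floor=0.0)


def _bilinear_crop(image: np.ndarray, pos: np.ndarray, size: int) -> np.ndarray:
    rows = np.arange(size, dtype=float) + pos[0]
    cols = np.arange(size, dtype=float) + pos[1]
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(image, grid, order=1, mode="constant", cval=0.0)


def render_tilescan(
    truth: GroundTruthImage,
    geometry: ScanGeometry,
    vignette: FlatFieldMesh | None = None,
    noise_gain: float = 0.0,
    z_falloff: float = 0.0,
    seed: int = 0,
    *,
    read_noise: float = 0.0,
    subpixel_jitter: bool = False,
    channel: str = "chan0",
) -> TileScan:
    """Render a specimen into a vignetted, noisy, z-stacked tile scan.

    Each tile is the crop of the truth at its jittered position, multiplied
    by the vignette gain, corrupted by Gaussian noise with variance
    ``noise_gain * signal + read_noise**2``, and quantized to 16-bit.
    Slices away from the focal (middle) plane are blurred by an isotropic
    Gaussian of width ``sigma = z_falloff * |z - z_focus|`` and attenuated
    by ``1 / (1 + sigma)``, emulating the defocus blur and out-of-focus
    signal loss that max projection is meant to compensate.  Stage jitter is
    drawn per (row, col) from N(0, jitter_sd) per axis, rounded to integers
    unless ``subpixel_jitter`` is set, and clamped so crops stay inside the
    truth.
    """
    if truth.pixels.shape != geometry.mosaic_shape:
        raise GeometryError(
            f"truth extent {truth.pixels.shape} does not match geometry "
            f"mosaic shape {geometry.mosaic_shape}"
        )
    if noise_gain < 0 or read_noise < 0 or z_falloff < 0:
        raise InvalidParameterError("noise_gain, read_noise, z_falloff must be >= 0")
    if vignette is not None and vignette.gain.shape != (geometry.tile_size,) * 2:
        raise GeometryError("vignette shape does not match tile_size")

    rng = np.random.default_rng(seed)
    g = geometry
    T = g.tile_size
    H, W = truth.pixels.shape

    true_positions: dict = {}
    for key in g.grid_keys():
        pos = g.nominal_position(*key)
        if g.jitter_sd > 0:
            pos = pos + rng.normal(0.0, g.jitter_sd, size=2)
            if not subpixel_jitter:
                pos = np.rint(pos)
        pos[0] = min(max(pos[0], 0.0), H - T)
        pos[1] = min(max(pos[1], 0.0), W - T)
        true_positions[key] = pos

    gain = vignette.gain if vignette is not None else 1.0
    tiles: dict = {}
    for z in range(g.n_z):
        sigma = z_falloff * abs(z - g.z_focus)
        if sigma > 0:
            plane = ndimage.gaussian_filter(truth.pixels, sigma) / (1.0 + sigma)
        else:
            plane = truth.pixels
        for key in g.grid_keys():
            pos = true_positions[key]
            if float(pos[0]).is_integer() and float(pos[1]).is_integer():
                y, x = int(pos[0]), int(pos[1])
                if y < 0 or x < 0 or y + T > H or x + T > W:
                    raise GeometryError(f"tile {key} crop exceeds truth bounds")
                crop = plane[y : y + T, x : x + T].astype(np.float64)
            else:
                crop = _bilinear_crop(plane, pos, T)
            signal = crop * gain
            if noise_gain > 0 or read_noise > 0:
                sd = np.sqrt(noise_gain * signal + read_noise**2)
                signal = signal + rng.standard_normal(signal.shape) * sd
            tiles[(*key, z)] = np.clip(np.rint(signal), 0, U16_MAX).astype(np.uint16)

    return TileScan(tiles=tiles, geometry=g, channel=channel, true_positions=true_positions)


def write_tilescan(scan: TileScan, directory) -> None:
    """Write tiles as r{row:02d}_c{col:02d}_z{z:02d}.tif plus scan.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for (r, c, z), tile in scan.tiles.items():
        tifffile.imwrite(directory / f"r{r:02d}_c{c:02d}_z{z:02d}.tif", tile)
    sidecar = {
        "geometry": scan.geometry.to_dict(),
        "channel": scan.channel,
        "true_positions": (
            {f"{r},{c}": [float(p[0]), float(p[1])] for (r, c), p in scan.true_positions.items()}
            if scan.true_positions is not None
            else None
        ),
    }
    (directory / "scan.json").write_text(json.dumps(sidecar, indent=1))


def read_tilescan(directory) -> TileScan:
    """Read a tile set written by :func:`write_tilescan`."""
    directory = Path(directory)
    sidecar = json.loads((directory / "scan.json").read_text())
    geometry = ScanGeometry.from_dict(sidecar["geometry"])
    tiles = {}
    for r in range(geometry.grid_rows):
        for c in range(geometry.grid_cols):
            for z in range(geometry.n_z):
                path = directory / f"r{r:02d}_c{c:02d}_z{z:02d}.tif"
                if not path.exists():
                    raise GeometryError(f"missing tile file {path.name}")
                tiles[(r, c, z)] = tifffile.imread(path)
    tp = sidecar.get("true_positions")
    true_positions = None
    if tp is not None:
        true_positions = {
            tuple(int(v) for v in k.split(",")): np.array(p, dtype=float) for k, p in tp.items()
        }
    return TileScan(
        tiles=tiles,
        geometry=geometry,
        channel=sidecar.get("channel", "chan0"),
        true_positions=true_positions,
    )
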