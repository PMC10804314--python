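"""Translation-only tile registration, global placement, and fusion.

Mirrors the grid/collection stitching workflow: pairwise normalized
cross-correlation between the nominal overlap regions of 4-neighbor tiles,
link filtering with the plugin-default thresholds (regression 0.3,
max/avg displacement 2.5, absolute displacement 3.5), a global
least-squares solve of tile positions, and five overlap fusion methods
(average, linear distance-weighted blend, max, min, median) with optional
subpixel placement via Fourier-upsampled peak refinement and bilinear
resampling.

Displacement filtering follows the plugin's global-optimization semantics:
after the least-squares solve, each accepted link's residual against the
solved positions is measured, and while the maximum residual exceeds the
absolute-displacement threshold or the mean residual exceeds the max/avg
threshold, the worst link is demoted and the solve repeated.  Demoted and
low-correlation links fall back to weakly weighted nominal-grid offsets so
the graph always stays connected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .errors import (
    ConnectivityError,
    GeometryError,
    InvalidParameterError,
)

__all__ = [
    "StitchThresholds",
    "LinkEstimate",
    "StitchedImage",
    "estimate_pairwise_shift",
    "build_links",
    "filter_links",
    "solve_positions",
    "fuse",
    "max_project",
    "stitch_tiles",
]

U16_MAX = 65535
FUSION_METHODS = ("average", "linear_blend", "max", "min", "median")

#: Weight of the nominal-grid fallback equations relative to accepted links.
NOMINAL_WEIGHT = 1e-4


@dataclass(frozen=True)
class StitchThresholds:
    """Link-filtering thresholds (plugin defaults 0.3 / 2.5 / 3.5)."""

    regression_threshold: float = 0.3
    max_avg_displacement: float = 2.5
    absolute_displacement: float = 3.5

    def __post_init__(self):
        if min(self.regression_threshold, self.max_avg_displacement,
               self.absolute_displacement) <= 0:
            raise InvalidParameterError("all thresholds must be positive")


@dataclass
class LinkEstimate:
    """Measured translation between two 4-neighbor tiles.

    ``shift`` is the offset of tile ``pair[1]`` relative to its nominal grid
    position with respect to ``pair[0]``, in (row, col) pixels.
    """

    pair: tuple
    shift: np.ndarray
    correlation: float
    status: str = "accepted"
    nominal_offset: np.ndarray | None = None

    def __post_init__(self):
        self.shift = np.asarray(self.shift, dtype=float)
        if self.nominal_offset is not None:
            self.nominal_offset = np.asarray(self.nominal_offset, dtype=float)
        (r0, c0), (r1, c1) = self.pair
        if abs(r0 - r1) + abs(c0 - c1) != 1:
            raise GeometryError("link tiles must be 4-neighbors")
        if not np.all(np.isfinite(self.shift)):
            raise InvalidParameterError("link shift must be finite")


@dataclass
class StitchedImage:
    """Fused 16-bit mosaic plus the resolved tile positions."""

    pixels: np.ndarray
    positions: dict
    fusion_method: str
    spa: bool
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))
    links: list | None = None


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float((a @ b) / denom)


def _overlap_correlation(tile_a, tile_b, offset_y, offset_x):
    """Pearson correlation of the overlap when b sits at (offset_y, offset_x)."""
    h, w = tile_a.shape
    ay0, ay1 = max(0, offset_y), min(h, offset_y + h)
    ax0, ax1 = max(0, offset_x), min(w, offset_x + w)
    if ay1 - ay0 < 4 or ax1 - ax0 < 4:
        return None
    sub_a = tile_a[ay0:ay1, ax0:ax1]
    sub_b = tile_b[ay0 - offset_y : ay1 - offset_y, ax0 - offset_x : ax1 - offset_x]
    return _pearson(sub_a, sub_b)


def _subpixel_refine(tile_a, tile_b, offset_y, offset_x, upsample: int = 50):
    """Refine an integer peak by Fourier-upsampled cross-correlation.

    The mean-subtracted overlap strips at the integer peak are registered
    with a locally upsampled DFT; the returned (dy, dx) is the correction to
    *subtract* from the integer shift.  Mean subtraction stops the smooth
    vignette pedestal from dominating the correlation peak.
    """
    h, w = tile_a.shape
    ay0, ay1 = max(0, offset_y), min(h, offset_y + h)
    ax0, ax1 = max(0, offset_x), min(w, offset_x + w)
    sub_a = tile_a[ay0:ay1, ax0:ax1].astype(np.float64)
    sub_b = tile_b[ay0 - offset_y : ay1 - offset_y, ax0 - offset_x : ax1 - offset_x].astype(
        np.float64
    )
    delta, _, _ = phase_cross_correlation(
        sub_a - sub_a.mean(),
        sub_b - sub_b.mean(),
        upsample_factor=upsample,
        normalization=None,
    )
    # Trust only sub-pixel corrections; a large delta means the integer
    # search already picked a different (better-correlated) peak.
    delta = np.asarray(delta, dtype=float)
    if np.max(np.abs(delta)) > 1.0:
        return np.zeros(2)
    return delta


def estimate_pairwise_shift(
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    nominal_offset,
    spa: bool = False,
    search_radius: float = 7.0,
    pair: tuple = ((0, 0), (0, 1)),
) -> LinkEstimate:
    """Find the shift maximizing overlap correlation near the nominal offset.

    Integer shifts within ``±floor(search_radius)`` of the nominal offset are
    searched exhaustively; the window deliberately exceeds the
    absolute-displacement rejection threshold so an out-of-range true offset
    is measured (and later rejected) instead of being aliased onto the
    window edge with a deceptively high correlation.  Ties in correlation go
    to the smaller shift.  With ``spa`` the integer peak is refined to
    subpixel precision by Fourier-upsampled cross-correlation of the
    mean-subtracted overlap strips.
    """
    tile_a = np.asarray(tile_a)
    tile_b = np.asarray(tile_b)
    if tile_a.shape != tile_b.shape:
        raise GeometryError("tiles must share one shape")
    h, w = tile_a.shape
    nominal_offset = np.asarray(nominal_offset, dtype=int)
    oy, ox = int(nominal_offset[0]), int(nominal_offset[1])
    nominal_overlap = min(h - abs(oy), w - abs(ox))
    if nominal_overlap < 4:
        raise GeometryError("nominal overlap smaller than 4 px")

    radius = int(np.floor(search_radius))
    size = 2 * radius + 1
    corr = np.full((size, size), -np.inf)
    for iy, sy in enumerate(range(-radius, radius + 1)):
        for ix, sx in enumerate(range(-radius, radius + 1)):
            r = _overlap_correlation(tile_a, tile_b, oy + sy, ox + sx)
            if r is not None:
                corr[iy, ix] = r

    best = None
    for iy in range(size):
        for ix in range(size):
            r = corr[iy, ix]
            if not np.isfinite(r):
                continue
            sy, sx = iy - radius, ix - radius
            norm = sy * sy + sx * sx
            if best is None or r > best[0] + 1e-12 or (
                abs(r - best[0]) <= 1e-12 and norm < best[1]
            ):
                best = (r, norm, iy, ix)
    if best is None:
        raise GeometryError("no valid overlap in the search window")
    r0, _, iy, ix = best
    shift = np.array([iy - radius, ix - radius], dtype=float)

    if spa:
        shift = shift - _subpixel_refine(
            tile_a, tile_b, oy + int(shift[0]), ox + int(shift[1])
        )

    return LinkEstimate(
        pair=pair,
        shift=shift,
        correlation=float(r0),
        status="accepted",
        nominal_offset=nominal_offset.astype(float),
    )


def build_links(tiles: dict, geometry, spa: bool = False,
                thresholds: StitchThresholds | None = None) -> list:
    """Estimate one link per adjacent (right / down) tile pair of one z-slice."""
    thresholds = thresholds or StitchThresholds()
    links = []
    for (r, c) in sorted(tiles):
        for dr, dc in ((0, 1), (1, 0)):
            nb = (r + dr, c + dc)
            if nb not in tiles:
                continue
            nominal = geometry.nominal_position(*nb) - geometry.nominal_position(r, c)
            links.append(
                estimate_pairwise_shift(
                    tiles[(r, c)],
                    tiles[nb],
                    nominal,
                    spa=spa,
                    search_radius=2.0 * thresholds.absolute_displacement,
                    pair=((r, c), nb),
                )
            )
    return links


def filter_links(links: list, thresholds: StitchThresholds | None = None) -> list:
    """Apply the regression and absolute-displacement checks.

    Links with correlation below the regression threshold become
    ``rejected_low_r``; links whose shift magnitude exceeds the absolute
    displacement threshold become ``rejected_displacement``.  Rejected links
    enter the solve as weak nominal-offset constraints.  The max/avg
    displacement check runs against the global solution inside
    :func:`solve_positions`.
    """
    thresholds = thresholds or StitchThresholds()
    out = []
    for ln in links:
        status = "accepted"
        if ln.correlation < thresholds.regression_threshold:
            status = "rejected_low_r"
        elif float(np.linalg.norm(ln.shift)) > thresholds.absolute_displacement:
            status = "rejected_displacement"
        out.append(
            LinkEstimate(
                pair=ln.pair,
                shift=ln.shift.copy(),
                correlation=ln.correlation,
                status=status,
                nominal_offset=ln.nominal_offset,
            )
        )
    if out and all(l.status != "accepted" for l in out):
        warnings.warn(
            "all links rejected; falling back to the nominal grid",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def _grid_keys_from_links(links, geometry):
    if geometry is not None:
        return [(r, c) for r in range(geometry.grid_rows) for c in range(geometry.grid_cols)]
    keys = sorted({k for ln in links for k in ln.pair})
    return keys


def _lstsq_solve(links, keys, geometry, active_mask):
    index = {k: i for i, k in enumerate(keys)}
    n = len(keys)
    rows = []
    rhs = []
    for ln, active in zip(links, active_mask):
        a, b = ln.pair
        nominal = (
            ln.nominal_offset
            if ln.nominal_offset is not None
            else geometry.nominal_position(*b) - geometry.nominal_position(*a)
        )
        # Weak nominal equation keeps the system anchored/connected.
        row = np.zeros(n)
        row[index[b]] = NOMINAL_WEIGHT
        row[index[a]] = -NOMINAL_WEIGHT
        rows.append(row)
        rhs.append(NOMINAL_WEIGHT * nominal)
        if active:
            row = np.zeros(n)
            row[index[b]] = 1.0
            row[index[a]] = -1.0
            rows.append(row)
            rhs.append(nominal + ln.shift)
    # Anchor tile (0, 0) at the origin.
    anchor = np.zeros(n)
    anchor[index[keys[0]]] = 1.0
    rows.append(anchor)
    rhs.append(np.zeros(2))

    A = np.asarray(rows)
    B = np.asarray(rhs, dtype=float)
    sol, *_ = np.linalg.lstsq(A, B, rcond=None)
    sol = sol - sol[index[keys[0]]]  # exact anchor
    return {k: sol[index[k]].copy() for k in keys}


def solve_positions(links: list, geometry=None,
                    thresholds: StitchThresholds | None = None) -> dict:
    """Globally place tiles by least squares over pairwise offsets.

    Accepted link equations carry unit weight; every link additionally
    contributes a weak nominal-offset equation so the solution is anchored
    and connected even when links are rejected.  When ``thresholds`` is
    given, the max/avg displacement check is applied iteratively against the
    solved positions: while the worst accepted link's residual exceeds
    ``absolute_displacement`` or the mean residual exceeds
    ``max_avg_displacement``, that link is demoted to
    ``rejected_displacement`` (in place) and the solve repeated.
    """
    if not links:
        raise ConnectivityError("no links supplied")
    keys = _grid_keys_from_links(links, geometry)
    key_set = set(keys)
    covered = {k for ln in links for k in ln.pair}
    if covered != key_set:
        raise ConnectivityError("links do not cover all tiles")

    active = [ln.status == "accepted" for ln in links]
    while True:
        positions = _lstsq_solve(links, keys, geometry, active)
        residuals = []
        for i, (ln, act) in enumerate(zip(links, active)):
            if not act:
                continue
            a, b = ln.pair
            nominal = (
                ln.nominal_offset
                if ln.nominal_offset is not None
                else geometry.nominal_position(*b) - geometry.nominal_position(*a)
            )
            measured = nominal + ln.shift
            resid = float(np.linalg.norm((positions[b] - positions[a]) - measured))
            residuals.append((resid, i))
        if thresholds is None or not residuals:
            return positions
        res_vals = np.array([r for r, _ in residuals])
        worst, worst_i = max(residuals)
        if worst > thresholds.absolute_displacement or res_vals.mean() > thresholds.max_avg_displacement:
            active[worst_i] = False
            links[worst_i].status = "rejected_displacement"
            continue
        return positions


def _tile_weights(size: int) -> np.ndarray:
    """Linear-blend weight: distance (>=1) to the tile's nearest edge."""
    idx = np.arange(size, dtype=float)
    d = np.minimum(idx + 1.0, size - idx)
    return np.minimum.outer(d, d)


def _resample_placement(tile: np.ndarray, pos: np.ndarray):
    """Bilinear-resample a tile onto the integer canvas grid at subpixel pos.

    Returns (y0, x0, values) where values covers the integer pixels whose
    source coordinates fall inside the tile.
    """
    T = tile.shape[0]
    y0 = int(np.ceil(pos[0] - 1e-9))
    x0 = int(np.ceil(pos[1] - 1e-9))
    ny = int(np.floor(pos[0] + T - 1 + 1e-9)) - y0 + 1
    nx = int(np.floor(pos[1] + T - 1 + 1e-9)) - x0 + 1
    rows = np.arange(ny, dtype=float) + (y0 - pos[0])
    cols = np.arange(nx, dtype=float) + (x0 - pos[1])
    grid = np.meshgrid(rows, cols, indexing="ij")
    values = ndimage.map_coordinates(tile.astype(np.float64), grid, order=1, mode="nearest")
    src_rows, src_cols = rows, cols
    return y0, x0, values, src_rows, src_cols


def fuse(
    tiles: dict,
    positions: dict,
    method: str = "linear_blend",
    spa: bool = False,
    canvas_shape: tuple | None = None,
    origin=None,
) -> StitchedImage:
    """Fuse registered tiles into one 16-bit mosaic.

    Non-overlap pixels are copied verbatim; overlap pixels are combined by
    the chosen method.  With ``spa`` each tile is bilinearly resampled to its
    subpixel position before combination; otherwise positions are rounded to
    integers.  ``origin``/``canvas_shape`` pin the output frame (useful to
    give every z-slice an identical canvas); by default the canvas tightly
    bounds the tiles.
    """
    if method not in FUSION_METHODS:
        raise InvalidParameterError(
            f"unknown fusion method {method!r}; expected one of {FUSION_METHODS}"
        )
    if not tiles:
        raise GeometryError("no tiles to fuse")
    T = next(iter(tiles.values())).shape[0]
    pos_arr = np.array([positions[k] for k in sorted(tiles)], dtype=float)
    if origin is None:
        # round guard: solver noise of ~1e-13 must not shift the canvas
        origin = np.floor(np.round(pos_arr.min(axis=0), 6))
    origin = np.asarray(origin, dtype=float)
    if canvas_shape is None:
        extent = np.ceil(np.round(pos_arr.max(axis=0) - origin, 6)).astype(int) + T
        canvas_shape = (int(extent[0]), int(extent[1]))
    H, W = canvas_shape

    placements = []
    base_w = _tile_weights(T)
    for key in sorted(tiles):
        tile = tiles[key]
        rel = positions[key] - origin
        if spa and not (float(rel[0]).is_integer() and float(rel[1]).is_integer()):
            y0, x0, vals, src_rows, src_cols = _resample_placement(tile, rel)
            dy = np.minimum(src_rows + 1.0, T - src_rows)
            dx = np.minimum(src_cols + 1.0, T - src_cols)
            w = np.minimum.outer(dy, dx)
        else:
            y0, x0 = int(np.rint(rel[0])), int(np.rint(rel[1]))
            vals = tile.astype(np.float64)
            w = base_w
        # Clip to canvas.
        cy0, cx0 = max(0, y0), max(0, x0)
        cy1, cx1 = min(H, y0 + vals.shape[0]), min(W, x0 + vals.shape[1])
        if cy1 <= cy0 or cx1 <= cx0:
            continue
        placements.append(
            (cy0, cx0, vals[cy0 - y0 : cy1 - y0, cx0 - x0 : cx1 - x0],
             w[cy0 - y0 : cy1 - y0, cx0 - x0 : cx1 - x0])
        )

    if method in ("average", "linear_blend"):
        num = np.zeros((H, W))
        den = np.zeros((H, W))
        for y0, x0, vals, w in placements:
            ww = w if method == "linear_blend" else np.ones_like(vals)
            num[y0 : y0 + vals.shape[0], x0 : x0 + vals.shape[1]] += vals * ww
            den[y0 : y0 + vals.shape[0], x0 : x0 + vals.shape[1]] += ww
        out = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    elif method in ("max", "min"):
        fill = -np.inf if method == "max" else np.inf
        acc = np.full((H, W), fill)
        op = np.maximum if method == "max" else np.minimum
        covered = np.zeros((H, W), dtype=bool)
        for y0, x0, vals, _ in placements:
            sl = (slice(y0, y0 + vals.shape[0]), slice(x0, x0 + vals.shape[1]))
            acc[sl] = op(acc[sl], vals)
            covered[sl] = True
        out = np.where(covered, acc, 0.0)
    else:  # median
        layers = 6
        stack = np.full((H, W, layers), np.nan, dtype=np.float32)
        count = np.zeros((H, W), dtype=np.int8)
        for y0, x0, vals, _ in placements:
            sl = (slice(y0, y0 + vals.shape[0]), slice(x0, x0 + vals.shape[1]))
            c = count[sl]
            ii, jj = np.indices(vals.shape)
            stack[y0 + ii, x0 + jj, np.minimum(c, layers - 1)] = vals
            count[sl] = c + 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(stack, axis=2)
        out = np.where(count > 0, med, 0.0)

    pixels = np.clip(np.rint(out), 0, U16_MAX).astype(np.uint16)
    return StitchedImage(
        pixels=pixels,
        positions={k: np.asarray(positions[k], dtype=float) for k in tiles},
        fusion_method=method,
        spa=spa,
        origin=origin,
    )


def max_project(stitched_per_z: list) -> StitchedImage:
    """Pixelwise maximum across per-z mosaics of identical shape."""
    if not stitched_per_z:
        raise GeometryError("empty z-stack")
    shape = stitched_per_z[0].pixels.shape
    for s in stitched_per_z:
        if s.pixels.shape != shape:
            raise GeometryError("per-z mosaics must share one shape")
    pixels = stitched_per_z[0].pixels.copy()
    for s in stitched_per_z[1:]:
        np.maximum(pixels, s.pixels, out=pixels)
    first = stitched_per_z[0]
    return StitchedImage(
        pixels=pixels,
        positions=first.positions,
        fusion_method=first.fusion_method,
        spa=first.spa,
        origin=first.origin,
    )


def stitch_tiles(
    tiles: dict,
    geometry,
    fusion: str = "linear_blend",
    spa: bool = False,
    thresholds: StitchThresholds | None = None,
    canvas_shape: tuple | None = None,
    origin=None,
) -> StitchedImage:
    """Register, filter, solve and fuse one z-slice's tiles."""
    thresholds = thresholds or StitchThresholds()
    links = build_links(tiles, geometry, spa=spa, thresholds=thresholds)
    links = filter_links(links, thresholds)
    positions = solve_positions(links, geometry, thresholds=thresholds)
    result = fuse(tiles, positions, method=fusion, spa=spa,
                  canvas_shape=canvas_shape, origin=origin)
    result.links = links
    return result
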