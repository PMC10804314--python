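"""Registration, link filtering, global placement, fusion, max projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicfix.errors import (
    ConnectivityError,
    GeometryError,
    InvalidParameterError,
)
from mosaicfix.stitcher import (
    FUSION_METHODS,
    LinkEstimate,
    StitchThresholds,
    StitchedImage,
    build_links,
    estimate_pairwise_shift,
    filter_links,
    fuse,
    max_project,
    solve_positions,
    stitch_tiles,
)
from mosaicfix.synthetic_scan import ScanGeometry, render_tilescan

from conftest import align_errors, textured_truth


def _pair_from_mosaic(seed, jitter=(0, 0), size=64, overlap=6):
    """Two horizontally adjacent tiles cropped from one textured mosaic."""
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    big = ndimage.gaussian_filter(rng.normal(2000, 600, (size + 16, 2 * size + 16)), 3)
    big = np.clip(big, 0, 65535)
    pitch = size - overlap
    a = big[8 : 8 + size, 8 : 8 + size]
    b = big[8 + jitter[0] : 8 + jitter[0] + size,
            8 + pitch + jitter[1] : 8 + pitch + jitter[1] + size]
    return a.astype(np.uint16), b.astype(np.uint16), np.array([0, pitch])


class TestPairwiseShift:
    def test_self_match_is_zero_shift_full_correlation(self):
        a, b, nominal = _pair_from_mosaic(seed=0)
        link = estimate_pairwise_shift(a, b, nominal)
        np.testing.assert_array_equal(link.shift, [0, 0])
        assert link.correlation == pytest.approx(1.0, abs=1e-9)

    def test_known_integer_jitter_recovered_exactly(self):
        a, b, nominal = _pair_from_mosaic(seed=1, jitter=(2, -1))
        link = estimate_pairwise_shift(a, b, nominal, spa=False)
        np.testing.assert_array_equal(link.shift, [2, -1])

    def test_pure_noise_correlation_below_regression_threshold(self):
        rng = np.random.default_rng(2)
        corrs = [
            estimate_pairwise_shift(
                rng.integers(0, 4000, (64, 64)).astype(np.uint16),
                rng.integers(0, 4000, (64, 64)).astype(np.uint16),
                np.array([0, 58]),
            ).correlation
            for _ in range(10)
        ]
        assert np.mean(corrs) < 0.3

    def test_too_small_overlap_rejected(self):
        a, b, _ = _pair_from_mosaic(seed=3)
        with pytest.raises(GeometryError):
            estimate_pairwise_shift(a, b, np.array([0, 62]))


class TestFilterLinks:
    def _link(self, shift, corr, pair=((0, 0), (0, 1))):
        return LinkEstimate(pair, np.asarray(shift, float), corr,
                            nominal_offset=np.array([0.0, 58.0]))

    def test_good_links_all_accepted(self):
        links = [self._link((0, 0), 0.9),
                 self._link((0, 0), 0.9, pair=((0, 0), (1, 0)))]
        assert all(l.status == "accepted" for l in filter_links(links))

    def test_low_correlation_rejected(self):
        links = [self._link((0, 0), 0.1),
                 self._link((0, 0), 0.9, pair=((0, 0), (1, 0)))]
        out = filter_links(links)
        assert out[0].status == "rejected_low_r"
        assert out[1].status == "accepted"

    def test_large_shift_rejected(self):
        out = filter_links([self._link((5, 0), 0.9)])
        assert out[0].status == "rejected_displacement"

    def test_all_rejected_warns(self):
        with pytest.warns(RuntimeWarning):
            filter_links([self._link((0, 0), 0.05)])


class TestSolvePositions:
    def test_zero_shifts_give_nominal_grid(self):
        g = ScanGeometry(3, 3, tile_size=64, n_z=1)
        tiles = {k: None for k in g.grid_keys()}
        links = []
        for (r, c) in tiles:
            for dr, dc in ((0, 1), (1, 0)):
                nb = (r + dr, c + dc)
                if nb in tiles:
                    nominal = g.nominal_position(*nb) - g.nominal_position(r, c)
                    links.append(LinkEstimate(((r, c), nb), np.zeros(2), 0.9,
                                              nominal_offset=nominal))
        pos = solve_positions(links, g)
        for k in tiles:
            np.testing.assert_allclose(pos[k], g.nominal_position(*k), atol=1e-6)

    def test_single_link_chain_is_exact(self):
        nominal = np.array([0.0, 58.0])
        links = [LinkEstimate(((0, 0), (0, 1)), np.array([3.0, 0.0]), 0.9,
                              nominal_offset=nominal)]
        pos = solve_positions(links, None)
        np.testing.assert_allclose(pos[(0, 1)], nominal + [3, 0], atol=1e-5)

    def test_disconnected_graph_rejected(self):
        g = ScanGeometry(3, 3, tile_size=64, n_z=1)
        links = [LinkEstimate(((0, 0), (0, 1)), np.zeros(2), 0.9,
                              nominal_offset=np.array([0.0, 58.0]))]
        with pytest.raises(ConnectivityError):
            solve_positions(links, g)

    def test_inconsistent_link_demoted_by_displacement_check(self):
        # A 2x2 loop with one wildly inconsistent measurement: the residual
        # check against the global solve demotes exactly that link.
        g = ScanGeometry(2, 2, tile_size=64, n_z=1)
        specs = {
            ((0, 0), (0, 1)): (0.0, 0.0),
            ((0, 0), (1, 0)): (0.0, 0.0),
            ((0, 1), (1, 1)): (0.0, 0.0),
            ((1, 0), (1, 1)): (3.0, -3.0),  # contradicts the consistent loop
        }
        links = [
            LinkEstimate(pair, np.array(s), 0.9,
                         nominal_offset=g.nominal_position(*pair[1])
                         - g.nominal_position(*pair[0]))
            for pair, s in specs.items()
        ]
        pos = solve_positions(links, g, thresholds=StitchThresholds(
            regression_threshold=0.3, max_avg_displacement=1.0,
            absolute_displacement=3.5))
        statuses = {l.pair: l.status for l in links}
        assert statuses[((1, 0), (1, 1))] == "rejected_displacement"
        for k in pos:
            np.testing.assert_allclose(pos[k], g.nominal_position(*k), atol=1e-3)

    @pytest.mark.parametrize("spa,tol", [(False, 0.5), (True, 0.25)])
    def test_jitter_recovery_single_seed(self, spa, tol):
        g = ScanGeometry(4, 4, tile_size=128, n_z=1, jitter_sd=1.0)
        truth = textured_truth(g, seed=60)
        scan = render_tilescan(truth, g, None, noise_gain=0.3, seed=61,
                               read_noise=1.0)
        th = StitchThresholds()
        links = filter_links(build_links(scan.tiles_at_z(0), g, spa=spa,
                                         thresholds=th), th)
        pos = solve_positions(links, g, thresholds=th)
        err = align_errors(pos, scan.true_positions)
        assert np.quantile(err, 0.95) <= tol


class TestFuse:
    def _two_tiles(self, val_a, val_b, size=16, overlap=8):
        tiles = {
            (0, 0): np.full((size, size), val_a, dtype=np.uint16),
            (0, 1): np.full((size, size), val_b, dtype=np.uint16),
        }
        positions = {(0, 0): np.array([0.0, 0.0]),
                     (0, 1): np.array([0.0, float(size - overlap)])}
        return tiles, positions, size, overlap

    def test_order_statistics_of_two_contributors(self):
        tiles, positions, size, overlap = self._two_tiles(100, 200)
        mid = size - overlap + overlap // 2
        expected = {"average": 150, "max": 200, "min": 100, "median": 150}
        for method, val in expected.items():
            out = fuse(tiles, positions, method=method)
            assert out.pixels[size // 2, mid] == val

    def test_linear_blend_midline_is_mean(self):
        tiles, positions, size, overlap = self._two_tiles(100, 200)
        out = fuse(tiles, positions, method="linear_blend")
        # the exact mid-line falls between two columns whose weights mirror
        # each other, so their values are symmetric around the mean
        row = out.pixels[size // 2].astype(int)
        v_lo, v_hi = row[size - overlap // 2 - 1], row[size - overlap // 2]
        assert 100 < v_lo < v_hi < 200
        assert abs((v_lo + v_hi) - 300) <= 2

    def test_non_overlap_pixels_copied_verbatim(self):
        tiles, positions, size, overlap = self._two_tiles(100, 200)
        for method in FUSION_METHODS:
            out = fuse(tiles, positions, method=method)
            assert np.all(out.pixels[:, : size - overlap] == 100)
            assert np.all(out.pixels[:, size:] == 200)

    def test_unknown_method_rejected(self):
        tiles, positions, *_ = self._two_tiles(1, 2)
        with pytest.raises(InvalidParameterError):
            fuse(tiles, positions, method="blur")

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_fusion_pixelwise_ordering_and_range(self, seed):
        # min <= average, median, linear blend <= max (within quantization),
        # and every output pixel within the range of its contributors.
        rng = np.random.default_rng(seed)
        g = ScanGeometry(2, 2, tile_size=24, overlap_fraction=0.25, n_z=1)
        tiles = {k: rng.integers(0, 60000, (24, 24)).astype(np.uint16)
                 for k in g.grid_keys()}
        positions = {k: g.nominal_position(*k) for k in tiles}
        fused = {mth: fuse(tiles, positions, method=mth).pixels.astype(int)
                 for mth in FUSION_METHODS}
        lo = np.minimum.reduce([t.astype(int) for t in tiles.values()]).min()
        hi = np.maximum.reduce([t.astype(int) for t in tiles.values()]).max()
        for mth in ("average", "median", "linear_blend"):
            assert np.all(fused["min"] <= fused[mth] + 1)
            assert np.all(fused[mth] <= fused["max"] + 1)
        for mth in FUSION_METHODS:
            covered = fused[mth] > 0
            assert fused[mth][covered].min() >= lo - 1
            assert fused[mth].max() <= hi + 1

    def test_spa_subpixel_placement_resamples(self):
        rng = np.random.default_rng(9)
        from scipy import ndimage

        base = ndimage.gaussian_filter(rng.normal(2000, 500, (40, 80)), 2)
        tiles = {(0, 0): np.rint(base[:32, :32]).astype(np.uint16),
                 (0, 1): np.rint(base[:32, 28:60]).astype(np.uint16)}
        positions = {(0, 0): np.array([0.0, 0.0]), (0, 1): np.array([0.0, 27.5])}
        out = fuse(tiles, positions, method="average", spa=True)
        expected = base[:32, : out.pixels.shape[1]]
        # the blended mosaic stays close to the continuous source
        assert np.abs(out.pixels[:, 1:59].astype(float) - expected[:, 1:59]).max() < 60


class TestMaxProject:
    def _stitched(self, arr):
        return StitchedImage(pixels=np.asarray(arr, dtype=np.uint16), positions={},
                             fusion_method="average", spa=False)

    def test_single_slice_is_identity(self):
        s = self._stitched(np.arange(16).reshape(4, 4))
        np.testing.assert_array_equal(max_project([s]).pixels, s.pixels)

    def test_pixelwise_maximum(self):
        stack = [self._stitched(np.full((2, 2), v)) for v in (120, 300, 80)]
        assert np.all(max_project(stack).pixels == 300)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(GeometryError):
            max_project([self._stitched(np.zeros((4, 4))),
                         self._stitched(np.zeros((4, 5)))])

    def test_projection_tracks_in_focus_slice(self, small_geometry, small_truth):
        # Defocused slices are blurred and attenuated, so the projection's
        # error against truth is far below every defocused slice's error and
        # close to the in-focus slice's.
        scan = render_tilescan(small_truth, small_geometry, None, noise_gain=0.0,
                               z_falloff=1.5, seed=12)
        per_z = [fuse(scan.tiles_at_z(z), scan.true_positions, "average")
                 for z in range(small_geometry.n_z)]
        proj = max_project(per_z)
        h, w = small_geometry.mosaic_shape

        def err(img):
            return np.sqrt(np.mean((img[:h, :w].astype(float)
                                    - small_truth.pixels) ** 2))

        errors = [err(s.pixels) for s in per_z]
        focus = small_geometry.z_focus
        assert err(proj.pixels) < min(
            e for i, e in enumerate(errors) if i != focus
        )


class TestStitchTiles:
    def test_end_to_end_zero_jitter_reconstructs_truth(self, small_geometry,
                                                       small_truth, clean_scan):
        out = stitch_tiles(clean_scan.tiles_at_z(0), small_geometry,
                           fusion="average")
        h, w = small_geometry.mosaic_shape
        err = np.abs(out.pixels[:h, :w].astype(float) - small_truth.pixels)
        assert err.max() <= 1.0
        assert all(l.status == "accepted" for l in out.links
                   if l.correlation > 0.3)
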