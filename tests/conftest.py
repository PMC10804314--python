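"""Shared fixtures: small synthetic scans exercised across the suite."""

import numpy as np
import pytest
from scipy import ndimage

from mosaicfix.synthetic_scan import (
    GroundTruthImage,
    ScanGeometry,
    VignetteParams,
    generate_specimen,
    make_vignette_field,
    render_tilescan,
)


@pytest.fixture(scope="session")
def small_geometry():
    return ScanGeometry(grid_rows=3, grid_cols=3, tile_size=64, overlap_fraction=0.10,
                        n_z=2, jitter_sd=0.0)


@pytest.fixture(scope="session")
def small_truth(small_geometry):
    return generate_specimen(small_geometry, texture_scale=3.0, seed=7)


@pytest.fixture(scope="session")
def clean_scan(small_geometry, small_truth):
    """Unit vignette, no noise, no jitter: tiles are exact crops of truth."""
    return render_tilescan(small_truth, small_geometry, None, noise_gain=0.0,
                           z_falloff=0.0, seed=8)


@pytest.fixture(scope="session")
def default_vignette():
    return make_vignette_field(
        64, VignetteParams(axial_slope_rows=0.4, axial_slope_cols=0.15,
                           radial_strength=0.25, asymmetry=(4.0, 0.0))
    )


@pytest.fixture(scope="session")
def vignetted_scan(small_geometry, small_truth, default_vignette):
    return render_tilescan(small_truth, small_geometry, default_vignette,
                           noise_gain=0.5, z_falloff=0.5, seed=9, read_noise=2.0)


def textured_truth(geometry, seed, peak=3000.0, scale=4.0):
    """Full-coverage textured specimen: every overlap carries registration signal."""
    rng = np.random.default_rng(seed)
    tex = ndimage.gaussian_filter(rng.standard_normal(geometry.mosaic_shape), scale)
    tex = (tex - tex.min()) / (tex.max() - tex.min())
    return GroundTruthImage(
        pixels=peak * (0.2 + 0.8 * tex),
        tissue_mask=np.ones(geometry.mosaic_shape, dtype=bool),
    )


def align_errors(solved, true_positions):
    """Per-tile position error after removing the median (gauge) offset."""
    keys = sorted(solved)
    d = np.array([solved[k] - true_positions[k] for k in keys])
    d = d - np.median(d, axis=0)
    return np.linalg.norm(d, axis=1)
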