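"""End-to-end experiment grid: FF mode x fusion x SPA x FT.

For each condition the tiles are optionally flat-field corrected (per tile,
before stitching), each z-slice is registered and fused on a common canvas,
the per-z mosaics are max-projected to compensate focal-plane brightness
drop-off, and the projection is optionally crosshair-filtered (always after
stitching).  Metrics are computed against a reference mosaic produced by
the identical stitching pathway with flat-fielding and frequency filtering
disabled, so metric differences isolate the corrections; when simulator
ground truth is available, a ground-truth RMSE is reported as well.
"""

from __future__ import annotations

import dataclasses
import itertools
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import flatfield, freqfilter, metrics, stitcher
from .errors import InvalidParameterError, StageError
from .freqfilter import CrosshairSpec
from .stitcher import StitchThresholds

__all__ = [
    "FF_MODES",
    "PipelineConfig",
    "ConditionResult",
    "run_condition",
    "run_grid",
    "make_reference",
]

FF_MODES = ("none", "cumulative", "individual")


@dataclass
class PipelineConfig:
    """Experiment-grid configuration with every stage default in one place."""

    ff_modes: tuple = FF_MODES
    fusion_methods: tuple = stitcher.FUSION_METHODS
    spa_options: tuple = (False, True)
    ft_options: tuple = (False, True)
    thresholds: StitchThresholds = field(default_factory=StitchThresholds)
    crosshair: CrosshairSpec = field(default_factory=CrosshairSpec)
    roi_size: int = 100
    clip_floor: float = 0.05
    mask_threshold: float | None = None  # None -> Otsu on nonzero pixels
    seed: int = 0
    output_dir: Path | None = None

    def __post_init__(self):
        for name, allowed, got in (
            ("ff_modes", FF_MODES, self.ff_modes),
            ("fusion_methods", stitcher.FUSION_METHODS, self.fusion_methods),
        ):
            if not got:
                raise InvalidParameterError(f"{name} must be non-empty")
            bad = [g for g in got if g not in allowed]
            if bad:
                raise InvalidParameterError(f"unknown {name}: {bad}")
        if not self.spa_options or not self.ft_options:
            raise InvalidParameterError("spa_options and ft_options must be non-empty")

    def conditions(self):
        return list(
            itertools.product(
                self.ff_modes, self.fusion_methods, self.spa_options, self.ft_options
            )
        )


@dataclass
class ConditionResult:
    condition: tuple
    mosaic: np.ndarray
    report: metrics.MetricsReport
    gt_rmse: float | None = None
    gt_pct_rmse: float | None = None
    timings: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    mosaic_path: Path | None = None


def _resolve_crosshair(spec, geometry):
    """Protect sub-fundamental frequencies when the user left the default.

    A tiling artifact with period equal to the tile pitch carries no energy
    below one cycle per pitch, so the pipeline restricts the crosshair mask
    to frequency indices at or above the grid fundamental (with a 2-bin
    leakage guard) unless ``min_frequency`` was set explicitly.
    """
    if spec.min_frequency != 0:
        return spec
    h, w = geometry.mosaic_shape
    fundamental = min(round(h / geometry.pitch), round(w / geometry.pitch))
    return dataclasses.replace(spec, min_frequency=max(1, fundamental - 2))


def _canvas(geometry, thresholds):
    margin = int(np.ceil(thresholds.absolute_displacement)) + 2
    h, w = geometry.mosaic_shape
    origin = np.array([-margin, -margin], dtype=float)
    return (h + 2 * margin, w + 2 * margin), origin, margin


def _stitch_and_project(scan, fusion, spa, thresholds):
    canvas_shape, origin, margin = _canvas(scan.geometry, thresholds)
    per_z = [
        stitcher.stitch_tiles(
            scan.tiles_at_z(z),
            scan.geometry,
            fusion=fusion,
            spa=spa,
            thresholds=thresholds,
            canvas_shape=canvas_shape,
            origin=origin,
        )
        for z in range(scan.geometry.n_z)
    ]
    return stitcher.max_project(per_z), margin


def make_reference(scan, fusion, spa, config: PipelineConfig):
    """Raw-pathway baseline: stitch + max-project with FF and FT off."""
    projected, margin = _stitch_and_project(scan, fusion, spa, config.thresholds)
    return projected, margin


def run_condition(
    scan,
    condition: tuple,
    config: PipelineConfig,
    truth=None,
    reference=None,
) -> ConditionResult:
    """Run one (ff_mode, fusion, spa, ft) cell of the grid.

    ``reference`` (a precomputed raw max-projected mosaic for the same
    fusion/SPA) is recomputed when not supplied.  ``truth`` enables the
    ground-truth RMSE columns.
    """
    ff_mode, fusion, spa, ft = condition
    if ff_mode not in FF_MODES:
        raise InvalidParameterError(f"stage flatfield: unknown ff mode {ff_mode!r}")
    if fusion not in stitcher.FUSION_METHODS:
        raise InvalidParameterError(f"stage fuse: unknown fusion method {fusion!r}")

    timings: dict = {}
    caught: list = []

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            with warnings.catch_warnings(record=True) as wrec:
                warnings.simplefilter("always")
                out = fn(*args, **kwargs)
            caught.extend(f"{name}: {w.message}" for w in wrec)
        except Exception as exc:  # noqa: BLE001 - stage identity attached
            raise StageError(name, exc) from exc
        timings[name] = time.perf_counter() - t0
        return out

    work = scan
    if ff_mode != "none":
        work = _stage("flatfield", flatfield.correct_scan, scan, ff_mode,
                      config.clip_floor)

    projected, margin = _stage(
        "stitch", _stitch_and_project, work, fusion, spa, config.thresholds
    )
    mosaic = projected.pixels
    if ft:
        spec = _resolve_crosshair(config.crosshair, scan.geometry)
        mosaic = _stage("freqfilter", freqfilter.crosshair_filter, mosaic, spec)

    if reference is None:
        reference, _ = _stage("reference", make_reference, scan, fusion, spa, config)
    ref_pixels = reference.pixels if hasattr(reference, "pixels") else reference

    g = scan.geometry
    roi_proc = metrics.extract_roi_mosaic(mosaic, g, config.roi_size,
                                          offset=(margin, margin))
    roi_ref = metrics.extract_roi_mosaic(ref_pixels, g, config.roi_size,
                                         offset=(margin, margin))
    r, pct = metrics.rmse(roi_proc.pixels, roi_ref.pixels)
    s = metrics.ssim(roi_proc.pixels, roi_ref.pixels)

    thr = config.mask_threshold
    if thr is None:
        thr = metrics.otsu_threshold_nonzero(mosaic)
    skew_x, kurt_x = metrics.profile_moments(metrics.axis_profile(mosaic, "x", thr))
    skew_y, kurt_y = metrics.profile_moments(metrics.axis_profile(mosaic, "y", thr))

    report = metrics.MetricsReport(
        rmse=r, pct_rmse=pct, ssim=s,
        skew_x=skew_x, kurt_x=kurt_x, skew_y=skew_y, kurt_y=kurt_y,
        condition=condition,
    )

    gt_rmse = gt_pct = None
    if truth is not None:
        h, w = g.mosaic_shape
        core = mosaic[margin : margin + h, margin : margin + w]
        gt_rmse, gt_pct = metrics.rmse(core, truth.pixels)

    return ConditionResult(
        condition=condition,
        mosaic=mosaic,
        report=report,
        gt_rmse=gt_rmse,
        gt_pct_rmse=gt_pct,
        timings=timings,
        warnings=caught,
    )


def run_grid(scan, config: PipelineConfig, truth=None) -> pd.DataFrame:
    """Run every grid cell; returns a tidy metrics table.

    Per-cell failures are recorded in the ``error`` column and the run
    continues.  When ``config.output_dir`` is set, per-condition mosaics,
    ``metrics.csv`` and ``heatmap.png`` are written there.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    ref_cache: dict = {}
    rows = []
    results = []
    for condition in config.conditions():
        ff_mode, fusion, spa, ft = condition
        key = (fusion, spa)
        try:
            if key not in ref_cache:
                ref_cache[key] = make_reference(scan, fusion, spa, config)[0]
            res = run_condition(scan, condition, config, truth=truth,
                                reference=ref_cache[key])
            if out_dir:
                import tifffile

                name = f"ff-{ff_mode}_fusion-{fusion}_spa-{int(spa)}_ft-{int(ft)}.tif"
                res.mosaic_path = out_dir / name
                tifffile.imwrite(res.mosaic_path, res.mosaic)
            rep = res.report
            rows.append(
                dict(
                    ff_mode=ff_mode, fusion=fusion, spa=spa, ft=ft,
                    rmse=rep.rmse, pct_rmse=rep.pct_rmse, ssim=rep.ssim,
                    skew_x=rep.skew_x, kurt_x=rep.kurt_x,
                    skew_y=rep.skew_y, kurt_y=rep.kurt_y,
                    gt_rmse=res.gt_rmse, gt_pct_rmse=res.gt_pct_rmse,
                    error="",
                )
            )
            results.append(res)
        except Exception as exc:  # noqa: BLE001 - per-cell failures recorded
            rows.append(
                dict(
                    ff_mode=ff_mode, fusion=fusion, spa=spa, ft=ft,
                    rmse=np.nan, pct_rmse=np.nan, ssim=np.nan,
                    skew_x=np.nan, kurt_x=np.nan, skew_y=np.nan, kurt_y=np.nan,
                    gt_rmse=np.nan, gt_pct_rmse=np.nan, error=repr(exc),
                )
            )
    table = pd.DataFrame(rows)
    if out_dir:
        table.to_csv(out_dir / "metrics.csv", index=False)
        _write_heatmap(table, out_dir / "heatmap.png")
    return table


def _write_heatmap(table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = table[table["error"] == ""]
    if ok.empty:
        return
    ok = ok.assign(
        row=lambda d: d.apply(
            lambda r: f"{r.ff_mode}|spa={int(r.spa)}|ft={int(r.ft)}", axis=1
        )
    )
    fig, axes = plt.subplots(1, 2, figsize=(10, 0.4 * ok["row"].nunique() + 2))
    for ax, metric in zip(axes, ("pct_rmse", "ssim")):
        pivot = ok.pivot_table(index="row", columns="fusion", values=metric)
        im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=45)
        ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=7)
        ax.set_title(metric)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
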