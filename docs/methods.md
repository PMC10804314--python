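# Methods

`mosaicfix` corrects grid-like *tiling artifacts* in stitched tile-scan
mosaics from automated scanning microscopes (two-photon autofluorescence /
SHG whole-slide imaging being the motivating modality). The artifact is a
periodic brightness modulation at the tile pitch, caused chiefly by per-tile
vignetting, and it confounds any quantitative analysis that compares regions
lying in different tiles. The package combines two corrections — a
retrospective flat-field (FF) division and a Fourier-domain "crosshair"
filter (FT) — around a translation-only stitching pipeline, and ships a
synthetic tile-scan simulator plus an evaluation suite so that every stage
can be scored against exact ground truth.

## Processing model

For a scan of `R x C` tiles of `T x T` 16-bit pixels acquired with overlap
fraction `f` (nominal pitch `p = T - round(f*T)` pixels) and `n_z` z-slices:

1. **Flat-field correction** (`flatfield`). The observed tile is modeled as
   `tile = gain(i,j) * scene + noise` with a smooth multiplicative gain
   (vignette). The gain is estimated from the tiles themselves: all tiles
   are averaged pixelwise (pooled over z in *cumulative* mode, per z-slice
   in *individual* mode) and max-normalized; least-squares straight lines
   are fitted to the row-mean profile `r(i)` and column-mean profile `c(j)`
   of the mean tile; the mesh is `outer(r_fit, c_fit)`, max-normalized and
   clipped below at `clip_floor` (default 0.05, bounding the correction at
   20x so dark corners do not blow up noise). Each tile is divided by the
   mesh and re-quantized. Lines that are more than 50% zero (pure
   background) contribute their nonzero mean to the profiles, consistent
   with the zero-ignoring conventions of the metrics.

   The mesh is *separable and linear* by construction. This is the only
   reading of a two-line-fit construction that yields a full-tile mesh; the
   consequences are testable: a separable linear ramp is recovered to 1e-6,
   whereas curvature (radial vignetting) is only partially captured and
   leaves a periodic residual for the frequency filter. Max-1 normalization
   (rather than mean-1) was chosen so gains never exceed 1 and corrected
   values only increase.

2. **Stitching** (`stitcher`). Adjacent (4-neighbor) tiles are registered by
   exhaustive normalized cross-correlation of their nominal overlap regions
   over integer shifts; ties go to the smaller shift. The search window is
   ±2x the absolute-displacement threshold: the window must exceed the
   rejection threshold, otherwise an out-of-range true offset is aliased
   onto the window edge with a deceptively high correlation and silently
   kept. With subpixel accuracy (SPA) enabled, the integer peak is refined
   by Fourier-upsampled cross-correlation of the mean-subtracted overlap
   strips (upsampling factor 50, ~0.04 px accuracy on realistic texture;
   simple parabolic peak interpolation was measured at ~0.12 px per link,
   too coarse to meet the 0.2 px placement target).

   Links are filtered with the plugin-default thresholds: correlation below
   the regression threshold 0.3 → `rejected_low_r`; shift magnitude above
   the absolute displacement 3.5 px → `rejected_displacement`. Tile
   positions are then solved globally by least squares over the pairwise
   offsets, anchored at tile (0,0). Every adjacent pair also contributes a
   weakly weighted (1e-4) nominal-offset equation, so the system stays
   connected and anchored even when links are rejected without dragging
   well-constrained tiles toward the nominal grid. The max/avg displacement
   threshold (2.5 px) is applied *against the global solution*: while the
   worst accepted link's residual exceeds the absolute threshold or the
   mean residual exceeds the max/avg threshold, that link is demoted and
   the solve repeated. (Filtering on deviation from the mean *shift*
   instead would mass-reject mutually consistent links under realistic
   independent stage jitter, whose neighbor offsets routinely exceed
   2.5 px.)

   Five fusion rules combine overlapping pixels: arithmetic average; linear
   blend with weights equal to each tile's distance to its own nearest edge;
   max, min and median order statistics (the median of two contributors is
   their mean). With SPA, tiles are bilinearly resampled to their subpixel
   positions before combination. Coordinates are 0-based pixel centers with
   half-open tile extents `[pos, pos + T)`. Per-z mosaics are fused on a
   common canvas and combined by pixelwise max projection to compensate
   focal-plane brightness drop-off.

3. **Crosshair frequency filter** (`freqfilter`). Horizontal/vertical
   tile-pitch periodicity concentrates on the zero-frequency row and column
   of the 2-D DFT. The filter takes the region `|u| <= halfwidth or
   |v| <= halfwidth` (default halfwidth 1), excludes DC, computes the
   threshold `tau = mean(log(1+|F|))` over the region, and suppresses every
   regional coefficient with `log(1+|F|) > tau` — either zeroed (default) or
   capped at magnitude `exp(tau)-1` with phase preserved (gentler; reduces
   the haloing that hard masking produces around high-contrast edges). The
   region is symmetric under frequency negation, so real input stays real;
   DC is untouched, so mean brightness is preserved up to the final clip to
   the input range. The filter always operates on the full stitched mosaic,
   never per tile.

   `min_frequency` optionally excludes the lowest frequencies from the
   region. A tiling artifact with period `p` has no energy below one cycle
   per pitch (≈ the tile count along the axis), whereas genuine global
   image structure concentrates exactly there; the pipeline therefore
   protects the sub-fundamental band by default (grid fundamental minus a
   2-bin leakage guard), which in measurement cut the filter's
   ground-truth content loss ~5x with unchanged stripe suppression. The
   standalone filter defaults to the full axis (`min_frequency=0`).

4. **Metrics** (`metrics`). Content retention is measured away from the
   corrected overlap zones on *ROI mosaics*: the central `roi x roi` crop
   (default 100 px for 256 px tiles) of every tile footprint, tiled in grid
   order. RMSE is reported both in digital numbers and as
   `%RMSE = RMSE/65535 x 100`. SSIM uses the Gaussian-weighted formulation
   (sigma 1.5, unit exponents, standard constants K1=0.01/K2=0.03 scaled by
   the data range). Brightness uniformity is quantified by the sample
   skewness and *excess* kurtosis (normal → 0) of the per-row (X) and
   per-column (Y) mean profiles, computed ignoring zeros and values below a
   background threshold (default: Otsu on the nonzero pixels); lines with
   no qualifying pixels are absent, not zero. Moments are computed on the
   profile values directly.

5. **Pipeline** (`pipeline`). The full grid — FF mode {none, cumulative,
   individual} x fusion {average, linear_blend, max, min, median} x SPA
   {off, on} x FT {off, on}, 60 conditions — is run per z-slice (FF per tile
   before stitching in both FF modes), max-projected, optionally filtered
   (always post-stitch), and scored against a reference produced by the
   identical stitching pathway with FF and FT disabled, so metric
   differences isolate the corrections. With simulator input, a
   ground-truth RMSE against the noiseless specimen is reported as well.
   The run is a pure function of (input, config, seed); per-cell failures
   are recorded and the grid continues.

## The simulator and what it does (not) emulate

`synthetic_scan` generates a specimen (Gaussian-smoothed white noise with
correlation length `texture_scale`, inside an irregular tissue blob whose
area fraction is set by quantile thresholding of a very smooth random field;
exactly zero outside), then renders tiles as overlapping crops at jittered
stage positions. Corruption model, in order: multiplicative vignette
(separable linear ramps x radial falloff centered at center+asymmetry,
max-normalized — multiplicative *before* noise, matching the division
correction); per-z defocus as isotropic Gaussian blur of width
`z_falloff*|z - z_focus|` plus `1/(1+sigma)` out-of-focus attenuation
(focus at the middle slice); Gaussian noise with variance
`noise_gain*signal + read_noise^2` (photon-like plus read floor, chosen over
true Poisson sampling to keep tiles bit-reproducible per seed); 16-bit
rounding and clipping. Stage jitter is N(0, jitter_sd) per axis per tile,
integer-rounded unless subpixel rendering is requested, and clamped so crops
stay inside the specimen.

Default study conditions: 10% overlap, 256 px tiles, 5 z-slices, grids from
7x7 up; vignette slopes 0.4 (rows) / 0.15 (cols), radial strength 0.25,
asymmetry 8 px (a pronounced top-to-bottom gradient with mild unevenness,
matching a badly vignetted autofluorescence channel); noise_gain 0.5,
read noise 2 DN; tissue fraction 0.6.

Not emulated: optical PSFs beyond Gaussian defocus, chromatic effects,
multichannel co-registration error, rotation/affine stage error, detector
nonlinearity, and structured (non-random) tissue morphology. Passing tests
therefore demonstrate correctness of the algorithms under a controlled
artifact model, not performance on arbitrary real tissue.

## Numerical choices and degenerate inputs

- All internal arithmetic in float64; quantization only at stage outputs.
- Correlation of constant overlap strips is defined as 0 (no signal).
- Canvas origins are floored after rounding at 1e-6 so solver noise cannot
  shift the frame by a pixel; per-z mosaics share one canvas (mosaic extent
  plus a margin of ceil(absolute_displacement)+2).
- If every link is rejected the solve falls back to the nominal grid with a
  warning; an all-zero mean tile, an empty tile selection, NaN inputs, and
  sub-4-px overlaps raise typed errors (`mosaicfix.errors`).
- Subpixel refinement corrections larger than 1 px are discarded (the
  integer search already chose a better peak).
- The tissue-mask quantile construction guarantees the requested tissue
  fraction; requests outside [0.4, 0.8] are rejected rather than silently
  regenerated.

## Problem sizes used by the test suite

Unit tests run on 2x2–6x6 grids of 24–128 px tiles. The acceptance tests
use: flat-field recovery on a 10x10 grid of 256 px tiles (slope-0.4 ramp,
low noise); registration recovery on 5x5 grids of 256 px tiles over 10
seeds with integer jitter SD 1.5 px, measured on fully textured specimens
(tiles lying wholly in zero background carry no registration signal and are
placed at nominal positions by design, so including them would measure
specimen coverage, not registration; position errors are compared after
removing the median offset, since a global translation is unobservable);
end-to-end condition ordering on 7x7 grids of 256 px tiles, 3 z-slices,
5 seeds.

## Known limitations

- The separable-linear mesh cannot represent radial or higher-order
  vignetting exactly; the residual is periodic and is what the crosshair
  filter targets. Strongly nonuniform specimens bias the mesh (correlation
  with the true field drops as tissue coverage falls — a measured,
  monotone effect).
- The crosshair filter trades genuine axis-aligned spectral content for
  artifact suppression. On textured specimens its ground-truth RMSE cost
  can exceed the energy of the post-FF periodic residual, so the combined
  FF+FT condition improves profile flatness and visual seam smoothness
  but does not necessarily improve ground-truth RMSE over FF alone; hard
  zeroing also produces haloing around high-contrast (SHG-like) edges,
  which the cap-at-threshold mode reduces.
- Registration is translation-only; rotation, scale and shear are out of
  scope, as are illumination-aware seam finding and out-of-core mosaics.
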