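# Methods

This note documents the models, conventions and parameter choices behind
`vasculometry`, what the synthetic generator does and does not emulate, and
the numerical decisions a user should know before trusting the output on
their own data.

## Vessel geometry and morphometry

Every lumen is summarized as an ellipse with semi-major axis *a* and
semi-minor axis *b* (μm). Three measurement modes produce these axes:

* **feret** (default for segmented regions): *a* is half the maximum and
  *b* half the minimum caliper width of the region — the same convention a
  microscopist applies when fitting an ellipse by hand to a lumen outline.
* **moment**: second-central-moment ellipse axes, provided as a cross-check;
  on cleanly rasterized ellipses the two modes agree within discretization
  error (tested at ≤5% median at 0.2 μm/px).
* **manual**: (*a*, *b*) pairs entered directly from hand measurements;
  lumen area is then the analytic π·a·b. Axes must arrive ordered
  (*a* ≥ *b*); a swapped pair raises rather than silently reordering,
  because a transposed column is a common and otherwise invisible data bug.

The idealized diameter d = (32(ab)³/(a²+b²))^(1/4) is the diameter of the
circular conduit with the same laminar conductance as the elliptical one;
it reduces to 2r for circles and is bounded above by the geometric-mean
diameter 2√(ab). The hydraulically weighted mean d_h = Σd⁵/Σd⁴ weights
conduits by their d⁴ conductance contribution, so d_h ≥ mean(d) always,
with equality only for uniform populations.

Relative lumen area is stored as a fraction in (0, 1]. Summary tables in
this field sometimes label the column "%" while printing fraction-magnitude
values; the API therefore exposes both readings (`A_lumen_rel`,
`A_lumen_pct`) and never rescales silently.

### Feret calipers

Calipers rotate in 1° steps over the convex hull of the region's
**subpixel boundary** — the marching-squares contour of the binary mask at
the 0.5 level, which places the boundary midway between the outermost
foreground pixel centre and the adjacent background centre and is therefore
a pointwise-unbiased estimate of the pre-rasterization outline. Calipering
the pixel *footprint* instead (the union of squares) systematically
over-measures: boundary squares protrude by up to half a pixel diagonal,
the max-Feret search selects exactly those directions, and the resulting
1.5–3% diameter bias at 0.2 μm/px is amplified to 6–12% in K by the
fourth power. The 1° angular resolution under-measures a smooth caliper by
at most (1 − cos 0.5°) ≈ 4×10⁻⁵ relative, far below pixel effects.

## Segmentation

The stage is deliberately simple and fully parameterized
(`SegmentationParams`): Gaussian smoothing (`smoothing_sigma_px`, default
1 px), global threshold (Otsu by default, fixed value optional), lumen
polarity (`bright`/`dark`), hole filling, 8-connected labelling, then area
(`min_area_um2` 3, `max_area_um2` 2000) and solidity (`min_solidity` 0.8)
filters. The solidity filter rejects concave fragments (ray parenchyma,
broken walls); the area range brackets the plausible lumen sizes at the
working magnification. Touching lumina are **not** split — no watershed —
so the stage is auditable and its failure mode (a merged pair) is visible
in the label raster; the synthetic generator guarantees separation, and
splitting is future work. Lumen area is always pixel count × pixel area, so
the label raster and the reported areas agree exactly.

## Hydraulics

K = (πρ / 128η·A) Σd⁴ with η = 1.002×10⁻⁹ MPa·s, ρ = 998.2 kg m⁻³ (water,
20 °C). Diameters convert μm→m and the region area μm²→m² inside this
module only, through two named constants — the d⁴ term turns any silent
unit slip into an error of 10⁴ per decade, so conversion is deliberately
single-sited.

The size-class decomposition uses right-open 4-μm bins, default
[0,4), [4,8), [8,12), [12,16), [16,20); a vessel at or beyond the last edge
goes to a flagged overflow class rather than being dropped. Each class's K
is computed against the **total** region area, which is what makes class
conductivities sum exactly to the total (additivity of Σd⁴); normalizing
per-class areas would break that conservation. A vessel exactly on an edge
belongs to the upper class (right-openness), a documented tie-break.

The replicate coefficient of variation uses the sample (n−1) standard
deviation, appropriate for the 3–4 replicates typical of anatomical
studies.

This is *potential* conductivity of open ideal conduits: pit membranes, end
walls, conduit connectivity and cavitation are all outside the model, and
measured conductances in real tissue are orders of magnitude smaller.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, with
known ground truth:

* **Vessel populations.** Diameters from a lognormal (default
  μ = ln 7, σ = 0.35 on the log scale — median 7 μm with most mass in
  4–13 μm, matching the observed receptacle size range) or an explicit
  five-class mixture of uniforms for class-structured truths. Aspect ratios
  b/a uniform on [0.7, 1] (near-circular lumina), orientations uniform.
  Placement is rejection sampling on a pixel raster (default 0.2 μm/px, a
  plausible high-magnification light-microscopy scale): each candidate
  ellipse is rasterized, dilated by `min_gap_px` (default 2), and accepted
  only if it touches no accepted lumen — simple and exactly auditable, with
  a hard attempt cap (10⁵) so an infeasible density fails loudly. The
  default region (76,400 μm² for 250 vessels) reproduces the observed
  vessel-density scale (~3270 mm⁻²).
* **Images.** Filled ellipses at `lumen_level` (0.85) over
  `background_level` (0.15), i.i.d. Gaussian noise (default sd 0.05),
  clipped to [0,1], written as 16-bit grayscale with a CSV ground-truth
  sidecar. The derived truths (d per vessel, d_h, VD, relative lumen area,
  K) are computed by the same morphometry/hydraulics operations applied to
  the true geometry, so truth is self-consistent by construction.
* **TSS series.** The constrained logistic plus additive Gaussian noise.
* **Area pairs.** Bivariate normal with population correlation exactly
  `target_r`; A_xylem has a fixed 25% CV, A_phloem relative spread is the
  `noise` parameter, and the regime sets the mean ratio
  (receptacle 0.2 — xylem ≈ 5× phloem; brush 2.0 — phloem ≈ 2× xylem).
  Non-positive draws are resampled (negligible at these CVs).

What it does **not** emulate — and what passing recovery tests therefore do
not demonstrate about real images: staining variability and fluorescence
physics, uneven illumination, touching or collapsed vessels, rays and
parenchyma interspersed with lumina, out-of-plane sectioning, and
non-elliptical lumen outlines. Recovery numbers here bound the
*discretization and noise* error of the chain, not biological measurement
error.

## Ripening kinetics

Y(x) = Y_M·Y_0 / ((Y_M−Y_0)e^(−kx) + Y_0) with Y_0 box-constrained to
[0, 5] °Brix and Y_M fixed at 32 °Brix (estimable via `estimate_ym=True`
for sensitivity analysis). Fitting is bounded least squares with an 8-point
log-spaced multistart on k over 10⁻³–1 day⁻¹, which avoids the flat
lag-phase local minima. A flat series leaves k unidentifiable and is
returned with a `degenerate` flag instead of a silent boundary estimate.

Model comparison uses the least-squares small-sample AIC,
AICc = n·ln(RSS/n) + 2p + 2p(p+1)/(n−p−1), with p counting (Y_0, k) per
shared-curve group plus one common residual-variance term; candidate
partitions always include fully pooled and fully separate, plus any
user-specified groupings. The AICc (rather than plain AIC) choice matters
at these n (≈12 points per series) and follows the convention of the
graphing packages standard in this field; the formula is centralized in
`aicc_from_rss` and switchable. In simulation at 0.5 °Brix noise, the
pooled model is selected ≥90% of the time when true, and the
0.07 vs 0.10 day⁻¹ rate contrast — the scale of real cultivar differences —
is resolved essentially always.

## Tissue allocation

Areas come from hand-traced binary masks (the package does not
auto-segment xylem vs phloem tissue); area = pixel count × pixel area.
When only a quadrant of a section fits the field of view, both areas are
multiplied by 4 and the record flagged — the extrapolation assumes radial
symmetry, and it cancels exactly in every ratio and correlation.
Correlations are plain Pearson r with the t-based two-sided p; the
headline contract is the estimate and n, with p reported alongside rather
than used as an acceptance surface.

## Comparative statistics

One-way designs use the classical decomposition. Two-way (possibly
unbalanced, n = 3 vs 4) designs default to partial Type-III sums of squares
with sum-to-zero contrasts, switchable to Type II — the SS family is a
genuine free choice for unbalanced data and is therefore explicit. Model
fitting is statsmodels OLS; the module owns design handling, Fisher's LSD
and the compact letter display.

Fisher's LSD is the unadjusted pairwise t on the pooled error MS and error
df. By default it is *protected*: it refuses to run when the omnibus effect
is not significant at α (override available, and required for studying the
unadjusted test's calibration — per-pair type-I error ≈ α, verified by
simulation). Letters are assigned by deterministic insert-and-absorb with
alphabetical tie-break, so letter displays are stable snapshot targets.
A Tukey–Kramer HSD with the same interface covers the occasional analysis
that calls for family-wise control; its p-values are verified against an
independent implementation.

## Pipeline

`run_pipeline` executes simulate → render → segment → morphometry →
hydraulics per replicate from a single config (dict or YAML), writing CSVs,
16-bit TIFFs, a human-readable report and a provenance record (config hash,
seed, package version, SHA-256 of every output). A rerun with an unchanged
config reuses the cached outputs; outputs are bit-for-bit reproducible for
a fixed seed. Config validation happens before any stage runs.

## Problem sizes and test design

The test suite and `scripts/acceptance.py` run entirely on synthetic data:
recovery runs use 250 vessels per replicate at 0.2 μm/px (three replicates
in the acceptance script), the resolution study compares 0.4 vs 0.1 μm/px
on the same population, logistic simulations use 12 timepoints over 40–130
days after anthesis with 0.5 °Brix noise and 100 seeds, and the LSD
calibration uses 3 groups × 4 replicates over 500–1000 simulated nulls.
These sizes mirror the scale of the motivating measurements while keeping
the full suite fast enough to run on every change.

## Known limitations

* No watershed splitting of touching lumina; merged vessels bias d upward
  and n downward on crowded real images.
* Global thresholding assumes reasonably uniform illumination.
* The quadrant ×4 extrapolation assumes radial symmetry of the section.
* Potential (not measured) conductivity only.
* The Type-III vs Type-II choice can matter for strongly unbalanced
  two-way designs; both are exposed, neither is adjudicated here.
* The fraction-vs-percent reading of "relative lumen area" in legacy
  tables is ambiguous; both are reported.
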