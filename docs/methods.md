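# Methods

## Phantom model

A phantom is a union of an axis-aligned (optionally in-plane rotated) core
ellipsoid and `n_lobes` satellite ellipsoids, rendered onto a CT-like voxel
grid. Satellites are scaled copies of the core (`lobe_scale`, default
0.25–0.4 of the core diameters) centred at `lobe_centre_frac` (default 0.85)
of the way to the core surface along a random direction, so they read as
surface lumps rather than detached blobs. `n_lobes = 0` is labelled
*regular*, anything lobed *irregular*. This one-knob irregularity model was
chosen because the union of ellipsoids keeps an exactly computable oracle
volume while producing the bumpy outlines and lumpy per-slice area profiles
that stress the slice-weighting of modified ABC/2.

**Rendering.** Voxel HU is a partial-volume mixture,
`occ·HU_lesion + (1−occ)·HU_background`, with sub-voxel occupancy `occ`
estimated by 4× supersampling per axis. Defaults: background 30 HU, lesion
mean 65 HU, global Gaussian acquisition noise SD 4 HU — values that keep
lesions inside the 40–80 HU range typical of acute blood on non-contrast CT.
Intra-lesion heterogeneity is a Gaussian random field (white noise smoothed
with σ = 2 voxels in-plane, 1 through-plane) scaled so that the
occupancy-weighted field SD on the lesion-dominant voxels of the largest
slice equals `hetero_sd_hu`; that slice is where the density index is
measured, and a correlated field carries less variance per slice than over
the whole volume, so normalising anywhere else under-delivers the requested
contrast. Slice thickness is a per-slice vector; a preset reproduces the
thin-below/thick-above acquisition style (4 mm then 8 mm) that defeats
region-growing tools which assume uniform stacks.

**Ground truth.** The oracle volume is computed by voxelising the analytic
union on a fine grid (quarter of the rendered spacing per axis) independent
of the rendered image — accurate to <0.5 % for ellipsoids. The oracle
longest 3D diameter comes from the convex hull of surface samples of the
union. The ordinal 1–5 density class is a generator-side surrogate (bins of
0.05 in generating CV); it is not calibrated to any visual rating study.

**Default cohort** (`CohortConfig`): n = 100; longest-core-diameter
categories <3 / 3–4.9 / 5–8 / >8 cm with proportions 0.41 / 0.41 / 0.16 /
0.02; probability of irregular shape increasing with size category
(0.50 / 0.65 / 0.85 / 0.95, overall ≈ 0.63) — in real cohorts larger
haematomas are disproportionately irregular, and the size–shape coupling is
what makes shape-stratified method differences reproducible; heterogeneity
SD uniform on 0–12 HU; 4 mm slices, 1 mm in-plane. The lobe embedding depth
was calibrated once so that ABC/2 tracks planimetry at the cohort level (the
behaviour reported for human cohorts) rather than systematically
overestimating it, as fully protruding satellites make it do; it was then
frozen. Cohort generation is a pure function of (config, seed).

## Measurement conventions

* All internal lengths are mm; diameters are reported in cm and volumes in
  cm³, converted only at the reporting boundary.
* **Segmentation** keeps the connected component (26-connectivity default)
  containing the seed, or the largest without one. Per-slice interior holes
  are filled by default: a planimetric ROI is the traced outline of the
  lesion, so hypoattenuating interior counts toward the area, as it does
  when a boundary is drawn or edited by hand. Voxel-level include/exclude
  edits are applied last, include overriding exclude.
* **HU window.** `window_from_tissue` derives the window the way an
  operator samples lesion and brain: lower bound at the tissue midpoint,
  upper bound a margin above the lesion mean. On partial-volume boundaries a
  midpoint threshold admits a voxel exactly when lesion occupies its
  majority, which keeps voxel-count volumes unbiased; a permissive fixed
  lower bound (e.g. 40 HU against a 65/30 phantom) admits minority-occupancy
  boundary voxels and inflates volume by ~5 %. Real thresholded ROIs share
  both behaviours; accuracy claims in the tests are stated at the sampled
  window.
* **Callipers.** A and B are measured on the sub-voxel lesion boundary: the
  iso-attenuation contour at the segmentation's lower bound where the image
  carries a partial-volume gradient, else the 0.5-level contour of the
  binary mask. The binary contour realises a count-based extent convention —
  `(max index − min index + 1) × spacing` along axis-aligned directions, one
  spacing for a single voxel — while avoiding the ~3 % diagonal-chord
  overshoot of literal centre-distance-plus-one-spacing rules. B is taken on
  the same slice as A (the slice is not fixed by the bedside protocol;
  same-slice matches workstation practice), as the boundary's extent
  perpendicular to the A direction. Ties on A break toward the lower slice.
* **C extent.** Standard C sums the thicknesses of slices containing any
  lesion voxel — the natural generalisation of "thickness × slice count" to
  variable-thickness series. Modified C weights slices 0 / 0.5 / 1 by area
  relative to the largest slice; areas exactly at the 25 % and 75 % cut-offs
  take weight 0.5.
* **Size categories** use half-open bins [0,3), [3,5), [5,8], (8,∞) cm;
  5.0 cm falls in "5–8" because the printed 3–4.9 and 5–8 categories are
  adjacent and exhaustive.
* **Perimeter** comes from the same sub-voxel contour as the callipers, not
  boundary-voxel counting (which biases a disc's perimeter upward by tens of
  percent) and not Crofton intercepts (accurate for discs but ~8 % low for
  axis-aligned polygons). The shape-index formula is a swappable strategy;
  circularity `P/(2√(πA))` is the default, the isoperimetric quotient
  `P²/(4πA)` is provided as an alternative.

## IVH scoring schemas

Schemas are YAML data, not code. The classic scale scores each lateral
ventricle 1 (trace) / 2 (≤ half) / 3 (> half) / 4 (full and expanded) and
the third and fourth ventricles 1 (blood present) / 2 (filled and expanded),
maximum 12; only the scale's endpoints are fixed by its usual one-line
description, and the interior levels follow the original scale. The modified
scale scores eight compartments (left/right frontal-horn-plus-body, temporal
horn, occipital horn; third; fourth) 1–4 by quartile of filling, maximum 32.
A per-ventricle expansion bonus is exposed as a schema flag and is off by
default: a four-compartment reading of the prose cannot reach the printed
maximum of 32, so the default schema honours the printed maximum and leaves
the bonus opt-in (enabling it raises the attainable maximum above 32).
"Trace" is a flag distinct from an epsilon fill fraction, because the
classic scale treats trace as its own state. States expressed in the fine
eight-compartment vocabulary are scored on the classic scale by averaging
each side's compartments.

The random ventricular-state generator draws a per-subject severity level
(Beta(1.5, 2.5)) shared across compartments with SD-0.2 jitter, occasional
trace states, and expansion of near-full ventricles — IVH spreads through
connected compartments, and the shared severity is what gives the two scales
their strong empirical rank correlation.

## Statistics

ICCs are computed from the two-way mean squares (subjects, raters, error) of
a complete grid; both single-measure forms are always labelled: absolute
agreement ICC(2,1) (default — observers are interchangeable raters of the
same scans) and consistency ICC(3,1). Missing cells are an error, never
imputed. Bland–Altman reports mean difference, SD, 1.96-SD limits of
agreement and the OLS regression of difference on pairwise mean
(proportional bias appears as a nonzero slope). Paired comparisons use the
paired t-test by default (Wilcoxon as an option); no multiple-testing
correction is applied. Spearman correlation uses average ranks for ties.

## Observer model

Human measurement variability is simulated as: multiplicative log-normal
error on the A and B callipers (`diameter_error_sd`, default 0.05), a
probability of toggling inclusion of slices with <10 % of the maximal area
(default 0.1), and uniform jitter on both HU window bounds (default
±2 HU). Sessions are independent noise draws with the same parameters —
repeat readings weeks apart and blinded are well modelled as exchangeable.
A zero-noise model reproduces the direct measurements bit-exactly. The
defaults are surrogates tuned only to land intra-/interobserver ICCs in the
high-reliability range reported for trained observers; reports carry a note
saying exactly that. No published quantitative error model for this task
exists to calibrate against.

## Problem sizes and numerics

The default study renders 100 phantoms (about 15 s) and measures each with
2 observers × 2 sessions; reference tests use 20–60 mm noise-free phantoms
at 1 mm grids, where the oracle, calliper and planimetry errors are all
below 1 %. ICC calibration checks use 200 replicates of 500 subjects × 2
raters. All randomness flows from explicit integer seeds through
`numpy.random.Generator`; identical (config, seed) inputs give bit-identical
phantoms, manifests and reports.

## What passing tests do and do not show

The phantoms emulate: hyperattenuating lesions on a uniform brain-like
background, partial-volume boundary blur, global acquisition noise, smooth
intra-lesion heterogeneity, lobulated shapes, variable slice thickness, and
a realistic size/shape case-mix. They do not emulate skull and beam
artefacts, perihaematomal oedema, ventricular or subarachnoid anatomy
(ventricular states are generated parametrically, never rendered),
scanner-specific reconstruction, or human perceptual errors beyond the
parametric observer model. Results on phantoms therefore demonstrate
estimator correctness and the geometry-driven component of method
disagreement — e.g. that modified ABC/2's slice down-weighting produces
size-dependent underestimation — but not the full error budget of clinical
measurement.
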