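# Methods

This note documents the models, conventions and numerical choices
behind `amoemig`, in the spirit of the model documentation of packages
like msprime or statsmodels: what is computed, under which assumptions,
and what the synthetic validation does and does not show.

## Coordinate, time and unit conventions

Positions are physical micrometres with the origin at the image
upper-left corner, x along columns, y along rows (increasing downward).
Frames are 0-based and the time of frame *k* is *k*·Δt, so with the
default acquisition (Δt = 10 s, 60 frames) the final frame sits at
t = 590 s. Spots tables use the common tracking-export CSV dialect
(`TRACK_ID, FRAME, POSITION_X, POSITION_Y, POSITION_T, QUALITY`),
overridable by a column map; non-numeric header-continuation rows that
some exporters emit below the header are skipped.

Only *complete* tracks — frames 0…59 with no gaps — enter the
statistics. Gap-closed tracks keep their bridged frames absent and are
therefore dropped by this filter; an optional linear interpolation
across closed gaps exists but is off by default, since nothing in the
upstream convention specifies whether bridged detections should be
fabricated.

## Trajectory statistics

For a track p₀…p₅₉:

* path length D = Σ|pₖ₊₁ − pₖ|; displacement d = |p₅₉ − p₀|;
  confinement ratio CR = d/D. A perfectly stationary track has CR
  = 0/0; it is carried as NaN and excluded from aggregation rather than
  forced to a value.
* maximum distance traveled defaults to the all-pairs diameter
  max_{i<j}|pᵢ − pⱼ|. A `from_origin` mode (max |pₜ − p₀|) is provided
  because the homonymous feature of common tracking software measures
  distance from the start; the two differ on looping tracks, and both
  are exposed.
* median speed = median over steps of |pₖ₊₁ − pₖ|/Δt (uniform Δt
  required).
* the directionality-ratio (CR-decay) curve is d(t)/D(t) per timepoint;
  timepoints with zero running path length are NaN.
* MSD uses overlapping time-averaging over all lags 1…T−1 (the
  behaviour of the standard spreadsheet macro used in this field);
  plots conventionally cap lags at (T−1)/2 because long-lag estimates
  average few intervals, but tables carry the full range.

Aggregation is two-stage and replicate-aware: within each replicate the
per-cell curves are reduced (median per timepoint for CR decay, mean
for MSD — matching how the two curves are conventionally reported),
then replicates are combined as mean ± sample SD (ddof = 1). NaNs are
dropped per timepoint.

## Replicate statistics

Cells within a replicate are not independent samples, so all tests run
on replicate medians (the SuperPlot convention): duplicating every
cell-level list changes nothing. One-way fixed-effects ANOVA is
computed from the explicit sum-of-squares decomposition with p from
F(k−1, N−k). The post hoc test is Tukey–Kramer: q = |mᵢ −
mⱼ|/√(MSW/2·(1/nᵢ + 1/nⱼ)) against the studentized range distribution
with N−k error df, valid for unequal replicate counts (designs with
n = 4 vs n = 5 occur routinely). Error bars on condition summaries are
sample SDs of the replicate medians; even-length medians are midpoint
averages. No correction beyond Tukey is applied.

Transwell normalizations: percent of input = 100·migrated/input;
migration index MI(c) = count(c)/count(reference), so the unstimulated
reference is exactly 1. A zero reference count makes the fold change
undefined; the result is flagged not-computable (NaN) instead of raised,
because that situation occurs in practice with essentially non-migrating
lines.

## Nucleus detection and linking

Detection is a scale-normalized Laplacian of Gaussian at
σ = diameter/(2√2) pixels (the LoG optimum for a blob of that
diameter). The DC offset is removed before filtering so kernel
truncation on a flat background cannot produce spurious response.
Candidates are 3×3 local maxima of the negated response; sub-pixel
positions come from a per-axis three-point parabola clamped to ±0.5 px.
Quality is the response divided by the brightest response of the movie,
making the 0.2 default threshold a unitless fraction — the absolute
quality scale of the original tracking tool is tool-internal, so a
relative definition is documented instead.

Linking solves each consecutive frame pair as an optimal assignment
(Hungarian algorithm) over squared distances within the 10 µm linking
radius, with a no-link alternative priced just above the radius;
unmatched detections start or terminate tracklets. Gap closing joins a
tracklet end to a later start when the frame gap is ≤ 2 and the
distance ≤ 15 µm, greedily by ascending distance. This is a
simplification of the full two-pass linear-assignment tracker; at the
cell densities this assay uses (well-separated nuclei) it is
behaviourally equivalent, which the end-to-end recovery property
checks (≥ 95% of tracks recovered spot-for-spot, mean position error
≤ 0.5 px on the default 20-cell movie). No drift correction is
implemented: synthetic movies are drift-free by construction.

## Vesicle-dispersion scoring

Segmentation: linear contrast stretch saturating 0.35% of pixels (the
common default of interactive imaging software; configurable), Gaussian
blur σ = 2 px, Huang fuzzy thresholding on the 256-bin histogram,
largest connected component. The Huang threshold minimizes the total
Shannon entropy of fuzzy memberships u(g) = 1/(1 + |g − μ_region|/C)
over all candidate levels, ties broken toward the lower level; the
implementation is verified against exhaustive minimization. Cells
touching the image border are flagged and excluded from scoring, as
cells in contact with the edge or with other cells cannot be scored
reliably.

Both scores reduce a cell to the median of all pairwise distances
between vesicle loci (µm):

* **Grid method**: the mask bounding box is tiled with 3×3-px squares
  (0.238 µm² at the default 0.1626 µm/px); squares whose *center pixel*
  is inside the mask are kept (the original subdivision script's
  inclusion rule is unpublished; the center rule is deterministic).
  Each square is summarized by its median raw intensity, and squares
  above 2× the *minimum square median of that cell* are
  vesicle-positive — the threshold is relative because absolute
  staining intensity varies between cells. Interpreting the "2×
  minimum" against the square-median table (not the global pixel
  minimum) follows from the threshold being applied to the square
  table; the alternative is a config switch. Square centroids are the
  loci. Cells with fewer than 2 positive squares are flagged
  `too_few_loci` and excluded.
* **Maxima method**: topographic prominence — the height of a maximum
  above the highest saddle connecting it to any *strictly higher*
  maximum — is computed by a union-find flood from the top intensity
  level down; maxima with prominence > 200 (raw units of the stored
  bit depth; the default presumes 16-bit data and should be scaled for
  8-bit images) are kept, the global maximum always. A connected
  plateau yields one locus at its centroid. Equal-height twin peaks
  joined by a low saddle both count, per the strict definition. The
  implementation is verified against an exhaustive saddle-search
  oracle.

## Synthetic data

The generators emulate the statistical structure of the assay, not its
physics; there is no confinement mechanics, chemotaxis or pharmacology.

* **Persistent random walk** (migratory phenotype): 2-D OU velocity
  with correlation time P (default 60 s) and stationary mean speed
  0.1 µm/s (per-axis σ_v = mean_speed·√(2/π)). Positions are the exact
  time integral of the velocity, sampled jointly with it using the
  analytic integrated-OU covariance, so the ensemble MSD equals the
  Fürth form 4σ_v²P·[t − P(1 − e^(−t/P))] exactly at the sample times
  — a naive Euler integration biases the fitted persistence time by
  ~15% at Δt/P = 1/6, which matters when recovery within 20% is the
  validation target.
* **Anchored oscillator** (nonmotile phenotype): AR(1) jitter around a
  fixed anchor with stationary per-axis SD a = 1 µm and mean per-frame
  step 2 µm. Those two constraints force the AR(1) coefficient to
  ρ = 1 − (step·√(2/π))²/(2a²) ≈ −0.27: the nucleus overshoots back and
  forth across the anchor, which is precisely the protrusion-driven
  jiggle being modelled. Note a consequence: with anti-correlated
  positions the pairwise-difference SD is ~1.6a per axis, so over 60
  frames the maximum excursion occasionally exceeds 6a (a Gaussian
  union bound puts P(max > 9a) below 10⁻³, which is what the test
  asserts, along with duration-independence of the excursion). At the
  defaults the dissociation is large: median path/max-distance ≈ 22
  for the oscillator vs ≈ 1.9 for the walker.
* **Nucleus movies**: each nucleus is a 2-D Gaussian (σ = 5.4 px,
  ~10 µm diameter at 0.65 µm/px — a 10× objective scale) on constant
  background with additive Gaussian noise, 16-bit; defaults give
  peak/noise ≈ 130. The default scene places up to 20 cells on a
  jittered grid with margins that keep walkers inside the field.
* **Vesicle scenes**: an elliptical cell (radius 8 µm, axis ratio 1.3)
  of *weak* diffuse intensity (120 over a 200 background) with
  Gaussian puncta (σ = 1.5 px, peak 3000) placed uniformly over the
  cytoplasm (dispersed) or over a polar cap holding 20% of the cell
  area (polarized — the uropod-accumulation geometry). The diffuse
  signal is deliberately weak relative to the puncta: the grid method's
  2×-minimum rule presumes vesicle squares stand out over the
  cytoplasmic level, as they do with a membrane stain; with a bright
  diffuse cytoplasm the rule saturates and the score degenerates to
  cell geometry. This is a documented regime of the method, not of the
  implementation.

All generators are pure functions of parameters and seed
(bit-reproducible).

## What the synthetic validation does not show

Synthetic nuclei are isotropic Gaussians on clean backgrounds; real
nuclei deform, defocus, vary in brightness, and the stage drifts (real
pipelines run a stabilization step first, which this package does not
implement). Synthetic vesicle scenes have a single cell per crop,
even background and isotropic puncta; real fields need cropping, have
uneven background, and contain touching cells that must be excluded by
eye or by the border flag. Passing tests therefore validate the
*computations* — the metric definitions, the estimators, the scoring
procedures and their statistics — not the robustness of detection or
segmentation to real-microscopy nuisance factors.

## Problem sizes

The validation suites use 100 random tracks (T ≤ 20) for oracle
equivalence, 200 tracks per arm for the dissociation fixture, 1000
tracks for the Fürth fit, a 20-cell 60-frame movie for tracking
recovery, 50 histograms / 8 toy images for the segmentation oracles,
and 50 + 50 cells in 5 replicates for dispersion discrimination —
sizes at which every stochastic check is stable across seeds while the
whole suite runs in well under a minute of compute per property.
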