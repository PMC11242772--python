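# Methods

## Relative-distance model

A ribbon cross-section is annotated by a simple closed polygon (outer
border) and an open polyline through its center (midline, the connected
sequence of manually placed midpoints; no smoothing or resampling is
applied — the reference line is exactly the connected midpoints). For a
particle at `p`, `d1` is the minimal Euclidean point-to-segment distance
to the midline polyline and `d2` the minimal distance to the border
(closing edge included). The relative distance is `d1/(d1+d2)` for
particles inside the border and `d1/(d1−d2)` outside. Both are ratios of
lengths, hence dimensionless and invariant under rigid motion and uniform
scaling; this is the point of the normalization, since the apparent width
of a sectioned ribbon depends on the section angle.

Distances and containment are computed with Shapely's exact planar
predicates. Conventions and guards:

- **Boundary convention.** A particle exactly on the border counts as
  inside with `d_rel = 1` (the limit of the inside formula as `d2 → 0`).
  This makes the inside/outside partition exhaustive and both formulas
  continuous at the border.
- **Degenerate outside records.** Outside a convex-enough annotation
  `d1 > d2` always holds, but manual annotations can produce near-equal
  values; when `d1 − d2 ≤ 1e−9·d1` the record is flagged degenerate,
  logged, and excluded from histograms, summaries and tests (the count is
  always reported).
- **Invalid annotations.** A midline touching the border at a particle
  (`d1 = d2 = 0`) and self-intersecting outlines are errors; in batch
  processing the offending annotation is skipped with a logged error and
  the run continues.
- The manual inside/outside color class is advisory: containment is
  recomputed and disagreements logged. `trust_annotation_class=True`
  honors the manual class instead, reproducing workflows that routed the
  two formulas by marking color.
- Coordinates are 0-based pixel coordinates, y down. All outputs are
  dimensionless, so the convention cannot leak into results.

The analysis is purely 2-D; distances through the section thickness and
geodesic (curvature-following) midline distances are out of scope.

## Histogram and logistic profile

`d_rel` values are binned at width 0.1 over [0, 13] (right-open bins, last
bin closed; values beyond the range are tallied as overflow and reported).
The bin width is a package default chosen to give ≥10 bins across the
on-ribbon interval [0, 1] at typical particle counts; it is configurable,
as is the range. The pooled per-group histogram is fitted with

    f(x) = a2 + (a1 − a2) / (1 + (x/c)^p),  c > 0, p > 0,

by nonlinear least squares on (bin-center, count) pairs
(`scipy.optimize.curve_fit`, initialization `a1 = max count, a2 = 0,
c = 1, p = 3`, positivity bounds on `c` and `p`, parameter tolerance
1e−8). Fits are to counts pooled per group by default (one curve per
antibody); per-replicate fits are available behind
`per_replicate_fit=True` for spread estimation. Failure modes are
explicit: fewer than five non-empty bins raises an underdetermined-fit
error (a model layer records the fit as unavailable and continues), a
non-converged optimizer is returned with `converged=False`, and a flat
fitted curve (`a1 ≈ a2`) is flagged `identifiable=False` since `c` and `p`
are then arbitrary.

Midline normalization divides the curve by `f(0) = a1` and scales to
percent; since this only rescales `a1` and `a2`, no refit is needed, and
the operation is idempotent and scale-invariant. The sup-norm difference
of two normalized curves on [0, 1] is reported as the comparison scale
between groups.

## Group statistics

The statistical replicate is the immunolabelled grid (grids nested in
mice/embeddings). Per replicate the pipeline reports particles-per-ribbon
inside (`d_rel ≤ 1`) and outside (`d_rel > 1`) and the percentage of all
particles in each class (the two percentages sum to 100 by construction).
Groups (antibody × location) are compared with a Kruskal–Wallis test on
replicate-level values and Dunn's post hoc pairwise z tests with tie
correction; adjusted p-values are unadjusted p times the number of
pairwise comparisons, capped at 1 (Bonferroni, the convention of common
plotting/statistics software; the method name is recorded in the output).
Dunn's test is implemented directly (rank sums, tie-corrected variance)
because no maintained post hoc package is part of the dependency set; it
is validated against a hand-computed no-ties case and the global test
against a permutation null. Box-plot statistics follow a fixed depiction
contract: Q1–Q3 box, whiskers at the 5% and 95% quantiles (linear/type-7
quantile definition, documented and fixed), thick mean and thin median
lines, diamonds for points beyond the whiskers.

When both samples passed to the global test are identical, the comparison
short-circuits to `H = 0, p = 1` rather than erroring on zero variance.

## Synthetic data generator

The generator emulates the study conditions so that every pipeline stage
is testable against known ground truth:

- **Geometry.** Ribbon width ~ U[30, 40] nm, length ~ U[300, 600] nm, at
  1.2 nm/px so the width spans 25–33 px (the scale of high-magnification
  acquisition). The midline is a 5–20 vertex polyline whose heading
  drifts by at most 25° in total (gentle curvature, matching manually
  marked ribbons); the outline is the midline buffered by the half-width
  with rounded end caps.
- **Radial density.** Particle positions are uniform in arc length along
  the midline with the radial coordinate following a density model of
  `d_rel`: uniform-inside, the clipped logistic `max(f, 0)` (published
  asymptotes are slightly negative, hence the clip), or monotone
  gradients `(1−r)^q` / `r^q` for center-/surface-weighted hypotheses.
  Sampling is by rejection against the *exact* `d_rel` recomputed from
  the generated geometry, so generator and analysis share one distance
  definition. Proposals are uniform in the normal offset, which maps
  linearly to `d_rel` on straight segments; residual curvature bias is
  negligible at the default bend angles. A 1-D sampler (`sample_drel`)
  draws scalar `d_rel` values directly for distribution-level
  experiments.
- **Label displacement.** A single isotropic 2-D Gaussian with σ = 10 nm
  by default, bracketing the IgG size (max dimension 14.5 nm) plus the
  5 nm gold conjugate; an explicit antibody-arm/gold linkage model is not
  attempted because only size bounds are known. σ is configurable for
  bracketing studies. At the default σ, displacement moves an appreciable
  fraction of near-border particles off the ribbon: with all true
  positions on the ribbon, observed on-ribbon fractions land around
  60–75% depending on the density model — the regime real labelling
  experiments report.
- **Background.** Nonspecific particles are Poisson with rate
  2 /µm² over the annotation frame (a deliberately small negative-control
  level; real nonspecific rates depend on blocking quality and are
  configurable).
- **Counts and hierarchy.** Particles per ribbon are Poisson with mean 15
  (plausible for labelled ribbon cross-sections; a config value, not a
  claim), in a 3 mice × 3 grids × 10 ribbons hierarchy. One seed
  determines every draw; identical configs serialize byte-identically.

What the generator does *not* model: 3-D section geometry and surface
labelling (the analysis itself is 2-D), electron-optical image formation,
antibody binding chemistry, and spatial clustering of epitopes. Passing
recovery tests therefore demonstrate correctness of the measurement and
inference chain under the stated generative assumptions, not the validity
of those assumptions for any particular micrograph.

The gradient-detection power utility frames the "is there a radial
gradient difference between two labels?" question as a detection problem:
the separation statistic is the sup-norm difference between
area-normalized `d_rel` histograms on [0, 1] (area-normalization rather
than midline-normalization, because a surface-weighted gradient has
`f(0) ≈ 0` and midline normalization would be unstable), with the null
distribution obtained from pairs of uniform-inside samples.

## Pipeline and reproducibility

`run_pipeline` consumes exactly one input source (annotation JSONs,
overlay rasters + palette, or synthetic configs) and emits a report
bundle: records/histogram/fit/normalized-curve/summary/comparison CSVs,
figures, and a manifest with the package version, seed and config hash.
Outputs are deterministic given config + seed. The blinding flag replaces
group labels with opaque hash codes in intermediate tables and filenames,
revealing the code→label map only in the manifest, emulating blinded
scoring. Structured per-stage logging reports skipped annotations and
excluded degenerate records.

Overlay parsing recovers particles and midpoints as centroids of
connected components of their palette colors (midpoints ordered along the
first principal axis of their point set — drawing order is not
recoverable from a flat raster; the dot centroid is taken as the particle
position), and the outline by filling the traced curve, contour-following
and decimating to an ordered polygon (tolerance 0.5 px). Color matching
is exact RGB with an optional per-channel tolerance for anti-aliased
markings. Components much larger than the typical dot are flagged as
possible merged (overlapping) dots.

## Test and experiment sizes

Parameter-recovery experiments use ~5000 particles (either as direct
`d_rel` draws or as a 3 × 3 × 6 ribbon study), which constrains the
logistic center and power to well within 10%; distribution-level checks
(KS/χ²) use 1000–4000 draws at α = 0.01; the distance oracle densely
samples segments at ~1e5 points for 1e−6 relative agreement. These sizes
make the full suite run in well under a minute while keeping every
statistical check comfortably powered.
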