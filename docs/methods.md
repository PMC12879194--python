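# Methods

This note records the models behind each module, the parameters that matter,
what the synthetic data do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Section registration

**Model.** A section is registered by ten anatomical anchors. Registration
is a rigid motion followed by a per-hemisection monotone piecewise-linear
warp:

1. *Rotation.* The dorsoventral junction is translated to the origin and all
   coordinates rotated so the dorsal-column base lies on the positive
   y-axis. Of the two rotations that verticalize the midline, this choice
   uniquely fixes dorsal = up.
2. *Warp.* Per hemisection (assigned by the sign of rotated x), y is mapped
   by the piecewise-linear function through six control pairs — ventral
   extreme → −2000, ventral-horn lateral level → Y_VLAT, junction → 0,
   dorsal-horn lateral level → Y_LAT, dorsal-column base → Y_DC, dorsal
   extreme → +2000 — extended linearly beyond the end segments. x is scaled
   so the lateral dorsal-horn anchor lands at ±2000 and the lateral
   ventral-horn anchor at ±X_VLAT, with the scale blended *linearly in y*
   between those two anchor levels and clamped to the nearer scale outside
   that span. The linear-in-y blend is an explicit modeling choice: the
   anatomical intent ("proximity to the lateral anchor levels") does not fix
   a functional form, and the linear blend is the simplest one that is exact
   at both anchored levels and keeps the warp invertible.

Cells exactly on the midline (x = 0) take the mean of the left/right y-maps;
their x stays 0. Anchor y-levels must be strictly ordered ventral-to-dorsal
per hemisection; violations raise an error naming the offending anchors.

**Parameters.** Template extremes are fixed at ±2000 arbitrary units (the
field's convention for this normalization). The intermediate levels default
to Y_DC = +1200, Y_LAT = +800, Y_VLAT = −800, X_VLAT = ±1600; they are
anatomically arbitrary, segment-dependent, and overridable per segment group
(`TemplateSpec.for_segment`). Because intermediate levels differ across
segments, cross-segment statistical comparisons are not meaningful — only
within-segment, between-condition ones.

**Guarantees.** Anchors land on their template positions to ≤1e−9; the warp
is monotone in y within a hemisection; the full normalization exactly
inverts the generator's distortion at zero jitter (observed round-trip error
~1e−13 over ±60° rotations).

**Overlays and downsampling.** Genotype overlays reflect reference cells to
x ≤ 0 and alternate cells to x ≥ 0, leaving y untouched. Count matching
multiplies each cell type's count by r = alt_total/ref_total and rounds
half-to-even (an unbiased tie rule; the ratio rule itself does not dictate
one), then samples without replacement within type; r > 1 is a warned no-op
since upsampling would fabricate cells. The per-type totals therefore match
⌊r·n_type⌉ exactly and the grand total matches the target within half the
number of types.

## Cumulative birthdating

**Model.** Each embryo contributes, per family and pulse time, the fraction
of marker⁺ cells that are EdU⁺; litters — not embryos — are the biological
replicate, so embryo fractions are averaged within litter. Litter-timepoints
with no marker cells become missing values (never 0) and are excluded
complete-case from the per-timepoint means. With m_t the litter-mean
fraction at pulse t, the percent born at t is p_t = 100·m_t/Σ_s m_s and a
litter's cumulative value is C_{ℓ,t} = 100·f_{ℓ,t}/Σ_s m_s + Σ_{s<t} p_s.
This preserves within-timepoint spread while pinning the litter-mean
cumulative at the final pulse to exactly 100. The litter-mean cumulative
curve is nondecreasing (p_t ≥ 0); individual litter curves may wobble around
it because each carries its own replicate term — only the mean is
normalized.

**Sigmoid fits.** Three forms are supported (x = embryonic day > 0):
logistic Asym/(1+exp((xmid−x)/scal)); 4PL a + (d−a)/(1+(c/x)^b) with
half-max at c; 5PL a + (d−a)/(1+(c/x)^b)^s with half-max at
c/(2^(1/s)−1)^(1/b) (closed form from setting y = (a+d)/2). Fitting is
bounded nonlinear least squares (tolerances 1e−10, ≤10,000 evaluations) with
data-driven initialization: bottom/top from the y-range, c from the
half-range crossing, slope ±5 by trend. A 4PL request falls back to the 5PL
when the 4PL fails to converge or fits with R² < 0.95 — a quantitative proxy
for curves whose slow-growth phase is negligible; the threshold is
configurable and the result records which form was used. Total failure
returns a flagged result rather than raising.

**Inflection statistics.** Per-litter logistic fits supply distributions of
inflection time (xmid) and steepness (scal) per family; every family pair is
compared by a two-sample t-test (equal-variance by default — the
conventional "standard t-test" — with Welch available by option), and
p-values are Benjamini–Hochberg adjusted within each statistic's set of
pairs. Zero variance in both groups leaves t undefined and is reported
missing. Replicate fits default to the cumulative series (the quantity the
half-max is defined on); fitting the raw fraction series instead is possible
by passing those values directly.

**Which points are fitted.** Family-level curve fits default to the pooled
litter-level cumulative replicates rather than the means: the replicates
carry the within-timepoint variance that the construction deliberately
preserves. Fitting means is available via `on="means"`.

## DTW similarity

**Distance.** Plain dynamic programming over local costs |a_i − b_j| with
steps {diagonal, down, right}, unit weights, no window, unnormalized total —
declared in each result's `step_pattern` tag. Established DTW packages
default to other step weightings and normalizations; with none mandated by
the analysis, the textbook form is used and tested against brute-force
enumeration of all monotone warping paths. Backtracking breaks ties
diagonal-first (the distance is tie-independent).

**Permutation null.** Each permutation shuffles the value ordering of both
curves independently (default) or of the second curve only; p = proportion
of permuted distances *strictly greater* than the observed one, so ties
count against significance and identical curves give p = 1. Identity
orderings are eligible; when the number of distinct orderings is ≤ n_perm
the null is enumerated exhaustively and flagged. Which curves the original
analysis shuffled, and whether identity was excluded, is not determinable;
both choices are exposed and the default (both, identity included) is
documented here rather than asserted as canonical. Default n_perm is
100,000; the test-suite calibration (1,000 simulated null pairs × 999
permutations) shows the p-distribution uniform to KS < 0.05.

## Spatial density

**KDE.** Axis-aligned Gaussian product kernel on a regular grid (default
100×100). Automatic bandwidth is the per-axis normal-reference rule
1.06·min(sd, IQR/1.34)·n^(−1/5) used as the kernel SD. Grid limits extend
the data range by 4 bandwidths so the discretized density integrates to ~1
(enforced to 1% in tests); densities at sample points are evaluated exactly,
not grid-interpolated.

**Highest-density contours.** Levels are anchored to fractions of *points*,
not of probability mass: for fraction α the threshold is the density of the
⌈αn⌉-th densest sample point and the member set is every point at or above
it (ties included). This makes nesting and threshold monotonicity exact by
construction and membership track α up to ties.

**Depth histograms.** Template-frame y-coordinates are assigned to 200
half-open bins spanning +2000…−2000, bin 1 dorsal-most, last bin closed;
out-of-range coordinates are clipped into the end bins with a warning so
counts are always conserved. Optional smoothing is a Gaussian kernel of 3
bins — a declared, configurable stand-in for a plotting-layer smoother — and
raw counts are always retained.

**Profile compression.** Raw profiles are aggregated by *sum* into a common
number of equal spans (default 80), pro-rating raw bins that straddle a
boundary by fractional overlap (implemented exactly via interpolation of the
cumulative sum), then normalized to each replicate's total so bins are
proportions of that replicate's signal. Sum-aggregation conserves total
signal before normalization; per-replicate normalization is the default
reading of "normalized to total counts per replicate", with the alternative
achievable by normalizing externally. The dorsal-most 56 bins form the
display view (the deepest lamina contributes little signal for these
markers); quintiles are 5 groups of 16 bins.

**Quintile ANOVA.** Quintile weights enter a three-way fixed-effects ANOVA
(genotype × quintile × cell-type, all interactions, classical sums of
squares on the balanced designs the generator produces; the cell-type factor
is dropped with a warning when only one type is present). Post-hoc Tukey HSD
compares genotypes within each quintile (× cell type). Composition tables
get the two-way analogue (cell-type × genotype) with Tukey per cell type.
Note that because profile weights sum to 1 per replicate, genotype main
effects are structurally null — the informative term is the
genotype × quintile interaction.

## Synthetic data: what it emulates, and what it does not

**Sections** are built in the template frame (six laminar family bands,
mirrored hemisections, left x < 0), pushed through a random invertible
per-hemisection distortion (control-level scale factors within
±`warp_strength`, midline dorsal-column level shared between sides), a rigid
rotation/translation, and finally coordinate jitter applied to cells only —
anchors stay exactly on the transform, emulating carefully placed landmarks
on noisily measured cells. Because the distortion divides x by exactly the
scale blend the forward warp reconstructs, registration is the exact inverse
at zero jitter; this is what makes round-trip recovery a meaningful test
rather than a tautology of shared code paths (the generator and the
registration module share only the control-level definitions).

**Birth counts** draw each cell's birthdate from its family's Gaussian wave;
a pulse at time t labels cells with birthdate in the half-day window
*ending* at t, (t − w, t]. Under this convention the cumulative co-labeling
at pulse t estimates the birth CDF at t, so the fitted half-max is an
unbiased estimate of the wave center μ — which is what the recovery suite
asserts (within 0.25 day in ≥90% of 100 runs at the 4-litter × 3-embryo ×
100-cell half-day design). Had the window been taken as starting at the
pulse instead, every half-max would shift earlier by exactly w; the
convention fixes the timestamp's meaning, not the biology. Each
(embryo, pulse) draws an independent cell sample, emulating separate
sections per pulse. Litter-level conception-time jitter (~±8 h is realistic)
is supported but off by default so ground truth stays exact.

**Composition curves** are multinomial draws per timepoint from normalized
Gaussian type-prominences over a quarter-day grid (E11.00–E16.75, 24
timepoints, 2,000 cells per timepoint by default). **Depth profiles** are
sums of Gaussian bumps over raw bins (default 240) plus truncated noise,
with genotype effects expressed as peak shifts.

Not emulated: transcript-level expression, segmentation errors, spatially
correlated landmark placement error, progenitor cell-cycle kinetics, or
litter-size imbalance. Passing tests therefore demonstrate the correctness
and calibration of the *procedures* under clean, known-truth conditions —
not robustness to every artifact of real imaging or sequencing data.

## Problem sizes

Defaults were chosen to mirror a realistic experiment at desk scale: 7
half-day pulses × 4 litters × 3 embryos × 100 cells for birthdating; 2,000
points for density/contour checks; 100 seeded simulations for the recovery
suite; 999-permutation DTW tests in the suites (the 100,000-permutation
default is for real analyses). The full test suite runs in well under a
minute on one core.

## Known limitations

* The x-warp outside the span between the two lateral anchor levels clamps
  to the nearer scale; ventral-of-ventral-horn or dorsal-of-dorsal-horn
  outliers are extrapolated linearly in y. Both are conventions, not
  anatomy.
* Welch degrees of freedom are not tabulated in the pairwise test table
  (t and p are exact; df is reported for the equal-variance case only).
* The 5PL half-max formula assumes b and s of the fitted sign produce a
  crossing; degenerate fits report NaN rather than a spurious time.
* Permutation p-values are discrete at resolution 1/n_perm; exhaustive mode
  removes Monte-Carlo error only for short series.
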