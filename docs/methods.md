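# Methods

This note documents the models, conventions and numerical choices behind
`chronotopo`, and what the synthetic-data experiments do and do not show.

## Duration pRF model and fitting

The response of one vertex to the 24 duration × position conditions is
modeled as `beta(d) = baseline + gain · exp(−(d − μ_d)²/(2 σ_d²))`,
position-invariant by construction. The underlying tuning model carries no
amplitude or offset; because measured amplitudes are GLM betas in percent
signal change, a per-vertex linear `gain` and `baseline` are solved in
closed form by least squares at every candidate `(μ_d, σ_d)`. This makes the
"negative pRF" exclusion well defined: a vertex whose best-fitting gain is
≤ 0 responds *least* at its nominal preference and is excluded
(`negative_prf`).

**Stimulus tensor.** The stimulus design is also represented as a
100×100×24 indicator tensor over two arbitrary-unit axes (space and
duration, units 1–100); predictions can be formed by integrating the pRF
over each condition slice. This is fidelity machinery, not a second model:
tensor and closed-form predictions agree to machine precision. The duration
axis uses 160 units per second with 0.2 s at unit 1, so all six design
durations (0.2, 0.3, 0.4, 0.6, 0.7, 0.8 s) land on integer unit columns
(1, 17, 33, 65, 81, 97); an affine map leaves the Gaussian argument
`(d − μ)/σ` unchanged, so the discretization introduces no error. A map
that stretched the design exactly onto units 1–100 would put 0.3 s and
0.7 s between columns and break this exactness, which is why the slightly
narrower scale was chosen.

**Two-stage fit.** Stage one is an exhaustive grid search — `μ_d` over
[0.1, 0.9] s in 0.01 steps, `σ_d` over [0.02, 0.5] s in 30 log-spaced steps
— ranking nodes by residual sum of squares, with ties broken by smaller σ
then smaller μ (the grid is enumerated σ-major so the first minimum wins).
Stage two refines `(μ_d, σ_d)` by Nelder–Mead, bounded to
μ ∈ [0.05, 1.0] s and σ ∈ [0.01, 1.0] s via a logistic coordinate squash,
re-solving gain/baseline at every evaluation (relative RSS tolerance 1e−8,
at most 2000 evaluations). The refined solution is kept only if it does not
worsen the grid RSS, so `r2_final ≥ r2_grid` always. Only vertices whose
grid fit explains ≥ 10% of the beta variance are refined; the rest are
excluded (`low_r2`). Constant beta rows have undefined R² (`fit_failure`).

**Multi-start refinement.** With narrow tuning widths the RSS surface over
`(μ_d, σ_d)` is multimodal — a narrow Gaussian centered between two design
durations can be mimicked by an even narrower one centered elsewhere — and
the single best grid node occasionally sits in the wrong basin.
`fit_field` therefore also refines up to two runner-up grid nodes that are
competitive (within 0.05 grid R²) and at least 0.05 s away in μ from
already-selected seeds, keeping the best refined solution. With noise-free
input this restores exact recovery (max μ error < 1e−7 s over 200 vertices
with μ ∈ [0.25, 0.75], σ ∈ [0.05, 0.3]).

**Identifiability.** Preferences are identifiable inside the design range;
outside [0.2, 0.8] s the likelihood flattens (only one Gaussian flank is
sampled) and fits remain finite but degrade gracefully toward the bounds.
The 10%-retention rule is a weak filter for 24-condition designs: the
best-of-grid R² on pure-noise input has a null median around 0.14 (three
effective parameters on 24 points), so roughly two-thirds of pure-noise
vertices survive the retention cut, and about a third of the total are
removed only later by the negative-pRF rule. Noise-floor expectations for
this design should be calibrated against these measured numbers, not
against the nominal 10% figure.

## Moran statistics

Values are centered on a scope mean — the hemisphere mean for the local
analysis (so "high"/"low" are relative to the hemisphere), the ROI mean for
the per-ROI global analysis. With `z_i` the centered values and
`m2 = Σz²/n`, the local statistic is `I_i = (z_i/m2)·Σ_j w_ij z_j` with
row-standardized k-nearest-neighbor weights (`1/k` each; distance ties
broken by ascending vertex id). The global statistic is the mean of the
local ones, which equals the textbook global Moran's I under
row-standardization. Invalid (excluded) vertices are removed *before*
neighborhoods are built. The local neighborhood size follows the
smallest-region rule (one fourth of the smallest ROI in scope); the global
analysis uses 12 nearest neighbors.

**Permutation nulls.** Local significance uses conditional permutation:
the focal value stays fixed while its k neighbor values are redrawn without
replacement from all other in-scope vertices, 999 times by default, with
one shared set of permutation draws across vertices. The reported pseudo
p-value is two-sided — twice the observed-side tail count `(R+1)/(999+1)`,
capped at 1 — because a one-sided tail whose side is chosen by the data
rejects at ~2α under an i.i.d. null; the two-sided default restores the
nominal false-positive rate (measured 0.046 at α = 0.05 over 50 null
fields). A `alternative="one-sided"` option reproduces the raw
observed-side convention. Global significance shuffles all values jointly
and is two-sided around the permutation mean. Significant vertices are
classified HH/LL/HL/LH from the signs of `z_i` and its spatial lag;
non-significant vertices are `ns`.

## Variograms

Preferences are z-scored within the analysis scope (population SD), so the
total variance — the sill reference — is exactly 1. Pairwise distances are
Euclidean between stored coordinates (a precomputed, e.g. geodesic, matrix
is accepted), grouped into 2 mm bins `[b·w, (b+1)·w)` centered at
`(b+½)·w`. The per-bin statistic is the Matheron semivariance
`γ(h) = Σ(z_i−z_j)²/(2N(h))`; an alternative `diff_variance` estimator
(half the variance of within-bin pairwise differences) is available behind
a flag, since "variance per distance bin" admits both readings. The nugget
is the γ of the first nonempty bin (minimum pair count configurable,
default 1) divided by the total variance; the range is the center of the
first bin whose γ reaches the total variance, divided by the maximum
inter-vertex distance, with `(1, reached_sill=False)` when the sill is
never reached. On white fields γ hovers at the sill so the crossing bin is
approximately geometrically distributed: the *median* crossing is in the
first bins, but individual fields can cross late — tests therefore assert
the median, not every seed.

## Categories, summaries, gradients, maps

Category edges are 0.2/0.32/0.44/0.56/0.68/0.8 s with left-closed,
right-open intervals and a closed final interval (so 0.32 is mid-short and
0.8 is long); out-of-range preferences are flagged `unassigned` and
reported, never silently binned. ROI summaries (median preference, category
fractions, LL−HH difference) use valid vertices only; hemispheres can be
kept separate or averaged for bilateral regions. Hierarchy gradients are
ordinary least squares of a per-ROI scalar on an explicit user-supplied
occipital→frontal rank (the ordering is a judgment call, not a formula);
a constant outcome is reported as slope 0, t 0, p 1. Preference maps are
rendered on a 2 mm isotropic grid as Gaussian-kernel-weighted means
(σ = FWHM/2.355, FWHM 4 mm), masking cells with negligible total weight.

## Behavior and long-range structure

Psychometric curves are binomial-logit GLM fits of the trial-level "longer"
response on comparison duration; PSE = −intercept/slope, flagged invalid
for non-positive slopes, and perfect separation or a single response class
yields `converged = False`. Kendall correlations are τ-b (tie-corrected),
with an exact p-value for n ≤ 9 untied samples and the normal approximation
otherwise; per-region p-values are uncorrected by default (a
Benjamini–Hochberg option exists but is off). The transform
`z(τ) = atanh(sin(πτ/2))` is strictly increasing and odd; |τ| = 1 maps to
±∞ and is a hard error unless clamped to 1−1e−6 (clamped values are finite
but extreme, and sin is kept strictly inside ±1 so float rounding cannot
produce infinities for |τ| < 1).

The long-range correlation matrix is τ-b over subjects for every region
pair (regions constant across subjects give missing entries). It is
converted to distances as Euclidean distances between the matrix rows —
the behaviour of handing a correlation matrix directly to a stock distance
function — with a `one_minus` alternative. Complete-linkage agglomeration
(scipy) produces the dendrogram; merge heights are non-decreasing, and
exact ties between merge candidates are resolved by scipy's deterministic
internal order. Newick export uses merge heights as node heights.

## Synthetic data

The generator emulates the study conditions: 6 comparison durations
0.2–0.8 s around a 0.5 s reference at 4 positions; per-vertex betas =
Gaussian tuning forward model + i.i.d. Gaussian noise (default 0.05 psc,
gain 1, baseline 0); logistic categorization behavior with a planted PSE.
Planted preference fields cover the observed regimes: linear gradients
(full-range topographic maps), Gaussian-random fields (kernel-smoothed
white noise rescaled to unit variance, mixed with fresh noise at a nugget
fraction; smoothing kernel SD = correlation length / 2), i.i.d. white
fields, boundary fields tight around 0.5 s, and constants. Preferences are
clipped to [0.2, 0.8] s after generation (clip fraction recorded). Tuning
widths default to i.i.d. uniform [0.05, 0.3] s — broad enough to span sharp
and shallow tuning within the design range; this distribution is a free
choice, not an empirical estimate. All randomness flows from one explicit
integer seed per call.

What the generator does **not** emulate: BOLD time series, HRF convolution
and GLM estimation noise structure (betas are the interface); curved,
triangulated cortical geometry and geodesic distances (flat lattices with
pluggable distance matrices stand in); spatially correlated measurement
noise; inter-subject variability beyond independent seeds and planted PSE
shifts. Passing tests therefore demonstrate the correctness and calibration
of the statistics under known truth, not that real cortical data satisfy
the model.

## Problem sizes and defaults

Default analyses use lattice patches of a few hundred to ~900 vertices,
999 permutations, α = 0.05, 2 mm variogram bins, k = 12 global neighbors,
and 13 simulated subjects in multi-subject stages — matching the study
constants where they exist and otherwise chosen as the smallest sizes at
which the planted effects are comfortably resolved. Monte-Carlo checks use
10–50 seeds per condition. The end-to-end demo pipeline completes in well
under a minute on one CPU.

## Known limitations

* Moran and variogram scopes assume the supplied distance metric is
  meaningful; on folded cortical surfaces Euclidean distances understate
  geodesic ones, so supply a geodesic matrix for real surfaces.
* The per-bin variogram statistic at large distances rests on few pairs and
  is noisy; nugget/range extraction deliberately does not fit a parametric
  variogram model.
* The retention threshold is weak for 24-condition designs (see above);
  interpreting exclusion fractions requires the measured null, and no
  multiple-testing correction is applied to local Moran p-values (matching
  the analysis convention this package mirrors).
* Group-level inference (mixed models, ANOVAs) is out of scope: the package
  emits tidy per-subject/per-ROI tables for external statistical software.
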