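# Methods

This note records the statistical models the package implements, the
conventions and defaults it commits to, what the synthetic generator does
and does not emulate, and the numerical choices a maintainer would want to
know about.

## Spatial weights

Contiguity weights are **binary and symmetric** with a zero diagonal, and
are used binary (not row-standardized) in both Moran statistics; a
row-standardized view exists but is off by default. Queen contiguity
(boundaries sharing at least a point) is the default rule because study
areas of irregular administrative units rarely justify the stricter rook
rule; rook (shared boundary segments of positive length) is available.
True islands — archipelago cities have no land border — would make local
statistics undefined, so island repair (link each island to its nearest
unit by centroid distance, symmetric, logged, original island list kept
for reporting) is on by default in the pipeline. Weights with no links at
all are refused.

## Moran's I

Global: `I = n·zᵀWz / (zᵀz·S₀)` with `z = x − x̄`. The Z-score is
`(I − E[I])/√Var(I)` with `E[I] = −1/(n−1)`; the variance uses the
Cliff–Ord moments under the **randomization** assumption by default
(normality optional) since the statistic is computed on fixed observed
values rather than a Gaussian superpopulation. A permutation variant
reports the pseudo-p `(1 + #{|I_perm − E[I]| ≥ |I_obs − E[I]|})/(1 + n_perm)`.
The often-quoted range [−1, 1] is not exact for arbitrary W; values outside
it are warned about, never clamped or treated as errors.

Local: `Iᵢ = n·zᵢ·Σⱼ Wᵢⱼzⱼ / zᵀz`, which satisfies `Σᵢ Iᵢ = S₀·I` exactly
(an identity the tests assert). No analytic variance is used; inference is
**conditional permutation** (hold unit i fixed, draw its neighbour values
from the remaining units without replacement; default 999 draws, seeded).
Labels follow the Moran scatterplot quadrants and require |Z| at the tier
threshold, with ≥ comparisons so a Z exactly at 1.96 counts as significant.
Units with zero neighbours get an undefined Iᵢ and the NS label with a
warning.

## Geodetector

`q = 1 − Σₕ Nₕσₕ²/(Nσ²)` with **population variances** (÷Nₕ): this is what
makes q ∈ [0, 1] and q = 0 for a single stratum, so the algebra forces the
convention. Significance uses the noncentral-F approximation from the
Geodetector literature — `F = (N−L)/(L−1) · q/(1−q)` referred to
`F(L−1, N−L; λ)` with `λ = (Σₕ NₕȲₕ² − (Σₕ √Nₕ Ȳₕ)²/N)/σ²` — matching
the reference software's behaviour; a seeded permutation fallback exists
for small or ill-conditioned strata. The ecological detector compares two
stratifications' within-stratum sums of squares by an F ratio oriented so
F ≥ 1 with df (N−1, N−1), one-sided; the orientation makes the Y/N decision
symmetric in its two arguments. The interaction detector overlays two
stratifications (distinct label pairs present in the data) and classifies
q(A∩B) against q_A, q_B and q_A + q_B into the five standard classes
(nonlinear-weaken / uni-weaken / bi-enhance / independent /
nonlinear-enhance); "independent" uses an equality tolerance of 1e-9.
Overlays that create more strata than half the sample size are flagged as
overfit.

Natural-breaks discretization is the **exact Fisher dynamic program**
minimizing within-class sum of squared deviations (O(k·n²)); it is
implemented in-package and verified against exhaustive partition search
because no installed library provides it. Default class count is 8.
Grid sampling lays a cell-center-offset lattice over the unit polygons
(planar km coordinates assumed — geographic inputs must be pre-projected,
equal-area recommended) with every point inheriting its containing unit's
attributes; default spacing 10 km. The pipeline's detectors run on unit
rows by default; the grid sampler supports point-level detection when
polygons are available.

## Screening

Correlation clustering uses distance **1 − |r|** (so strong negative
correlates also merge; 1 − r available) with single linkage, and drops all
but the first member of every group at the user cut (default 0.2). The
screen runs cluster-drop first, VIF second, so near-duplicates never
inflate the VIFs of the survivors. VIFs come from the two-stage regression
definition (R² of covariate j on the others, with intercept); perfect
collinearity reports +inf/Failed rather than raising. Threshold default 5.

## GWR and MGWR

The kernel is Gaussian, `w = exp(−(d/b)²)`. The default bandwidth mode is
**adaptive** (b = number of nearest neighbours; the kernel scale at unit i
is the distance to its k-th nearest site, the focal site counting first):
areal units of very uneven density make fixed-distance kernels either
singular in sparse regions or over-smooth in dense ones, and adaptive
bandwidths are what per-covariate bandwidth tables in the field report.
Fixed-distance mode is available throughout. Distances are planar
Euclidean on pre-projected km coordinates.

Diagnostics come from the exact hat matrix: ENP = tr(S), `sigma =
√(RSS/(n − tr S))`, `AICc = 2n·ln(σ̂) + n·ln(2π) + n(n + trS)/(n − 2 − trS)`
with the maximum-likelihood scale `σ̂² = RSS/n`, R²/adjusted R², and a
local weighted R² per focal unit. Bandwidth selection minimizes AICc.
Because adaptive AICc profiles are **not reliably unimodal** (a deep local
minimum can coexist with a shallow dip near the global end — observed on
the sinusoid fixtures), a pure golden section can collapse to the wrong
side; selection therefore scans all integer candidates exhaustively when
the range has ≤ 256 of them and otherwise brackets the minimum with a
16-point geometric grid before golden refinement, ties breaking toward the
smaller (more local) bandwidth. A non-unimodal evaluated trace triggers a
warning and a grid fallback.

MGWR treats every term — intercept included — as a varying coefficient
with its own bandwidth, fitted by **backfitting**: initialize from a
single-bandwidth GWR decomposition (so each term starts with a plausible
spatial pattern; OLS start available), then cycle over terms, regressing
each partial residual on its covariate with a term-specific AICc-optimal
bandwidth. Starting from OLS with greedy per-term selection can park the
fit in a local optimum where the intercept soaks up unexplained spatial
structure; the GWR start avoids this. Convergence uses a SOC-f style
score — the RMS change of the fitted values between sweeps, normalized by
their RMS — with tolerance 1e-5 and at most 200 sweeps; bandwidths are
re-selected during the first 5 sweeps and then frozen, so later sweeps
only polish coefficient surfaces (re-selection rarely moves after the
pattern stabilizes, and freezing keeps the smoother chain well defined).
Non-convergence returns the fit with `converged=False` and a warning.
Per-term smoother matrices are chained exactly
(`S_j ← L_j(I − Σ_{k≠j}S_k)`), so per-covariate ENP values are exact for
the realized smoother and sum to the total ENP.

Both models **z-score y and X by default** (the convention of the standard
multiscale-GWR software; it makes coefficient magnitudes comparable across
covariates and keeps backfitting well-scaled); raw-scale coefficients are
recovered by exact back-transformation. With all bandwidths forced to a
common value, the backfitting fixed point coincides with the joint GWR
solution only as locality weakens; at a generous common bandwidth the two
agree to better than 1e-4 (asserted), while at strongly local bandwidths
they differ at the 1e-3 level — an inherent property of backfitting, not a
convergence failure.

Regional summaries take unweighted means of local coefficients within each
group label and flag the largest-|mean| covariate per group (intercept
excluded from the argmax).

## Temporal aggregation

Hourly station records aggregate hourly → daily → monthly →
seasonal/annual. A period is reported only when at least a fraction
(default 0.75, configurable — the ambient-standard completeness practice)
of its sub-periods is present. City means are unweighted means of station
means; annual and seasonal means average monthly means so months weigh
equally regardless of length or missingness. Seasons are
March–May/June–August/September–November, and winter groups December with
the following January and February, carrying the following year's label.
Timestamps are naive local time; no timezone arithmetic.

## Synthetic generator

The generator emulates the *statistical shape* of a multi-agglomeration
city panel: a rectangular lattice of square units (default study shape: 75
units split 17/31/27 into three contiguous groups, five covariates, four
annual periods), covariates as unit-variance Gaussian random fields with
exponential covariance `exp(−d/range)` (Cholesky construction; a 1e-9
diagonal jitter for definiteness), optional injected pairwise correlation
for collinearity tests, and responses built as `y = β₀(u,v) +
Σⱼ βⱼ(u,v)xⱼ + ε` from constant / linear-gradient / sinusoidal coefficient
surfaces — the standard triad of the multiscale-GWR simulation literature —
with the true surfaces returned for recovery scoring. Strata scenes draw
stratum means N(0, between-sd²) and samples N(meanₕ, within-sd²), returning
the realized q so recovery compares like with like. Everything is a pure
function of (spec, seed); specs round-trip through YAML.

The **multi-scale recovery fixture** is a 20×20 lattice (10 km spacing)
with β₀ = 3 constant, a gradient β₁ and a one-wavelength-per-half-side
sinusoid β₂, noise SD 0.5, and *spatially uncorrelated* covariates: with
iid covariates the additive terms are identifiable and each selected
bandwidth reflects its own surface's smoothness. With strongly
spatially-correlated covariates the attribution of smooth structure
between intercept and covariate terms is confounded and bandwidth ordering
degrades — a genuine identifiability limit, not an implementation one.

What the generator does **not** emulate: real administrative geometries,
observational covariate distributions (skewness, units, measurement
error), temporal dependence between periods (years share covariates but
have independent noise), or station-level microvariability. Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated generative model, not the field validity of any particular
empirical finding.

## Problem sizes and defaults used in checks

The shipped verification runs use: oracle comparisons at n ≤ 50 (Jenks
n ≤ 12, k ≤ 4, against exhaustive search), null calibration with 300–500
replicates × 199 permutations on a 5×5 lattice, q recovery at n = 20 000,
the 20-seed multi-scale recovery experiment at n = 400, and pipeline
determinism on the 75-unit study shape with two periods. These sizes give
stable Monte-Carlo margins while keeping the whole suite fast on a single
CPU.

## Known limitations

- Backfitting MGWR standard errors / coefficient inference are not
  implemented (point surfaces and ENP only).
- Fixed-distance bandwidth search bounds are heuristic (max distance
  scaled); adaptive mode is the recommended default.
- The ecological detector's F reference with df (N−1, N−1) follows the
  reference software; its small-sample behaviour under heavy ties is
  approximate.
- Great-circle distances are not implemented; inputs must be planar.
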