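# Methods

This note documents the models, estimators, defaults and numerical
choices behind `rangediv`, and what the synthetic-data experiments do
and do not establish.

## Trees and covariance algebra

Trees are rooted, branch-length-bearing `dendropy.Tree` objects parsed
from Newick with strict validation (duplicate tip labels and missing
branch lengths are errors; polytomies are preserved). All analyses
assume an ultrametric (time-calibrated) tree; every simulated tree is
rescaled to unit root depth, matching the convention of fixing the root
age to one, so all rates are in units of "per tree depth".

The Brownian covariance C has entry (i, j) equal to the root-to-MRCA
depth of the tip pair; it is built in one postorder sweep and always
carries tip labels — consumers align data by label, never by row order.
Pagel's λ multiplies the off-diagonal entries only, which is well
defined only when the diagonal is constant, i.e. on ultrametric trees;
non-ultrametric input is rejected whenever λ < 1. For the mixed model
the covariance is standardized by dividing by det(C)^(1/n), giving a
unit determinant (asserted to 1e-6 before every fit), the convention
used when a precision matrix is passed to latent Gaussian engines.

## Tip rates

DR is the inverse of the equal-splits measure
ES_i = Σ_j l_j (1/2)^(j−1) along the tip-to-root path (pendant edge
first, root edge excluded). It is computed by the preorder recurrence
S(child) = l_child + S(parent)/2, which is algebraically identical to
the per-tip path walk. log DR uses the natural log (recorded in the
table metadata). DR is a nonparametric proxy for recent speciation
rate; on pure-birth trees its tip mean increases with the true birth
rate, which the tests verify by rank correlation across replicates.

## λ-PGLS

The regression model is y = Xβ + ε, ε ~ N(0, σ²C(λ)). λ is estimated
by bounded scalar maximization of the concentrated ML log-likelihood on
[0, 1] (tolerance 1e-6) with explicit endpoint evaluation; when an
interior optimum and an endpoint tie within 1e-8 the interior value is
kept. ML rather than REML is used; the choice is recorded in the fit
metadata. Standard errors use the unbiased variance RSS_gls/(n−p) and
two-sided t tests with n−p degrees of freedom; no multiple-testing
correction is applied (raw p values are reported). Predictors are
z-scored in the model-frame step so effect sizes are comparable; the
response is left on its own scale. With λ = 0 on a unit-depth
ultrametric tree the fit reduces exactly to OLS, and with λ = 1 the
slope equals the independent-contrasts estimator — both are test
oracles.

Interaction analysis fits the full model with island × predictor terms,
then refits island-only and continental-only subsets on pruned trees
(branch lengths preserved); a class with fewer than p + 2 species is
skipped with a warning.

## Path model

The structural diagram is a DAG over {lat/lon midpoint, island flag,
body mass, hand-wing index, range size, shape index, speciation}, with
speciation constrained to be a sink. Each endogenous variable is
regressed on its DAG parents by λ-PGLS; an edge is significant when the
95% interval of its coefficient excludes zero. This is a deliberate
estimator swap relative to fitting the system jointly with a Bayesian
sampler: per-equation ML preserves the DAG, the phylogenetic residual
structure, and the sign/significance surface, at a tiny fraction of the
cost; every `PathFit` records the estimator. An optional parametric
bootstrap (resimulated λ-Brownian residuals, percentile intervals,
default 1000 draws when enabled) is provided as a cross-check on the
analytic intervals.

## State-dependent diversification

### Likelihood core

BiSSE/HiSSE likelihoods integrate, along every branch, the standard
coupled ODEs for per-state extinction probabilities E_s and conditional
likelihoods D_s (state-specific speciation λ_s, extinction μ_s,
transition matrix Q), combining daughters at nodes as
D_s ← λ_s D_s^L D_s^R with per-node renormalization against underflow.
The integrator is an adaptive Cash–Karp Runge–Kutta (rel/abs tolerance
1e-8/1e-10) compiled with numba; the state count is generic, serving
BiSSE (2), HiSSE (4: 0A, 1A, 0B, 1B) and CID-4 (8) from one kernel.
Branches of exactly zero length are integrated over 1e-9 instead, only
inside the ODE step. Observed tips are ambiguous over hidden states
(D initialized on all compatible completions); dual transitions
(simultaneous observed + hidden change) are structural zeros.

Root treatment defaults to weighting root states by their conditional
likelihoods, with flat weights or explicit frequencies as options;
conditioning on survival is off by default. Both switches are recorded,
because they materially shift the absolute log-likelihood.

The primary correctness oracle is the factorization identity: with
state-independent rates, the joint likelihood equals the constant-rate
birth–death likelihood (implemented in closed form — logistic survival
probability — independently of the ODE code) times the Mk character
likelihood (matrix-exponential pruning). A second oracle is the exact
collapse of HiSSE onto BiSSE when hidden states are tied.

### Model set

Twenty models are compared: sixteen HiSSE variants and four CID nulls.
The sixteen are the cross of {λ depending on the observed state only,
λ free across all four states} × {single μ, per-state μ} × four
transition-matrix tying schemes (all rates equal; observed-change vs
hidden-change rates; directional observed rates plus one hidden rate;
all eight rates free). The exact constraint enumeration is this
package's own, since only the count and the CID complexity equivalences
are fixed by convention: the two CID-2 nulls (λ tied to the hidden
state) are built with k = 6 free parameters, matching the full BiSSE
model, and the two CID-4 nulls spread λ over four hidden states.
Fitting is bounded L-BFGS-B on log parameters (bounds [1e-6, 1e3] on
the unit-depth tree) with seeded multistarts (default 5; 2–3 in the
scripted runs). AIC = 2k − 2lnL and Akaike weights
w_i = exp(−Δ_i/2)/Σ exp(−Δ_j/2) drive model choice; below 800 tips the
individual transition-rate estimates are flagged unreliable and only
the weights should be interpreted.

### Threshold binarization and FiSSE

Continuous traits (range size) are binarized by median/quartile/fixed
thresholds with a strict "less than" convention — state 0 is strictly
below the cut, ties go to the upper state — plus a quartile-grouping
mode (outer quartiles vs interquartile range). FiSSE compares
state-specific mean DR tip rates; the null distribution comes from
neutral binary characters simulated on the same tree under a symmetric
Mk model whose rate is ML-fitted to the observed tip pattern (an
ML stand-in for the original test's parsimony calibration, recorded in
the result). The two-tailed p uses the small-sample correction
p = 2·min(r, n_sim − r + 1)/(n_sim + 1), r = #{null ≤ observed},
clipped into (0, 1].

## Spatiophylogenetic mixed model

y = Xβ + u_p + u_s + ε with u_p ~ N(0, σ²_p C_std),
u_s ~ N(0, σ²_s Matérn(ρ, ν)) and iid ε. The spatial field is
evaluated at one representative coordinate per species (range
centroid/midpoint) — a deliberate swap for integrating a mesh-based
latent field over every occurrence record: it preserves the per-species
spatial random effect (each species contributes one likelihood term)
without mesh machinery, and is recorded in the fit metadata. ν defaults
to 1.5 (once-differentiable field); ρ is estimated, but clipped to
[1e-3, 1e3] × the median pairwise distance because it is unidentifiable
as σ²_s → 0. Variance components are fitted by Nelder–Mead on log
scale with boundary checks (the optimum is compared against switching
either random effect off); fixed effects get Wald 95% intervals, and
significance means the interval excludes zero — the confidence-interval
analogue of a credible-interval overlap rule. With σ²_s and σ²_e pinned
to zero the model is exactly GLS under C_std, i.e. PGLS with λ = 1;
this is the reduction identity tested to 1e-6. The σ_e-free model is
only proportionally equivalent to λ-PGLS (same covariance family,
different parameterization), so no exact cross-optimizer equality is
asserted there.

## Range geometry and trait preparation

All geometry is planar on equal-area-projected km coordinates
(projection is upstream metadata; synthetic tests are projection-free).
Area sums over parts with holes subtracting; perimeter sums over all
rings; the shape index area/perimeter therefore shrinks for elongated
or disjunct ranges — two disjoint unit squares share the area of a 2×1
rectangle but carry more perimeter. Bounding-box midpoints (not the
area-weighted centroids, which are computed but only exported) feed the
regressions as |lat| and |lon|. HWI = 100 × Kipp's distance / wing
length, with individual measurements averaged per species before the
ratio. Missing body mass is filled by genus means; missing HWI by the
Brownian conditional expectation given observed tips (GLS mean plus
C_mo C_oo⁻¹ kriging term). Model frames natural-log positive continuous
variables (log base recorded), take absolute midpoints, and z-score
predictors.

## Synthetic data

The generator's defaults are the study conditions: 192 tips, island
fraction 68/192 (iid Bernoulli by default; an Mk-evolved flag and a
jointly simulated BiSSE state are options), pure-birth trees of unit
depth, and log-normal range sizes per setting (island meanlog 9.2,
sdlog 1.6; continental meanlog 12.2, sdlog 1.8). The log-normal family
is an assumption — chosen to reproduce a right-skewed distribution
spanning roughly 4×10¹ to 7×10⁶ km² with island ranges systematically
smaller and ~90% of island species below 100,000 km² — validated only
qualitatively. Traits follow a linear structural simulation along the
path diagram with settable standardized coefficients (defaults of
magnitude 0.2–0.3 carrying the expected signs; the source analyses fix
signs, not magnitudes) and λ-Brownian residuals, so regression slopes
are recoverable and zeroing the coefficients yields calibrated nulls.
Shape indices scale as √area with noise, so they correlate with range
size without being geometrically derived from actual polygons. Tree
simulation is Gillespie with retry-on-extinction (max 100), stopping
just before the first event after the target tip count so pendant
edges are strictly positive.

What passing tests show: estimator correctness (oracles), calibration
(type-I error, interval coverage) and power under the generator's
assumptions — phylogenetically clean traits, exact binary settings, one
coordinate per species. What they do not show: robustness to range-map
error, occurrence sampling bias, non-Brownian trait evolution, or
island flags that are phylogenetically clustered in ways the Mk option
does not capture.

## Problem sizes in the scripted runs

The acceptance experiments use the sizes stated with each check:
500 trees for the DR oracle, 20 ten-tip trees for the likelihood
factorization, 100 replicates at n = 200 for PGLS and mixed-model
recovery, 200 neutral + 50 powered replicates for FiSSE, and 30
replicates at n = 300 with the reduced model set (full BiSSE vs both
CID-2 nulls) for the model-selection check. The acceptance script runs
the full 20-model set once at n = 192. These sizes are the package's
own desk-scale choices; all are seeded and deterministic.
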