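# Methods

## Model

Data are n i.i.d. samples of p jointly Gaussian variables. The GGM is the
matrix P of partial correlations, obtained by standardizing the negated
precision matrix Ω (the inverse of the correlation matrix R):
P_ij = −Ω_ij / √(Ω_ii Ω_jj). Zeros of P encode conditional
independencies. All estimators operate on the correlation scale: columns
are centred and scaled to unit sample standard deviation (ddof = 1)
before any fit, and zero-variance columns are rejected by name. Variances
belong to reporting, not to the conditional-dependence structure.

## Shrinkage

The shrunk correlation is the convex combination
R(λ) = (1 − λ) R̂ + λ I. Because the target is the identity, the
eigenvectors of R̂ are untouched and each eigenvalue a_k maps to
(1 − λ) a_k + λ, so R(λ) is positive definite for every λ in (0, 1] as
soon as the a_k are non-negative. Eigenvalues in a narrow negative
round-off band (more negative than −1e−10 × max a_k is an error) are
clamped to zero. Partial correlations at any λ are computed through this
single eigendecomposition, Ω(λ) = V diag(1/a(λ)) Vᵗ, which is both
cheaper along a λ grid and more stable than repeated dense inversion; the
two routes agree to 1e−10 on well-conditioned input (tested).

The data-driven intensity λ\* is the analytic mean-squared-error
minimizer of Schäfer–Strimmer type,

λ\* = Σ_{i<j} var̂(r_ij) / Σ_{i<j} r_ij²,  clipped to [0, 1],

with var̂(r_ij) = n/(n−1)³ Σ_k (w_kij − w̄_ij)² built from the centred
cross-products w_kij = x_ki x_kj of the standardized data. This is an
implementation choice: the originating literature optimizes the expected
squared distance between R(λ) and the population R, and several variance
estimators circulate; this one is the standard analytic form and is
deterministic in the data. The test suite pins it against an independent
loop-based evaluation.

Shrinkage has an equivalent data-level reading: replacing the singular
values s_k of the standardized data matrix by
√((n−1)((1−λ)s_k²/(n−1) + λ)) yields a dataset whose sample covariance
is exactly R(λ). The identity is exact when n > p (all p directions are
representable in the data); for n ≤ p only the non-null spectrum can be
re-weighted. The simulator exposes this as `shrink_data`, and the
equivalence is asserted to 1e−10.

## The un-shrunk partial correlation

The estimator of interest is the limit P⁰_ij = lim_{λ→0} P^[λ]_ij. Two
routes:

**Analytic.** Scale invariance of the standardized ratio lets one replace
Ω(λ) by N(λ) = V diag(λ/a(λ)) Vᵗ. As λ → 0 the diagonal factors go to 1
on the null space of R̂ and to 0 elsewhere, so N → M = V₀V₀ᵗ, the
orthogonal projector onto the null space. For nonsingular R̂ the limit is
the classical partial correlation; for singular R̂ it is
−M_ij/√(M_ii M_jj). When some M_ii = 0 (a variable orthogonal to the
null space) the limit direction is degenerate and the implementation
raises rather than guessing; the automatic dispatcher then falls back to
the spline route. The zero-eigenvalue threshold is a_k < 1e−8 × max a_k.

**Spline extrapolation.** On real data, round-off blurs the null space
and the analytic branch becomes unreliable, so the practical route
evaluates P^[λ] on a λ grid, applies the Fisher transform z = atanh(ρ)
(variance-stabilizing, unbounded), fits one weighted cubic smoothing
spline per edge and evaluates the fit at λ = 0. Numerical choices:

- **Grid:** 21 evenly spaced points on [0.05, 0.95]. The grid is
  deliberately data-independent: two datasets with the same sample
  correlation then get the same profile and hence identical un-shrunk
  estimates, which is precisely the comparability property the estimator
  exists for. Denser grids change results by less than the extrapolation
  error; callers may pass their own grid (e.g. with λ\* inserted).
- **Weights:** the reciprocal condition number of R(λ),
  min a(λ)/max a(λ). Near λ = 0 a singular R̂ makes the profile wild and
  the weight vanishes; near λ = 1 the weight approaches 1.
- **Penalty selection:** generalized cross-validation per edge over a
  fixed log-spaced grid of 41 penalties (1e−8 … 1e2). All edges share the
  grid and the weight vector, so each candidate penalty is one banded
  solve with all edges (plus the identity, which supplies the smoother
  trace) as right-hand sides — this is what makes p ≈ 100 problems take
  fractions of a second. Fits whose smoother trace equals the number of
  knots (interpolation) are excluded, since GCV is undefined there.
- **Extrapolation:** linear from the boundary knot (value and first
  derivative at λ = 0.05), the natural-spline convention; cubic
  extrapolation of the boundary polynomial is unstable and is not what
  reference smoothing-spline implementations do. The package's
  extrapolated values were cross-checked against R's
  `stats::smooth.spline` + `predict` during development.
- **Clamping:** back-transformed values outside (−1, 1) are clamped to
  ±(1 − 1e−12) and counted in the diagnostics, together with per-edge
  weighted residual RMS.

The analytic limit is the arbiter of correctness: the spline route
reproduces it to 2e−2 on the structured singular case (all-ones) and to
1e−3 against the classical values when R̂ is well-conditioned. For
generic strongly singular samples (e.g. p = 8 from n = 6) the two routes
disagree by design: the exact limit is dominated by the sampling-noise
null space (with rank deficiency one it degenerates to ±1 for every
pair), which carries no information about the population network, while
the weighted extrapolation ignores the ill-conditioned boundary layer.
This is why the spline route, not the analytic one, is the default for
n ≤ p data.

## Significance

Under the null, a shrunk partial correlation computed at λ has density
f₀(ρ) ∝ ((1−λ)² − ρ²)^((df−3)/2) on (−(1−λ), 1−λ); equivalently
(ρ/(1−λ))² ~ Beta(½, (df−1)/2). The df parameter absorbs the effective
sample size (at λ = 0 and p conditioned variables it is near n − p) and
is fitted by maximizing the log-likelihood over df ∈ (3, 1e4] with a
bounded scalar search; values on or beyond the support edge are excluded
and counted, and hitting the upper bound (e.g. for degenerate constant
input) is flagged. Two-sided p-values are the symmetric tail mass,
computed exactly as the Beta survival function — the quadrature of f₀
serves as the oracle in tests, not as the implementation. The un-shrunk
route is tested with λ = 0 and df re-fitted on the un-shrunk values.
P-values are nominal; a Benjamini–Hochberg layer is deliberately not
applied by default so that edge counts remain comparable with
nominal-threshold workflows. Edge selection reports, for every pair, the
magnitude flag (|ρ| ≥ 0.1 by default, Cohen's criterion for a weak
correlation) and the significance flag (p < α), plus the four volcano
quadrant counts.

## Simulator

`simulate_network` draws a support uniformly among the p(p−1)/2 pairs
(exactly round(frac · pairs) edges), samples precision off-diagonals
uniformly from ±[0.25, 0.75], and sets the diagonal to one plus the
absolute row sum. Strict diagonal dominance guarantees positive
definiteness for any support, and with the default effect range the
median nonzero |pcor| is ≈ 0.3 — the moderate-effect regime shown in the
estimator-consistency experiments. Data are exact multivariate-normal
draws via the Cholesky factor of the inverse precision. Every stochastic
operation takes an explicit seed; replicate r of a benchmark derives its
seeds from `seed + r`.

What the generator does *not* emulate: library-size or mean–variance
effects of counts, heavy tails, batch structure, temporal correlation
between samples, hub-dominated (scale-free) topologies, and
near-singular population covariances (diagonal dominance keeps marginal
correlations of non-adjacent pairs below those of adjacent ones). Tests
passing on this generator therefore certify the estimators' behaviour
under clean Gaussian sampling, not robustness to real expression data
pathologies.

## Benchmark harness

`run_benchmark` runs a full factorial over sample sizes and replicates
with a fresh network per replicate and identical datasets across methods
(paired design). Edges are ranked by |pcor|; since the fitted null has a
single (λ, df) per method, a p-value ranking would be a monotone
transform of the same order. AUROC is the rank-based Mann–Whitney area
(sklearn), verified against a brute-force concordance count. Between-
method differences are assessed with two-sided paired t-tests across
replicates.

A known limitation, measured rather than assumed: under this generator
(and several stronger-effect and hub-structured variants explored during
development), ranking by the shrunk estimate at λ\* is at least as good
as ranking by the spline-extrapolated un-shrunk estimate for p = 100 and
n ≤ 100 — regularization helps pure edge *ranking* in variance-limited
regimes, even though it demonstrably biases magnitudes, distorts
relative order along λ, and destroys cross-experiment comparability. The
un-shrunk estimator's measurable advantages in this package are on
estimation and comparability: on true edges it is closer to the
population partial correlations for n ≥ 30 (tested at p = 50, n = 90),
and duplicated-data experiments agree to ~1e−14 versus ~1e−1 for the
shrunk estimates.

## Problem sizes

The default test run uses p ≤ 100 with up to 25 replicates for the
benchmark designs, 200 replicated null datasets (p = 10, n = 50) for
type-I calibration, 10⁶ Beta draws for the Monte-Carlo p-value oracle,
and 50 random singular instances for the analytic-limit oracle. The whole
suite completes in well under a minute except the benchmark, which takes
a few tens of seconds.
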