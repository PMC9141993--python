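# Methods

## Model and data

Line 1 lifetimes are i.i.d. GIED(θ₁, λ), line 2 lifetimes i.i.d. GIED(θ₂, λ),
with density `f(x) = θλ e^(−λ/x) x⁻² (1 − e^(−λ/x))^(θ−1)` on x > 0. The two
lines share the rate λ; the exponents differ. Under joint progressive
type-II censoring the pooled test yields, at each of k failures, the failure
time `wᵢ`, the source-line flag `zᵢ`, and the random split `(sᵢ, tᵢ)` of the
`Rᵢ` withdrawals between lines. Conditional on the failure history, each
withdrawal subset is uniform over the active units, i.e. the line split is
hypergeometric. Ties between pooled lifetimes (possible only for rounded
real data) are broken by stable input order, line 1 first.

The observed-data log-likelihood, up to an additive constant, is

    l(θ₁,θ₂,λ) = k₁ lnθ₁ + k₂ lnθ₂ + k lnλ
               + Σᵢ [θ₁sᵢ + θ₂tᵢ + zᵢθ₁ + (1−zᵢ)θ₂ − 1]·Aᵢ(λ)
               − Σᵢ [2 ln wᵢ + λ/wᵢ],      Aᵢ(λ) = ln(1 − e^(−λ/wᵢ)).

No MLE exists when either line contributes no failure (k₁ = 0 or k₂ = 0):
the likelihood is then monotone in the silent line's exponent. The package
raises `NoMLEError`, and the stochastic drivers (bootstrap, Monte Carlo)
discard and redraw such replicates, counting them.

## Maximum likelihood

**Profile route.** At fixed λ the exponents maximize in closed form
(θ̂₁ = −k₁/M(λ), θ̂₂ = −k₂/N(λ) with M, N the weighted sums of Aᵢ), leaving
a one-dimensional profile in λ that is unimodal for identifiable samples.
The profile log-likelihood is evaluated by direct substitution into the
observed-data log-likelihood rather than through a separately coded display
formula — the substituted form is algebraically identical and testable
against the likelihood itself. Maximization brackets an interior peak on an
expanding geometric grid (41 points per pass) and polishes with bounded
Brent (`xatol = 1e−10`).

**EM route.** Withdrawn lifetimes are the missing data. The E-step needs
three conditional moments of a withdrawn lifetime U given U > w:
E[ln U], E[1/U] and E[ln(1 − e^(−λ′/U))]. Given U > w, the survival value
S(U) is uniform on (0, S(w)), so each moment is a bounded integral of the
quantile function — no infinite domains or density evaluations. The public
`estep`/`truncated_expectation` use adaptive quadrature (`scipy` QUADPACK,
tolerances 1e−11); the identity E[ln(1−e^(−λ/U)) | U > w] =
ln(1−e^(−λ/w)) − 1/θ at the conditioning rate provides an exact cross-check,
satisfied to 1e−8 and better.

The M-step maximizes the expected complete-data log-likelihood over λ with
the exponents profiled out in closed form; the censored ln(1−e^(−λ′/U))
expectations are re-evaluated at every candidate λ′ (true EM, preserving the
ascent property). Inside the iteration these re-evaluations use a fixed-node
rule: 240 Gauss–Legendre nodes after the additional substitution q = p³,
which clusters nodes against the logarithmic endpoint singularity in the
deep right tail. The node positions depend only on the current parameters,
so each candidate λ′ costs one vectorized dot product; agreement with
adaptive quadrature is at the 1e−13 level. Iteration stops when all three
successive absolute parameter changes fall below `tol = 1e−4` (default), or
after `max_iter = 500`. Default initialization is a 20-point coarse profile
scan for λ with closed-form exponents; `init` accepts an explicit start
(the Monte Carlo driver can start at the generating truth via
`init_truth=True`).

The two routes solve the same maximization; the test suite requires
agreement to 1e−3 per coordinate across seeded censored datasets.

**Degenerate samples.** For very small samples a boundary pathology exists:
when each line's censored weight is concentrated on a single failure time,
the leading exponential rates in the profile cancel exactly against
−λΣ1/wᵢ and the profile grows like k·lnλ without bound, so no finite MLE
exists even with k₁, k₂ > 0. The two-failure toy sample used in the unit
tests sits exactly on this margin; it is used for closed-form value checks
only, never for fitting. Samples of realistic size (many distinct failure
times) have an interior maximum, which the unimodality tests verify on
random instances.

## Observed information and standard errors

The observed information is assembled by the missing-information principle:

    I_o = m·I₁ + n·I₂ − [Σᵢ sᵢ·I_{U|wᵢ} + Σᵢ tᵢ·I_{V|wᵢ}],

where I₁/I₂ are per-unit *expected* information matrices of one complete
observation (the rows and columns of the other line's exponent are zero) and
the subtracted blocks are conditional expected informations of each
withdrawn lifetime given survival past its withdrawal time. The θθ entries
are exact (1/θ²; the log-density is linear in θ apart from ln θ); the
λ-entries are adaptive-quadrature expectations, cross-checked against Monte
Carlo averages of the analytic second derivatives. The covariance estimate
is I_o⁻¹.

Because the assembled matrix uses expected per-unit information, it matches
the realized observed Hessian (exposed as `observed_hessian`, a
finite-difference diagnostic) only up to O(1/√N) sampling noise — exactly
for the θθ entries when no unit is censored. Standard errors from I_o are
asymptotic; for the small samples this design targets, the bootstrap and
credible intervals are the recommended interval procedures.

## Bootstrap-p intervals

Parametric bootstrap: B refits of samples simulated from the fitted
parameters under the *same* censoring scheme (a resampling bootstrap has no
coherent analogue for a two-line censored design). Refits inside the loop
use the profile route (same maximizer as EM, far cheaper). Endpoints are the
⌊Bζ/2⌋-th and ⌊B(1−ζ/2)⌋-th order statistics (1-based, clipped to the
sample; B = 1 collapses to a degenerate interval). Replicates without a
valid MLE are discarded, redrawn and counted in `n_discarded`.

## Bayesian inference

Independent Gamma priors θ₁ ~ Ga(a₁,b₁), θ₂ ~ Ga(a₂,b₂), λ ~ Ga(c,d); the
non-informative preset sets all six hyper-parameters to 1e−5. The posterior
factorizes into a Ga(c+k, d+Σ1/wᵢ) marginal proposal for λ, conditional
Gamma proposals for the exponents (rates `bᵢ − Σ(...)Aᵢ(λ) > bᵢ` since
Aᵢ < 0), and an importance weight depending on λ only. All weight
arithmetic is in log space with log-sum-exp normalization — the
Πᵢ(1−e^(−λ/wᵢ))⁻¹ factor overflows naively for k beyond a few dozen. The
effective sample size (Σqᵢ²)⁻¹ is reported as a diagnostic; heavily censored
or large-k datasets deserve a look at it before trusting the estimates.

Linex estimates use `−(1/h)·logsumexp(−h·g, weights)`; h → 0 recovers the
posterior mean, and h > 0 shades the estimate downward (Jensen). Default
h = 2.

**Credible intervals.** The symmetric-tail rule is implemented on the
sorted weighted draws: among index pairs whose enclosed normalized weight
does not exceed the level but would with one more draw, the pair with the
most nearly equal tail masses is returned (ties to the lower pair). For
uniform weights this coincides with the percentile rule up to one order
statistic; at exact-tie boundaries (e.g. M·ζ/2 integral) it selects the pair
whose tails are exactly ζ/2 each, which can differ by one position from the
naive ⌊Mζ/2⌋ index. Shortest-interval variants are deliberately not offered;
the symmetric-tail convention is the documented one.

A one-dimensional grid-integration oracle (exponents integrated analytically
as Gamma integrals) validates the sampler: posterior means agree within 1%
at M = 50,000.

## Order restriction θ₁ < θ₂

At fixed λ, if the unrestricted exponents already satisfy the order they are
kept; otherwise the constrained maximum lies on the diagonal with the pooled
closed form θ̃ = −k / Σ(Rᵢ+1)Aᵢ(λ) (the unique positive stationary point on
θ₁ = θ₂, verified against a grid maximization). The restricted profile in λ
is maximized the same way; the result never exceeds the unrestricted
likelihood and equals it exactly off the boundary.

The order-restricted prior symmetrizes the exponent shapes across lines and
truncates to θ₁ < θ₂. Sampling proceeds from the implied *unrestricted*
two-component Gamma mixture (components mixed in proportion to their
normalizing constants at each drawn λ) and zeroes the weight of draws
violating the order. The acceptance fraction then estimates the posterior
probability of the ordering, validated against a grid oracle. This sampler
is this package's own completion of an otherwise unspecified step and is
validated only against internal oracles. How interval calibration should
treat boundary solutions is left to the user; `on_boundary` is always
reported.

## Goodness of fit and the shared-rate test

`ks_gof` computes the Kolmogorov–Smirnov distance between the fitted cdf and
the empirical distribution under two conventions: `"mean_rank"` (default)
uses the plotting positions i/(n+1), the convention common in reliability
work and the one under which the worked example's printed distances
reproduce; `"sup"` is the classical two-sided statistic. P-values use the
exact one-sample Kolmogorov distribution for n ≤ 100 (asymptotic beyond) and
are calibrated for the classical statistic with known parameters; with
estimated parameters and the mean-rank convention they are descriptive, not
exact.

`lrt_common_lambda` tests one shared rate across two complete samples:
alternative = two free (θ, λ) fits; null = (θ₁, θ₂, common λ) fitted
jointly; 2·Δloglik referred to χ²(1). Both logliks include all data-only
terms so the statistic is invariant to the ÷1000 rescaling.

## Synthetic data and study driver

`simulate_jpc` draws the two complete samples by inverse transform and
applies the withdrawal process exactly as specified (uniform subsets).
Defaults in the shipped study configuration follow the simulation design the
package targets: truth (θ₁, θ₂, λ) = (1, 1, 0.5), m = 20, n = 25,
k ∈ {20, 25, 30}, the tabulated withdrawal schemes, non-informative
hyper-parameters 1e−5, informative prior (a₁,b₁,a₂,b₂,c,d) = (2,1,1,2,3,2),
h = 2, 90% intervals. The generator emulates exactly the model's
assumptions — independent GIED lifetimes, uniformly random withdrawals, a
genuinely shared λ. Real life tests can violate all three (dependence,
informative withdrawal, heterogeneous rates), so passing tests certify the
procedures under the model, not robustness to its failure.

The test suite and acceptance checks run scaled-down designs chosen as the
package's defaults for routine verification: 200 replicates with B = 200
bootstrap refits and M = 2000 draws for interval calibration (coverage
asserted within the Monte Carlo band [0.80, 0.97] at nominal 90%), 20
datasets for the EM/profile agreement check, 50 random instances for
unimodality scans. The Monte Carlo driver accepts arbitrary replicate
counts for full-scale studies.

## Known limitations

- Expected (not realized) per-unit information in I_o; see above.
- The importance sampler degrades (low ESS) for large k with heavy
  censoring; an MCMC alternative is out of scope.
- The mean-rank/classical K-S duality is a convention choice, not a
  statistical resolution; distances under the two differ at n = 30 by
  ~0.02.
- Two populations only; no order restriction on λ; type-I/hybrid censoring
  variants are out of scope.
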