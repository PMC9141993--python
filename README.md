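# jpcgied

Statistical inference for **two lifetime populations following the
generalized inverted exponential distribution (GIED)** observed under
**joint progressive type-II censoring (JPC)**.

## The problem

Two production lines contribute `m` and `n` units to a single pooled life
test. Each line's lifetimes follow a GIED with cdf

    F(x; θ, λ) = 1 − (1 − e^(−λ/x))^θ ,   x > 0,

with a **shared rate λ** across lines and **distinct exponents θ₁, θ₂**. The
GIED has a unimodal hazard, which suits aging phenomena whose failure rate
first rises and then falls. At the *i*-th observed failure `wᵢ`, `Rᵢ` of the
surviving units are withdrawn at random from the pooled risk set; the test
stops after `k` failures. The observed record is `((wᵢ, zᵢ, sᵢ, tᵢ))`,
where `zᵢ` flags a line-1 failure and `sᵢ + tᵢ = Rᵢ` splits the withdrawals
between lines. Schemes use the compact notation `(0(4),25,0(15))` (four
zeros, one 25, fifteen zeros), constrained by `Σ(Rᵢ+1) = m + n`.

The package implements, for this model:

- **Maximum likelihood** by two independent routes: a one-dimensional
  *profile* in λ (the exponents maximize in closed form,
  `θ̂₁(λ) = −k₁/Σ(zᵢ+sᵢ)ln(1−e^(−λ/wᵢ))`), and an **EM algorithm** that
  treats the withdrawn units' lifetimes as missing data. The profile is
  unimodal whenever each line contributes at least one failure; no MLE
  exists otherwise.
- **Observed Fisher information** by the missing-information principle
  (complete-data information minus the information carried by each withdrawn
  lifetime), with standard errors from its inverse.
- **Bootstrap-p intervals**: parametric refits under the same scheme,
  percentile endpoints.
- **Bayesian inference** with independent Gamma priors: the posterior
  factorizes into three Gamma components plus a λ-only importance weight;
  point estimates under squared-error and linex (`−(1/h)·ln E[e^(−hω)]`)
  losses, and symmetric-tail weighted credible intervals.
- **Order-restricted inference** under `θ₁ < θ₂`: profile MLE with a pooled
  closed form on the boundary, and an indicator-weighted mixture importance
  sampler for the symmetrized prior.
- **Study drivers**: a seeded Monte Carlo engine (average estimates, MSE,
  interval length and coverage per scheme cell) and the complete jute-fiber
  worked analysis.

## Worked example

The package embeds the jute-fiber breaking-strength data (two gauge lengths,
30 specimens each, analyzed on the ÷1000 scale):

```python
import jpcgied as J

x1, x2 = J.load_jute()
p1 = J.complete_sample_mle(x1)
D1, pv1 = J.ks_gof(x1, p1)
print(p1.theta, p1.lam, D1)        # 1.841  0.293  0.121

stat, pv, joint = J.lrt_common_lambda(x1, x2)
print(joint)                        # theta1=1.454, theta2=1.596, lam=0.228
```

The first fit says the 10 mm-gauge strengths are well described by a GIED
with exponent 1.841 and rate 0.293 (K-S distance 0.121, p ≈ 0.72: no
evidence against the fit). The likelihood-ratio test compares separate-rate
fits against a shared rate; on these data `stat = 1.944` (p = 0.163), so a
common λ is tenable and the joint fit pools both samples through one rate.

Censored-data workflow on simulated data:

```python
sch = J.parse_scheme("(0(4),25,0(15))", m=20, n=25, k=20)
d = J.simulate_jpc(J.JointGIEDParams(1.0, 1.0, 0.5), sch, seed=42)

fr = J.fit_profile(d)               # theta1=1.049 theta2=1.027 lam=0.620
J.observed_info(fr.params, d).standard_errors   # [0.369 0.408 0.137]
J.bootstrap_p(d, B=1000, level=0.90, seed=7)["lam"]   # (0.470, 0.973)

is_ = J.importance_sample(d, J.PriorSpec.noninformative(), M=10_000, seed=8)
J.bayes_estimate(is_, "lam")                    # 0.611 (posterior mean)
J.bayes_estimate(is_, "lam", "linex", h=2.0)    # 0.592 (penalizes over-estimation)
J.credible_interval(is_, "lam", 0.90)           # (0.398, 0.858)
```

The shared rate is estimated much more precisely than either exponent — it
pools information from both lines — a pattern the Monte Carlo driver
(`jpcgied.monte_carlo`) reproduces across schemes.

A `jpcgied` console script exposes the same steps
(`simulate`, `fit`, `bootstrap`, `bayes`, `montecarlo`, `realdata`,
`gied`); see `jpcgied --help`.

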