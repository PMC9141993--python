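"""Inference under the order restriction ``theta1 < theta2``.

A smaller exponent means stochastically larger lifetimes in this family, so
the restriction encodes prior knowledge that line 1 outlives line 2.  At
fixed ``lam`` the restricted exponent MLEs equal the unrestricted ones when
those already satisfy the order; otherwise the constrained maximum sits on
the boundary ``theta1 = theta2`` where the pooled closed form

    theta_tilde = -k / sum_i (R_i + 1) ln(1 - e^(-lam/w_i))

maximizes the likelihood along the diagonal.  The restricted profile in
``lam`` remains unimodal and is maximized by the same one-dimensional
machinery as the unrestricted fit.

The order-restricted posterior symmetrizes the exponent prior across the two
lines and truncates to ``theta1 < theta2``.  Sampling uses the unrestricted
two-component Gamma mixture implied by the symmetrized prior and multiplies
each importance weight by the order indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .bayes import ImportanceSample, PriorSpec, posterior_components
from .gied import JointGIEDParams, log1mexp
from .mle import _maximize_scalar, observed_loglik, profile_shapes
from .scheme import JPCSample

__all__ = [
    "RestrictedFitResult",
    "restricted_shapes",
    "fit_restricted",
    "restricted_bayes",
]


@dataclass
class RestrictedFitResult:
    params: JointGIEDParams
    on_boundary: bool
    loglik: float


def restricted_shapes(lam: float, data: JPCSample) -> tuple[float, float, bool]:
    """Exponent MLEs at fixed ``lam`` under ``theta1 <= theta2``."""
    th1, th2 = profile_shapes(lam, data)
    if th1 < th2:
        return th1, th2, False
    a = log1mexp(lam / data.w)
    pooled = float(-data.k / np.sum((1 + data.s + data.t) * a))
    return pooled, pooled, True


def _restricted_profile_loglik(lam: float, data: JPCSample) -> float:
    th1, th2, _ = restricted_shapes(lam, data)
    return observed_loglik(JointGIEDParams(th1, th2, lam), data)


def fit_restricted(data: JPCSample, bracket: tuple[float, float] = (1e-4, 4.0)) -> RestrictedFitResult:
    """Order-restricted MLE by maximizing the restricted profile in ``lam``."""
    lam, _ = _maximize_scalar(lambda l: _restricted_profile_loglik(l, data), *bracket)
    th1, th2, boundary = restricted_shapes(lam, data)
    params = JointGIEDParams(th1, th2, lam)
    return RestrictedFitResult(params=params, on_boundary=boundary,
                               loglik=observed_loglik(params, data))


def restricted_bayes(data: JPCSample, prior: PriorSpec, M: int = 10_000, seed=None) -> ImportanceSample:
    """Importance sample from the order-restricted posterior.

    The symmetrized prior yields, at each sampled ``lam``, a two-component
    mixture of conditional Gamma pairs for the exponents — one with shapes
    ``(a1 + k1, a2 + k2)`` and one with the prior shapes swapped — mixed in
    proportion to their normalizing constants.  Draws violating
    ``theta1 < theta2`` receive zero weight.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = posterior_components(data, prior)
    a1, a2 = prior.a1, prior.a2
    k1, k2 = data.k1, data.k2

    lam = rng.gamma(shape=comp.lam_shape, scale=1.0 / comp.lam_rate, size=M)
    r1, r2 = comp.theta_rates(lam)
    # log normalizing constants of the two exponent components at each lam
    logZA = (gammaln(a1 + k1) - (a1 + k1) * np.log(r1)
             + gammaln(a2 + k2) - (a2 + k2) * np.log(r2))
    logZB = (gammaln(a2 + k1) - (a2 + k1) * np.log(r1)
             + gammaln(a1 + k2) - (a1 + k2) * np.log(r2))
    pA = np.exp(logZA - np.logaddexp(logZA, logZB))
    pick_A = rng.uniform(size=M) < pA
    sh1 = np.where(pick_A, a1 + k1, a2 + k1)
    sh2 = np.where(pick_A, a2 + k2, a1 + k2)
    th1 = rng.gamma(shape=sh1, scale=1.0 / r1)
    th2 = rng.gamma(shape=sh2, scale=1.0 / r2)

    A = log1mexp(lam[:, None] / data.w[None, :])
    logw = -np.sum(A, axis=1) + np.logaddexp(logZA, logZB)
    keep = th1 < th2
    if not np.any(keep):
        raise RuntimeError(
            "all draws violated theta1 < theta2; increase M or reconsider the restriction"
        )
    logw = np.where(keep, logw, -np.inf)
    q = np.exp(logw - logsumexp(logw[keep]))
    return ImportanceSample(theta1=th1, theta2=th2, lam=lam,
                            log_raw_weights=logw, weights=q, M=M, seed=seed)
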