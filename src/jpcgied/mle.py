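"""Likelihood and maximum-likelihood estimation for the two-population model.

The observed-data log-likelihood for a JPC sample, up to an additive
constant, is

    l = k1 ln th1 + k2 ln th2 + k ln lam
        + sum_i [th1 s_i + th2 t_i + z_i th1 + (1-z_i) th2 - 1] * A_i(lam)
        - sum_i [2 ln w_i + lam / w_i],        A_i(lam) = ln(1 - e^(-lam/w_i)).

For fixed ``lam`` the maximizing exponents are available in closed form,

    th1(lam) = -k1 / M(lam),   M(lam) = sum_i (z_i + s_i) A_i(lam),
    th2(lam) = -k2 / N(lam),   N(lam) = sum_i (1 - z_i + t_i) A_i(lam),

so the three-dimensional problem reduces to a one-dimensional profile in
``lam``, which is unimodal whenever ``k1 > 0`` and ``k2 > 0``.  No MLE exists
when either line contributes no failure.

Two routes to the same maximizer are provided: direct profile maximization
(:func:`fit_profile`) and an EM algorithm (:func:`fit_em`) that treats the
withdrawn units' unobserved lifetimes as missing data.  The E-step moments of
a withdrawn lifetime ``U`` given ``U > w`` are computed by quadrature after
the probability-integral substitution ``v = S(u)``, which maps the truncated
expectation onto a bounded interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .gied import GIEDParams, JointGIEDParams, log1mexp, quantile, sf
from .scheme import JPCSample

__all__ = [
    "NoMLEError",
    "FitResult",
    "EStepExpectations",
    "observed_loglik",
    "profile_shapes",
    "profile_loglik",
    "fit_profile",
    "truncated_expectation",
    "estep",
    "fit_em",
]


class NoMLEError(ValueError):
    """Raised when a maximum likelihood estimate does not exist (k1 or k2 = 0)."""


@dataclass
class FitResult:
    params: JointGIEDParams
    loglik: float
    method: str  # "profile" | "em"
    iterations: int = 0
    converged: bool = True
    trace: list = field(default_factory=list, repr=False)


def _A(lam, w):
    return log1mexp(lam / w)


def observed_loglik(params: JointGIEDParams, data: JPCSample) -> float:
    """Observed-data log-likelihood (normalizing constant omitted)."""
    a = _A(params.lam, data.w)
    coef = (
        params.theta1 * data.s
        + params.theta2 * data.t
        + data.z * params.theta1
        + (1 - data.z) * params.theta2
        - 1.0
    )
    return float(
        data.k1 * np.log(params.theta1)
        + data.k2 * np.log(params.theta2)
        + data.k * np.log(params.lam)
        + np.sum(coef * a)
        - np.sum(2.0 * np.log(data.w) + params.lam / data.w)
    )


def _check_identifiable(data: JPCSample) -> None:
    if data.k1 == 0 or data.k2 == 0:
        raise NoMLEError(
            f"no MLE exists when a line has no observed failure (k1={data.k1}, k2={data.k2})"
        )


def profile_shapes(lam: float, data: JPCSample) -> tuple[float, float]:
    """Closed-form exponent MLEs at fixed ``lam``."""
    _check_identifiable(data)
    a = _A(lam, data.w)
    M = np.sum((data.z + data.s) * a)
    N = np.sum((1 - data.z + data.t) * a)
    return float(-data.k1 / M), float(-data.k2 / N)


def profile_loglik(lam: float, data: JPCSample) -> float:
    """Profile log-likelihood of ``lam``: exponents plugged in at their MLEs.

    Returns ``-inf`` when ``lam`` is so large that every censored-survival
    term underflows (the closed-form exponents overflow there); such values
    lie far beyond any interior maximum for non-degenerate samples.
    """
    th1, th2 = profile_shapes(lam, data)
    if not (np.isfinite(th1) and np.isfinite(th2)):
        return -np.inf
    return observed_loglik(JointGIEDParams(th1, th2, lam), data)


def _maximize_scalar(f, lo: float = 1e-4, hi: float = 4.0, expand_cap: int = 60):
    """Maximize a unimodal scalar function on (0, inf).

    A geometric grid locates an interior bracket (expanding ``hi`` and
    shrinking ``lo`` as needed), then bounded Brent polishes the maximum.
    """
    for _ in range(expand_cap):
        grid = np.geomspace(lo, hi, 41)
        vals = np.array([f(g) for g in grid])
        j = int(np.nanargmax(vals))
        if j == len(grid) - 1:
            hi *= 8.0
        elif j == 0:
            lo /= 8.0
        else:
            break
    else:
        raise RuntimeError("could not bracket an interior maximum")
    res = minimize_scalar(
        lambda x: -f(x),
        bounds=(grid[j - 1], grid[j + 1]),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), bool(res.success)


def fit_profile(data: JPCSample, bracket: tuple[float, float] = (1e-4, 4.0)) -> FitResult:
    """MLE of ``(theta1, theta2, lam)`` by profile maximization over ``lam``."""
    _check_identifiable(data)
    lam, ok = _maximize_scalar(lambda l: profile_loglik(l, data), *bracket)
    th1, th2 = profile_shapes(lam, data)
    params = JointGIEDParams(th1, th2, lam)
    return FitResult(params=params, loglik=observed_loglik(params, data),
                     method="profile", iterations=0, converged=ok)


# ---------------------------------------------------------------------------
# EM algorithm
# ---------------------------------------------------------------------------


def truncated_expectation(g, p: GIEDParams, w: float) -> float:
    """``E[g(U) | U > w]`` for ``U ~`` GIED(``p``), by quadrature.

    Given ``U > w`` the survival value ``V = S(U)`` is uniform on
    ``(0, S(w))``, so the expectation is a bounded integral of
    ``g(quantile(1 - S(w) q))`` over ``q in (0, 1)``.
    """
    Sw = float(sf(w, p))

    def integrand(q):
        u = quantile(1.0 - Sw * q, p)
        return g(u)

    val, _ = quad(integrand, 0.0, 1.0, epsabs=1e-11, epsrel=1e-11, limit=200)
    return val


@dataclass
class EStepExpectations:
    """Per-failure conditional moments of the withdrawn units' lifetimes.

    Entries are 0 where the corresponding withdrawal count is 0.
    ``e_log1mexp_*`` is evaluated with the kernel rate ``lam_eval``, which the
    EM M-step varies, while the conditioning distribution uses the current
    parameter iterate.
    """

    e_log_u: np.ndarray
    e_inv_u: np.ndarray
    e_log1mexp_u: np.ndarray
    e_log_v: np.ndarray
    e_inv_v: np.ndarray
    e_log1mexp_v: np.ndarray
    lam_eval: float


def estep(params: JointGIEDParams, data: JPCSample, lam_eval: float | None = None) -> EStepExpectations:
    """Conditional expectations of the latent withdrawn lifetimes."""
    if lam_eval is None:
        lam_eval = params.lam
    k = data.k
    out = {name: np.zeros(k) for name in
           ("e_log_u", "e_inv_u", "e_log1mexp_u", "e_log_v", "e_inv_v", "e_log1mexp_v")}
    for i in range(k):
        w = float(data.w[i])
        if data.s[i] > 0:
            p1 = params.line1
            out["e_log_u"][i] = truncated_expectation(np.log, p1, w)
            out["e_inv_u"][i] = truncated_expectation(lambda u: 1.0 / u, p1, w)
            out["e_log1mexp_u"][i] = truncated_expectation(
                lambda u: log1mexp(lam_eval / u), p1, w)
        if data.t[i] > 0:
            p2 = params.line2
            out["e_log_v"][i] = truncated_expectation(np.log, p2, w)
            out["e_inv_v"][i] = truncated_expectation(lambda u: 1.0 / u, p2, w)
            out["e_log1mexp_v"][i] = truncated_expectation(
                lambda u: log1mexp(lam_eval / u), p2, w)
    return EStepExpectations(lam_eval=float(lam_eval), **out)


class _TruncatedGrid:
    """Fixed-node quadrature for truncated expectations inside EM.

    Precomputes, per censored failure index, the latent-lifetime values
    ``u_{ij} = quantile(1 - S(w_i) q_j)`` at transformed Gauss-Legendre nodes
    ``q_j`` (the substitution ``q = p**3`` clusters nodes near the deep right
    tail, where the integrands have a logarithmic endpoint singularity).  The
    nodes depend only on the conditioning parameters, so expectations of any
    function — in particular ``ln(1 - e^(-lam'/u))`` at every candidate
    ``lam'`` of the M-step — become vectorized dot products.
    """

    _cache: dict = {}

    def __init__(self, params: JointGIEDParams, data: JPCSample, n_nodes: int = 240):
        if n_nodes not in self._cache:
            p, wt = np.polynomial.legendre.leggauss(n_nodes)
            p = 0.5 * (p + 1.0)
            wt = 0.5 * wt
            self._cache[n_nodes] = (p**3, 3.0 * wt * p**2)
        q, self.wq = self._cache[n_nodes]
        self.data = data
        self.u1 = {}  # i -> latent line-1 lifetimes at the nodes
        self.u2 = {}
        for i in range(data.k):
            w = float(data.w[i])
            if data.s[i] > 0:
                Sw = float(sf(w, params.line1))
                self.u1[i] = quantile(1.0 - Sw * q, params.line1)
            if data.t[i] > 0:
                Sw = float(sf(w, params.line2))
                self.u2[i] = quantile(1.0 - Sw * q, params.line2)

    def weighted_sums(self, g):
        """``sum_i s_i E[g(U_i)]`` and ``sum_i t_i E[g(V_i)]``."""
        d = self.data
        a1 = sum(d.s[i] * float(self.wq @ g(u)) for i, u in self.u1.items())
        a2 = sum(d.t[i] * float(self.wq @ g(u)) for i, u in self.u2.items())
        return a1, a2


def fit_em(
    data: JPCSample,
    init: JointGIEDParams | None = None,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> FitResult:
    """EM iteration for the MLE, treating withdrawn lifetimes as missing data.

    Each iteration (i) computes the conditional moments of the withdrawn
    lifetimes under the current parameters, (ii) maximizes the expected
    complete-data log-likelihood over ``lam`` by a one-dimensional search in
    which the censored ``ln(1-e^(-lam'/U))`` expectations are re-evaluated at
    every candidate ``lam'`` (with the exponents profiled out in closed form),
    then (iii) refreshes ``theta1, theta2``.  Iteration stops when all three
    successive absolute changes fall below ``tol``.
    """
    _check_identifiable(data)
    m, n = data.scheme.m, data.scheme.n
    if init is None:
        # coarse profile scan for lam, closed-form exponents
        grid = np.geomspace(1e-3, 10.0, 20)
        lam0 = grid[int(np.argmax([profile_loglik(g, data) for g in grid]))]
        th1, th2 = profile_shapes(lam0, data)
        cur = JointGIEDParams(th1, th2, float(lam0))
    else:
        cur = init

    trace = [cur]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: fix the truncated-lifetime node grid at the current params
        grid = _TruncatedGrid(cur, data)
        inv1, inv2 = grid.weighted_sums(lambda u: 1.0 / u)
        C = float(np.sum(1.0 / data.w)) + inv1 + inv2

        def q_profile(lam_new: float) -> float:
            A1, A2 = grid.weighted_sums(lambda u: log1mexp(lam_new / u))
            a_w = _A(lam_new, data.w)
            d1 = A1 + float(np.sum(data.z * a_w))
            d2 = A2 + float(np.sum((1 - data.z) * a_w))
            th1n, th2n = -m / d1, -n / d2
            return (
                m * np.log(th1n)
                + n * np.log(th2n)
                + (m + n) * np.log(lam_new)
                - lam_new * C
                + (th1n - 1.0) * A1
                + (th2n - 1.0) * A2
                + float(np.sum((data.z * th1n + (1 - data.z) * th2n - 1.0) * a_w))
            )

        lam_new, _ = _maximize_scalar(q_profile, cur.lam / 16.0, cur.lam * 16.0)
        A1, A2 = grid.weighted_sums(lambda u: log1mexp(lam_new / u))
        a_w = _A(lam_new, data.w)
        th1_new = float(-m / (A1 + np.sum(data.z * a_w)))
        th2_new = float(-n / (A2 + np.sum((1 - data.z) * a_w)))
        new = JointGIEDParams(th1_new, th2_new, lam_new)
        trace.append(new)
        if (
            abs(th1_new - cur.theta1) <= tol
            and abs(th2_new - cur.theta2) <= tol
            and abs(lam_new - cur.lam) <= tol
        ):
            cur = new
            converged = True
            break
        cur = new

    return FitResult(params=cur, loglik=observed_loglik(cur, data),
                     method="em", iterations=it, converged=converged, trace=trace)
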