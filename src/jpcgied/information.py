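"""Observed Fisher information via the missing-information principle.

The observed information for ``(theta1, theta2, lam)`` is assembled as

    I_o = m I_1 + n I_2 - [ sum_i s_i I_{U|w_i} + sum_i t_i I_{V|w_i} ]

where ``I_1`` / ``I_2`` are the per-unit expected information matrices of a
single GIED observation from each line (rows and columns of the absent
exponent are zero) and the subtracted blocks are the expected information
carried by each withdrawn unit's unobserved lifetime given that it exceeds
its withdrawal time.  The inverse of ``I_o`` estimates the covariance of the
MLEs.

All expectations are computed by adaptive quadrature after the
probability-integral substitution; the ``theta``-``theta`` entries are exact
(``1/theta**2``) because the log-density is linear in ``theta`` apart from
``ln theta``.  A finite-difference Hessian of the observed log-likelihood is
exposed separately as a diagnostic: the assembled ``I_o`` uses *expected*
per-unit information, so the two agree only up to sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .gied import GIEDParams, JointGIEDParams, quantile, sf
from .mle import observed_loglik
from .scheme import JPCSample

__all__ = [
    "InfoMatrices",
    "unit_expected_info",
    "missing_unit_info",
    "observed_info",
    "observed_hessian",
]


def _dA_dlam(x, lam):
    """d/dlam ln(1 - e^(-lam/x)) = (1/x) e^(-lam/x) / (1 - e^(-lam/x))."""
    t = lam / x
    return (1.0 / x) * np.exp(-t) / (-np.expm1(-t))


def _neg_d2A_dlam2(x, lam):
    """-d2/dlam2 ln(1 - e^(-lam/x)) = (1/x^2) e^(-lam/x) / (1 - e^(-lam/x))^2."""
    t = lam / x
    return (1.0 / x**2) * np.exp(-t) / (-np.expm1(-t)) ** 2


def _expect(g, p: GIEDParams) -> float:
    """E[g(X)] for X ~ GIED(p) via X = quantile(1 - V), V uniform on (0,1)."""
    val, _ = quad(lambda v: g(quantile(1.0 - v, p)), 0.0, 1.0,
                  epsabs=1e-11, epsrel=1e-11, limit=200)
    return val


def _trunc_expect(g, p: GIEDParams, w: float) -> float:
    Sw = float(sf(w, p))
    val, _ = quad(lambda q: g(quantile(1.0 - Sw * q, p)), 0.0, 1.0,
                  epsabs=1e-11, epsrel=1e-11, limit=200)
    return val


def _place(theta_idx: int, i_tt: float, i_tl: float, i_ll: float) -> np.ndarray:
    out = np.zeros((3, 3))
    out[theta_idx, theta_idx] = i_tt
    out[theta_idx, 2] = out[2, theta_idx] = i_tl
    out[2, 2] = i_ll
    return out


def _theta_index(which_theta: str) -> int:
    if which_theta not in ("theta1", "theta2"):
        raise ValueError("which_theta must be 'theta1' or 'theta2'")
    return 0 if which_theta == "theta1" else 1


def unit_expected_info(p: GIEDParams, which_theta: str) -> np.ndarray:
    """Expected information of one complete GIED observation, embedded 3x3.

    Entries are ``-E[second derivatives of ln f]``: the exponent-exponent
    entry is ``1/theta**2`` exactly; the cross and rate-rate entries are
    quadrature expectations.  Rows/columns of the other line's exponent are
    zero.
    """
    idx = _theta_index(which_theta)
    i_tt = 1.0 / p.theta**2
    i_tl = -_expect(lambda x: _dA_dlam(x, p.lam), p)
    i_ll = 1.0 / p.lam**2 + (p.theta - 1.0) * _expect(
        lambda x: _neg_d2A_dlam2(x, p.lam), p)
    return _place(idx, i_tt, i_tl, i_ll)


def missing_unit_info(p: GIEDParams, w: float, which_theta: str) -> np.ndarray:
    """Expected information of a withdrawn unit's lifetime given ``U > w``.

    The conditional log-density is ``ln f(u) - theta * ln(1 - e^(-lam/w))``;
    the truncation term is linear in ``theta`` so the exponent-exponent entry
    is again ``1/theta**2``, while the rate derivatives pick up boundary
    terms at ``w``.
    """
    if w <= 0:
        raise ValueError("w must be positive")
    idx = _theta_index(which_theta)
    i_tt = 1.0 / p.theta**2
    i_tl = -_trunc_expect(lambda u: _dA_dlam(u, p.lam), p, w) + _dA_dlam(w, p.lam)
    i_ll = (
        1.0 / p.lam**2
        + (p.theta - 1.0) * _trunc_expect(lambda u: _neg_d2A_dlam2(u, p.lam), p, w)
        - p.theta * _neg_d2A_dlam2(w, p.lam)
    )
    return _place(idx, i_tt, i_tl, i_ll)


@dataclass
class InfoMatrices:
    complete_unit_line1: np.ndarray
    complete_unit_line2: np.ndarray
    missing_per_censored: list
    observed: np.ndarray
    covariance: np.ndarray

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.covariance))


def observed_info(params: JointGIEDParams, data: JPCSample) -> InfoMatrices:
    """Assemble ``I_o`` and its inverse for a fitted (or candidate) parameter."""
    I1 = unit_expected_info(params.line1, "theta1")
    I2 = unit_expected_info(params.line2, "theta2")
    missing = []
    Imiss = np.zeros((3, 3))
    for i in range(data.k):
        w = float(data.w[i])
        if data.s[i] > 0:
            block = missing_unit_info(params.line1, w, "theta1")
            missing.extend([block] * int(data.s[i]))
            Imiss += data.s[i] * block
        if data.t[i] > 0:
            block = missing_unit_info(params.line2, w, "theta2")
            missing.extend([block] * int(data.t[i]))
            Imiss += data.t[i] * block
    Io = data.scheme.m * I1 + data.scheme.n * I2 - Imiss
    try:
        cov = np.linalg.inv(Io)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "observed information matrix is singular; the sample may be too "
            "small or the estimate on the parameter boundary"
        ) from exc
    return InfoMatrices(
        complete_unit_line1=I1,
        complete_unit_line2=I2,
        missing_per_censored=missing,
        observed=Io,
        covariance=cov,
    )


def observed_hessian(params: JointGIEDParams, data: JPCSample, rel_step: float = 1e-5) -> np.ndarray:
    """Negative finite-difference Hessian of the observed log-likelihood.

    Diagnostic companion to :func:`observed_info`; central differences with
    multiplicative steps (all parameters are positive).
    """
    p0 = np.array([params.theta1, params.theta2, params.lam])
    h = rel_step * p0

    def f(v):
        return observed_loglik(JointGIEDParams(*v), data)

    H = np.zeros((3, 3))
    f0 = f(p0)
    for a in range(3):
        for b in range(a, 3):
            if a == b:
                vp, vm = p0.copy(), p0.copy()
                vp[a] += h[a]
                vm[a] -= h[a]
                H[a, a] = (f(vp) - 2.0 * f0 + f(vm)) / h[a] ** 2
            else:
                vpp, vpm, vmp, vmm = (p0.copy() for _ in range(4))
                vpp[[a, b]] += h[[a, b]]
                vpm[a] += h[a]; vpm[b] -= h[b]
                vmp[a] -= h[a]; vmp[b] += h[b]
                vmm[[a, b]] -= h[[a, b]]
                H[a, b] = H[b, a] = (f(vpp) - f(vpm) - f(vmp) + f(vmm)) / (4.0 * h[a] * h[b])
    return -H
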