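"""Generalized inverted exponential distribution (GIED).

The GIED has cdf ``F(x) = 1 - (1 - exp(-lam/x))**theta`` on ``x > 0`` with
``theta, lam > 0``.  It is the distribution of ``1/Y`` when ``Y`` follows a
generalized exponential law, and its hazard rate is unimodal, which makes it
a convenient lifetime model for aging phenomena whose failure rate first
rises and then declines.

The literature is inconsistent about which of ``theta`` and ``lam`` is the
"shape" and which the "scale"; this module stores the symbols and avoids the
labels.  ``theta`` is the exponent applied to ``1 - exp(-lam/x)`` and ``lam``
is the rate inside the exponential kernel.  Under the time rescaling
``x -> c*x`` the family is closed with ``lam -> c*lam``.

All evaluation is done in log space: the factor ``(1-exp(-lam/x))**(theta-1)``
loses precision quickly when computed naively because the exponent amplifies
rounding in the base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GIEDParams",
    "JointGIEDParams",
    "logpdf",
    "pdf",
    "cdf",
    "sf",
    "hazard",
    "quantile",
    "rvs",
]


@dataclass(frozen=True)
class GIEDParams:
    """Parameter pair of a single GIED population.

    Attributes
    ----------
    theta : float
        Exponent parameter, ``theta > 0``.
    lam : float
        Rate parameter inside ``exp(-lam/x)``, ``lam > 0``.
    """

    theta: float
    lam: float

    def __post_init__(self) -> None:
        if not (self.theta > 0 and np.isfinite(self.theta)):
            raise ValueError(f"theta must be a positive finite real, got {self.theta}")
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ValueError(f"lam must be a positive finite real, got {self.lam}")


@dataclass(frozen=True)
class JointGIEDParams:
    """Parameters of the two-population model: distinct exponents, shared rate."""

    theta1: float
    theta2: float
    lam: float

    def __post_init__(self) -> None:
        for name in ("theta1", "theta2", "lam"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be a positive finite real, got {v}")

    @property
    def line1(self) -> GIEDParams:
        return GIEDParams(self.theta1, self.lam)

    @property
    def line2(self) -> GIEDParams:
        return GIEDParams(self.theta2, self.lam)


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError("x must be strictly positive and finite")
    return x


def log1mexp(t):
    """``log(1 - exp(-t))`` for ``t > 0``, stable in both tails.

    Below ``ln 2`` use ``log(-expm1(-t))`` (accurate as ``1-exp(-t) ~ t``);
    above it use ``log1p(-exp(-t))``, which keeps the result nonzero down to
    ``-exp(-t)`` near the underflow limit instead of rounding to 0.
    """
    t = np.asarray(t, dtype=float)
    big = t > 0.693
    # clamp each branch's argument into its safe region; np.where evaluates both
    return np.where(
        big,
        np.log1p(-np.exp(-np.maximum(t, 0.5))),
        np.log(-np.expm1(-np.minimum(t, 1.0))),
    )


def logpdf(x, p: GIEDParams):
    x = _check_x(x)
    t = p.lam / x
    return (
        np.log(p.theta)
        + np.log(p.lam)
        - t
        - 2.0 * np.log(x)
        + (p.theta - 1.0) * log1mexp(t)
    )


def pdf(x, p: GIEDParams):
    """Density ``theta*lam*exp(-lam/x)*x**-2*(1-exp(-lam/x))**(theta-1)``."""
    return np.exp(logpdf(x, p))


def logsf(x, p: GIEDParams):
    """Log survival function ``theta * log(1 - exp(-lam/x))``."""
    x = _check_x(x)
    return p.theta * log1mexp(p.lam / x)


def sf(x, p: GIEDParams):
    return np.exp(logsf(x, p))


def cdf(x, p: GIEDParams):
    """``F(x) = 1 - (1 - exp(-lam/x))**theta``."""
    return -np.expm1(logsf(x, p))


def hazard(x, p: GIEDParams):
    """Hazard rate ``pdf / sf``; unimodal in ``x`` for every parameter pair."""
    return np.exp(logpdf(x, p) - logsf(x, p))


def quantile(u, p: GIEDParams):
    """Inverse cdf: ``lam / (-log(1 - (1-u)**(1/theta)))`` for ``u in (0,1)``."""
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1):
        raise ValueError("u must lie strictly inside (0, 1)")
    t = np.exp(np.log1p(-u) / p.theta)  # (1-u)**(1/theta)
    return p.lam / (-np.log1p(-t))


def rvs(p: GIEDParams, size: int, seed=None):
    """Inverse-transform draws; reproducible for a fixed seed or Generator."""
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return quantile(rng.uniform(size=size), p)
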