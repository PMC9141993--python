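"""Percentile (bootstrap-p) confidence intervals for ``(theta1, theta2, lam)``.

Parametric bootstrap: refit the model to ``B`` JPC samples simulated from the
fitted parameters under the *same* censoring scheme, then read interval
endpoints off the sorted replicate estimates.  Replicates in which one line
contributes no failure admit no MLE and are discarded and redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mle import NoMLEError, fit_profile
from .scheme import JPCSample, simulate_jpc

__all__ = ["IntervalSet", "bootstrap_p"]

_PARAMS = ("theta1", "theta2", "lam")


@dataclass
class IntervalSet:
    """Per-parameter interval endpoints at a common confidence level."""

    intervals: dict
    level: float
    B: int
    n_discarded: int = 0

    def __getitem__(self, name: str):
        return self.intervals[name]


def percentile_endpoints(sorted_vals: np.ndarray, level: float) -> tuple[float, float]:
    """Order-statistic endpoints: the ``[B zeta/2]``-th and ``[B(1-zeta/2)]``-th
    sorted replicates (1-based, clipped to the sample)."""
    B = len(sorted_vals)
    zeta = 1.0 - level
    # 1e-9 guards against 0.05*B landing just below an integer in floating point
    lo = max(int(np.floor(B * zeta / 2.0 + 1e-9)), 1)
    hi = min(int(np.floor(B * (1.0 - zeta / 2.0) + 1e-9)), B)
    return float(sorted_vals[lo - 1]), float(sorted_vals[hi - 1])


def bootstrap_p(
    data: JPCSample,
    B: int = 1000,
    level: float = 0.90,
    seed=None,
    fitter=fit_profile,
    max_redraw_factor: int = 50,
) -> IntervalSet:
    """Bootstrap-p intervals from ``B`` parametric refits under the same scheme."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fit0 = fitter(data)

    reps = np.empty((B, 3))
    n_discarded = 0
    b = 0
    attempts = 0
    while b < B:
        attempts += 1
        if attempts > max_redraw_factor * B:
            raise RuntimeError("too many degenerate bootstrap replicates")
        boot = simulate_jpc(fit0.params, data.scheme, rng)
        try:
            fb = fitter(boot)
        except NoMLEError:
            n_discarded += 1
            continue
        reps[b] = (fb.params.theta1, fb.params.theta2, fb.params.lam)
        b += 1

    intervals = {}
    for j, name in enumerate(_PARAMS):
        intervals[name] = percentile_endpoints(np.sort(reps[:, j]), level)
    return IntervalSet(intervals=intervals, level=level, B=B, n_discarded=n_discarded)
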