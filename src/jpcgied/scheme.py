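"""Joint progressive type-II censoring (JPC): schemes, samples, simulation.

Two production lines contribute ``m`` and ``n`` units to a pooled life test.
At the *i*-th observed failure, ``R_i`` of the surviving units are withdrawn
at random from the pooled risk set; the test stops after ``k`` failures.  The
withdrawal counts must exhaust all ``N = m + n`` units:
``sum_i (R_i + 1) = m + n``.

The observed record at failure *i* is ``(w_i, z_i, s_i, t_i)``: the failure
time, an indicator that the failing unit came from line 1, and the split of
the ``R_i`` withdrawals between line 1 (``s_i``) and line 2 (``t_i``).

Scheme notation follows the compact convention ``(0(4),25,0(15))`` meaning
four zeros, one 25, fifteen zeros.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gied import JointGIEDParams, rvs

__all__ = ["JPCScheme", "JPCSample", "parse_scheme", "simulate_jpc", "censor_complete"]

_TOKEN = re.compile(r"^\s*(\d+)\s*(?:\(\s*(\d+)\s*\))?\s*$")


@dataclass(frozen=True)
class JPCScheme:
    """Censoring design: sample sizes, effective size and withdrawal vector."""

    m: int
    n: int
    k: int
    R: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", tuple(int(r) for r in self.R))
        if self.m < 1 or self.n < 1 or self.k < 1:
            raise ValueError("m, n, k must be positive integers")
        if self.k > self.m + self.n:
            raise ValueError(f"k={self.k} exceeds total units N={self.m + self.n}")
        if len(self.R) != self.k:
            raise ValueError(f"withdrawal vector has length {len(self.R)}, expected k={self.k}")
        if any(r < 0 for r in self.R):
            raise ValueError("withdrawal counts must be nonnegative")
        total = sum(self.R) + self.k
        if total != self.m + self.n:
            raise ValueError(
                f"sum(R_i + 1) = {total} must equal m + n = {self.m + self.n}: "
                "the scheme must exhaust all units"
            )

    @property
    def N(self) -> int:
        return self.m + self.n

    @property
    def notation(self) -> str:
        """Compact run-length notation, e.g. ``(0(4),25,0(15))``."""
        parts = []
        i = 0
        while i < self.k:
            j = i
            while j < self.k and self.R[j] == self.R[i]:
                j += 1
            run = j - i
            parts.append(f"{self.R[i]}({run})" if run > 1 else f"{self.R[i]}")
            i = j
        return "(" + ",".join(parts) + ")"

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"m": self.m, "n": self.n, "k": self.k, "R": list(self.R), "notation": self.notation},
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "JPCScheme":
        d = json.loads(Path(path).read_text())
        return cls(m=d["m"], n=d["n"], k=d["k"], R=tuple(d["R"]))


def parse_scheme(text: str, m: int, n: int, k: int) -> JPCScheme:
    """Expand ``value(count)`` run-length notation into a validated scheme.

    ``"(0(4),25,0(15))"`` with ``m=20, n=25, k=20`` yields ``R_5 = 25`` and
    zeros elsewhere.
    """
    s = text.strip()
    if s.startswith("(") and s.endswith(")"):
        s = s[1:-1]
    R: list[int] = []
    for tok in s.split(","):
        mobj = _TOKEN.match(tok)
        if mobj is None:
            raise ValueError(f"malformed scheme token {tok!r} in {text!r}")
        value = int(mobj.group(1))
        count = int(mobj.group(2)) if mobj.group(2) else 1
        R.extend([value] * count)
    return JPCScheme(m=m, n=n, k=k, R=tuple(R))


@dataclass
class JPCSample:
    """Observed JPC data ``((w_i, z_i, s_i, t_i))_{i=1..k}`` plus its scheme."""

    w: np.ndarray
    z: np.ndarray
    s: np.ndarray
    t: np.ndarray
    scheme: JPCScheme

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.z = np.asarray(self.z, dtype=int)
        self.s = np.asarray(self.s, dtype=int)
        self.t = np.asarray(self.t, dtype=int)
        k = self.scheme.k
        for name in ("w", "z", "s", "t"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have length k={k}")
        # nondecreasing: ties are admitted for rounded real data pooled
        # across lines (simulated lifetimes are distinct with probability 1)
        if np.any(np.diff(self.w) < 0):
            raise ValueError("failure times w must be nondecreasing")
        if np.any(self.w <= 0):
            raise ValueError("failure times must be positive")
        if not set(np.unique(self.z)) <= {0, 1}:
            raise ValueError("z must be 0/1 valued")
        if np.any(self.s < 0) or np.any(self.t < 0):
            raise ValueError("withdrawal splits must be nonnegative")
        if np.any(self.s + self.t != np.asarray(self.scheme.R)):
            raise ValueError("s_i + t_i must equal R_i for every i")
        if self.k1 + self.s.sum() != self.scheme.m:
            raise ValueError("line-1 failures plus withdrawals must equal m")
        if self.k2 + self.t.sum() != self.scheme.n:
            raise ValueError("line-2 failures plus withdrawals must equal n")

    @property
    def k(self) -> int:
        return self.scheme.k

    @property
    def k1(self) -> int:
        """Number of observed failures from line 1."""
        return int(self.z.sum())

    @property
    def k2(self) -> int:
        return self.k - self.k1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(1, self.k + 1),
                "w": self.w,
                "z": self.z,
                "s": self.s,
                "t": self.t,
            }
        )

    def to_csv(self, path, scheme_path=None) -> None:
        self.to_frame().to_csv(path, index=False)
        if scheme_path is not None:
            self.scheme.to_json(scheme_path)

    @classmethod
    def from_csv(cls, path, scheme: "JPCScheme | str | Path") -> "JPCSample":
        if not isinstance(scheme, JPCScheme):
            scheme = JPCScheme.from_json(scheme)
        df = pd.read_csv(path)
        return cls(w=df["w"].to_numpy(), z=df["z"].to_numpy(), s=df["s"].to_numpy(),
                   t=df["t"].to_numpy(), scheme=scheme)


def censor_complete(x1, x2, scheme: JPCScheme, seed=None) -> JPCSample:
    """Apply the JPC withdrawal process to fixed lifetime vectors.

    ``x1`` (length ``m``) and ``x2`` (length ``n``) are pooled; at each of the
    ``k`` failure rounds the smallest active lifetime fails and ``R_i``
    survivors are withdrawn as a uniformly random subset of the active units
    (a hypergeometric split between the two lines).  Ties between lifetimes
    are broken by stable input order with line 1 first.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if len(x1) != scheme.m or len(x2) != scheme.n:
        raise ValueError("lifetime vectors must have lengths (m, n)")
    if np.any(x1 <= 0) or np.any(x2 <= 0):
        raise ValueError("lifetimes must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    life = np.concatenate([x1, x2])
    line1 = np.arange(scheme.N) < scheme.m
    active = np.ones(scheme.N, dtype=bool)

    w = np.empty(scheme.k)
    z = np.empty(scheme.k, dtype=int)
    s = np.empty(scheme.k, dtype=int)
    t = np.empty(scheme.k, dtype=int)
    for i, Ri in enumerate(scheme.R):
        idx_active = np.flatnonzero(active)
        fail = idx_active[np.argmin(life[idx_active])]  # argmin is stable: line 1 first
        w[i] = life[fail]
        z[i] = int(line1[fail])
        active[fail] = False
        if Ri > 0:
            survivors = np.flatnonzero(active)
            drop = rng.choice(survivors, size=Ri, replace=False)
            active[drop] = False
            s[i] = int(line1[drop].sum())
            t[i] = Ri - s[i]
        else:
            s[i] = t[i] = 0
    return JPCSample(w=w, z=z, s=s, t=t, scheme=scheme)


def simulate_jpc(params: JointGIEDParams, scheme: JPCScheme, seed=None) -> JPCSample:
    """Simulate one JPC sample from two GIED populations sharing ``lam``."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x1 = rvs(params.line1, scheme.m, rng)
    x2 = rvs(params.line2, scheme.n, rng)
    return censor_complete(x1, x2, scheme, rng)
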