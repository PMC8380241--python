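"""Continuous dose-response model families and benchmark-dose inversion.

Functional forms are the standard 4-parameter EFSA/PROAST members:

* exponential: y = a * (c - (c - 1) * exp(-(x/b)^d))
* Hill:        y = a * (1 + (c - 1) * x^d / (b^d + x^d))

Both satisfy y(0) = a and y -> a*c as x -> inf. The BMD at critical effect
size ``ces`` solves y(BMD) = a * (1 + ces), which requires c > 1 + ces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

FAMILIES = ("exponential", "hill")


@dataclass(frozen=True)
class BMDModelParams:
    """Parameters of one concentration-response curve.

    a: background response (> 0); b: potency, concentration units (> 0);
    c: maximum fold-change (>= 1 for an increasing response); d: log-steepness
    (> 0); var: within-group log-variance (> 0).
    """

    a: float
    b: float
    c: float
    d: float
    var: float = 1e-2

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError(f"background a must be > 0, got {self.a}")
        if self.b <= 0:
            raise ValueError(f"potency b must be > 0, got {self.b}")
        if self.c < 1:
            raise ValueError(f"maximum fold-change c must be >= 1, got {self.c}")
        if self.d <= 0:
            raise ValueError(f"log-steepness d must be > 0, got {self.d}")
        if self.var <= 0:
            raise ValueError(f"within-group variance must be > 0, got {self.var}")


@dataclass(frozen=True)
class BMDConfig:
    """Benchmark-dose analysis settings."""

    model_family: str = "hill"  # "exponential" | "hill" | "both" (fit both)
    ces: float = 0.50
    ci_level: float = 0.90
    acceptance_alpha: float = 0.05

    def __post_init__(self):
        if self.model_family not in FAMILIES + ("both",):
            raise ValueError(f"model_family must be one of {FAMILIES + ('both',)}")
        if self.ces <= 0:
            raise ValueError("ces must be > 0")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if not 0 < self.acceptance_alpha < 1:
            raise ValueError("acceptance_alpha must be in (0, 1)")


def _check_family(family: str) -> str:
    fam = family.lower()
    if fam not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}; expected one of {FAMILIES}")
    return fam


def model_response(x, p: BMDModelParams, family: str = "hill"):
    """Expected response at concentration(s) x under the given family."""
    fam = _check_family(family)
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("concentrations must be >= 0")
    a, b, c, d = p.a, p.b, p.c, p.d
    if fam == "exponential":
        y = a * (c - (c - 1.0) * np.exp(-((x / b) ** d)))
    else:
        xd = np.power(x, d, where=x > 0, out=np.zeros_like(x))
        y = a * (1.0 + (c - 1.0) * xd / (b**d + xd))
    return y if y.ndim else float(y)


def bmd_from_bcd(b: float, c: float, d: float, ces: float, family: str) -> float:
    """Closed-form BMD given potency/shape parameters (a cancels)."""
    fam = _check_family(family)
    if c <= 1.0 + ces:
        raise ValueError(
            f"benchmark response unreachable: requires c > 1 + ces "
            f"(c = {c}, ces = {ces})"
        )
    if fam == "hill":
        t = ces / (c - 1.0)
        return float(b * (t / (1.0 - t)) ** (1.0 / d))
    q = -np.log((c - 1.0 - ces) / (c - 1.0))
    return float(b * q ** (1.0 / d))


def compute_bmd(p: BMDModelParams, family: str = "hill", ces: float = 0.5) -> float:
    """Concentration where the response reaches a * (1 + ces).

    Uses the closed-form inversion; raises ValueError when the benchmark
    response is unreachable (c <= 1 + ces).
    """
    return bmd_from_bcd(p.b, p.c, p.d, ces, family)


def compute_bmd_numeric(p: BMDModelParams, family: str = "hill", ces: float = 0.5,
                        rtol: float = 1e-10) -> float:
    """Bracketing root-finder fallback/cross-check for the BMD."""
    fam = _check_family(family)
    if p.c <= 1.0 + ces:
        raise ValueError("benchmark response unreachable")
    target = p.a * (1.0 + ces)

    def f(x):
        return model_response(x, p, fam) - target

    hi = p.b
    while f(hi) < 0:
        hi *= 2.0
        if hi > p.b * 1e12:
            raise ValueError("failed to bracket the benchmark dose")
    return float(brentq(f, 0.0, hi, rtol=rtol))
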