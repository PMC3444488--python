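"""Retrospective power: minimum detectable odds ratio for an allelic test.

Power is evaluated for the two-proportion chi-square test with the Fleiss
continuity correction (the default of the classic PS sample-size program for
dichotomous outcomes), applied to allele counts: a group of n subjects
contributes 2n chromosomes.  The minimum detectable OR is the smallest odds
ratio above 1 whose power reaches the target, found by bisection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

__all__ = ["PowerSpec", "power_allelic", "min_detectable_or"]


@dataclass(frozen=True)
class PowerSpec:
    p0: float  # control minor-allele frequency
    n_case: int  # subjects; alleles = 2 * n_case
    n_ctrl: int
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValueError("p0 must lie strictly inside (0, 1)")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.n_case <= 0 or self.n_ctrl <= 0:
            raise ValueError("group sizes must be positive")


def _p1_from_or(p0: float, oratio: float) -> float:
    return oratio * p0 / (1.0 + p0 * (oratio - 1.0))


def power_allelic(spec: PowerSpec, oratio: float, corrected: bool = True) -> float:
    """Power of the allelic two-proportion chi-square at a given odds ratio.

    Fleiss formulation with n1 = case alleles, n0 = control alleles and
    allocation ratio m = n0/n1; the continuity correction subtracts
    (m+1)/(2 m n1) from the detectable difference.
    """
    if oratio <= 0:
        raise ValueError("odds ratio must be positive")
    p0 = spec.p0
    p1 = _p1_from_or(p0, oratio)
    n1 = 2.0 * spec.n_case
    n0 = 2.0 * spec.n_ctrl
    m = n0 / n1
    pbar = (p1 + m * p0) / (1.0 + m)
    qbar = 1.0 - pbar
    delta = abs(p1 - p0)
    if corrected:
        delta = max(0.0, delta - (m + 1.0) / (2.0 * m * n1))
    if delta == 0.0 or pbar in (0.0, 1.0):
        return float(spec.alpha)
    za = norm.ppf(1.0 - spec.alpha / 2.0)
    num = delta * math.sqrt(n1) - za * math.sqrt((1.0 + 1.0 / m) * pbar * qbar)
    den = math.sqrt(p1 * (1.0 - p1) + p0 * (1.0 - p0) / m)
    return float(norm.cdf(num / den))


def min_detectable_or(
    spec: PowerSpec, tol: float = 1e-4, or_max: float = 100.0
) -> float:
    """Smallest OR > 1 at which the allelic test attains the target power.

    Solved by bisection on the (monotone) power curve.  Raises if even
    ``or_max`` cannot reach the target (sample too small: power unbounded).
    """
    lo, hi = 1.0, or_max
    if power_allelic(spec, hi) < spec.power:
        raise ValueError(
            f"target power {spec.power} unreachable below OR={or_max}; "
            "sample too small"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if power_allelic(spec, mid) >= spec.power:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
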