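"""Bahadur efficiency slopes for combined p-value tests.

The Bahadur slope of a test sequence {T_n} is the almost-sure limit
c(theta) = lim -2 ln(P_n)/n under the alternative: the exponential decay
rate of its significance level. The ratio of two slopes equals the
limiting inverse ratio of sample sizes the two tests need to reach an
equally small significance level, which is the relevant comparison when
signals are sparse.

For m component tests with sample-size fractions lambda_i and individual
slopes c_i(theta), the combiners' slopes are

    Lancaster / Fisher : sum_i lambda_i c_i                 (weight-free)
    weighted Z         : (sum_i w_i sqrt(lambda_i c_i))^2 / sum_i w_i^2
    regular Z          : (sum_i sqrt(lambda_i c_i))^2 / m
    Good               : sum_i w_i lambda_i c_i / max_i w_i

The Lancaster slope dominates all of these (Cauchy-Schwarz for the Z
family, a termwise bound for Good), which is the sense in which the
Lancaster procedure is the optimal generalized Fisher's method. Under
correlation, approximate slopes multiply the independent slope by a
penalty factor driven by the pairwise covariances of the transformed
statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SlopeInputs",
    "SlopeResult",
    "EmpiricalSlope",
    "slope_lancaster",
    "slope_fisher",
    "slope_weighted_z",
    "slope_regular_z",
    "slope_good",
    "slope_correlated",
    "relative_efficiency",
    "empirical_slope",
]


@dataclass(frozen=True)
class SlopeInputs:
    """Per-test sample-size fractions, individual slopes, and weights.

    theta never appears numerically: the theory is parameter-free once the
    individual slopes c_i(theta) are supplied.
    """

    lam: np.ndarray
    c_ind: np.ndarray
    w: np.ndarray

    def __init__(self, lam: Sequence[float], c_ind: Sequence[float], w: Sequence[float]):
        lam_, c_, w_ = (np.asarray(a, dtype=float) for a in (lam, c_ind, w))
        if not (lam_.shape == c_.shape == w_.shape) or lam_.ndim != 1:
            raise ValueError("lambda, c and w must be 1-d arrays of equal length")
        for name, a in (("lambda", lam_), ("c", c_), ("w", w_)):
            if np.any(~np.isfinite(a)) or np.any(a <= 0):
                raise ValueError(f"{name} entries must be finite and positive")
        object.__setattr__(self, "lam", lam_)
        object.__setattr__(self, "c_ind", c_)
        object.__setattr__(self, "w", w_)

    def __len__(self) -> int:
        return self.lam.size


@dataclass(frozen=True)
class SlopeResult:
    method: str
    slope: float
    correlated: bool = False
    correlation_penalty: float = 1.0

    def __post_init__(self):
        if not (self.slope > 0):
            raise ValueError("Bahadur slope must be positive")
        if not self.correlated and self.correlation_penalty != 1.0:
            raise ValueError("independent slopes carry no correlation penalty")


def slope_lancaster(s: SlopeInputs) -> SlopeResult:
    """sum lambda_i c_i — independent of the weights w."""
    return SlopeResult("lancaster", float((s.lam * s.c_ind).sum()))


def slope_fisher(s: SlopeInputs) -> SlopeResult:
    """Fisher = Lancaster with w = 2; the slope is the same weight-free sum."""
    return SlopeResult("fisher", float((s.lam * s.c_ind).sum()))


def slope_weighted_z(s: SlopeInputs) -> SlopeResult:
    """(sum w_i sqrt(lambda_i c_i))^2 / sum w_i^2."""
    num = float((s.w * np.sqrt(s.lam * s.c_ind)).sum()) ** 2
    return SlopeResult("weighted_z", num / float((s.w**2).sum()))


def slope_regular_z(s: SlopeInputs) -> SlopeResult:
    """(sum sqrt(lambda_i c_i))^2 / m — the equal-weight special case."""
    num = float(np.sqrt(s.lam * s.c_ind).sum()) ** 2
    return SlopeResult("regular_z", num / len(s))


def slope_good(s: SlopeInputs) -> SlopeResult:
    """sum w_i lambda_i c_i / max_i w_i; equals Lancaster when w is constant."""
    return SlopeResult(
        "good", float((s.w * s.lam * s.c_ind).sum()) / float(s.w.max())
    )


_CORRELATED_METHODS = ("lancaster", "good", "fisher")


def slope_correlated(method: str, s: SlopeInputs, rho_sum: float) -> SlopeResult:
    """Approximate slope under correlation.

    ``rho_sum`` is sum_{i<j} rho_ij of the transformed statistics for the
    Lancaster method, or sum_{i<j} cov(ln P_i, ln P_j) for Good/Fisher.
    Penalty factors:

        Lancaster: sum w / (sum w + 2 rho_sum)         x  sum lambda_i c_i
        Good:      sum w / (sum w^2 + 2 rho_sum)       x  sum w_i lambda_i c_i
        Fisher:    m / (m + 2 rho_sum)                 x  sum lambda_i c_i

    Good's denominator uses sum w^2 as printed; it does not reduce to the
    independent max-weight form at rho_sum = 0 (see the package docs).
    """
    if method not in _CORRELATED_METHODS:
        raise ValueError(f"method must be one of {_CORRELATED_METHODS}")
    m = len(s)
    sw = float(s.w.sum())
    base = float((s.lam * s.c_ind).sum())
    if method == "lancaster":
        denom = sw + 2.0 * rho_sum
        penalty, indep = sw / denom if denom > 0 else -1.0, base
    elif method == "fisher":
        denom = m + 2.0 * rho_sum
        penalty, indep = m / denom if denom > 0 else -1.0, base
    else:  # good
        denom = float((s.w**2).sum()) + 2.0 * rho_sum
        penalty = sw / denom if denom > 0 else -1.0
        indep = float((s.w * s.lam * s.c_ind).sum())
    if denom <= 0 or penalty <= 0:
        raise ValueError("non-positive denominator in the correlation penalty")
    return SlopeResult(
        method, penalty * indep, correlated=True, correlation_penalty=penalty
    )


def relative_efficiency(c1: SlopeResult, c2: SlopeResult) -> float:
    """phi_12 = c1/c2: the limiting sample-size ratio N2/N1."""
    if not (c1.slope > 0 and c2.slope > 0):
        raise ValueError("slopes must be positive")
    return c1.slope / c2.slope


@dataclass(frozen=True)
class EmpiricalSlope:
    slope: float
    se: float
    n_points: int
    clamped: bool


def empirical_slope(
    pvalue_generator: Callable[[int, np.random.Generator], float],
    n_grid: Sequence[int],
    reps: int,
    seed: int | None = None,
) -> EmpiricalSlope:
    """Estimate a Bahadur slope by simulation.

    ``pvalue_generator(n, rng)`` returns one significance level at sample
    size n under the alternative. -2 ln P_n is regressed on n through the
    origin over the top half of the (increasing) grid, which reduces
    pre-asymptotic bias; returns the slope estimate with its standard
    error. A verification harness, not a production estimator.
    """
    grid = np.asarray(n_grid, dtype=int)
    if grid.size < 3 or np.any(np.diff(grid) <= 0):
        raise ValueError("n_grid must be increasing with at least 3 points")
    if reps < 50:
        raise ValueError("need at least 50 replicates per grid point")
    rng = np.random.default_rng(seed)
    clamped = False
    xs, ys = [], []
    top = grid[grid.size // 2 :]
    for n in grid:  # consume randomness over the whole grid for determinism
        for _ in range(reps):
            p = float(pvalue_generator(int(n), rng))
            if p <= 0.0:
                p, clamped = 1e-300, True
            elif p > 1.0:
                raise ValueError("generator returned p > 1")
            if n in top:
                xs.append(float(n))
                ys.append(-2.0 * math.log(p))
    x = np.array(xs)
    y = np.array(ys)
    sxx = float((x * x).sum())
    slope = float((x * y).sum() / sxx)
    resid = y - slope * x
    se = math.sqrt(float((resid * resid).sum()) / (x.size - 1) / sxx)
    return EmpiricalSlope(slope=slope, se=se, n_points=x.size, clamped=clamped)
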