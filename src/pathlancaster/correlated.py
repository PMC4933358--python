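"""Correlation-corrected (self-contained) Lancaster procedure.

Gene-level p-values entering a pathway statistic are correlated through
linkage disequilibrium and shared subjects, so the independence null
chi2(sum w) is wrong — ignoring the correlation inflates type I error.
The corrected null matches the first two moments of

    T = sum_i F_i^{-1}(1 - P_i)

to a scaled chi-square c * chi2(v) (Satterthwaite). Under the null

    E(T)   = sum_i w_i,
    var(T) = 2 sum_i w_i + 2 sum_{i<j} rho_ij,

with rho_ij = cov(F_i^{-1}(1-P_i), F_j^{-1}(1-P_j)) estimated by null
resampling (phenotype permutation in the pipeline). Moment matching gives
c = var/(2 E) and v = 2 E^2 / var; zero covariance recovers the exact
independent chi2(sum w) null.

Also provides the Q-Q inflation-factor diagnostic: the ratio of the area
under the observed-vs-expected -log10 p curve to the area under the
identity line (lambda ~ 1 for calibrated p-values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import chi2

from .combiners import (
    ChiSquareWeights,
    CombinedResult,
    PValueVector,
    chi_square_transform,
    lancaster_statistic,
)

__all__ = [
    "CovarianceEstimate",
    "ScaledChiSquareNull",
    "satterthwaite_params",
    "null_moments",
    "estimate_covariance_by_permutation",
    "correlated_lancaster_test",
    "inflation_factor",
]


@dataclass(frozen=True)
class CovarianceEstimate:
    """Pairwise covariances rho_ij of the chi-square-transformed statistics.

    ``method`` records provenance: "permutation" (null-resample estimate),
    "analytic-zero" (independence), or "user-supplied".
    """

    rho: np.ndarray
    method: str = "user-supplied"
    n_resamples: int | None = None

    def __post_init__(self):
        rho = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "rho", rho)
        if rho.ndim != 2 or rho.shape[0] != rho.shape[1]:
            raise ValueError("covariance estimate must be a square matrix")
        if not np.allclose(rho, rho.T, atol=1e-8):
            raise ValueError("covariance estimate must be symmetric")

    @classmethod
    def analytic_zero(cls, w: ChiSquareWeights) -> "CovarianceEstimate":
        """Independence: off-diagonals 0, diagonal var(chi2_w) = 2w."""
        return cls(np.diag(2.0 * w.values), method="analytic-zero")

    @property
    def m(self) -> int:
        return self.rho.shape[0]

    def offdiagonal_sum(self) -> float:
        """sum_{i<j} rho_ij."""
        return float((self.rho.sum() - np.trace(self.rho)) / 2.0)


@dataclass(frozen=True)
class ScaledChiSquareNull:
    """T ~ c * chi2(v); c*v = E(T) and 2*c^2*v = var(T) by construction."""

    c: float
    v: float

    def __post_init__(self):
        if not (self.c > 0 and self.v > 0):
            raise ValueError("scale and degrees of freedom must be positive")

    def sf(self, statistic: float | np.ndarray) -> float | np.ndarray:
        return chi2.sf(np.asarray(statistic) / self.c, self.v)

    def logsf(self, statistic: float | np.ndarray) -> float | np.ndarray:
        return chi2.logsf(np.asarray(statistic) / self.c, self.v)


def satterthwaite_params(mean_T: float, var_T: float) -> ScaledChiSquareNull:
    """Match mean and variance of T to c*chi2(v).

    c = 0.5 var(T)/E(T), v = 2 [E(T)]^2 / var(T).
    """
    if not (mean_T > 0):
        raise ValueError("mean of the statistic must be positive")
    if not (var_T > 0):
        raise ValueError("variance of the statistic must be positive")
    return ScaledChiSquareNull(c=0.5 * var_T / mean_T, v=2.0 * mean_T**2 / var_T)


def null_moments(
    w: ChiSquareWeights, cov: CovarianceEstimate
) -> tuple[float, float]:
    """Null mean and variance of the Lancaster statistic.

    mean = sum w_i; var = 2 sum w_i + 2 sum_{i<j} rho_ij. The diagonal of
    the covariance estimate is replaced by its theoretical value 2 w_i.
    """
    if cov.m != len(w):
        raise ValueError("covariance dimension does not match the weights")
    mean = float(np.sum(w.values))
    var = 2.0 * mean + 2.0 * cov.offdiagonal_sum()
    if var <= 0:
        raise ValueError(
            "implied null variance is non-positive; the covariance estimate "
            "is degenerate"
        )
    return mean, var


def estimate_covariance_by_permutation(
    gene_test_runner: Callable[[np.random.Generator], PValueVector],
    B: int,
    w: ChiSquareWeights,
    seed: int | None = None,
) -> CovarianceEstimate:
    """Estimate rho_ij from B null resamples of the gene-level tests.

    ``gene_test_runner(rng)`` must return one PValueVector drawn under the
    null (e.g. by permuting the phenotype and rerunning the gene tests).
    Each resampled vector is transformed by F_i^{-1}(1 - p) and the sample
    covariance across resamples is returned. Deterministic given ``seed``.
    """
    if B < 100:
        raise ValueError("need at least 100 resamples for a usable estimate")
    rng = np.random.default_rng(seed)
    m = len(w)
    transformed = np.empty((B, m))
    for b in range(B):
        pv = gene_test_runner(rng)
        if len(pv) != m:
            raise ValueError("resampled p-value vector has wrong length")
        transformed[b] = chi_square_transform(pv.values, w.values)
    spread = transformed.std(axis=0)
    if np.any(spread <= 1e-12 * (np.abs(transformed.mean(axis=0)) + 1.0)):
        raise ValueError("degenerate resamples: at least one test is constant")
    return CovarianceEstimate(
        np.cov(transformed, rowvar=False), method="permutation", n_resamples=B
    )


def _guarded_variance(mean: float, offsum: float) -> float:
    """2*mean + 2*offsum, shrinking the off-diagonal part if non-positive."""
    var = 2.0 * mean + 2.0 * offsum
    if var <= 0:
        # minimal shrink factor restoring positivity (keeps 1% of the budget)
        s = 0.99 * mean / (-offsum)
        warnings.warn(
            "estimated covariance implies non-positive variance; "
            f"off-diagonals shrunk by factor {s:.4g}",
            RuntimeWarning,
            stacklevel=3,
        )
        var = 2.0 * mean + 2.0 * s * offsum
    return var


def correlated_lancaster_test(
    p: PValueVector, w: ChiSquareWeights, cov: CovarianceEstimate
) -> CombinedResult:
    """Lancaster statistic referred to the Satterthwaite scaled chi-square.

    With an analytic-zero covariance this reproduces the independent
    chi2(sum w) test exactly.
    """
    if cov.m != len(w) or len(p) != len(w):
        raise ValueError("p-values, weights and covariance dimensions differ")
    stat = lancaster_statistic(p, w)
    mean = float(np.sum(w.values))
    var = _guarded_variance(mean, cov.offdiagonal_sum())
    null = satterthwaite_params(mean, var)
    logp = null.logsf(stat)
    return CombinedResult(
        method="lancaster",
        statistic=stat,
        null_params={"c": null.c, "v": null.v, "covariance": cov.method},
        p_value=float(np.exp(logp)),
        log10_p=float(logp / np.log(10.0)),
    )


def inflation_factor(observed_p: PValueVector | np.ndarray) -> float:
    """Q-Q inflation factor lambda of a set of p-values.

    Ratio of the area under the empirical Q-Q curve of sorted -log10 p
    against -log10 expected uniform quantiles (i - 0.5)/m to the area under
    the identity line, both integrated by the trapezoid rule over the
    expected-quantile range [0, -log10(0.5/m)]. lambda ~ 1 indicates
    calibrated p-values; lambda > 1 indicates inflation.
    """
    vals = observed_p.values if isinstance(observed_p, PValueVector) else np.asarray(
        observed_p, dtype=float
    )
    m = vals.size
    if m < 10:
        raise ValueError("need at least 10 p-values for a stable Q-Q area")
    if np.any(vals <= 0) or np.any(vals > 1):
        raise ValueError("p-values must lie in (0, 1]")
    expected = (np.arange(1, m + 1) - 0.5) / m
    x = np.sort(-np.log10(expected))  # ascending, max = -log10(0.5/m)
    y = np.sort(-np.log10(vals))  # rank-matched: extreme with extreme
    # anchor the integration range at the origin
    x = np.concatenate(([0.0], x))
    y = np.concatenate(([0.0], y))
    area_curve = np.trapezoid(y, x)
    area_diag = np.trapezoid(x, x)
    return float(area_curve / area_diag)
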