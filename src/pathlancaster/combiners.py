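"""Combined p-value statistics for independent tests.

Implements the classical combiners used at the pathway level: Fisher's
method, the regular and weighted Z-tests (Stouffer-type, one-sided), Good's
weighted-product test, and the Lancaster procedure, which generalizes
Fisher's method by transforming each p-value through the inverse CDF of a
chi-square with per-test degrees of freedom ``w_i > 0``:

    T = sum_i  F_i^{-1}(1 - P_i),      F_i = CDF of chi2(w_i).

Under independence T ~ chi2(sum_i w_i); Fisher's method is the special case
w_i = 2 for every test, where the transform reduces to -2 ln p exactly.
The correlated-null variant lives in :mod:`pathlancaster.correlated`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm

__all__ = [
    "PValueVector",
    "ChiSquareWeights",
    "CombinedResult",
    "chi_square_transform",
    "lancaster_statistic",
    "lancaster_pvalue_independent",
    "lancaster_combine",
    "fisher_combine",
    "weighted_z_combine",
    "regular_z_combine",
    "good_lambda_coefficients",
    "good_null_cdf",
    "good_combine",
]

# Clamp policy for the normal-quantile transform only: p = 1 maps to
# Phi^{-1}(0) = -inf, so Z-methods floor/ceil p at these bounds. The
# chi-square combiners accept p = 1 exactly (transform gives 0).
Z_P_FLOOR = 1e-300
Z_P_CEIL = 1.0 - 1e-15

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class PValueVector:
    """Per-test significance levels with identifiers.

    Each value must lie in (0, 1]; a value of exactly 0 is rejected because
    the chi-square transform diverges there.
    """

    ids: tuple
    values: np.ndarray

    def __init__(self, ids: Sequence, values: Sequence[float]):
        object.__setattr__(self, "ids", tuple(str(i) for i in ids))
        vals = np.asarray(values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("need a one-dimensional vector of at least one p-value")
        if len(self.ids) != vals.size:
            raise ValueError("ids and values have different lengths")
        if not np.all(np.isfinite(vals)):
            raise ValueError("p-values must be finite")
        if np.any(vals <= 0.0) or np.any(vals > 1.0):
            raise ValueError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ChiSquareWeights:
    """Per-test chi-square degrees of freedom w_i > 0 (Lancaster weights)."""

    values: np.ndarray

    def __init__(self, values: Sequence[float]):
        vals = np.asarray(values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("need a one-dimensional vector of at least one weight")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0.0):
            raise ValueError("chi-square weights must be finite and strictly positive")

    @classmethod
    def uniform(cls, m: int, w: float = 2.0) -> "ChiSquareWeights":
        return cls(np.full(m, float(w)))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CombinedResult:
    """Outcome of a p-value combination.

    ``null_params`` records the parameters of the null distribution used
    (degrees of freedom for chi-square nulls, the Lambda coefficients for
    Good's test, nothing for the unit-normal Z nulls). ``log10_p`` is
    computed in log space so statistics far beyond double-precision
    underflow still report a usable magnitude.
    """

    method: str
    statistic: float
    null_params: dict = field(default_factory=dict)
    p_value: float = float("nan")
    log10_p: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0) and not math.isnan(self.p_value):
            raise ValueError("combined p-value outside [0, 1]")
        if not math.isfinite(self.statistic):
            raise ValueError("combined statistic must be finite")


def _check_lengths(p: PValueVector, w: ChiSquareWeights) -> None:
    if len(p) != len(w):
        raise ValueError(
            f"p-value vector (m={len(p)}) and weights (m={len(w)}) differ in length"
        )


def chi_square_transform(p: np.ndarray, w: np.ndarray) -> np.ndarray:
    """F^{-1}(1 - p) for chi2 with df w, elementwise with broadcasting.

    w = 2 is special-cased to the exact closed form -2 ln p so that the
    Lancaster statistic with uniform weight 2 is bit-identical to Fisher's
    statistic.
    """
    p = np.asarray(p, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(p <= 0.0):
        raise ValueError("chi-square transform diverges at p <= 0")
    p, w = np.broadcast_arrays(p, w)
    out = np.empty(p.shape, dtype=float)
    two = w == 2.0
    if np.any(two):
        out[two] = -2.0 * np.log(p[two])
    rest = ~two
    if np.any(rest):
        out[rest] = chi2.isf(p[rest], w[rest])
    return out


def lancaster_statistic(p: PValueVector, w: ChiSquareWeights) -> float:
    """T = sum_i F_i^{-1}(1 - P_i); non-negative, 0 when every p is 1."""
    _check_lengths(p, w)
    return float(chi_square_transform(p.values, w.values).sum())


def lancaster_pvalue_independent(
    statistic: float, w: ChiSquareWeights
) -> CombinedResult:
    """Refer the Lancaster statistic to its independence null chi2(sum w)."""
    if statistic < 0:
        raise ValueError("Lancaster statistic cannot be negative")
    df = float(np.sum(w.values))
    logp = chi2.logsf(statistic, df)
    return CombinedResult(
        method="lancaster",
        statistic=float(statistic),
        null_params={"df": df},
        p_value=float(np.exp(logp)),
        log10_p=float(logp / _LN10),
    )


def lancaster_combine(p: PValueVector, w: ChiSquareWeights) -> CombinedResult:
    """Lancaster procedure under independence: statistic plus chi2(sum w) p."""
    return lancaster_pvalue_independent(lancaster_statistic(p, w), w)


def fisher_combine(p: PValueVector) -> CombinedResult:
    """Fisher's method, T = -2 sum ln P_i ~ chi2(2m) under the null.

    Identical (statistic bit-for-bit) to the Lancaster procedure with every
    weight equal to 2.
    """
    w = ChiSquareWeights.uniform(len(p))
    res = lancaster_pvalue_independent(lancaster_statistic(p, w), w)
    return CombinedResult(
        method="fisher",
        statistic=res.statistic,
        null_params=res.null_params,
        p_value=res.p_value,
        log10_p=res.log10_p,
    )


def _z_clamp(p: np.ndarray) -> np.ndarray:
    return np.clip(p, Z_P_FLOOR, Z_P_CEIL)


def weighted_z_combine(
    p: PValueVector, z_weights: Sequence[float] | None = None
) -> CombinedResult:
    """One-sided weighted Z-test: T = sum w_i Phi^{-1}(1-P_i) / sqrt(sum w_i^2).

    Null is standard normal, upper-tail rejection. Equal weights reduce
    exactly to the regular Z-test. p-values at the boundaries are clamped
    (documented floor/ceiling) to avoid infinite quantiles.
    """
    if z_weights is None:
        zw = np.ones(len(p))
        method = "regular_z"
    else:
        zw = np.asarray(z_weights, dtype=float)
        if zw.shape != (len(p),):
            raise ValueError("z-weights length must match the p-value vector")
        if np.any(~np.isfinite(zw)) or np.any(zw <= 0.0):
            raise ValueError("z-weights must be finite and strictly positive")
        method = "weighted_z"
    z = norm.isf(_z_clamp(p.values))  # Phi^{-1}(1 - p)
    t = float((zw * z).sum() / math.sqrt(float((zw**2).sum())))
    logp = norm.logsf(t)
    return CombinedResult(
        method=method,
        statistic=t,
        null_params={},
        p_value=float(np.exp(logp)),
        log10_p=float(logp / _LN10),
    )


def regular_z_combine(p: PValueVector) -> CombinedResult:
    """Unweighted (regular) Z-test: sum Phi^{-1}(1-P_i) / sqrt(m)."""
    return weighted_z_combine(p, None)


def good_lambda_coefficients(w: ChiSquareWeights) -> np.ndarray:
    """Lambda_i = w_i^{m-1} / prod_{j != i}(w_i - w_j) for distinct weights."""
    vals = w.values
    m = vals.size
    diffs = vals[:, None] - vals[None, :]
    if np.any(np.abs(diffs[~np.eye(m, dtype=bool)]) == 0.0):
        raise ValueError(
            "Good's closed-form null requires pairwise-distinct weights; "
            "use the Monte-Carlo null for tied weights"
        )
    np.fill_diagonal(diffs, 1.0)
    return vals ** (m - 1) / np.prod(diffs, axis=1)


def good_null_cdf(q: float | np.ndarray, w: ChiSquareWeights) -> float | np.ndarray:
    """Null CDF of Q = prod P_i^{w_i}: Pr(Q < q) = sum_i Lambda_i q^{1/w_i}.

    Valid for pairwise-distinct weights; raises on ties, directing the
    caller to the Monte-Carlo fallback in :func:`good_combine`.
    """
    q_arr = np.asarray(q, dtype=float)
    if np.any(q_arr < 0.0) or np.any(q_arr > 1.0):
        raise ValueError("q must lie in [0, 1]")
    lam = good_lambda_coefficients(w)
    cdf = np.clip((lam * q_arr[..., None] ** (1.0 / w.values)).sum(axis=-1), 0.0, 1.0)
    return float(cdf) if np.isscalar(q) or q_arr.ndim == 0 else cdf


def good_combine(
    p: PValueVector,
    w: ChiSquareWeights,
    mc_draws: int = 10**6,
    seed: int | None = 0,
) -> CombinedResult:
    """Good's weighted-product test: statistic -ln Q = -sum w_i ln P_i.

    With pairwise-distinct weights the exact null CDF is used. With all
    weights equal the statistic is a rescaled Fisher statistic and the null
    is the exact chi2(2m) after rescaling. Partial ties have no closed form
    and fall back to a seeded Monte-Carlo null of ``mc_draws`` draws.
    """
    _check_lengths(p, w)
    wv = w.values
    stat = float(-(wv * np.log(p.values)).sum())
    m = len(p)
    if np.all(wv == wv[0]):
        # -ln Q = (w/2) * T_Fisher; null chi2(2m) on the Fisher scale.
        logp = chi2.logsf(2.0 * stat / wv[0], 2 * m)
        return CombinedResult(
            method="good",
            statistic=stat,
            null_params={"equal_weight": float(wv[0]), "df": 2.0 * m},
            p_value=float(np.exp(logp)),
            log10_p=float(logp / _LN10),
        )
    try:
        lam = good_lambda_coefficients(w)
    except ValueError:
        rng = np.random.default_rng(seed)
        draws = np.zeros(mc_draws)
        # blockwise to bound memory at ~8 MB
        block = max(1, 10**6 // max(m, 1))
        for start in range(0, mc_draws, block):
            u = rng.random((min(block, mc_draws - start), m))
            draws[start : start + u.shape[0]] = -(np.log(u) * wv).sum(axis=1)
        pval = float(np.mean(draws >= stat))
        return CombinedResult(
            method="good",
            statistic=stat,
            null_params={"monte_carlo_draws": mc_draws},
            p_value=pval,
            log10_p=float(np.log10(pval)) if pval > 0 else float("-inf"),
        )
    # Pr(-ln Q > stat) = Pr(Q < exp(-stat)) = sum Lambda_i exp(-stat / w_i)
    terms = lam * np.exp(-stat / wv)
    pval = float(np.clip(terms.sum(), 0.0, 1.0))
    return CombinedResult(
        method="good",
        statistic=stat,
        null_params={"lambda": lam},
        p_value=pval,
        log10_p=float(np.log10(pval)) if pval > 0 else float("-inf"),
    )
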