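"""Competitive Lancaster test by gene-shuffling permutation.

The self-contained test asks whether a pathway has any effect; the
competitive test asks whether it is more associated than a random gene set
of the same size drawn from the gene universe. The procedure:

  Step 1: P_i = Lancaster p-value of the real pathway.
  Step 2: draw L permuted pathways of the same size by shuffling genes
          among pathways; P^l = Lancaster p-value of the l-th permuted set.
  Step 3: competitive p = sum_l I{P_i >= P^l} / L.

Gene weights travel with the gene (a gene keeps its own w_i wherever it is
shuffled), permuted sets match the real pathway size exactly, and the
printed Step-3 estimator (which can return 0) is the default; an add-one
corrected variant is available for downstream FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .combiners import ChiSquareWeights, PValueVector, chi_square_transform
from .correlated import (
    CovarianceEstimate,
    _guarded_variance,
    satterthwaite_params,
)

__all__ = [
    "PathwayDB",
    "CompetitiveResult",
    "permute_pathways",
    "competitive_pvalue",
    "run_competitive",
]


@dataclass(frozen=True)
class PathwayDB:
    """Named gene sets plus the universe of all genes they mention."""

    pathways: dict
    descriptions: dict | None = None

    def __post_init__(self):
        pws = {str(k): tuple(dict.fromkeys(str(g) for g in v)) for k, v in self.pathways.items()}
        object.__setattr__(self, "pathways", pws)
        for name, genes in pws.items():
            if len(genes) == 0:
                raise ValueError(f"pathway {name!r} is empty")

    @property
    def gene_universe(self) -> tuple:
        seen: dict = {}
        for genes in self.pathways.values():
            for g in genes:
                seen[g] = None
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass(frozen=True)
class CompetitiveResult:
    pathway: str
    self_contained_p: float
    competitive_p: float
    L: int

    def __post_init__(self):
        if not (0.0 <= self.competitive_p <= 1.0):
            raise ValueError("competitive p-value outside [0, 1]")
        if self.L < 1:
            raise ValueError("permutation count must be at least 1")


def _sample_index_sets(
    n_universe: int, size: int, L: int, rng: np.random.Generator
) -> np.ndarray:
    """L index sets of ``size`` distinct genes from a universe of n genes."""
    if size > n_universe:
        raise ValueError("pathway larger than the gene universe")
    if L * n_universe <= 5 * 10**7:
        keys = rng.random((L, n_universe))
        idx = np.argpartition(keys, size - 1, axis=1)[:, :size]
    else:
        idx = np.empty((L, size), dtype=np.intp)
        for l in range(L):
            idx[l] = rng.choice(n_universe, size=size, replace=False)
    # sorted indices make the statistic's summation order deterministic
    return np.sort(idx, axis=1)


def permute_pathways(
    db: PathwayDB, L: int, seed: int | None = None
) -> Iterator[tuple[str, list]]:
    """Yield (pathway name, list of L permuted gene sets of matching size).

    Each permuted set is drawn without replacement from the gene universe;
    permuted sets are drawn independently per pathway. Deterministic given
    ``seed``.
    """
    if L < 1:
        raise ValueError("permutation count must be at least 1")
    rng = np.random.default_rng(seed)
    universe = np.array(db.gene_universe, dtype=object)
    for name, genes in db.pathways.items():
        idx = _sample_index_sets(universe.size, len(genes), L, rng)
        yield name, [tuple(universe[row]) for row in idx]


def competitive_pvalue(observed_p: float, permuted_p: Sequence[float]) -> float:
    """Step-3 estimator: fraction of permuted p-values <= the observed one."""
    perm = np.asarray(permuted_p, dtype=float)
    if perm.size == 0:
        raise ValueError("empty permutation list")
    if not (0.0 <= observed_p <= 1.0) or np.any(perm < 0) or np.any(perm > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return float(np.count_nonzero(observed_p >= perm) / perm.size)


def _lancaster_pvalues_for_sets(
    t: np.ndarray, w: np.ndarray, idx: np.ndarray, cov: CovarianceEstimate | None
) -> np.ndarray:
    """Lancaster p for each row-index set, independent or Satterthwaite."""
    stats = t[idx].sum(axis=1)
    dfs = w[idx].sum(axis=1)
    if cov is None:
        return chi2.sf(stats, dfs)
    out = np.empty(stats.size)
    rho = cov.rho
    for l in range(stats.size):
        sub = rho[np.ix_(idx[l], idx[l])]
        offsum = float((sub.sum() - np.trace(sub)) / 2.0)
        null = satterthwaite_params(dfs[l], _guarded_variance(dfs[l], offsum))
        out[l] = null.sf(stats[l])
    return out


def run_competitive(
    gene_p: PValueVector,
    gene_w: ChiSquareWeights,
    db: PathwayDB,
    L: int,
    cov_policy: CovarianceEstimate | None = None,
    seed: int | None = None,
    add_one: bool = False,
) -> list[CompetitiveResult]:
    """Competitive Lancaster test for every pathway in the database.

    ``cov_policy`` is None for the independence null or a CovarianceEstimate
    over the full gene universe (aligned with ``gene_p.ids``) applied — by
    the same policy — to both the real and the permuted pathways. With
    ``add_one`` the estimator (1 + count)/(1 + L) replaces the plain
    fraction. Results are ordered by pathway id; deterministic given seed.
    """
    if L < 100:
        raise ValueError("need at least 100 permutations")
    if len(gene_p) != len(gene_w):
        raise ValueError("gene p-values and weights differ in length")
    pos: Mapping[str, int] = {g: i for i, g in enumerate(gene_p.ids)}
    missing = sorted(
        {g for genes in db.pathways.values() for g in genes if g not in pos}
    )
    if missing:
        raise ValueError(f"genes without p-values: {missing[:10]}")
    if cov_policy is not None and cov_policy.m != len(gene_p):
        raise ValueError("covariance must cover the full gene p-value vector")

    t = chi_square_transform(gene_p.values, gene_w.values)
    w = gene_w.values
    universe = db.gene_universe
    uni_idx = np.array([pos[g] for g in universe], dtype=np.intp)
    rng = np.random.default_rng(seed)

    results = []
    for name in sorted(db.pathways):
        genes = db.pathways[name]
        member_idx = np.array([pos[g] for g in genes], dtype=np.intp)
        obs_p = float(
            _lancaster_pvalues_for_sets(
                t, w, member_idx[None, :], cov_policy
            )[0]
        )
        sets = _sample_index_sets(len(universe), len(genes), L, rng)
        perm_p = _lancaster_pvalues_for_sets(t, w, uni_idx[sets], cov_policy)
        count = int(np.count_nonzero(obs_p >= perm_p))
        comp = (1 + count) / (1 + L) if add_one else count / L
        results.append(
            CompetitiveResult(
                pathway=name,
                self_contained_p=obs_p,
                competitive_p=float(comp),
                L=L,
            )
        )
    return results
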