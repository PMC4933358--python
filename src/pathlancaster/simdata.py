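"""Synthetic-data engine for the two-stage pathway-testing method.

Emulates an exome-sequencing pathway study: a rare-skewed minor-allele
frequency spectrum with blockwise linkage disequilibrium, genes of varying
variant counts grouped into overlapping pathways, a stochastic hierarchical
effect model

    beta_pgv = C_p x C_g d_g x C_gv d_gv x e_pgv

(C: causal-inclusion indicators at pathway/gene/variant level, d: +/- sign
draws, e: MAF-driven magnitude), noise scaled to a target heritability
h^2 = Var(Xb)/(Var(Xb) + sigma^2), and full scenario evaluation: gene-level
SKAT p-values, correlation-corrected Lancaster pathway tests under four
gene-weight functions, type I error / stringent and lenient power at a
Bonferroni-corrected level, and the Q-Q inflation factor.

Scenario defaults mirror the reference study design: 822 subjects, 353
pathways of 10-100 genes drawn from a pool of 3304 genes (~12 variants per
gene), 50% causal genes and 70% causal variants inside one central causal
pathway, 80/20 detrimental/protective signs at both levels, h^2 = 20%,
alpha = 0.05 with Bonferroni correction across pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2, norm

from .combiners import ChiSquareWeights, chi_square_transform
from .competitive import PathwayDB
from .correlated import inflation_factor
from .gene_level import GenotypeMatrix, liu_moment_params, variant_weights_from_maf

__all__ = [
    "SimScenario",
    "PathwayStructure",
    "EffectAssignment",
    "SchemeOutcome",
    "ScenarioReport",
    "simulate_genotypes",
    "build_pathways",
    "assign_effects",
    "scale_noise_to_heritability",
    "gene_weights",
    "run_scenario",
]

GENE_WEIGHT_SCHEMES = ("uniform", "gene_size", "aic", "bic")


@dataclass(frozen=True)
class SimScenario:
    """One simulation configuration (defaults = the reference study design)."""

    n_subjects: int = 822
    n_pathways: int = 353
    n_genes: int = 3304
    genes_per_pathway: tuple[int, int] = (10, 100)
    variants_per_gene_mean: float = 12.4
    maf_rare_fraction: float = 0.8
    maf_rare_range: tuple[float, float] = (0.001, 0.03)
    maf_common_range: tuple[float, float] = (0.03, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.5
    causal_gene_fraction: float = 0.5
    causal_variant_fraction: float = 0.7
    detrimental_gene_fraction: float = 0.8
    detrimental_variant_fraction: float = 0.8
    effect_law: str = "null"  # null | log10maf | inv_sd_maf | inv_var_maf_literal
    h2: float = 0.2
    alpha: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        for name in (
            "maf_rare_fraction",
            "causal_gene_fraction",
            "causal_variant_fraction",
            "detrimental_gene_fraction",
            "detrimental_variant_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.effect_law not in (
            "null",
            "log10maf",
            "inv_sd_maf",
            "inv_var_maf_literal",
        ):
            raise ValueError(f"unknown effect law {self.effect_law!r}")
        if self.effect_law != "null" and not (0.0 < self.h2 < 1.0):
            raise ValueError("heritability must lie in (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")


def _draw_maf(scn: SimScenario, count: int, rng: np.random.Generator) -> np.ndarray:
    rare = rng.random(count) < scn.maf_rare_fraction
    maf = np.empty(count)
    maf[rare] = rng.uniform(*scn.maf_rare_range, rare.sum())
    maf[~rare] = rng.uniform(*scn.maf_common_range, (~rare).sum())
    return maf


def simulate_genotypes(
    n: int,
    variant_count: int,
    maf_spectrum: Sequence[float] | None = None,
    ld_block_size: int = 10,
    ld_rho: float = 0.5,
    seed: int | None = None,
    scenario: SimScenario | None = None,
) -> GenotypeMatrix:
    """Dosage matrix with target MAFs and blockwise LD.

    Haplotypes come from a Gaussian-threshold copula: within each block of
    ``ld_block_size`` adjacent variants the latent normals share an
    exchangeable correlation ``ld_rho``; an allele is carried when the
    latent value falls below the MAF quantile, and the dosage is the sum of
    two independent haplotypes. ``maf_spectrum`` may give explicit
    per-variant MAFs; by default they are drawn rare-heavy (80% below
    0.03) from the scenario's spectrum.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scn = scenario or SimScenario(ld_block_size=ld_block_size, ld_rho=ld_rho)
    if maf_spectrum is None:
        maf = _draw_maf(scn, variant_count, rng)
    else:
        maf = np.asarray(maf_spectrum, dtype=float)
        if maf.shape != (variant_count,):
            raise ValueError("maf_spectrum length must equal variant_count")
        if np.any(maf <= 0) or np.any(maf > 0.5):
            raise ValueError("MAF spectrum must lie in (0, 0.5]")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must lie in [0, 1)")
    thresh = norm.ppf(maf)
    dosage = np.zeros((n, variant_count), dtype=np.int8)
    sr, si = np.sqrt(ld_rho), np.sqrt(1.0 - ld_rho)
    for _ in range(2):  # two haplotypes per subject
        z = np.empty((n, variant_count))
        for start in range(0, variant_count, ld_block_size):
            stop = min(start + ld_block_size, variant_count)
            shared = rng.standard_normal(n)[:, None]
            z[:, start:stop] = sr * shared + si * rng.standard_normal(
                (n, stop - start)
            )
        dosage += (z < thresh).astype(np.int8)
    return GenotypeMatrix(dosage, maf=maf)


@dataclass(frozen=True)
class PathwayStructure:
    """Pathway membership plus the gene -> variant-column layout."""

    db: PathwayDB
    gene_ids: tuple
    snp_counts: np.ndarray
    gene_slices: dict = field(repr=False, default_factory=dict)

    @property
    def n_variants(self) -> int:
        return int(self.snp_counts.sum())


def build_pathways(
    scn: SimScenario,
    seed: int | None = None,
    overlap_fraction: float | None = None,
) -> PathwayStructure:
    """Partition or overlap genes into pathways and lay out their variants.

    ``overlap_fraction=None`` (default): each pathway is a random subset of
    the shared gene pool, so overlap arises naturally — the regime of real
    pathway databases where pathways heavily share genes. ``0.0``: pathways
    partition the gene pool (error if the sizes do not fit). A value f in
    (0, 1] draws f of each pathway's genes from genes already used and the
    rest from unused genes.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo, hi = scn.genes_per_pathway
    if not (1 <= lo <= hi):
        raise ValueError("invalid genes-per-pathway range")
    sizes = rng.integers(lo, hi + 1, scn.n_pathways)
    genes = tuple(f"g{i}" for i in range(scn.n_genes))
    pathways: dict[str, tuple] = {}
    if overlap_fraction is None:
        if hi > scn.n_genes:
            raise ValueError("pathway size range exceeds the gene pool")
        for k, size in enumerate(sizes):
            idx = rng.choice(scn.n_genes, size=size, replace=False)
            pathways[f"pw{k}"] = tuple(genes[i] for i in idx)
    else:
        if not (0.0 <= overlap_fraction <= 1.0):
            raise ValueError("overlap fraction must lie in [0, 1]")
        unused = list(range(scn.n_genes))
        rng.shuffle(unused)
        used: list[int] = []
        for k, size in enumerate(sizes):
            n_shared = int(round(overlap_fraction * size)) if used else 0
            n_new = size - n_shared
            if n_new > len(unused):
                raise ValueError(
                    "gene pool exhausted: pathway sizes infeasible at this "
                    "overlap fraction"
                )
            fresh = [unused.pop() for _ in range(n_new)]
            shared = (
                list(rng.choice(used, size=n_shared, replace=False))
                if n_shared
                else []
            )
            members = fresh + shared
            used.extend(fresh)
            pathways[f"pw{k}"] = tuple(genes[i] for i in members)
    db = PathwayDB(pathways)
    member_genes = tuple(g for g in genes if g in set(db.gene_universe))
    # every gene present in a pathway gets at least one variant
    counts = 1 + rng.poisson(max(scn.variants_per_gene_mean - 1.0, 0.0), len(member_genes))
    slices: dict[str, slice] = {}
    start = 0
    for g, c in zip(member_genes, counts):
        slices[g] = slice(start, start + int(c))
        start += int(c)
    return PathwayStructure(
        db=db,
        gene_ids=member_genes,
        snp_counts=counts.astype(int),
        gene_slices=slices,
    )


@dataclass(frozen=True)
class EffectAssignment:
    """Per-variant effect sizes from the hierarchical causal model."""

    beta: np.ndarray
    causal_variants: np.ndarray
    causal_genes: tuple
    central_pathway: str | None

    def __post_init__(self):
        if np.any((np.abs(self.beta) > 0) != self.causal_variants):
            raise ValueError("nonzero effects must coincide with causal flags")


def _effect_magnitude(law: str, maf: np.ndarray) -> np.ndarray:
    if law == "log10maf":
        return np.abs(np.log10(maf))
    if law == "inv_sd_maf":
        return 1.0 / np.sqrt(maf * (1.0 - maf))
    if law == "inv_var_maf_literal":
        return 1.0 / (maf * (1.0 - maf))
    raise ValueError(f"no magnitude law for {law!r}")


def assign_effects(
    scn: SimScenario,
    maf: np.ndarray,
    structure: PathwayStructure,
    seed: int | None = None,
) -> EffectAssignment:
    """Sample the hierarchical effect model for one replicate.

    Picks one central causal pathway, flags the configured fraction of its
    genes and of their variants as causal, draws detrimental/protective
    signs at both levels, and sets |beta| by the configured MAF law. The
    null law returns all-zero effects.
    """
    V = structure.n_variants
    if maf.shape != (V,):
        raise ValueError("maf length must match the variant layout")
    if scn.effect_law == "null":
        return EffectAssignment(
            beta=np.zeros(V),
            causal_variants=np.zeros(V, dtype=bool),
            causal_genes=(),
            central_pathway=None,
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = list(structure.db.pathways)
    central = names[int(rng.integers(len(names)))]
    member_genes = list(structure.db.pathways[central])
    for _ in range(100):
        causal_genes = [
            g for g in member_genes if rng.random() < scn.causal_gene_fraction
        ]
        if causal_genes:
            break
        warnings.warn("no causal genes sampled; resampling", RuntimeWarning)
    beta = np.zeros(V)
    causal_v = np.zeros(V, dtype=bool)
    mag = _effect_magnitude(scn.effect_law, maf)
    for g in causal_genes:
        sl = structure.gene_slices[g]
        d_g = 1.0 if rng.random() < scn.detrimental_gene_fraction else -1.0
        j = np.arange(sl.start, sl.stop)
        take = rng.random(j.size) < scn.causal_variant_fraction
        if not take.any():
            take[rng.integers(j.size)] = True  # a causal gene keeps >= 1 variant
        idx = j[take]
        d_gv = np.where(
            rng.random(idx.size) < scn.detrimental_variant_fraction, 1.0, -1.0
        )
        beta[idx] = d_g * d_gv * mag[idx]
        causal_v[idx] = True
    return EffectAssignment(
        beta=beta,
        causal_variants=causal_v,
        causal_genes=tuple(causal_genes),
        central_pathway=central,
    )


def scale_noise_to_heritability(X_beta: np.ndarray, h2: float) -> float:
    """sigma^2 giving Var(Xb)/(Var(Xb) + sigma^2) = h2 in expectation."""
    if not (0.0 < h2 < 1.0):
        raise ValueError("heritability must lie in (0, 1)")
    vg = float(np.var(np.asarray(X_beta, dtype=float)))
    if vg <= 0.0:
        raise ValueError("zero genetic variance: cannot target a positive h2")
    return vg * (1.0 - h2) / h2


def gene_weights(
    scheme: str,
    snp_counts: np.ndarray | None = None,
    criterion_delta: np.ndarray | None = None,
    mean_maf: np.ndarray | None = None,
    floor: float = 0.1,
) -> np.ndarray:
    """Per-gene Lancaster weights.

    uniform: 2. gene_size: 2*median(n_i)/n_i (n_i = SNPs in gene i).
    aic/bic: 2*Delta_i/median(Delta) floored at ``floor``, where Delta_i is
    the AIC/BIC difference of the gene's null-vs-full multi-SNP regression.
    maf_common (w2): 4*MAF(1-MAF); maf_rare (w3): 1/(MAF(1-MAF)), both at
    the gene's mean MAF.
    """
    if scheme == "uniform":
        if snp_counts is None:
            raise ValueError("need gene count (snp_counts) for sizing")
        return np.full(len(snp_counts), 2.0)
    if scheme == "gene_size":
        counts = np.asarray(snp_counts, dtype=float)
        if np.any(counts < 1):
            raise ValueError("every gene needs at least one SNP")
        return 2.0 * np.median(counts) / counts
    if scheme in ("aic", "bic"):
        delta = np.asarray(criterion_delta, dtype=float)
        med = np.median(delta)
        if med == 0.0:
            return np.full(delta.size, 2.0)
        return np.maximum(2.0 * delta / med, floor)
    if scheme == "maf_common":
        m = np.asarray(mean_maf, dtype=float)
        return 4.0 * m * (1.0 - m)
    if scheme == "maf_rare":
        m = np.asarray(mean_maf, dtype=float)
        if np.any(m <= 0):
            raise ValueError("maf_rare weight undefined at MAF = 0")
        return 1.0 / (m * (1.0 - m))
    raise ValueError(f"unknown gene weight scheme {scheme!r}")


@dataclass(frozen=True)
class SchemeOutcome:
    """Per-weight-function summary of one scenario run."""

    type1_error: float | None
    stringent_power: float | None
    lenient_power: float | None
    inflation_lambda: float


@dataclass(frozen=True)
class ScenarioReport:
    scheme_results: dict
    replicates: int
    n_pathways: int
    alpha: float
    alpha_per_pathway: float
    effect_law: str
    pathway_pvalues: dict = field(repr=False, default_factory=dict)


# ----------------------------------------------------------------------
# scenario engine
# ----------------------------------------------------------------------


def _vector_liu_sf(q: np.ndarray, prm: dict) -> np.ndarray:
    """Liu survival probabilities for many statistics of one gene."""
    t = (q - prm["mu_q"]) / prm["sigma_q"] * prm["sigma_x"] + prm["mu_x"]
    if prm["delta"] > 0:
        from scipy.stats import ncx2

        p = ncx2.sf(t, prm["df"], prm["delta"])
    else:
        p = chi2.sf(t, prm["df"])
    return np.clip(p, 1e-300, 1.0)


class _Batch:
    """Fixed genotypes/pathways; phenotypes are redrawn per replicate."""

    def __init__(self, scn: SimScenario, rng: np.random.Generator):
        self.scn = scn
        self.structure = build_pathways(scn, rng)
        st = self.structure
        geno = simulate_genotypes(
            scn.n_subjects,
            st.n_variants,
            ld_block_size=scn.ld_block_size,
            ld_rho=scn.ld_rho,
            seed=rng,
            scenario=scn,
        )
        self.maf = geno.maf
        G = geno.dosages
        self.n = scn.n_subjects
        vwt = variant_weights_from_maf(self.maf).w
        Gc = G - G.mean(axis=0)  # intercept-only null projection
        self.B = Gc * np.sqrt(vwt)  # (I-H) G W^{1/2}
        self.G = G
        self.genes = st.gene_ids
        self.slices = [st.gene_slices[g] for g in self.genes]
        # per-gene mixture eigenvalues (unscaled by sigma^2) + Liu params
        self.liu: list[dict] = []
        qr_blocks = []
        self.qr_slices: list[slice] = []
        start = 0
        for sl in self.slices:
            Bg = self.B[:, sl]
            lam = np.linalg.eigvalsh(Bg.T @ Bg)
            lam = lam[lam > max(1e-10, 1e-10 * lam.max(initial=0.0))]
            self.liu.append(liu_moment_params(lam if lam.size else np.array([1.0])))
            # orthonormal basis of the gene's residualized genotype span,
            # for the AIC/BIC criterion regressions
            Qg, Rg = np.linalg.qr(Gc[:, sl])
            keep = np.abs(np.diag(Rg)) > 1e-8 * max(1.0, np.abs(np.diag(Rg)).max())
            Qg = Qg[:, keep]
            qr_blocks.append(Qg)
            self.qr_slices.append(slice(start, start + Qg.shape[1]))
            start += Qg.shape[1]
        self.Qall = np.concatenate(qr_blocks, axis=1)
        self.snp_counts = st.snp_counts.astype(float)
        # pathway membership matrix (pathways x genes)
        gene_pos = {g: i for i, g in enumerate(self.genes)}
        names = list(st.db.pathways)
        self.pathway_names = names
        M = np.zeros((len(names), len(self.genes)))
        for r, name in enumerate(names):
            for g in st.db.pathways[name]:
                M[r, gene_pos[g]] = 1.0
        self.M = M

    def gene_pvalues_and_deltas(
        self, Y: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """SKAT p-values and AIC/BIC criterion differences per phenotype.

        Y is n x k; returns (p, delta_aic, delta_bic), each genes x k.
        """
        n = self.n
        Yc = Y - Y.mean(axis=0)
        rss0 = (Yc * Yc).sum(axis=0)
        sigma2 = rss0 / (n - 1)
        U = self.B.T @ Yc
        P2 = self.Qall.T @ Yc
        G_ = len(self.genes)
        k = Y.shape[1]
        p = np.empty((G_, k))
        d_aic = np.empty((G_, k))
        d_bic = np.empty((G_, k))
        logn = np.log(n)
        for gi, (sl, qsl) in enumerate(zip(self.slices, self.qr_slices)):
            Q = (U[sl] ** 2).sum(axis=0)
            p[gi] = _vector_liu_sf(Q / sigma2, self.liu[gi])
            drop = (P2[qsl] ** 2).sum(axis=0)
            rss1 = np.maximum(rss0 - drop, 1e-12 * rss0)
            lr = n * np.log(rss0 / rss1)
            J = float(self.snp_counts[gi])
            d_aic[gi] = lr - 2.0 * J
            d_bic[gi] = lr - logn * J
        return p, d_aic, d_bic


def _pathway_pvalues_fixed_w(
    batch: _Batch,
    w: np.ndarray,
    p_real: np.ndarray,
    p_perm: np.ndarray,
) -> np.ndarray:
    """Satterthwaite pathway p-values for one fixed gene-weight vector."""
    M = batch.M
    t_perm = chi_square_transform(p_perm, w[:, None])
    t_real = chi_square_transform(p_real, w[:, None])
    S = M @ t_perm  # pathways x B
    colvar = t_perm.var(axis=1, ddof=1)
    mean = M @ w
    var = 2.0 * mean + (S.var(axis=1, ddof=1) - M @ colvar)
    var = np.maximum(var, 0.02 * 2.0 * mean)  # positivity guard
    c = 0.5 * var / mean
    v = 2.0 * mean**2 / var
    T = M @ t_real  # pathways x reps
    return chi2.sf(T / c[:, None], v[:, None])


def run_scenario(
    scn: SimScenario,
    replicates: int,
    weight_schemes: Sequence[str] = GENE_WEIGHT_SCHEMES,
    seed: int | None = None,
    batches: int = 5,
    B_perm: int = 400,
) -> ScenarioReport:
    """Full scenario evaluation.

    Per batch, genotypes and pathway structure are fixed and phenotypes are
    redrawn per replicate; the null covariance of the transformed gene
    statistics is estimated once per batch from ``B_perm`` null-phenotype
    resamples. Each replicate produces per-pathway Satterthwaite-corrected
    Lancaster p-values for every weight scheme, thresholded at
    alpha / n_pathways (Bonferroni). Null scenarios report the pathway
    type I error rate; effect scenarios report stringent power (the central
    causal pathway is detected) and lenient power (any pathway sharing a
    causal gene with it is detected). Deterministic given ``seed``.
    """
    if replicates < 20:
        raise ValueError("need at least 20 replicates")
    for s in weight_schemes:
        if s not in GENE_WEIGHT_SCHEMES:
            raise ValueError(f"unknown weight scheme {s!r}")
    rng = np.random.default_rng(seed if seed is not None else scn.seed)
    alpha_pw = scn.alpha / scn.n_pathways
    per_batch = [replicates // batches] * batches
    for i in range(replicates - sum(per_batch)):
        per_batch[i] += 1

    pooled: dict[str, list[np.ndarray]] = {s: [] for s in weight_schemes}
    n_sig: dict[str, int] = {s: 0 for s in weight_schemes}
    n_tests = 0
    stringent: dict[str, int] = {s: 0 for s in weight_schemes}
    lenient: dict[str, int] = {s: 0 for s in weight_schemes}

    for reps_b in per_batch:
        if reps_b == 0:
            continue
        batch = _Batch(scn, rng)
        n = batch.n
        if scn.effect_law == "null":
            gval = np.zeros(n)
            sigma = 1.0
            eff = None
        else:
            eff = assign_effects(scn, batch.maf, batch.structure, rng)
            gval = batch.G @ eff.beta
            sigma = np.sqrt(scale_noise_to_heritability(gval, scn.h2))
        Y = gval[:, None] + sigma * rng.standard_normal((n, reps_b))
        Yperm = rng.standard_normal((n, B_perm))  # null resamples
        p_real, da_real, db_real = batch.gene_pvalues_and_deltas(Y)
        p_perm, _, _ = batch.gene_pvalues_and_deltas(Yperm)

        causal_rows: np.ndarray | None = None
        if eff is not None:
            causal_set = set(eff.causal_genes)
            causal_rows = np.array(
                [
                    any(g in causal_set for g in batch.structure.db.pathways[name])
                    for name in batch.pathway_names
                ]
            )

        for s in weight_schemes:
            if s in ("uniform", "gene_size"):
                w = gene_weights(s, snp_counts=batch.snp_counts)
                pv = _pathway_pvalues_fixed_w(batch, w, p_real, p_perm)
            else:
                deltas = da_real if s == "aic" else db_real
                cols = []
                for r in range(reps_b):
                    w_r = gene_weights(s, criterion_delta=deltas[:, r])
                    cols.append(
                        _pathway_pvalues_fixed_w(
                            batch, w_r, p_real[:, r : r + 1], p_perm
                        )[:, 0]
                    )
                pv = np.column_stack(cols)
            pooled[s].append(pv.ravel())
            sig = pv < alpha_pw
            n_sig[s] += int(sig.sum())
            if causal_rows is not None:
                central_idx = batch.pathway_names.index(eff.central_pathway)
                stringent[s] += int(sig[central_idx].sum())
                lenient[s] += int(sig[causal_rows].any(axis=0).sum())
        n_tests += reps_b * len(batch.pathway_names)

    results: dict[str, SchemeOutcome] = {}
    pooled_out: dict[str, np.ndarray] = {}
    is_null = scn.effect_law == "null"
    for s in weight_schemes:
        pvals = np.concatenate(pooled[s])
        pooled_out[s] = pvals
        results[s] = SchemeOutcome(
            type1_error=n_sig[s] / n_tests if is_null else None,
            stringent_power=None if is_null else stringent[s] / replicates,
            lenient_power=None if is_null else lenient[s] / replicates,
            inflation_lambda=inflation_factor(np.clip(pvals, 1e-300, 1.0)),
        )
    return ScenarioReport(
        scheme_results=results,
        replicates=replicates,
        n_pathways=scn.n_pathways,
        alpha=scn.alpha,
        alpha_per_pathway=alpha_pw,
        effect_law=scn.effect_law,
        pathway_pvalues=pooled_out,
    )
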