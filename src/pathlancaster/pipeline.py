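"""Top-level pipeline: gene p-values -> pathway results -> multiplicity.

Two entry modes mirror how the method is used in practice:

* full two-stage: genotype dosages + phenotype + variant-to-gene map run
  Stage I (SKAT per gene) before the pathway stage;
* meta-analysis: per-gene (or per-SNP plus a SNP-to-gene map) p-values are
  supplied directly and Stage I is skipped — the pathway stage only needs
  significance levels, so it applies unchanged to published summary
  statistics.

The pathway stage runs the self-contained (Satterthwaite-corrected or
independence) Lancaster test and optionally the competitive permutation
test, then adjusts for multiple testing by Bonferroni (FWER) or
Benjamini-Hochberg (FDR). Every run writes a manifest (config echo, seed,
version) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from .combiners import ChiSquareWeights, PValueVector, lancaster_combine
from .competitive import PathwayDB, run_competitive
from .correlated import CovarianceEstimate, correlated_lancaster_test
from . import io as plio

__all__ = ["RunConfig", "adjust_multiplicity", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline configuration (exactly one covariance policy applies)."""

    gene_level: bool = False  # off: p-values supplied directly
    weight_scheme: str = "uniform"
    cov_policy: str = "zero"  # zero | permutation | file
    cov_B: int = 1000
    cov_file: str | None = None
    competitive_L: int = 0  # 0: skip the competitive stage
    alpha_policy: str = "bonferroni"  # bonferroni | fdr_bh
    alpha: float = 0.05
    fdr_q: float = 0.05
    inner_combiner_weight: float = 2.0  # per-SNP -> gene combination
    seed: int | None = None

    def __post_init__(self):
        if self.cov_policy not in ("zero", "permutation", "file"):
            raise ValueError("cov_policy must be zero, permutation or file")
        if self.cov_policy == "file" and not self.cov_file:
            raise ValueError("cov_policy 'file' needs cov_file")
        if self.alpha_policy not in ("bonferroni", "fdr_bh"):
            raise ValueError("alpha_policy must be bonferroni or fdr_bh")
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("FDR q must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def adjust_multiplicity(
    pvalues: np.ndarray | list[float],
    policy: str = "bonferroni",
    alpha: float = 0.05,
) -> dict:
    """Multiple-testing adjustment over one family of p-values.

    bonferroni: reject iff p < alpha/m (threshold reported); adjusted
    values are min(m*p, 1). fdr_bh: Benjamini-Hochberg step-up adjusted
    values, rejecting at adjusted <= alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to adjust")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if policy == "bonferroni":
        threshold = alpha / m
        return {
            "adjusted": np.minimum(p * m, 1.0),
            "reject": p < threshold,
            "threshold": threshold,
        }
    if policy == "fdr_bh":
        reject, adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
        return {"adjusted": adjusted, "reject": reject, "threshold": alpha}
    raise ValueError(f"unknown multiplicity policy {policy!r}")


def _snps_to_gene_pvalues(
    snp_p: PValueVector, snp_gene: dict[str, str], inner_weight: float
) -> PValueVector:
    """Combine per-SNP p-values to gene level by an inner Lancaster (w=2)."""
    by_gene: dict[str, list[float]] = {}
    for sid, p in zip(snp_p.ids, snp_p.values):
        gene = snp_gene.get(sid)
        if gene is None:
            raise ValueError(f"SNP {sid!r} missing from the SNP-to-gene map")
        by_gene.setdefault(gene, []).append(float(p))
    ids, vals = [], []
    for gene, ps in by_gene.items():
        pv = PValueVector([f"{gene}:{k}" for k in range(len(ps))], ps)
        w = ChiSquareWeights.uniform(len(ps), inner_weight)
        ids.append(gene)
        vals.append(lancaster_combine(pv, w).p_value)
    return PValueVector(ids, np.clip(vals, 1e-300, 1.0))


def _gene_pvalues_from_genotypes(
    genotypes, phenotype, variant_gene: dict[str, str], seed: int | None
):
    """Stage I: SKAT per gene on a shared phenotype design."""
    from .gene_level import (
        GenotypeMatrix,
        skat_test,
        variant_weights_from_maf,
    )

    genes: dict[str, list[int]] = {}
    for j, vid in enumerate(genotypes.variant_ids):
        g = variant_gene.get(vid)
        if g is None:
            raise ValueError(f"variant {vid!r} missing from the gene map")
        genes.setdefault(g, []).append(j)
    rows = []
    for gene in sorted(genes):
        cols = genes[gene]
        sub = GenotypeMatrix(
            genotypes.dosages[:, cols].astype(int),
            variant_ids=[genotypes.variant_ids[j] for j in cols],
            maf=genotypes.maf[cols],
        )
        vw = variant_weights_from_maf(sub.maf)
        rows.append(skat_test(phenotype, sub, vw, gene=gene))
    pv = PValueVector(
        [r.gene for r in rows], np.clip([r.p for r in rows], 1e-300, 1.0)
    )
    return pv, rows


def run_pipeline(
    cfg: RunConfig,
    out_dir: str | Path,
    db: PathwayDB,
    gene_p: PValueVector | None = None,
    gene_w: ChiSquareWeights | None = None,
    snp_gene_map: dict[str, str] | None = None,
    genotypes=None,
    phenotype=None,
    variant_gene_map: dict[str, str] | None = None,
    allow_missing_genes: bool = False,
) -> dict:
    """Execute the configured stages and write result TSVs plus a manifest.

    Returns a dict with the output paths and the per-pathway DataFrame.
    Deterministic given ``cfg.seed`` (the manifest timestamp aside).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict = {}

    gene_rows = None
    if cfg.gene_level:
        if genotypes is None or phenotype is None or variant_gene_map is None:
            raise ValueError(
                "gene-level stage needs genotypes, phenotype and a variant map"
            )
        gene_p, gene_rows = _gene_pvalues_from_genotypes(
            genotypes, phenotype, variant_gene_map, cfg.seed
        )
    elif gene_p is None:
        raise ValueError("either enable the gene-level stage or supply gene_p")
    elif snp_gene_map is not None:
        gene_p = _snps_to_gene_pvalues(gene_p, snp_gene_map, cfg.inner_combiner_weight)
        gene_w = None

    if gene_w is None:
        gene_w = ChiSquareWeights.uniform(len(gene_p))

    pos = {g: i for i, g in enumerate(gene_p.ids)}
    missing = sorted(
        {g for genes in db.pathways.values() for g in genes if g not in pos}
    )
    if missing:
        if not allow_missing_genes:
            raise ValueError(
                f"{len(missing)} pathway gene(s) missing from the p-value "
                f"table; first 10: {missing[:10]}"
            )
        db = PathwayDB(
            {
                name: [g for g in genes if g in pos]
                for name, genes in db.pathways.items()
                if any(g in pos for g in genes)
            },
            descriptions=db.descriptions,
        )

    cov: CovarianceEstimate | None = None
    cov_ids: tuple | None = None
    if cfg.cov_policy == "file":
        cov, cov_ids = plio.read_covariance_tsv(cfg.cov_file)
        if cov_ids != gene_p.ids:
            raise ValueError("covariance header does not match the gene ids")

    rows = []
    for name in sorted(db.pathways):
        genes = db.pathways[name]
        idx = [pos[g] for g in genes]
        sub_p = PValueVector(genes, gene_p.values[idx])
        sub_w = ChiSquareWeights(gene_w.values[idx])
        if cov is not None:
            sub_cov = CovarianceEstimate(
                cov.rho[np.ix_(idx, idx)], method=cov.method
            )
            res = correlated_lancaster_test(sub_p, sub_w, sub_cov)
            c, v = res.null_params["c"], res.null_params["v"]
        else:
            res = lancaster_combine(sub_p, sub_w)
            c, v = 1.0, res.null_params["df"]
        rows.append(
            {
                "pathway": name,
                "m_genes": len(genes),
                "statistic": res.statistic,
                "c": c,
                "v": v,
                "p_value": res.p_value,
            }
        )
    pathway_df = pd.DataFrame(rows)
    adj = adjust_multiplicity(
        pathway_df["p_value"].to_numpy(),
        policy=cfg.alpha_policy,
        alpha=cfg.alpha if cfg.alpha_policy == "bonferroni" else cfg.fdr_q,
    )
    pathway_df["adjusted_p"] = adj["adjusted"]
    pathway_df["significant"] = adj["reject"]
    pathway_path = out / "pathways.tsv"
    pathway_df.to_csv(pathway_path, sep="\t", index=False)
    outputs["pathways"] = str(pathway_path)

    gene_path = out / "genes.tsv"
    if gene_rows is not None:
        pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "J_variants": r.n_variants,
                    "Q": r.Q,
                    "p": r.p,
                    "fallback": r.used_fallback,
                }
                for r in gene_rows
            ]
        ).to_csv(gene_path, sep="\t", index=False)
    else:
        plio.write_pvalue_table(gene_p, gene_path, gene_w)
    outputs["genes"] = str(gene_path)

    if cfg.competitive_L:
        comp = run_competitive(
            gene_p, gene_w, db, cfg.competitive_L,
            cov_policy=cov, seed=cfg.seed,
        )
        comp_path = out / "competitive.tsv"
        plio.write_competitive_results(comp, comp_path)
        outputs["competitive"] = str(comp_path)

    from . import __version__

    manifest = {
        "config": asdict(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "n_genes": len(gene_p),
        "n_pathways": len(db),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": outputs,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    outputs["manifest"] = str(manifest_path)
    outputs["pathway_table"] = pathway_df
    return outputs
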