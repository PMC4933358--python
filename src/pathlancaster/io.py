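"""File-format adapters: GMT gene sets, TSV tables, covariance matrices.

All formats are plain text. The p-value table is TSV with columns ``id``,
``p`` and an optional ``weight`` column (missing weights default to the
Fisher value 2). Genotype dosages are TSV with variant ids in the header
and one 0/1/2 row per subject.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .combiners import ChiSquareWeights, CombinedResult, PValueVector
from .competitive import CompetitiveResult, PathwayDB
from .correlated import CovarianceEstimate
from .gene_level import GenotypeMatrix

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_pvalue_table",
    "write_pvalue_table",
    "write_combined_results",
    "read_genotype_tsv",
    "read_vcf_dosages",
    "read_snp_gene_map",
    "read_covariance_tsv",
    "write_competitive_results",
]


def read_gmt(path: str | Path) -> PathwayDB:
    """Read pathway definitions: one ``name<TAB>description<TAB>genes...`` per line.

    Duplicate genes within a line are deduplicated with a warning; a line
    without genes is an error reported with its line number.
    """
    pathways: dict[str, tuple] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    "at least one gene"
                )
            name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: pathway {name!r} has no genes")
            if name in pathways:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            deduped = tuple(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                warnings.warn(
                    f"{path}:{lineno}: {len(genes) - len(deduped)} duplicate "
                    f"gene(s) removed from {name!r}",
                    stacklevel=2,
                )
            pathways[name] = deduped
            descriptions[name] = desc
    if not pathways:
        raise ValueError(f"{path}: no pathways found")
    return PathwayDB(pathways, descriptions=descriptions)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in db.pathways.items():
            desc = (db.descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_pvalue_table(path: str | Path) -> tuple[PValueVector, ChiSquareWeights]:
    """TSV with columns id, p, optional weight (default: uniform 2)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("id", "p"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    pv = PValueVector(df["id"].astype(str).tolist(), df["p"].to_numpy(float))
    if "weight" in df.columns:
        w = ChiSquareWeights(df["weight"].to_numpy(float))
    else:
        w = ChiSquareWeights.uniform(len(pv))
    return pv, w


def write_pvalue_table(
    pv: PValueVector, path: str | Path, w: ChiSquareWeights | None = None
) -> None:
    data = {"id": list(pv.ids), "p": pv.values}
    if w is not None:
        data["weight"] = w.values
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_combined_results(
    results: Sequence[CombinedResult], path: str | Path, labels: Sequence[str] | None = None
) -> None:
    """TSV: method, statistic, df_or_params, p_value, log10_p."""
    rows = []
    for i, res in enumerate(results):
        params = ";".join(
            f"{k}={v:.6g}" if isinstance(v, float) else f"{k}={v}"
            for k, v in res.null_params.items()
            if not isinstance(v, np.ndarray)
        )
        row = {
            "method": res.method,
            "statistic": res.statistic,
            "df_or_params": params,
            "p_value": res.p_value,
            "log10_p": res.log10_p,
        }
        if labels is not None:
            row = {"id": labels[i], **row}
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    """Dosage TSV: header = variant ids, one row of 0/1/2 per subject."""
    df = pd.read_csv(path, sep="\t")
    return GenotypeMatrix(df.to_numpy(), variant_ids=list(df.columns))


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Minimal VCF ingestion: biallelic sites with hard-called genotypes."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF ingestion requires cyvcf2") from exc
    ids, cols = [], []
    for var in VCF(str(path)):
        if len(var.ALT) != 1:
            continue
        gts = np.asarray(var.gt_types)
        if np.any(gts == 2):  # UNKNOWN in cyvcf2 coding
            raise ValueError(f"missing genotype at {var.ID or var.POS}")
        dos = np.where(gts == 3, 2, gts)  # HOM_ALT is coded 3
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        cols.append(dos)
    if not cols:
        raise ValueError(f"{path}: no biallelic sites found")
    return GenotypeMatrix(np.column_stack(cols), variant_ids=ids)


def read_snp_gene_map(path: str | Path) -> dict[str, str]:
    """TSV ``variant_id<TAB>gene_id`` -> mapping dict."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: need variant_id and gene_id columns")
    return dict(zip(df[cols[0]].astype(str), df[cols[1]].astype(str)))


def read_covariance_tsv(path: str | Path) -> tuple[CovarianceEstimate, tuple]:
    """Square TSV with test ids as header; returns the estimate and ids."""
    df = pd.read_csv(path, sep="\t")
    ids = tuple(str(c) for c in df.columns)
    mat = df.to_numpy(float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{path}: covariance matrix must be square")
    return CovarianceEstimate(mat, method="user-supplied"), ids


def write_competitive_results(
    results: Sequence[CompetitiveResult], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "self_contained_p": r.self_contained_p,
                "competitive_p": r.competitive_p,
                "L": r.L,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False)
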