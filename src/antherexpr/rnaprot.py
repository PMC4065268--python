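"""Transcript-protein concordance across developmental stages.

Protein stage-ratios (replicate-averaged log2) are paired by gene id with
RNA stage-ratios (gene-collapsed, stage-mean normalized intensities); the
joint distribution is summarized by Pearson correlation and a decile-bin
table.  Protein sets from different studies can be compared after
restriction to molecular-weight size classes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ProbeAnnotation, ProteinAbundanceTable

logger = logging.getLogger(__name__)

#: the 11 gel size-fraction bins, kD
MW_BINS = [
    ("3.5-10kD", 3.5, 10.0),
    ("10-15kD", 10.0, 15.0),
    ("15-20kD", 15.0, 20.0),
    ("20-30kD", 20.0, 30.0),
    ("30-40kD", 30.0, 40.0),
    ("40-50kD", 40.0, 50.0),
    ("50-60kD", 50.0, 60.0),
    ("60-80kD", 60.0, 80.0),
    ("80-110kD", 80.0, 110.0),
    ("110-160kD", 110.0, 160.0),
    ("160-260kD", 160.0, 260.0),
]
MW_LABELS = [b[0] for b in MW_BINS]


def protein_stage_ratio(
    proteins: ProteinAbundanceTable, stage_a: str, stage_b: str
) -> pd.DataFrame:
    """Per-protein replicate-averaged log2 abundance ratio of stage A vs B.

    Only proteins observed at both stages (constitutively present across the
    compared stages) are ratioed.  Returns protein_id-indexed DataFrame with
    gene_id and log2_ratio.
    """
    t = proteins.table
    means = (
        t[t["stage"].isin([stage_a, stage_b])]
        .groupby(["protein_id", "stage"])["abundance"].mean().unstack()
    )
    means = means.dropna()
    genes = t.drop_duplicates("protein_id").set_index("protein_id")["gene_id"]
    out = pd.DataFrame({
        "gene_id": genes.reindex(means.index),
        "log2_ratio": np.log2(means[stage_a]) - np.log2(means[stage_b]),
    })
    return out


def rna_stage_ratio(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    stage_a: str,
    stage_b: str,
    **criteria: str,
) -> pd.Series:
    """Gene-collapsed RNA log2 ratio of stage-mean intensities A vs B.

    Probes of the same gene are collapsed by mean intensity before ratioing.
    """
    gene_map = annotation.gene_map()
    probes = matrix.probes.intersection(gene_map.index)
    mean_a = matrix.values.loc[probes, matrix.sample_ids(stage=stage_a, **criteria)].mean(axis=1)
    mean_b = matrix.values.loc[probes, matrix.sample_ids(stage=stage_b, **criteria)].mean(axis=1)
    df = pd.DataFrame({"gene": gene_map.loc[probes], "a": mean_a, "b": mean_b})
    by_gene = df.groupby("gene")[["a", "b"]].mean()
    return np.log2(by_gene["a"]) - np.log2(by_gene["b"])


def pair_stage_ratios(
    proteins: ProteinAbundanceTable,
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    stage_a: str,
    stage_b: str,
    **criteria: str,
) -> pd.DataFrame:
    """Inner join of protein and RNA stage-ratios on gene id.

    Multiple proteins of one gene are collapsed by summed abundance before
    ratioing.  Returns gene-indexed DataFrame with protein_log2_ratio and
    rna_log2_ratio; empty (with a warning) when no genes are shared.
    """
    t = proteins.table
    summed = (
        t.groupby(["gene_id", "stage", "replicate"])["abundance"].sum().reset_index()
    )
    summed["protein_id"] = summed["gene_id"]
    prot = protein_stage_ratio(
        ProteinAbundanceTable(summed[["protein_id", "gene_id", "stage", "replicate", "abundance"]]
                              .assign(mw_fraction="")),
        stage_a, stage_b,
    )
    rna = rna_stage_ratio(matrix, annotation, stage_a, stage_b, **criteria)
    shared = prot.index.intersection(rna.index)
    if len(shared) == 0:
        logger.warning("no genes shared between protein table and array")
        return pd.DataFrame(columns=["protein_log2_ratio", "rna_log2_ratio"])
    out = pd.DataFrame({
        "protein_log2_ratio": prot.loc[shared, "log2_ratio"],
        "rna_log2_ratio": rna.loc[shared],
    })
    logger.info("paired %d genes for stages %s vs %s", len(out), stage_a, stage_b)
    return out


def paired_correlation(paired: pd.DataFrame) -> float:
    """Pearson r of the paired protein and RNA log2 ratios."""
    return float(np.corrcoef(paired["protein_log2_ratio"], paired["rna_log2_ratio"])[0, 1])


def _decile_index(x: np.ndarray) -> np.ndarray:
    """Decile bin (1..10) per value; ties broken by stable first-occurrence order
    so bins have size n/10 +- 1 and tables are bit-reproducible."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * 10) // n + 1


def decile_table(paired: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """10x10 joint count table of per-axis decile bins plus the two margins.

    Deciles are computed independently per axis over the paired set; margins
    are each n/10 +- 1.  Requires at least 10 rows.
    """
    n = len(paired)
    if n < 10:
        raise ValueError(f"need >= 10 paired rows for a decile table, got {n}")
    dp = _decile_index(paired["protein_log2_ratio"].to_numpy())
    dr = _decile_index(paired["rna_log2_ratio"].to_numpy())
    table = pd.crosstab(pd.Series(dp, name="protein_decile"),
                        pd.Series(dr, name="rna_decile"))
    table = table.reindex(index=range(1, 11), columns=range(1, 11), fill_value=0)
    return table, table.sum(axis=1), table.sum(axis=0)


def mw_labels_in_range(low_kd: float, high_kd: float) -> list[str]:
    """Size-class labels fully contained in [low, high] kD.

    Bins straddling a boundary are included only when fully contained.
    """
    return [lab for lab, lo, hi in MW_BINS if lo >= low_kd and hi <= high_kd]


def set_overlap_mw(
    set_a: dict[str, str] | pd.Series,
    set_b: dict[str, str] | pd.Series,
    low_kd: float,
    high_kd: float,
) -> dict:
    """Overlap of two protein sets restricted to MW fractions within a range.

    Each set maps protein id -> MW fraction label (one of the 11 bins).
    Returns sizes of the intersection and the two set differences.
    """
    labels = set(mw_labels_in_range(low_kd, high_kd))
    def _filter(s) -> set[str]:
        items = s.items() if hasattr(s, "items") else s
        out = set()
        for pid, lab in items:
            if lab not in MW_LABELS:
                raise ValueError(f"unknown MW fraction label {lab!r}")
            if lab in labels:
                out.add(pid)
        return out
    a, b = _filter(set_a), _filter(set_b)
    return {"common": len(a & b), "only_a": len(a - b), "only_b": len(b - a)}
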