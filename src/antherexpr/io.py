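"""Readers, writers and the shared tabular data model.

All on-disk formats are plain TSV (UTF-8, '.' decimal).  An expression
experiment is two files: an intensity matrix (probes x samples, linear
fluorescence units) and a sample-metadata table keyed by sample id.  Probe
annotation, gene lists, gene-set maps and protein abundance tables each have
their own small format documented on the reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: metadata columns every sample carries, in canonical order
SAMPLE_META_COLUMNS = ["array_id", "channel", "stage", "genotype", "tissue", "replicate"]

#: the two dye labels of a two-color array
CHANNELS = ("Cy5", "Cy3")


class ParseError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Probe x sample linear intensities plus per-sample metadata.

    ``values`` is a DataFrame indexed by probe id with one column per sample
    id; ``samples`` is indexed by sample id with :data:`SAMPLE_META_COLUMNS`.
    Sample ids are ``"<array_id>.<channel>"`` so the (array, channel) pair is
    unique by construction.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate probe id: {dup!r}")
        missing = [c for c in self.values.columns if c not in self.samples.index]
        if missing:
            raise ParseError(f"samples without metadata: {missing}")
        if len(self.values.columns) and not (self.values.to_numpy() > 0).all():
            r, c = np.argwhere(~(self.values.to_numpy() > 0))[0]
            raise ParseError(
                f"non-positive intensity at probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}"
            )
        key = self.samples[["array_id", "channel"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ParseError(f"duplicate (array, channel): {key[key.duplicated()].iloc[0]}")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    def arrays(self) -> list[str]:
        return list(dict.fromkeys(self.samples["array_id"]))

    def sample_ids(self, **criteria: str) -> list[str]:
        """Sample ids whose metadata match all keyword criteria (e.g. stage="0.4")."""
        mask = pd.Series(True, index=self.samples.index)
        for col, val in criteria.items():
            mask &= self.samples[col] == val
        ids = self.samples.index[mask]
        return [s for s in self.values.columns if s in set(ids)]

    def subset(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[sample_ids].copy(), self.samples.loc[sample_ids].copy())

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and self.samples.equals(other.samples)


@dataclass
class ProbeAnnotation:
    """Probe id -> gene id / negative-control flag / optional labels."""

    table: pd.DataFrame  # index probe_id; columns gene_id, is_negative_control, tf_family, tags

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ParseError(f"duplicate probe id in annotation: {dup!r}")
        neg = self.table["is_negative_control"].astype(bool)
        has_gene = self.table["gene_id"].notna() & (self.table["gene_id"] != "")
        bad = self.table.index[neg & has_gene]
        if len(bad):
            raise ParseError(f"negative-control probe with a gene id: {bad[0]!r}")

    @property
    def negative_controls(self) -> pd.Index:
        return self.table.index[self.table["is_negative_control"].astype(bool)]

    @property
    def regular_probes(self) -> pd.Index:
        return self.table.index[~self.table["is_negative_control"].astype(bool)]

    def gene_map(self) -> pd.Series:
        """probe id -> gene id for probes that have one."""
        g = self.table["gene_id"]
        return g[g.notna() & (g != "")]

    def probes_for_genes(self, genes: list[str]) -> dict[str, list[str]]:
        """gene id -> list of probe ids (empty list when not on the array)."""
        inv: dict[str, list[str]] = {g: [] for g in genes}
        for probe, gene in self.gene_map().items():
            if gene in inv:
                inv[gene].append(probe)
        return inv


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_matrix(matrix_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    samples = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    samples["replicate"] = samples["replicate"].astype(int)
    samples = samples[SAMPLE_META_COLUMNS]
    logger.info("read matrix %s: %d probes x %d samples", matrix_path, *values.shape)
    return ExpressionMatrix(values, samples)


def write_matrix(matrix: ExpressionMatrix, matrix_path: str | Path, meta_path: str | Path) -> None:
    cols = list(matrix.values.columns)
    matrix.values.to_csv(matrix_path, sep="\t", index_label="probe_id", float_format="%.6f")
    matrix.samples.loc[cols, SAMPLE_META_COLUMNS].to_csv(meta_path, sep="\t", index_label="sample_id")


def read_annotation(path: str | Path) -> ProbeAnnotation:
    t = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    t.index = t.index.astype(str)
    t["is_negative_control"] = t["is_negative_control"].map(
        {"True": True, "False": False, "1": True, "0": False, "true": True, "false": False}
    )
    for col in ("gene_id", "tf_family", "tags"):
        if col not in t.columns:
            t[col] = pd.NA
    return ProbeAnnotation(t[["gene_id", "is_negative_control", "tf_family", "tags"]])


def write_annotation(annotation: ProbeAnnotation, path: str | Path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# gene lists / gene-set maps / protein tables
# ---------------------------------------------------------------------------

def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line, order preserved, duplicates collapsed with a warning."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    ids = [ln for ln in lines if ln and not ln.startswith("#")]
    if not ids:
        raise ParseError(f"empty gene list: {path}")
    seen: dict[str, None] = {}
    dups = 0
    for g in ids:
        if g in seen:
            dups += 1
        seen[g] = None
    if dups:
        logger.warning("%s: collapsed %d duplicate gene ids", path, dups)
    logger.info("read gene list %s: %d ids", path, len(seen))
    return list(seen)


def read_gene_set_map(path: str | Path) -> dict[str, list[str]]:
    """Two-column TSV (set id, gene id) -> set id -> ordered unique gene ids."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_id", "gene_id"], dtype=str)
    if df.empty:
        raise ParseError(f"empty gene-set map: {path}")
    out: dict[str, list[str]] = {}
    for set_id, sub in df.groupby("set_id", sort=False):
        genes = list(dict.fromkeys(sub["gene_id"]))
        if not genes or any(not g for g in genes):
            raise ParseError(f"gene set {set_id!r} has empty gene ids")
        out[set_id] = genes
    return out


@dataclass
class ProteinAbundanceTable:
    """Long-format per-protein per-sample normalized abundances.

    Columns: protein_id, gene_id, mw_fraction, stage, replicate, abundance.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        key = self.table[["protein_id", "stage", "replicate"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ParseError(f"duplicate (protein, sample) row: {key[key.duplicated()].iloc[0]}")
        if len(self.table) and not (self.table["abundance"].to_numpy() > 0).all():
            bad = self.table.loc[~(self.table["abundance"] > 0)].iloc[0]
            raise ParseError(f"non-positive abundance for protein {bad['protein_id']!r}")

    def stages(self) -> list[str]:
        return list(dict.fromkeys(self.table["stage"]))


def read_protein_table(path: str | Path) -> ProteinAbundanceTable:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "gene_id": str,
                                            "mw_fraction": str, "stage": str})
    if df.empty:
        raise ParseError(f"empty protein table: {path}")
    df["replicate"] = df["replicate"].astype(int)
    df["abundance"] = df["abundance"].astype(float)
    return ProteinAbundanceTable(df)


def write_protein_table(table: ProteinAbundanceTable, path: str | Path) -> None:
    table.table.to_csv(path, sep="\t", index=False, float_format="%.6f")
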