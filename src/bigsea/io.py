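"""Readers/writers for the tab-delimited formats the pipeline touches.

Formats: expression TSV (genes x samples or transposed), sample-group TSV
(columns ``sample_id``, ``group``), marker TSV (samples x markers), GMT gene
sets, and Cytoscape-compatible SIF + edge-attribute exports.  Also houses
the low-expression filter and the HOMA-IR phenotype index.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSetCollection,
    MarkerMatrix,
    SampleGroups,
    SimilarityNetwork,
)

logger = logging.getLogger("bigsea")

__all__ = [
    "read_expression",
    "write_expression",
    "read_sample_groups",
    "write_sample_groups",
    "read_markers",
    "write_markers",
    "read_gene_sets",
    "write_gene_sets",
    "gene_sets_from_table",
    "filter_low_expression",
    "homa_ir",
    "write_network",
]


def _read_numeric_table(path) -> pd.DataFrame:
    """Read a TSV with one header row and a leading id column; all cells numeric."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate row identifier: {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate column identifier: {dup!r}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(converted.isna().to_numpy())
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"{path}: non-numeric or missing value at row {df.index[i]!r}, "
                f"column {col!r}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    return pd.DataFrame(values, index=df.index.astype(str), columns=df.columns.astype(str))


def read_expression(path, orientation: str = "rows-are-genes") -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    Parameters
    ----------
    path
        TSV with one header row and a leading identifier column.
    orientation
        ``"rows-are-genes"`` (default) or ``"rows-are-samples"``.
    """
    if orientation not in ("rows-are-genes", "rows-are-samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_numeric_table(path)
    if orientation == "rows-are-samples":
        df = df.T
    return ExpressionMatrix.from_frame(df)


def write_expression(x: ExpressionMatrix, path) -> None:
    x.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_sample_groups(path) -> SampleGroups:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample identifier: {dup!r}")
    return SampleGroups(dict(zip(df["sample_id"], df["group"])))


def write_sample_groups(groups: SampleGroups, path) -> None:
    pd.DataFrame(
        {"sample_id": list(groups.assignment), "group": list(groups.assignment.values())}
    ).to_csv(path, sep="\t", index=False)


def read_markers(path) -> MarkerMatrix:
    """Read a samples x markers TSV (rows are samples)."""
    return MarkerMatrix.from_frame(_read_numeric_table(path))


def write_markers(m: MarkerMatrix, path) -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def read_gene_sets(path, min_size: int = 1, universe=None) -> GeneSetCollection:
    """Read gene sets in GMT format.

    Each line: set name, description, then member gene ids, tab-separated.
    If ``universe`` is given, members are intersected with it; sets with
    fewer than ``min_size`` members after intersection are dropped.
    """
    allowed = set(universe) if universe is not None else None
    sets: dict[str, list[str]] = {}
    n_dropped = 0
    with open(path, encoding="utf-8") as fh:
        lines = [line.rstrip("\n") for line in fh if line.strip()]
    if not lines:
        raise ValueError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}: line {lineno}: expected >= 3 tab-separated fields "
                f"(name, description, members...), got {len(fields)}"
            )
        name, _desc, *members = fields
        members = [m for m in members if m]
        if name in sets:
            raise ValueError(f"{path}: duplicate set name: {name!r}")
        if allowed is not None:
            members = [m for m in members if m in allowed]
        if len(members) < min_size:
            n_dropped += 1
            continue
        sets[name] = members
    if n_dropped:
        logger.info("read_gene_sets: dropped %d sets smaller than %d", n_dropped, min_size)
    return GeneSetCollection(sets)


def write_gene_sets(sets: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def gene_sets_from_table(path) -> GeneSetCollection:
    """Build a collection from a two-column gene -> set-name TSV.

    Convenience for pathway annotations distributed as membership tables
    rather than GMT; columns must be named ``gene_id`` and ``set_name``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "set_name"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    sets: dict[str, list[str]] = {}
    for gene, name in zip(df["gene_id"], df["set_name"]):
        sets.setdefault(name, [])
        if gene not in sets[name]:
            sets[name].append(gene)
    return GeneSetCollection(sets)


def filter_low_expression(
    x: ExpressionMatrix, intensity_floor: float = 3.0, fraction: float = 0.5
) -> ExpressionMatrix:
    """Drop genes with low expression on most arrays.

    A gene is removed iff the number of samples with value strictly below
    ``intensity_floor`` strictly exceeds ``fraction`` of the samples, i.e.
    low on *more than* that share of arrays.  A gene low on exactly half the
    arrays (default fraction) is retained.  Gene order is preserved.
    """
    n_low = (x.values < intensity_floor).sum(axis=1)
    keep = n_low <= fraction * x.n_samples
    if not keep.any():
        raise ValueError(
            "low-expression filter removed every gene; review intensity_floor "
            f"({intensity_floor}) against the input scale"
        )
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_low_expression: removed %d of %d genes", n_removed, x.n_genes)
    kept_ids = [g for g, k in zip(x.gene_ids, keep) if k]
    return ExpressionMatrix(x.values[keep], kept_ids, x.sample_ids)


def homa_ir(glucose: float, insulin: float) -> float:
    """Homeostasis-model insulin-resistance index.

    glucose in mg/dl, insulin in uU/ml; returns glucose * insulin / 22.5.
    """
    if glucose < 0 or insulin < 0:
        raise ValueError("glucose and insulin must be non-negative")
    return glucose * insulin / 22.5


def write_network(network: SimilarityNetwork, path_prefix) -> tuple[Path, Path]:
    """Export a thresholded network as Cytoscape SIF + edge-attribute TSV.

    Writes ``<prefix>.sif`` (one ``gene pp marker`` line per retained edge)
    and ``<prefix>.edges.tsv`` (gene, marker, similarity, sign), rows sorted
    by gene then marker id.  Returns the two paths.
    """
    prefix = Path(path_prefix)
    sif_path = prefix.with_name(prefix.name + ".sif")
    attr_path = prefix.with_name(prefix.name + ".edges.tsv")
    edges = sorted(network.edges, key=lambda e: (e[0], e[1]))
    with open(sif_path, "w", encoding="utf-8") as fh:
        for gene, marker, _s, _sign in edges:
            fh.write(f"{gene}\tpp\t{marker}\n")
    with open(attr_path, "w", encoding="utf-8") as fh:
        fh.write("gene\tmarker\tsimilarity\tsign\n")
        for gene, marker, s, sign in edges:
            fh.write(f"{gene}\t{marker}\t{s:.12g}\t{sign}\n")
    return sif_path, attr_path
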