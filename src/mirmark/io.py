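"""Tabular input/output and quantile normalization.

All formats are plain tab-separated text:

* expression matrix — first column feature id, header row sample ids,
  log2-scale numeric cells;
* sample annotation — columns ``sample_id``, ``label`` (cancer/normal);
* edge list — columns ``mirna_id``, ``gene_id``, ``origin``
  (validated/predicted) with optional ``corr``/``corr_p``;
* network export — Cytoscape SIF plus a node-attribute table.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import (
    ORIGINS,
    EdgeSet,
    ExpressionMatrix,
    SampleAnnotation,
    TargetEdge,
)
from .errors import DegenerateInputError, FormatError, ParseError

logger = logging.getLogger(__name__)


def read_expression_table(path, feature_kind: str, dataset_id: str = "") -> ExpressionMatrix:
    """Read a features x samples TSV into an :class:`ExpressionMatrix`.

    Duplicate feature ids are collapsed by averaging their rows (logged).
    Non-numeric cells raise :class:`ParseError` naming the offending
    row and column.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression table") from exc
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty expression table")
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = num.isna() & df.notna() | df.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    num.index = num.index.astype(str)
    num.index.name = None
    if num.index.has_duplicates:
        n_dup = int(num.index.duplicated().sum())
        logger.info("%s: collapsing %d duplicate feature rows by mean", path, n_dup)
        order = num.index.drop_duplicates()
        num = num.groupby(level=0, sort=False).mean().loc[order]
    return ExpressionMatrix(values=num, feature_kind=feature_kind, dataset_id=dataset_id or path.stem)


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id")


def read_annotation_table(path, dataset_id: str = "") -> SampleAnnotation:
    """Read a two-column (sample_id, label) TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    labels = pd.Series(df["label"].to_numpy(), index=df["sample_id"].to_numpy())
    return SampleAnnotation(labels=labels, dataset_id=dataset_id or path.stem)


def write_annotation_table(annotation: SampleAnnotation, path) -> None:
    pd.DataFrame(
        {"sample_id": annotation.sample_ids, "label": annotation.labels.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common empirical distribution.

    The reference distribution is the vector of row-wise means of the
    column-sorted values. Within-column ranks are preserved; tied values
    receive the mean of the reference values at the tied positions.
    Applying the transform twice equals applying it once.
    """
    if matrix.n_samples < 2:
        raise DegenerateInputError("quantile normalization needs at least 2 samples")
    V = matrix.values.to_numpy(dtype=float)
    ref = np.sort(V, axis=0).mean(axis=1)
    out = np.empty_like(V)
    for j in range(V.shape[1]):
        col = V[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # ties: average the reference values mapped onto the tied block
        uniq, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
        if len(uniq) < len(col):
            sums = np.bincount(inv, weights=assigned)
            assigned = (sums / counts)[inv]
        out[:, j] = assigned
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values=values, feature_kind=matrix.feature_kind, dataset_id=matrix.dataset_id)


def read_edge_list(path) -> EdgeSet:
    """Read a miRNA->gene edge TSV (mirna_id, gene_id, origin).

    Duplicate (miRNA, gene) rows are merged; a "validated" origin wins over
    "predicted". Optional corr/corr_p columns are carried through.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_id": str, "origin": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty edge list") from exc
    for col in ("mirna_id", "gene_id", "origin"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    edges = EdgeSet(provenance=str(path))
    has_corr = "corr" in df.columns and "corr_p" in df.columns
    for idx, row in df.iterrows():
        if pd.isna(row["mirna_id"]) or pd.isna(row["gene_id"]) or str(row["gene_id"]).strip() == "":
            raise FormatError(f"{path}: missing mirna_id/gene_id in row {idx + 2}")
        origin = str(row["origin"]).strip()
        if origin not in ORIGINS:
            raise FormatError(
                f"{path}: unknown origin {origin!r} in row {idx + 2}; expected one of {ORIGINS}"
            )
        corr = corr_p = None
        if has_corr and not pd.isna(row["corr"]) and not pd.isna(row["corr_p"]):
            corr, corr_p = float(row["corr"]), float(row["corr_p"])
        edges.add(TargetEdge(str(row["mirna_id"]), str(row["gene_id"]), origin, corr, corr_p))
    return edges


def write_edge_list(edges: EdgeSet, path) -> None:
    edges.to_frame().to_csv(path, sep="\t", index=False)


def export_network(
    edges: EdgeSet,
    path,
    annotations: Optional[Mapping[str, str]] = None,
    highlight: Optional[set[str]] = None,
    node_path=None,
) -> tuple[Path, Path]:
    """Write a Cytoscape SIF file plus a node-attribute table.

    SIF lines read ``MIRNA targets GENE`` in lexicographic order. The node
    table has columns node, type (miRNA/gene), term (empty when the gene is
    unannotated) and, when ``highlight`` is given, a ``highlight`` flag.
    Returns the pair of written paths.
    """
    if len(edges) == 0:
        raise DegenerateInputError("cannot export an empty network")
    path = Path(path)
    node_path = Path(node_path) if node_path is not None else path.with_suffix(".nodes.tsv")
    annotations = dict(annotations or {})
    lines = sorted(f"{e.mirna_id}\ttargets\t{e.gene_id}" for e in edges)
    path.write_text("\n".join(lines) + "\n")

    rows = []
    for m in edges.mirna_ids():
        rows.append({"node": m, "type": "miRNA", "term": ""})
    for g in edges.gene_ids():
        rows.append({"node": g, "type": "gene", "term": annotations.get(g, "")})
    nodes = pd.DataFrame(rows, columns=["node", "type", "term"])
    if highlight is not None:
        nodes["highlight"] = [
            r["type"] == "gene" and r["node"] in highlight for _, r in nodes.iterrows()
        ]
    nodes.to_csv(node_path, sep="\t", index=False)
    return path, node_path


def read_annotation_terms(path) -> dict[str, str]:
    """Read a two-column (gene, term) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (gene, term)")
    gene_col, term_col = df.columns[:2]
    return {
        str(g): ("" if pd.isna(t) else str(t))
        for g, t in zip(df[gene_col], df[term_col])
    }
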