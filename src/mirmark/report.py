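"""Coregulation analysis and annotated network export for validated edges."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .datatypes import EdgeSet
from .io import export_network

#: Gene-ontology terms treated as cancer-related when highlighting network
#: nodes (overridable).
DEFAULT_CANCER_TERMS = frozenset(
    {
        "apoptosis",
        "angiogenesis",
        "cell proliferation",
        "blood vessel development",
        "transcriptional regulation",
        "immune response",
    }
)


@dataclass(frozen=True)
class CoregulationRecord:
    """One gene targeted by several distinct miRNAs in the validated set."""

    gene_id: str
    n_mirnas: int
    mirna_ids: tuple[str, ...]
    annotation: str = ""


def _gene_to_mirnas(edges: EdgeSet) -> dict[str, set[str]]:
    mapping: dict[str, set[str]] = {}
    for e in edges:
        mapping.setdefault(e.gene_id, set()).add(e.mirna_id)
    return mapping


def coregulation_table(
    edges: EdgeSet,
    min_mirnas: int = 6,
    annotations: Optional[Mapping[str, str]] = None,
) -> list[CoregulationRecord]:
    """Genes regulated by strictly more than ``min_mirnas`` distinct miRNAs.

    Sorted by descending miRNA count, then gene id. ``min_mirnas=0`` lists
    every gene of the edge set.
    """
    annotations = dict(annotations or {})
    records = [
        CoregulationRecord(
            gene_id=g,
            n_mirnas=len(ms),
            mirna_ids=tuple(sorted(ms)),
            annotation=annotations.get(g, ""),
        )
        for g, ms in _gene_to_mirnas(edges).items()
        if len(ms) > min_mirnas
    ]
    return sorted(records, key=lambda r: (-r.n_mirnas, r.gene_id))


def coregulated_fraction(edges: EdgeSet) -> tuple[int, int]:
    """(#distinct target genes, #genes hit by >= 2 distinct miRNAs)."""
    mapping = _gene_to_mirnas(edges)
    return len(mapping), sum(1 for ms in mapping.values() if len(ms) >= 2)


def coregulation_frame(records: list[CoregulationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "annotation": r.annotation,
                "n_mirnas": r.n_mirnas,
                "mirna_ids": ",".join(r.mirna_ids),
            }
            for r in records
        ],
        columns=["gene_id", "annotation", "n_mirnas", "mirna_ids"],
    )


def build_annotated_network(
    edges: EdgeSet,
    path,
    annotations: Optional[Mapping[str, str]] = None,
    cancer_terms: frozenset[str] = DEFAULT_CANCER_TERMS,
    node_path=None,
):
    """Export the validated network with cancer-related genes highlighted.

    A gene node is highlighted when any of its annotation terms (comma or
    semicolon separated) matches ``cancer_terms`` case-insensitively; miRNA
    nodes are never highlighted. Delegates file writing to
    :func:`mirmark.io.export_network`.
    """
    annotations = dict(annotations or {})
    terms_lower = {t.lower() for t in cancer_terms}
    highlight = set()
    for gene, term in annotations.items():
        parts = [p.strip().lower() for p in str(term).replace(";", ",").split(",")]
        if any(p in terms_lower for p in parts):
            highlight.add(gene)
    return export_network(
        edges, path, annotations=annotations, highlight=highlight, node_path=node_path
    )
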