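"""Synthetic paired miRNA/mRNA cohorts with planted regulatory structure.

The generator emulates the data model the pipeline assumes: a set of marker
miRNAs whose mean expression shifts between cancer and normal samples, each
miRNA repressing a block of target genes through a negative linear slope, and
an edge database containing every planted edge plus spurious
predicted edges standing in for the false-positive load of sequence-based
target prediction. All randomness flows from ``CohortConfig.seed``; the same
config yields bit-identical output.

Default condition: 104 cancer / 17 normal samples (the imbalanced discovery
cohort design), 20 miRNAs with 10 targets each out of 200 genes, unit noise,
one decoy edge per true edge, a +4 log2 class shift (4 x noise_sd) on half
the miRNAs, and regulation slope -1.0 so that a planted marker edge carries
strong class signal on the gene side as well (separation 4/sqrt(2) sigma,
Bayes-optimal BA about 0.92), not only on the miRNA side.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    CANCER,
    MIRNA,
    MRNA,
    NORMAL,
    PREDICTED,
    VALIDATED,
    DatasetBundle,
    EdgeSet,
    ExpressionMatrix,
    SampleAnnotation,
    TargetEdge,
)
from .errors import ConfigError

_BASELINE_LO, _BASELINE_HI = 6.0, 10.0


@dataclass
class CohortConfig:
    """Generative parameters of one synthetic cohort.

    ``regulation_strength`` is the (negative) slope of each target gene on
    its miRNA, ``de_effect`` the log2 mean shift of marker miRNAs in cancer
    samples, ``fp_edge_rate`` the number of decoy edges added per true edge,
    and ``fraction_marker_mirnas`` the fraction of miRNAs given a class
    shift.
    """

    n_cancer: int = 104
    n_normal: int = 17
    n_mirna: int = 20
    n_gene: int = 200
    targets_per_mirna: int = 10
    regulation_strength: float = -1.0
    de_effect: float = 4.0
    noise_sd: float = 1.0
    fp_edge_rate: float = 1.0
    fraction_marker_mirnas: float = 0.5
    validated_edge_fraction: float = 0.2
    coregulation_k: int = 0  # extra gene wired to the first k miRNAs
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cancer", "n_normal", "n_mirna", "n_gene", "targets_per_mirna"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.regulation_strength >= 0:
            raise ConfigError("regulation_strength must be < 0 (repression)")
        if not 0 <= self.fp_edge_rate <= 1e9:
            raise ConfigError("fp_edge_rate must be >= 0")
        if not 0 < self.fraction_marker_mirnas <= 1:
            raise ConfigError("fraction_marker_mirnas must be in (0, 1]")
        if self.targets_per_mirna * self.n_mirna > self.n_gene:
            raise ConfigError(
                f"targets_per_mirna * n_mirna = {self.targets_per_mirna * self.n_mirna} "
                f"exceeds n_gene = {self.n_gene}"
            )
        if self.coregulation_k > self.n_mirna:
            raise ConfigError("coregulation_k cannot exceed n_mirna")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every synthetic cohort."""

    true_edges: list[tuple[str, str, float]]
    marker_mirnas: set[str]
    decoy_edges: set[tuple[str, str]] = field(default_factory=set)
    # frozen generative parameters so independent datasets follow the same law
    params: dict = field(default_factory=dict)

    @property
    def true_edge_keys(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _ in self.true_edges}

    def to_json(self, path) -> None:
        payload = {
            "true_edges": [list(e) for e in self.true_edges],
            "marker_mirnas": sorted(self.marker_mirnas),
            "decoy_edges": sorted(list(e) for e in self.decoy_edges),
            "params": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.params.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        params = {
            k: (np.asarray(v) if isinstance(v, list) else v) for k, v in d["params"].items()
        }
        return cls(
            true_edges=[tuple(e) for e in d["true_edges"]],
            marker_mirnas=set(d["marker_mirnas"]),
            decoy_edges={tuple(e) for e in d["decoy_edges"]},
            params=params,
        )


def _mirna_id(i: int) -> str:
    return f"miR-{i + 1:04d}"


def _gene_id(j: int) -> str:
    return f"GENE{j + 1:04d}"


def _draw_samples(
    cfg: CohortConfig,
    rng: np.random.Generator,
    n_cancer: int,
    n_normal: int,
    prefix: str,
    params: dict,
) -> tuple[np.ndarray, np.ndarray, SampleAnnotation]:
    """Draw one cohort from the frozen generative law in ``params``."""
    n = n_cancer + n_normal
    is_cancer = np.zeros(n, dtype=bool)
    is_cancer[:n_cancer] = True
    sample_ids = [f"{prefix}{i + 1:04d}" for i in range(n)]
    labels = pd.Series(np.where(is_cancer, CANCER, NORMAL), index=sample_ids)

    baseline = np.asarray(params["mirna_baseline"], dtype=float)
    is_marker = np.asarray(params["is_marker"], dtype=bool)
    M = (
        baseline[:, None]
        + cfg.de_effect * (is_marker[:, None] & is_cancer[None, :])
        + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_mirna, n))
    )

    intercept = np.asarray(params["gene_intercept"], dtype=float)
    G = intercept[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_gene, n))
    gene_mirna = np.asarray(params["gene_mirna"], dtype=int)  # -1: untargeted
    targeted = gene_mirna >= 0
    G[targeted] += cfg.regulation_strength * M[gene_mirna[targeted]]
    coreg = params.get("coreg_gene", -1)
    if coreg >= 0:
        k = int(params["coreg_k"])
        G[coreg] += (cfg.regulation_strength / k) * M[:k].sum(axis=0)
    annotation = SampleAnnotation(labels=labels)
    return M, G, annotation


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Generate the paired discovery cohort and its ground truth."""
    rng = np.random.default_rng(config.seed)
    n_marker = max(1, int(round(config.fraction_marker_mirnas * config.n_mirna)))
    is_marker = np.zeros(config.n_mirna, dtype=bool)
    is_marker[:n_marker] = True

    gene_mirna = np.full(config.n_gene, -1, dtype=int)
    for m in range(config.n_mirna):
        lo = m * config.targets_per_mirna
        gene_mirna[lo : lo + config.targets_per_mirna] = m

    coreg_gene = -1
    if config.coregulation_k > 0:
        free = np.flatnonzero(gene_mirna < 0)
        if free.size == 0:
            raise ConfigError("coregulation preset needs at least one untargeted gene")
        coreg_gene = int(free[-1])

    params = {
        "mirna_baseline": rng.uniform(_BASELINE_LO, _BASELINE_HI, size=config.n_mirna),
        "gene_intercept": rng.uniform(_BASELINE_LO, _BASELINE_HI, size=config.n_gene),
        "is_marker": is_marker,
        "gene_mirna": gene_mirna,
        "coreg_gene": coreg_gene,
        "coreg_k": config.coregulation_k,
    }
    M, G, annotation = _draw_samples(
        config, rng, config.n_cancer, config.n_normal, "S", params
    )
    annotation.dataset_id = "synthetic_discovery"

    mirna_ids = [_mirna_id(i) for i in range(config.n_mirna)]
    gene_ids = [_gene_id(j) for j in range(config.n_gene)]
    mirna = ExpressionMatrix(
        pd.DataFrame(M, index=mirna_ids, columns=annotation.sample_ids),
        feature_kind=MIRNA,
        dataset_id="synthetic_discovery",
    )
    mrna = ExpressionMatrix(
        pd.DataFrame(G, index=gene_ids, columns=annotation.sample_ids),
        feature_kind=MRNA,
        dataset_id="synthetic_discovery",
    )

    true_edges = [
        (mirna_ids[gene_mirna[j]], gene_ids[j], config.regulation_strength)
        for j in range(config.n_gene)
        if gene_mirna[j] >= 0
    ]
    if coreg_gene >= 0:
        slope = config.regulation_strength / config.coregulation_k
        true_edges += [
            (mirna_ids[i], gene_ids[coreg_gene], slope) for i in range(config.coregulation_k)
        ]
    truth = SyntheticTruth(
        true_edges=true_edges,
        marker_mirnas={mirna_ids[i] for i in range(config.n_mirna) if is_marker[i]},
        params=params,
    )
    return mirna, mrna, annotation, truth


def generate_prediction_db(truth: SyntheticTruth, config: CohortConfig) -> EdgeSet:
    """True edges plus decoy predicted edges at ``fp_edge_rate`` per true edge.

    Emulates a target-prediction database: every planted edge is present
    (a configurable fraction flagged "validated"), and decoys connect random
    miRNA/gene pairs with no planted relationship. Fills
    ``truth.decoy_edges`` as a side effect.
    """
    rng = np.random.default_rng((config.seed, 9151))
    true_keys = truth.true_edge_keys
    n_true = len(truth.true_edges)
    n_decoy = int(round(config.fp_edge_rate * n_true))

    mirna_ids = [_mirna_id(i) for i in range(config.n_mirna)]
    gene_ids = [_gene_id(j) for j in range(config.n_gene)]
    decoys: set[tuple[str, str]] = set()
    guard = 0
    while len(decoys) < n_decoy:
        m = mirna_ids[int(rng.integers(config.n_mirna))]
        g = gene_ids[int(rng.integers(config.n_gene))]
        if (m, g) not in true_keys:
            decoys.add((m, g))
        guard += 1
        if guard > 1000 * (n_decoy + 1):
            raise ConfigError("could not place decoy edges; feature universe too small")
    truth.decoy_edges = decoys

    edges = EdgeSet(provenance="synthetic prediction database")
    for i, (m, g, _slope) in enumerate(sorted(truth.true_edges)):
        origin = VALIDATED if rng.random() < config.validated_edge_fraction else PREDICTED
        edges.add(TargetEdge(m, g, origin))
    for m, g in sorted(decoys):
        edges.add(TargetEdge(m, g, PREDICTED))
    return edges


def generate_independent_dataset(
    truth: SyntheticTruth,
    config: CohortConfig,
    mrna_only: bool = False,
    batch_shift: float = 0.0,
    n_cancer: Optional[int] = None,
    n_normal: Optional[int] = None,
    seed: Optional[int] = None,
    dataset_id: str = "synthetic_independent",
) -> DatasetBundle:
    """Draw a fresh cohort from the same generative law.

    ``batch_shift`` is added to every mRNA value to emulate a platform/batch
    offset; with ``mrna_only`` the bundle carries no miRNA matrix (the
    situation miRNA-activity estimation exists for).
    """
    rng = np.random.default_rng((config.seed, 7307) if seed is None else seed)
    n_cancer = config.n_cancer if n_cancer is None else n_cancer
    n_normal = config.n_normal if n_normal is None else n_normal
    M, G, annotation = _draw_samples(config, rng, n_cancer, n_normal, "V", truth.params)
    annotation.dataset_id = dataset_id
    G = G + batch_shift
    mirna_ids = [_mirna_id(i) for i in range(config.n_mirna)]
    gene_ids = [_gene_id(j) for j in range(config.n_gene)]
    mrna = ExpressionMatrix(
        pd.DataFrame(G, index=gene_ids, columns=annotation.sample_ids),
        feature_kind=MRNA,
        dataset_id=dataset_id,
    )
    mirna = None
    if not mrna_only:
        mirna = ExpressionMatrix(
            pd.DataFrame(M, index=mirna_ids, columns=annotation.sample_ids),
            feature_kind=MIRNA,
            dataset_id=dataset_id,
        )
    return DatasetBundle(mrna=mrna, annotation=annotation, mirna=mirna, dataset_id=dataset_id)
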