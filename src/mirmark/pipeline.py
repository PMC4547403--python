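"""End-to-end orchestration: discovery -> filtering -> marker scoring ->
activity models -> multi-dataset validation -> coregulation report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .activity import MEAN_OF_PREDICTIONS, ActivityModel, fit_activity_model
from .datatypes import DatasetBundle, EdgeSet
from .errors import ConfigError
from .markers import (
    DiscoveryResult,
    SelectionThresholds,
    SVMConfig,
    discover_markers,
)
from .network import filter_edges
from .report import coregulated_fraction, coregulation_table
from .validation import (
    MultiMarker,
    ValidationThresholds,
    cross_cohort_evaluation,
    infer_regulation_direction,
    validate_multimarkers,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    filtered_edges: EdgeSet
    discovery: DiscoveryResult
    candidates: list[MultiMarker]
    validated: list[MultiMarker]
    activity_models: dict[str, ActivityModel]
    coregulation: list = field(default_factory=list)
    cross_cohort: Optional[pd.DataFrame] = None

    @property
    def validated_edge_set(self) -> EdgeSet:
        out = EdgeSet(provenance="validated multi-markers")
        for mm in self.validated:
            edge = self.filtered_edges.get(mm.mirna_id, mm.gene_id)
            if edge is not None:
                out.add(edge)
        return out


def build_activity_models(
    filtered: EdgeSet,
    discovery_bundle: DatasetBundle,
    mirna_ids: Sequence[str],
    combination: str = MEAN_OF_PREDICTIONS,
) -> dict[str, ActivityModel]:
    """One activity model per miRNA from its filtered targets on the
    discovery cohort."""
    models: dict[str, ActivityModel] = {}
    if discovery_bundle.mirna is None:
        raise ConfigError("discovery cohort must carry miRNA profiles")
    for mid in mirna_ids:
        targets = {
            e.gene_id: discovery_bundle.mrna.feature(e.gene_id)
            for e in filtered
            if e.mirna_id == mid and e.gene_id in discovery_bundle.mrna.values.index
        }
        if not targets or mid not in discovery_bundle.mirna.values.index:
            continue
        models[mid] = fit_activity_model(
            mid, discovery_bundle.mirna.feature(mid), targets, combination
        )
    return models


def run_pipeline(
    discovery: DatasetBundle,
    edge_db: EdgeSet,
    dataset1: DatasetBundle,
    mrna_only_datasets: Sequence[DatasetBundle],
    other_datasets: Sequence[DatasetBundle] = (),
    corr_max: float = -0.3,
    p_max: float = 0.05,
    selection: SelectionThresholds = SelectionThresholds(),
    validation: ValidationThresholds = ValidationThresholds(),
    n_perm: int = 25,
    seed: int = 0,
    svm_config: SVMConfig = SVMConfig(),
    combination: str = MEAN_OF_PREDICTIONS,
    min_coreg_mirnas: int = 6,
) -> PipelineResult:
    """Run the full multi-marker discovery and validation pipeline."""
    if discovery.mirna is None:
        raise ConfigError("discovery cohort must carry miRNA profiles")
    filtered = filter_edges(edge_db, discovery.mirna, discovery.mrna, corr_max, p_max)
    disc = discover_markers(
        discovery.mirna,
        discovery.mrna,
        discovery.annotation,
        filtered,
        thresholds=selection,
        n_perm=n_perm,
        seed=seed,
        svm_config=svm_config,
    )
    y = discovery.annotation.y(discovery.mirna.sample_ids)
    candidates = [
        MultiMarker(
            mirna_id=m,
            gene_id=g,
            mirna_regulation=infer_regulation_direction(discovery.mirna.feature(m), y),
        )
        for m, g in disc.selected_pairs
    ]
    models = build_activity_models(
        filtered, discovery, sorted({mm.mirna_id for mm in candidates}), combination
    )
    validated = [
        mm
        for mm in validate_multimarkers(
            candidates, dataset1, mrna_only_datasets, validation, models, svm_config
        )
        if mm.status == "validated"
    ]
    result = PipelineResult(
        filtered_edges=filtered,
        discovery=disc,
        candidates=candidates,
        validated=validated,
        activity_models=models,
    )
    result.coregulation = coregulation_table(result.validated_edge_set, min_coreg_mirnas)
    if other_datasets and validated:
        result.cross_cohort = cross_cohort_evaluation(
            validated, other_datasets, models, svm_config
        )
    n_genes, n_multi = (
        coregulated_fraction(result.validated_edge_set) if validated else (0, 0)
    )
    logger.info(
        "pipeline: %d filtered edges, %d candidate pairs, %d validated "
        "(%d genes, %d coregulated)",
        len(filtered),
        len(candidates),
        len(validated),
        n_genes,
        n_multi,
    )
    return result
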