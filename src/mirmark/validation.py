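"""Multi-dataset validation of multi-marker candidates.

A candidate (miRNA, gene) pair from discovery is *validated* when

a. the pair's expression is negatively correlated in the paired validation
   cohort (dataset1),
b. both endpoints exceed BA > 0.7 there (the miRNA observed directly), and
c. in at least one mRNA-only cohort both the gene and the miRNA's
   *estimated* activity exceed BA > 0.7,

all comparisons strict. Datasets missing a marker's features count as not
passed for validation but are reported as unavailable rather than failed.
Validated markers can finally be scored, without thresholding, on cohorts
of other cancer types to probe disease specificity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .activity import ActivityModel, estimated_marker_performance
from .datatypes import DatasetBundle, ExpressionMatrix, SampleAnnotation
from .errors import ConfigError, DegenerateInputError
from .markers import (
    KIND_GENE,
    KIND_MIRNA,
    ClassWeights,
    MarkerPerformance,
    SVMConfig,
    compute_class_weights,
    score_single_marker,
)
from .network import correlate_pair

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"

CANDIDATE = "candidate"
VALIDATED_STATUS = "validated"
REJECTED = "rejected"


@dataclass(frozen=True)
class ValidationThresholds:
    """Strict BA cutoffs for the validation stage."""

    ba_min_dataset1: float = 0.7
    ba_min_dataset23: float = 0.7
    require_negative_corr_d1: bool = True
    min_passing_mrna_only_datasets: int = 1

    def __post_init__(self) -> None:
        for v in (self.ba_min_dataset1, self.ba_min_dataset23):
            if not 0 < v < 1:
                raise ConfigError("validation BA thresholds must lie in (0, 1)")
        if self.min_passing_mrna_only_datasets < 0:
            raise ConfigError("min_passing_mrna_only_datasets must be >= 0")


@dataclass
class MultiMarker:
    """One miRNA-target pair tracked through discovery and validation."""

    mirna_id: str
    gene_id: str
    mirna_regulation: str = UP
    performances: dict[str, list[MarkerPerformance]] = field(default_factory=dict)
    status: str = CANDIDATE
    corr_d1: Optional[float] = None

    def record(self, dataset_id: str, perf: MarkerPerformance) -> None:
        self.performances.setdefault(dataset_id, []).append(perf)


def infer_regulation_direction(feature_expr, labels: SampleAnnotation | np.ndarray) -> str:
    """"up" when the cancer-class mean exceeds the normal-class mean."""
    x = np.asarray(feature_expr, dtype=float)
    y = labels.y() if isinstance(labels, SampleAnnotation) else np.asarray(labels)
    if x.shape != y.shape:
        raise ConfigError("expression and labels must share length")
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateInputError("both classes required to infer a regulation direction")
    diff = x[y == 1].mean() - x[y == 0].mean()
    if diff == 0:
        warnings.warn("exact class-mean tie; reporting 'up'", RuntimeWarning)
        return UP
    return UP if diff > 0 else DOWN


def _score_if_present(
    matrix: Optional[ExpressionMatrix],
    feature_id: str,
    bundle: DatasetBundle,
    weights: ClassWeights,
    svm_config: SVMConfig,
    kind: str,
) -> Optional[MarkerPerformance]:
    if matrix is None or feature_id not in matrix.values.index:
        return None
    return score_single_marker(
        matrix.feature(feature_id),
        bundle.annotation.y(matrix.sample_ids),
        weights,
        svm_config,
        kind,
        feature_id,
        bundle.dataset_id,
    )


def validate_multimarkers(
    candidates: Sequence[MultiMarker],
    dataset1: DatasetBundle,
    mrna_only_datasets: Sequence[DatasetBundle],
    thresholds: ValidationThresholds = ValidationThresholds(),
    activity_models: Optional[Mapping[str, ActivityModel]] = None,
    svm_config: SVMConfig = SVMConfig(),
) -> list[MultiMarker]:
    """Apply the validation rule set to each candidate; returns candidates
    with status, correlation and per-dataset performances filled in.

    Class weights are recomputed per dataset from its own class counts.
    """
    if dataset1.mirna is None:
        raise ConfigError("dataset1 must carry both miRNA and mRNA profiles")
    activity_models = dict(activity_models or {})
    w1 = compute_class_weights(dataset1.annotation.n_cancer, dataset1.annotation.n_normal)

    # candidates share endpoints; score each (dataset, feature) only once
    score_cache: dict[tuple, Optional[MarkerPerformance]] = {}

    def cached_score(matrix, feature_id, bundle, weights, kind):
        key = (bundle.dataset_id, kind, feature_id)
        if key not in score_cache:
            score_cache[key] = _score_if_present(
                matrix, feature_id, bundle, weights, svm_config, kind
            )
        return score_cache[key]

    def cached_activity(model, ds, wds):
        key = (ds.dataset_id, "activity", model.mirna_id)
        if key not in score_cache:
            try:
                score_cache[key] = estimated_marker_performance(
                    model, ds.mrna, ds.annotation, wds, svm_config
                )
            except DegenerateInputError:
                score_cache[key] = None
        return score_cache[key]

    for cand in candidates:
        ok = True
        # (a) negative correlation in dataset1 (pooled samples)
        mi_present = cand.mirna_id in dataset1.mirna.values.index
        g_present = cand.gene_id in dataset1.mrna.values.index
        if mi_present and g_present:
            r, _p = correlate_pair(
                dataset1.mirna.feature(cand.mirna_id), dataset1.mrna.feature(cand.gene_id)
            )
            cand.corr_d1 = r
            if thresholds.require_negative_corr_d1 and not r < 0:
                ok = False
        else:
            logger.info(
                "marker (%s, %s): endpoint missing from dataset1", cand.mirna_id, cand.gene_id
            )
            ok = False

        # (b) both endpoints' observed BAs in dataset1
        pm = cached_score(dataset1.mirna, cand.mirna_id, dataset1, w1, KIND_MIRNA)
        pg = cached_score(dataset1.mrna, cand.gene_id, dataset1, w1, KIND_GENE)
        for perf in (pm, pg):
            if perf is not None:
                cand.record(dataset1.dataset_id, perf)
        if pm is None or pg is None:
            ok = False
        elif not (pm.ba > thresholds.ba_min_dataset1 and pg.ba > thresholds.ba_min_dataset1):
            ok = False

        # (c) estimated activity + gene BA in the mRNA-only cohorts
        n_passing = 0
        model = activity_models.get(cand.mirna_id)
        for ds in mrna_only_datasets:
            wds = compute_class_weights(ds.annotation.n_cancer, ds.annotation.n_normal)
            pg2 = cached_score(ds.mrna, cand.gene_id, ds, wds, KIND_GENE)
            pa = None
            if model is not None:
                pa = cached_activity(model, ds, wds)
                if pa is None:
                    logger.info(
                        "marker (%s, %s): activity not estimable on %s",
                        cand.mirna_id,
                        cand.gene_id,
                        ds.dataset_id,
                    )
            for perf in (pg2, pa):
                if perf is not None:
                    cand.record(ds.dataset_id, perf)
            if (
                pg2 is not None
                and pa is not None
                and pg2.ba > thresholds.ba_min_dataset23
                and pa.ba > thresholds.ba_min_dataset23
            ):
                n_passing += 1
        if n_passing < thresholds.min_passing_mrna_only_datasets:
            ok = False
        cand.status = VALIDATED_STATUS if ok else REJECTED
    return list(candidates)


def cross_cohort_evaluation(
    validated: Sequence[MultiMarker],
    other_datasets: Sequence[DatasetBundle],
    activity_models: Optional[Mapping[str, ActivityModel]] = None,
    svm_config: SVMConfig = SVMConfig(),
) -> pd.DataFrame:
    """BA of each validated marker on each extra cohort; reporting only.

    Rows are markers ("miRNA:gene"); columns are "<dataset>:gene" and
    "<dataset>:activity". Cells are NaN when the dataset lacks the
    features needed (marked unavailable, the run continues).
    """
    if not validated:
        raise DegenerateInputError("no validated markers to evaluate")
    activity_models = dict(activity_models or {})
    rows = {}
    for cand in validated:
        key = f"{cand.mirna_id}:{cand.gene_id}"
        row = {}
        for ds in other_datasets:
            wds = compute_class_weights(ds.annotation.n_cancer, ds.annotation.n_normal)
            pg = _score_if_present(ds.mrna, cand.gene_id, ds, wds, svm_config, KIND_GENE)
            row[f"{ds.dataset_id}:gene"] = pg.ba if pg is not None else np.nan
            ba = np.nan
            model = activity_models.get(cand.mirna_id)
            if model is not None:
                try:
                    ba = estimated_marker_performance(
                        model, ds.mrna, ds.annotation, wds, svm_config
                    ).ba
                except DegenerateInputError:
                    pass
            row[f"{ds.dataset_id}:activity"] = ba
        rows[key] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()
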