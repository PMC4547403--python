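"""Class-weighted SVM marker scoring under leave-one-out cross-validation.

Every candidate feature (miRNA or target gene) is scored as a single-feature
classifier of cancer vs normal. Because the discovery cohort is heavily
imbalanced (e.g. 104 cancer vs 17 normal), the SVM misclassification
penalty is weighted per class — alpha_cancer = 1, alpha_normal =
n_cancer/n_normal — so the degenerate all-cancer solution is no longer
optimal. Performance is summarized by balanced accuracy (BA), the
Mann-Whitney AUC of the pooled LOOCV decision values, and a permutation
p-value against an empirical null distribution of BAs, Bonferroni-adjusted
within each feature kind.

A (miRNA, gene) edge becomes a *multi-marker* when the edge survived
negative-correlation filtering and both endpoints individually pass
BA > 0.8, AUC > 0.8 and adjusted p < 0.05 (all strict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import rankdata
from sklearn.svm import SVC

from . import _svm1d
from .datatypes import EdgeSet, ExpressionMatrix, SampleAnnotation
from .errors import ConfigError, DegenerateFoldError, DegenerateInputError

logger = logging.getLogger(__name__)

KIND_MIRNA = "miRNA"
KIND_GENE = "gene"
KIND_PAIR = "pair"


@dataclass(frozen=True)
class ClassWeights:
    """Per-class SVM penalty multipliers (cancer is the positive class)."""

    w_cancer: float = 1.0
    w_normal: float = 1.0

    def __post_init__(self) -> None:
        if self.w_cancer <= 0 or self.w_normal <= 0:
            raise ConfigError("class weights must be positive")


@dataclass(frozen=True)
class SVMConfig:
    """SVM hyperparameters; the pipeline default is a linear kernel, C=1."""

    kernel: str = "linear"
    C: float = 1.0


@dataclass
class MarkerPerformance:
    """LOOCV performance of one marker on one dataset."""

    feature_ids: tuple[str, ...]
    kind: str  # miRNA | gene | pair
    ba: float
    auc: float
    perm_p: Optional[float] = None
    adj_p: Optional[float] = None
    dataset_id: str = ""


@dataclass(frozen=True)
class SelectionThresholds:
    """Strict cutoffs a single marker must exceed to be selected."""

    ba_min: float = 0.8
    auc_min: float = 0.8
    adj_p_max: float = 0.05

    def __post_init__(self) -> None:
        for v in (self.ba_min, self.auc_min, self.adj_p_max):
            if not 0 < v <= 1:
                raise ConfigError("selection thresholds must lie in (0, 1]")

    def passes(self, perf: MarkerPerformance) -> bool:
        if perf.adj_p is None:
            raise ConfigError("marker has no adjusted p-value; run permutation testing")
        return perf.ba > self.ba_min and perf.auc > self.auc_min and perf.adj_p < self.adj_p_max


def compute_class_weights(n_cancer: int, n_normal: int) -> ClassWeights:
    """alpha_cancer = 1, alpha_normal = n_cancer / n_normal (full precision).

    With 104 cancer and 17 normal samples this gives alpha_normal =
    6.117647..., equalizing the total penalty mass of the two classes.
    """
    if n_cancer < 1 or n_normal < 1:
        raise ConfigError("both class counts must be >= 1")
    return ClassWeights(w_cancer=1.0, w_normal=n_cancer / n_normal)


def balanced_accuracy(tp: int, fn: int, tn: int, fp: int) -> float:
    """(sensitivity + specificity) / 2 from a confusion matrix."""
    if min(tp, fn, tn, fp) < 0:
        raise ConfigError("confusion counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise DegenerateInputError("balanced accuracy undefined with an empty class")
    return 0.5 * (tp / (tp + fn) + tn / (tn + fp))


def _as_feature_array(features) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ConfigError("features must be a vector or a (k, n) matrix")
    return X


def _as_y(labels, n: int) -> np.ndarray:
    if isinstance(labels, SampleAnnotation):
        y = labels.y()
    else:
        y = np.asarray(labels, dtype=np.int64)
    if y.shape != (n,):
        raise ConfigError(f"labels length {y.shape} does not match {n} samples")
    if not set(np.unique(y)) <= {0, 1}:
        raise ConfigError("labels must be 0 (normal) / 1 (cancer)")
    return y


def loocv_scores(
    features,
    labels,
    weights: ClassWeights,
    svm_config: SVMConfig = SVMConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """LOOCV predicted labels and signed decision values (positive = cancer).

    For each sample the SVM is trained on the remaining n-1 samples with the
    given class weights; features are z-scored inside each training fold
    only. A decision value of exactly 0 is classified as cancer. Single-
    feature linear problems use an exact closed-form solver; other shapes
    fall back to sklearn's SVC.
    """
    X = _as_feature_array(features)
    k, n = X.shape
    if n < 4:
        raise DegenerateInputError(f"LOOCV needs >= 4 samples, got {n}")
    y = _as_y(labels, n)
    if y.sum() == 0 or y.sum() == n:
        raise DegenerateInputError("both classes must be present")
    counts = np.array([n - y.sum(), y.sum()])
    if counts.min() == 1:
        cls = int(np.argmin(counts))
        i = int(np.flatnonzero(y == cls)[0])
        raise DegenerateFoldError(
            f"training fold holding out sample {i} contains a single class "
            f"(only one {'cancer' if cls else 'normal'} sample overall)"
        )

    if k == 1 and svm_config.kernel == "linear":
        dec = _svm1d.loocv_decisions_1d(
            np.ascontiguousarray(X[0]),
            y,
            svm_config.C * weights.w_cancer,
            svm_config.C * weights.w_normal,
        )
    else:
        dec = np.empty(n)
        clf = SVC(
            kernel=svm_config.kernel,
            C=svm_config.C,
            class_weight={0: weights.w_normal, 1: weights.w_cancer},
        )
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            Xtr, ytr = X[:, mask], y[mask]
            mu = Xtr.mean(axis=1)
            sd = Xtr.std(axis=1)
            sd[sd < 1e-12] = 1.0
            clf.fit(((Xtr - mu[:, None]) / sd[:, None]).T, ytr)
            dec[i] = clf.decision_function(((X[:, i] - mu) / sd)[None, :])[0]
            mask[i] = True
    pred = (dec >= 0).astype(np.int64)
    return pred, dec


def loocv_ba(pred: np.ndarray, y: np.ndarray) -> float:
    """Balanced accuracy of LOOCV predictions."""
    tp = int(((pred == 1) & (y == 1)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    return balanced_accuracy(tp, fn, tn, fp)


def auc_from_scores(decision_values, labels) -> float:
    """Mann-Whitney AUC: P(score_cancer > score_normal), ties counted 1/2."""
    s = np.asarray(decision_values, dtype=float)
    y = _as_y(labels, s.size)
    n1 = int(y.sum())
    n0 = s.size - n1
    if n1 == 0 or n0 == 0:
        raise DegenerateInputError("AUC requires both classes")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def permutation_pvalue(
    features,
    labels,
    weights: ClassWeights,
    svm_config: SVMConfig = SVMConfig(),
    n_perm: int = 999,
    seed: int = 0,
    null_pool: Optional[np.ndarray] = None,
) -> tuple[float, np.ndarray]:
    """Permutation p-value of the LOOCV BA against an empirical null.

    Labels are permuted ``n_perm`` times and the full LOOCV BA recomputed
    per permutation (the SVM is refitted; decision values are not reused).
    p = (b + 1) / (n_perm + 1) with b = #{null BA >= observed BA}. When a
    shared ``null_pool`` of BAs is supplied, p is computed against it
    instead of refitting.
    """
    if n_perm < 1 and null_pool is None:
        raise ConfigError("n_perm must be >= 1")
    X = _as_feature_array(features)
    y = _as_y(labels, X.shape[1])
    pred, _ = loocv_scores(X, y, weights, svm_config)
    observed = loocv_ba(pred, y)
    if null_pool is not None:
        null = np.asarray(null_pool, dtype=float)
    else:
        null = null_ba_distribution(X, y, weights, svm_config, n_perm, seed)
    b = int((null >= observed - 1e-12).sum())
    return (b + 1) / (null.size + 1), null


def null_ba_distribution(
    features,
    y: np.ndarray,
    weights: ClassWeights,
    svm_config: SVMConfig,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """LOOCV BAs under ``n_perm`` seeded label permutations."""
    X = _as_feature_array(features)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
    if X.shape[0] == 1 and svm_config.kernel == "linear":
        return _svm1d.perm_loocv_bas_1d(
            np.ascontiguousarray(X[0]),
            perms,
            svm_config.C * weights.w_cancer,
            svm_config.C * weights.w_normal,
        )
    bas = np.empty(n_perm)
    for p in range(n_perm):
        pred, _ = loocv_scores(X, perms[p], weights, svm_config)
        bas[p] = loocv_ba(pred, perms[p])
    return bas


@dataclass
class DiscoveryResult:
    """Single-marker performances plus the selected multi-marker pairs."""

    performances: list[MarkerPerformance]
    selected_pairs: list[tuple[str, str]]
    pair_performances: list[MarkerPerformance] = field(default_factory=list)

    def performance_of(self, feature_id: str) -> Optional[MarkerPerformance]:
        for p in self.performances:
            if p.feature_ids == (feature_id,):
                return p
        return None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "feature": "|".join(p.feature_ids),
                    "kind": p.kind,
                    "ba": p.ba,
                    "auc": p.auc,
                    "perm_p": p.perm_p,
                    "adj_p": p.adj_p,
                    "dataset_id": p.dataset_id,
                }
                for p in self.performances + self.pair_performances
            ]
        )


def score_single_marker(
    vector: np.ndarray,
    y: np.ndarray,
    weights: ClassWeights,
    svm_config: SVMConfig,
    kind: str,
    feature_id: str,
    dataset_id: str = "",
) -> MarkerPerformance:
    """BA and AUC of one feature under weighted-SVM LOOCV (no permutation)."""
    pred, dec = loocv_scores(vector, y, weights, svm_config)
    return MarkerPerformance(
        feature_ids=(feature_id,),
        kind=kind,
        ba=loocv_ba(pred, y),
        auc=auc_from_scores(dec, y),
        dataset_id=dataset_id,
    )


def discover_markers(
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    labels: SampleAnnotation,
    edges: EdgeSet,
    thresholds: SelectionThresholds = SelectionThresholds(),
    n_perm: int = 25,
    seed: int = 0,
    weights: Optional[ClassWeights] = None,
    svm_config: SVMConfig = SVMConfig(),
    null_mode: str = "pooled",
    pair_mode: str = "endpoints",
) -> DiscoveryResult:
    """Score every miRNA and gene of the edge set; select multi-marker pairs.

    ``n_perm`` is the permutation budget per feature. With
    ``null_mode="pooled"`` (default) each feature contributes ``n_perm``
    label permutations to one shared empirical null distribution of BAs per
    feature kind, so the pool holds m * n_perm BAs and the smallest
    achievable Bonferroni-adjusted p is about 1/n_perm regardless of how
    many features are tested; ``"per_marker"`` tests each feature against
    its own ``n_perm``-permutation null (which needs n_perm > m/alpha to
    clear a Bonferroni cutoff). Bonferroni adjustment multiplies each p by
    the number of features tested of the same kind. With
    ``pair_mode="joint"`` each surviving edge is additionally scored as one
    2-feature SVM and the pair's own joint performance decides selection.
    """
    if null_mode not in ("pooled", "per_marker"):
        raise ConfigError(f"unknown null_mode {null_mode!r}")
    if pair_mode not in ("endpoints", "joint"):
        raise ConfigError(f"unknown pair_mode {pair_mode!r}")
    if len(edges) == 0:
        logger.warning("empty edge set: nothing to score")
        return DiscoveryResult(performances=[], selected_pairs=[])
    sample_ids = mirna.sample_ids
    if mrna.sample_ids != sample_ids:
        raise ConfigError("miRNA and mRNA matrices must share sample order")
    y = labels.y(sample_ids)
    if weights is None:
        weights = compute_class_weights(int(y.sum()), int(y.size - y.sum()))

    kinds = {
        KIND_MIRNA: [m for m in edges.mirna_ids() if m in mirna.values.index],
        KIND_GENE: [g for g in edges.gene_ids() if g in mrna.values.index],
    }
    n_missing = (len(edges.mirna_ids()) - len(kinds[KIND_MIRNA])) + (
        len(edges.gene_ids()) - len(kinds[KIND_GENE])
    )
    if n_missing:
        logger.info("skipping %d edge endpoints absent from the matrices", n_missing)

    performances: list[MarkerPerformance] = []
    perf_by_id: dict[str, MarkerPerformance] = {}
    rng = np.random.default_rng(seed)
    for kind, ids in kinds.items():
        matrix = mirna if kind == KIND_MIRNA else mrna
        scored = [
            score_single_marker(
                matrix.feature(fid), y, weights, svm_config, kind, fid, labels.dataset_id
            )
            for fid in ids
        ]
        m = len(ids)
        if m == 0:
            continue
        if null_mode == "pooled":
            pool = np.concatenate(
                [
                    null_ba_distribution(
                        matrix.feature(fid), y, weights, svm_config, n_perm,
                        int(rng.integers(2**31)),
                    )
                    for fid in ids
                ]
            )
            for perf, fid in zip(scored, ids):
                p, _ = permutation_pvalue(
                    matrix.feature(fid), y, weights, svm_config, null_pool=pool
                )
                perf.perm_p = p
        else:
            for perf, fid in zip(scored, ids):
                p, _ = permutation_pvalue(
                    matrix.feature(fid), y, weights, svm_config, n_perm,
                    int(rng.integers(2**31)),
                )
                perf.perm_p = p
        for perf in scored:
            perf.adj_p = min(1.0, m * perf.perm_p)
            perf_by_id[perf.feature_ids[0]] = perf
        performances.extend(scored)

    selected: list[tuple[str, str]] = []
    pair_perfs: list[MarkerPerformance] = []
    for edge in edges:
        pm = perf_by_id.get(edge.mirna_id)
        pg = perf_by_id.get(edge.gene_id)
        if pm is None or pg is None:
            continue
        if pair_mode == "endpoints":
            if thresholds.passes(pm) and thresholds.passes(pg):
                selected.append(edge.key)
        else:
            X = np.vstack([mirna.feature(edge.mirna_id), mrna.feature(edge.gene_id)])
            pred, dec = loocv_scores(X, y, weights, svm_config)
            joint = MarkerPerformance(
                feature_ids=edge.key,
                kind=KIND_PAIR,
                ba=loocv_ba(pred, y),
                auc=auc_from_scores(dec, y),
                dataset_id=labels.dataset_id,
            )
            p, _ = permutation_pvalue(
                X, y, weights, svm_config, n_perm, int(rng.integers(2**31))
            )
            joint.perm_p = p
            joint.adj_p = min(1.0, len(edges) * p)
            pair_perfs.append(joint)
            if thresholds.passes(joint):
                selected.append(edge.key)
    return DiscoveryResult(
        performances=performances, selected_pairs=selected, pair_performances=pair_perfs
    )
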