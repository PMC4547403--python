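"""miRNA activity estimation from target-gene expression.

Validation cohorts often profile only mRNA. A miRNA's expression can still
be estimated there: on a paired training cohort each filtered target gene
yields a simple linear regression of the miRNA on that gene; on an
mRNA-only dataset the miRNA's activity is the average of the per-target
predictions over whichever target genes the platform carries (robust to
gene dropout). A joint multivariate fit on all targets is available behind
a flag. The estimated activity vector is then scored as a single marker
with the same weighted-SVM LOOCV machinery used for observed features.

The baseline this scheme is compared against is the older convention of
taking the arithmetic mean of the target genes' own balanced accuracies as
the miRNA's activity performance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import ExpressionMatrix, SampleAnnotation
from .errors import ConfigError, DegenerateInputError
from .markers import (
    KIND_MIRNA,
    ClassWeights,
    MarkerPerformance,
    SVMConfig,
    auc_from_scores,
    loocv_ba,
    loocv_scores,
)

logger = logging.getLogger(__name__)

MEAN_OF_PREDICTIONS = "mean_of_predictions"
MULTIVARIATE = "multivariate"
_COMBINATIONS = (MEAN_OF_PREDICTIONS, MULTIVARIATE)


@dataclass(frozen=True)
class ActivityComponent:
    gene_id: str
    intercept: float
    slope: float
    train_corr: float


@dataclass
class ActivityModel:
    """Per-miRNA set of per-target regressions (miRNA regressed ON targets)."""

    mirna_id: str
    components: list[ActivityComponent]
    combination: str = MEAN_OF_PREDICTIONS

    def __post_init__(self) -> None:
        if not self.components:
            raise ConfigError(f"activity model for {self.mirna_id} has no components")
        if self.combination not in _COMBINATIONS:
            raise ConfigError(f"unknown combination {self.combination!r}")

    @property
    def gene_ids(self) -> list[str]:
        return [c.gene_id for c in self.components]


class ActivityRegressor(BaseEstimator, RegressorMixin):
    """Estimate miRNA expression from its target genes' expression.

    Parameters
    ----------
    combination : {"mean_of_predictions", "multivariate"}
        ``mean_of_predictions`` fits one simple least-squares regression of
        the miRNA on each target and averages the per-target predictions;
        ``multivariate`` fits one joint ordinary-least-squares model on all
        targets. A rank-deficient multivariate design falls back to
        ``mean_of_predictions`` with a warning.

    Attributes
    ----------
    components_ : list of ActivityComponent
        Per-gene (intercept, slope, training correlation) records. In
        multivariate mode all components share the joint intercept.
    feature_names_ : list of str
        Target gene ids in training column order.
    """

    def __init__(self, combination: str = MEAN_OF_PREDICTIONS):
        self.combination = combination

    def fit(self, X, y, feature_names: Optional[Sequence[str]] = None):
        if self.combination not in _COMBINATIONS:
            raise ConfigError(f"unknown combination {self.combination!r}")
        if isinstance(X, pd.DataFrame):
            feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ConfigError("X must be (n_samples, n_targets)")
        n, k = X.shape
        if k < 1:
            raise DegenerateInputError("at least one target gene is required")
        if y.shape != (n,):
            raise ConfigError("y length must match the number of samples")
        if n < 3:
            raise DegenerateInputError("need at least 3 training samples")
        if feature_names is None:
            feature_names = [f"x{i}" for i in range(k)]
        self.feature_names_ = list(feature_names)

        mode = self.combination
        if mode == MULTIVARIATE:
            design = np.column_stack([np.ones(n), X])
            if np.linalg.matrix_rank(design) < design.shape[1]:
                warnings.warn(
                    "collinear multivariate design; falling back to mean_of_predictions",
                    RuntimeWarning,
                )
                mode = MEAN_OF_PREDICTIONS
            else:
                beta, *_ = np.linalg.lstsq(design, y, rcond=None)
                self.components_ = [
                    ActivityComponent(
                        gene_id=self.feature_names_[j],
                        intercept=float(beta[0]),
                        slope=float(beta[j + 1]),
                        train_corr=float(np.corrcoef(X[:, j], y)[0, 1]),
                    )
                    for j in range(k)
                ]
        if mode == MEAN_OF_PREDICTIONS:
            comps = []
            xbar = X.mean(axis=0)
            ybar = y.mean()
            for j in range(k):
                dx = X[:, j] - xbar[j]
                sxx = float(dx @ dx)
                if sxx == 0:
                    raise DegenerateInputError(
                        f"target {self.feature_names_[j]} has zero variance"
                    )
                slope = float(dx @ (y - ybar)) / sxx
                comps.append(
                    ActivityComponent(
                        gene_id=self.feature_names_[j],
                        intercept=float(ybar - slope * xbar[j]),
                        slope=slope,
                        train_corr=float(np.corrcoef(X[:, j], y)[0, 1]),
                    )
                )
            self.components_ = comps
        self.fitted_combination_ = mode
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "components_"):
            raise ConfigError("ActivityRegressor is not fitted")
        if isinstance(X, pd.DataFrame):
            X = X.loc[:, self.feature_names_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if self.fitted_combination_ == MULTIVARIATE:
            out = np.full(X.shape[0], self.components_[0].intercept)
            for j, c in enumerate(self.components_):
                out = out + c.slope * X[:, j]
            return out
        preds = np.stack(
            [c.intercept + c.slope * X[:, j] for j, c in enumerate(self.components_)]
        )
        return preds.mean(axis=0)

    def to_model(self, mirna_id: str) -> ActivityModel:
        combo = MULTIVARIATE if self.fitted_combination_ == MULTIVARIATE else MEAN_OF_PREDICTIONS
        return ActivityModel(mirna_id=mirna_id, components=list(self.components_), combination=combo)


def fit_activity_model(
    mirna_id: str,
    mirna_expr,
    target_exprs: Mapping[str, Sequence[float]],
    combination: str = MEAN_OF_PREDICTIONS,
) -> ActivityModel:
    """Fit per-target regressions of one miRNA on its filtered targets."""
    if not target_exprs:
        raise DegenerateInputError(f"no target genes supplied for {mirna_id}")
    genes = list(target_exprs)
    X = np.column_stack([np.asarray(target_exprs[g], dtype=float) for g in genes])
    reg = ActivityRegressor(combination=combination)
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        reg.fit(X, np.asarray(mirna_expr, dtype=float), feature_names=genes)
    return reg.to_model(mirna_id)


def estimate_activity(model: ActivityModel, mrna: ExpressionMatrix) -> np.ndarray:
    """Per-sample estimated miRNA expression from an mRNA matrix.

    mean_of_predictions averages over the components whose gene the matrix
    carries (absent genes are skipped and logged); multivariate prediction
    needs every gene and otherwise falls back to the mean over available
    components.
    """
    present = [c for c in model.components if c.gene_id in mrna.values.index]
    if not present:
        raise DegenerateInputError(
            f"none of the {len(model.components)} target genes of {model.mirna_id} "
            "are present in the matrix"
        )
    if len(present) < len(model.components):
        logger.info(
            "estimate_activity(%s): %d/%d target genes absent, using the rest",
            model.mirna_id,
            len(model.components) - len(present),
            len(model.components),
        )
    if model.combination == MULTIVARIATE:
        if len(present) == len(model.components):
            out = np.full(mrna.n_samples, model.components[0].intercept)
            for c in model.components:
                out = out + c.slope * mrna.feature(c.gene_id)
            return out
        logger.info(
            "estimate_activity(%s): multivariate model missing genes; "
            "falling back to mean of per-target predictions",
            model.mirna_id,
        )
    preds = np.stack([c.intercept + c.slope * mrna.feature(c.gene_id) for c in present])
    return preds.mean(axis=0)


def estimated_marker_performance(
    model: ActivityModel,
    mrna: ExpressionMatrix,
    labels: SampleAnnotation,
    weights: ClassWeights,
    svm_config: SVMConfig = SVMConfig(),
) -> MarkerPerformance:
    """Score estimated miRNA activity as a single marker on an mRNA-only set.

    The activity vector is standardized for the dataset (regression
    intercepts learned on another platform do not transfer) and run through
    the same weighted-SVM LOOCV used for observed features.
    """
    activity = estimate_activity(model, mrna)
    sd = activity.std()
    activity = (activity - activity.mean()) / (sd if sd > 0 else 1.0)
    y = labels.y(mrna.sample_ids)
    pred, dec = loocv_scores(activity, y, weights, svm_config)
    return MarkerPerformance(
        feature_ids=(model.mirna_id,),
        kind=KIND_MIRNA,
        ba=loocv_ba(pred, y),
        auc=auc_from_scores(dec, y),
        dataset_id=labels.dataset_id,
    )


def previous_method_activity_ba(target_bas: Sequence[float]) -> float:
    """Baseline miRNA activity performance: mean of the targets' own BAs."""
    bas = np.asarray(list(target_bas), dtype=float)
    if bas.size == 0:
        raise DegenerateInputError("no target BAs supplied")
    return float(bas.mean())


@dataclass
class EstimationReport:
    """Estimated vs observed BA pairs and their mean squared error."""

    pairs: list[tuple[str, float, Optional[float]]] = field(default_factory=list)
    mse: Optional[float] = None


def evaluate_estimation(estimated_bas, observed_bas, mirna_ids=None) -> EstimationReport:
    """Mean squared error between paired estimated and observed BAs."""
    est = np.asarray(list(estimated_bas), dtype=float)
    obs = np.asarray(list(observed_bas), dtype=float)
    if est.size == 0 or est.shape != obs.shape:
        raise DegenerateInputError("estimated/observed BA vectors must be equal-length, nonempty")
    if mirna_ids is None:
        mirna_ids = [f"feature_{i}" for i in range(est.size)]
    pairs = [(m, float(e), float(o)) for m, e, o in zip(mirna_ids, est, obs)]
    return EstimationReport(pairs=pairs, mse=float(np.mean((est - obs) ** 2)))
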