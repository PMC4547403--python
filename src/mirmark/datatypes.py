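"""Core in-memory containers for the pipeline.

Expression data live in a pandas DataFrame (features x samples, log2 scale)
wrapped with the feature kind; sample labels are a pandas Series keyed by
sample id; the miRNA->gene relationship universe is an :class:`EdgeSet` of
:class:`TargetEdge` records keyed on the (miRNA, gene) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError

CANCER = "cancer"
NORMAL = "normal"
LABELS = (CANCER, NORMAL)

MIRNA = "miRNA"
MRNA = "mRNA"
FEATURE_KINDS = (MIRNA, MRNA)

VALIDATED = "validated"
PREDICTED = "predicted"
ORIGINS = (VALIDATED, PREDICTED)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values for one feature kind.

    ``values`` is features x samples with unique, ordered feature ids as the
    index and unique sample ids as columns. All values must be finite;
    expression is assumed to be already log2-transformed and background
    corrected upstream.
    """

    values: pd.DataFrame
    feature_kind: str
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ConfigError(
                f"feature_kind must be one of {FEATURE_KINDS}, got {self.feature_kind!r}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ConfigError(f"duplicate feature ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ConfigError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr.astype(float)).all():
            raise ConfigError("expression values must all be finite")
        self.values = self.values.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def feature(self, feature_id: str) -> np.ndarray:
        """Expression vector of one feature across samples."""
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[:, list(sample_ids)])


@dataclass
class SampleAnnotation:
    """Cancer/normal labels for the samples of one dataset."""

    labels: pd.Series  # index: sample_id, values in {"cancer", "normal"}
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ConfigError("duplicate sample ids in annotation")
        bad = set(self.labels.unique()) - set(LABELS)
        if bad:
            raise ConfigError(f"unknown labels {sorted(bad)}; expected {LABELS}")
        self.labels = self.labels.astype(str)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def n_cancer(self) -> int:
        return int((self.labels == CANCER).sum())

    @property
    def n_normal(self) -> int:
        return int((self.labels == NORMAL).sum())

    def y(self, sample_ids: Optional[Iterable[str]] = None) -> np.ndarray:
        """Integer labels (cancer=1, normal=0) in the given sample order."""
        lab = self.labels if sample_ids is None else self.labels.loc[list(sample_ids)]
        return (lab == CANCER).to_numpy(dtype=np.int64)

    def require_both_classes(self) -> None:
        if self.n_cancer == 0 or self.n_normal == 0:
            raise DegenerateInputError(
                f"both classes required, got {self.n_cancer} cancer / {self.n_normal} normal"
            )


@dataclass(frozen=True)
class TargetEdge:
    """One miRNA->gene relationship, optionally annotated with the
    expression correlation computed on a paired cohort."""

    mirna_id: str
    gene_id: str
    origin: str = PREDICTED
    corr: Optional[float] = None
    corr_p: Optional[float] = None

    def __post_init__(self) -> None:
        if self.origin not in ORIGINS:
            raise ConfigError(f"unknown origin {self.origin!r}; expected {ORIGINS}")
        if (self.corr is None) != (self.corr_p is None):
            raise ConfigError("corr and corr_p must be set together")
        if self.corr is not None and abs(self.corr) > 1 + 1e-12:
            raise ConfigError(f"|corr| must be <= 1, got {self.corr}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_id)


class EdgeSet:
    """A deduplicated set of :class:`TargetEdge`, unique on (miRNA, gene).

    When the same pair is added twice, the "validated" origin wins and any
    correlation annotation from the later add is kept. Iteration is in
    sorted (miRNA, gene) order for deterministic output.
    """

    def __init__(self, edges: Iterable[TargetEdge] = (), provenance: str = ""):
        self._edges: dict[tuple[str, str], TargetEdge] = {}
        self.provenance = provenance
        for e in edges:
            self.add(e)

    def add(self, edge: TargetEdge) -> None:
        prev = self._edges.get(edge.key)
        if prev is not None and prev.origin == VALIDATED and edge.origin == PREDICTED:
            edge = replace(edge, origin=VALIDATED)
        self._edges[edge.key] = edge

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self) -> Iterator[TargetEdge]:
        return iter(sorted(self._edges.values(), key=lambda e: e.key))

    def __contains__(self, key: tuple[str, str]) -> bool:
        return tuple(key) in self._edges

    def get(self, mirna_id: str, gene_id: str) -> Optional[TargetEdge]:
        return self._edges.get((mirna_id, gene_id))

    def mirna_ids(self) -> list[str]:
        return sorted({e.mirna_id for e in self._edges.values()})

    def gene_ids(self) -> list[str]:
        return sorted({e.gene_id for e in self._edges.values()})

    def keys(self) -> set[tuple[str, str]]:
        return set(self._edges)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mirna_id": e.mirna_id,
                "gene_id": e.gene_id,
                "origin": e.origin,
                "corr": e.corr,
                "corr_p": e.corr_p,
            }
            for e in self
        ]
        return pd.DataFrame(rows, columns=["mirna_id", "gene_id", "origin", "corr", "corr_p"])


@dataclass
class DatasetBundle:
    """A cohort used by the pipeline: mRNA matrix, optional miRNA matrix and
    sample labels sharing the same sample order."""

    mrna: ExpressionMatrix
    annotation: SampleAnnotation
    mirna: Optional[ExpressionMatrix] = None
    dataset_id: str = ""

    def __post_init__(self) -> None:
        sids = set(self.annotation.sample_ids)
        for m in (self.mrna, self.mirna):
            if m is not None and not set(m.sample_ids) <= sids:
                missing = sorted(set(m.sample_ids) - sids)
                raise ConfigError(f"samples without annotation: {missing[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return self.mrna.sample_ids

    def y(self) -> np.ndarray:
        return self.annotation.y(self.sample_ids)
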