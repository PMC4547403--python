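"""Condition-specific miRNA-target network filtering.

Sequence-based target prediction massively over-predicts: most predicted
miRNA->gene edges are not active in a given tissue. Because a functional
miRNA represses its target, an active edge should show negative expression
correlation across the paired cohort. The filter keeps an edge only when
the Pearson correlation between miRNA and gene expression (all samples
pooled) satisfies r < corr_max (default -0.3) and the two-sided p-value of
the regression-slope t-test (n-2 df) satisfies p < p_max (default 0.05),
both strict.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy import stats

from .datatypes import EdgeSet, ExpressionMatrix
from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

CORR_MAX_DEFAULT = -0.3
P_MAX_DEFAULT = 0.05


def correlate_pair(mirna_expr, gene_expr) -> tuple[float, float]:
    """Pearson r and its two-sided p-value for one miRNA/gene pair.

    The p-value equals the t-test on the simple-regression slope with n-2
    degrees of freedom (the two tests are algebraically identical).
    """
    x = np.asarray(mirna_expr, dtype=float)
    y = np.asarray(gene_expr, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("expression vectors must share length")
    if x.size < 3:
        raise DegenerateInputError("need at least 3 samples for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("zero-variance vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def filter_edges(
    candidates: EdgeSet,
    mirna: ExpressionMatrix,
    mrna: ExpressionMatrix,
    corr_max: float = CORR_MAX_DEFAULT,
    p_max: float = P_MAX_DEFAULT,
) -> EdgeSet:
    """Keep edges with r < corr_max and p < p_max on the pooled samples.

    Edges whose miRNA or gene is absent from the matrices are skipped with a
    logged count (platform coverage differs between datasets). Retained
    edges carry their corr / corr_p annotation. An empty result is a
    warning, not an error. The operation is idempotent: re-filtering its
    output changes nothing.
    """
    if mirna.sample_ids != mrna.sample_ids:
        raise DegenerateInputError("miRNA and mRNA matrices must share sample order")
    out = EdgeSet(provenance=f"filtered: corr<{corr_max}, p<{p_max}")
    n_skipped = 0
    mirna_index = set(mirna.values.index)
    gene_index = set(mrna.values.index)
    for edge in candidates:
        if edge.mirna_id not in mirna_index or edge.gene_id not in gene_index:
            n_skipped += 1
            continue
        r, p = correlate_pair(mirna.feature(edge.mirna_id), mrna.feature(edge.gene_id))
        if r < corr_max and p < p_max:
            out.add(replace(edge, corr=r, corr_p=p))
    if n_skipped:
        logger.info("filter_edges: skipped %d edges with absent endpoints", n_skipped)
    if len(out) == 0:
        logger.warning("filter_edges: no edges survived the correlation filter")
    return out
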