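"""Normalization and sample alignment ahead of factorization.

The pipeline normalizes expression gene-wise: Z-score (population SD) then
min-max to [0, 1].  The min-max step last guarantees a valid non-negative
NMF input while the Z-score step removes per-gene location/scale effects.
Both transforms are rank-preserving within each gene row.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)


def zscore_by_gene(m: ExpressionMatrix, eps: float = 1e-12) -> ExpressionMatrix:
    """Center and scale each gene row to mean 0, population SD 1.

    Constant genes cannot be scaled and are dropped (count logged).
    Raises if every gene is constant.
    """
    if m.n_samples < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    v = m.values.astype(float)
    sd = v.std(axis=1, ddof=0)
    keep = sd > eps
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d constant genes at z-score stage", n_dropped)
    if not keep.any():
        raise ValueError("all genes constant; nothing to normalize")
    v = v[keep]
    z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, ddof=0, keepdims=True)
    df = m.data.loc[np.asarray(m.gene_ids)[keep]].copy()
    df.iloc[:, :] = z
    return ExpressionMatrix(df, value_scale="zscore")


def minmax_by_gene(m: ExpressionMatrix, eps: float = 1e-12) -> ExpressionMatrix:
    """Rescale each gene row to span exactly [0, 1] (valid NMF input)."""
    v = m.values.astype(float)
    lo = v.min(axis=1, keepdims=True)
    hi = v.max(axis=1, keepdims=True)
    span = hi - lo
    flat = span.ravel() <= eps
    if flat.any():
        gene = np.asarray(m.gene_ids)[flat][0]
        raise ValueError(f"constant gene {gene!r}: min-max undefined (z-score first)")
    scaled = (v - lo) / span
    df = m.data.copy()
    df.iloc[:, :] = scaled
    return ExpressionMatrix(df, value_scale="minmax")


def normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standard preprocessing: gene-wise Z-score then min-max."""
    return minmax_by_gene(zscore_by_gene(m))


def align_to_clinical(
    m: ExpressionMatrix, c: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both inputs to their shared samples, in matrix order."""
    shared = [s for s in m.sample_ids if s in set(c.sample_ids)]
    if not shared:
        raise ValueError("no samples shared between expression matrix and clinical table")
    logger.info("aligned to %d shared samples", len(shared))
    return m.subset_samples(shared), c.subset(shared)
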