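"""Per-sample immune/stromal scoring and TME subtype classification.

Scores are single-sample GSEA (ssGSEA) enrichment statistics: within each
sample, genes are ranked by expression; the score integrates the running
difference between the weighted cumulative distribution of signature genes
and the uniform cumulative distribution of the remaining genes.  Being
rank-based, the score is invariant to any strictly increasing per-sample
transform, which is what makes it portable across platforms and tolerant
of a few missing signature genes.

Cohort scores are min-max normalized to [0, 1] and the cohort medians split
samples into the four TME subtypes HH / HL / LH / LL (first letter: immune
high/low; second: stromal).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix, GeneSet
from .refine import SignaturePair

logger = logging.getLogger(__name__)

#: T-cell exhaustion marker ratio: co-inhibitory over co-stimulatory
#: receptors.  HGNC symbols (PD-1 -> PDCD1, TIM-3 -> HAVCR2).
EXHAUSTION_RATIO = (["PDCD1", "CTLA4", "LAG3", "HAVCR2"], ["CD28", "CD40LG"])
#: Angiopoietin balance (vessel stabilization over destabilization).
ANGIOPOIETIN_RATIO = (["ANGPT1"], ["ANGPT2"])


def _sample_es(stat: np.ndarray, hit: np.ndarray, alpha: float) -> float:
    """Integrated running-sum enrichment score for one sample.

    ``stat`` are per-gene rank statistics (higher = more expressed),
    ``hit`` marks signature genes.  Positions are walked in decreasing
    statistic order; hit increments are |stat|^alpha normalized over hits,
    miss increments uniform.  The score sums the running difference at
    every position.
    """
    order = np.argsort(-stat, kind="stable")
    hit_o = hit[order]
    stat_o = np.abs(stat[order])
    n = len(stat)
    n_hit = int(hit_o.sum())
    w = np.where(hit_o, stat_o**alpha, 0.0)
    total_w = w.sum()
    cum_hit = np.cumsum(w) / total_w
    cum_miss = np.cumsum(~hit_o) / (n - n_hit)
    return float(np.sum(cum_hit - cum_miss))


def ssgsea_score(m: ExpressionMatrix, gene_set: GeneSet, alpha: float = 0.25) -> pd.Series:
    """ssGSEA enrichment of ``gene_set`` in every sample of ``m``.

    Set genes absent from the matrix are dropped with a logged count.
    Deterministic; tie ranks are averaged.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    present = [g for g in gene_set.genes if g in set(m.gene_ids)]
    n_missing = len(gene_set.genes) - len(present)
    if not present:
        raise ValueError(f"no genes of set {gene_set.name!r} present in the matrix")
    if n_missing:
        logger.info("set %s: %d genes absent from the matrix", gene_set.name, n_missing)
    if len(present) >= m.n_genes:
        raise ValueError("gene set covers the whole matrix; enrichment undefined")
    hit = np.isin(np.asarray(m.gene_ids), present)
    V = m.values
    scores = np.empty(m.n_samples)
    for j in range(m.n_samples):
        stat = rankdata(V[:, j], method="average")  # ascending: top gene gets rank N
        scores[j] = _sample_es(stat, hit, alpha)
    return pd.Series(scores, index=m.sample_ids, name=gene_set.name)


def normalize_scores(raw: pd.Series) -> pd.Series:
    """Min-max normalize a cohort score vector to [0, 1]."""
    if len(raw) < 2:
        raise ValueError("need >=2 samples to normalize")
    lo, hi = float(raw.min()), float(raw.max())
    if hi - lo <= 0:
        raise ValueError("constant scores cannot be min-max normalized")
    return (raw - lo) / (hi - lo)


@dataclass
class ScoreTable:
    """Per-sample raw and normalized immune/stromal scores."""

    table: pd.DataFrame  # columns immune_raw, stromal_raw, immune_norm, stromal_norm
    genes_used: dict[str, int]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class SubtypeAssignment:
    labels: pd.Series  # sample -> HH/HL/LH/LL
    immune_median: float
    stromal_median: float


def compute_istme(
    m: ExpressionMatrix,
    sig: SignaturePair,
    alpha: float = 0.25,
    min_genes: int = 10,
) -> ScoreTable:
    """Immune and stromal ssGSEA scores plus cohort-level normalization.

    Requires at least ``min_genes`` of each signature in the matrix
    (errors below the floor, warns below 50% coverage).
    """
    genes_used = {}
    raw = {}
    for role, gset in (("immune", sig.immune), ("stromal", sig.stromal)):
        present = [g for g in gset.genes if g in set(m.gene_ids)]
        if len(present) < min_genes:
            missing = sorted(set(gset.genes) - set(present))
            raise ValueError(
                f"{role} signature coverage {len(present)} < {min_genes}; "
                f"missing e.g. {missing[:10]}"
            )
        if len(present) < 0.5 * len(gset.genes):
            warnings.warn(
                f"{role} signature coverage below 50% "
                f"({len(present)}/{len(gset.genes)} genes present)"
            )
        genes_used[role] = len(present)
        raw[role] = ssgsea_score(m, gset, alpha=alpha)
    table = pd.DataFrame(
        {
            "immune_raw": raw["immune"],
            "stromal_raw": raw["stromal"],
            "immune_norm": normalize_scores(raw["immune"]),
            "stromal_norm": normalize_scores(raw["stromal"]),
        }
    )
    return ScoreTable(table=table, genes_used=genes_used)


def assign_subtypes(scores: ScoreTable) -> SubtypeAssignment:
    """Median-split the cohort into the HH / HL / LH / LL subtypes.

    High means strictly above the cohort median (values at the median
    class as low).  First letter = immune, second = stromal.
    """
    t = scores.table
    if len(t) < 4:
        raise ValueError("need >=4 samples to assign subtypes")
    med_i = float(t["immune_norm"].median())
    med_s = float(t["stromal_norm"].median())
    hi_i = t["immune_norm"] > med_i
    hi_s = t["stromal_norm"] > med_s
    labels = pd.Series(
        np.char.add(np.where(hi_i, "H", "L"), np.where(hi_s, "H", "L")),
        index=t.index,
        name="subtype",
    )
    return SubtypeAssignment(labels=labels, immune_median=med_i, stromal_median=med_s)


def marker_ratio(
    m: ExpressionMatrix, numerator: list[str], denominator: list[str]
) -> pd.Series:
    """Per-sample ratio of summed marker expressions (raw/linear scale).

    Samples whose denominator sums to 0 get NaN (flagged undefined).
    Missing genes raise with their symbols.
    """
    have = set(m.gene_ids)
    missing = [g for g in list(numerator) + list(denominator) if g not in have]
    if missing:
        raise KeyError(f"marker genes absent from matrix: {missing}")
    num = m.data.loc[list(numerator)].sum(axis=0)
    den = m.data.loc[list(denominator)].sum(axis=0)
    undef = den == 0
    if undef.any():
        warnings.warn(f"{int(undef.sum())} samples have zero denominator; ratio undefined")
    ratio = num / den.where(~undef)
    ratio.name = "marker_ratio"
    return ratio


class SSGSEAScorer(TransformerMixin, BaseEstimator):
    """Transformer mapping expression profiles to immune/stromal scores.

    ``fit(X)`` (X: DataFrame samples x genes) scores the training cohort
    and freezes its raw-score ranges; ``transform(X)`` scores new samples
    and normalizes against the frozen ranges, enabling single-sample
    deployment.  With ``cohort_normalize=True`` transform re-normalizes
    within the transformed cohort instead (the in-study behavior).
    """

    def __init__(self, signatures: SignaturePair = None, alpha: float = 0.25,
                 cohort_normalize: bool = False, min_genes: int = 10):
        self.signatures = signatures
        self.alpha = alpha
        self.cohort_normalize = cohort_normalize
        self.min_genes = min_genes

    def _score_frame(self, X: pd.DataFrame) -> ScoreTable:
        m = ExpressionMatrix(X.T.copy())
        return compute_istme(m, self.signatures, alpha=self.alpha, min_genes=self.min_genes)

    def fit(self, X: pd.DataFrame, y=None):
        if self.signatures is None:
            raise ValueError("signatures must be provided")
        st = self._score_frame(X)
        self.train_scores_ = st.table
        self.ranges_ = {
            "immune": (st.table["immune_raw"].min(), st.table["immune_raw"].max()),
            "stromal": (st.table["stromal_raw"].min(), st.table["stromal_raw"].max()),
        }
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "ranges_")
        st = self._score_frame(X)
        out = st.table.copy()
        if self.cohort_normalize:
            return out
        for role in ("immune", "stromal"):
            lo, hi = self.ranges_[role]
            out[f"{role}_norm"] = (out[f"{role}_raw"] - lo) / (hi - lo)
        return out


class TMESubtypeClassifier(BaseEstimator):
    """Median-split TME subtype classifier over normalized score pairs.

    ``fit`` learns the cohort medians from a score frame (columns
    immune_norm / stromal_norm); ``predict`` labels samples HH/HL/LH/LL
    against the learned thresholds.
    """

    def fit(self, X: pd.DataFrame, y=None):
        self.immune_median_ = float(X["immune_norm"].median())
        self.stromal_median_ = float(X["stromal_norm"].median())
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "immune_median_")
        hi_i = np.where(X["immune_norm"].values > self.immune_median_, "H", "L")
        hi_s = np.where(X["stromal_norm"].values > self.stromal_median_, "H", "L")
        return np.char.add(hi_i, hi_s)
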