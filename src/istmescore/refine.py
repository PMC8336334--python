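"""Refine the multitask gene list into immune and stromal signatures.

The cohort is split into two consensus clusters using repeated rank-2 NMF
runs on the selected-gene submatrix; differential expression between the
clusters (moderated t by default) with BH adjustment then partitions the
genes: significantly up in the immune-high reference cluster -> immune
signature, significantly down -> stromal signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, GeneSet, GeneSetCollection
from .nmf import KLNMF, _consensus_from_labels

logger = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    consensus: pd.DataFrame  # samples x samples in [0, 1]
    labels: pd.Series  # sample -> {1, 2}
    n_runs: int


@dataclass
class DGEResult:
    table: pd.DataFrame  # index gene; columns logfc, t, p, adj_p
    reference: int  # label of the reference (logFC = ref minus other) cluster


@dataclass
class SignaturePair:
    immune: GeneSet
    stromal: GeneSet
    provenance: pd.DataFrame  # per signature gene: logfc, adj_p

    def __post_init__(self):
        if set(self.immune.genes) & set(self.stromal.genes):
            raise ValueError("immune and stromal signatures must be disjoint")

    def as_collection(self) -> GeneSetCollection:
        return GeneSetCollection([self.immune, self.stromal])


def consensus_cluster(
    m: ExpressionMatrix,
    n_clusters: int = 2,
    n_runs: int = 20,
    seed: int = 0,
    rank_normalize: bool = True,
) -> ConsensusResult:
    """Stability clustering of samples via repeated seeded rank-2 NMF.

    Each run fits NMF with a distinct seed and labels samples by argmax of
    H; the consensus matrix holds co-assignment fractions; final labels cut
    the average-linkage tree of 1 - consensus at ``n_clusters``.

    With ``rank_normalize`` (default) each gene row is replaced by its
    within-gene ranks scaled to (0, 1] before factorization.  Expression
    marginals are heavy-tailed, and on raw values the rank-2 factorization
    tends to isolate a small extreme-tail sample group instead of the
    dominant two-group structure; uniform margins keep the split balanced
    while leaving the consensus mechanics unchanged.
    """
    if m.n_samples < 4:
        raise ValueError("consensus clustering needs >=4 samples")
    if n_runs < 2:
        raise ValueError("n_runs must be >=2")
    V = m.values
    if np.ptp(V, axis=0).max() == 0:
        raise ValueError("all samples identical; clustering degenerate")
    if rank_normalize:
        from scipy.stats import rankdata

        V = np.apply_along_axis(rankdata, 1, V) / m.n_samples
    labels = []
    for r in range(n_runs):
        est = KLNMF(
            n_components=n_clusters, max_iter=500, tol=1e-5, random_state=seed + 7919 * r
        )
        est.fit(V.T)
        labels.append(est.H_.argmax(axis=0))
    cons = _consensus_from_labels(np.asarray(labels))
    d = 1.0 - cons
    np.fill_diagonal(d, 0.0)
    Z = average(squareform((d + d.T) / 2, checks=False))
    lab = fcluster(Z, t=n_clusters, criterion="maxclust")
    if len(np.unique(lab)) < n_clusters:
        raise ValueError("consensus clustering degenerate: fewer clusters than requested")
    return ConsensusResult(
        consensus=pd.DataFrame(cons, index=m.sample_ids, columns=m.sample_ids),
        labels=pd.Series(lab, index=m.sample_ids),
        n_runs=n_runs,
    )


def orient_reference(cons: ConsensusResult, immune_eigen: pd.Series) -> int:
    """Pick the reference cluster: the one with higher mean immune activity.

    Anchors the logFC sign convention so immune genes come out positive.
    """
    common = [s for s in cons.labels.index if s in immune_eigen.index]
    if not common:
        raise ValueError("no shared samples between labels and eigenvalue")
    lab = cons.labels[common]
    eig = immune_eigen[common]
    means = eig.groupby(lab).mean()
    if len(means) < 2:
        raise ValueError("need two clusters to orient")
    if np.isclose(means.max(), means.min()):
        raise ValueError("cluster immune-activity means tie; choose the reference manually")
    return int(means.idxmax())


def _inv_trigamma(y: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    x = 0.5 + 1.0 / y  # standard starting value
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x - delta
        if abs(delta) < tol * x:
            break
    return float(x)


def _moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene variances toward a pooled prior.

    Moment-matches log variances against the scaled-F marginal: returns the
    posterior variances (d0*s0^2 + df*s2)/(d0 + df) and the prior df d0
    (inf when the observed spread is below the chi-square baseline, in
    which case every variance collapses to the prior).
    """
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - special.digamma(df / 2) + np.log(df / 2)
    mean_e = float(np.mean(e))
    var_z = float(np.var(z, ddof=1)) if len(z) > 1 else 0.0
    excess = var_z - float(special.polygamma(1, df / 2))
    if excess <= 1e-12:
        d0 = np.inf
        s02 = float(np.exp(mean_e))
        return np.full_like(s2, s02), d0
    d0 = 2.0 * _inv_trigamma(excess)
    s02 = float(np.exp(mean_e + special.digamma(d0 / 2) - np.log(d0 / 2)))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0


def dge(
    m: ExpressionMatrix,
    labels: pd.Series,
    reference: int,
    moderated: bool = True,
) -> DGEResult:
    """Two-group differential expression with optional variance moderation.

    logFC is mean(reference cluster) - mean(other cluster) on the input
    scale.  By default a moderated t-statistic is used (per-gene variances
    shrunk toward an empirical-Bayes prior, df inflated by the prior df);
    ``moderated=False`` gives the plain Welch t-test.
    """
    lab = labels[m.sample_ids]
    groups = sorted(lab.unique())
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    if reference not in groups:
        raise ValueError(f"reference {reference} not among labels {groups}")
    other = [g for g in groups if g != reference][0]
    a = m.data.loc[:, lab[lab == reference].index].values
    b = m.data.loc[:, lab[lab == other].index].values
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >=2 samples")
    logfc = a.mean(axis=1) - b.mean(axis=1)
    if moderated:
        df = n1 + n2 - 2
        s2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / df
        s2_post, d0 = _moderate_variances(s2, df)
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = np.where(se > 0, logfc / np.maximum(se, 1e-300), 0.0)
        dof = df + (0 if np.isinf(d0) else d0)
        p = 2.0 * stats.t.sf(np.abs(t), dof if np.isfinite(dof) else 1e9)
    else:
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        t = np.nan_to_num(t)
        p = np.nan_to_num(p, nan=1.0)
    table = pd.DataFrame(
        {"logfc": logfc, "t": t, "p": p, "adj_p": bh_adjust(p)}, index=m.gene_ids
    )
    return DGEResult(table=table, reference=reference)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def extract_signatures(
    dge_result: DGEResult,
    mtl_genes: list[str],
    p_thresh: float = 0.05,
    use_adjusted: bool = True,
) -> SignaturePair:
    """Split the selected genes into immune/stromal signatures by logFC sign.

    immune = genes with P < p_thresh and logFC > 0 (up in the immune-high
    reference cluster); stromal = P < p_thresh and logFC < 0.  Genes with
    logFC exactly 0 are excluded.  Raises when either list comes out empty.
    """
    table = dge_result.table
    missing = [g for g in mtl_genes if g not in table.index]
    if missing:
        raise ValueError(f"DGE table does not cover genes: {missing[:5]}")
    sub = table.loc[mtl_genes]
    pcol = "adj_p" if use_adjusted else "p"
    sig = sub[sub[pcol] < p_thresh]
    immune = sig[sig["logfc"] > 0].index.tolist()
    stromal = sig[sig["logfc"] < 0].index.tolist()
    logger.info("signatures: %d immune, %d stromal genes", len(immune), len(stromal))
    if not immune or not stromal:
        raise ValueError(
            f"signature extraction failed: {len(immune)} immune / {len(stromal)} stromal "
            f"genes at {pcol} < {p_thresh}"
        )
    prov = sub.loc[immune + stromal, ["logfc", pcol]].rename(columns={pcol: "adj_p"})
    return SignaturePair(
        immune=GeneSet("ISTME_IMMUNE", "immune-related signature", immune),
        stromal=GeneSet("ISTME_STROMAL", "stromal-related signature", stromal),
        provenance=prov,
    )
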