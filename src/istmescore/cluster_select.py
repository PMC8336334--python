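"""Identify the immune- and stromal-activation NMF clusters.

A latent cluster is called *immune* when its top-weight genes are enriched
for immune reference sets and its per-sample eigenvalue is a favorable
prognostic factor (Cox HR < 1); *stromal* when enriched for stromal sets
with an adverse eigenvalue (HR > 1).  Enrichment is hypergeometric
over-representation of the cluster's top-100 weight genes against
user-supplied reference collections, BH-adjusted across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import ClinicalTable, GeneSetCollection
from .nmf import ClusterAssignment, NMFModel, eigenvalue, top_weight_genes
from .survival import CoxFit, cox_univariate

logger = logging.getLogger(__name__)


def hypergeom_enrich(
    query: list[str], refs: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each reference set.

    Each reference set is intersected with the universe first.  The P value
    is the upper tail P[X >= overlap]; BH adjustment runs across sets.
    Returns a table with columns set, overlap, set_size, p, adj_p.
    """
    from .refine import bh_adjust

    if not universe:
        raise ValueError("empty gene universe")
    if not query:
        raise ValueError("empty query gene list")
    uni = set(universe)
    q = set(query) & uni
    if not q:
        raise ValueError("query has no genes in the universe")
    M, N = len(uni), len(q)
    rows = []
    for s in refs:
        ref = set(s.genes) & uni
        overlap = len(q & ref)
        # P[X >= overlap] for X ~ Hypergeom(M, |ref|, N); overlap 0 -> P = 1
        p = float(hypergeom.sf(overlap - 1, M, len(ref), N)) if ref else 1.0
        rows.append({"set": s.name, "overlap": overlap, "set_size": len(ref), "p": min(p, 1.0)})
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p"].values)
    return table


@dataclass
class ClusterAnnotation:
    """Role call for one NMF cluster."""

    cluster: int
    enrichment: pd.DataFrame
    cox: CoxFit
    label: str  # immune | stromal | other

    @property
    def best_adj_p(self) -> float:
        return float(self.enrichment["adj_p"].min())

    def __post_init__(self):
        if self.label == "immune" and self.cox.hr[0] >= 1:
            raise ValueError("immune label requires HR < 1")
        if self.label == "stromal" and self.cox.hr[0] <= 1:
            raise ValueError("stromal label requires HR > 1")


def identify_tme_clusters(
    model: NMFModel,
    assign: ClusterAssignment,
    immune_refs: GeneSetCollection,
    stromal_refs: GeneSetCollection,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    n_top: int = 100,
) -> tuple[ClusterAnnotation, ClusterAnnotation]:
    """Pick the immune and stromal clusters by enrichment + Cox direction.

    For each cluster the top ``n_top`` weight genes are tested against each
    reference collection and the eigenvalue is screened by univariate Cox.
    The immune cluster minimizes the adjusted immune-enrichment P among
    clusters with cox_p < alpha and HR < 1; the stromal cluster analogously
    with HR > 1.  Ties break by smaller enrichment P then lower index.
    """
    if len(immune_refs) == 0 or len(stromal_refs) == 0:
        raise ValueError("reference collections must be non-empty")
    universe = model.gene_ids
    samples = [s for s in model.sample_ids if s in set(clinical.sample_ids)]
    clin = clinical.subset(samples)
    candidates: dict[int, dict] = {}
    for c in range(1, model.rank + 1):
        top = top_weight_genes(model, c, n=n_top)
        eig = eigenvalue(model, c)[samples].values
        try:
            cox = cox_univariate(eig, clin)
        except Exception as exc:  # degenerate eigenvalue
            logger.warning("cluster %d Cox screen failed: %s", c, exc)
            continue
        candidates[c] = {
            "top": top,
            "cox": cox,
            "imm": hypergeom_enrich(top, immune_refs, universe),
            "str": hypergeom_enrich(top, stromal_refs, universe),
        }

    def _pick(key: str, want_protective: bool) -> tuple[int, dict]:
        eligible = []
        for c, info in candidates.items():
            hr, p = info["cox"].hr[0], info["cox"].p[0]
            if p >= alpha:
                continue
            if want_protective and hr >= 1:
                continue
            if not want_protective and hr <= 1:
                continue
            eligible.append((float(info[key]["adj_p"].min()), c, info))
        if not eligible:
            near = {
                c: (round(info["cox"].hr[0], 3), round(info["cox"].p[0], 4),
                    round(float(info[key]["adj_p"].min()), 4))
                for c, info in candidates.items()
            }
            role = "immune" if want_protective else "stromal"
            raise ValueError(
                f"no cluster satisfies the {role} criteria "
                f"(near-misses cluster->(hr,cox_p,enrich_adj_p): {near})"
            )
        eligible.sort(key=lambda t: (t[0], t[1]))
        return eligible[0][1], eligible[0][2]

    k_imm, info_imm = _pick("imm", want_protective=True)
    k_str, info_str = _pick("str", want_protective=False)
    if k_imm == k_str:
        raise ValueError(f"immune and stromal selection collapsed onto cluster {k_imm}")
    imm = ClusterAnnotation(k_imm, info_imm["imm"], info_imm["cox"], "immune")
    stro = ClusterAnnotation(k_str, info_str["str"], info_str["cox"], "stromal")
    logger.info("immune cluster = %d, stromal cluster = %d", k_imm, k_str)
    return imm, stro
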