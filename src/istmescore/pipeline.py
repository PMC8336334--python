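"""End-to-end training and scoring pipelines.

``run_train`` executes the full signature-discovery chain on an expression
matrix with survival annotations: normalization, rank-k KL-NMF, immune/
stromal cluster identification (enrichment + Cox screening), L2,1 multitask
gene selection against the two cluster eigenvalues, and consensus/DGE
refinement into the final immune and stromal gene signatures.

``run_score`` is independent of training: given any expression matrix and a
signature pair (e.g. a published GMT), it computes ssGSEA scores and the
four-class TME subtype.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .cluster_select import ClusterAnnotation, identify_tme_clusters
from .containers import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .mtl import MTLProblem, MTLResult, fit_mtl, rho1_max, selected_genes
from .nmf import NMFModel, assign_clusters, eigenvalue, nmf_fit
from .preprocess import align_to_clinical, minmax_by_gene, zscore_by_gene
from .refine import SignaturePair, consensus_cluster, dge, extract_signatures, orient_reference
from .scoring import ScoreTable, SubtypeAssignment, assign_subtypes, compute_istme

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Every tunable of the training pipeline, with its default.

    ``rho1`` may be given absolutely; when None it is set to
    ``rho1_frac`` times the smallest value that zeroes all coefficients
    (a data-adaptive sparsity level).
    """

    k: int = 11
    seed: int = 0
    nmf_max_iter: int = 2000
    nmf_tol: float = 1e-6
    n_top: int = 100
    cox_alpha: float = 0.05
    rho1: float | None = None
    rho1_frac: float = 0.15
    rhoL2: float = 10.0
    mtl_max_iter: int = 10_000
    mtl_tol: float = 1e-8
    standardize_y: bool = True
    zero_tol: float = 1e-10
    consensus_runs: int = 20
    consensus_rank_normalize: bool = True
    dge_moderated: bool = True
    p_thresh: float = 0.05
    use_adjusted_p: bool = True
    ssgsea_alpha: float = 0.25

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TrainResult:
    model: NMFModel
    immune_cluster: ClusterAnnotation
    stromal_cluster: ClusterAnnotation
    mtl: MTLResult
    mtl_genes: list[str]
    signatures: SignaturePair
    normalized: ExpressionMatrix
    config: dict


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_train(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    immune_refs: GeneSetCollection,
    stromal_refs: GeneSetCollection,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Run the full signature-discovery pipeline (stages 1-3)."""
    cfg = config or TrainConfig()
    with _stage("preprocess"):
        expr, clinical = align_to_clinical(expr, clinical)
        norm = minmax_by_gene(zscore_by_gene(expr))
    with _stage("nmf"):
        model = nmf_fit(
            norm, k=cfg.k, seed=cfg.seed, max_iter=cfg.nmf_max_iter, tol=cfg.nmf_tol
        )
        assign = assign_clusters(model)
    with _stage("select-clusters"):
        imm, stro = identify_tme_clusters(
            model, assign, immune_refs, stromal_refs, clinical,
            alpha=cfg.cox_alpha, n_top=cfg.n_top,
        )
    with _stage("mtl"):
        Y = np.vstack(
            [eigenvalue(model, imm.cluster).values, eigenvalue(model, stro.cluster).values]
        )
        problem = MTLProblem(
            X=norm.values, Y=Y, rho1=0.0, rhoL2=cfg.rhoL2,
            gene_ids=norm.gene_ids, standardize_y=cfg.standardize_y,
        )
        problem.rho1 = cfg.rho1 if cfg.rho1 is not None else cfg.rho1_frac * rho1_max(problem)
        mtl_res = fit_mtl(problem, max_iter=cfg.mtl_max_iter, tol=cfg.mtl_tol)
        genes = selected_genes(mtl_res, zero_tol=cfg.zero_tol)
        if not genes:
            raise ValueError("MTL selected no genes; lower rho1")
        logger.info("MTL selected %d genes (rho1=%.4g)", len(genes), problem.rho1)
    with _stage("refine"):
        sub = norm.subset_genes(genes)
        cons = consensus_cluster(
            sub, n_clusters=2, n_runs=cfg.consensus_runs, seed=cfg.seed,
            rank_normalize=cfg.consensus_rank_normalize,
        )
        ref = orient_reference(cons, eigenvalue(model, imm.cluster))
        # BH multiplicity spans the selected genes: they are the hypotheses
        # under refinement
        dge_res = dge(sub, cons.labels, reference=ref, moderated=cfg.dge_moderated)
        signatures = extract_signatures(
            dge_res, genes, p_thresh=cfg.p_thresh, use_adjusted=cfg.use_adjusted_p
        )
    return TrainResult(
        model=model,
        immune_cluster=imm,
        stromal_cluster=stro,
        mtl=mtl_res,
        mtl_genes=genes,
        signatures=signatures,
        normalized=norm,
        config=cfg.resolved(),
    )


def run_score(
    expr: ExpressionMatrix,
    signatures: SignaturePair,
    ssgsea_alpha: float = 0.25,
) -> tuple[ScoreTable, SubtypeAssignment]:
    """Score a cohort with a signature pair and assign TME subtypes."""
    scores = compute_istme(expr, signatures, alpha=ssgsea_alpha)
    subtypes = assign_subtypes(scores)
    return scores, subtypes
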