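"""Non-negative matrix factorization by KL-divergence multiplicative updates.

Factorizes a non-negative gene x sample matrix V (i x j) as V ~ W H with
W (i x k) the gene basis and H (k x j) the per-sample coefficient matrix.
Each row of H is the "eigenvalue" of one latent cluster: a per-sample
activity profile.  Samples are assigned to the cluster maximizing their H
column and genes to the cluster maximizing their W row.

The multiplicative updates are the classic KL (generalized Kullback-Leibler
divergence) variant, which guarantees a monotonically non-increasing
objective; entries are clipped at a small floor to avoid the zero-locking /
division-by-zero pathology.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized KL divergence D(V || WH) = sum V log(V/WH) - V + WH."""
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    div = np.sum(WH) - np.sum(V)
    div += np.sum(V[mask] * np.log(V[mask] / WH[mask]))
    return float(div)


def _mu_kl_step(V, W, H):
    """One alternating KL multiplicative update (H then W), in place-ish."""
    WH = np.maximum(W @ H, _EPS)
    H = H * (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
    H = np.maximum(H, _EPS)
    WH = np.maximum(W @ H, _EPS)
    W = W * ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], _EPS)
    W = np.maximum(W, _EPS)
    return W, H


class KLNMF(TransformerMixin, BaseEstimator):
    """KL-divergence NMF with multiplicative updates (scikit-learn style).

    Follows the sklearn sample-major convention: ``fit(X)`` takes X of shape
    (n_samples, n_features).  Internally the factorization is V = X.T ~ W H
    with W the feature (gene) basis.

    Parameters
    ----------
    n_components : int
        Rank k of the factorization.
    max_iter : int
        Maximum multiplicative-update iterations.
    tol : float
        Relative objective-change stopping threshold.
    random_state : int
        Seed for the uniform random initialization.

    Attributes
    ----------
    W_ : ndarray (n_features, k)
        Gene basis matrix.
    H_ : ndarray (k, n_samples)
        Per-sample coefficient matrix (rows = cluster eigenvalues).
    objective_trace_ : ndarray
        KL divergence after each iteration (non-increasing).
    n_iter_ : int
    """

    def __init__(self, n_components=2, max_iter=2000, tol=1e-6, random_state=0):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        V = X.T  # genes x samples
        i, j = V.shape
        k = int(self.n_components)
        if np.min(V) < 0:
            raise ValueError("NMF input must be non-negative")
        if not (1 <= k < min(i, j)):
            raise ValueError(f"rank k={k} out of range for a {i}x{j} matrix")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        rng = np.random.default_rng(self.random_state)
        scale = np.sqrt(max(V.mean(), _EPS) / k)
        W = np.maximum(rng.uniform(0, 2 * scale, size=(i, k)), _EPS)
        H = np.maximum(rng.uniform(0, 2 * scale, size=(k, j)), _EPS)
        trace = []
        prev = kl_divergence(V, W @ H)
        for it in range(1, self.max_iter + 1):
            W, H = _mu_kl_step(V, W, H)
            obj = kl_divergence(V, W @ H)
            trace.append(obj)
            if prev - obj < self.tol * max(abs(prev), 1e-30) and it > 1:
                break
            prev = obj
        self.W_ = W
        self.H_ = H
        self.objective_trace_ = np.asarray(trace)
        self.n_iter_ = len(trace)
        self.reconstruction_err_ = trace[-1]
        return self

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.H_.T

    def transform(self, X):
        """Project new samples onto the fitted gene basis (H update only)."""
        check_is_fitted(self, "W_")
        V = np.asarray(X, dtype=float).T
        rng = np.random.default_rng(self.random_state)
        k = self.W_.shape[1]
        H = np.maximum(rng.uniform(0, 1, size=(k, V.shape[1])), _EPS)
        W = self.W_
        prev = np.inf
        for _ in range(self.max_iter):
            WH = np.maximum(W @ H, _EPS)
            H = H * (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], _EPS)
            H = np.maximum(H, _EPS)
            obj = kl_divergence(V, W @ H)
            if prev - obj < self.tol * max(abs(prev), 1e-30):
                break
            prev = obj
        return H.T


@dataclass
class NMFModel:
    """Fitted factorization keyed by gene/sample ids."""

    W: pd.DataFrame  # genes x k
    H: pd.DataFrame  # k x samples
    rank: int
    objective_trace: np.ndarray
    seed: int
    n_iter: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.W.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.H.columns)


@dataclass
class ClusterAssignment:
    sample_cluster: pd.Series  # sample -> 1..k
    gene_cluster: pd.Series  # gene -> 1..k
    n_ties: int = 0


def nmf_fit(
    V: ExpressionMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> NMFModel:
    """Factorize a non-negative expression matrix at rank ``k`` (seeded)."""
    est = KLNMF(n_components=k, max_iter=max_iter, tol=tol, random_state=seed)
    est.fit(V.values.T)  # estimator is sample-major
    comps = [f"k{c}" for c in range(1, k + 1)]
    return NMFModel(
        W=pd.DataFrame(est.W_, index=V.gene_ids, columns=comps),
        H=pd.DataFrame(est.H_, index=comps, columns=V.sample_ids),
        rank=k,
        objective_trace=est.objective_trace_,
        seed=seed,
        n_iter=est.n_iter_,
    )


def assign_clusters(model: NMFModel) -> ClusterAssignment:
    """Argmax cluster membership: samples over H columns, genes over W rows.

    Ties go to the lowest cluster index (logged).
    """
    H = model.H.values
    W = model.W.values
    if (H.max(axis=0) <= _EPS * 10).any():
        bad = np.asarray(model.sample_ids)[H.max(axis=0) <= _EPS * 10][0]
        raise ValueError(f"sample {bad!r} has an all-zero H column; cannot assign")
    s_lab = H.argmax(axis=0) + 1  # argmax takes first (lowest) index on ties
    g_lab = W.argmax(axis=1) + 1
    n_ties = int(
        ((H == H.max(axis=0, keepdims=True)).sum(axis=0) > 1).sum()
        + ((W == W.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum()
    )
    if n_ties:
        logger.info("%d argmax ties broken toward the lowest cluster index", n_ties)
    return ClusterAssignment(
        sample_cluster=pd.Series(s_lab, index=model.sample_ids),
        gene_cluster=pd.Series(g_lab, index=model.gene_ids),
        n_ties=n_ties,
    )


def top_weight_genes(model: NMFModel, cluster: int, n: int = 100) -> list[str]:
    """The ``n`` genes with the largest basis weight in ``cluster`` (1-based).

    Descending weight; ties broken by lexicographic gene id.  ``n`` larger
    than the gene count is truncated with a warning.
    """
    if not (1 <= cluster <= model.rank):
        raise IndexError(f"cluster {cluster} out of range 1..{model.rank}")
    col = model.W.iloc[:, cluster - 1]
    if n > len(col):
        warnings.warn(f"n={n} exceeds {len(col)} genes; truncating")
        n = len(col)
    order = sorted(col.index, key=lambda g: (-col[g], g))
    return order[:n]


def eigenvalue(model: NMFModel, cluster: int) -> pd.Series:
    """Row ``cluster`` of H: the per-sample activity of that latent factor."""
    if not (1 <= cluster <= model.rank):
        raise IndexError(f"cluster {cluster} out of range 1..{model.rank}")
    return model.H.iloc[cluster - 1].copy()


def _consensus_from_labels(label_runs: np.ndarray) -> np.ndarray:
    """Co-assignment fraction over runs; labels shaped (n_runs, n_samples)."""
    n_runs, n = label_runs.shape
    cons = np.zeros((n, n))
    for r in range(n_runs):
        lab = label_runs[r]
        cons += (lab[:, None] == lab[None, :]).astype(float)
    return cons / n_runs


def cophenetic_correlation(consensus: np.ndarray) -> float:
    """Cophenetic correlation of average-linkage clustering of 1 - consensus."""
    d = 1.0 - consensus
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    condensed = squareform(d, checks=False)
    if np.allclose(condensed, condensed[0]):
        return 1.0  # perfectly stable (or perfectly flat) consensus
    Z = average(condensed)
    coph, _ = cophenet(Z, condensed)
    return float(coph)


def select_k(
    V: ExpressionMatrix,
    candidates: list[int],
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> tuple[int, pd.DataFrame]:
    """Survey candidate ranks by consensus stability.

    For each candidate rank, ``n_restarts`` seeded NMF fits are run, sample
    cluster labels collected, and the cophenetic correlation of the
    consensus matrix computed.  Returns the rank maximizing it plus the full
    survey table.
    """
    if not candidates:
        raise ValueError("no candidate ranks supplied")
    rows = []
    for k in candidates:
        labels = []
        for r in range(n_restarts):
            model = nmf_fit(V, k, seed=seed + 1000 * r, max_iter=max_iter, tol=tol)
            labels.append(assign_clusters(model).sample_cluster.values)
        coph = cophenetic_correlation(_consensus_from_labels(np.asarray(labels)))
        rows.append({"k": k, "cophenetic": coph})
    survey = pd.DataFrame(rows)
    best = int(survey.loc[survey["cophenetic"].idxmax(), "k"])
    return best, survey
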