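"""L2,1-regularized two-task least squares for joint gene selection.

The immune and stromal latent activities (two rows of the NMF coefficient
matrix H) are regressed jointly on the full normalized expression matrix:

    min_W  sum_t ||W_t^T X - Y_t||_F^2 + rho1 ||W||_{2,1} + rhoL2 ||W||_F^2

with ``||W||_{2,1} = sum_rows sqrt(sum_tasks w^2)``.  The row-grouped
penalty zeroes whole gene rows across both tasks at once, so the nonzero
rows are the genes carrying shared immune/stromal information.  The solver
is accelerated proximal gradient (FISTA) on the smooth part with the exact
row-wise group soft-threshold as the proximal step, backtracking line
search, W = 0 start, and restart-on-increase so the recorded objective is
non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


@dataclass
class MTLProblem:
    """Joint regression problem: X (genes n x samples s), Y (tasks m x s)."""

    X: np.ndarray
    Y: np.ndarray
    rho1: float
    rhoL2: float
    gene_ids: list[str] | None = None
    standardize_y: bool = True

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D")
        if self.X.shape[1] != self.Y.shape[1]:
            raise ValueError(
                f"X has {self.X.shape[1]} samples but Y has {self.Y.shape[1]}"
            )
        if self.rho1 < 0 or self.rhoL2 < 0:
            raise ValueError("rho1 and rhoL2 must be non-negative")
        if self.gene_ids is not None and len(self.gene_ids) != self.X.shape[0]:
            raise ValueError("gene_ids length does not match X")

    @property
    def n_genes(self) -> int:
        return self.X.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.Y.shape[0]

    def effective_y(self) -> np.ndarray:
        """Y with each task row z-scored (population SD) when requested."""
        if not self.standardize_y:
            return self.Y
        mu = self.Y.mean(axis=1, keepdims=True)
        sd = self.Y.std(axis=1, ddof=0, keepdims=True)
        if (sd == 0).any():
            raise ValueError("cannot standardize a constant Y row")
        return (self.Y - mu) / sd


@dataclass
class MTLResult:
    W: np.ndarray  # genes x tasks
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    gene_ids: list[str] | None = None


def l21_norm(W: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(W, axis=1)))


def mtl_cost(W: np.ndarray, problem: MTLProblem, Y: np.ndarray | None = None) -> float:
    """Evaluate the printed objective at W (genes x tasks)."""
    W = np.asarray(W, dtype=float)
    if W.shape != (problem.n_genes, problem.n_tasks):
        raise ValueError(
            f"W shape {W.shape} incompatible with ({problem.n_genes}, {problem.n_tasks})"
        )
    Y = problem.effective_y() if Y is None else Y
    resid = W.T @ problem.X - Y
    loss = float(np.sum(resid**2))
    return loss + problem.rho1 * l21_norm(W) + problem.rhoL2 * float(np.sum(W**2))


def prox_l21(W: np.ndarray, theta: float) -> np.ndarray:
    """Row-wise group soft-threshold: argmin_Z 1/2||Z-W||_F^2 + theta||Z||_2,1.

    Each row is scaled by max(0, 1 - theta/||row||_2); zero rows stay zero,
    so the output has exact row-group sparsity.
    """
    if theta < 0:
        raise ValueError("theta must be non-negative")
    if theta == 0:
        return W.copy()
    norms = np.linalg.norm(W, axis=1, keepdims=True)
    scale = np.where(norms > theta, 1.0 - theta / np.maximum(norms, 1e-300), 0.0)
    return W * scale


def fit_mtl(
    problem: MTLProblem,
    max_iter: int = 10_000,
    tol: float = 1e-6,
    L0: float | None = None,
) -> MTLResult:
    """Minimize the L2,1 multitask objective by accelerated proximal gradient.

    FISTA on the smooth part (least squares + Frobenius ridge) with
    ``prox_l21`` steps, backtracking line search on the Lipschitz estimate,
    W = 0 initialization, and adaptive restart whenever the objective would
    rise, which keeps the recorded trace non-increasing.  Deterministic.
    """
    X = problem.X
    Y = problem.effective_y()
    n, m = problem.n_genes, problem.n_tasks
    rho1, rhoL2 = problem.rho1, problem.rhoL2
    G = X @ X.T  # n x n Gram; n is the gene count (may be large but dense ops are fine)
    XY = X @ Y.T  # n x m

    def smooth(Wm: np.ndarray) -> float:
        resid = Wm.T @ X - Y
        return float(np.sum(resid**2)) + rhoL2 * float(np.sum(Wm**2))

    def grad(Wm: np.ndarray) -> np.ndarray:
        return 2.0 * (G @ Wm - XY) + 2.0 * rhoL2 * Wm

    W = np.zeros((n, m))
    Z = W.copy()
    t_mom = 1.0
    # modest lower bound on the Lipschitz constant; backtracking grows it
    L = L0 if L0 is not None else 2.0 * (float(np.max(np.diag(G))) + rhoL2 + 1e-12)
    cost_prev = mtl_cost(W, problem, Y=Y)
    trace = [cost_prev]
    converged = False
    backtrack_budget = 200
    for it in range(1, max_iter + 1):
        g = grad(Z)
        fz = smooth(Z)
        # backtracking: find L with f(P) <= f(Z) + <g, P-Z> + L/2 ||P-Z||^2
        for _ in range(backtrack_budget):
            P = prox_l21(Z - g / L, rho1 / L)
            diff = P - Z
            if smooth(P) <= fz + float(np.sum(g * diff)) + 0.5 * L * float(np.sum(diff**2)) + 1e-12:
                break
            L *= 2.0
        else:
            raise RuntimeError("backtracking line search exhausted; objective diverging")
        cost_new = mtl_cost(P, problem, Y=Y)
        if cost_new > cost_prev + 1e-12:
            # momentum overshoot: restart from the last accepted iterate
            t_mom = 1.0
            Z = W.copy()
            g = grad(Z)
            fz = smooth(Z)
            for _ in range(backtrack_budget):
                P = prox_l21(Z - g / L, rho1 / L)
                diff = P - Z
                if smooth(P) <= fz + float(np.sum(g * diff)) + 0.5 * L * float(np.sum(diff**2)) + 1e-12:
                    break
                L *= 2.0
            cost_new = mtl_cost(P, problem, Y=Y)
            if cost_new > cost_prev + 1e-9 * max(1.0, abs(cost_prev)):
                raise RuntimeError("objective increased beyond the backtracking budget")
            cost_new = min(cost_new, cost_prev)
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2)) / 2.0
        Z = P + ((t_mom - 1.0) / t_next) * (P - W)
        W = P
        t_mom = t_next
        trace.append(cost_new)
        if abs(cost_prev - cost_new) < tol * max(abs(cost_prev), 1e-30):
            converged = True
            cost_prev = cost_new
            break
        cost_prev = cost_new
    return MTLResult(
        W=W,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=len(trace) - 1,
        gene_ids=problem.gene_ids,
    )


def selected_genes(result: MTLResult, zero_tol: float = 1e-10) -> list[str]:
    """Genes whose coefficient row has L2 norm above ``zero_tol``.

    The prox produces exactly-zero rows, so the tolerance only guards
    accumulated floating-point noise.
    """
    norms = np.linalg.norm(result.W, axis=1)
    idx = np.flatnonzero(norms > zero_tol)
    if result.gene_ids is None:
        return [str(i) for i in idx]
    return [result.gene_ids[i] for i in idx]


def rho1_max(problem: MTLProblem) -> float:
    """Smallest rho1 at which W = 0 is optimal: 2 * max_row ||X Y^T||_2."""
    XY = problem.X @ problem.effective_y().T
    return 2.0 * float(np.max(np.linalg.norm(XY, axis=1)))


def rho1_grid(problem: MTLProblem, n: int = 10, lo_frac: float = 1e-3) -> np.ndarray:
    """Log-spaced rho1 candidates from ``lo_frac * rho1_max`` up to rho1_max."""
    hi = rho1_max(problem)
    return np.geomspace(lo_frac * hi, hi, n)


class MultiTaskL21(BaseEstimator):
    """scikit-learn style wrapper for the L2,1 multitask selector.

    ``fit(X, Y)`` follows sklearn conventions: X (n_samples, n_features),
    Y (n_samples, n_tasks).  Fitted attributes: ``coef_`` (n_features x
    n_tasks), ``objective_trace_``, ``n_iter_``.  ``get_support()`` returns
    the boolean mask of features with nonzero coefficient rows.
    """

    def __init__(self, rho1=1.0, rhoL2=0.1, max_iter=10_000, tol=1e-6, standardize_y=True):
        self.rho1 = rho1
        self.rhoL2 = rhoL2
        self.max_iter = max_iter
        self.tol = tol
        self.standardize_y = standardize_y

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        problem = MTLProblem(
            X=X.T, Y=Y.T, rho1=self.rho1, rhoL2=self.rhoL2, standardize_y=self.standardize_y
        )
        res = fit_mtl(problem, max_iter=self.max_iter, tol=self.tol)
        self.coef_ = res.W
        self.objective_trace_ = res.objective_trace
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        return self

    def get_support(self, zero_tol: float = 1e-10) -> np.ndarray:
        return np.linalg.norm(self.coef_, axis=1) > zero_tol

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.coef_
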