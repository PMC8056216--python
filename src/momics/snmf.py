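"""Signed non-negative matrix factorization (sNMF) bi-clustering.

The centered expression matrix carries signs, so it is split into stacked
positive and negative parts, Y = [max(X,0); max(-X,0)], which is then
factorized with standard Frobenius multiplicative updates. Sample clusters
come from the coefficient matrix H (after absorbing basis column norms);
signed gene-cluster associations come from recombining the two halves of
the basis matrix W.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .preprocess import NormalizedMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class FactorizationResult:
    """One multiplicative-update run from a seeded random start."""

    W: np.ndarray  # (2m, k), non-negative
    H: np.ndarray  # (k, n), non-negative
    objective_trace: list  # squared Frobenius residual per iteration
    converged: bool
    seed: object

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


@dataclass
class ConsensusResult:
    """Co-clustering frequencies across restarts plus the best restart."""

    C: np.ndarray  # (n, n) consensus
    restart_assignments: np.ndarray  # (n_restarts, n) labels
    best_restart: int
    best: FactorizationResult
    objectives: list


@dataclass
class SubtypeModel:
    """Sample cluster labels plus signed gene-cluster associations."""

    k: int
    sample_ids: list
    labels: np.ndarray  # cluster id per sample, 1..k (0 = unassigned)
    genes: pd.DataFrame  # columns: feature, cluster, loading, dominance, associated

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([self.labels[index[s]] for s in sample_ids])

    def associated_genes(self, cluster: Optional[int] = None) -> list:
        g = self.genes[self.genes["associated"]]
        if cluster is not None:
            g = g[g["cluster"] == cluster]
        return list(g["feature"])


def split_signs(X: Union[NormalizedMatrix, np.ndarray]) -> np.ndarray:
    """Stack positive and negative parts: Y = [max(X,0); max(-X,0)].

    X is recoverable exactly as ``Y[:m] - Y[m:]``.
    """
    arr = X.values if isinstance(X, NormalizedMatrix) else np.asarray(X, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite values")
    return np.vstack([np.maximum(arr, 0.0), np.maximum(-arr, 0.0)])


def factorize(
    Y: np.ndarray,
    k: int,
    seed: object = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> FactorizationResult:
    """Minimize ||Y - WH||_F^2 by Lee-Seung multiplicative updates.

    Starts from a seeded uniform(0,1) initialization and stops when the
    relative objective change drops below ``tol`` or after ``max_iter``
    iterations. The objective trace is non-increasing.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-dimensional")
    if (Y < 0).any():
        raise ValueError("Y must be non-negative")
    if not Y.any():
        raise ValueError("Y is all zero")
    m, n = Y.shape
    if not (1 <= k < min(m, n)):
        raise ValueError(f"k={k} out of range for shape {Y.shape}")
    rng = np.random.default_rng(seed)
    W = rng.uniform(size=(m, k))
    H = rng.uniform(size=(k, n))
    trace = []
    prev = np.inf
    converged = False
    for _ in range(max_iter):
        H *= (W.T @ Y) / (W.T @ W @ H + _EPS)
        W *= (Y @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = float(np.linalg.norm(Y - W @ H) ** 2)
        trace.append(obj)
        if prev < np.inf and abs(prev - obj) <= tol * max(prev, _EPS):
            converged = True
            break
        prev = obj
    return FactorizationResult(
        W=W, H=H, objective_trace=trace, converged=converged, seed=seed
    )


def assign_samples(H: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Cluster labels from H after absorbing W's column norms.

    Columns of W are scaled to unit Euclidean norm with the scale absorbed
    into the rows of H; each sample gets the argmax row of its scaled H
    column (1-based; ties go to the lowest cluster index). An all-zero
    column is labeled 0 ("unassigned").
    """
    norms = np.linalg.norm(W, axis=0)
    Hs = norms[:, None] * H
    labels = np.argmax(Hs, axis=0) + 1
    zero = ~Hs.any(axis=0)
    if zero.any():
        logger.warning("assign_samples: %d unassigned sample(s)", zero.sum())
        labels[zero] = 0
    return labels


def rescale_factors(W: np.ndarray, H: np.ndarray):
    """Unit-norm W columns with scales absorbed into H; W@H is unchanged."""
    norms = np.linalg.norm(W, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    return W / safe, H * norms[:, None]


def consensus(
    Y: np.ndarray,
    k: int,
    n_restarts: int = 50,
    base_seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> ConsensusResult:
    """Multi-restart factorization and the sample co-clustering matrix.

    ``C[i, j]`` is the fraction of restarts assigning samples i and j to the
    same (assigned) cluster; the diagonal is forced to 1. Per-restart seeds
    are derived deterministically from ``base_seed``.
    """
    if n_restarts < 2:
        raise ValueError("n_restarts must be at least 2")
    n = Y.shape[1]
    assignments = np.zeros((n_restarts, n), dtype=int)
    objectives = []
    best = None
    best_idx = -1
    for r in range(n_restarts):
        res = factorize(Y, k, seed=(base_seed, r), max_iter=max_iter, tol=tol)
        assignments[r] = assign_samples(res.H, res.W)
        objectives.append(res.objective)
        if best is None or res.objective < best.objective:
            best, best_idx = res, r
    C = np.zeros((n, n))
    for r in range(n_restarts):
        lab = assignments[r]
        same = (lab[:, None] == lab[None, :]) & (lab[:, None] > 0)
        C += same
    C /= n_restarts
    np.fill_diagonal(C, 1.0)
    return ConsensusResult(
        C=C,
        restart_assignments=assignments,
        best_restart=best_idx,
        best=best,
        objectives=objectives,
    )


def gene_associations(
    W: np.ndarray, threshold_tau: float = 0.5
) -> pd.DataFrame:
    """Signed gene-cluster loadings and association calls from a stacked W.

    For gene g and cluster c the signed loading is
    ``W[g, c] - W[g + m, c]``. The gene is associated with the cluster of
    its largest absolute loading iff that loading's dominance
    (max|loading| / sum|loadings|) reaches ``threshold_tau``.
    """
    W = np.asarray(W, float)
    if W.shape[0] % 2 != 0:
        raise ValueError("W must have an even number of rows (stacked signs)")
    m = W.shape[0] // 2
    S = W[:m] - W[m:]
    A = np.abs(S)
    tot = A.sum(axis=1)
    top = np.argmax(A, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dominance = np.where(tot > 0, A[np.arange(m), top] / tot, 0.0)
    loading = S[np.arange(m), top]
    associated = (dominance >= threshold_tau) & (tot > 0)
    return pd.DataFrame(
        {
            "cluster": top + 1,
            "loading": loading,
            "dominance": dominance,
            "associated": associated,
        }
    )


def fit_subtypes(
    X: NormalizedMatrix,
    k: int,
    n_restarts: int = 50,
    seed: int = 0,
    tau: float = 0.5,
    max_iter: int = 2000,
    tol: float = 1e-6,
):
    """End-to-end bi-clustering: split signs, consensus, best-restart model.

    Returns ``(SubtypeModel, ConsensusResult)``.
    """
    Y = split_signs(X)
    cons = consensus(
        Y, k, n_restarts=n_restarts, base_seed=seed, max_iter=max_iter, tol=tol
    )
    labels = assign_samples(cons.best.H, cons.best.W)
    genes = gene_associations(cons.best.W, threshold_tau=tau)
    genes.insert(0, "feature", X.feature_ids)
    model = SubtypeModel(
        k=k, sample_ids=list(X.sample_ids), labels=labels, genes=genes
    )
    return model, cons
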