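"""Rank selection for the sNMF bi-clustering.

Seven quality metrics (cophenetic, dispersion, explained variance,
residuals, RSS, silhouette, sparseness) are computed for each candidate
cluster number on both the real data and a randomized negative control in
which every feature row is independently permuted across samples. The
chosen rank maximizes the real-data cophenetic coefficient among candidates
that beat the control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score as _sk_silhouette

from .preprocess import NormalizedMatrix
from .snmf import (
    FactorizationResult,
    assign_samples,
    consensus,
    split_signs,
)

METRIC_NAMES = (
    "cophenetic",
    "dispersion",
    "evar",
    "residuals",
    "rss",
    "silhouette",
    "sparseness",
)


class NoStructureError(RuntimeError):
    """No candidate rank beat the randomized negative control.

    Carries the full metrics table as ``.table``.
    """

    def __init__(self, message: str, table: pd.DataFrame):
        super().__init__(message)
        self.table = table


def _validate_consensus(C: np.ndarray) -> np.ndarray:
    C = np.asarray(C, float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("consensus matrix must be square")
    if not np.allclose(C, C.T, atol=1e-9):
        raise ValueError("consensus matrix must be symmetric")
    if (C < -1e-9).any() or (C > 1 + 1e-9).any():
        raise ValueError("consensus entries must lie in [0, 1]")
    return C


def cophenetic_coefficient(C: np.ndarray) -> float:
    """Correlation between consensus distances and their dendrogram.

    Pearson correlation between the condensed entries of ``1 - C`` and the
    cophenetic distances of their average-linkage hierarchical clustering.
    Returns NaN (undefined) when either vector is constant.
    """
    C = _validate_consensus(C)
    n = C.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    d = squareform(np.clip(D, 0.0, None), checks=False)
    Z = linkage(d, method="average")
    coph = cophenet(Z)
    if np.std(d) < 1e-15 or np.std(coph) < 1e-15:
        return float("nan")
    return float(np.corrcoef(d, coph)[0, 1])


def dispersion_coefficient(C: np.ndarray) -> float:
    """Mean of 4*(C - 0.5)^2: 1 for a binary consensus, 0 for all-0.5."""
    C = _validate_consensus(C)
    return float(np.mean(4.0 * (C - 0.5) ** 2))


def evar_rss_residuals(
    result: FactorizationResult, Y: np.ndarray
) -> Tuple[float, float, float]:
    """Explained variance, squared Frobenius residual, and the final
    objective-trace entry (equal to RSS under the Frobenius objective)."""
    Y = np.asarray(Y, float)
    rss = float(np.linalg.norm(Y - result.W @ result.H) ** 2)
    total = float(np.linalg.norm(Y) ** 2)
    evar = 1.0 - rss / total
    residuals = float(result.objective_trace[-1])
    return evar, rss, residuals


def silhouette_from_consensus(C: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width using distance 1 - C."""
    C = _validate_consensus(C)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    D = np.clip(1.0 - C, 0.0, None)
    np.fill_diagonal(D, 0.0)
    return float(_sk_silhouette(D, labels, metric="precomputed"))


def sparseness_hoyer(v: np.ndarray) -> float:
    """Hoyer sparseness (sqrt(n) - L1/L2) / (sqrt(n) - 1), in [0, 1]."""
    v = np.asarray(v, float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 entries")
    l2 = np.linalg.norm(v)
    if l2 == 0:
        raise ValueError("zero vector has undefined sparseness")
    l1 = np.abs(v).sum()
    rn = np.sqrt(v.size)
    return float((rn - l1 / l2) / (rn - 1.0))


def matrix_sparseness(W: np.ndarray) -> float:
    """Mean Hoyer sparseness over the columns of W (zero columns skipped)."""
    W = np.asarray(W, float)
    vals = [
        sparseness_hoyer(W[:, j])
        for j in range(W.shape[1])
        if np.linalg.norm(W[:, j]) > 0
    ]
    if not vals:
        raise ValueError("all columns are zero")
    return float(np.mean(vals))


def randomize_matrix(X: NormalizedMatrix, seed: int = 0) -> NormalizedMatrix:
    """Negative control: permute each feature row independently across
    samples, preserving every row's multiset of values exactly."""
    rng = np.random.default_rng(seed)
    vals = np.empty_like(X.values)
    for i in range(X.values.shape[0]):
        vals[i] = X.values[i, rng.permutation(X.values.shape[1])]
    prov = dict(X.provenance)
    prov["randomized_seed"] = seed
    return NormalizedMatrix(
        feature_ids=list(X.feature_ids),
        sample_ids=list(X.sample_ids),
        values=vals,
        provenance=prov,
    )


def _metrics_row(Y: np.ndarray, k: int, n_restarts, base_seed, max_iter, tol):
    cons = consensus(
        Y, k, n_restarts=n_restarts, base_seed=base_seed,
        max_iter=max_iter, tol=tol,
    )
    labels = assign_samples(cons.best.H, cons.best.W)
    evar, rss, residuals = evar_rss_residuals(cons.best, Y)
    try:
        sil = silhouette_from_consensus(cons.C, labels)
    except ValueError:
        sil = float("nan")
    try:
        coph = cophenetic_coefficient(cons.C)
    except ValueError:
        coph = float("nan")
    return {
        "cophenetic": coph,
        "dispersion": dispersion_coefficient(cons.C),
        "evar": evar,
        "residuals": residuals,
        "rss": rss,
        "silhouette": sil,
        "sparseness": matrix_sparseness(cons.best.W),
    }


def quality_metrics(
    X: NormalizedMatrix,
    k_range=(2, 6),
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """The seven metrics per k for real data and the randomized control."""
    lo, hi = int(k_range[0]), int(k_range[1])
    n = X.n_samples
    if lo < 2 or hi >= min(2 * X.n_features, n):
        raise ValueError(f"k range [{lo}, {hi}] out of bounds")
    Y_real = split_signs(X)
    Y_rand = split_signs(randomize_matrix(X, seed=seed))
    rows = []
    for k in range(lo, hi + 1):
        for cond, Y in (("real", Y_real), ("randomized", Y_rand)):
            row = _metrics_row(
                Y, k, n_restarts,
                base_seed=hash((seed, k, cond)) % (2**31),
                max_iter=max_iter, tol=tol,
            )
            row.update({"k": k, "condition": cond})
            rows.append(row)
    return pd.DataFrame(rows)[["k", "condition", *METRIC_NAMES]]


def select_k(
    X: NormalizedMatrix,
    k_range=(2, 6),
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> Tuple[int, pd.DataFrame]:
    """Choose the cluster number from the metrics table.

    Eligible k have real-data cophenetic strictly above the randomized
    control's. Among those, pick the highest real cophenetic; break ties by
    higher dispersion, then smaller k. Raises :class:`NoStructureError`
    (carrying the table) when no k is eligible.
    """
    table = quality_metrics(
        X, k_range=k_range, n_restarts=n_restarts, seed=seed,
        max_iter=max_iter, tol=tol,
    )
    real = table[table.condition == "real"].set_index("k")
    rand = table[table.condition == "randomized"].set_index("k")
    candidates = []
    for k in real.index:
        c_real = real.loc[k, "cophenetic"]
        c_rand = rand.loc[k, "cophenetic"]
        if np.isfinite(c_real) and (not np.isfinite(c_rand) or c_real > c_rand):
            candidates.append(
                (-c_real, -real.loc[k, "dispersion"], k)
            )
    if not candidates:
        raise NoStructureError(
            "no candidate k beat the randomized negative control", table
        )
    candidates.sort()
    return int(candidates[0][2]), table
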