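"""Low-detection filtering and per-feature normalization for omics layers.

Each layer (RNA FPKM-UQ, protein LC-MS/MS intensity, metabolite
concentration) is handled identically: features undetected in more than half
the samples are discarded, then each surviving feature row is
log-transformed, mean-centered, and scaled by its root mean square
(population convention, divisor n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_LAYERS = ("rna", "protein", "metabolite")


class EmptyResultError(ValueError):
    """Raised when a filter removes every feature."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class OmicsMatrix:
    """Feature x sample abundance matrix with a detection mask.

    Parameters
    ----------
    feature_ids, sample_ids : sequences of unique identifiers.
    values : array of shape (n_features, n_samples); non-negative
        abundances. NaN encodes a missing (undetected) measurement.
    layer : one of ``rna``, ``protein``, ``metabolite``.
    detected : optional boolean mask congruent with ``values``. When
        omitted, an entry is detected iff it is finite and strictly
        positive.
    """

    feature_ids: list
    sample_ids: list
    values: np.ndarray
    layer: str = "rna"
    detected: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        m, n = self.values.shape
        if len(self.feature_ids) != m:
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {m} rows"
            )
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n} columns"
            )
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.layer not in VALID_LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.detected is None:
            self.detected = np.isfinite(self.values) & (self.values > 0)
        else:
            self.detected = np.asarray(self.detected, dtype=bool)
            if self.detected.shape != self.values.shape:
                raise ValueError("detected mask shape mismatch")
        # detected entries must be finite; undetected must be 0 or missing
        bad = self.detected & ~np.isfinite(self.values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "non-finite detected value at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        undet = ~self.detected
        bad = undet & np.isfinite(self.values) & (self.values != 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                "undetected entry with non-zero value at feature "
                f"{self.feature_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_features(self, keep: np.ndarray) -> "OmicsMatrix":
        keep = np.asarray(keep)
        return OmicsMatrix(
            feature_ids=[self.feature_ids[i] for i in np.flatnonzero(keep)]
            if keep.dtype == bool
            else [self.feature_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            values=self.values[keep],
            layer=self.layer,
            detected=self.detected[keep],
        )


@dataclass
class NormalizedMatrix:
    """Unit-free normalized matrix: per-feature mean 0, RMS 1.

    ``provenance`` records the filter and transform parameters applied so
    that every downstream artifact can echo them.
    """

    feature_ids: list
    sample_ids: list
    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("shape mismatch")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def filter_low_detected(matrix: OmicsMatrix) -> OmicsMatrix:
    """Drop features undetected in more than half the samples.

    A feature survives iff its undetected-sample count is <= n/2 (strictly
    more than half undetected is discarded; exactly half survives). Feature
    order is preserved.
    """
    if matrix.n_features == 0 or matrix.n_samples == 0:
        raise ValueError("empty matrix")
    n = matrix.n_samples
    undetected = (~matrix.detected).sum(axis=1)
    keep = undetected <= n / 2.0
    if not keep.any():
        raise EmptyResultError(
            "no feature detected in at least half the samples"
        )
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "filter_low_detected[%s]: dropped %d/%d features",
            matrix.layer,
            n_dropped,
            matrix.n_features,
        )
    return matrix.subset_features(keep)


def default_pseudocount(matrix: OmicsMatrix) -> float:
    """Layer-appropriate pseudocount: 1 for RNA, half the smallest positive
    detected value for protein/metabolite layers."""
    if matrix.layer == "rna":
        return 1.0
    pos = matrix.values[matrix.detected & (matrix.values > 0)]
    if pos.size == 0:
        raise ValueError("no positive detected values in matrix")
    return float(pos.min()) / 2.0


def center_scale(values: np.ndarray) -> np.ndarray:
    """Mean-center each row and divide by its root mean square (divisor n).

    This is the transform applied after the log step; it is idempotent (a
    row that is already mean 0 / RMS 1 is unchanged). Constant rows are
    returned as-is (the caller decides whether to drop them).
    """
    values = np.asarray(values, float)
    centered = values - values.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(centered**2, axis=1))
    safe = np.where(rms > 1e-12, rms, 1.0)
    return centered / safe[:, None]


def normalize(
    matrix: OmicsMatrix,
    log_base: float = 2.0,
    pseudocount: Optional[float] = None,
) -> NormalizedMatrix:
    """Log-transform, center, and RMS-scale each feature row.

    Each row becomes ``log(value + pseudocount)`` (undetected entries count
    as 0), minus its mean, divided by its root mean square with divisor n.
    Constant rows cannot be scaled and are dropped with a warning.
    """
    if pseudocount is None:
        pseudocount = default_pseudocount(matrix)
    if log_base <= 1.0:
        raise ValueError("log_base must exceed 1")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    vals = np.where(matrix.detected, matrix.values, 0.0)
    if (vals < 0).any():
        i, j = np.argwhere(vals < 0)[0]
        raise ValueError(
            f"negative value at feature {matrix.feature_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}"
        )
    logged = np.log(vals + pseudocount) / np.log(log_base)
    centered = logged - logged.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(centered**2, axis=1))
    scaled = center_scale(logged)
    keep = rms > 1e-12
    dropped = [matrix.feature_ids[i] for i in np.flatnonzero(~keep)]
    if dropped:
        logger.warning(
            "normalize[%s]: dropped %d constant feature(s): %s%s",
            matrix.layer,
            len(dropped),
            ", ".join(dropped[:5]),
            "..." if len(dropped) > 5 else "",
        )
    if not keep.any():
        raise EmptyResultError("all features constant after log transform")
    out = scaled[keep]
    return NormalizedMatrix(
        feature_ids=[matrix.feature_ids[i] for i in np.flatnonzero(keep)],
        sample_ids=list(matrix.sample_ids),
        values=out,
        provenance={
            "layer": matrix.layer,
            "log_base": log_base,
            "pseudocount": pseudocount,
            "dropped_constant": dropped,
        },
    )
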