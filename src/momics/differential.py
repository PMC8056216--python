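"""Empirical-Bayes moderated two-group differential analysis.

Per-feature variances are shrunk toward a prior variance whose degrees of
freedom and scale are estimated by matching moments of log sample variances
to a scaled F distribution; the moderated t-statistic then uses the
posterior variance and d0 + d_g degrees of freedom. Multiple testing is
controlled with Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm as normal_dist
from scipy.stats import t as t_dist

from .preprocess import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class IndicatorDefinition:
    """Derived metabolite feature: sum(numerator) / sum(denominator)."""

    name: str
    numerator: List[str]
    denominator: List[str]

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise ValueError(
                f"indicator {self.name!r}: numerator and denominator "
                "must be non-empty"
            )


@dataclass
class EBayesPrior:
    """Prior degrees of freedom (possibly infinite) and prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not (self.d0 > 0):
            raise ValueError("d0 must be positive")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be positive")

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.d0)


def compute_indicators(
    metabolites: OmicsMatrix, defs: Sequence[IndicatorDefinition]
) -> OmicsMatrix:
    """Append ratio indicators computed on raw (pre-log) concentrations.

    Per sample, indicator = sum(numerator values) / sum(denominator
    values). A zero denominator yields a missing value for that sample
    (logged). Unresolvable metabolite names raise with the offending name.
    """
    index = {f: i for i, f in enumerate(metabolites.feature_ids)}
    vals = np.where(metabolites.detected, metabolites.values, np.nan)
    rows = []
    for d in defs:
        for name in list(d.numerator) + list(d.denominator):
            if name not in index:
                raise KeyError(
                    f"indicator {d.name!r} references unknown metabolite "
                    f"{name!r}"
                )
        num = np.nansum(
            [vals[index[m]] for m in d.numerator], axis=0
        )
        den = np.nansum(
            [vals[index[m]] for m in d.denominator], axis=0
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(den > 0, num / den, np.nan)
        n_zero = int((~(den > 0)).sum())
        if n_zero:
            logger.warning(
                "indicator %s: zero denominator in %d sample(s)",
                d.name,
                n_zero,
            )
        rows.append(ratio)
    base = np.where(metabolites.detected, metabolites.values, np.nan)
    new_vals = np.vstack([base] + rows) if rows else base
    feature_ids = metabolites.feature_ids + [d.name for d in defs]
    return OmicsMatrix(
        feature_ids=feature_ids,
        sample_ids=list(metabolites.sample_ids),
        values=new_vals,
        layer=metabolites.layer,
        detected=np.isfinite(new_vals) & (new_vals > 0),
    )


def trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("y must be positive")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def fit_ebayes_prior(variances, d_g) -> EBayesPrior:
    """Estimate (d0, s0^2) from per-feature sample variances.

    Moment-matching on z = log(s^2): the excess of the empirical variance
    of z over the trigamma term attributable to the residual degrees of
    freedom identifies trigamma(d0/2); the mean equation then gives s0^2.
    When the empirical spread does not exceed the theoretical minimum, d0
    is infinite and s0^2 is the (bias-corrected) geometric mean.
    """
    s2 = np.asarray(variances, float)
    d = np.broadcast_to(np.asarray(d_g, float), s2.shape).copy()
    ok = np.isfinite(s2) & (s2 > 0) & (d >= 1)
    if ok.sum() < 2:
        raise ValueError("need at least 2 positive variances")
    s2, d = s2[ok], d[ok]
    e = np.log(s2) - digamma(d / 2.0) + np.log(d / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1))
    if evar < 1e-12:
        # no spread at all: the common variance is the only sensible prior
        return EBayesPrior(
            d0=float("inf"), s0_sq=float(np.exp(np.mean(np.log(s2))))
        )
    excess = evar - float(np.mean(polygamma(1, d / 2.0)))
    if excess <= 0:
        return EBayesPrior(d0=float("inf"), s0_sq=float(np.exp(emean)))
    d0 = 2.0 * trigamma_inverse(excess)
    s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR: fdr_(i) = min_{j>=i} p_(j) m / j."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    fdr_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = np.minimum(fdr_sorted, 1.0)
    return fdr


def moderated_t_test(
    values: np.ndarray,
    groups,
    prior: Optional[EBayesPrior] = None,
    feature_ids: Optional[Sequence[str]] = None,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Moderated two-group t-test per feature.

    Parameters
    ----------
    values : (features x samples) matrix on a log or normalized scale; NaN
        entries are treated as missing (available-case analysis).
    groups : length-n labels with exactly two levels; log_fc is the second
        level's mean minus the first's (levels ordered by first appearance).
    prior : optional pre-fitted prior; fitted from the data when omitted.

    Returns a DataFrame with columns feature, log_fc, t, p_value, fdr,
    significant.
    """
    X = np.asarray(values, float)
    groups = np.asarray(groups)
    if X.shape[1] != groups.size:
        raise ValueError("groups length must match sample count")
    levels = list(dict.fromkeys(groups.tolist()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    g1 = groups == levels[0]
    g2 = groups == levels[1]
    if g1.sum() < 2 or g2.sum() < 2:
        raise ValueError("each group needs at least 2 samples")

    def _group_stats(mask):
        sub = X[:, mask]
        n = np.isfinite(sub).sum(axis=1).astype(float)
        mean = np.nanmean(np.where(np.isfinite(sub), sub, np.nan), axis=1)
        ss = np.nansum((sub - mean[:, None]) ** 2, axis=1)
        return n, mean, ss

    with np.errstate(invalid="ignore"):
        n1, m1, ss1 = _group_stats(g1)
        n2, m2, ss2 = _group_stats(g2)
    d_g = n1 + n2 - 2
    valid = (n1 >= 2) & (n2 >= 2)
    log_fc = m2 - m1
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(valid & (d_g > 0), (ss1 + ss2) / d_g, np.nan)
    if prior is None:
        prior = fit_ebayes_prior(s2[valid & (s2 > 0)], d_g[valid & (s2 > 0)])
    if prior.is_infinite:
        s2_post = np.full_like(s2, prior.s0_sq)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (prior.d0 * prior.s0_sq + d_g * s2) / (prior.d0 + d_g)
        # features with zero sample variance still get the prior component
        s2_post = np.where(
            np.isfinite(s2), s2_post,
            prior.d0 * prior.s0_sq / (prior.d0 + d_g),
        )
        df_total = prior.d0 + d_g
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = log_fc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    p = np.full(X.shape[0], np.nan)
    fin = valid & np.isfinite(t_mod)
    if np.isscalar(df_total) or np.ndim(df_total) == 0:
        df_arr = np.full(X.shape[0], float(df_total))
    else:
        df_arr = np.asarray(df_total, float)
    inf_df = ~np.isfinite(df_arr)
    use_t = fin & ~inf_df
    use_n = fin & inf_df
    p[use_t] = 2.0 * t_dist.sf(np.abs(t_mod[use_t]), df_arr[use_t])
    p[use_n] = 2.0 * normal_dist.sf(np.abs(t_mod[use_n]))
    fdr = np.full(X.shape[0], np.nan)
    has_p = np.isfinite(p)
    fdr[has_p] = bh_adjust(p[has_p])
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(X.shape[0])]
    return pd.DataFrame(
        {
            "feature": list(feature_ids),
            "log_fc": log_fc,
            "t": np.where(fin, t_mod, np.nan),
            "p_value": p,
            "fdr": fdr,
            "significant": np.where(np.isfinite(fdr), fdr <= fdr_threshold, False),
        }
    )
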