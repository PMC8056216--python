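"""Non-parametric survival analysis: Kaplan-Meier and log-rank.

Implements the product-limit estimator with Greenwood variance and
log(-log)-transformed 95% confidence bounds, the standard two-group
log-rank test, and subtype-level comparisons for the overall-survival (os)
and distant-brain-failure (dbf) endpoints.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .snmf import SubtypeModel

CLINICAL_COLUMNS = (
    "sample_id",
    "os_time",
    "os_event",
    "dbf_time",
    "dbf_event",
    "primary_site",
)

_Z95 = 1.959963984540054


@dataclass
class ClinicalTable:
    """Per-patient clinical endpoints.

    Wraps a DataFrame with columns sample_id, os_time, os_event, dbf_time,
    dbf_event, primary_site (extra covariate columns are allowed).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"clinical table missing columns: {missing}")
        df = self.data.reset_index(drop=True)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        for col in ("os_time", "dbf_time"):
            if (df[col] < 0).any():
                raise ValueError(f"negative {col}")
        for col in ("os_event", "dbf_event"):
            if not df[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be 0/1")
        self.data = df

    @property
    def sample_ids(self) -> list:
        return list(self.data["sample_id"])

    def endpoint(self, which: str) -> Tuple[np.ndarray, np.ndarray]:
        """(times, events) arrays for endpoint 'os' or 'dbf'."""
        if which not in ("os", "dbf"):
            raise ValueError(f"unknown endpoint {which!r}")
        return (
            self.data[f"{which}_time"].to_numpy(float),
            self.data[f"{which}_event"].to_numpy(int),
        )


@dataclass
class SurvivalCurve:
    """Kaplan-Meier estimate with Greenwood standard errors."""

    event_times: np.ndarray  # sorted distinct times with >= 1 event
    survival: np.ndarray  # S(t) immediately after each event time
    greenwood_se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float  # NaN if S never reaches 0.5
    n_subjects: int = 0

    @property
    def median_defined(self) -> bool:
        return math.isfinite(self.median)


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    df: int = 1
    defined: bool = True


@dataclass
class SubtypeComparison:
    """Per-subtype curves plus the headline two-largest-subtype test."""

    endpoint: str
    curves: Dict[int, SurvivalCurve]
    group_sizes: Dict[int, int]
    largest_pair: Tuple[int, int]
    test: LogRankResult
    pairwise: Dict[Tuple[int, int], LogRankResult] = field(default_factory=dict)


def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit estimator.

    At tied times events precede censorings (a subject censored at t is
    still at risk for the events at t). 95% CI uses the log(-log S)
    transform, so the bounds stay inside [0, 1].
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if (times < 0).any():
        raise ValueError("negative survival time")
    if times.shape != events.shape:
        raise ValueError("times/events length mismatch")
    distinct = np.unique(times[events == 1])
    S = 1.0
    gw = 0.0  # running Greenwood sum d / (n (n - d))
    surv, se, lo, hi = [], [], [], []
    median = float("nan")
    for t in distinct:
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        S *= 1.0 - d / n_risk
        if n_risk > d:
            gw += d / (n_risk * (n_risk - d))
            se_t = S * math.sqrt(gw)
        else:
            gw = float("inf")
            se_t = 0.0  # S = 0 exactly
        surv.append(S)
        se.append(se_t)
        if 0.0 < S < 1.0 and math.isfinite(gw):
            se_theta = math.sqrt(gw) / abs(math.log(S))
            lo.append(S ** math.exp(_Z95 * se_theta))
            hi.append(S ** math.exp(-_Z95 * se_theta))
        else:
            lo.append(S)
            hi.append(S)
        if math.isnan(median) and S <= 0.5:
            median = float(t)
    return SurvivalCurve(
        event_times=distinct,
        survival=np.array(surv),
        greenwood_se=np.array(se),
        ci_lower=np.array(lo),
        ci_upper=np.array(hi),
        median=median,
        n_subjects=int(times.size),
    )


def survival_at(curve: SurvivalCurve, t: float):
    """Right-continuous step evaluation of S(t) with its 95% CI."""
    if t < 0:
        raise ValueError("t must be non-negative")
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return 1.0, (1.0, 1.0)
    return (
        float(curve.survival[idx]),
        (float(curve.ci_lower[idx]), float(curve.ci_upper[idx])),
    )


def log_rank(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Standard two-group log-rank test (chi-square with 1 df).

    Sums observed-minus-expected events for group A over the shared risk
    sets and divides the square by the summed hypergeometric variances. A
    zero total variance yields an undefined-flagged result.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    all_t = np.concatenate([ta, tb])
    all_e = np.concatenate([ea, eb])
    if all_e.sum() == 0:
        raise ValueError("need at least one event overall")
    U = 0.0
    V = 0.0
    for t in np.unique(all_t[all_e == 1]):
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        n = n1 + n2
        d1 = int(((ta == t) & (ea == 1)).sum())
        d2 = int(((tb == t) & (eb == 1)).sum())
        d = d1 + d2
        U += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if V <= 0:
        return LogRankResult(
            chi_square=float("nan"), p_value=float("nan"), defined=False
        )
    chi = U * U / V
    return LogRankResult(chi_square=float(chi), p_value=float(chi2.sf(chi, 1)))


def compare_subtypes(
    model: SubtypeModel,
    clinical: ClinicalTable,
    endpoint: str = "os",
    bonferroni: bool = False,
) -> SubtypeComparison:
    """KM curves per subtype and log-rank on the two largest subtypes.

    Labels are joined to clinical rows by sample id (unassigned label 0 is
    excluded). Pairwise tests for every subtype pair are included; the
    headline test is for the two largest subtypes (ties broken toward the
    lower label). With ``bonferroni=True`` pairwise p-values are multiplied
    by the number of pairs (capped at 1).
    """
    label_map = dict(zip(model.sample_ids, model.labels))
    df = clinical.data[clinical.data["sample_id"].isin(label_map)].copy()
    if df.empty:
        raise ValueError("no overlap between subtype model and clinical ids")
    df["subtype"] = df["sample_id"].map(label_map)
    df = df[df["subtype"] > 0]
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    if endpoint not in ("os", "dbf"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    groups = {}
    for lab, sub in df.groupby("subtype"):
        groups[int(lab)] = (
            sub[tcol].to_numpy(float),
            sub[ecol].to_numpy(int),
        )
    if len(groups) < 2:
        raise ValueError("need at least 2 subtypes with subjects")
    curves = {lab: kaplan_meier(t, e) for lab, (t, e) in groups.items()}
    sizes = {lab: len(t) for lab, (t, e) in groups.items()}
    order = sorted(sizes, key=lambda lab: (-sizes[lab], lab))
    a, b = order[0], order[1]
    pairwise = {}
    pairs = list(itertools.combinations(sorted(groups), 2))
    for x, y in pairs:
        try:
            res = log_rank(*groups[x], *groups[y])
        except ValueError:
            res = LogRankResult(float("nan"), float("nan"), defined=False)
        if bonferroni and res.defined:
            res = LogRankResult(
                res.chi_square, min(1.0, res.p_value * len(pairs)), res.df
            )
        pairwise[(x, y)] = res
    key = (min(a, b), max(a, b))
    return SubtypeComparison(
        endpoint=endpoint,
        curves=curves,
        group_sizes=sizes,
        largest_pair=key,
        test=pairwise[key],
        pairwise=pairwise,
    )
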