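"""Synthetic multi-omics cohort generator.

Produces a patient cohort with three overlapping omics layers (RNA,
protein, metabolite), planted transcriptomic sample clusters with
cluster-specific signed signature-gene blocks, attenuated correlated
protein signals, metabolite panels with planted log-fold-changes, and
subtype-dependent exponential survival with censoring — the statistical
structure every downstream stage assumes, with full ground truth retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .preprocess import OmicsMatrix
from .survival import ClinicalTable

LN2 = math.log(2.0)

#: planted log2 fold changes for the leading metabolites (high-contrast
#: subtype minus the reference subtype)
DEFAULT_METABOLITE_LOGFC = (
    1.33, -0.70, 0.82, 0.77, -1.03, -0.62, -0.94,
    1.02, -0.76, 0.83, 0.54, 0.55, -1.71, -0.89,
)

PRIMARY_SITES = ("lung", "breast", "melanoma", "other")
PRIMARY_SITE_PROBS = (0.47, 0.21, 0.18, 0.14)


class OverlapInfeasibleError(ValueError):
    """No layer-membership assignment satisfies the configured counts."""


@dataclass
class SyntheticConfig:
    """Parameters of the generated cohort. Defaults mirror a ~78-patient
    three-layer design with a 17-patient triple overlap."""

    n_patients: int = 78
    cohort_sizes: Tuple[int, int, int] = (46, 64, 41)  # (rna, protein, metabolite)
    triple_overlap: int = 17
    n_genes: int = 2000
    k_true: int = 4
    signature_size: int = 100
    effect_size: float = 2.0
    noise_sd: float = 1.0
    protein_attenuation: float = 0.5
    n_proteins: int = 500
    n_metabolites: int = 180
    survival_medians: Tuple[float, ...] = (7.89, 42.27, 12.0, 20.0)
    dbf_median_factor: float = 0.7
    censor_rate: float = 0.25
    metabolite_logfc: Tuple[float, ...] = DEFAULT_METABOLITE_LOGFC
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if any(s > self.n_patients for s in self.cohort_sizes):
            raise ValueError("cohort sizes cannot exceed n_patients")
        if not (0 <= self.triple_overlap <= min(self.cohort_sizes)):
            raise ValueError("triple_overlap must be <= min cohort size")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.censor_rate < 1.0):
            raise ValueError("censor_rate must lie in [0, 1)")
        if not (0.0 <= self.protein_attenuation <= 1.0):
            raise ValueError("protein_attenuation must lie in [0, 1]")
        if self.k_true < 1:
            raise ValueError("k_true must be positive")
        if len(self.survival_medians) < self.k_true:
            raise ValueError("need a survival median per subtype")
        if any(m <= 0 for m in self.survival_medians):
            raise ValueError("survival medians must be positive")
        if self.k_true * self.signature_size > self.n_genes:
            raise ValueError("signature blocks exceed n_genes")
        if len(self.metabolite_logfc) > self.n_metabolites:
            raise ValueError("more planted logFCs than metabolites")


@dataclass
class SyntheticCohort:
    """Generated layers, clinical table, and complete planted truth."""

    config: SyntheticConfig
    rna: OmicsMatrix
    protein: OmicsMatrix
    metabolite: OmicsMatrix
    clinical: ClinicalTable
    truth: dict = field(default_factory=dict)

    @property
    def layers(self) -> Dict[str, OmicsMatrix]:
        return {
            "rna": self.rna,
            "protein": self.protein,
            "metabolite": self.metabolite,
        }

    def memberships(self) -> Dict[str, set]:
        return {name: set(m.sample_ids) for name, m in self.layers.items()}


def solve_overlap_design(
    sizes: Tuple[int, int, int], n_patients: int, triple: int
) -> Dict[str, int]:
    """Region counts for a 3-set Venn design from marginal constraints.

    Requires union == n_patients (every patient has >= 1 layer). Pairwise
    intersections follow from inclusion-exclusion; the pairwise-only mass
    is distributed as evenly as feasibility (non-negative exclusive
    regions) allows, ties resolved lexicographically.
    """
    a, b, c = sizes
    pair_total = a + b + c - n_patients + triple  # sum of pairwise intersections
    pair_only_total = pair_total - 3 * triple
    if pair_only_total < 0 or pair_total < 0:
        raise OverlapInfeasibleError(
            f"sizes {sizes} with union {n_patients} and triple {triple} "
            "violate inclusion-exclusion"
        )
    best = None
    for ab in range(pair_only_total + 1):
        for ac in range(pair_only_total - ab + 1):
            bc = pair_only_total - ab - ac
            a_only = a - triple - ab - ac
            b_only = b - triple - ab - bc
            c_only = c - triple - ac - bc
            if min(a_only, b_only, c_only) < 0:
                continue
            spread = max(ab, ac, bc) - min(ab, ac, bc)
            key = (spread, ab, ac, bc)
            if best is None or key < best[0]:
                best = (key, dict(
                    abc=triple, ab=ab, ac=ac, bc=bc,
                    a=a_only, b=b_only, c=c_only,
                ))
    if best is None:
        raise OverlapInfeasibleError(
            f"no non-negative region assignment for sizes {sizes}, "
            f"union {n_patients}, triple {triple}"
        )
    return best[1]


def _layer_members(design: Dict[str, int], patient_ids) -> Dict[str, list]:
    """Assign patients to Venn regions in a fixed deterministic order."""
    order = ["abc", "ab", "ac", "bc", "a", "b", "c"]
    in_a = {"abc", "ab", "ac", "a"}
    in_b = {"abc", "ab", "bc", "b"}
    in_c = {"abc", "ac", "bc", "c"}
    members = {"rna": [], "protein": [], "metabolite": []}
    pos = 0
    for region in order:
        for _ in range(design[region]):
            pid = patient_ids[pos]
            pos += 1
            if region in in_a:
                members["rna"].append(pid)
            if region in in_b:
                members["protein"].append(pid)
            if region in in_c:
                members["metabolite"].append(pid)
    return members


def simulate_survival_times(
    median: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Exponential event times with the given median (rate ln2 / median)."""
    if median <= 0:
        raise ValueError("median must be positive")
    return rng.exponential(scale=median / LN2, size=n)


def _censor(
    times: np.ndarray,
    censor_rate: float,
    horizon: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Independent uniform censoring on [0, horizon] applied to a
    Bernoulli(censor_rate) subset of subjects."""
    n = times.size
    sel = rng.random(n) < censor_rate
    cens = rng.uniform(0.0, horizon, size=n)
    obs = np.where(sel, np.minimum(times, cens), times)
    event = np.where(sel & (cens < times), 0, 1)
    return obs, event


def generate_cohort(config: Optional[SyntheticConfig] = None) -> SyntheticCohort:
    """Generate a full multi-omics cohort; deterministic given the seed."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    patients = [f"P{i + 1:03d}" for i in range(cfg.n_patients)]

    design = solve_overlap_design(
        cfg.cohort_sizes, cfg.n_patients, cfg.triple_overlap
    )
    members = _layer_members(design, patients)

    # planted subtypes: balanced assignment over a seeded permutation
    perm = rng.permutation(cfg.n_patients)
    subtype = np.zeros(cfg.n_patients, dtype=int)
    for rank, idx in enumerate(perm):
        subtype[idx] = rank % cfg.k_true + 1
    subtype_of = dict(zip(patients, subtype))

    # signature blocks: k_true disjoint blocks, alternating signs inside
    gene_ids = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    sig_cluster = np.zeros(cfg.n_genes, dtype=int)
    sig_sign = np.zeros(cfg.n_genes, dtype=int)
    for c in range(cfg.k_true):
        block = slice(c * cfg.signature_size, (c + 1) * cfg.signature_size)
        sig_cluster[block] = c + 1
        signs = np.ones(cfg.signature_size, dtype=int)
        signs[1::2] = -1
        sig_sign[block] = signs

    # RNA layer: log-normal baseline with signed shifts in own-cluster samples
    rna_samples = members["rna"]
    rna_sub = np.array([subtype_of[s] for s in rna_samples])
    base_mu = rng.normal(5.0, 1.0, size=cfg.n_genes)
    log_rna = base_mu[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_genes, len(rna_samples))
    )
    shift = (
        (sig_cluster[:, None] == rna_sub[None, :])
        * sig_sign[:, None]
        * cfg.effect_size
    )
    log_rna = log_rna + shift
    rna = OmicsMatrix(
        feature_ids=gene_ids,
        sample_ids=rna_samples,
        values=np.exp2(log_rna),
        layer="rna",
    )

    # protein layer: the first proteins mirror signature genes with an
    # attenuated shift; the rest are independent noise
    prot_samples = members["protein"]
    prot_sub = np.array([subtype_of[s] for s in prot_samples])
    prot_ids = [f"PR{i + 1:04d}" for i in range(cfg.n_proteins)]
    n_linked = min(cfg.n_proteins, cfg.k_true * cfg.signature_size)
    prot_mu = rng.normal(20.0, 1.0, size=cfg.n_proteins)
    log_prot = prot_mu[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_proteins, len(prot_samples))
    )
    pshift = (
        (sig_cluster[:n_linked, None] == prot_sub[None, :])
        * sig_sign[:n_linked, None]
        * cfg.effect_size
        * cfg.protein_attenuation
    )
    log_prot[:n_linked] += pshift
    protein = OmicsMatrix(
        feature_ids=prot_ids,
        sample_ids=prot_samples,
        values=np.exp2(log_prot),
        layer="protein",
    )

    # metabolite layer: independent log-normal with planted logFC between
    # the high-contrast subtype (2) and everyone else
    met_samples = members["metabolite"]
    met_sub = np.array([subtype_of[s] for s in met_samples])
    met_ids = [f"M{i + 1:03d}" for i in range(cfg.n_metabolites)]
    met_mu = rng.normal(3.0, 0.5, size=cfg.n_metabolites)
    log_met = met_mu[:, None] + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_metabolites, len(met_samples))
    )
    met_lfc = np.zeros(cfg.n_metabolites)
    met_lfc[: len(cfg.metabolite_logfc)] = cfg.metabolite_logfc
    high = 2 if cfg.k_true >= 2 else 1
    log_met += met_lfc[:, None] * (met_sub[None, :] == high)
    metabolite = OmicsMatrix(
        feature_ids=met_ids,
        sample_ids=met_samples,
        values=np.exp2(log_met),
        layer="metabolite",
    )

    # survival: exponential per subtype with independent uniform censoring
    medians = np.array(cfg.survival_medians[: cfg.k_true], float)
    horizon = 3.0 * float(medians.max())
    os_raw = np.array(
        [
            simulate_survival_times(medians[subtype_of[p] - 1], 1, rng)[0]
            for p in patients
        ]
    )
    os_time, os_event = _censor(os_raw, cfg.censor_rate, horizon, rng)
    dbf_raw = np.array(
        [
            simulate_survival_times(
                medians[subtype_of[p] - 1] * cfg.dbf_median_factor, 1, rng
            )[0]
            for p in patients
        ]
    )
    dbf_time, dbf_event = _censor(dbf_raw, cfg.censor_rate, horizon, rng)
    sites = rng.choice(
        PRIMARY_SITES, size=cfg.n_patients, p=PRIMARY_SITE_PROBS
    )
    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": patients,
                "os_time": os_time,
                "os_event": os_event,
                "dbf_time": dbf_time,
                "dbf_event": dbf_event,
                "primary_site": sites,
            }
        )
    )

    truth = {
        "subtype": {p: int(subtype_of[p]) for p in patients},
        "signature": {
            gene_ids[i]: {
                "cluster": int(sig_cluster[i]),
                "sign": int(sig_sign[i]),
            }
            for i in range(cfg.n_genes)
            if sig_cluster[i] > 0
        },
        "metabolite_logfc": {
            met_ids[i]: float(met_lfc[i])
            for i in range(cfg.n_metabolites)
            if met_lfc[i] != 0.0
        },
        "survival_medians": {
            c + 1: float(medians[c]) for c in range(cfg.k_true)
        },
        "overlap_design": design,
    }
    return SyntheticCohort(
        config=cfg,
        rna=rna,
        protein=protein,
        metabolite=metabolite,
        clinical=clinical,
        truth=truth,
    )


def planted_truth_report(cohort: SyntheticCohort) -> dict:
    """Read-only summary of the planted ground truth."""
    subtype = cohort.truth["subtype"]
    counts: Dict[int, int] = {}
    for lab in subtype.values():
        counts[lab] = counts.get(lab, 0) + 1
    signature_genes: Dict[int, list] = {}
    for g, info in cohort.truth["signature"].items():
        signature_genes.setdefault(info["cluster"], []).append(g)
    return {
        "subtype_counts": dict(sorted(counts.items())),
        "signature_genes": {
            c: sorted(gs) for c, gs in sorted(signature_genes.items())
        },
        "survival_medians": dict(cohort.truth["survival_medians"]),
        "metabolite_logfc": dict(cohort.truth["metabolite_logfc"]),
        "layer_sizes": {
            name: m.n_samples for name, m in cohort.layers.items()
        },
    }
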