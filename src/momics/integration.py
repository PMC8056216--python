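"""Cross-omics integration utilities.

Subtype label transfer to other layers, hypergeometric pathway enrichment
with -log10(p) scores, the summed two-layer overall pathway score, cohort
overlap accounting by inclusion-exclusion, and cohort percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .snmf import SubtypeModel


@dataclass
class PathwayScore:
    pathway_id: str
    score_rna: float
    score_prot: float
    overall: float
    category: Optional[str] = None


@dataclass
class OverlapSummary:
    """Cohort-membership overlap accounting for 2-3 omics layers."""

    set_sizes: Dict[str, int]
    union_size: int
    triple_count: int
    pairwise_sum: int
    at_least_two_count: int

    @classmethod
    def from_counts(
        cls,
        sizes: Mapping[str, int],
        union_size: int,
        triple_count: int,
    ) -> "OverlapSummary":
        """Inclusion-exclusion from marginal counts only.

        pairwise_sum = sum(sizes) - union + triple;
        at_least_two = pairwise_sum - 2 * triple.
        """
        pairwise_sum = sum(sizes.values()) - union_size + triple_count
        return cls(
            set_sizes=dict(sizes),
            union_size=union_size,
            triple_count=triple_count,
            pairwise_sum=pairwise_sum,
            at_least_two_count=pairwise_sum - 2 * triple_count,
        )


def transfer_labels(
    model: SubtypeModel, target_samples: Iterable[str]
) -> Tuple[Dict[str, int], int, int]:
    """Restrict subtype labels to ids present in both cohorts.

    Returns (labels on the intersection, n retained, n dropped from the
    target). Raises when the intersection is empty.
    """
    target = list(dict.fromkeys(target_samples))
    label_map = dict(zip(model.sample_ids, (int(x) for x in model.labels)))
    kept = {s: label_map[s] for s in target if s in label_map}
    if not kept:
        raise ValueError("no samples shared between model and target cohort")
    return kept, len(kept), len(target) - len(kept)


def enrich_hypergeometric(
    selected: Set[str], pathway: Set[str], universe_size: int
) -> Tuple[float, float]:
    """Upper-tail hypergeometric enrichment p and its -log10 score.

    P(overlap >= observed) drawing |selected| features from a universe of
    ``universe_size`` containing |pathway| pathway members.
    """
    selected, pathway = set(selected), set(pathway)
    if len(selected) > universe_size or len(pathway) > universe_size:
        raise ValueError("set larger than the universe")
    overlap = len(selected & pathway)
    p = float(
        hypergeom.sf(
            overlap - 1, universe_size, len(pathway), len(selected)
        )
    )
    p = min(p, 1.0)
    score = -math.log10(p) if p > 0 else float("inf")
    return p, score


def combine_scores(score_rna: float, score_prot: float) -> float:
    """Overall pathway score: arithmetic sum of the two layer scores."""
    if score_rna < 0 or score_prot < 0:
        raise ValueError("scores must be non-negative")
    return float(score_rna + score_prot)


def score_table(
    rna_scores: Mapping[str, float],
    prot_scores: Mapping[str, float],
    categories: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Combine per-layer pathway scores into a table sorted by the overall
    score, descending. Pathways absent from one layer score 0 there."""
    pathways = sorted(set(rna_scores) | set(prot_scores))
    rows = []
    for pw in pathways:
        r = float(rna_scores.get(pw, 0.0))
        p = float(prot_scores.get(pw, 0.0))
        rows.append(
            {
                "pathway": pw,
                "score_rna": r,
                "score_prot": p,
                "overall": combine_scores(r, p),
                "category": (categories or {}).get(pw, ""),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        "overall", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def overlap_summary(memberships: Mapping[str, Set[str]]) -> OverlapSummary:
    """Overlap accounting computed both directly from memberships and via
    inclusion-exclusion; the two routes must agree."""
    names = list(memberships)
    sets = [set(memberships[n]) for n in names]
    if not (2 <= len(sets) <= 3):
        raise ValueError("need 2 or 3 membership sets")
    union = set().union(*sets)
    pairwise_sum = 0
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            pairwise_sum += len(sets[i] & sets[j])
    triple = len(sets[0] & sets[1] & sets[2]) if len(sets) == 3 else 0
    counts = {}
    for s in sets:
        for x in s:
            counts[x] = counts.get(x, 0) + 1
    at_least_two_direct = sum(1 for v in counts.values() if v >= 2)
    formula = OverlapSummary.from_counts(
        {n: len(s) for n, s in zip(names, sets)}, len(union), triple
    )
    if formula.at_least_two_count != at_least_two_direct:
        raise AssertionError(
            "inclusion-exclusion disagrees with the direct count "
            f"({formula.at_least_two_count} vs {at_least_two_direct})"
        )
    return formula


def percent_of_cohort(count: int, total: int) -> int:
    """Percentage rounded half away from zero to the nearest integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= count <= total):
        raise ValueError("count must lie in [0, total]")
    return int(math.floor(100.0 * count / total + 0.5))
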