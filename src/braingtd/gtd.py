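"""The Global Tree Difference (GTD) between pairs of brain-wide count maps.

Two region-assigned cell-count maps over the same hierarchical ontology are
compared region by region.  At each region the two brains' *subregion
composition vectors* (cumulative counts of the id-sorted children, with the
region's own directly-assigned cells appended as one extra component when
either brain has any) are compared by cosine difference D = 1 - cos(u, v),
and weighted by the mean fraction M of total labelled input that the region
carries across the two brains.  The GTD is the normalized weighted sum

    GTD = sum(M_r * D_r) / sum(M_r)   over all included regions r,

a scalar in [0, 1]: 0 for identical maps, 1 only when the maps are
orthogonal in subregional composition at every level that carries weight.
Regions whose composition vector has fewer than two components, and regions
where either brain's vector is all-zero (cosine undefined; the absence is
already expressed one level up), are excluded from both sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._stats import mann_whitney_p, median_iqr
from .ontology import BrainCounts, GroupTable, OntologyTree, RegionId


class DegenerateTreeError(ValueError):
    """No region of the ontology is eligible for the GTD sums."""


def composition_vector(
    region_id: RegionId,
    brain: BrainCounts,
    tree: OntologyTree,
    include_direct: bool | None = None,
) -> np.ndarray:
    """Subregion composition vector of a region in one brain.

    Components are the cumulative counts of the region's children in
    ascending-id order.  If ``include_direct`` is true an extra component
    holding the region's own directly-assigned cells is appended; pairwise
    comparisons set this from *either* brain of the pair so both vectors
    share a dimension.  ``None`` (single-brain use) appends it iff this
    brain has any direct cells there.  A leaf yields an empty vector.
    """
    region = tree[region_id]
    direct = brain.direct[region_id]
    if include_direct is None:
        include_direct = direct > 0
    parts = [brain.cumulative[c] for c in region.children]
    if include_direct:
        parts.append(direct)
    return np.asarray(parts, dtype=float)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two non-negative vectors, in [0, 1].

    Computed as sqrt((u.v)^2 / (|u|^2 |v|^2)) so that scaling either vector
    by an integer leaves the result bit-identical; identical vectors return
    exactly 1.  Raises on zero vectors or mismatched dimensions — callers
    handle those via the region exclusion rule.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    uu = float(u @ u)
    vv = float(v @ v)
    if uu == 0.0 or vv == 0.0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    if np.array_equal(u, v):
        return 1.0
    dot = float(u @ v)
    return min(math.sqrt((dot * dot) / (uu * vv)), 1.0)


@dataclass(frozen=True)
class RegionContribution:
    """Per-region audit entry of a GTD computation."""

    region_id: RegionId
    M: float
    D: float
    included: bool
    reason: str | None = None  # exclusion reason when not included


@dataclass
class GtdResult:
    brain_a: str
    brain_b: str
    gtd: float
    contributions: list[RegionContribution]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region_id": c.region_id,
                    "M": c.M,
                    "D": c.D,
                    "included": c.included,
                    "reason": c.reason,
                }
                for c in self.contributions
            ]
        )


def global_tree_difference(
    a: BrainCounts, b: BrainCounts, tree: OntologyTree
) -> GtdResult:
    """Compute the GTD between two brains over the full ontology.

    Returns the scalar together with the per-region (M, D) ledger,
    including exclusion reasons, for audit.
    """
    numerator = 0.0
    denominator = 0.0
    contributions: list[RegionContribution] = []
    for rid in sorted(tree.regions):
        include_direct = a.direct[rid] > 0 or b.direct[rid] > 0
        n_components = len(tree.children(rid)) + (1 if include_direct else 0)
        if n_components < 2:
            contributions.append(
                RegionContribution(rid, math.nan, math.nan, False, "fewer-than-2-children")
            )
            continue
        u = composition_vector(rid, a, tree, include_direct)
        v = composition_vector(rid, b, tree, include_direct)
        if not u.any() or not v.any():
            contributions.append(
                RegionContribution(rid, math.nan, math.nan, False, "zero-composition-vector")
            )
            continue
        m = (a.fraction(rid) + b.fraction(rid)) / 2.0
        d = 1.0 - cosine_similarity(u, v)
        contributions.append(RegionContribution(rid, m, d, True))
        numerator += m * d
        denominator += m
    if denominator == 0.0:
        raise DegenerateTreeError(
            f"no region eligible for GTD between {a.brain_id!r} and {b.brain_id!r}"
        )
    return GtdResult(a.brain_id, b.brain_id, numerator / denominator, contributions)


@dataclass(frozen=True)
class PairGtd:
    brain_a: str
    brain_b: str
    group_a: str
    group_b: str
    relation: str  # "within" | "between"
    gtd: float


@dataclass
class PairSet:
    """Within-group and between-group GTD values for a comparison."""

    within: list[PairGtd] = field(default_factory=list)
    between: list[PairGtd] = field(default_factory=list)

    @property
    def within_values(self) -> list[float]:
        return [p.gtd for p in self.within]

    @property
    def between_values(self) -> list[float]:
        return [p.gtd for p in self.between]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "brain_a": p.brain_a,
                    "brain_b": p.brain_b,
                    "relation": p.relation,
                    "group_a": p.group_a,
                    "group_b": p.group_b,
                    "gtd": p.gtd,
                }
                for p in self.within + self.between
            ],
            columns=["brain_a", "brain_b", "relation", "group_a", "group_b", "gtd"],
        )


def pairwise_gtd(
    brains: Mapping[str, BrainCounts],
    groups: GroupTable,
    tree: OntologyTree,
    comparison: tuple[str, str] | None = None,
) -> PairSet:
    """GTD for all within-group pairs, pooled over every group, plus the
    between-group pairs of one named two-group comparison.

    The within set pools same-group pairs across *all* groups — the
    within-line floor against which any between-line comparison is judged.
    Each unordered pair is computed once.
    """
    if len(brains) < 2:
        raise ValueError("need at least 2 brains")
    result = PairSet()
    for label in sorted(groups.groups):
        members = groups.members(label)
        for ba, bb in combinations(members, 2):
            r = global_tree_difference(brains[ba], brains[bb], tree)
            result.within.append(PairGtd(ba, bb, label, label, "within", r.gtd))
    if comparison is not None:
        ga, gb = comparison
        members_a, members_b = groups.members(ga), groups.members(gb)
        if not members_a or not members_b:
            raise ValueError(f"empty group in comparison {comparison}")
        for ba, bb in product(members_a, members_b):
            r = global_tree_difference(brains[ba], brains[bb], tree)
            result.between.append(PairGtd(ba, bb, ga, gb, "between", r.gtd))
    return result


def compare_pair_sets(
    within: Sequence[float], between: Sequence[float]
) -> dict[str, float]:
    """Summarize and compare two sets of GTD values.

    Returns medians and interquartile ranges of each set and the two-sided
    Wilcoxon rank-sum p-value (exact enumeration for small samples,
    tie-corrected normal approximation otherwise).
    """
    if len(within) == 0 or len(between) == 0:
        raise ValueError("both pair sets must be non-empty")
    med_w, iqr_w = median_iqr(within)
    med_b, iqr_b = median_iqr(between)
    return {
        "n_within": len(within),
        "n_between": len(between),
        "median_within": med_w,
        "iqr_within": iqr_w,
        "median_between": med_b,
        "iqr_between": iqr_b,
        "p": mann_whitney_p(within, between, alternative="two-sided"),
    }
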