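"""Ontology simplification for a two-line comparison.

Sparse subregions cannot support line-to-line tests, so before testing, each
region's children are screened: a child is retained if, in at least one of
the two lines, it holds at least ``min_mean`` cells on average across the
line's brains AND at least ``min_presence_count`` cells in strictly more
than ``presence_fraction`` of them.  Counts are cumulative (region plus
descendants).  All cells in non-retained children, together with cells
assigned directly to the region itself, are amalgamated into a single
"not otherwise specified" (NOS) pseudo-subregion per brain, so every cell
is conserved.  Regions keeping at least two real children are *analysable*.

Simplification is recomputed for every comparison pair of lines; two
different pairings may retain different regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import BrainCounts, OntologyTree, RegionId


@dataclass(frozen=True)
class SelectionCriteria:
    """Region-retention thresholds for a line.

    Defaults: at least 5 cells on average across the line's brains, and at
    least 1 cell in a strict majority (> 50%) of them.
    """

    min_mean: float = 5.0
    presence_fraction: float = 0.5
    min_presence_count: int = 1

    def __post_init__(self) -> None:
        if self.min_mean < 0 or self.presence_fraction < 0 or self.min_presence_count < 0:
            raise ValueError("selection thresholds must be non-negative")


def passes_criteria(
    region_id: RegionId,
    line_brains: Sequence[BrainCounts],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> bool:
    """Whether a region passes the retention criteria within one line."""
    if not line_brains:
        raise ValueError("line must contain at least one brain")
    counts = np.array([b.cumulative[region_id] for b in line_brains], dtype=float)
    if counts.mean() < criteria.min_mean:
        return False
    present = int((counts >= criteria.min_presence_count).sum())
    return present / len(counts) > criteria.presence_fraction


@dataclass
class SimplifiedRegion:
    """One region after simplification for a given line pair."""

    region_id: RegionId
    retained_children: list[RegionId]
    excluded_children: dict[RegionId, str]  # child id -> exclusion reason
    nos_counts: dict[str, int]  # brain id -> NOS cell count
    analysable: bool


def simplify(
    tree: OntologyTree,
    line_a: Sequence[BrainCounts],
    line_b: Sequence[BrainCounts],
    criteria: SelectionCriteria = SelectionCriteria(),
) -> dict[RegionId, SimplifiedRegion]:
    """Simplify every internal region of the ontology for one line pair.

    A child is retained iff it passes the criteria in line_a OR line_b.
    Children with zero cells in every brain of both lines are excluded
    outright (labelled ``no-neurons``); this is subsumed by the two-clause
    test but short-circuits it and names the reason.
    """
    all_brains = list(line_a) + list(line_b)
    out: dict[RegionId, SimplifiedRegion] = {}
    for rid in tree.iter_breadth_first():
        children = tree.children(rid)
        if not children:
            continue
        retained: list[RegionId] = []
        excluded: dict[RegionId, str] = {}
        for child in children:
            if all(b.cumulative[child] == 0 for b in all_brains):
                excluded[child] = "no-neurons"
            elif passes_criteria(child, line_a, criteria) or passes_criteria(
                child, line_b, criteria
            ):
                retained.append(child)
            else:
                excluded[child] = "below-criteria"
        nos = {
            b.brain_id: sum(b.cumulative[c] for c in excluded) + b.direct[rid]
            for b in all_brains
        }
        out[rid] = SimplifiedRegion(
            region_id=rid,
            retained_children=retained,
            excluded_children=excluded,
            nos_counts=nos,
            analysable=len(retained) >= 2,
        )
    return out


def simplification_report(
    simplified: Mapping[RegionId, SimplifiedRegion], tree: OntologyTree
) -> pd.DataFrame:
    """Tidy per-region report of retention decisions and NOS counts."""
    rows = []
    for rid, simp in simplified.items():
        rows.append(
            {
                "region_id": rid,
                "acronym": tree[rid].acronym,
                "retained_children": ";".join(
                    tree[c].acronym for c in simp.retained_children
                ),
                "excluded_children": ";".join(
                    f"{tree[c].acronym}:{reason}"
                    for c, reason in simp.excluded_children.items()
                ),
                "analysable": simp.analysable,
                **{f"nos_{b}": n for b, n in simp.nos_counts.items()},
            }
        )
    return pd.DataFrame(rows)
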