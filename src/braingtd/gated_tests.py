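"""Gated two-stage localization of between-line composition differences.

Testing every region's every subregion against every other line invites
false positives.  Instead each analysable region is first screened by a
*vector-space gate*: every brain's subregional composition (fractions of
the region's cumulative count across retained children plus NOS) is a
point on the simplex, cosine distances are computed for all within-line
and all between-line brain pairs, and a one-tailed Mann-Whitney test asks
whether between-line distances are stochastically greater — i.e. whether
brains of the same line are more alike in composition than brains of
different lines.  Only where that gate fires (p < alpha) are the region's
retained children compared line-to-line with unpaired t-tests on
parent-relative fractions.  Expressing each child as a fraction of its
parent's cells (not of the brain total) removes the positive dependence
that cumulative fractions inherit down the hierarchy.  The NOS component
participates in the gate vectors but is never itself t-tested.
Shapiro-Wilk normality p-values are reported per line alongside every
t-test but do not alter the test.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import mann_whitney_p, mean_sem
from .gtd import cosine_similarity
from .ontology import BrainCounts, OntologyTree, RegionId
from .simplification import SimplifiedRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositionSample:
    """One brain's subregional composition vector at one region.

    Components are fractions of the region's cumulative count: retained
    children in id order, then NOS.  They sum to 1.
    """

    region_id: RegionId
    brain_id: str
    vector: np.ndarray


def composition_samples(
    region: SimplifiedRegion, brains: Sequence[BrainCounts]
) -> list[CompositionSample]:
    """Per-brain normalized composition vectors over retained children + NOS.

    Brains with zero cells in the region carry no composition information
    and are dropped with a warning.
    """
    samples: list[CompositionSample] = []
    for brain in brains:
        region_total = brain.cumulative[region.region_id]
        if region_total <= 0:
            logger.warning(
                "brain %s has no cells in region %s; dropped from its composition",
                brain.brain_id,
                region.region_id,
            )
            continue
        parts = [brain.cumulative[c] for c in region.retained_children]
        parts.append(region.nos_counts[brain.brain_id])
        samples.append(
            CompositionSample(
                region.region_id,
                brain.brain_id,
                np.asarray(parts, dtype=float) / region_total,
            )
        )
    return samples


@dataclass
class GateResult:
    """Vector-space gate outcome at one region."""

    region_id: RegionId
    within_distances: list[float]
    between_distances: list[float]
    p: float
    significant: bool
    testable: bool = True
    reason: str | None = None

    @classmethod
    def untestable(cls, region_id: RegionId, reason: str) -> "GateResult":
        return cls(region_id, [], [], math.nan, False, testable=False, reason=reason)


def _cosine_distance(a: CompositionSample, b: CompositionSample) -> float:
    return 1.0 - cosine_similarity(a.vector, b.vector)


def vector_space_gate(
    samples_a: Sequence[CompositionSample],
    samples_b: Sequence[CompositionSample],
    alpha: float = 0.05,
) -> GateResult:
    """One-tailed Mann-Whitney comparison of within- vs between-line
    cosine distances of composition vectors.

    Significant (p < alpha) means within-line pairs are reliably more
    similar than between-line pairs.  If every distance is identical the
    test is uninformative and p = 1 by convention.
    """
    if len(samples_a) < 2 or len(samples_b) < 2:
        region_id = (list(samples_a) + list(samples_b))[0].region_id
        return GateResult.untestable(region_id, "fewer-than-2-brains-per-line")
    region_id = samples_a[0].region_id
    within = [_cosine_distance(x, y) for x, y in combinations(samples_a, 2)]
    within += [_cosine_distance(x, y) for x, y in combinations(samples_b, 2)]
    between = [_cosine_distance(x, y) for x, y in product(samples_a, samples_b)]
    p = mann_whitney_p(between, within, alternative="greater")
    return GateResult(region_id, within, between, p, significant=p < alpha)


@dataclass
class ChildTestResult:
    """Unpaired t-test of one retained child's parent-relative fraction."""

    region_id: RegionId
    child_id: RegionId
    n_a: int
    n_b: int
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t: float
    p: float
    shapiro_p_a: float
    shapiro_p_b: float
    p_adj: float = math.nan  # BH-adjusted p, filled only when requested


def _shapiro_p(values: np.ndarray) -> float:
    if values.size < 3 or np.all(values == values[0]):
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(values).pvalue)


def _parent_fractions(
    region: SimplifiedRegion, child: RegionId, brains: Sequence[BrainCounts]
) -> np.ndarray:
    vals = [
        b.cumulative[child] / b.cumulative[region.region_id]
        for b in brains
        if b.cumulative[region.region_id] > 0
    ]
    return np.asarray(vals, dtype=float)


def child_t_tests(
    region: SimplifiedRegion,
    brains_a: Sequence[BrainCounts],
    brains_b: Sequence[BrainCounts],
    equal_var: bool = True,
) -> list[ChildTestResult]:
    """Per retained child, a two-sided unpaired t-test comparing the two
    lines' parent-relative fractions (Student's pooled-variance by default,
    Welch with ``equal_var=False``).  NOS is never tested.
    """
    results: list[ChildTestResult] = []
    for child in region.retained_children:
        fa = _parent_fractions(region, child, brains_a)
        fb = _parent_fractions(region, child, brains_b)
        if fa.size < 2 or fb.size < 2:
            logger.warning(
                "child %s of region %s untestable (a line has < 2 brains with cells)",
                child,
                region.region_id,
            )
            t_stat, p = math.nan, math.nan
        elif np.all(fa == fa[0]) and np.all(fb == fb[0]) and fa[0] == fb[0]:
            t_stat, p = 0.0, 1.0  # identical constant fractions
        else:
            res = stats.ttest_ind(fa, fb, equal_var=equal_var)
            t_stat, p = float(res.statistic), float(res.pvalue)
        ma, sa = mean_sem(fa) if fa.size else (math.nan, math.nan)
        mb, sb = mean_sem(fb) if fb.size else (math.nan, math.nan)
        results.append(
            ChildTestResult(
                region_id=region.region_id,
                child_id=child,
                n_a=int(fa.size),
                n_b=int(fb.size),
                mean_a=ma,
                sem_a=sa,
                mean_b=mb,
                sem_b=sb,
                t=t_stat,
                p=p,
                shapiro_p_a=_shapiro_p(fa),
                shapiro_p_b=_shapiro_p(fb),
            )
        )
    return results


@dataclass
class TestReport:
    """Full gated-test report for one line pair."""

    gates: dict[RegionId, GateResult] = field(default_factory=dict)
    child_tests: list[ChildTestResult] = field(default_factory=list)

    def to_frame(self, tree: OntologyTree | None = None) -> pd.DataFrame:
        rows = []
        for res in self.child_tests:
            gate = self.gates[res.region_id]
            rows.append(
                {
                    "region_id": res.region_id,
                    "region": tree[res.region_id].acronym if tree else res.region_id,
                    "child_id": res.child_id,
                    "child": tree[res.child_id].acronym if tree else res.child_id,
                    "n_a": res.n_a,
                    "n_b": res.n_b,
                    "frac_a_mean": res.mean_a,
                    "frac_a_sem": res.sem_a,
                    "frac_b_mean": res.mean_b,
                    "frac_b_sem": res.sem_b,
                    "gate_p": gate.p,
                    "t": res.t,
                    "p": res.p,
                    "shapiro_p_a": res.shapiro_p_a,
                    "shapiro_p_b": res.shapiro_p_b,
                    "p_adj": res.p_adj,
                    "tested": True,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "region_id", "region", "child_id", "child", "n_a", "n_b",
                "frac_a_mean", "frac_a_sem", "frac_b_mean", "frac_b_sem",
                "gate_p", "t", "p", "shapiro_p_a", "shapiro_p_b", "p_adj",
                "tested",
            ],
        )

    def gate_frame(self, tree: OntologyTree | None = None) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region_id": rid,
                    "region": tree[rid].acronym if tree else rid,
                    "gate_p": g.p,
                    "significant": g.significant,
                    "testable": g.testable,
                    "reason": g.reason,
                }
                for rid, g in self.gates.items()
            ]
        )


def traverse_and_test(
    tree: OntologyTree,
    simplified: Mapping[RegionId, SimplifiedRegion],
    brains_a: Sequence[BrainCounts],
    brains_b: Sequence[BrainCounts],
    alpha: float = 0.05,
    equal_var: bool = True,
    p_adjust: str = "none",
) -> TestReport:
    """Run the gated procedure over the whole simplified ontology.

    Regions are visited top-down (breadth-first, children id-sorted); at
    every analysable region the vector-space gate runs, and child t-tests
    run only where the gate fires.  The gate gates *tests*, not descent:
    traversal always continues into children.

    The gate is the procedure's multiplicity control; ``p_adjust="bh"``
    additionally fills ``p_adj`` with Benjamini-Hochberg adjusted p-values
    across all executed child t-tests (off by default).
    """
    if p_adjust not in ("none", "bh"):
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    report = TestReport()
    for rid in tree.iter_breadth_first():
        simp = simplified.get(rid)
        if simp is None or not simp.analysable:
            continue
        samples_a = composition_samples(simp, brains_a)
        samples_b = composition_samples(simp, brains_b)
        if len(samples_a) < 2 or len(samples_b) < 2:
            report.gates[rid] = GateResult.untestable(
                rid, "fewer-than-2-brains-per-line"
            )
            continue
        gate = vector_space_gate(samples_a, samples_b, alpha=alpha)
        report.gates[rid] = gate
        if gate.significant:
            report.child_tests.extend(
                child_t_tests(simp, brains_a, brains_b, equal_var=equal_var)
            )
    if p_adjust == "bh" and report.child_tests:
        testable = [t for t in report.child_tests if not math.isnan(t.p)]
        if testable:
            adjusted = stats.false_discovery_control(
                [t.p for t in testable], method="bh"
            )
            for t, adj in zip(testable, adjusted):
                t.p_adj = float(adj)
    return report
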