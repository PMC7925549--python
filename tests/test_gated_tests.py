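import math

import numpy as np
import pytest

from braingtd.gated_tests import (
    child_t_tests,
    composition_samples,
    traverse_and_test,
    vector_space_gate,
)
from braingtd.ontology import BrainCounts
from braingtd.simplification import SimplifiedRegion, simplify
from braingtd.synthetic import build_toy_ontology


def _simple_region(tree, brains, retained):
    """SimplifiedRegion for the root with the given retained children."""
    excluded = [c for c in tree.children(tree.root_id) if c not in retained]
    return SimplifiedRegion(
        region_id=tree.root_id,
        retained_children=list(retained),
        excluded_children={c: "below-criteria" for c in excluded},
        nos_counts={
            b.brain_id: sum(b.cumulative[c] for c in excluded) + b.direct[tree.root_id]
            for b in brains
        },
        analysable=len(retained) >= 2,
    )


class TestCompositionSamples:
    def test_fractions_with_empty_nos(self, flat_tree):
        brain = BrainCounts.from_direct("b", {2: 8, 3: 2}, flat_tree)
        region = _simple_region(flat_tree, [brain], [2, 3])
        [sample] = composition_samples(region, [brain])
        assert sample.vector.tolist() == [0.8, 0.2, 0.0]

    def test_direct_cells_fill_nos_component(self, flat_tree):
        brain = BrainCounts.from_direct("b", {2: 3, 3: 3, 1: 4}, flat_tree)
        region = _simple_region(flat_tree, [brain], [2, 3])
        [sample] = composition_samples(region, [brain])
        assert sample.vector.tolist() == [0.3, 0.3, 0.4]

    def test_components_sum_to_one(self):
        rng = np.random.default_rng(5)
        tree = build_toy_ontology(1, 4)
        for _ in range(20):
            direct = {rid: int(rng.integers(0, 30)) for rid in tree.regions}
            direct[tree.root_id] = int(rng.integers(1, 10))
            brain = BrainCounts.from_direct("b", direct, tree)
            region = _simple_region(tree, [brain], list(tree.children(1))[:2])
            [sample] = composition_samples(region, [brain])
            assert sample.vector.sum() == pytest.approx(1.0)

    def test_zero_count_brain_dropped(self, flat_tree):
        full = BrainCounts.from_direct("full", {2: 5}, flat_tree)
        empty = BrainCounts.from_direct("empty", {3: 5}, flat_tree)
        region = SimplifiedRegion(2, [], {}, {"full": 0, "empty": 0}, False)
        samples = composition_samples(region, [full, empty])
        # region 2 holds no cells in brain "empty"
        assert [s.brain_id for s in samples] == ["full"]


class TestVectorSpaceGate:
    def _samples(self, tree, vectors, line):
        brains = [
            BrainCounts.from_direct(f"{line}{i}", {2: a, 3: b}, tree)
            for i, (a, b) in enumerate(vectors)
        ]
        region = _simple_region(tree, brains, [2, 3])
        return composition_samples(region, brains)

    def test_complete_separation_exact_p(self, flat_tree):
        # 2 brains per line, within distances tiny, all 4 between large:
        # exactly 1 of C(6,2)=15 rank assignments is as extreme
        samples_a = self._samples(flat_tree, [(100, 1), (99, 2)], "a")
        samples_b = self._samples(flat_tree, [(1, 100), (2, 99)], "b")
        gate = vector_space_gate(samples_a, samples_b)
        assert gate.p == pytest.approx(1 / 15)
        assert not gate.significant

    def test_identical_lines_uninformative(self, flat_tree):
        samples_a = self._samples(flat_tree, [(5, 5), (6, 4)], "a")
        samples_b = self._samples(flat_tree, [(5, 5), (6, 4)], "b")
        gate = vector_space_gate(samples_a, samples_b)
        assert gate.p >= 0.5

    def test_distance_set_sizes(self, flat_tree):
        samples_a = self._samples(flat_tree, [(5, 5), (6, 4), (7, 3)], "a")
        samples_b = self._samples(flat_tree, [(1, 9), (2, 8)], "b")
        gate = vector_space_gate(samples_a, samples_b)
        assert len(gate.within_distances) == 3 + 1
        assert len(gate.between_distances) == 6

    def test_single_brain_line_untestable(self, flat_tree):
        samples_a = self._samples(flat_tree, [(5, 5)], "a")
        samples_b = self._samples(flat_tree, [(1, 9), (2, 8)], "b")
        gate = vector_space_gate(samples_a, samples_b)
        assert not gate.testable and math.isnan(gate.p)

    def test_null_type_one_error_near_nominal(self, flat_tree):
        """With both lines drawn identically the gate fires ~5% of the time."""
        rng = np.random.default_rng(8)
        fired = 0
        n_sim = 400
        for _ in range(n_sim):
            draws = rng.integers(1, 100, size=(8, 2))
            samples_a = self._samples(flat_tree, draws[:4], "a")
            samples_b = self._samples(flat_tree, draws[4:], "b")
            fired += vector_space_gate(samples_a, samples_b).significant
        assert 0.02 <= fired / n_sim <= 0.09


class TestChildTTests:
    def _region_and_lines(self, tree, fractions_a, fractions_b, denom=10):
        def make(line, fracs):
            return [
                BrainCounts.from_direct(
                    f"{line}{i}",
                    {2: int(f * denom), 3: denom - int(f * denom)},
                    tree,
                )
                for i, f in enumerate(fracs)
            ]

        brains_a = make("a", fractions_a)
        brains_b = make("b", fractions_b)
        region = _simple_region(tree, brains_a + brains_b, [2, 3])
        return region, brains_a, brains_b

    def test_pooled_variance_t_reference_value(self, flat_tree):
        region, brains_a, brains_b = self._region_and_lines(
            flat_tree, (0.2, 0.3, 0.4), (0.6, 0.7, 0.8)
        )
        result = next(r for r in child_t_tests(region, brains_a, brains_b) if r.child_id == 2)
        assert result.t == pytest.approx(-4.899, abs=1e-3)
        assert result.p == pytest.approx(0.00806, abs=1e-4)
        assert result.mean_a == pytest.approx(0.3)
        assert result.sem_a == pytest.approx(0.1 / np.sqrt(3))

    def test_identical_fractions_give_t_zero(self, flat_tree):
        region, brains_a, brains_b = self._region_and_lines(
            flat_tree, (0.4, 0.4, 0.4), (0.4, 0.4, 0.4)
        )
        result = child_t_tests(region, brains_a, brains_b)[0]
        assert result.t == 0.0 and result.p == 1.0

    def test_nos_never_tested(self, flat_tree):
        region, brains_a, brains_b = self._region_and_lines(
            flat_tree, (0.2, 0.3), (0.6, 0.7)
        )
        region.retained_children = [2]  # 3 fell below criteria -> NOS
        results = child_t_tests(region, brains_a, brains_b)
        assert [r.child_id for r in results] == [2]

    def test_welch_variant_available(self, flat_tree):
        region, brains_a, brains_b = self._region_and_lines(
            flat_tree, (0.2, 0.3, 0.4), (0.6, 0.7, 0.8)
        )
        student = child_t_tests(region, brains_a, brains_b)[0]
        welch = child_t_tests(region, brains_a, brains_b, equal_var=False)[0]
        # equal group sizes and equal sample variances: the two variants agree
        assert student.t == pytest.approx(welch.t)
        assert student.p == pytest.approx(welch.p)


class TestTraverseAndTest:
    def _study(self, seed, effect=False):
        from braingtd.experiments import _study, _split_lines

        study = _study(seed, effect_fold=2.0 if effect else None)
        return (study, *_split_lines(study))

    def test_identical_lines_run_zero_t_tests(self, flat_tree):
        brains_a = [
            BrainCounts.from_direct(f"a{i}", {2: 10 + i, 3: 10}, flat_tree)
            for i in range(3)
        ]
        brains_b = [
            BrainCounts.from_direct(f"b{i}", {2: 10 + i, 3: 10}, flat_tree)
            for i in range(3)
        ]
        simplified = simplify(flat_tree, brains_a, brains_b)
        report = traverse_and_test(flat_tree, simplified, brains_a, brains_b)
        assert report.child_tests == []

    def test_row_count_matches_gated_children(self):
        study, brains_a, brains_b = self._study(99, effect=True)
        simplified = simplify(study.tree, brains_a, brains_b)
        report = traverse_and_test(study.tree, simplified, brains_a, brains_b)
        expected = sum(
            len(simplified[rid].retained_children)
            for rid, gate in report.gates.items()
            if gate.significant
        )
        assert len(report.child_tests) == expected

    def test_injected_effect_is_minimum_p_child(self):
        """At a large injected effect the affected child wins the t-tests."""
        from braingtd.experiments import _split_lines, _study

        hits = 0
        for seed in range(20):
            study = _study(1000 + seed, effect_fold=4.0)
            affected = int(study.ground_truth["effects"][0]["region"])
            parent = study.tree[affected].parent_id
            brains_a, brains_b = _split_lines(study)
            simplified = simplify(study.tree, brains_a, brains_b)
            report = traverse_and_test(study.tree, simplified, brains_a, brains_b)
            root_tests = [t for t in report.child_tests if t.region_id == parent]
            if root_tests and min(root_tests, key=lambda t: t.p).child_id == affected:
                hits += 1
        assert hits >= 18

    def test_bh_adjustment_optional_and_off_by_default(self):
        from scipy import stats as sps

        study, brains_a, brains_b = self._study(99, effect=True)
        simplified = simplify(study.tree, brains_a, brains_b)
        plain = traverse_and_test(study.tree, simplified, brains_a, brains_b)
        assert all(math.isnan(t.p_adj) for t in plain.child_tests)
        adjusted = traverse_and_test(
            study.tree, simplified, brains_a, brains_b, p_adjust="bh"
        )
        raw = [t.p for t in adjusted.child_tests if not math.isnan(t.p)]
        expected = sps.false_discovery_control(raw, method="bh")
        got = [t.p_adj for t in adjusted.child_tests if not math.isnan(t.p)]
        assert got == pytest.approx(list(expected))

    def test_permuting_one_regions_children_leaves_others_unchanged(self, toy_tree):
        """Parent-relative fractions decorrelate the hierarchy levels."""
        rng = np.random.default_rng(77)
        direct = {rid: int(rng.integers(1, 30)) for rid in toy_tree.regions}
        brain = BrainCounts.from_direct("b", direct, toy_tree)
        swapped = dict(direct)
        swapped[5], swapped[6] = direct[6], direct[5]  # children of region 2
        brain_swapped = BrainCounts.from_direct("b", swapped, toy_tree)
        for rid in toy_tree.regions:
            if rid in (2, 5, 6):
                continue
            parent = toy_tree[rid].parent_id
            if parent is None:
                continue
            assert (
                brain.cumulative[rid] / brain.cumulative[parent]
                == brain_swapped.cumulative[rid] / brain_swapped.cumulative[parent]
            )
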