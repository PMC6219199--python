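"""Richness curves, node diversity, the 0.70 rule, and conservation laws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lindiv import (
    Conventions,
    LineageDiversity,
    RegionSet,
    StatePosterior,
    diversity_from_node_table,
    diversity_table,
    lineage_count,
    node_diversity,
    regional_richness,
    simulate_yule,
)

from conftest import toy_nodes


class TestRegionalRichness:
    def test_onehot_counts(self, toy_tree, regions2, toy_onehot):
        r = regional_richness(toy_tree, toy_onehot, regions2, 0.5)
        np.testing.assert_allclose(r, [3, 1])

    def test_probabilistic_sums(self, toy_tree, regions2, toy_probs):
        r = regional_richness(toy_tree, toy_probs, regions2, 1.0)
        np.testing.assert_allclose(r, [2.0, 1.0], atol=1e-12)

    def test_above_root_only_origin_remains(self, toy_tree, regions2, toy_probs):
        r = regional_richness(toy_tree, toy_probs, regions2, 10.0)
        np.testing.assert_allclose(r, [0.7, 0.3])
        assert r.sum() == pytest.approx(1.0)

    def test_missing_node_vector_names_node(self, toy_tree, regions2):
        root, ab, cd = toy_nodes(toy_tree)
        partial = StatePosterior(regions2, {root: [1, 0], ab: [0, 1]})
        with pytest.raises(ValueError, match=str(cd)):
            regional_richness(toy_tree, partial, regions2, 0.5)

    def test_without_origin_totals_drop_by_one(self, toy_tree, regions2,
                                               toy_probs):
        conv = Conventions(include_origin=False)
        r = regional_richness(toy_tree, toy_probs, regions2, 0.5, conv)
        assert r.sum() == pytest.approx(
            lineage_count(toy_tree, 0.5, include_origin=False))


class TestNodeDiversity:
    def test_weighted_mean_at_ab_node(self, toy_tree, regions2, toy_probs):
        root, ab, cd = toy_nodes(toy_tree)
        rec = node_diversity(toy_tree, toy_probs, regions2, ab)
        assert rec.diversity == pytest.approx(1.1, abs=1e-12)
        assert rec.processed  # max prob 0.9 >= 0.70

    def test_even_probabilities_not_processed(self, toy_tree, regions2):
        root, ab, cd = toy_nodes(toy_tree)
        post = StatePosterior(
            regions2, {root: [1, 0], cd: [1, 0], ab: [0.5, 0.5]})
        rec = node_diversity(toy_tree, post, regions2, ab)
        assert not rec.processed
        assert rec.diversity is None

    def test_onehot_diversity_is_integer_count(self, toy_tree, regions2,
                                               toy_onehot):
        for v in toy_tree.internal_nodes:
            rec = node_diversity(toy_tree, toy_onehot, regions2, v)
            assert rec.diversity == int(rec.diversity)

    def test_tip_focal_rejected(self, toy_tree, regions2, toy_onehot):
        with pytest.raises(ValueError, match="tip"):
            node_diversity(toy_tree, toy_onehot, regions2, toy_tree.tips[0])

    def test_diversity_bounded_by_lineage_count(self):
        rng = np.random.default_rng(2)
        tree = simulate_yule(40, 1.0, rng)
        regions = RegionSet(("I", "II", "III", "IV"))
        post = StatePosterior(regions, {
            v: rng.dirichlet(np.ones(4)) for v in tree.internal_nodes})
        analysis = LineageDiversity(tree, post, regions,
                                    Conventions(threshold=0.0))
        ages = tree.ages()
        for rec in analysis.table():
            assert 0.0 <= rec.diversity <= lineage_count(tree, ages[rec.node_id]) + 1e-9


class TestDiversityTable:
    def test_one_record_per_internal_node_sorted_old_to_young(
            self, toy_tree, regions2, toy_onehot):
        recs = diversity_table(toy_tree, toy_onehot, regions2)
        assert len(recs) == 3
        assert [r.age for r in recs] == sorted((r.age for r in recs),
                                               reverse=True)
        assert all(r.processed for r in recs)

    def test_unprocessed_record_retained_and_still_counted(
            self, toy_tree, regions2):
        root, ab, cd = toy_nodes(toy_tree)
        post = StatePosterior(
            regions2, {root: [1, 0], cd: [1, 0], ab: [0.5, 0.5]})
        recs = diversity_table(toy_tree, post, regions2)
        assert len(recs) == 3
        assert sum(r.processed for r in recs) == 2
        # the skipped AB node still feeds richness at younger ages:
        r = regional_richness(toy_tree, post, regions2, 0.5)
        assert r.sum() == pytest.approx(4.0)
        np.testing.assert_allclose(r, [3.5, 0.5])

    def test_threshold_boundary_inclusive(self, toy_tree, regions2):
        root, ab, cd = toy_nodes(toy_tree)
        for p, expect in [(0.69, False), (0.70, True)]:
            post = StatePosterior(
                regions2, {root: [1, 0], cd: [1, 0], ab: [1 - p, p]})
            rec = node_diversity(toy_tree, post, regions2, ab, threshold=0.70)
            assert rec.processed is expect


class TestThroughTime:
    def test_grid_totals_match_ltt(self, toy_tree, regions2, toy_onehot):
        analysis = LineageDiversity(toy_tree, toy_onehot, regions2)
        grid_frame, _ = analysis.through_time([0, 0.5, 1.5, 2.5, 3.5])
        totals = grid_frame.groupby("age")["richness"].sum()
        np.testing.assert_allclose(totals.to_numpy(), [4, 4, 3, 2, 1])

    def test_empty_grid_gives_empty_table(self, toy_tree, regions2, toy_onehot):
        grid_frame, nodes = LineageDiversity(
            toy_tree, toy_onehot, regions2).through_time([])
        assert grid_frame.empty
        assert len(nodes) == 3

    def test_value_at_breakpoint_is_right_continuous(self, toy_tree, regions2,
                                                     toy_onehot):
        analysis = LineageDiversity(toy_tree, toy_onehot, regions2)
        at = analysis.richness(2.0)          # exactly the CD node's age
        just_above = analysis.richness(2.0 + 1e-9)
        np.testing.assert_allclose(at, just_above)
        assert at.sum() == pytest.approx(2.0)

    def test_highlight_flags_modal_region(self, toy_tree, regions2, toy_probs):
        _, nodes = LineageDiversity(toy_tree, toy_probs, regions2).through_time(
            [], highlight_region="IV")
        flagged = nodes.set_index("node")["highlight"]
        root, ab, cd = toy_nodes(toy_tree)
        assert flagged[ab]
        assert not flagged[root] and not flagged[cd]


class TestInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_yule(int(rng.integers(5, 60)), 1.0, rng)
        regions = RegionSet(("I", "II", "III", "IV"))
        post = StatePosterior(regions, {
            v: rng.dirichlet(np.ones(4)) for v in tree.internal_nodes})
        analysis = LineageDiversity(tree, post, regions)
        for t in rng.uniform(0, tree.root_age * 1.2, size=60):
            assert analysis.richness(t).sum() == pytest.approx(
                lineage_count(tree, float(t)), abs=1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        rows=st.lists(
            st.tuples(
                st.floats(0.01, 10.0),
                st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4),
            ),
            min_size=1,
            max_size=12,
        ),
        t=st.floats(0.0, 12.0),
    )
    def test_node_table_conservation_property(self, rows, t):
        # for any node table, total richness at age t = origin + one per
        # strictly older row, regardless of the probability vectors
        regions = RegionSet(("I", "II", "III", "IV"))
        frame = pd.DataFrame(
            [{"node": i, "age": age,
              **dict(zip(regions.labels, np.asarray(p) / np.sum(p)))}
             for i, (age, p) in enumerate(rows)])
        out = diversity_from_node_table(frame, regions,
                                        Conventions(threshold=0.0))
        from lindiv.diversity import RichnessCurve

        ages = frame["age"].to_numpy()
        P = frame[list(regions.labels)].to_numpy()
        curve = RichnessCurve(ages, P, np.ones(len(ages)),
                              P[np.argmax(ages)], regions)
        expect = 1 + np.sum(ages > t)
        assert curve(float(t)).sum() == pytest.approx(expect, abs=1e-9)
        assert out["lineage_diversity"].notna().all()

    def test_permutation_equivariance(self, toy_tree, toy_probs, regions2):
        flipped_regions = RegionSet(("IV", "I"))
        root, ab, cd = toy_nodes(toy_tree)
        flipped = StatePosterior(flipped_regions, {
            v: toy_probs[v][::-1] for v in toy_tree.internal_nodes})
        for t in (0.0, 0.5, 1.0, 2.5):
            a = regional_richness(toy_tree, toy_probs, regions2, t)
            b = regional_richness(toy_tree, flipped, flipped_regions, t)
            np.testing.assert_allclose(a, b[::-1])

    def test_extra_node_never_decreases_younger_richness(self):
        regions = RegionSet(("I", "IV"))
        base = pd.DataFrame({
            "node": [1, 2], "age": [3.0, 2.0],
            "I": [0.8, 0.3], "IV": [0.2, 0.7]})
        extra = pd.concat([base, pd.DataFrame(
            {"node": [3], "age": [2.5], "I": [0.4], "IV": [0.6]})],
            ignore_index=True)
        out_base = diversity_from_node_table(base, regions)
        out_extra = diversity_from_node_table(extra, regions)
        # richness feeding the youngest common node can only grow
        d_base = out_base.loc[out_base["node"] == 2, "lineage_diversity"].item()
        d_extra = out_extra.loc[out_extra["node"] == 2, "lineage_diversity"].item()
        assert d_extra >= d_base - 1e-12


class TestNodeTableOnlyPath:
    def test_matches_tree_based_computation(self, toy_tree, regions2, toy_probs):
        ages = toy_tree.ages()
        rows = [{"node": v, "age": float(ages[v]),
                 "I": toy_probs[v][0], "IV": toy_probs[v][1]}
                for v in toy_tree.internal_nodes]
        out = diversity_from_node_table(pd.DataFrame(rows), regions2,
                                        Conventions(threshold=0.0))
        recs = {r.node_id: r for r in diversity_table(
            toy_tree, toy_probs, regions2, threshold=0.0)}
        for _, row in out.iterrows():
            assert row["lineage_diversity"] == pytest.approx(
                recs[int(row["node"])].diversity, abs=1e-12)
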