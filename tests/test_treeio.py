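"""Tree parsing, ages, annotations, clock scaling, and table output."""

import io

import numpy as np
import pandas as pd
import pytest

from lindiv import (
    ClockRate,
    RegionSet,
    attach_state_probabilities,
    node_ages,
    parse_tree,
    scale_to_time,
    simulate_yule,
    write_node_table,
)
from lindiv.diversity import NodeDiversityRecord
from lindiv.treeio import (
    AnnotationError,
    TreeParseError,
    UltrametricityError,
    format_sigfig,
)

from conftest import toy_nodes


class TestParse:
    def test_toy_counts_and_root_age(self, toy_tree):
        assert toy_tree.n_tips == 4
        assert len(toy_tree.internal_nodes) == 3
        assert toy_tree.root_age == pytest.approx(3.0)

    def test_single_tip_tree_accepted(self):
        tree, _ = parse_tree(text="(A:1);")
        assert tree.n_tips == 1
        assert tree.root_age == pytest.approx(1.0)

    def test_nexus_annotation_vector_preserved(self):
        nx = (
            "#NEXUS\nBEGIN TREES;\nTREE t = ((A:1.0,B:1.0)"
            "[&loc.prob={0.2,0.8}]:2.0,(C:2.0,D:2.0):1.0);\nEND;\n"
        )
        tree, ann = parse_tree(text=nx)
        vectors = [v["loc.prob"] for v in ann.values() if "loc.prob" in v]
        assert len(vectors) == 1
        assert sum(vectors[0]) == pytest.approx(1.0)

    def test_malformed_input_reports_position(self):
        with pytest.raises(TreeParseError, match="col"):
            parse_tree(text="((A:1,B:1:2,(C:2,D:2):1);")

    def test_missing_branch_length_names_node(self):
        with pytest.raises(TreeParseError, match="branch length.*'C'"):
            parse_tree(text="((A:1,B:1):2,(C,D:2):1);")

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_roundtrip_preserves_structure_lengths_annotations(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_yule(int(rng.integers(3, 30)), 1.0, rng)
        ann = {tree.root: {"posterior": 0.97, "probs": (0.25, 0.75)}}
        text = tree.write_newick(annotations=ann)
        back, ann2 = parse_tree(text=text)
        assert back.n_tips == tree.n_tips
        assert back.write_newick() == tree.write_newick()
        np.testing.assert_allclose(back.branch_lengths, tree.branch_lengths,
                                   atol=1e-9)
        assert ann2[back.root]["posterior"] == pytest.approx(0.97)
        assert tuple(ann2[back.root]["probs"]) == pytest.approx((0.25, 0.75))


class TestAges:
    def test_toy_ages(self, toy_tree):
        ages = node_ages(toy_tree)
        root, ab, cd = toy_nodes(toy_tree)
        assert ages[root] == pytest.approx(3.0)
        assert ages[ab] == pytest.approx(1.0)
        assert ages[cd] == pytest.approx(2.0)
        assert all(ages[v] == pytest.approx(0.0) for v in toy_tree.tips)

    def test_all_zero_branch_lengths(self):
        tree, _ = parse_tree(text="((A:0,B:0):0,C:0);")
        assert all(a == 0.0 for a in node_ages(tree).values())

    def test_non_ultrametric_beyond_tolerance_names_worst_tip(self):
        tree, _ = parse_tree(text="((A:3.0,B:2.9):1.0,C:4.0);")
        with pytest.raises(UltrametricityError, match="B"):
            tree.ages(tol=0.01)

    def test_ages_invariant_under_child_order_permutation(self):
        t1, _ = parse_tree(text="((A:1,B:1):2,(C:2,D:2):1);")
        t2, _ = parse_tree(text="((D:2,C:2):1,(B:1,A:1):2);")
        a1 = {frozenset(t1.descendant_tip_labels(v)): t1.ages()[v]
              for v in t1.internal_nodes}
        a2 = {frozenset(t2.descendant_tip_labels(v)): t2.ages()[v]
              for v in t2.internal_nodes}
        assert a1 == a2


class TestClockScaling:
    def test_point_rate_division(self):
        tree, _ = parse_tree(text="(A:0.0412,B:0.0412);")
        scaled = scale_to_time(tree, 0.0206)
        assert scaled.root_age == pytest.approx(2.0)

    def test_interval_rate_orders_ages(self):
        tree, _ = parse_tree(text="(A:0.025,B:0.025);")
        older, younger = scale_to_time(tree, ClockRate(0.0125, 0.0206))
        assert older.root_age == pytest.approx(2.0)
        assert younger.root_age == pytest.approx(0.025 / 0.0206)
        assert older.root_age > younger.root_age

    def test_scaling_inverts_to_substitution_lengths(self):
        rng = np.random.default_rng(5)
        tree = simulate_yule(12, 1.0, rng)
        rate = 0.0171
        scaled = scale_to_time(tree, rate)
        np.testing.assert_allclose(scaled.branch_lengths * rate,
                                   tree.branch_lengths, atol=1e-12)

    def test_zero_length_branch_stays_zero(self):
        tree, _ = parse_tree(text="((A:0.0,B:0.01):0.01,C:0.02);")
        with pytest.raises(UltrametricityError):
            tree.ages(tol=1e-6)  # sanity: input is not ultrametric
        scaled = scale_to_time(tree, 0.0125)
        assert scaled.branch_length(scaled.tip_id("A")) == 0.0

    @pytest.mark.parametrize("bad", [0.0, -0.1])
    def test_invalid_rate_rejected(self, bad):
        with pytest.raises(ValueError):
            ClockRate(bad)


class TestAttachProbabilities:
    def test_by_node_id_complete(self, toy_tree, regions2):
        root, ab, cd = toy_nodes(toy_tree)
        post = attach_state_probabilities(
            toy_tree, {root: [1, 0], ab: [0, 1], cd: [1, 0]}, regions2)
        assert all(v in post for v in toy_tree.internal_nodes)

    def test_by_clade_with_tip_onehots(self, toy_tree, regions2):
        table = {"A|B|C|D": [0.5, 0.5], "A|B": [0, 1], "C|D": [1, 0]}
        post = attach_state_probabilities(
            toy_tree, table, regions2,
            tip_regions={"A": "IV", "B": "IV", "C": "I", "D": "I"})
        root, ab, cd = toy_nodes(toy_tree)
        np.testing.assert_allclose(post[ab], [0, 1])
        np.testing.assert_allclose(post[toy_tree.tip_id("C")], [1, 0])

    def test_small_deficit_renormalized(self, toy_tree, regions2):
        root, ab, cd = toy_nodes(toy_tree)
        post = attach_state_probabilities(
            toy_tree,
            {root: [0.5, 0.499], ab: [0, 1], cd: [1, 0]}, regions2)
        np.testing.assert_allclose(post[root], [0.5005, 0.4995], rtol=1e-4)

    def test_large_deficit_is_hard_error(self, toy_tree, regions2):
        root, ab, cd = toy_nodes(toy_tree)
        with pytest.raises(AnnotationError, match="sum"):
            attach_state_probabilities(
                toy_tree, {root: [0.5, 0.4], ab: [0, 1], cd: [1, 0]}, regions2)

    def test_unmatched_clade_lists_tip_set(self, toy_tree, regions2):
        with pytest.raises(AnnotationError, match="A.*C"):
            attach_state_probabilities(toy_tree, {"A|C": [1, 0]}, regions2)

    def test_duplicate_match_rejected(self, toy_tree, regions2):
        root, ab, cd = toy_nodes(toy_tree)
        with pytest.raises(AnnotationError, match="more than once"):
            attach_state_probabilities(
                toy_tree, {str(ab): [0, 1], "A|B": [0, 1]}, regions2)

    def test_missing_internal_node_rejected(self, toy_tree, regions2):
        root, ab, cd = toy_nodes(toy_tree)
        with pytest.raises(AnnotationError, match="not matched"):
            attach_state_probabilities(toy_tree, {root: [1, 0]}, regions2)


class TestNodeTableOutput:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.0977, "0.0977"), (0.999, "0.999"), (121, "121"),
         (5.8421, "5.84"), (0.0003, "0.0003"), (0, "0"), (None, "")],
    )
    def test_three_significant_figures(self, x, expected):
        assert format_sigfig(x) == expected

    def test_rows_render_at_printed_precision(self):
        regions = RegionSet(("I", "II", "III", "IV"))
        rec = NodeDiversityRecord(
            node_id=20, age=0.0977, probs=np.array([0.0008, 0.0001, 0.0, 0.999]),
            diversity=121.0, processed=True, age_ci_lower=0.0018,
            age_ci_upper=0.272, support=1.0)
        buf = io.StringIO()
        write_node_table([rec], buf, regions)
        row = buf.getvalue().splitlines()[1].split("\t")
        assert row[1] == "0.0977"
        assert row[-2] == "0.999"
        assert row[-1] == "121"

    def test_unprocessed_row_has_blank_diversity(self):
        regions = RegionSet(("I", "IV"))
        rec = NodeDiversityRecord(
            node_id=3, age=1.0, probs=np.array([0.5, 0.5]),
            diversity=None, processed=False)
        buf = io.StringIO()
        write_node_table([rec], buf, regions)
        assert buf.getvalue().splitlines()[1].split("\t")[-1] == ""

    def test_empty_record_list_writes_header_only(self):
        buf = io.StringIO()
        write_node_table([], buf, RegionSet(("I", "IV")))
        lines = [l for l in buf.getvalue().splitlines() if l]
        assert len(lines) == 1
        assert lines[0].startswith("node\t")
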