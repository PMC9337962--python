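import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from physfit.cohort import LabeledDataset
from physfit.errors import DegenerateWindowError, TreeInputError
from physfit.id3 import (
    DecisionNode,
    build_id3,
    expected_info,
    info_gain,
    select_attribute,
    split_info,
    train_windowed,
    training_accuracy,
)

from oracles import (
    brute_best_attribute,
    brute_expected_info,
    brute_info_gain,
    brute_split_info,
    random_dataset,
)


def _two_subset_dataset():
    # subsets by 'a': value u -> class counts (2,2); value v -> (1,3); s = 8
    rows = [{"a": "u"}] * 4 + [{"a": "v"}] * 4
    labels = ["pos", "pos", "neg", "neg", "pos", "neg", "neg", "neg"]
    return LabeledDataset(["a"], rows, labels)


@pytest.mark.parametrize(
    "counts,expected",
    [([8, 8], 1.0), ([5, 0], 0.0), ([9, 5], 0.9403)],
)
def test_expected_info_known_values(counts, expected):
    assert expected_info(counts) == pytest.approx(expected, abs=1e-4)


def test_expected_info_all_zero_is_domain_error():
    with pytest.raises(ValueError):
        expected_info([0, 0])


@given(st.lists(st.integers(0, 50), min_size=1, max_size=6).filter(lambda c: sum(c) > 0))
def test_expected_info_bounds(counts):
    h = expected_info(counts)
    k = sum(1 for c in counts if c > 0)
    assert -1e-12 <= h <= np.log2(max(k, 1)) + 1e-12


def test_expected_info_maximal_at_uniform_counts():
    assert expected_info([7, 7, 7]) == pytest.approx(np.log2(3))


def test_split_info_single_valued_attribute_equals_parent_info():
    rows = [{"a": "only"}] * 5
    ds = LabeledDataset(["a"], rows, ["x", "x", "y", "y", "y"])
    assert split_info(ds, "a") == pytest.approx(expected_info([2, 3]))


def test_split_info_pure_subsets_is_zero():
    rows = [{"a": "u"}] * 3 + [{"a": "v"}] * 3
    ds = LabeledDataset(["a"], rows, ["x"] * 3 + ["y"] * 3)
    assert split_info(ds, "a") == 0.0


def test_split_info_two_subset_example():
    assert split_info(_two_subset_dataset(), "a") == pytest.approx(0.9057, abs=1e-4)


def test_info_gain_two_subset_example():
    ds = _two_subset_dataset()
    assert expected_info(list(ds.class_counts.values())) == pytest.approx(0.9544, abs=1e-4)
    assert info_gain(ds, "a") == pytest.approx(0.0488, abs=1e-4)


def test_gain_zero_for_single_valued_and_full_for_separator():
    rows = [{"c": "only", "sep": lab} for lab in ["x", "y", "x", "y"]]
    ds = LabeledDataset(["c", "sep"], rows, [r["sep"] for r in rows])
    assert info_gain(ds, "c") == pytest.approx(0.0)
    assert info_gain(ds, "sep") == pytest.approx(expected_info([2, 2]))


def test_select_attribute_prefers_separator_over_constant():
    rows = [{"c": "k", "sep": lab} for lab in ["x", "y", "x", "y"]]
    ds = LabeledDataset(["c", "sep"], rows, [r["sep"] for r in rows])
    assert select_attribute(ds, ["c", "sep"]) == "sep"
    assert select_attribute(ds, ["c"]) == "c"  # single candidate


def test_entropy_and_selection_agree_with_brute_force_oracle():
    """Gain arithmetic and argmax match an independent re-derivation."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        attrs, rows, labels = random_dataset(rng, max_rows=30, max_attrs=3)
        ds = LabeledDataset(attrs, rows, labels)
        counts = list(ds.class_counts.values())
        assert expected_info(counts) == pytest.approx(brute_expected_info(counts))
        for a in attrs:
            assert split_info(ds, a) == pytest.approx(brute_split_info(rows, labels, a))
            assert info_gain(ds, a) == pytest.approx(brute_info_gain(rows, labels, a))
        assert select_attribute(ds, attrs) == brute_best_attribute(rows, labels, attrs)


@given(st.integers(0, 2**31 - 1))
def test_info_gain_never_negative(seed):
    attrs, rows, labels = random_dataset(np.random.default_rng(seed), max_rows=25)
    ds = LabeledDataset(attrs, rows, labels)
    for a in attrs:
        assert info_gain(ds, a) >= -1e-12


# ---------------------------------------------------------------------------
# Tree building


def test_single_class_collapses_to_leaf():
    ds = LabeledDataset(["a"], [{"a": "u"}, {"a": "v"}], ["x", "x"])
    tree = build_id3(ds)
    assert tree.is_leaf and tree.label == "x"


def test_perfect_separator_gives_depth_one_pure_tree():
    rows = [{"sep": lab, "junk": "k"} for lab in ["x", "y", "x", "y"]]
    ds = LabeledDataset(["sep", "junk"], rows, [r["sep"] for r in rows])
    tree = build_id3(ds)
    assert tree.attribute == "sep"
    assert all(child.is_leaf for child in tree.children.values())
    assert training_accuracy(tree, ds) == 1.0


def test_tennis_tree_is_consistent_and_respects_structure(tennis_dataset):
    tree = build_id3(tennis_dataset)
    assert tree.attribute == "outlook"  # the classic gain-maximizing root
    assert training_accuracy(tree, tennis_dataset) == 1.0

    def no_repeats(node, seen):
        if node.is_leaf:
            return True
        assert node.attribute not in seen
        assert len(node.children) >= 1
        return all(no_repeats(c, seen | {node.attribute}) for c in node.children.values())

    assert no_repeats(tree, set())

    def depth(node):
        return 0 if node.is_leaf else 1 + max(depth(c) for c in node.children.values())

    assert depth(tree) <= len(tennis_dataset.attributes)


def test_classify_unseen_value_falls_through_to_majority(tennis_dataset):
    tree = build_id3(tennis_dataset)
    row = {"outlook": "blizzard", "temperature": "hot", "humidity": "high", "wind": "weak"}
    assert tree.classify(row) == tree.majority


def test_classify_missing_tested_attribute_is_input_error(tennis_dataset):
    tree = build_id3(tennis_dataset)
    with pytest.raises(TreeInputError):
        tree.classify({"temperature": "hot"})


def test_single_leaf_tree_classifies_everything_alike():
    leaf = DecisionNode(support=3, majority="x", label="x")
    assert leaf.classify({}) == "x"
    assert leaf.classify({"anything": "v"}) == "x"


def test_planted_rule_training_accuracy_is_total(planted_dataset):
    small = planted_dataset.subset([i < 30 for i in range(len(planted_dataset))])
    tree = build_id3(small)
    assert training_accuracy(tree, small) == 1.0


# ---------------------------------------------------------------------------
# Windowed training


def test_window_covering_everything_matches_plain_build(tennis_dataset):
    full = train_windowed(tennis_dataset, window_size=len(tennis_dataset), seed=0)
    assert full.to_dict() == build_id3(tennis_dataset).to_dict()


def test_windowed_terminates_consistent_on_separable_data(tennis_dataset):
    tree = train_windowed(tennis_dataset, window_size=4, max_rounds=20, seed=5)
    assert training_accuracy(tree, tennis_dataset) == 1.0


def test_windowed_round_cap_returns_first_round_tree(tennis_dataset):
    capped = train_windowed(tennis_dataset, window_size=4, max_rounds=1, seed=5)
    assert isinstance(capped, DecisionNode)


def test_windowed_single_class_is_degenerate():
    ds = LabeledDataset(["a"], [{"a": "u"}] * 4, ["x"] * 4)
    with pytest.raises(DegenerateWindowError):
        train_windowed(ds, window_size=2)


def test_windowed_is_deterministic_given_seed(tennis_dataset):
    t1 = train_windowed(tennis_dataset, window_size=5, seed=11)
    t2 = train_windowed(tennis_dataset, window_size=5, seed=11)
    assert t1.to_dict() == t2.to_dict()


# ---------------------------------------------------------------------------
# Serialization


def test_json_roundtrip(tennis_dataset):
    tree = build_id3(tennis_dataset)
    clone = DecisionNode.from_dict(json.loads(tree.to_json()))
    assert clone.to_dict() == tree.to_dict()
    for row, label in zip(tennis_dataset.rows, tennis_dataset.labels):
        assert clone.classify(row) == label


def test_dot_export_names_attributes_and_leaves(tennis_dataset):
    dot = build_id3(tennis_dataset).to_dot()
    assert dot.startswith("digraph")
    assert "outlook?" in dot and "->" in dot
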