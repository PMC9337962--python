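"""Classic ID3 decision-tree induction.

Implements the textbook greedy recursion: at each node the attribute with
the highest information gain

    G(A) = I(s_1, ..., s_n) - E(A),
    I = -sum_i p_i log2 p_i,
    E(A) = sum_d (|S_d| / s) * I(S_d),

is selected, the data are split multiway on its values, and the recursion
continues on each subset with the remaining attributes.  Also provides the
windowed main algorithm: train on a random window, add misclassified rows,
repeat until the tree is consistent with all the data or a round cap hits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import GRADES, LabeledDataset
from .errors import DatasetError, DegenerateWindowError, TreeInputError


def expected_info(class_counts: Sequence[int]) -> float:
    """Expected information -sum p_i log2 p_i of a class-count vector, in bits.

    Zero counts contribute nothing; an all-zero vector is a domain error.
    """
    total = sum(class_counts)
    if total <= 0:
        raise ValueError("all class counts are zero")
    if any(c < 0 for c in class_counts):
        raise ValueError("negative class count")
    bits = 0.0
    for c in class_counts:
        if c > 0:
            p = c / total
            bits -= p * math.log2(p)
    return bits


def split_info(dataset: LabeledDataset, attribute: str) -> float:
    """E(A): subset-size-weighted expected information after splitting on A."""
    s = len(dataset)
    if s == 0:
        raise DatasetError("empty dataset")
    total = 0.0
    for subset in dataset.partition(attribute).values():
        weight = len(subset) / s
        total += weight * expected_info(list(subset.class_counts.values()))
    return total


def info_gain(dataset: LabeledDataset, attribute: str) -> float:
    """Information gain G(A) = I - E(A); non-negative up to rounding."""
    parent = expected_info(list(dataset.class_counts.values()))
    return parent - split_info(dataset, attribute)


def select_attribute(dataset: LabeledDataset, candidates: Sequence[str]) -> str:
    """Attribute with the highest gain; ties break by candidate-list order."""
    if not candidates:
        raise ValueError("no candidate attributes")
    best = candidates[0]
    best_gain = info_gain(dataset, best)
    for a in candidates[1:]:
        g = info_gain(dataset, a)
        if g > best_gain + 1e-12:
            best, best_gain = a, g
    return best


def majority_label(dataset: LabeledDataset) -> str:
    """Most frequent class; ties prefer the better grade, then lexicographic."""
    counts = dataset.class_counts
    if not counts:
        raise DatasetError("empty dataset has no majority")
    top = max(counts.values())
    tied = [label for label, c in counts.items() if c == top]

    def key(label: str) -> tuple[int, str]:
        rank = GRADES.index(label) if label in GRADES else -1
        return (-rank, label)

    return min(tied, key=key)


@dataclass
class DecisionNode:
    """One node of a multiway ID3 tree.

    A leaf carries ``label``; an internal node carries the tested
    ``attribute`` and one child per observed value.  Every node stores its
    training ``support`` and ``majority`` class so that unseen attribute
    values at classification time fall through to the local majority.
    """

    support: int
    majority: str
    label: str | None = None
    attribute: str | None = None
    children: dict[str, "DecisionNode"] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def classify(self, row: Mapping[str, str]) -> str:
        if self.is_leaf:
            return self.label  # type: ignore[return-value]
        assert self.attribute is not None
        if self.attribute not in row:
            raise TreeInputError(f"row lacks tested attribute {self.attribute!r}")
        child = self.children.get(row[self.attribute])
        if child is None:
            return self.majority  # value unseen in training
        return child.classify(row)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"kind": "leaf", "label": self.label, "support": self.support}
        return {
            "kind": "multiway-test",
            "attribute": self.attribute,
            "support": self.support,
            "majority": self.majority,
            "children": {v: c.to_dict() for v, c in self.children.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DecisionNode":
        if data["kind"] == "leaf":
            return cls(support=data["support"], majority=data["label"], label=data["label"])
        return cls(
            support=data["support"],
            majority=data["majority"],
            attribute=data["attribute"],
            children={v: cls.from_dict(c) for v, c in data["children"].items()},
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_dot(self, name: str = "id3") -> str:
        """Graphviz DOT source for the tree (plain text, not rendered)."""
        lines = [f"digraph {name} {{", "  node [shape=box];"]
        counter = [0]

        def walk(node: "DecisionNode") -> int:
            idx = counter[0]
            counter[0] += 1
            if node.is_leaf:
                lines.append(f'  n{idx} [label="{node.label}\\n(n={node.support})", shape=ellipse];')
            else:
                lines.append(f'  n{idx} [label="{node.attribute}?"];')
                for value, child in node.children.items():
                    cidx = walk(child)
                    lines.append(f'  n{idx} -> n{cidx} [label="{value}"];')
            return idx

        walk(self)
        lines.append("}")
        return "\n".join(lines)


def build_id3(
    dataset: LabeledDataset,
    candidates: Sequence[str] | None = None,
    _parent_majority: str | None = None,
) -> DecisionNode:
    """Grow a multiway ID3 tree by recursive gain-maximizing splits.

    Recursion stops at a single-class subset (leaf of that class), when
    candidates are exhausted or the rows are attribute-uniform (leaf of the
    majority class), or when a branch receives no rows (leaf of the parent's
    majority class).  No attribute repeats along any root-to-leaf path.
    """
    if len(dataset) == 0:
        if _parent_majority is None:
            raise DatasetError("empty dataset at root")
        return DecisionNode(support=0, majority=_parent_majority, label=_parent_majority)
    if candidates is None:
        candidates = list(dataset.attributes)

    counts = dataset.class_counts
    majority = majority_label(dataset)
    if len(counts) == 1:
        only = next(iter(counts))
        return DecisionNode(support=len(dataset), majority=only, label=only)

    usable = [a for a in candidates if len(dataset.attribute_values(a)) > 1]
    if not usable:  # exhausted or attribute-uniform
        return DecisionNode(support=len(dataset), majority=majority, label=majority)

    attribute = select_attribute(dataset, usable)
    remaining = [a for a in usable if a != attribute]
    node = DecisionNode(support=len(dataset), majority=majority, attribute=attribute)
    for value, subset in dataset.partition(attribute).items():
        node.children[value] = build_id3(subset, remaining, _parent_majority=majority)
    return node


def training_accuracy(tree, dataset: LabeledDataset) -> float:
    """Fraction of dataset rows the tree labels correctly."""
    if len(dataset) == 0:
        raise DatasetError("empty dataset")
    hits = sum(tree.classify(row) == label for row, label in zip(dataset.rows, dataset.labels))
    return hits / len(dataset)


def train_windowed(
    dataset: LabeledDataset,
    window_size: int | None = None,
    max_rounds: int = 10,
    seed: int = 0,
) -> DecisionNode:
    """Windowed main algorithm around :func:`build_id3`.

    A random window (containing at least two classes) seeds the first tree;
    each round the rows the current tree misclassifies are added to the
    window and the tree is rebuilt.  Stops when the tree classifies every
    row outside the window correctly, or after *max_rounds* rounds.
    Deterministic for a given seed.
    """
    n = len(dataset)
    if n == 0:
        raise DatasetError("empty dataset")
    if len(dataset.class_counts) < 2:
        raise DegenerateWindowError("windowed training needs at least two classes")
    if window_size is None:
        window_size = max(2, n // 2)
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    window_size = min(window_size, n)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    in_window = np.zeros(n, dtype=bool)
    in_window[order[:window_size]] = True
    # guarantee a mixed window: pull in one row of any class not yet present
    present = {dataset.labels[i] for i in np.flatnonzero(in_window)}
    for cls in dataset.classes:
        if cls not in present:
            for i in order:
                if dataset.labels[i] == cls:
                    in_window[i] = True
                    break

    tree = build_id3(dataset.subset(in_window.tolist()))
    for _ in range(max_rounds - 1):
        wrong = [
            i
            for i in range(n)
            if not in_window[i] and tree.classify(dataset.rows[i]) != dataset.labels[i]
        ]
        if not wrong:
            break
        in_window[wrong] = True
        tree = build_id3(dataset.subset(in_window.tolist()))
    return tree


def classify(tree: DecisionNode, row: Mapping[str, str]) -> str:
    """Module-level alias for ``tree.classify(row)``."""
    return tree.classify(row)
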