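"""Binary-tree ID3 variant with the Maclaurin-simplified split criterion.

The classic criterion scores a split by the entropy of each child,

    H = -(p/(p+n)) log2(p/(p+n)) - (n/(p+n)) log2(n/(p+n)),

which is expensive (logarithms) and biased toward many-valued attributes.
Substituting the second-order Maclaurin expansion ln(1+x) ~ x - x^2/2 into
the child entropies collapses the size-weighted sum, up to a constant
factor 2/ln 2 and the 1/s normalization, to

    G'(F) = sum_j p_j n_j / (p_j + n_j),

with (p_j, n_j) the positive/negative counts in branch j.  G'(F)
approximates the *post-split impurity*, so the best test minimizes it.
Tests are one-vs-rest on (attribute, value) pairs, giving a strictly
binary tree: the yes-branch holds rows with F = f_j, the no-branch the rest.

For more than two classes the criterion generalizes through the identity
p n / (p + n) = |S| (1 - q_+^2 - q_-^2) / 2 to the Gini-style impurity
sum_j |S_j| (1 - sum_i q_ij^2) / 2, which reduces exactly to G'(F) in the
two-class case.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .cohort import LabeledDataset
from .errors import DatasetError, TreeInputError
from .id3 import majority_label

_LN2 = math.log(2.0)


def binary_node_info(p: int, n: int) -> float:
    """Exact two-class node information in bits; 0 for a pure node."""
    total = p + n
    if total <= 0:
        raise ValueError("p + n must be >= 1")
    if p < 0 or n < 0:
        raise ValueError("counts must be non-negative")
    if p == 0 or n == 0:
        return 0.0
    fp, fn = p / total, n / total
    return -fp * math.log2(fp) - fn * math.log2(fn)


def simplified_gain(splits: Sequence[tuple[int, int]]) -> float:
    """Maclaurin-simplified split criterion sum_j p_j n_j / (p_j + n_j).

    Lower is better: the sum approximates the size-weighted post-split
    impurity, and it is 0 exactly when every branch is pure.
    """
    if not splits:
        raise ValueError("empty split list")
    total = 0.0
    for p, n in splits:
        if p + n < 1:
            raise ValueError("every branch needs at least one row")
        total += p * n / (p + n)
    return total


def generalized_impurity(branch_counts: Sequence[Sequence[int]]) -> float:
    """Multiclass extension sum_j |S_j| (1 - sum_i q_ij^2) / 2.

    Identical to :func:`simplified_gain` whenever each branch has exactly
    two classes (the identity p n/(p+n) = |S|(1 - q_+^2 - q_-^2)/2).
    """
    if not branch_counts:
        raise ValueError("empty branch list")
    total = 0.0
    for counts in branch_counts:
        size = sum(counts)
        if size < 1:
            raise ValueError("every branch needs at least one row")
        gini = 1.0 - sum((c / size) ** 2 for c in counts)
        total += size * gini / 2.0
    return total


def approximation_error(p: int, n: int) -> float:
    """Gap between exact node information and its Maclaurin surrogate.

    |H(p, n) - (2/ln 2) * p n / (p + n)^2|; tends to 0 as the node
    approaches purity (the expansion is taken around a vanishing minority
    fraction) and is largest, ~0.279 bits, at the balanced point.
    """
    total = p + n
    exact = binary_node_info(p, n)
    if p == 0 or n == 0:
        return 0.0
    surrogate = (2.0 / _LN2) * p * n / (total * total)
    return abs(exact - surrogate)


@dataclass(frozen=True)
class BinaryTest:
    """One-vs-rest test: does the row have ``value`` for ``attribute``?"""

    attribute: str
    value: str

    def matches(self, row: Mapping[str, str]) -> bool:
        if self.attribute not in row:
            raise TreeInputError(f"row lacks tested attribute {self.attribute!r}")
        return row[self.attribute] == self.value


@dataclass
class BinaryNode:
    """Node of the strictly binary tree: a leaf or a test with yes/no children."""

    support: int
    majority: str
    label: str | None = None
    test: BinaryTest | None = None
    yes: "BinaryNode | None" = None
    no: "BinaryNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def classify(self, row: Mapping[str, str]) -> str:
        if self.is_leaf:
            return self.label  # type: ignore[return-value]
        assert self.test is not None and self.yes is not None and self.no is not None
        return (self.yes if self.test.matches(row) else self.no).classify(row)

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"kind": "leaf", "label": self.label, "support": self.support}
        return {
            "kind": "binary-test",
            "attribute": self.test.attribute,  # type: ignore[union-attr]
            "value": self.test.value,  # type: ignore[union-attr]
            "support": self.support,
            "majority": self.majority,
            "yes": self.yes.to_dict(),  # type: ignore[union-attr]
            "no": self.no.to_dict(),  # type: ignore[union-attr]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BinaryNode":
        if data["kind"] == "leaf":
            return cls(support=data["support"], majority=data["label"], label=data["label"])
        return cls(
            support=data["support"],
            majority=data["majority"],
            test=BinaryTest(data["attribute"], data["value"]),
            yes=cls.from_dict(data["yes"]),
            no=cls.from_dict(data["no"]),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_dot(self, name: str = "binary_id3") -> str:
        lines = [f"digraph {name} {{", "  node [shape=box];"]
        counter = [0]

        def walk(node: "BinaryNode") -> int:
            idx = counter[0]
            counter[0] += 1
            if node.is_leaf:
                lines.append(f'  n{idx} [label="{node.label}\\n(n={node.support})", shape=ellipse];')
            else:
                t = node.test
                lines.append(f'  n{idx} [label="{t.attribute} = {t.value}?"];')
                yidx = walk(node.yes)
                lines.append(f'  n{idx} -> n{yidx} [label="Y"];')
                nidx = walk(node.no)
                lines.append(f'  n{idx} -> n{nidx} [label="N"];')
            return idx

        walk(self)
        lines.append("}")
        return "\n".join(lines)


def _branch_counts(dataset: LabeledDataset, test: BinaryTest) -> tuple[list[int], list[int]]:
    classes = dataset.classes
    index = {c: i for i, c in enumerate(classes)}
    yes = [0] * len(classes)
    no = [0] * len(classes)
    for row, label in zip(dataset.rows, dataset.labels):
        (yes if test.matches(row) else no)[index[label]] += 1
    return yes, no


def candidate_tests(
    dataset: LabeledDataset, exclude: frozenset[tuple[str, str]] = frozenset()
) -> list[BinaryTest]:
    """All (attribute, value) one-vs-rest tests, in deterministic order."""
    tests = []
    for attribute in dataset.attributes:
        for value in dataset.attribute_values(attribute):
            if (attribute, value) not in exclude:
                tests.append(BinaryTest(attribute, value))
    return tests


def split_impurity(dataset: LabeledDataset, test: BinaryTest) -> float | None:
    """Simplified-criterion impurity of a test, or None if it is degenerate."""
    yes, no = _branch_counts(dataset, test)
    if sum(yes) == 0 or sum(no) == 0:
        return None
    return generalized_impurity([yes, no])


def select_binary_test(
    dataset: LabeledDataset, candidates: Sequence[BinaryTest]
) -> BinaryTest | None:
    """Test minimizing the simplified criterion; None when no test splits.

    Two-class datasets score by G'(F) directly; more classes use the
    generalized impurity.  Ties break by candidate order.
    """
    if not candidates:
        raise ValueError("no candidate tests")
    best: BinaryTest | None = None
    best_score = math.inf
    for test in candidates:
        score = split_impurity(dataset, test)
        if score is not None and score < best_score - 1e-12:
            best, best_score = test, score
    return best


def attribute_simplified_gain(dataset: LabeledDataset, attribute: str) -> float:
    """The per-attribute reading of the criterion: G' summed over the
    attribute's multiway partition rather than over a single yes/no test.

    Provided for analysis; tree construction uses one-vs-rest tests.
    """
    parts = dataset.partition(attribute)
    classes = dataset.classes
    branch_counts = [
        [sub.class_counts.get(c, 0) for c in classes] for sub in parts.values()
    ]
    return generalized_impurity(branch_counts)


def build_binary_tree(dataset: LabeledDataset, max_depth: int = 25) -> BinaryNode:
    """Grow the strictly binary tree by recursive impurity-minimizing tests.

    Stops on purity, on depth exhaustion, or when no candidate test splits
    the rows into two non-empty halves.  A tested (attribute, value) pair is
    not retested on its own yes-path (there it is vacuously true).  The
    default depth cap guarantees termination on label-inconsistent data.
    """
    if len(dataset) == 0:
        raise DatasetError("empty dataset at root")
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    return _grow(dataset, max_depth, frozenset())


def _grow(
    dataset: LabeledDataset, depth_left: int, exclude: frozenset[tuple[str, str]]
) -> BinaryNode:
    majority = majority_label(dataset)
    if len(dataset.class_counts) == 1:
        return BinaryNode(support=len(dataset), majority=majority, label=majority)

    candidates = candidate_tests(dataset, exclude)
    test = select_binary_test(dataset, candidates) if candidates else None
    if test is None or depth_left < 1:
        return BinaryNode(support=len(dataset), majority=majority, label=majority)

    mask = [test.matches(row) for row in dataset.rows]
    return BinaryNode(
        support=len(dataset),
        majority=majority,
        test=test,
        yes=_grow(dataset.subset(mask), depth_left - 1, exclude | {(test.attribute, test.value)}),
        no=_grow(dataset.subset([not m for m in mask]), depth_left - 1, exclude),
    )


def classify(tree: BinaryNode, row: Mapping[str, str]) -> str:
    """Module-level alias for ``tree.classify(row)``."""
    return tree.classify(row)
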