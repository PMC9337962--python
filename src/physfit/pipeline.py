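"""End-to-end evaluation: composite scoring, hierarchical decisions,
sports-mode recommendation and the two-algorithm comparison metrics.

The hierarchy is two-level: secondary indicators (the measured battery)
roll up into primary indicators (body composition, cardiorespiratory
fitness, flexibility, speed, strength) by AHP-weighted means; primaries
roll up into the overall score the same way.  Decision trees reproduce the
same secondary -> primary -> overall structure categorically: per-primary
trees read secondary grades, the overall tree reads primary grades.

Comparison metrics between the improved (binary, simplified-criterion) and
classic trees:

* entropy ratio — 100 x the ratio of the subset-weighted class-entropy sums
  accumulated over every node of each tree (improved / classic); below 100%
  means the improved tree carries less residual disorder;
* information loss rate — 100 x (1 - I(Y; Yhat) / H(Y)), the share of label
  information the classifier fails to transmit;
* accuracy — agreement with ground-truth labels on held-out rows;
* relative time — wall-clock training time, reported but never asserted.
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .ahp import WeightVector
from .binary_tree import BinaryNode, build_binary_tree
from .cohort import GRADES, LabeledDataset, ScoredRecord, discretize, grade_rank
from .errors import ConfigurationError, DatasetError, TreeInputError, UndefinedMetricError
from .id3 import DecisionNode, build_id3, expected_info, training_accuracy

#: Representative 0-100 score of each grade band (band midpoints), used when
#: a composite must be formed from grades rather than raw scores.
GRADE_VALUES: dict[str, float] = {"excellent": 92.5, "good": 80.0, "medium": 67.5, "poor": 30.0}


# ---------------------------------------------------------------------------
# Hierarchy


@dataclass
class PrimaryIndicator:
    """A primary indicator: named children with an AHP weight vector."""

    name: str
    children: list[str]
    weights: WeightVector

    def __post_init__(self) -> None:
        if len(self.children) != len(self.weights):
            raise ConfigurationError(
                f"primary {self.name!r}: {len(self.children)} children but "
                f"{len(self.weights)} weights"
            )


@dataclass
class IndicatorHierarchy:
    """Two-level indicator hierarchy with AHP weights at both levels."""

    primaries: list[PrimaryIndicator]
    primary_weights: WeightVector

    def __post_init__(self) -> None:
        if len(self.primaries) != len(self.primary_weights):
            raise ConfigurationError("primary count does not match primary weight count")

    @property
    def primary_names(self) -> list[str]:
        return [p.name for p in self.primaries]

    @property
    def secondary_names(self) -> list[str]:
        names: list[str] = []
        for p in self.primaries:
            for c in p.children:
                if c not in names:
                    names.append(c)
        return names


def primary_scores(
    scores: Mapping[str, float], hierarchy: IndicatorHierarchy
) -> dict[str, float]:
    """AHP-weighted mean of child scores for each primary indicator."""
    out = {}
    for p in hierarchy.primaries:
        try:
            out[p.name] = sum(p.weights[i] * scores[c] for i, c in enumerate(p.children))
        except KeyError as exc:
            raise ValueError(f"missing score for secondary indicator {exc}") from None
    return out


def composite_score(scores: Mapping[str, float], hierarchy: IndicatorHierarchy) -> float:
    """Overall 0-100 score: weighted primaries of weighted secondaries."""
    prim = primary_scores(scores, hierarchy)
    return sum(
        hierarchy.primary_weights[i] * prim[p.name] for i, p in enumerate(hierarchy.primaries)
    )


# -- planted grade rule ------------------------------------------------------


def planted_primary_grades(
    grades: Mapping[str, str], hierarchy: IndicatorHierarchy
) -> dict[str, str]:
    """Primary grades as the discretized weighted mean of child grade values.

    Working on grade *values* (band midpoints) rather than raw scores makes
    the result a deterministic function of the secondary grades — the
    property the consistency tests of the tree builders rely on.
    """
    out = {}
    for p in hierarchy.primaries:
        value = sum(p.weights[i] * GRADE_VALUES[grades[c]] for i, c in enumerate(p.children))
        out[p.name] = discretize(value)
    return out


def planted_overall_grade(grades: Mapping[str, str], hierarchy: IndicatorHierarchy) -> str:
    """Overall grade: weighted mean of primary grade values, discretized."""
    prim = planted_primary_grades(grades, hierarchy)
    value = sum(
        hierarchy.primary_weights[i] * GRADE_VALUES[prim[p.name]]
        for i, p in enumerate(hierarchy.primaries)
    )
    return discretize(value)


# ---------------------------------------------------------------------------
# Hierarchical decision


def evaluate_hierarchy(
    record: ScoredRecord,
    hierarchy: IndicatorHierarchy,
    trees: Mapping[str, DecisionNode | BinaryNode],
) -> dict[str, str]:
    """Run the secondary -> primary -> overall tree cascade for one record.

    *trees* maps each primary name to a tree over secondary grades and
    ``"overall"`` to a tree over primary grades.  Returns the per-primary
    grades plus the ``"overall"`` grade; deterministic.
    """
    profile: dict[str, str] = {}
    try:
        for p in hierarchy.primaries:
            profile[p.name] = trees[p.name].classify(record.grades)
        profile["overall"] = trees["overall"].classify(profile)
    except KeyError as exc:
        raise ConfigurationError(f"no tree for level {exc}") from None
    except TreeInputError as exc:
        raise ConfigurationError(str(exc)) from None
    return profile


def train_hierarchy_trees(
    datasets: Sequence[tuple[dict[str, str], str]],
    hierarchy: IndicatorHierarchy,
    algorithm: str = "improved",
    max_depth: int = 25,
) -> dict[str, DecisionNode | BinaryNode]:
    """Train the per-primary and overall trees from (secondary-grades, label)
    pairs, labelling intermediate levels with the planted weighted-rollup rule.
    """

    def fit(attributes: list[str], rows: list[dict[str, str]], labels: list[str]):
        ds = LabeledDataset(attributes, rows, labels)
        if algorithm == "improved":
            return build_binary_tree(ds, max_depth=max_depth)
        if algorithm == "classic":
            return build_id3(ds)
        raise ValueError(f"unknown algorithm {algorithm!r}")

    trees: dict[str, DecisionNode | BinaryNode] = {}
    primary_rows: list[dict[str, str]] = []
    for grades, _ in datasets:
        primary_rows.append(planted_primary_grades(grades, hierarchy))
    for p in hierarchy.primaries:
        trees[p.name] = fit(
            list(p.children),
            [{c: g[c] for c in p.children} for g, _ in datasets],
            [pr[p.name] for pr in primary_rows],
        )
    trees["overall"] = fit(
        hierarchy.primary_names, primary_rows, [label for _, label in datasets]
    )
    return trees


# ---------------------------------------------------------------------------
# Recommendation


@dataclass
class RecommendationRule:
    """First-match recommendation rule over a grade profile.

    ``kind`` is ``"weakest-primary"`` (matches when ``primary`` is the
    weakest primary indicator — ties broken by profile order — and is not
    excellent) or ``"always"`` (the required default).
    """

    name: str
    kind: str
    modes: list[str]
    primary: str | None = None
    rationale: str = ""

    def matches(self, profile: Mapping[str, str]) -> bool:
        if self.kind == "always":
            return True
        if self.kind == "weakest-primary":
            primaries = [k for k in profile if k != "overall"]
            if self.primary not in primaries:
                return False
            weakest = min(primaries, key=lambda k: (grade_rank(profile[k]), primaries.index(k)))
            return weakest == self.primary and profile[self.primary] != "excellent"
        raise ConfigurationError(f"unknown rule kind {self.kind!r}")


def check_rule_table(rules: Sequence[RecommendationRule], primary_names: Sequence[str]) -> None:
    """Verify totality by exhausting all 4^(p+1) grade profiles."""
    if not rules:
        raise ConfigurationError("empty rule table")
    for combo in itertools.product(GRADES, repeat=len(primary_names) + 1):
        profile = dict(zip([*primary_names, "overall"], combo))
        if not any(r.matches(profile) for r in rules):
            raise ConfigurationError(f"rule table not total: no rule matches {profile}")


def recommend(
    profile: Mapping[str, str], rules: Sequence[RecommendationRule]
) -> list[str]:
    """Sports modes of the first rule matching the grade profile."""
    for rule in rules:
        if rule.matches(profile):
            return list(rule.modes)
    raise ConfigurationError("rule table not total: no rule matched")


# ---------------------------------------------------------------------------
# Comparison metrics


def _entropy_bits(labels: Sequence[str]) -> float:
    counts = pd.Series(labels).value_counts().to_numpy()
    return expected_info(counts.tolist())


def _node_entropy_sum(tree, rows: list[dict[str, str]], labels: list[str], total: int) -> float:
    """Sum of (|subset|/total) x H(subset) over every node the rows visit."""
    if not rows:
        return 0.0
    acc = (len(rows) / total) * _entropy_bits(labels)
    if tree.is_leaf:
        return acc
    if isinstance(tree, BinaryNode):
        mask = [tree.test.matches(r) for r in rows]
        for child, keep in ((tree.yes, True), (tree.no, False)):
            sub = [r for r, m in zip(rows, mask) if m is keep]
            lab = [l for l, m in zip(labels, mask) if m is keep]
            acc += _node_entropy_sum(child, sub, lab, total)
        return acc
    # multiway node: rows with values unseen in training stop here
    buckets: dict[str, tuple[list, list]] = {}
    for r, l in zip(rows, labels):
        value = r[tree.attribute]
        if value in tree.children:
            b = buckets.setdefault(value, ([], []))
            b[0].append(r)
            b[1].append(l)
    for value, (sub, lab) in buckets.items():
        acc += _node_entropy_sum(tree.children[value], sub, lab, total)
    return acc


def entropy_ratio(tree_improved, tree_classic, dataset: LabeledDataset) -> float:
    """100 x (node-entropy sum of improved tree) / (same for classic tree)."""
    if len(dataset) == 0:
        raise DatasetError("empty dataset")
    num = _node_entropy_sum(tree_improved, dataset.rows, dataset.labels, len(dataset))
    den = _node_entropy_sum(tree_classic, dataset.rows, dataset.labels, len(dataset))
    if den == 0.0:
        if num == 0.0:
            return 100.0
        raise UndefinedMetricError("classic-tree entropy sum is zero with nonzero numerator")
    return 100.0 * num / den


def information_loss_rate(tree, dataset: LabeledDataset) -> float:
    """100 x (1 - I(Y; Yhat)/H(Y)): share of label information not transmitted."""
    if len(dataset) == 0:
        raise DatasetError("empty dataset")
    h = _entropy_bits(dataset.labels)
    if h == 0.0:
        raise UndefinedMetricError("label entropy is zero (single-class dataset)")
    predictions = [tree.classify(row) for row in dataset.rows]
    mi = mutual_info_score(dataset.labels, predictions) / np.log(2)  # nats -> bits
    return float(np.clip(100.0 * (1.0 - mi / h), 0.0, 100.0))


# ---------------------------------------------------------------------------
# Group comparison


@dataclass
class GroupResult:
    group: str
    entropy_ratio: float
    loss_improved: float
    loss_classic: float
    accuracy_improved: float
    accuracy_classic: float
    time_improved: float
    time_classic: float

    @property
    def relative_time(self) -> float:
        return self.time_improved / self.time_classic if self.time_classic > 0 else float("nan")


@dataclass
class ComparisonReport:
    """Per-group and averaged metrics for the two algorithms."""

    groups: list[GroupResult] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g.group,
                "entropy_ratio_pct": g.entropy_ratio,
                "loss_improved_pct": g.loss_improved,
                "loss_classic_pct": g.loss_classic,
                "accuracy_improved_pct": g.accuracy_improved,
                "accuracy_classic_pct": g.accuracy_classic,
                "time_improved_s": g.time_improved,
                "time_classic_s": g.time_classic,
            }
            for g in self.groups
        ]
        frame = pd.DataFrame(rows)
        mean = frame.drop(columns="group").mean()
        mean["group"] = "mean"
        return pd.concat([frame, mean.to_frame().T], ignore_index=True)

    def to_json(self, **kwargs) -> str:
        frame = self.to_frame()
        return json.dumps(frame.to_dict(orient="records"), **kwargs)

    def mean(self, column: str) -> float:
        frame = self.to_frame()
        return float(frame.loc[frame["group"] == "mean", column].iloc[0])


def _split_dataset(
    dataset: LabeledDataset, fraction: float, rng: np.random.Generator
) -> tuple[LabeledDataset, LabeledDataset]:
    n = len(dataset)
    if n < 2:
        raise DatasetError("group too small to split")
    k = int(np.ceil(fraction * n))
    k = min(max(k, 1), n - 1)
    train_idx = set(rng.permutation(n)[:k].tolist())
    mask = [i in train_idx for i in range(n)]
    return dataset.subset(mask), dataset.subset([not m for m in mask])


def compare(
    groups: Sequence[LabeledDataset],
    seed: int = 0,
    train_fraction: float = 0.5,
    improved_enabled: bool = True,
    max_depth: int = 25,
) -> ComparisonReport:
    """Train both algorithms on each group and collect the comparison metrics.

    Each group is split into train/held-out halves (seeded).  The entropy
    ratio is computed on the training rows the trees were grown from; loss
    rates and accuracies on the held-out rows.  Timings are wall-clock and
    reported only.  With *improved_enabled* false the classic tree stands in
    on both sides (self-comparison: entropy ratio 100%, equal accuracies).
    """
    if not groups:
        raise ValueError("at least one group is required")
    rng = np.random.default_rng(seed)
    report = ComparisonReport()
    for g, dataset in enumerate(groups, start=1):
        train, test = _split_dataset(dataset, train_fraction, rng)

        t0 = time.perf_counter()
        classic = build_id3(train)
        t_classic = time.perf_counter() - t0

        if improved_enabled:
            t0 = time.perf_counter()
            improved = build_binary_tree(train, max_depth=max_depth)
            t_improved = time.perf_counter() - t0
        else:
            improved, t_improved = classic, t_classic

        eval_set = test if len(set(test.labels)) > 1 else dataset
        report.groups.append(
            GroupResult(
                group=f"group{g}",
                entropy_ratio=entropy_ratio(improved, classic, train),
                loss_improved=information_loss_rate(improved, eval_set),
                loss_classic=information_loss_rate(classic, eval_set),
                accuracy_improved=100.0 * training_accuracy(improved, test),
                accuracy_classic=100.0 * training_accuracy(classic, test),
                time_improved=t_improved,
                time_classic=t_classic,
            )
        )
    return report
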