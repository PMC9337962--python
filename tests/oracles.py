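"""Independent brute-force oracles used by the test suite.

Everything here is written from the definitions alone, with plain loops and
``math.log2``, deliberately sharing no code with the package under test.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def brute_entropy(labels) -> float:
    """-sum p log2 p over the label frequencies."""
    n = len(labels)
    h = 0.0
    for count in Counter(labels).values():
        p = count / n
        h -= p * math.log2(p)
    return h


def brute_expected_info(counts) -> float:
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c:
            h -= (c / total) * math.log2(c / total)
    return h


def brute_split_info(rows, labels, attribute) -> float:
    groups: dict[str, list] = {}
    for row, label in zip(rows, labels):
        groups.setdefault(row[attribute], []).append(label)
    s = len(rows)
    return sum((len(g) / s) * brute_entropy(g) for g in groups.values())


def brute_info_gain(rows, labels, attribute) -> float:
    return brute_entropy(labels) - brute_split_info(rows, labels, attribute)


def brute_best_attribute(rows, labels, candidates) -> str:
    """Exhaustive argmax of information gain, first-wins on ties."""
    best, best_gain = candidates[0], brute_info_gain(rows, labels, candidates[0])
    for a in candidates[1:]:
        g = brute_info_gain(rows, labels, a)
        if g > best_gain + 1e-12:
            best, best_gain = a, g
    return best


def binary_partition_gain(rows, labels, attribute, value) -> float | None:
    """Exact gain of the one-vs-rest split on (attribute, value)."""
    yes = [l for r, l in zip(rows, labels) if r[attribute] == value]
    no = [l for r, l in zip(rows, labels) if r[attribute] != value]
    if not yes or not no:
        return None
    s = len(labels)
    return (
        brute_entropy(labels)
        - (len(yes) / s) * brute_entropy(yes)
        - (len(no) / s) * brute_entropy(no)
    )


def brute_mutual_information(xs, ys) -> float:
    """I(X; Y) in bits from the raw contingency counts."""
    n = len(xs)
    joint = Counter(zip(xs, ys))
    px = Counter(xs)
    py = Counter(ys)
    mi = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        mi += pxy * math.log2(pxy / ((px[x] / n) * (py[y] / n)))
    return mi


def dominant_eigenvalue(matrix) -> float:
    """Largest-magnitude eigenvalue via numpy's full eigendecomposition."""
    eigenvalues = np.linalg.eigvals(np.asarray(matrix, dtype=float))
    return float(np.max(eigenvalues.real))


def random_dataset(rng, max_rows=50, max_attrs=4, max_values=4, classes=("pos", "neg")):
    """A random categorical dataset with at least two classes present."""
    n_rows = int(rng.integers(4, max_rows + 1))
    n_attrs = int(rng.integers(1, max_attrs + 1))
    attrs = [f"a{i}" for i in range(n_attrs)]
    domains = [int(rng.integers(2, max_values + 1)) for _ in range(n_attrs)]
    rows = [
        {a: f"v{rng.integers(0, d)}" for a, d in zip(attrs, domains)} for _ in range(n_rows)
    ]
    labels = [str(rng.choice(classes)) for _ in range(n_rows)]
    if len(set(labels)) < 2:
        labels[0], labels[1] = classes[0], classes[1]
    return attrs, rows, labels
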