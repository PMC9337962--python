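"""Analytic hierarchy process: judgment matrices, weights, consistency.

A judgment matrix M = (m_ij) records pairwise relative importances of n
indicators on Saaty's 1-9 scale.  It must be positive, unit-diagonal and
reciprocal (m_ij * m_ji = 1).  Weights are extracted by the normalized
column-sum scheme: column-normalize M, sum each row, normalize the row sums
to 1.  Consistency is judged through

    lambda_max = (1/n) * sum_i (M w)_i / w_i,
    CI = (lambda_max - n) / (n - 1),
    CR = CI / RI(n),

accepting the matrix when CR < 0.1 (orders 1-2 are consistent by
construction and always pass).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import MatrixValidationError, UnsupportedOrderError

#: Saaty's average random consistency index, indexed by matrix order.
RANDOM_INDEX: dict[int, float] = {
    1: 0.0,
    2: 0.0,
    3: 0.58,
    4: 0.90,
    5: 1.12,
    6: 1.24,
    7: 1.32,
    8: 1.41,
    9: 1.45,
}

RECIPROCITY_TOL = 1e-9


@dataclass(frozen=True)
class JudgmentMatrix:
    """Validated positive reciprocal pairwise-comparison matrix."""

    entries: np.ndarray

    @property
    def order(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class WeightVector:
    """Strictly positive weights summing to 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be positive and sum to 1")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)

    def __getitem__(self, i: int) -> float:
        return float(self.weights[i])


@dataclass(frozen=True)
class ConsistencyReport:
    """Consistency diagnostics of a judgment matrix."""

    lambda_max: float
    CI: float
    RI: float
    CR: float
    passed: bool

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "lambda_max": self.lambda_max,
                "CI": self.CI,
                "RI": self.RI,
                "CR": self.CR,
                "pass": self.passed,
            },
            **kwargs,
        )


def validate_matrix(entries) -> JudgmentMatrix:
    """Check squareness, positivity, unit diagonal and reciprocity.

    Reciprocity (m_ij * m_ji = 1) is enforced to within 1e-9; violations
    report the offending index pair.
    """
    m = np.asarray(entries, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise MatrixValidationError(f"matrix must be square, got shape {m.shape}")
    n = m.shape[0]
    if n < 2:
        raise MatrixValidationError("order must be >= 2")
    bad = np.argwhere(m <= 0)
    if len(bad):
        i, j = bad[0]
        raise MatrixValidationError(f"non-positive entry m[{i},{j}] = {m[i, j]}")
    for i in range(n):
        if abs(m[i, i] - 1.0) > RECIPROCITY_TOL:
            raise MatrixValidationError(f"diagonal entry m[{i},{i}] = {m[i, i]} != 1")
    for i in range(n):
        for j in range(i + 1, n):
            if abs(m[i, j] * m[j, i] - 1.0) > RECIPROCITY_TOL:
                raise MatrixValidationError(
                    f"reciprocity violated at ({i},{j}): {m[i, j]} * {m[j, i]} != 1"
                )
    return JudgmentMatrix(entries=m)


def compute_weights(matrix: JudgmentMatrix) -> WeightVector:
    """Normalized column-sum weight extraction.

    t_ij = m_ij / sum_i m_ij; v_i = sum_j t_ij; w_i = v_i / sum v_i.
    Exact for perfectly consistent matrices (m_ij = w_i / w_j).
    """
    m = matrix.entries
    t = m / m.sum(axis=0, keepdims=True)
    v = t.sum(axis=1)
    return WeightVector(weights=v / v.sum())


def lambda_max(matrix: JudgmentMatrix, weights: WeightVector) -> float:
    """Dominant-eigenvalue approximation (1/n) sum_i (M w)_i / w_i."""
    m = matrix.entries
    w = weights.weights
    if len(w) != matrix.order:
        raise ValueError("weight length does not match matrix order")
    aw = m @ w
    return float(np.mean(aw / w))


def consistency(matrix: JudgmentMatrix) -> ConsistencyReport:
    """Full consistency test: CI = (lambda_max - n)/(n - 1), CR = CI/RI.

    Passes when CR < 0.1.  Orders 1-2 are structurally consistent: CI and
    CR are defined as 0 and the test always passes.
    """
    n = matrix.order
    if n not in RANDOM_INDEX:
        raise UnsupportedOrderError(f"no random index for order {n}")
    w = compute_weights(matrix)
    lam = lambda_max(matrix, w)
    if n <= 2:
        return ConsistencyReport(lambda_max=lam, CI=0.0, RI=RANDOM_INDEX[n], CR=0.0, passed=True)
    ci = (lam - n) / (n - 1)
    ri = RANDOM_INDEX[n]
    cr = ci / ri
    return ConsistencyReport(lambda_max=lam, CI=ci, RI=ri, CR=cr, passed=cr < 0.1)


def matrix_to_json(matrix: JudgmentMatrix, **kwargs) -> str:
    """Serialize as {"order": n, "entries": row-major list}."""
    return json.dumps(
        {"order": matrix.order, "entries": matrix.entries.ravel().tolist()}, **kwargs
    )


def matrix_from_json(text: str) -> JudgmentMatrix:
    data = json.loads(text)
    n = data["order"]
    return validate_matrix(np.asarray(data["entries"], dtype=float).reshape(n, n))
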