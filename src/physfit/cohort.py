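"""Student fitness records: tabular I/O, preprocessing and labeled datasets.

The cohort model covers the data-handling half of the evaluation tool:

* :class:`StudentRecord` — one subject's raw, sex-specific measurements;
* :class:`IndicatorDefinition` — a piecewise-linear scoring table turning a
  raw measurement into a 0-100 score;
* :func:`discretize` — the four-grade cut (excellent / good / medium / poor
  at 85 / 75 / 60, left-closed);
* :class:`LabeledDataset` — the categorical attribute matrix the decision
  trees consume, with cached class counts;
* preprocessing: :func:`impute_missing` (drop-row or sex-stratified
  attribute mean) and :func:`reduce_attributes` (normalized-mutual-information
  relevance filter).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .errors import (
    CohortFormatError,
    CohortValidationError,
    DatasetError,
    ImputationError,
    MissingScoreError,
)

# ---------------------------------------------------------------------------
# Grades

#: Grades from worst to best; comparisons use this total order.
GRADES: tuple[str, ...] = ("poor", "medium", "good", "excellent")

#: Left-closed lower bounds of each grade band on the 0-100 score scale.
GRADE_CUTS: dict[str, float] = {"excellent": 85.0, "good": 75.0, "medium": 60.0, "poor": 0.0}

SEXES = ("male", "female")

#: Canonical secondary-indicator names, in the fixed order used throughout.
INDICATORS: tuple[str, ...] = (
    "bmi",
    "vital_capacity",
    "sit_and_reach",
    "standing_long_jump",
    "sprint_50m",
    "endurance_run",
    "strength_count",
)


def grade_rank(grade: str) -> int:
    """Position of *grade* in the worst-to-best order (poor=0 ... excellent=3)."""
    try:
        return GRADES.index(grade)
    except ValueError:
        raise ValueError(f"unknown grade {grade!r}") from None


def discretize(score: float) -> str:
    """Map a 0-100 score to a grade with left-closed bands.

    [85, 100] -> excellent, [75, 85) -> good, [60, 75) -> medium,
    [0, 60) -> poor.  Scores outside [0, 100] are a domain error.
    """
    if not (0.0 <= score <= 100.0):
        raise ValueError(f"score {score} outside [0, 100]")
    if score >= 85.0:
        return "excellent"
    if score >= 75.0:
        return "good"
    if score >= 60.0:
        return "medium"
    return "poor"


# ---------------------------------------------------------------------------
# Records


@dataclass
class StudentRecord:
    """Raw fitness measurements for one subject.

    ``measurements`` maps indicator name to a finite value in the
    indicator's native unit; a missing measurement is stored as ``None``.
    """

    subject_id: str
    sex: str
    measurements: dict[str, float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortValidationError(
                f"subject {self.subject_id!r}: sex must be one of {SEXES}, got {self.sex!r}"
            )
        for name, value in self.measurements.items():
            if value is None:
                continue
            if not math.isfinite(value):
                raise CohortValidationError(
                    f"subject {self.subject_id!r}: non-finite {name} = {value!r}"
                )

    def is_missing(self, indicator: str) -> bool:
        return self.measurements.get(indicator) is None

    @property
    def missing_indicators(self) -> list[str]:
        return [k for k, v in self.measurements.items() if v is None]


@dataclass
class ScoredRecord:
    """Per-indicator 0-100 scores and grades for one subject.

    ``composite`` is the AHP-weighted overall score; it is ``None`` until
    the evaluation pipeline fills it in.
    """

    subject_id: str
    scores: dict[str, float]
    grades: dict[str, str]
    composite: float | None = None

    @property
    def composite_grade(self) -> str:
        if self.composite is None:
            raise MissingScoreError(f"subject {self.subject_id!r} has no composite score")
        return discretize(self.composite)


# ---------------------------------------------------------------------------
# Scoring tables


@dataclass(frozen=True)
class IndicatorDefinition:
    """Sex-specific piecewise-linear scoring table for one indicator.

    ``breakpoints[sex]`` is a sequence of ``(raw_value, score)`` pairs with
    strictly increasing raw values; scores are linearly interpolated between
    breakpoints and clipped to the end scores outside the table.  For a
    lower-is-better indicator the scores decrease along the raw axis.
    """

    name: str
    unit: str
    direction: str  # "higher-better" | "lower-better"
    breakpoints: Mapping[str, Sequence[tuple[float, float]]]

    def __post_init__(self) -> None:
        if self.direction not in ("higher-better", "lower-better"):
            raise ValueError(f"{self.name}: bad direction {self.direction!r}")
        for sex, pts in self.breakpoints.items():
            xs = [p[0] for p in pts]
            ys = [p[1] for p in pts]
            if len(pts) < 2 or any(b <= a for a, b in zip(xs, xs[1:])):
                raise ValueError(f"{self.name}/{sex}: breakpoints must strictly increase")
            if any(not (0.0 <= y <= 100.0) for y in ys):
                raise ValueError(f"{self.name}/{sex}: scores must lie in [0, 100]")
            diffs = [b - a for a, b in zip(ys, ys[1:])]
            if self.direction == "higher-better" and any(d < 0 for d in diffs):
                raise ValueError(f"{self.name}/{sex}: scores must be non-decreasing")
            if self.direction == "lower-better" and any(d > 0 for d in diffs):
                raise ValueError(f"{self.name}/{sex}: scores must be non-increasing")

    def score(self, raw: float, sex: str) -> float:
        """Interpolate *raw* into [0, 100] using the table for *sex*."""
        pts = self.breakpoints[sex]
        xs = np.array([p[0] for p in pts])
        ys = np.array([p[1] for p in pts])
        return float(np.interp(raw, xs, ys))


def score_indicator(record: StudentRecord, definition: IndicatorDefinition) -> float:
    """Score one indicator of one record; the measurement must be present."""
    value = record.measurements.get(definition.name)
    if value is None:
        raise MissingScoreError(
            f"subject {record.subject_id!r}: {definition.name} is missing; impute first"
        )
    return definition.score(value, record.sex)


def score_record(
    record: StudentRecord, definitions: Mapping[str, IndicatorDefinition]
) -> ScoredRecord:
    """Score and grade every defined indicator of *record*."""
    scores = {name: score_indicator(record, d) for name, d in definitions.items()}
    grades = {name: discretize(s) for name, s in scores.items()}
    return ScoredRecord(subject_id=record.subject_id, scores=scores, grades=grades)


# ---------------------------------------------------------------------------
# Cohort I/O


def read_cohort(path: str) -> list[StudentRecord]:
    """Read a delimited cohort file into records.

    The file is comma-separated UTF-8 with a header row; the ``id`` and
    ``sex`` columns are required and every other column is taken as an
    indicator.  Blank or unparseable numeric cells become missing entries.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CohortFormatError(f"{path}: no header row") from None
    cols = list(frame.columns)
    if "id" not in cols or "sex" not in cols:
        raise CohortFormatError(f"{path}: header must contain 'id' and 'sex', got {cols}")
    indicators = [c for c in cols if c not in ("id", "sex")]

    records: list[StudentRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        sid = row["id"].strip()
        if sid in seen:
            raise CohortValidationError(f"{path}: duplicate subject id {sid!r}")
        seen.add(sid)
        measurements: dict[str, float | None] = {}
        for name in indicators:
            cell = row[name].strip()
            try:
                measurements[name] = float(cell)
            except ValueError:
                measurements[name] = None
        records.append(StudentRecord(sid, row["sex"].strip(), measurements))
    return records


def write_cohort(records: Iterable[StudentRecord], path: str) -> None:
    """Write records to the same delimited format :func:`read_cohort` reads."""
    records = list(records)
    indicators: list[str] = []
    for r in records:
        for name in r.measurements:
            if name not in indicators:
                indicators.append(name)
    rows = []
    for r in records:
        row: dict[str, object] = {"id": r.subject_id, "sex": r.sex}
        for name in indicators:
            v = r.measurements.get(name)
            row[name] = "" if v is None else repr(v)
        rows.append(row)
    pd.DataFrame(rows, columns=["id", "sex", *indicators]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Imputation


def impute_missing(
    records: Sequence[StudentRecord], strategy: str = "attribute-mean"
) -> list[StudentRecord]:
    """Resolve missing measurements.

    ``drop-row`` removes every record with any missing measurement;
    ``attribute-mean`` fills each missing cell with the mean of the observed
    values for that indicator *within the same sex* (every indicator in the
    battery is sex-specific, so pooling sexes would bias the fill).
    """
    if strategy == "drop-row":
        return [replace(r, measurements=dict(r.measurements))
                for r in records if not r.missing_indicators]
    if strategy != "attribute-mean":
        raise ValueError(f"unknown strategy {strategy!r}")

    observed: dict[tuple[str, str], list[float]] = {}
    for r in records:
        for name, v in r.measurements.items():
            if v is not None:
                observed.setdefault((r.sex, name), []).append(v)

    out: list[StudentRecord] = []
    for r in records:
        filled = dict(r.measurements)
        for name, v in filled.items():
            if v is None:
                pool = observed.get((r.sex, name))
                if not pool:
                    raise ImputationError(
                        f"indicator {name!r} has no observed value for sex {r.sex!r}"
                    )
                filled[name] = float(np.mean(pool))
        out.append(replace(r, measurements=filled))
    return out


# ---------------------------------------------------------------------------
# Labeled datasets


@dataclass
class LabeledDataset:
    """Categorical attribute matrix with class labels.

    ``rows[i][a]`` is the (string) value of attribute ``a`` for row ``i`` and
    ``labels[i]`` its class label.  Class counts are cached on construction.
    """

    attributes: list[str]
    rows: list[dict[str, str]]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.labels):
            raise DatasetError("rows and labels differ in length")
        self._class_counts = Counter(self.labels)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def class_counts(self) -> Counter:
        return self._class_counts

    @property
    def classes(self) -> list[str]:
        return sorted(self._class_counts)

    def attribute_values(self, attribute: str) -> list[str]:
        """Distinct observed values of *attribute*, sorted for determinism."""
        if attribute not in self.attributes:
            raise DatasetError(f"unknown attribute {attribute!r}")
        return sorted({row[attribute] for row in self.rows})

    def subset(self, mask: Sequence[bool]) -> "LabeledDataset":
        return LabeledDataset(
            attributes=list(self.attributes),
            rows=[r for r, m in zip(self.rows, mask) if m],
            labels=[l for l, m in zip(self.labels, mask) if m],
        )

    def partition(self, attribute: str) -> dict[str, "LabeledDataset"]:
        """Split rows by their value of *attribute* (classic multiway split)."""
        if attribute not in self.attributes:
            raise DatasetError(f"unknown attribute {attribute!r}")
        buckets: dict[str, tuple[list[dict[str, str]], list[str]]] = {}
        for row, label in zip(self.rows, self.labels):
            rows, labels = buckets.setdefault(row[attribute], ([], []))
            rows.append(row)
            labels.append(label)
        return {
            value: LabeledDataset(list(self.attributes), rows, labels)
            for value, (rows, labels) in sorted(buckets.items())
        }

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.rows, columns=self.attributes)
        frame["_label"] = self.labels
        return frame


def to_labeled_dataset(
    records: Sequence[ScoredRecord],
    labels: Mapping[str, str] | None = None,
    dichotomy: Iterable[str] | None = None,
) -> LabeledDataset:
    """Build a grade-valued dataset from scored records.

    Attributes are the per-indicator grades.  Class labels come from
    *labels* (subject id -> label) when given, otherwise from each record's
    composite grade.  Records without a label are dropped.  When *dichotomy*
    is given, labels in that set become ``positive`` and all others
    ``negative`` — the two-class setting the simplified split criterion
    assumes.
    """
    records = list(records)
    if not records:
        raise DatasetError("empty record list")
    attributes = list(records[0].grades)
    rows: list[dict[str, str]] = []
    out_labels: list[str] = []
    positive = set(dichotomy) if dichotomy is not None else None
    for r in records:
        if labels is not None:
            label = labels.get(r.subject_id)
            if label is None:
                continue  # missing class label drops the row
        else:
            if r.composite is None:
                continue
            label = r.composite_grade
        if positive is not None:
            label = "positive" if label in positive else "negative"
        rows.append(dict(r.grades))
        out_labels.append(label)
    if not rows:
        raise DatasetError("no labeled rows")
    return LabeledDataset(attributes, rows, out_labels)


def attribute_relevance(dataset: LabeledDataset, attribute: str) -> float:
    """Normalized mutual information of *attribute* with the class label.

    MI(attribute; label) / H(label), in [0, 1]; 0 when the label is constant.
    """
    if attribute not in dataset.attributes:
        raise DatasetError(f"unknown attribute {attribute!r}")
    values = [row[attribute] for row in dataset.rows]
    mi = mutual_info_score(values, dataset.labels)
    counts = np.array(list(dataset.class_counts.values()), dtype=float)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())  # natural log; base cancels in the ratio
    if h == 0.0:
        return 0.0
    return float(mi / h)


def reduce_attributes(dataset: LabeledDataset, min_relevance: float = 0.01) -> LabeledDataset:
    """Drop attributes whose class relevance falls below *min_relevance*.

    The single most relevant attribute is always retained, so the result is
    never attribute-free.
    """
    if len(dataset) == 0:
        raise DatasetError("empty dataset")
    relevance = {a: attribute_relevance(dataset, a) for a in dataset.attributes}
    kept = [a for a in dataset.attributes if relevance[a] >= min_relevance]
    if not kept:
        kept = [max(dataset.attributes, key=lambda a: relevance[a])]
    return LabeledDataset(
        attributes=kept,
        rows=[{a: row[a] for a in kept} for row in dataset.rows],
        labels=list(dataset.labels),
    )
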