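import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from physfit.cohort import (
    GRADES,
    LabeledDataset,
    StudentRecord,
    attribute_relevance,
    discretize,
    grade_rank,
    impute_missing,
    read_cohort,
    reduce_attributes,
    score_indicator,
    to_labeled_dataset,
    write_cohort,
)
from physfit.defaults import default_definitions
from physfit.errors import (
    CohortFormatError,
    CohortValidationError,
    ImputationError,
    MissingScoreError,
)
from physfit.cohort import ScoredRecord


# ---------------------------------------------------------------------------
# I/O


def _write(tmp_path, text):
    path = tmp_path / "cohort.csv"
    path.write_text(text)
    return str(path)


def test_read_header_only_gives_empty_cohort(tmp_path):
    assert read_cohort(_write(tmp_path, "id,sex,bmi\n")) == []


def test_read_missing_id_column_is_format_error(tmp_path):
    with pytest.raises(CohortFormatError):
        read_cohort(_write(tmp_path, "sex,bmi\nmale,21\n"))


def test_read_duplicate_id_is_validation_error(tmp_path):
    with pytest.raises(CohortValidationError):
        read_cohort(_write(tmp_path, "id,sex,bmi\ns1,male,21\ns1,female,22\n"))


def test_blank_cell_becomes_missing(tmp_path):
    records = read_cohort(_write(tmp_path, "id,sex,bmi,vital_capacity\ns1,male,21.5,\n"))
    assert records[0].is_missing("vital_capacity")
    assert records[0].measurements["bmi"] == 21.5


def test_unparseable_cell_becomes_missing(tmp_path):
    records = read_cohort(_write(tmp_path, "id,sex,bmi\ns1,male,n/a\n"))
    assert records[0].is_missing("bmi")


def test_roundtrip_preserves_values_and_missingness(tmp_path):
    records = [
        StudentRecord("s1", "male", {"bmi": 21.456789, "vital_capacity": None}),
        StudentRecord("s2", "female", {"bmi": 23.0, "vital_capacity": 3100.0}),
        StudentRecord("s3", "male", {"bmi": None, "vital_capacity": 4000.25}),
    ]
    path = str(tmp_path / "out.csv")
    write_cohort(records, path)
    back = read_cohort(path)
    assert [r.subject_id for r in back] == ["s1", "s2", "s3"]
    for orig, copy in zip(records, back):
        assert copy.sex == orig.sex
        assert copy.measurements == orig.measurements


def test_nonfinite_measurement_rejected():
    with pytest.raises(CohortValidationError):
        StudentRecord("s1", "male", {"bmi": math.inf})


# ---------------------------------------------------------------------------
# Imputation


def test_impute_identity_without_missing():
    records = [StudentRecord("s1", "male", {"bmi": 20.0})]
    out = impute_missing(records, "attribute-mean")
    assert out[0].measurements == {"bmi": 20.0}


def test_attribute_mean_fills_with_mean_of_observed():
    records = [
        StudentRecord("s1", "male", {"x": 10.0}),
        StudentRecord("s2", "male", {"x": 20.0}),
        StudentRecord("s3", "male", {"x": None}),
    ]
    out = impute_missing(records, "attribute-mean")
    assert out[2].measurements["x"] == 15.0


def test_attribute_mean_is_sex_stratified():
    records = [
        StudentRecord("m1", "male", {"x": 10.0}),
        StudentRecord("f1", "female", {"x": 30.0}),
        StudentRecord("f2", "female", {"x": None}),
    ]
    out = impute_missing(records, "attribute-mean")
    assert out[2].measurements["x"] == 30.0


def test_impute_preserves_observed_cells_and_mean():
    records = [
        StudentRecord("s1", "male", {"x": 10.0}),
        StudentRecord("s2", "male", {"x": 30.0}),
        StudentRecord("s3", "male", {"x": None}),
    ]
    out = impute_missing(records, "attribute-mean")
    observed = [r.measurements["x"] for r in out[:2]]
    assert observed == [10.0, 30.0]
    # the fill equals the observed mean, so the observed mean is unchanged
    assert out[2].measurements["x"] == sum(observed) / 2


def test_drop_row_removes_incomplete_records():
    records = [
        StudentRecord("s1", "male", {"x": 1.0, "y": 2.0}),
        StudentRecord("s2", "male", {"x": None, "y": None}),
    ]
    out = impute_missing(records, "drop-row")
    assert [r.subject_id for r in out] == ["s1"]


def test_fully_missing_indicator_is_unimputable():
    records = [StudentRecord("s1", "male", {"x": None})]
    with pytest.raises(ImputationError):
        impute_missing(records, "attribute-mean")


# ---------------------------------------------------------------------------
# Scoring and grades


def test_score_interpolates_linearly_between_breakpoints():
    d = default_definitions()["vital_capacity"]
    # male table: (3100, 60) -> (4100, 80); halfway in raw is halfway in score
    r = StudentRecord("s1", "male", {"vital_capacity": 3600.0})
    assert score_indicator(r, d) == pytest.approx(70.0)


def test_score_boundaries_hit_full_and_zero_marks():
    d = default_definitions()["vital_capacity"]
    assert score_indicator(StudentRecord("a", "male", {"vital_capacity": 5040.0}), d) == 100.0
    assert score_indicator(StudentRecord("b", "male", {"vital_capacity": 2000.0}), d) == 0.0


def test_score_missing_measurement_errors():
    d = default_definitions()["bmi"]
    with pytest.raises(MissingScoreError):
        score_indicator(StudentRecord("s1", "male", {"bmi": None}), d)


@pytest.mark.parametrize(
    "score,grade",
    [(92, "excellent"), (85, "excellent"), (84.999, "good"), (75, "good"),
     (74.5, "medium"), (60, "medium"), (59.9, "poor"), (0, "poor"), (100, "excellent")],
)
def test_discretize_bands(score, grade):
    assert discretize(score) == grade


@pytest.mark.parametrize("score", [-0.1, 100.1])
def test_discretize_domain_error(score):
    with pytest.raises(ValueError):
        discretize(score)


@given(st.floats(0, 100), st.floats(0, 100))
def test_discretize_is_monotone(a, b):
    lo, hi = sorted((a, b))
    assert grade_rank(discretize(lo)) <= grade_rank(discretize(hi))


def test_lower_better_indicator_scores_monotone_in_direction():
    d = default_definitions()["sprint_50m"]
    times = [6.7, 7.0, 8.0, 9.5, 11.0]
    scores = [d.score(t, "male") for t in times]
    assert scores == sorted(scores, reverse=True)


# ---------------------------------------------------------------------------
# Labeled datasets


def _scored(sid, grades):
    return ScoredRecord(subject_id=sid, scores={k: 80.0 for k in grades}, grades=dict(grades))


def test_to_labeled_dataset_counts_classes():
    records = [_scored("a", {"x": "good"}), _scored("b", {"x": "good"})]
    ds = to_labeled_dataset(records, labels={"a": "good", "b": "good"})
    assert ds.class_counts == {"good": 2}
    records = [_scored(s, {"x": "good"}) for s in "abc"]
    ds = to_labeled_dataset(records, labels={"a": "excellent", "b": "poor", "c": "poor"})
    assert ds.class_counts == {"excellent": 1, "poor": 2}


def test_to_labeled_dataset_dichotomy():
    records = [_scored("a", {"x": "good"}), _scored("b", {"x": "medium"})]
    ds = to_labeled_dataset(
        records,
        labels={"a": "good", "b": "medium"},
        dichotomy={"excellent", "good"},
    )
    assert ds.labels == ["positive", "negative"]


def test_to_labeled_dataset_drops_unlabeled_rows():
    records = [_scored("a", {"x": "good"}), _scored("b", {"x": "poor"})]
    ds = to_labeled_dataset(records, labels={"a": "good"})
    assert len(ds) == 1


def test_class_counts_sum_to_row_count(planted_dataset):
    assert sum(planted_dataset.class_counts.values()) == len(planted_dataset)


# ---------------------------------------------------------------------------
# Attribute reduction


def _toy_dataset():
    rows = [
        {"signal": label, "noise": "k", "semi": label if i % 2 else "other"}
        for i, label in enumerate(["good", "poor", "good", "poor", "good", "poor"])
    ]
    labels = [r["signal"] for r in rows]
    return LabeledDataset(["signal", "noise", "semi"], rows, labels)


def test_zero_threshold_keeps_all_attributes():
    ds = _toy_dataset()
    assert reduce_attributes(ds, min_relevance=0.0).attributes == ds.attributes


def test_constant_attribute_removed():
    ds = _toy_dataset()
    assert "noise" not in reduce_attributes(ds, min_relevance=0.01).attributes


def test_label_copy_attribute_has_unit_relevance_and_survives():
    ds = _toy_dataset()
    assert attribute_relevance(ds, "signal") == pytest.approx(1.0)
    assert "signal" in reduce_attributes(ds, min_relevance=0.9).attributes


def test_reduction_never_empties_attribute_set():
    rows = [{"k": "c"} for _ in range(4)]
    ds = LabeledDataset(["k"], rows, ["a", "b", "a", "b"])
    out = reduce_attributes(ds, min_relevance=0.99)
    assert out.attributes == ["k"]
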