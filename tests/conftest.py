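import pytest
from hypothesis import settings

from physfit.cohort import LabeledDataset
from physfit.synthetic import CohortSpec, cohort_to_dataset, generate_cohort

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def tennis_dataset() -> LabeledDataset:
    """Quinlan's play-tennis table: 14 rows, 4 attributes, 2 classes."""
    columns = ["outlook", "temperature", "humidity", "wind"]
    data = [
        ("sunny", "hot", "high", "weak", "no"),
        ("sunny", "hot", "high", "strong", "no"),
        ("overcast", "hot", "high", "weak", "yes"),
        ("rain", "mild", "high", "weak", "yes"),
        ("rain", "cool", "normal", "weak", "yes"),
        ("rain", "cool", "normal", "strong", "no"),
        ("overcast", "cool", "normal", "strong", "yes"),
        ("sunny", "mild", "high", "weak", "no"),
        ("sunny", "cool", "normal", "weak", "yes"),
        ("rain", "mild", "normal", "weak", "yes"),
        ("sunny", "mild", "normal", "strong", "yes"),
        ("overcast", "mild", "high", "strong", "yes"),
        ("overcast", "hot", "normal", "weak", "yes"),
        ("rain", "mild", "high", "strong", "no"),
    ]
    rows = [dict(zip(columns, r[:4])) for r in data]
    return LabeledDataset(columns, rows, [r[4] for r in data])


@pytest.fixture(scope="session")
def planted_cohort():
    """Noise-free 300-subject cohort with ground-truth labels (seed 7)."""
    records, labels = generate_cohort(CohortSpec(n=300, seed=7))
    return records, labels


@pytest.fixture(scope="session")
def planted_dataset(planted_cohort) -> LabeledDataset:
    records, labels = planted_cohort
    return cohort_to_dataset(records, labels)
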