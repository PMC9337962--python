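"""Synthetic student cohorts with a planted grade-generating rule.

The generator emulates the statistical structure the evaluation pipeline
assumes: sex-stratified continuous measurement distributions (truncated
normals per indicator, in native units), ground-truth overall grades
planted by the AHP-weighted rollup of the discretized indicator grades,
plus configurable label noise and missingness.  With noise and missingness
at zero the label is a deterministic function of the secondary grades, so
consistent decision trees can reach 100% training accuracy.

The default cohort is 300 subjects split 150/150 into training and test
halves; the grouped variant produces the 5-groups-of-30 layout used by the
algorithm comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .cohort import (
    INDICATORS,
    GRADES,
    LabeledDataset,
    StudentRecord,
    impute_missing,
    score_record,
    to_labeled_dataset,
)
from .defaults import default_definitions, default_hierarchy
from .pipeline import planted_overall_grade

#: (mean, sd, lower, upper) of each indicator's truncated normal, per sex.
#: The cohort emulated is a relatively homogeneous student body: locations
#: sit in the medium/good score bands and spreads are tight enough that each
#: indicator's grades concentrate on one or two bands, keeping the joint
#: grade space compact enough for a 150-row training half to cover it.
DEFAULT_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "bmi": {"male": (22.5, 0.8, 15.0, 35.0), "female": (21.5, 0.8, 15.0, 34.0)},
    "vital_capacity": {"male": (3800.0, 190.0, 2000.0, 6500.0), "female": (2700.0, 145.0, 1500.0, 4500.0)},
    "sit_and_reach": {"male": (12.0, 1.9, -10.0, 28.0), "female": (14.0, 1.8, -5.0, 28.0)},
    "standing_long_jump": {"male": (225.0, 6.5, 140.0, 300.0), "female": (170.0, 5.5, 90.0, 230.0)},
    "sprint_50m": {"male": (7.8, 0.2, 6.2, 11.5), "female": (9.2, 0.22, 7.2, 13.0)},
    "endurance_run": {"male": (245.0, 8.0, 180.0, 420.0), "female": (238.0, 7.0, 180.0, 380.0)},
    "strength_count": {"male": (11.0, 1.3, 0.0, 25.0), "female": (35.0, 3.2, 5.0, 60.0)},
}


@dataclass
class CohortSpec:
    """Everything needed to regenerate a cohort deterministically."""

    n: int = 300
    seed: int = 0
    sex_ratio: float = 0.5  # fraction male
    distributions: dict[str, dict[str, tuple[float, float, float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DISTRIBUTIONS.items()}
    )
    label_noise: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name, p in (
            ("sex_ratio", self.sex_ratio),
            ("label_noise", self.label_noise),
            ("missing_rate", self.missing_rate),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for ind, per_sex in self.distributions.items():
            for sex, (mean, sd, low, high) in per_sex.items():
                if sd <= 0 or not (low < high):
                    raise ValueError(f"bad distribution for {ind}/{sex}")


def _draw(params: tuple[float, float, float, float], rng: np.random.Generator) -> float:
    mean, sd, low, high = params
    a, b = (low - mean) / sd, (high - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_cohort(
    spec: CohortSpec,
    definitions=None,
    hierarchy=None,
    id_prefix: str = "s",
) -> tuple[list[StudentRecord], dict[str, str]]:
    """Generate records plus ground-truth overall grades.

    Labels are planted *before* cells are blanked, so the ground truth always
    reflects the complete measurements; with ``label_noise`` > 0 each label
    is flipped to a uniformly chosen different grade with that probability.
    """
    definitions = definitions or default_definitions()
    hierarchy = hierarchy or default_hierarchy()
    rng = np.random.default_rng(spec.seed)

    records: list[StudentRecord] = []
    labels: dict[str, str] = {}
    for i in range(spec.n):
        sid = f"{id_prefix}{i + 1:04d}"
        sex = "male" if rng.random() < spec.sex_ratio else "female"
        measurements: dict[str, float | None] = {
            ind: _draw(spec.distributions[ind][sex], rng) for ind in INDICATORS
        }
        record = StudentRecord(sid, sex, measurements)
        scored = score_record(record, definitions)
        label = planted_overall_grade(scored.grades, hierarchy)
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            label = str(rng.choice([g for g in GRADES if g != label]))
        labels[sid] = label
        if spec.missing_rate > 0:
            for ind in INDICATORS:
                if rng.random() < spec.missing_rate:
                    measurements[ind] = None
        records.append(StudentRecord(sid, sex, dict(measurements)))
    return records, labels


def cohort_to_dataset(
    records, labels, definitions=None, hierarchy=None
) -> LabeledDataset:
    """Impute, score, grade and assemble the grade-valued labeled dataset."""
    definitions = definitions or default_definitions()
    records = impute_missing(records, strategy="attribute-mean")
    scored = [score_record(r, definitions) for r in records]
    return to_labeled_dataset(scored, labels=labels)


def generate_grouped_cohort(
    n_groups: int = 5, group_size: int = 30, spec: CohortSpec | None = None
) -> list[LabeledDataset]:
    """Independent groups in the 5-x-30 comparison layout.

    Group g reuses *spec* with ``n = group_size`` and a derived seed, and
    prefixes subject ids with ``g<g>_`` so ids stay globally unique.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if group_size < 2:
        raise ValueError("group_size must be >= 2")
    spec = spec or CohortSpec()
    groups = []
    for g in range(n_groups):
        sub = CohortSpec(
            n=group_size,
            seed=spec.seed + 1000 * (g + 1),
            sex_ratio=spec.sex_ratio,
            distributions=spec.distributions,
            label_noise=spec.label_noise,
            missing_rate=spec.missing_rate,
        )
        records, labels = generate_cohort(sub, id_prefix=f"g{g + 1}_s")
        groups.append(cohort_to_dataset(records, labels))
    return groups


def train_test_split(records: list, fraction: float = 0.5, seed: int = 0) -> tuple[list, list]:
    """Seeded random partition into ceil(fraction*n) training items and the rest."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    k = int(np.ceil(fraction * n))
    order = np.random.default_rng(seed).permutation(n)
    train = [records[i] for i in sorted(order[:k])]
    test = [records[i] for i in sorted(order[k:])]
    return train, test
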