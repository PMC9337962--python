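"""Shipped default configuration: scoring tables, hierarchy, rule table.

The scoring tables are illustrative sex-specific piecewise-linear tables in
the spirit of national student fitness-test standards (which publish scores
by sex for exactly this indicator battery); they are editable configuration,
not a transcription of any official standard.  The hierarchy groups the
seven scored secondary indicators under five primary indicators, with AHP
judgment matrices supplying every weight vector.

All defaults round-trip through a single JSON configuration document via
:func:`config_to_json` / :func:`config_from_json`.
"""

from __future__ import annotations

import json
from typing import Mapping

import numpy as np

from .ahp import JudgmentMatrix, WeightVector, compute_weights, consistency, validate_matrix
from .cohort import IndicatorDefinition
from .errors import ConfigurationError
from .pipeline import IndicatorHierarchy, PrimaryIndicator, RecommendationRule

# ---------------------------------------------------------------------------
# Scoring tables (raw value, score); raw axis strictly increasing.

_TABLES: dict[str, dict] = {
    "bmi": {
        "unit": "kg/m^2",
        "direction": "lower-better",
        "male": [(17.0, 100.0), (24.0, 100.0), (26.5, 80.0), (28.0, 60.0), (32.0, 0.0)],
        "female": [(17.0, 100.0), (23.5, 100.0), (26.0, 80.0), (27.5, 60.0), (31.0, 0.0)],
    },
    "vital_capacity": {
        "unit": "mL",
        "direction": "higher-better",
        "male": [(2000.0, 0.0), (3100.0, 60.0), (4100.0, 80.0), (5040.0, 100.0)],
        "female": [(1500.0, 0.0), (2000.0, 60.0), (2900.0, 80.0), (3400.0, 100.0)],
    },
    "sit_and_reach": {
        "unit": "cm",
        "direction": "higher-better",
        "male": [(-10.0, 0.0), (3.7, 60.0), (14.5, 80.0), (21.3, 100.0)],
        "female": [(-5.0, 0.0), (6.0, 60.0), (16.0, 80.0), (22.2, 100.0)],
    },
    "standing_long_jump": {
        "unit": "cm",
        "direction": "higher-better",
        "male": [(150.0, 0.0), (208.0, 60.0), (240.0, 80.0), (273.0, 100.0)],
        "female": [(100.0, 0.0), (151.0, 60.0), (181.0, 80.0), (207.0, 100.0)],
    },
    "sprint_50m": {
        "unit": "s",
        "direction": "lower-better",
        "male": [(6.7, 100.0), (7.7, 80.0), (9.1, 60.0), (11.0, 0.0)],
        "female": [(7.5, 100.0), (8.9, 80.0), (10.3, 60.0), (12.5, 0.0)],
    },
    "endurance_run": {
        "unit": "s",
        "direction": "lower-better",
        "male": [(195.0, 100.0), (235.0, 80.0), (272.0, 60.0), (360.0, 0.0)],
        "female": [(195.0, 100.0), (226.0, 80.0), (264.0, 60.0), (330.0, 0.0)],
    },
    "strength_count": {
        "unit": "repetitions",
        "direction": "higher-better",
        "male": [(0.0, 0.0), (10.0, 60.0), (15.0, 80.0), (19.0, 100.0)],
        "female": [(10.0, 0.0), (26.0, 60.0), (42.0, 80.0), (56.0, 100.0)],
    },
}


def default_definitions() -> dict[str, IndicatorDefinition]:
    """The shipped scoring tables as indicator definitions."""
    return {
        name: IndicatorDefinition(
            name=name,
            unit=spec["unit"],
            direction=spec["direction"],
            breakpoints={"male": spec["male"], "female": spec["female"]},
        )
        for name, spec in _TABLES.items()
    }


# ---------------------------------------------------------------------------
# Hierarchy: five primaries over the seven secondaries, AHP-weighted.

#: Pairwise importances over [body_composition, cardiorespiratory,
#: flexibility, speed, strength]; cardiorespiratory fitness judged most
#: important, flexibility least.
PRIMARY_MATRIX = np.array(
    [
        [1.0, 1 / 4, 2.0, 1 / 2, 1 / 3],
        [4.0, 1.0, 5.0, 3.0, 2.0],
        [1 / 2, 1 / 5, 1.0, 1 / 3, 1 / 4],
        [2.0, 1 / 3, 3.0, 1.0, 1 / 2],
        [3.0, 1 / 2, 4.0, 2.0, 1.0],
    ]
)

#: Within-primary matrices for the two multi-child primaries.
CHILD_MATRICES: dict[str, np.ndarray] = {
    # endurance run judged twice as informative as resting vital capacity
    "cardiorespiratory": np.array([[1.0, 1 / 2], [2.0, 1.0]]),
    # lower-body power and upper-body/core strength weighted equally
    "strength": np.array([[1.0, 1.0], [1.0, 1.0]]),
}

_PRIMARY_CHILDREN: dict[str, list[str]] = {
    "body_composition": ["bmi"],
    "cardiorespiratory": ["vital_capacity", "endurance_run"],
    "flexibility": ["sit_and_reach"],
    "speed": ["sprint_50m"],
    "strength": ["standing_long_jump", "strength_count"],
}


def _weights_from(matrix: np.ndarray, context: str) -> WeightVector:
    jm: JudgmentMatrix = validate_matrix(matrix)
    report = consistency(jm)
    if not report.passed:
        raise ConfigurationError(f"{context}: judgment matrix fails consistency (CR={report.CR:.3f})")
    return compute_weights(jm)


def default_hierarchy() -> IndicatorHierarchy:
    """Five-primary hierarchy with all weights derived from judgment matrices."""
    primaries = []
    for name, children in _PRIMARY_CHILDREN.items():
        if len(children) == 1:
            weights = WeightVector(weights=np.array([1.0]))
        else:
            weights = _weights_from(CHILD_MATRICES[name], f"children of {name}")
        primaries.append(PrimaryIndicator(name=name, children=children, weights=weights))
    return IndicatorHierarchy(
        primaries=primaries,
        primary_weights=_weights_from(PRIMARY_MATRIX, "primary indicators"),
    )


# ---------------------------------------------------------------------------
# Recommendation rules: one per weakest primary, plus maintenance default.

def default_rules() -> list[RecommendationRule]:
    return [
        RecommendationRule(
            name="cardio-deficit",
            kind="weakest-primary",
            primary="cardiorespiratory",
            modes=["aerobic running program", "interval jogging", "swimming"],
            rationale="cardiorespiratory fitness is the weakest primary indicator",
        ),
        RecommendationRule(
            name="strength-deficit",
            kind="weakest-primary",
            primary="strength",
            modes=["resistance circuit", "bodyweight strength training"],
            rationale="strength is the weakest primary indicator",
        ),
        RecommendationRule(
            name="flexibility-deficit",
            kind="weakest-primary",
            primary="flexibility",
            modes=["daily stretching routine", "yoga"],
            rationale="flexibility is the weakest primary indicator",
        ),
        RecommendationRule(
            name="speed-deficit",
            kind="weakest-primary",
            primary="speed",
            modes=["sprint intervals", "agility drills"],
            rationale="speed is the weakest primary indicator",
        ),
        RecommendationRule(
            name="body-composition-deficit",
            kind="weakest-primary",
            primary="body_composition",
            modes=["mixed aerobic training", "dietary guidance"],
            rationale="body composition is the weakest primary indicator",
        ),
        RecommendationRule(
            name="maintenance",
            kind="always",
            primary=None,
            modes=["general fitness maintenance", "recreational sports"],
            rationale="no primary indicator is deficient",
        ),
    ]


# ---------------------------------------------------------------------------
# One-document JSON configuration.


def config_to_json(
    definitions: Mapping[str, IndicatorDefinition] | None = None,
    hierarchy: IndicatorHierarchy | None = None,
    rules: list[RecommendationRule] | None = None,
    **kwargs,
) -> str:
    definitions = definitions or default_definitions()
    hierarchy = hierarchy or default_hierarchy()
    rules = rules if rules is not None else default_rules()
    doc = {
        "scoring_tables": {
            name: {
                "unit": d.unit,
                "direction": d.direction,
                "breakpoints": {s: [list(p) for p in pts] for s, pts in d.breakpoints.items()},
            }
            for name, d in definitions.items()
        },
        "hierarchy": {
            "primaries": [
                {"name": p.name, "children": p.children, "weights": p.weights.weights.tolist()}
                for p in hierarchy.primaries
            ],
            "primary_weights": hierarchy.primary_weights.weights.tolist(),
        },
        "rules": [
            {
                "name": r.name,
                "kind": r.kind,
                "primary": r.primary,
                "modes": r.modes,
                "rationale": r.rationale,
            }
            for r in rules
        ],
        "grade_cuts": {"excellent": 85.0, "good": 75.0, "medium": 60.0},
    }
    return json.dumps(doc, **kwargs)


def config_from_json(text: str):
    """Parse a configuration document; returns (definitions, hierarchy, rules)."""
    doc = json.loads(text)
    definitions = {
        name: IndicatorDefinition(
            name=name,
            unit=spec["unit"],
            direction=spec["direction"],
            breakpoints={s: [tuple(p) for p in pts] for s, pts in spec["breakpoints"].items()},
        )
        for name, spec in doc["scoring_tables"].items()
    }
    hierarchy = IndicatorHierarchy(
        primaries=[
            PrimaryIndicator(
                name=p["name"],
                children=p["children"],
                weights=WeightVector(weights=np.asarray(p["weights"], dtype=float)),
            )
            for p in doc["hierarchy"]["primaries"]
        ],
        primary_weights=WeightVector(
            weights=np.asarray(doc["hierarchy"]["primary_weights"], dtype=float)
        ),
    )
    rules = [
        RecommendationRule(
            name=r["name"],
            kind=r["kind"],
            primary=r.get("primary"),
            modes=list(r["modes"]),
            rationale=r.get("rationale", ""),
        )
        for r in doc["rules"]
    ]
    return definitions, hierarchy, rules
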