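"""Outcome definitions for the integrated-care MCDA.

The evaluation scores each study arm on a set of patient-reported outcomes
spanning the Triple Aim domains (health/well-being, experience of care,
resource use).  Each outcome is measured by a validated instrument with a
bounded scale and a direction: on some instruments a higher score is better
(e.g. MHI-5 psychological well-being), on others a higher score is worse
(e.g. Katz-15 ADL dependence, costs).  The direction drives both the sign
annotation of treatment effects and the reciprocal transform used in
relative standardization.

Two outcome sets are distinguished: the *core* set of eight outcomes that
every programme evaluation shares, and *programme-specific* additions for
frail-elderly care (autonomy, medication burden, informal-care costs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping


class Direction(str, Enum):
    """Orientation of an instrument's natural scale."""

    HIGHER_BETTER = "higher_better"
    HIGHER_WORSE = "higher_worse"


class OutcomeSet(str, Enum):
    CORE = "core"
    PROGRAMME_SPECIFIC = "programme_specific"


@dataclass(frozen=True)
class OutcomeSpec:
    """A single MCDA criterion: instrument, admissible range and direction."""

    name: str
    instrument: str
    scale_min: float
    scale_max: float
    direction: Direction
    outcome_set: OutcomeSet = OutcomeSet.CORE

    def __post_init__(self) -> None:
        if not self.scale_min < self.scale_max:
            raise ValueError(
                f"outcome {self.name!r}: scale_min ({self.scale_min}) must be "
                f"< scale_max ({self.scale_max})"
            )

    @property
    def higher_is_better(self) -> bool:
        return self.direction is Direction.HIGHER_BETTER

    def in_range(self, value: float) -> bool:
        return self.scale_min <= value <= self.scale_max


#: The eight core outcomes, with instrument scale ranges and orientations.
CORE_OUTCOMES: tuple[OutcomeSpec, ...] = (
    OutcomeSpec("physical_functioning", "Katz-15 (ADL)", 0, 15,
                Direction.HIGHER_WORSE),
    OutcomeSpec("psychological_wellbeing", "MHI-5", 0, 100,
                Direction.HIGHER_BETTER),
    OutcomeSpec("social_participation",
                "IPA, social life & relationships domain", 0, 28,
                Direction.HIGHER_WORSE),
    OutcomeSpec("enjoyment_of_life", "ICECAP-O", 1, 4,
                Direction.HIGHER_BETTER),
    OutcomeSpec("resilience", "Brief Resilience Scale", 6, 30,
                Direction.HIGHER_BETTER),
    OutcomeSpec("person_centeredness", "P3CEQ, person-centred care domain",
                0, 18, Direction.HIGHER_BETTER),
    OutcomeSpec("continuity_of_care", "NCQ + CPCQ waiting item", 1, 5,
                Direction.HIGHER_BETTER),
    OutcomeSpec("total_costs", "3-month health & social care costs (NOK)",
                0, math.inf, Direction.HIGHER_WORSE),
)

#: Programme-specific additions for frail-elderly care programmes.
PROGRAMME_SPECIFIC_OUTCOMES: tuple[OutcomeSpec, ...] = (
    OutcomeSpec("autonomy", "Pearlin Mastery Scale", 7, 35,
                Direction.HIGHER_BETTER, OutcomeSet.PROGRAMME_SPECIFIC),
    OutcomeSpec("burden_of_medication", "Living with Medicines Questionnaire",
                0, 10, Direction.HIGHER_WORSE, OutcomeSet.PROGRAMME_SPECIFIC),
    OutcomeSpec("informal_care_costs", "3-month informal care costs (NOK)",
                0, math.inf, Direction.HIGHER_WORSE,
                OutcomeSet.PROGRAMME_SPECIFIC),
)

ALL_OUTCOMES: tuple[OutcomeSpec, ...] = CORE_OUTCOMES + PROGRAMME_SPECIFIC_OUTCOMES

CORE_OUTCOME_NAMES: tuple[str, ...] = tuple(o.name for o in CORE_OUTCOMES)


def outcome_registry(
    specs: tuple[OutcomeSpec, ...] = ALL_OUTCOMES,
) -> dict[str, OutcomeSpec]:
    return {spec.name: spec for spec in specs}


class Stakeholder(str, Enum):
    PATIENTS = "patients"
    PARTNERS = "partners"
    PROFESSIONALS = "professionals"
    PAYERS = "payers"
    POLICY_MAKERS = "policy_makers"
    CUSTOM = "custom"


class WeightSource(str, Enum):
    DCE = "dce"
    SWING = "swing"


@dataclass(frozen=True)
class StakeholderWeights:
    """Importance weights over the outcome set for one stakeholder group.

    Weights are applied exactly as given (no renormalization): published
    discrete-choice-experiment weight columns sum to roughly but not
    exactly one, and the additive value model uses them as printed.
    """

    stakeholder: Stakeholder
    weights: Mapping[str, float]
    source: WeightSource = WeightSource.DCE
    label: str | None = None

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.weights.items() if v < 0}
        if bad:
            raise ValueError(f"negative weights not allowed: {bad}")

    def __getitem__(self, outcome: str) -> float:
        return self.weights[outcome]

    @property
    def outcome_names(self) -> tuple[str, ...]:
        return tuple(self.weights)


def weights_to_frame(
    weight_sets: Mapping[object, "StakeholderWeights"] | list["StakeholderWeights"],
):
    """Weight sets as a table: rows = outcomes, columns = stakeholders."""
    import pandas as pd

    if isinstance(weight_sets, Mapping):
        weight_sets = list(weight_sets.values())
    return pd.DataFrame(
        {ws.label or ws.stakeholder.value: dict(ws.weights)
         for ws in weight_sets})


def weights_from_frame(df, source: "WeightSource" = None) -> list["StakeholderWeights"]:
    """Parse a rows-by-outcomes, columns-by-stakeholders weight table."""
    source = source or WeightSource.DCE
    known = {s.value: s for s in Stakeholder}
    out = []
    for col in df.columns:
        st = known.get(str(col).strip().lower().replace(" ", "_"),
                       Stakeholder.CUSTOM)
        out.append(StakeholderWeights(
            st, {str(o): float(v) for o, v in df[col].dropna().items()},
            source=source, label=str(col)))
    return out


#: Relative DCE importance weights of the core outcome set, one column per
#: stakeholder group, as elicited in the Norwegian stakeholder preference
#: study (N per group: patients 158, partners 156, professionals 161,
#: payers 122, policy makers 180).
DCE_WEIGHTS: dict[Stakeholder, StakeholderWeights] = {
    st: StakeholderWeights(st, dict(zip(CORE_OUTCOME_NAMES, col)))
    for st, col in {
        Stakeholder.PATIENTS: (0.178, 0.175, 0.110, 0.249, 0.109, 0.047,
                               0.110, 0.023),
        Stakeholder.PARTNERS: (0.107, 0.184, 0.154, 0.273, 0.088, 0.064,
                               0.112, 0.017),
        Stakeholder.PROFESSIONALS: (0.124, 0.167, 0.141, 0.263, 0.110, 0.055,
                                    0.106, 0.034),
        Stakeholder.PAYERS: (0.141, 0.155, 0.117, 0.263, 0.130, 0.042,
                             0.092, 0.060),
        Stakeholder.POLICY_MAKERS: (0.115, 0.149, 0.144, 0.243, 0.126, 0.058,
                                    0.128, 0.035),
    }.items()
}
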