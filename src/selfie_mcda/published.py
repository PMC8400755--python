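"""Published evaluation results used as reproduction inputs.

The original evaluation's value table prints, per core outcome, the
standardized performance scores of the two arms (3 decimals) and, per
stakeholder group, the overall value scores.  The raw predicted scores
behind the standardization were not printed, so a reproduction of the
aggregation step starts from these standardized scores and the published
stakeholder weight columns (:data:`selfie_mcda.outcomes.DCE_WEIGHTS`).

Because the printed inputs are themselves rounded to 3 decimals, a few
published overall cells differ from the re-aggregated values in the third
decimal; those carry rounding slack downstream.
"""

from __future__ import annotations

import pandas as pd

from .outcomes import Stakeholder

#: Standardized performance scores (S_hcpc, S_uc) per core outcome, as
#: printed in the published value table.
PUBLISHED_STANDARDIZED: pd.DataFrame = pd.DataFrame(
    {
        "physical_functioning": (0.708, 0.706),
        "psychological_wellbeing": (0.730, 0.683),
        "social_participation": (0.729, 0.685),
        "enjoyment_of_life": (0.732, 0.681),
        "resilience": (0.744, 0.669),
        "person_centeredness": (0.730, 0.683),
        "continuity_of_care": (0.702, 0.712),
        "total_costs": (0.842, 0.539),
    },
    index=["S_hcpc", "S_uc"],
).T

#: Published overall value scores per stakeholder group (HCPC, UC).
PUBLISHED_OVERALL: dict[Stakeholder, tuple[float, float]] = {
    Stakeholder.PATIENTS: (0.728, 0.685),
    Stakeholder.PARTNERS: (0.728, 0.685),
    Stakeholder.PROFESSIONALS: (0.730, 0.682),
    Stakeholder.PAYERS: (0.733, 0.678),
    Stakeholder.POLICY_MAKERS: (0.730, 0.682),
}

#: Cells whose published value the re-aggregation reproduces exactly at
#: 3 decimals (the remaining cells inherit input-rounding slack).
EXACT_CELLS: tuple[tuple[Stakeholder, str], ...] = (
    (Stakeholder.PATIENTS, "HCPC"),
    (Stakeholder.PROFESSIONALS, "HCPC"),
    (Stakeholder.PROFESSIONALS, "UC"),
    (Stakeholder.PAYERS, "HCPC"),
    (Stakeholder.PAYERS, "UC"),
)

#: Published per-cell weighted scores spot-checked in tests:
#: (stakeholder, outcome, arm) -> weighted score.
PUBLISHED_WEIGHTED_CELLS: dict[tuple[Stakeholder, str, str], float] = {
    (Stakeholder.PARTNERS, "enjoyment_of_life", "HCPC"): 0.200,
    (Stakeholder.PAYERS, "total_costs", "HCPC"): 0.051,
}

#: Published percentage of Monte Carlo replications preferring the
#: programme arm, per stakeholder group.
PUBLISHED_PCT_HCPC_BETTER: dict[Stakeholder, float] = {
    Stakeholder.PATIENTS: 94.8,
    Stakeholder.PARTNERS: 94.9,
    Stakeholder.PROFESSIONALS: 94.7,
    Stakeholder.PAYERS: 95.1,
    Stakeholder.POLICY_MAKERS: 98.7,
}
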