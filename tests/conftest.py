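import numpy as np
import pandas as pd
import pytest

import selfie_mcda as sm


def make_cohort(rows: list[dict]) -> sm.CohortTable:
    """Build a small cohort table from row dicts, filling defaults."""
    defaults = {"age_years": 80.0, "sex": "female",
                "living_condition": "alone", "smoking": "never",
                "multimorbid": True, "education": "low"}
    full = [{**defaults, **r} for r in rows]
    return sm.CohortTable(pd.DataFrame(full))


@pytest.fixture
def four_patient_cohort() -> sm.CohortTable:
    """Well-formed 2x2 mini cohort: two patients per arm, both waves."""
    rows = []
    for i, arm in enumerate(["HCPC", "HCPC", "UC", "UC"]):
        for t in ("T0", "T1"):
            rows.append({"patient_id": f"P{i}", "arm": arm, "time": t,
                         "resilience": 20.0 + i, "enjoyment_of_life": 2.5})
    return make_cohort(rows)


@pytest.fixture(scope="session")
def confounded_large():
    """2,000-per-arm confounded cohort, complete (no attrition/missingness)."""
    cfg = sm.SimulationConfig(
        n_hcpc=2000, n_uc=2000, seed=11,
        attrition_prob={"HCPC": 0.0, "UC": 0.0},
        item_missing_prob=0.0, followup_only_count=0)
    table, truth = sm.simulate_cohort(cfg)
    return table, truth


@pytest.fixture(scope="session")
def weighted_large(confounded_large):
    table, _ = confounded_large
    return sm.fit_propensity(table)


@pytest.fixture(scope="session")
def study_pipeline():
    """Default (study-sized) cohort run through rules, imputation, weighting."""
    table, truth = sm.simulate_cohort(sm.SimulationConfig(seed=7))
    table, removed = sm.apply_cohort_rules(table)
    table, _ = sm.impute_outcomes_by_group(table)
    weighted = sm.fit_propensity(table)
    return table, truth, removed, weighted


def unit_weighted(table: sm.CohortTable) -> sm.WeightedCohort:
    """Wrap a cohort with all-ones weights (no reweighting)."""
    pid = table.patients
    return sm.WeightedCohort(
        table,
        propensity=pd.Series(0.5, index=pid),
        att_weight=pd.Series(1.0, index=pid),
        linear_index=pd.Series(0.0, index=pid),
    )
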