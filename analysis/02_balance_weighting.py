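#!/usr/bin/env python
"""Apply cohort rules, impute, fit the propensity model and report balance.

Follow-up-only respondents are removed, sporadic missing outcome values
are mean-imputed within arm x wave, a logit propensity model is fitted on
baseline covariates, and usual-care patients are reweighted to the
programme arm's covariate distribution (ATT weights ps/(1-ps)).  The
balance table reports per-covariate standardized bias and Rubin's B/R
before and after weighting.

Reads results/cohort.csv; writes results/weighted.csv and
results/balance.csv.
"""

from pathlib import Path

import pandas as pd

import selfie_mcda as sm

RESULTS = Path(__file__).resolve().parents[1] / "results"


def prepare_cohort() -> sm.CohortTable:
    path = RESULTS / "cohort.csv"
    if not path.exists():
        raise SystemExit(f"{path} not found - run 01_simulate_cohort.py first")
    table = sm.read_cohort_csv(path)
    table, removed = sm.apply_cohort_rules(table)
    print(f"removed {len(removed)} follow-up-only patients: {removed}")
    table, log = sm.impute_outcomes_by_group(table)
    print(f"mean-imputed {sum(e.n_imputed for e in log)} outcome values "
          f"across {len(log)} arm x wave strata")
    return table


def main() -> None:
    table = prepare_cohort()
    weighted = sm.fit_propensity(table)
    if weighted.n_truncated:
        print(f"truncated {weighted.n_truncated} propensities to [0.01, 0.99]")

    out = table.data.copy()
    out["propensity"] = weighted.propensity.reindex(
        out["patient_id"]).to_numpy()
    out["att_weight"] = weighted.att_weight.reindex(
        out["patient_id"]).to_numpy()
    out.to_csv(RESULTS / "weighted.csv", index=False)

    report = sm.balance_table(weighted)
    pd.concat([report.rows,
               report.summary.assign(variable="(summary)")],
              ignore_index=True).to_csv(RESULTS / "balance.csv", index=False)

    print(report.summary.round(2).to_string(index=False))
    s = report.summary.set_index("stage")
    verdict = "sufficient" if report.passes("after") else "insufficient"
    print(f"weighting reduced mean standardized bias from "
          f"{s.loc['before', 'mean_bias']:.1f} to "
          f"{s.loc['after', 'mean_bias']:.1f}; balance after weighting is "
          f"{verdict} (B < 25 and 0.5 < R < 2)")


if __name__ == "__main__":
    main()
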