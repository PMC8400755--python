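#!/usr/bin/env python
"""Standardize performance and compute stakeholder-weighted value scores.

Two computations:

1. reproduction of the published value table: the printed standardized
   performance scores aggregated under the published DCE weight columns;
2. the same aggregation for the synthetic cohort's model-predicted
   performance matrix (from 03_effect_models.py).

Writes results/published_reproduction.csv and results/value_scores.csv.
"""

from pathlib import Path

import pandas as pd

import selfie_mcda as sm
from selfie_mcda.published import PUBLISHED_OVERALL, PUBLISHED_STANDARDIZED

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    weight_sets = list(sm.DCE_WEIGHTS.values())

    repro = sm.value_scores_from_standardized(PUBLISHED_STANDARDIZED,
                                              weight_sets)
    cmp = repro.overall.round(3).copy()
    cmp.columns = ["recomputed_HCPC", "recomputed_UC"]
    cmp["published_HCPC"] = [PUBLISHED_OVERALL[sm.Stakeholder(s)][0]
                             for s in cmp.index]
    cmp["published_UC"] = [PUBLISHED_OVERALL[sm.Stakeholder(s)][1]
                           for s in cmp.index]
    cmp.to_csv(RESULTS / "published_reproduction.csv")
    print("published value-table reproduction (printed inputs):")
    print(cmp.to_string())
    dev = (cmp["recomputed_HCPC"] - cmp["published_HCPC"]).abs().max()
    print(f"max |recomputed - published| on HCPC overalls: {dev:.3f} "
          "(input rounding)")

    perf_path = RESULTS / "performance.csv"
    if not perf_path.exists():
        raise SystemExit(f"{perf_path} not found - run 03_effect_models.py "
                         "first")
    perf = pd.read_csv(perf_path, index_col="outcome")
    vs = sm.value_scores(perf, weight_sets)
    out = pd.concat([vs.standardized.round(3), vs.weighted_cells.round(3)],
                    axis=1)
    out.to_csv(RESULTS / "value_cells.csv")
    vs.overall.round(3).to_csv(RESULTS / "value_scores.csv")
    print("\nsynthetic-cohort overall value scores:")
    print(vs.overall.round(3).to_string())
    better = (vs.overall["HCPC"] > vs.overall["UC"]).all()
    print("HCPC preferred by every stakeholder group" if better
          else "preference differs across stakeholder groups")


if __name__ == "__main__":
    main()
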