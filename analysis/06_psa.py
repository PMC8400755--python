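#!/usr/bin/env python
"""Monte Carlo sensitivity analysis of the synthetic-cohort value scores.

Draws 10,000 correlated replications of the raw performance scores (from
the model predictions' standard errors and between-arm covariances),
re-standardizes and re-aggregates each, and reports 95% uncertainty
intervals around the overall value scores, the percentage of
replications preferring the programme arm, and whether the arms'
intervals overlap.

Reads results/performance.csv; writes results/psa.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import selfie_mcda as sm

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--reps", type=int, default=10_000)
    args = parser.parse_args()

    perf_path = RESULTS / "performance.csv"
    if not perf_path.exists():
        raise SystemExit(f"{perf_path} not found - run 03_effect_models.py "
                         "first")
    perf = pd.read_csv(perf_path, index_col="outcome")
    res = sm.run_psa(perf, list(sm.DCE_WEIGHTS.values()),
                     sm.PsaConfig(n_replications=args.reps, seed=args.seed))

    out = res.summary.copy()
    out["pct_hcpc_better"] = res.pct_hcpc_better.reindex(
        out.index.get_level_values("stakeholder")).to_numpy()
    out["intervals_overlap"] = res.intervals_overlap.reindex(
        out.index.get_level_values("stakeholder")).to_numpy()
    out.to_csv(RESULTS / "psa.csv")

    print(out.round(3).to_string())
    print(f"\nHCPC preferred in "
          f"{res.pct_hcpc_better.min():.1f}-"
          f"{res.pct_hcpc_better.max():.1f}% of {args.reps:,} replications "
          "across stakeholder groups")
    n_sep = int((~res.intervals_overlap).sum())
    print(f"{n_sep} of {len(res.intervals_overlap)} stakeholder groups have "
          "non-overlapping 95% intervals")
    print(f"wrote {RESULTS / 'psa.csv'}")


if __name__ == "__main__":
    main()
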