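#!/usr/bin/env python
"""Cost the cohort's 3-month resource use from a societal perspective.

Applies the unit-price table (weighted GP fee grossed up by the 30%
co-payment convention, NOK 8,400 hospital bed days, home-care-valued
informal care, uniform CPI inflation) and summarises total health and
social care costs and informal-care costs by arm and wave, in NOK and
EUR (1 EUR = NOK 9.8527).

Reads results/cohort.csv; writes results/costs.csv.
"""

from pathlib import Path

import selfie_mcda as sm

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    path = RESULTS / "cohort.csv"
    if not path.exists():
        raise SystemExit(f"{path} not found - run 01_simulate_cohort.py first")
    table = sm.read_cohort_csv(path)
    prices = sm.PriceTable()
    costs = sm.cost_cohort(table, prices)
    costs.to_csv(RESULTS / "costs.csv", index=False)

    print(f"weighted GP consultation fee: {sm.weighted_gp_fee(prices):.0f} "
          f"NOK (provider cost "
          f"{sm.provider_cost_from_tariff(sm.weighted_gp_fee(prices), prices):.0f} NOK)")
    by = costs.groupby(["arm", "time"])[
        ["total_health_social_care_nok", "informal_care_nok",
         "total_health_social_care_eur"]].mean()
    print(by.round(0).to_string())
    t1 = by.xs("T1", level="time")["total_health_social_care_nok"]
    print(f"\nfollow-up total-cost difference (HCPC - UC): "
          f"{t1['HCPC'] - t1['UC']:.0f} NOK per patient per 3 months")
    print(f"wrote {RESULTS / 'costs.csv'}")


if __name__ == "__main__":
    main()
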