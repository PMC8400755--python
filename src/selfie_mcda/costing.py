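"""Societal-perspective costing of 3-month resource-use counts.

Converts service-use counts collected by questionnaire (contacts with the
GP and other primary-care professionals, hospital days, home care,
informal care hours, medication days) into Norwegian kroner at the 2019
price level, with EUR equivalents.

Conventions:

* the GP consultation fee is the weighted average of the non-specialist
  (NOK 165) and approved-specialist (NOK 257) tariffs;
* public tariffs are grossed up to actual provider cost by dividing by
  (1 - co-payment share), with co-payments assumed to be 30% of provider
  cost;
* a general-ward hospital bed day costs NOK 8,400;
* informal care hours are valued at the home-care-service unit cost
  (proxy-good method);
* all components are inflated to 2019 prices with a single consumer price
  index factor and converted to EUR at the 2019 average rate
  (1 EUR = NOK 9.8527).

Informal-care costs are kept separate from the total health and social
care costs, mirroring how the two cost outcomes enter the MCDA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .schema import CohortTable

logger = logging.getLogger(__name__)

EUR_PER_NOK_2019 = 9.8527   # 2019 average exchange rate, NOK per EUR

#: services whose tariff is grossed up by the co-payment convention
_TARIFF_SERVICES = frozenset({
    "gp_contacts", "physiotherapist_contacts", "specialist_contacts",
    "hospital_outpatient_visits",
})

#: services valued separately as informal care
_INFORMAL_SERVICES = frozenset({"informal_care_hours"})


@dataclass(frozen=True)
class PriceTable:
    """Unit prices (NOK) and costing conventions; every field overridable."""

    unit_prices: dict[str, float] = field(default_factory=lambda: {
        "nurse_contacts": 320.0,
        "physiotherapist_contacts": 180.0,
        "specialist_contacts": 386.0,
        "hospital_outpatient_visits": 500.0,
        "home_care_hours": 450.0,
        "nursing_home_days": 3100.0,
        "medication_ddd_days": 12.0,
    })
    cpi_factor: float = 1.0
    copay_share: float = 0.30
    gp_fee_nonspecialist: float = 165.0
    gp_fee_specialist: float = 257.0
    gp_specialist_share: float = 0.5
    hospital_per_diem: float = 8400.0
    eur_per_nok: float = EUR_PER_NOK_2019
    informal_care_unit_price: float = 450.0   # home-care unit cost per hour

    def __post_init__(self) -> None:
        if not 0.0 <= self.copay_share <= 1.0:
            raise ValueError(f"copay_share={self.copay_share} not in [0, 1]")
        if not 0.0 <= self.gp_specialist_share <= 1.0:
            raise ValueError(
                f"gp_specialist_share={self.gp_specialist_share} not in [0, 1]")
        if self.cpi_factor <= 0:
            raise ValueError("cpi_factor must be > 0")
        negative = {k: v for k, v in self.unit_prices.items() if v < 0}
        for name in ("gp_fee_nonspecialist", "gp_fee_specialist",
                     "hospital_per_diem", "informal_care_unit_price"):
            if getattr(self, name) < 0:
                negative[name] = getattr(self, name)
        if negative:
            raise ValueError(f"negative prices: {negative}")

    @classmethod
    def from_mapping(cls, cfg: dict) -> "PriceTable":
        base = cls()
        prices = dict(base.unit_prices)
        prices.update(cfg.get("unit_prices", {}))
        scalar = {k: v for k, v in cfg.items() if k != "unit_prices"}
        return replace(base, unit_prices=prices, **scalar)


def weighted_gp_fee(prices: PriceTable) -> float:
    """Weighted average GP consultation tariff (NOK)."""
    s = prices.gp_specialist_share
    return s * prices.gp_fee_specialist + (1 - s) * prices.gp_fee_nonspecialist


def provider_cost_from_tariff(tariff: float, prices: PriceTable) -> float:
    """Gross a public tariff up to actual provider cost.

    With co-payments assumed to be ``copay_share`` of actual provider
    cost, the provider cost implied by a tariff is tariff/(1 - share).
    """
    if tariff < 0:
        raise ValueError(f"tariff must be >= 0, got {tariff}")
    if prices.copay_share >= 1.0:
        raise ValueError("copay_share = 1 leaves provider cost undefined")
    return tariff / (1.0 - prices.copay_share)


def _unit_provider_cost(service: str, prices: PriceTable) -> float:
    """Per-unit provider cost in NOK for one service, before CPI inflation."""
    if service == "gp_contacts":
        return provider_cost_from_tariff(weighted_gp_fee(prices), prices)
    if service == "hospital_days":
        return prices.hospital_per_diem
    if service in _INFORMAL_SERVICES:
        return prices.informal_care_unit_price
    if service not in prices.unit_prices:
        raise KeyError(service)
    price = prices.unit_prices[service]
    if service in _TARIFF_SERVICES:
        return provider_cost_from_tariff(price, prices)
    return price


@dataclass
class CostBreakdown:
    """Per-component 3-month costs for one patient record (NOK and EUR)."""

    components_nok: dict[str, float]
    informal_care_nok: float
    eur_per_nok: float
    metadata: dict = field(default_factory=dict)

    @property
    def total_health_social_care_nok(self) -> float:
        return float(sum(self.components_nok.values()))

    @property
    def total_health_social_care_eur(self) -> float:
        return self.total_health_social_care_nok / self.eur_per_nok

    @property
    def informal_care_eur(self) -> float:
        return self.informal_care_nok / self.eur_per_nok


def cost_record(resource_use: dict[str, float],
                prices: PriceTable | None = None) -> CostBreakdown:
    """Cost one patient-wave's resource-use counts.

    Missing counts (``None``/NaN) are treated as zero use, with a logged
    warning so the substitution is auditable.  Unknown service names are
    an error.
    """
    prices = prices or PriceTable()
    components: dict[str, float] = {}
    informal = 0.0
    unknown: list[str] = []
    n_missing = 0
    for service, count in resource_use.items():
        if count is None or pd.isna(count):
            n_missing += 1
            count = 0.0
        if count < 0:
            raise ValueError(f"negative count for {service}: {count}")
        try:
            unit = _unit_provider_cost(service, prices)
        except KeyError:
            unknown.append(service)
            continue
        nok = float(count) * unit * prices.cpi_factor
        if service in _INFORMAL_SERVICES:
            informal += nok
        else:
            components[service] = nok
    if unknown:
        raise KeyError(f"no unit price for services: {sorted(unknown)}")
    if n_missing:
        logger.warning("%d missing resource-use counts treated as zero",
                       n_missing)
    return CostBreakdown(
        components, informal, prices.eur_per_nok,
        metadata={"copay_convention": "tariff grossed up by /(1-copay_share)",
                  "cpi_factor": prices.cpi_factor,
                  "n_missing_counts_zeroed": n_missing})


def cost_cohort(table: CohortTable,
                prices: PriceTable | None = None) -> pd.DataFrame:
    """Cost every patient x wave in a cohort.

    Returns one row per record with per-component NOK costs, the total
    health and social care cost, the informal-care cost, and EUR
    equivalents.
    """
    prices = prices or PriceTable()
    services = table.resource_columns
    if not services:
        raise ValueError("cohort has no resource-use columns to cost")
    rows = []
    for _, rec in table.data.iterrows():
        bd = cost_record({svc: rec[svc] for svc in services}, prices)
        row = {"patient_id": rec["patient_id"], "arm": rec["arm"],
               "time": rec["time"]}
        row.update({f"cost_{k}": v for k, v in bd.components_nok.items()})
        row["total_health_social_care_nok"] = bd.total_health_social_care_nok
        row["total_health_social_care_eur"] = bd.total_health_social_care_eur
        row["informal_care_nok"] = bd.informal_care_nok
        row["informal_care_eur"] = bd.informal_care_eur
        rows.append(row)
    return pd.DataFrame(rows)
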