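"""Synthetic two-arm longitudinal cohorts with known ground truth.

The generator realises the data-generating process the analysis assumes:

.. math::

    y_{jt} = \\beta_0 + \\beta_2 T_t + \\beta_3 I_j T_t
             + \\chi X_{jt} + \\psi_j + \\varepsilon_{jt}

with a patient random intercept :math:`\\psi_j`, an age covariate
:math:`X_{jt}`, and the treatment effect on the treated :math:`\\beta_3`
acting only on the programme arm at follow-up.  Baseline arm differences
are *not* injected directly (no structural :math:`\\beta_1`); they emerge
from confounded treatment assignment: the arm is drawn from a logistic
model on age, sex and the observed baseline scores of two outcomes, which
is exactly the propensity model the weighting stage fits.

Realism features layered on top: instrument scores are clipped to their
bounded scales, cost outcomes get a heavy right tail via a mean-preserving
lognormal patient factor (the treatment effect stays additive, so the
configured effect remains the exact ATT truth), follow-up records are
dropped with arm-specific attrition probabilities, observed values are
masked sporadically, and a configurable number of follow-up-only
respondents is injected for the cohort-rule stage to remove.

Every random draw comes from one seeded generator, so a given seed yields
a byte-identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .outcomes import ALL_OUTCOMES, OutcomeSpec, outcome_registry
from .schema import CohortTable

# default ICC used to split a plain baseline_sd into intercept + residual
_DEFAULT_ICC = 0.6


@dataclass(frozen=True)
class OutcomeParams:
    """Generating parameters for one outcome.

    ``baseline_sd`` is the total cross-sectional SD at baseline; if
    ``random_intercept_sd``/``residual_sd`` are not given explicitly it is
    split between them with an intraclass correlation of 0.6 (a typical
    value for repeated patient-reported measures).  ``treatment_effect``
    is the additive effect in the programme arm at follow-up (the ATT
    truth); ``time_trend`` is the common change from baseline to
    follow-up; ``age_slope`` is the age coefficient.  ``skewed`` switches
    the patient-level heterogeneity to a mean-preserving lognormal factor
    (for cost outcomes, whose SD can exceed their mean).
    """

    baseline_mean: float
    baseline_sd: float
    time_trend: float = 0.0
    treatment_effect: float = 0.0
    age_slope: float = 0.0
    random_intercept_sd: float | None = None
    residual_sd: float | None = None
    skewed: bool = False

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")
        for name in ("random_intercept_sd", "residual_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def intercept_sd(self) -> float:
        if self.random_intercept_sd is not None:
            return self.random_intercept_sd
        return self.baseline_sd * math.sqrt(_DEFAULT_ICC)

    @property
    def noise_sd(self) -> float:
        if self.residual_sd is not None:
            return self.residual_sd
        return self.baseline_sd * math.sqrt(1.0 - _DEFAULT_ICC)


#: Default outcome-generating parameters.  Baseline means/SDs follow the
#: observed baseline distributions of the study instruments; time trends
#: are the usual-care 6-month changes and treatment effects the estimated
#: differences in change, so the default cohort reproduces the study's
#: effect-size regime.  Costs are in NOK per 3 months.
DEFAULT_OUTCOME_PARAMS: dict[str, OutcomeParams] = {
    "physical_functioning": OutcomeParams(5.3, 3.2, time_trend=-0.04,
                                          treatment_effect=-0.03,
                                          age_slope=0.08),
    "psychological_wellbeing": OutcomeParams(73.0, 18.5, time_trend=-2.8,
                                             treatment_effect=4.8),
    "social_participation": OutcomeParams(7.5, 4.4, time_trend=1.16,
                                          treatment_effect=-0.56,
                                          age_slope=0.06),
    "enjoyment_of_life": OutcomeParams(2.62, 0.80, time_trend=-0.03,
                                       treatment_effect=0.20),
    "resilience": OutcomeParams(20.3, 4.9, time_trend=-1.53,
                                treatment_effect=2.08),
    "person_centeredness": OutcomeParams(11.3, 4.3, time_trend=-1.09,
                                         treatment_effect=0.71),
    "continuity_of_care": OutcomeParams(3.53, 0.72, time_trend=0.08,
                                        treatment_effect=-0.05),
    "total_costs": OutcomeParams(132_000, 140_000, time_trend=-50_950,
                                 treatment_effect=-29_550, skewed=True),
    "autonomy": OutcomeParams(23.1, 5.3, time_trend=1.97,
                              treatment_effect=-2.92),
    "burden_of_medication": OutcomeParams(2.4, 2.6, time_trend=-0.51,
                                          treatment_effect=0.23),
    "informal_care_costs": OutcomeParams(16_000, 60_000, time_trend=5_770,
                                         treatment_effect=-20_660,
                                         skewed=True),
}

#: Default assignment log-odds per SD of each driver: the programme arm is
#: younger, has fewer men, better (lower) ADL dependence and worse (higher)
#: social-participation restriction than usual care.
DEFAULT_CONFOUNDING: dict[str, float] = {
    "age_years": -0.50,
    "male": -0.40,
    "physical_functioning": -0.35,
    "social_participation": 0.30,
}

#: Mean 3-month resource-use counts (usual care level) per service.
DEFAULT_RESOURCE_RATES: dict[str, float] = {
    "gp_contacts": 3.0,
    "nurse_contacts": 8.0,
    "physiotherapist_contacts": 4.0,
    "specialist_contacts": 1.0,
    "hospital_days": 1.5,
    "hospital_outpatient_visits": 0.8,
    "home_care_hours": 30.0,
    "nursing_home_days": 2.0,
    "informal_care_hours": 25.0,
    "medication_ddd_days": 75.0,
}

#: Multiplicative shift of follow-up resource rates in the programme arm
#: (more primary care, fewer hospital/institutional days).
DEFAULT_PROGRAMME_RATE_RATIO: dict[str, float] = {
    "gp_contacts": 1.25,
    "specialist_contacts": 1.1,
    "nurse_contacts": 0.9,
    "hospital_days": 0.6,
    "nursing_home_days": 0.6,
    "informal_care_hours": 0.8,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the evaluated cohort: 120 programme and 89
    usual-care baseline respondents, attrition to about 86 and 41 at
    6 months, four follow-up-only respondents, and sporadic (2%) item
    missingness.
    """

    n_hcpc: int = 120
    n_uc: int = 89
    seed: int = 0
    confounding_strength: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDING))
    outcome_params: Mapping[str, OutcomeParams] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_PARAMS))
    attrition_prob: Mapping[str, float] = field(
        default_factory=lambda: {"HCPC": 1 - 86 / 120, "UC": 1 - 41 / 89})
    item_missing_prob: float = 0.02
    followup_only_count: int = 4
    age_mean: float = 81.5
    age_sd: float = 8.5
    age_range: tuple[float, float] = (65.0, 100.0)
    simulate_resource_use: bool = True

    def validate(self) -> None:
        if self.n_hcpc < 2 or self.n_uc < 2:
            raise ValueError("n_hcpc and n_uc must each be >= 2")
        for arm, p in self.attrition_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"attrition_prob[{arm}]={p} not in [0, 1]")
        if not 0 <= self.item_missing_prob <= 1:
            raise ValueError(
                f"item_missing_prob={self.item_missing_prob} not in [0, 1]")
        if self.followup_only_count < 0:
            raise ValueError("followup_only_count must be >= 0")
        for name, p in self.outcome_params.items():
            if not isinstance(p, OutcomeParams):
                raise ValueError(f"outcome_params[{name!r}] must be "
                                 "an OutcomeParams")


@dataclass
class TruthRecord:
    """Ground truth of one simulated cohort.

    Sufficient to compute every downstream estimand's truth: the ATT per
    outcome equals the configured ``treatment_effect``; the true
    assignment propensities allow exact balance checks; injected
    follow-up-only ids and per-arm dropout counts allow the cohort-rule
    and attrition accounting to be verified.
    """

    config: SimulationConfig
    att: dict[str, float]
    propensity: pd.Series               # patient_id -> true P(HCPC | X)
    n_baseline: dict[str, int]
    n_followup: dict[str, int]
    followup_only_ids: list[str]
    random_intercepts: pd.DataFrame     # patient_id x outcome

    def to_dict(self) -> dict:
        return {
            "att": self.att,
            "n_baseline": self.n_baseline,
            "n_followup": self.n_followup,
            "followup_only_ids": list(self.followup_only_ids),
            "config": {
                k: (dict(v) if isinstance(v, Mapping) and not any(
                    isinstance(x, OutcomeParams) for x in v.values())
                    else {n: asdict(p) for n, p in v.items()}
                    if isinstance(v, Mapping) else v)
                for k, v in asdict(self.config).items()
            },
        }


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():                       # redraw; truncation region is wide
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=0)
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def _mean_preserving_lognormal_factor(
    rng: np.random.Generator, cv: float, size: int,
) -> np.ndarray:
    """exp(s z - s^2/2) with E = 1 and coefficient of variation ``cv``."""
    s = math.sqrt(math.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * s * s, s, size))


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[CohortTable, TruthRecord]:
    """Generate one synthetic cohort and its ground truth.

    The order of operations matters for the causal structure: covariates
    and baseline outcomes are drawn first, the arm is then assigned from
    the logistic confounding model on those *observed* baselines, and the
    treatment effect enters only the follow-up wave of the programme arm.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    specs = outcome_registry(ALL_OUTCOMES)
    params = dict(config.outcome_params)
    unknown = set(params) - set(specs)
    if unknown:
        raise ValueError(f"outcome_params for unknown outcomes: {sorted(unknown)}")

    n = config.n_hcpc + config.n_uc
    pid = np.array([f"P{i:04d}" for i in range(n)])

    # ------------------------------------------------------------ covariates
    age = _truncated_normal(rng, config.age_mean, config.age_sd,
                            *config.age_range, n)
    male = rng.random(n) < 0.45
    living = rng.choice(["alone", "with_others", "missing"], n,
                        p=[0.57, 0.42, 0.01])
    smoking = rng.choice(["current", "previous", "never", "missing"], n,
                         p=[0.12, 0.53, 0.34, 0.01])
    multimorbid = rng.random(n) < 0.94
    education = rng.choice(["low", "medium", "high", "missing"], n,
                           p=[0.37, 0.36, 0.24, 0.03])

    # -------------------------------------------- latent + baseline outcomes
    intercepts = {}
    y0, y1_latent = {}, {}
    for name, p in params.items():
        spec = specs[name]
        if p.skewed:
            cv = p.intercept_sd / p.baseline_mean if p.baseline_mean > 0 else 0.5
            patient_mean = p.baseline_mean * _mean_preserving_lognormal_factor(
                rng, cv, n)
            psi = patient_mean - p.baseline_mean
        else:
            psi = rng.normal(0.0, p.intercept_sd, n)
            patient_mean = p.baseline_mean + psi
        intercepts[name] = psi
        mu = patient_mean + p.age_slope * (age - config.age_mean)
        y0[name] = np.clip(mu + rng.normal(0, p.noise_sd, n),
                           spec.scale_min, spec.scale_max)
        # follow-up, before the treatment effect; age advances half a year
        y1_latent[name] = (mu + p.age_slope * 0.5 + p.time_trend
                           + rng.normal(0, p.noise_sd, n))

    # ------------------------------------------------------- arm assignment
    drivers = {"age_years": age, "male": male.astype(float)}
    for name in params:
        drivers[name] = np.asarray(y0[name], dtype=float)
    score = np.zeros(n)
    for cov, strength in config.confounding_strength.items():
        if cov not in drivers:
            raise ValueError(f"confounding_strength refers to unknown "
                             f"covariate {cov!r}")
        score += strength * _standardize(drivers[cov])
    target = config.n_hcpc

    def excess(c0: float) -> float:
        return float(expit(c0 + score).sum() - target)

    c0 = brentq(excess, -30.0, 30.0)
    propensity = expit(c0 + score)
    is_hcpc = rng.random(n) < propensity
    if is_hcpc.all() or not is_hcpc.any():
        raise RuntimeError("degenerate assignment: one arm is empty; "
                           "lower confounding_strength or raise n")
    arm = np.where(is_hcpc, "HCPC", "UC")

    # ------------------------------------------------- treatment effect @ T1
    y1 = {}
    for name, p in params.items():
        spec = specs[name]
        y1[name] = np.clip(y1_latent[name] + p.treatment_effect * is_hcpc,
                           spec.scale_min, spec.scale_max)

    # ------------------------------------------------------------- attrition
    drop_t1 = np.zeros(n, dtype=bool)
    for a in ("HCPC", "UC"):
        mask = arm == a
        drop_t1[mask] = rng.random(mask.sum()) < config.attrition_prob[a]

    # --------------------------------------------------------- resource use
    ru0 = ru1 = None
    if config.simulate_resource_use:
        frail = _standardize(age)      # older patients consume more care
        ru0, ru1 = {}, {}
        for svc, rate in DEFAULT_RESOURCE_RATES.items():
            lam0 = rate * np.exp(0.25 * frail)
            ratio = np.where(is_hcpc,
                             DEFAULT_PROGRAMME_RATE_RATIO.get(svc, 1.0), 1.0)
            ru0[svc] = rng.poisson(lam0)
            ru1[svc] = rng.poisson(lam0 * ratio)

    # ------------------------------------------------------------- assemble
    def wave(time: str, idx: np.ndarray) -> pd.DataFrame:
        d = {
            "patient_id": pid[idx], "arm": arm[idx], "time": time,
            "age_years": np.round(age[idx] + (0.5 if time == "T1" else 0.0), 1),
            "sex": np.where(male[idx], "male", "female"),
            "living_condition": living[idx], "smoking": smoking[idx],
            "multimorbid": multimorbid[idx], "education": education[idx],
        }
        src = y0 if time == "T0" else y1
        for name in params:
            d[name] = np.round(src[name][idx], 4)
        if ru0 is not None:
            rsrc = ru0 if time == "T0" else ru1
            for svc in DEFAULT_RESOURCE_RATES:
                d[svc] = rsrc[svc][idx]
        return pd.DataFrame(d)

    all_idx = np.arange(n)
    frames = [wave("T0", all_idx), wave("T1", all_idx[~drop_t1])]
    df = pd.concat(frames, ignore_index=True)

    # item missingness (outcomes only, covariates stay complete)
    if config.item_missing_prob > 0:
        for name in params:
            mask = rng.random(len(df)) < config.item_missing_prob
            df.loc[mask, name] = np.nan

    # follow-up-only respondents, for the cohort-rule stage to remove
    followup_only_ids: list[str] = []
    if config.followup_only_count > 0:
        m = config.followup_only_count
        fage = _truncated_normal(rng, config.age_mean, config.age_sd,
                                 *config.age_range, m)
        rows = {
            "patient_id": [f"F{i:04d}" for i in range(m)],
            "arm": rng.choice(["HCPC", "UC"], m), "time": "T1",
            "age_years": np.round(fage, 1),
            "sex": rng.choice(["male", "female"], m),
            "living_condition": rng.choice(["alone", "with_others"], m),
            "smoking": rng.choice(["current", "previous", "never"], m),
            "multimorbid": rng.random(m) < 0.94,
            "education": rng.choice(["low", "medium", "high"], m),
        }
        for name, p in params.items():
            spec = specs[name]
            rows[name] = np.round(np.clip(
                rng.normal(p.baseline_mean, p.baseline_sd, m),
                spec.scale_min, spec.scale_max), 4)
        if ru0 is not None:
            for svc, rate in DEFAULT_RESOURCE_RATES.items():
                rows[svc] = rng.poisson(rate, m)
        followup_only_ids = list(rows["patient_id"])
        df = pd.concat([df, pd.DataFrame(rows)], ignore_index=True)

    table = CohortTable(df.reset_index(drop=True), specs)
    truth = TruthRecord(
        config=config,
        att={name: p.treatment_effect for name, p in params.items()},
        propensity=pd.Series(propensity, index=pid, name="propensity"),
        n_baseline={"HCPC": int(is_hcpc.sum()), "UC": int((~is_hcpc).sum())},
        n_followup={"HCPC": int((is_hcpc & ~drop_t1).sum()),
                    "UC": int((~is_hcpc & ~drop_t1).sum())},
        followup_only_ids=followup_only_ids,
        random_intercepts=pd.DataFrame(intercepts, index=pid),
    )
    return table, truth
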