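"""Propensity scores, ATT inverse-probability weights, balance diagnostics.

Treatment status (programme arm vs usual care) is regressed on baseline
socio-demographics and two baseline outcome scores with a logit link.
Weights target the average treatment effect on the treated (ATT): every
programme patient gets weight 1 and every usual-care patient gets
ps/(1 - ps), which reweights the comparison group to the covariate
distribution of the programme group.

Balance before and after weighting is summarised by

* the absolute standardized bias per covariate,
  100 |mean_T - mean_C| / sqrt((var_T + var_C)/2);
* Rubin's B, the standardized difference of the arms' mean propensity
  linear index (sufficient balance: B < 25); and
* Rubin's R, the ratio of the arms' linear-index variances
  (sufficient balance: 0.5 < R < 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .schema import CATEGORICAL_COVARIATES, CohortTable

logger = logging.getLogger(__name__)

RUBIN_B_THRESHOLD = 25.0
RUBIN_R_RANGE = (0.5, 2.0)

DEFAULT_PS_COVARIATES = (
    "age_years", "sex", "living_condition", "smoking", "multimorbid",
    "physical_functioning", "social_participation",
)


@dataclass(frozen=True)
class PropensityModelSpec:
    """Covariate list for the logit propensity model."""

    covariates: Sequence[str] = DEFAULT_PS_COVARIATES
    propensity_bounds: tuple[float, float] = (0.01, 0.99)


@dataclass
class WeightedCohort:
    """A cohort plus fitted propensities and ATT weights (per patient)."""

    cohort: CohortTable
    propensity: pd.Series          # patient_id -> P(HCPC | X), truncated
    att_weight: pd.Series          # patient_id -> 1 (HCPC) or ps/(1-ps) (UC)
    linear_index: pd.Series        # patient_id -> X @ beta (log-odds)
    coefficients: pd.Series = field(default_factory=pd.Series)
    converged: bool = True
    n_truncated: int = 0

    def weights_for(self, records: pd.DataFrame) -> np.ndarray:
        return self.att_weight.reindex(records["patient_id"]).to_numpy()


#: indicator levels rarer than this are merged into the reference level
MIN_LEVEL_COUNT = 5


def _design_matrix(baseline: pd.DataFrame,
                   covariates: Sequence[str]) -> pd.DataFrame:
    """Expand covariates to a numeric design; categoricals become
    indicator sets with the most frequent level as reference.  Levels
    observed fewer than :data:`MIN_LEVEL_COUNT` times (e.g. near-empty
    ``missing`` categories) are folded into the reference to keep the
    logit Hessian well conditioned."""
    cols = {}
    for cov in covariates:
        if cov not in baseline.columns:
            raise KeyError(f"propensity covariate {cov!r} not in cohort")
        x = baseline[cov]
        if cov in CATEGORICAL_COVARIATES or x.dtype == object:
            levels = x.value_counts().index.tolist()
            for level in levels[1:]:       # most frequent level is reference
                ind = (x == level).astype(float)
                if ind.sum() < MIN_LEVEL_COUNT:
                    logger.info("folding rare level %s=%s (n=%d) into the "
                                "reference", cov, level, int(ind.sum()))
                    continue
                cols[f"{cov}[{level}]"] = ind
        elif x.dtype == bool:
            cols[cov] = x.astype(float)
        else:
            cols[cov] = pd.to_numeric(x, errors="raise").astype(float)
    X = pd.DataFrame(cols, index=baseline.index)
    X = X.loc[:, X.std(ddof=0) > 0]        # drop constants
    return sm.add_constant(X, has_constant="add")


def fit_propensity(
    cohort: CohortTable,
    spec: PropensityModelSpec | None = None,
) -> WeightedCohort:
    """Fit the logit propensity model on baseline records and weight.

    Raises a ``ValueError`` on perfect separation or non-convergence,
    naming the remedy (reduce the covariate set).
    """
    spec = spec or PropensityModelSpec()
    baseline = cohort.baseline()
    if baseline.empty:
        raise ValueError("cohort has no baseline (T0) records")
    if baseline[list(dict.fromkeys(
            c for c in spec.covariates if c in baseline.columns))].isna().any().any():
        raise ValueError("missing covariate/outcome values at baseline; "
                         "impute outcomes before fitting the propensity model")
    y = (baseline["arm"] == "HCPC").astype(float)
    X = _design_matrix(baseline, spec.covariates)
    import warnings

    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            result = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:       # singular Hessian / separation: retry below
            result = None
        if result is None or not result.mle_retvals.get("converged", False):
            # Newton stalls or breaks under quasi-separation; BFGS usually
            # reaches the (possibly boundary-drifting) optimum, and
            # propensity truncation bounds the resulting weights
            logger.info("logit Newton failed; retrying with BFGS")
            try:
                result = sm.Logit(y, X).fit(disp=0, method="bfgs",
                                            maxiter=1000)
            except Exception as exc:
                raise ValueError(
                    f"propensity model failed ({exc}); consider reducing "
                    f"the covariate set {tuple(spec.covariates)}") from exc
    if not result.mle_retvals.get("converged", False):
        raise ValueError(
            "propensity model did not converge after "
            f"{result.mle_retvals.get('iterations')} iterations; "
            "consider reducing the covariate set")

    pid = baseline["patient_id"].to_numpy()
    linear = pd.Series(np.asarray(X @ result.params), index=pid,
                       name="linear_index")
    ps_raw = pd.Series(result.predict(X).to_numpy(), index=pid,
                       name="propensity")
    lo, hi = spec.propensity_bounds
    ps = ps_raw.clip(lo, hi)
    n_trunc = int((ps_raw != ps).sum())
    if n_trunc:
        logger.warning("truncated %d propensities to [%g, %g]",
                       n_trunc, lo, hi)
    is_hcpc = baseline.set_axis(pid)["arm"] == "HCPC"
    weight = pd.Series(np.where(is_hcpc, 1.0, ps / (1.0 - ps)), index=pid,
                       name="att_weight")
    return WeightedCohort(cohort, ps, weight, linear,
                          coefficients=result.params, converged=True,
                          n_truncated=n_trunc)


def _wmean_wvar(x: np.ndarray, w: np.ndarray | None) -> tuple[float, float, float]:
    """Weighted mean, frequency-normalized weighted variance, effective n."""
    x = np.asarray(x, dtype=float)
    if w is None:
        w = np.ones_like(x)
    w = np.asarray(w, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    w = w * (len(w) / w.sum())           # frequency normalization
    mean = float(np.average(x, weights=w))
    denom = w.sum() - 1.0
    var = float((w * (x - mean) ** 2).sum() / denom) if denom > 0 else 0.0
    n_eff = float(w.sum() ** 2 / (w ** 2).sum())
    return mean, var, n_eff


def standardized_bias(
    x_hcpc: np.ndarray,
    x_uc: np.ndarray,
    weights_uc: np.ndarray | None = None,
    weights_hcpc: np.ndarray | None = None,
) -> float:
    """Absolute standardized bias in percent.

    100 |mean_T - mean_C| / sqrt((var_T + var_C)/2); weighted moments are
    used where weights are given.
    """
    m1, v1, _ = _wmean_wvar(x_hcpc, weights_hcpc)
    m2, v2, _ = _wmean_wvar(x_uc, weights_uc)
    pooled = (v1 + v2) / 2.0
    if pooled <= 0:
        raise ValueError("zero pooled variance: degenerate covariate")
    return 100.0 * abs(m1 - m2) / np.sqrt(pooled)


def _welch_p(x1, x2, w1=None, w2=None) -> float:
    """Weighted Welch test p-value using effective sample sizes."""
    m1, v1, n1 = _wmean_wvar(x1, w1)
    m2, v2, n2 = _wmean_wvar(x2, w2)
    se2 = v1 / n1 + v2 / n2
    if se2 <= 0:
        return float("nan")
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(2 * stats.t.sf(abs(t), df))


def rubins_B_R(
    weighted: WeightedCohort, use_weights: bool = True,
) -> tuple[float, float]:
    """Rubin's B and R on the propensity linear index.

    B is 100x the standardized difference of the arms' mean linear index;
    R is the ratio of the arms' linear-index variances (HCPC over UC).
    With ``use_weights`` the UC moments are ATT-weighted.
    """
    arm = weighted.cohort.arm_of().reindex(weighted.linear_index.index)
    li = weighted.linear_index
    t, c = li[arm == "HCPC"], li[arm == "UC"]
    if len(t) == 0 or len(c) == 0:
        raise ValueError("both arms required for Rubin's B/R")
    wc = weighted.att_weight[arm == "UC"].to_numpy() if use_weights else None
    m1, v1, _ = _wmean_wvar(t.to_numpy(), None)
    m2, v2, _ = _wmean_wvar(c.to_numpy(), wc)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("zero variance of the linear index in one arm")
    B = 100.0 * abs(m1 - m2) / np.sqrt((v1 + v2) / 2.0)
    R = v1 / v2
    return float(B), float(R)


@dataclass
class BalanceReport:
    """Before/after covariate balance in the layout of a baseline table."""

    rows: pd.DataFrame        # per covariate/level: means, bias, p, both stages
    summary: pd.DataFrame     # mean/median bias, Rubin's B and R, pass flags

    def passes(self, stage: str = "after") -> bool:
        s = self.summary.set_index("stage").loc[stage]
        return bool(s["rubins_B_pass"] and s["rubins_R_pass"])


def _balance_rows(baseline: pd.DataFrame, columns: Sequence[str],
                  w_uc: np.ndarray | None) -> list[dict]:
    is_t = (baseline["arm"] == "HCPC").to_numpy()
    rows = []
    for col in columns:
        x = baseline[col]
        if col in CATEGORICAL_COVARIATES or x.dtype == object:
            expanded = [(f"{col}[{lvl}]", (x == lvl).astype(float).to_numpy())
                        for lvl in sorted(x.unique())]
        elif x.dtype == bool:
            expanded = [(col, x.astype(float).to_numpy())]
        else:
            expanded = [(col, pd.to_numeric(x).to_numpy())]
        for label, vals in expanded:
            xt, xc = vals[is_t], vals[~is_t]
            try:
                bias = standardized_bias(xt, xc, weights_uc=w_uc)
                p = _welch_p(xt, xc, None, w_uc)
            except ValueError:        # degenerate level
                bias, p = float("nan"), float("nan")
            mt, vt, _ = _wmean_wvar(xt, None)
            mc, vc, _ = _wmean_wvar(xc, w_uc)
            rows.append({"variable": label, "mean_hcpc": mt,
                         "sd_hcpc": np.sqrt(vt), "mean_uc": mc,
                         "sd_uc": np.sqrt(vc), "std_bias": bias,
                         "p_value": p})
    return rows


def balance_table(weighted: WeightedCohort,
                  covariates: Sequence[str] | None = None,
                  include_outcomes: bool = True) -> BalanceReport:
    """Full before/after balance report over covariates and baseline outcomes."""
    cohort = weighted.cohort
    baseline = cohort.baseline()
    cols = list(covariates) if covariates is not None else [
        "age_years", "sex", "living_condition", "education", "smoking",
        "multimorbid"]
    if include_outcomes:
        cols += [c for c in cohort.outcome_columns if c not in cols]

    is_uc = (baseline["arm"] == "UC").to_numpy()
    w_uc = weighted.att_weight.reindex(
        baseline.loc[is_uc, "patient_id"]).to_numpy()

    frames = []
    for stage, w in (("before", None), ("after", w_uc)):
        rows = pd.DataFrame(_balance_rows(baseline, cols, w))
        rows.insert(0, "stage", stage)
        frames.append(rows)
    rows = pd.concat(frames, ignore_index=True)

    summaries = []
    for stage, use_w in (("before", False), ("after", True)):
        biases = rows.loc[rows["stage"] == stage, "std_bias"].dropna()
        B, R = rubins_B_R(weighted, use_weights=use_w)
        summaries.append({
            "stage": stage, "mean_bias": float(biases.mean()),
            "median_bias": float(biases.median()),
            "rubins_B": B, "rubins_R": R,
            "rubins_B_pass": B < RUBIN_B_THRESHOLD,
            "rubins_R_pass": RUBIN_R_RANGE[0] < R < RUBIN_R_RANGE[1],
        })
    return BalanceReport(rows, pd.DataFrame(summaries))
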