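"""Random-intercept difference-in-differences models on IPTW-weighted data.

For each outcome y the model

.. math::

    y_{jt} = \\beta_0 + \\beta_1 I_j + \\beta_2 T_t + \\beta_3 I_j T_t
             + \\chi X_{jt} + \\psi_j + \\varepsilon_{jt}

is fitted by maximum likelihood on the pooled baseline/follow-up rows,
where :math:`I_j` indicates the programme arm, :math:`T_t` the follow-up
wave, :math:`X_{jt}` is age, and :math:`\\psi_j` a patient random
intercept.  :math:`\\beta_3` — the arm-by-time interaction — is the
difference in change, i.e. the treatment effect on the treated.
Patients lost to follow-up contribute their baseline row (no listwise
deletion).

ATT weights enter as patient-level probability weights in a weighted
(pseudo-)likelihood: each patient's marginal log-likelihood contribution
is multiplied by the patient's weight, and inference uses a
cluster-robust sandwich covariance.  The marginal covariance of a
patient's residual vector is :math:`\\sigma_\\psi^2 J + \\sigma_e^2 I`;
with at most two waves per patient these blocks are 1x1 or 2x2 and are
evaluated in closed form, so the profile likelihood over the two variance
components is cheap to optimise.

Performance scores for the MCDA are the model-predicted follow-up means:
the programme arm's predicted mean at its own covariate profile, and a
usual-care counterfactual anchored at the programme arm's baseline —
obtained by subtracting :math:`\\beta_3`, so the gap between the two
predictions is the treatment effect exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .outcomes import Direction
from .weighting import WeightedCohort

DEFAULT_COVARIATES = ("age_years",)
_FIXED_TERMS = ("const", "arm", "time", "arm_time")


@dataclass
class DiDModelFit:
    """One fitted random-intercept DiD model.

    ``params`` holds the fixed effects in the order const, arm, time,
    arm x time, then covariates; ``cov_robust`` is the cluster-robust
    (sandwich) covariance of those estimates.
    """

    outcome_name: str
    params: pd.Series
    cov_robust: pd.DataFrame
    psi_variance: float
    residual_variance: float
    loglik: float
    n_obs: int
    n_patients: int
    converged: bool
    covariates: tuple[str, ...] = ()
    profile: dict[str, float] = field(default_factory=dict)

    @property
    def beta0(self) -> float:
        return float(self.params["const"])

    @property
    def beta1(self) -> float:
        return float(self.params["arm"])

    @property
    def beta2(self) -> float:
        return float(self.params["time"])

    @property
    def beta3(self) -> float:
        """Difference in change: the treatment effect on the treated."""
        return float(self.params["arm_time"])

    @property
    def robust_se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_robust)),
                         index=self.params.index)

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = self.robust_se
        return pd.DataFrame({"lower": self.params - z * se,
                             "upper": self.params + z * se})


def _design(rows: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    X = pd.DataFrame({
        "const": 1.0,
        "arm": (rows["arm"] == "HCPC").astype(float),
        "time": (rows["time"] == "T1").astype(float),
    }, index=rows.index)
    X["arm_time"] = X["arm"] * X["time"]
    for cov in covariates:
        X[cov] = pd.to_numeric(rows[cov], errors="raise").astype(float)
    return X


def _block_arrays(rows: pd.DataFrame, X: pd.DataFrame, y: np.ndarray,
                  w: np.ndarray):
    """Split patient blocks into singletons and wave pairs (T0, T1)."""
    order = np.lexsort((rows["time"].to_numpy(), rows["patient_id"].to_numpy()))
    pid = rows["patient_id"].to_numpy()[order]
    Xo, yo, wo = X.to_numpy()[order], y[order], w[order]
    _, start, counts = np.unique(pid, return_index=True, return_counts=True)
    if counts.max() > 2:
        raise ValueError("more than two records for one patient; "
                         "validate the cohort first")
    s1 = start[counts == 1]
    s2 = start[counts == 2]
    singles = (Xo[s1], yo[s1], wo[s1])
    pairs = (np.stack([Xo[s2], Xo[s2 + 1]], axis=1),
             np.stack([yo[s2], yo[s2 + 1]], axis=1), wo[s2])
    return singles, pairs


def _profile_beta(theta: np.ndarray, singles, pairs):
    """GLS fixed effects and log-likelihood pieces at given variances.

    theta = (sigma_psi^2, sigma_eps^2).  For a singleton, V = a + s; for a
    pair, V = s I + a J, so V^-1 = (1/s) I - (a / (s (s + 2a))) J.
    """
    a, s = theta
    X1, y1, w1 = singles
    X2, y2, w2 = pairs
    p = X1.shape[1] if X1.size else X2.shape[2]

    A = np.zeros((p, p))
    b = np.zeros(p)
    if len(X1):
        v1 = a + s
        A += (w1[:, None] * X1 / v1).T @ X1
        b += (w1 * y1 / v1) @ X1
    if len(X2):
        c1 = 1.0 / s
        c2 = -a / (s * (s + 2.0 * a))
        Xi = X2            # (m, 2, p)
        Sx = X2.sum(axis=1)          # (m, p)
        Sy = y2.sum(axis=1)          # (m,)
        A += c1 * np.einsum("m,mtp,mtq->pq", w2, Xi, Xi)
        A += c2 * np.einsum("m,mp,mq->pq", w2, Sx, Sx)
        b += c1 * np.einsum("m,mtp->p", w2, Xi * y2[:, :, None])
        b += c2 * np.einsum("m,mp->p", w2 * Sy, Sx)
    beta = np.linalg.solve(A, b)
    return beta, A


def _neg_loglik(log_theta: np.ndarray, singles, pairs) -> float:
    theta = np.exp(log_theta)
    a, s = theta
    beta, _ = _profile_beta(theta, singles, pairs)
    X1, y1, w1 = singles
    X2, y2, w2 = pairs
    ll = 0.0
    if len(X1):
        v1 = a + s
        r = y1 - X1 @ beta
        ll += -0.5 * float((w1 * (np.log(2 * np.pi * v1) + r * r / v1)).sum())
    if len(X2):
        det = s * (s + 2.0 * a)
        c1, c2 = 1.0 / s, -a / (s * (s + 2.0 * a))
        R = y2 - np.einsum("mtp,p->mt", X2, beta)
        quad = c1 * (R * R).sum(axis=1) + c2 * R.sum(axis=1) ** 2
        ll += -0.5 * float((w2 * (2 * np.log(2 * np.pi)
                                  + np.log(det) + quad)).sum())
    return -ll


def fit_did_model(
    weighted: WeightedCohort,
    outcome_name: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> DiDModelFit:
    """Fit the weighted random-intercept DiD model for one outcome.

    Rows with a missing outcome value are dropped (impute first to keep
    them); patients keep whatever waves they have.
    """
    cohort = weighted.cohort
    if outcome_name not in cohort.data.columns:
        raise KeyError(f"outcome {outcome_name!r} not in cohort")
    rows = cohort.data[cohort.data[outcome_name].notna()].copy()
    if rows.empty:
        raise ValueError(f"outcome {outcome_name!r} has no observed values")
    for arm in ("HCPC", "UC"):
        for t in ("T0", "T1"):
            if ((rows["arm"] == arm) & (rows["time"] == t)).sum() == 0:
                raise ValueError(
                    f"outcome {outcome_name!r}: no observations in "
                    f"arm={arm}, time={t}; model not identifiable")
    y = pd.to_numeric(rows[outcome_name]).to_numpy(dtype=float)
    X = _design(rows, covariates)
    w = weighted.att_weight.reindex(rows["patient_id"]).to_numpy(dtype=float)
    if np.isnan(w).any():
        raise ValueError("some records lack an ATT weight; fit the "
                         "propensity model on the same cohort first")
    singles, pairs = _block_arrays(rows, X, y, w)

    # moment-based start: split total residual variance 50/50
    var0 = max(float(np.var(y)), 1e-8)
    x0 = np.log([var0 / 2, var0 / 2])
    res = optimize.minimize(
        _neg_loglik, x0, args=(singles, pairs), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    a, s = np.exp(res.x)
    beta, A = _profile_beta((a, s), singles, pairs)
    if not np.all(np.isfinite(beta)):
        raise ValueError(f"singular fit for outcome {outcome_name!r}")

    # cluster-robust sandwich: bread = A^-1, meat = sum over patients of
    # (w_j X_j' V_j^-1 r_j) outer products
    p = len(beta)
    meat = np.zeros((p, p))
    X1, y1, w1 = singles
    X2, y2, w2 = pairs
    if len(X1):
        g = (w1 * (y1 - X1 @ beta) / (a + s))[:, None] * X1
        meat += g.T @ g
    if len(X2):
        c1, c2 = 1.0 / s, -a / (s * (s + 2.0 * a))
        R = y2 - np.einsum("mtp,p->mt", X2, beta)
        Vr = c1 * R + c2 * R.sum(axis=1, keepdims=True)
        g = w2[:, None] * np.einsum("mtp,mt->mp", X2, Vr)
        meat += g.T @ g
    bread = np.linalg.inv(A)
    cov = bread @ meat @ bread

    names = list(X.columns)
    return DiDModelFit(
        outcome_name=outcome_name,
        params=pd.Series(beta, index=names),
        cov_robust=pd.DataFrame(cov, index=names, columns=names),
        psi_variance=float(a), residual_variance=float(s),
        loglik=-float(res.fun), n_obs=len(rows),
        n_patients=int(rows["patient_id"].nunique()),
        converged=bool(res.success), covariates=tuple(covariates),
    )


@dataclass
class PerformanceRow:
    """Predicted follow-up means for both arms, sharing the HCPC anchor."""

    outcome: str
    mean_hcpc: float
    se_hcpc: float
    mean_uc: float
    se_uc: float
    covariance: float
    direction: Direction


def predict_performance(fit: DiDModelFit,
                        weighted: WeightedCohort) -> PerformanceRow:
    """Predicted follow-up performance of both arms for one outcome.

    The programme prediction is the fitted mean at I=1, T=1 and the
    programme arm's mean covariate profile at follow-up; the usual-care
    counterfactual subtracts the treatment effect, anchoring both arms at
    the programme baseline, so their difference equals beta3 exactly.
    """
    data = weighted.cohort.data
    hcpc_t1 = data[(data["arm"] == "HCPC") & (data["time"] == "T1")]
    if hcpc_t1.empty:                  # fall back to the baseline profile
        hcpc_t1 = data[data["arm"] == "HCPC"]
    names = list(fit.params.index)
    g_h = pd.Series(0.0, index=names)
    g_h[["const", "arm", "time", "arm_time"]] = 1.0
    for cov in fit.covariates:
        g_h[cov] = float(pd.to_numeric(hcpc_t1[cov]).mean())
    g_u = g_h.copy()
    g_u["arm_time"] = 0.0              # subtract beta3

    C = fit.cov_robust.to_numpy()
    gh, gu = g_h.to_numpy(), g_u.to_numpy()
    mean_h = float(g_h @ fit.params)
    mean_u = float(g_u @ fit.params)
    direction = weighted.cohort.outcome_specs[fit.outcome_name].direction
    return PerformanceRow(
        outcome=fit.outcome_name,
        mean_hcpc=mean_h, se_hcpc=float(np.sqrt(gh @ C @ gh)),
        mean_uc=mean_u, se_uc=float(np.sqrt(gu @ C @ gu)),
        covariance=float(gh @ C @ gu), direction=direction,
    )


def performance_matrix(rows: Sequence[PerformanceRow]) -> pd.DataFrame:
    """Assemble prediction rows into the per-outcome performance matrix."""
    return pd.DataFrame([{
        "outcome": r.outcome, "mean_hcpc": r.mean_hcpc, "se_hcpc": r.se_hcpc,
        "mean_uc": r.mean_uc, "se_uc": r.se_uc, "covariance": r.covariance,
        "direction": r.direction.value,
    } for r in rows]).set_index("outcome")


def effects_table(fits: Sequence[DiDModelFit], level: float = 0.95,
                  time_step_years: float = 0.5) -> pd.DataFrame:
    """Within- and between-arm 6-month changes per outcome.

    The usual-care change is beta2 (plus the age drift over the follow-up
    interval when age is in the model); the programme change adds beta3.
    The difference in change is beta3 with its robust CI.  The
    ``improvement`` column annotates the sign of beta3 according to the
    outcome's direction (a negative effect on a higher-is-worse scale is
    an improvement).
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    out = []
    for fit in fits:
        drift = sum(float(fit.params[c]) * time_step_years
                    for c in fit.covariates if c == "age_years")
        se3 = float(fit.robust_se["arm_time"])
        b3 = fit.beta3
        out.append({
            "outcome": fit.outcome_name,
            "change_hcpc": fit.beta2 + b3 + drift,
            "change_uc": fit.beta2 + drift,
            "diff_in_change": b3,
            "ci_lower": b3 - z * se3,
            "ci_upper": b3 + z * se3,
            "robust_se": se3,
            "n_obs": fit.n_obs,
        })
    return pd.DataFrame(out).set_index("outcome")


def annotate_improvement(table: pd.DataFrame,
                         specs) -> pd.DataFrame:
    """Add an ``improvement`` column: does beta3's sign favour the programme?

    ``specs`` maps outcome name to :class:`OutcomeSpec`.
    """
    def verdict(outcome: str, b3: float) -> str:
        direction = specs[outcome].direction
        favourable = b3 > 0 if direction is Direction.HIGHER_BETTER else b3 < 0
        if b3 == 0:
            return "none"
        return "HCPC" if favourable else "UC"

    out = table.copy()
    out["improvement"] = [verdict(o, b) for o, b in
                          zip(out.index, out["diff_in_change"])]
    return out
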