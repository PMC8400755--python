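"""Probabilistic sensitivity analysis of the overall value scores.

Monte Carlo propagation of the joint uncertainty in (a) the raw
performance scores, via the standard errors and between-arm covariances
of the model predictions, and (b) the stakeholder importance weights.
Correlated draws are generated as mean + L z with L a Cholesky (or, for
numerically indefinite inputs, eigenvalue-floored) factor of the
covariance and z independent standard normals.  Each replication
re-standardizes the drawn raw scores and recomputes the additive overall
value per stakeholder and arm; the replication distribution yields
equal-tailed uncertainty intervals, the percentage of replications in
which the programme beats usual care, and an interval-overlap flag (the
arm difference is called significant when the two intervals do not
overlap).

Weight and score draws are sampled independently of each other (each
block internally correlated); negative weight draws are truncated at
zero, and score draws that violate the positivity needed by the
ratio/reciprocal standardization are resampled within a bounded retry
budget.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mcda import ValueScoreTable, value_scores
from .outcomes import Direction, StakeholderWeights, WeightSource

logger = logging.getLogger(__name__)


def _factor(cov: np.ndarray) -> np.ndarray:
    """Cholesky factor, with an eigen-floor repair for indefinite input."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape[0] != cov.shape[1]:
        raise ValueError(f"covariance must be square, got {cov.shape}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if not cov.any():
        return np.zeros_like(cov)
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(cov)
        floor = 1e-12 * max(vals.max(), 1.0)
        n_fixed = int((vals < floor).sum())
        logger.warning("covariance not positive definite; flooring %d "
                       "eigenvalues", n_fixed)
        vals = np.clip(vals, floor, None)
        return vecs * np.sqrt(vals)


def sample_correlated(
    mean: np.ndarray,
    covariance: np.ndarray,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw ``n`` correlated normal vectors (rows) with the given moments."""
    mean = np.asarray(mean, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    if covariance.shape != (mean.size, mean.size):
        raise ValueError(
            f"dimension mismatch: mean has {mean.size} entries but "
            f"covariance is {covariance.shape}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L = _factor(covariance)
    z = rng.standard_normal((n, mean.size))
    return mean + z @ L.T


@dataclass
class PsaConfig:
    """Monte Carlo settings and uncertainty inputs.

    Score uncertainty defaults to the performance matrix's standard
    errors with the between-arm covariance per outcome (outcomes
    independent); a full joint covariance over the stacked
    (HCPC scores, UC scores) vector may be supplied instead.  Weight
    uncertainty defaults to none (fixed weights); per-stakeholder
    standard errors (independent normals) or full covariances may be
    supplied.
    """

    n_replications: int = 10_000
    seed: int = 0
    interval_level: float = 0.95
    weight_se: Mapping[str, Mapping[str, float]] | float | None = None
    weight_covariance: Mapping[str, np.ndarray] | None = None
    score_covariance: np.ndarray | None = None
    shift: float = 1.0
    max_resample_rounds: int = 100

    def validate(self) -> None:
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        if not 0 < self.interval_level < 1:
            raise ValueError("interval_level must be in (0, 1)")


@dataclass
class PsaResult:
    """Replication summaries of the overall value scores."""

    summary: pd.DataFrame          # (stakeholder, arm) x mean/lower/upper
    pct_hcpc_better: pd.Series     # stakeholder -> % replications HCPC > UC
    intervals_overlap: pd.Series   # stakeholder -> bool
    n_replications: int
    n_weight_truncated: int = 0
    n_score_resampled: int = 0
    deterministic: ValueScoreTable | None = None


def _score_moments(perf: pd.DataFrame,
                   override: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Stacked mean vector (HCPC block then UC block) and joint covariance."""
    k = len(perf)
    mean = np.concatenate([perf["mean_hcpc"].to_numpy(dtype=float),
                           perf["mean_uc"].to_numpy(dtype=float)])
    if override is not None:
        cov = np.asarray(override, dtype=float)
        if cov.shape != (2 * k, 2 * k):
            raise ValueError(f"score_covariance must be {2*k}x{2*k}")
        return mean, cov
    cov = np.zeros((2 * k, 2 * k))
    se_h = perf.get("se_hcpc", pd.Series(0.0, index=perf.index))
    se_u = perf.get("se_uc", pd.Series(0.0, index=perf.index))
    c_hu = perf.get("covariance", pd.Series(0.0, index=perf.index))
    for i in range(k):
        cov[i, i] = float(se_h.iloc[i]) ** 2
        cov[k + i, k + i] = float(se_u.iloc[i]) ** 2
        cov[i, k + i] = cov[k + i, i] = float(c_hu.iloc[i])
    return mean, cov


def _draw_scores(perf: pd.DataFrame, config: PsaConfig,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int]:
    """Score draws (n, k) per arm, resampling non-positive rows."""
    k = len(perf)
    n = config.n_replications
    mean, cov = _score_moments(perf, config.score_covariance)
    draws = sample_correlated(mean, cov, n, rng)
    degenerate = not cov.any()
    n_resampled = 0
    if not degenerate:
        # ratio standardization needs strictly positive raw scores
        bad = (draws <= 0).any(axis=1)
        rounds = 0
        n_resampled = int(bad.sum())
        while bad.any():
            rounds += 1
            if rounds > config.max_resample_rounds:
                raise RuntimeError(
                    f"{int(bad.sum())} of {n} replications still have "
                    "non-positive score draws after "
                    f"{config.max_resample_rounds} resampling rounds; "
                    "check the performance means/SEs")
            draws[bad] = sample_correlated(mean, cov, int(bad.sum()), rng)
            bad = (draws <= 0).any(axis=1)
    elif (mean <= 0).any():
        raise ValueError("non-positive performance means with zero "
                         "uncertainty cannot be standardized")
    if n_resampled:
        logger.warning("resampled %d replications with non-positive score "
                       "draws", n_resampled)
    return draws[:, :k], draws[:, k:], n_resampled


def _draw_weights(ws: StakeholderWeights, config: PsaConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Weight draws (n, k); negatives truncated at zero."""
    label = ws.label or ws.stakeholder.value
    mean = np.array([ws.weights[o] for o in ws.outcome_names], dtype=float)
    k = mean.size
    cov = None
    if config.weight_covariance and label in config.weight_covariance:
        cov = np.asarray(config.weight_covariance[label], dtype=float)
    elif isinstance(config.weight_se, Mapping) and label in config.weight_se:
        se = np.array([config.weight_se[label].get(o, 0.0)
                       for o in ws.outcome_names])
        cov = np.diag(se ** 2)
    elif isinstance(config.weight_se, (int, float)) and config.weight_se:
        cov = np.eye(k) * float(config.weight_se) ** 2
    if cov is None or not cov.any():
        return np.tile(mean, (config.n_replications, 1)), 0
    draws = sample_correlated(mean, cov, config.n_replications, rng)
    n_trunc = int((draws < 0).sum())
    if n_trunc:
        logger.warning("truncated %d negative weight draws to 0 for %s",
                       n_trunc, label)
        draws = np.clip(draws, 0.0, None)
    return draws, n_trunc


def run_psa(
    perf: pd.DataFrame,
    weight_sets: Sequence[StakeholderWeights] | Mapping[object, StakeholderWeights],
    config: PsaConfig | None = None,
) -> PsaResult:
    """Monte Carlo uncertainty analysis of the overall value scores.

    ``perf`` is the performance matrix (index = outcome; columns
    ``mean_hcpc``, ``se_hcpc``, ``mean_uc``, ``se_uc``, ``covariance``,
    ``direction``).  With all covariances zero the replication means
    reproduce the deterministic value scores exactly.
    """
    config = config or PsaConfig()
    config.validate()
    if isinstance(weight_sets, Mapping):
        weight_sets = list(weight_sets.values())
    rng = np.random.default_rng(config.seed)

    deterministic = value_scores(perf, weight_sets, shift=config.shift)

    x_h, x_u, n_resampled = _draw_scores(perf, config, rng)
    reverse = np.array([Direction(d) is Direction.HIGHER_WORSE
                        for d in perf["direction"]])
    # shift both arms where a draw dips <= 0 only in the degenerate path;
    # stochastic draws were resampled to positivity above
    xr_h = np.where(reverse, 1.0 / x_h, x_h)
    xr_u = np.where(reverse, 1.0 / x_u, x_u)
    norm = np.sqrt(xr_h ** 2 + xr_u ** 2)
    S_h, S_u = xr_h / norm, xr_u / norm       # (n, k)

    alpha = (1.0 - config.interval_level) / 2.0
    rows, pct, overlap = [], {}, {}
    n_wtrunc = 0
    outcome_order = list(perf.index)
    for ws in weight_sets:
        label = ws.label or ws.stakeholder.value
        missing = [o for o in ws.outcome_names if o not in outcome_order]
        if missing:
            raise KeyError(f"weights for {label!r} name outcomes absent from "
                           f"the performance matrix: {missing}")
        w, nt = _draw_weights(ws, config, rng)
        n_wtrunc += nt
        cols = [outcome_order.index(o) for o in ws.outcome_names]
        v_h = (w * S_h[:, cols]).sum(axis=1)
        v_u = (w * S_u[:, cols]).sum(axis=1)
        bounds = {}
        for arm, v in (("HCPC", v_h), ("UC", v_u)):
            if (v == v[0]).all():      # degenerate: intervals collapse exactly
                m = lo = hi = float(v[0])
            else:
                m = float(v.mean())
                lo, hi = (float(q) for q in
                          np.quantile(v, [alpha, 1.0 - alpha]))
            bounds[arm] = (lo, hi)
            rows.append({"stakeholder": label, "arm": arm,
                         "mean": m, "lower": lo, "upper": hi})
        pct[label] = 100.0 * float((v_h > v_u).mean())
        (lo_h, hi_h), (lo_u, hi_u) = bounds["HCPC"], bounds["UC"]
        overlap[label] = bool(lo_h <= hi_u and lo_u <= hi_h)

    summary = pd.DataFrame(rows).set_index(["stakeholder", "arm"])
    return PsaResult(
        summary=summary,
        pct_hcpc_better=pd.Series(pct, name="pct_hcpc_better"),
        intervals_overlap=pd.Series(overlap, name="intervals_overlap"),
        n_replications=config.n_replications,
        n_weight_truncated=n_wtrunc,
        n_score_resampled=n_resampled,
        deterministic=deterministic,
    )


def swing_sensitivity(
    perf: pd.DataFrame,
    swing_weight_sets: Sequence[StakeholderWeights] | Mapping[object, StakeholderWeights],
    shift: float = 1.0,
) -> ValueScoreTable:
    """Deterministic re-analysis under swing weights.

    Swing weights may cover the extended outcome set (core plus
    programme-specific outcomes such as autonomy, medication burden and
    informal-care costs); every weighted outcome must have a performance
    row, otherwise a ``KeyError`` lists what is missing.
    """
    if isinstance(swing_weight_sets, Mapping):
        swing_weight_sets = list(swing_weight_sets.values())
    for ws in swing_weight_sets:
        if ws.source is not WeightSource.SWING:
            logger.warning("weight set %s is not marked as swing-derived",
                           ws.label or ws.stakeholder.value)
    table = value_scores(perf, swing_weight_sets, shift=shift)
    table.metadata["analysis"] = "swing-weight sensitivity"
    return table
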