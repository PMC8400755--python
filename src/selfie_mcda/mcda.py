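"""Relative standardization and stakeholder-weighted overall value scores.

A pair of arm-level performance scores (x_a, x_b) on an outcome's natural
scale is standardized to the unit circle:

.. math::

    S_a = \\frac{x_a}{\\sqrt{x_a^2 + x_b^2}}, \\qquad
    S_b = \\frac{x_b}{\\sqrt{x_a^2 + x_b^2}}

so that :math:`S_a^2 + S_b^2 = 1`, each score lies in (0, 1], and the
ratio of the raw scores is preserved.  For reverse-coded outcomes (higher
raw score = worse performance, e.g. ADL dependence or costs) the raw
values are replaced by their reciprocals first, so a higher standardized
score always means better performance.

The overall value score of an arm for a stakeholder group is the
weighted sum of its standardized scores under that group's importance
weights (additive value model); weights are applied exactly as given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .outcomes import Direction, StakeholderWeights

logger = logging.getLogger(__name__)


def standardize_pair(
    x_a: float,
    x_b: float,
    direction: Direction = Direction.HIGHER_BETTER,
    shift: float = 1.0,
    outcome: str = "",
) -> tuple[float, float]:
    """Relative standardization of one outcome's two arm scores.

    For reverse-coded outcomes the reciprocal transform requires strictly
    positive inputs; non-positive raw values (possible for scales
    anchored at zero) are shifted by ``shift`` in both arms first — a
    loudly-logged fallback that preserves the ordering.

    Returns ``(S_a, S_b)`` with ``S_a**2 + S_b**2 == 1``.
    """
    if not (math.isfinite(x_a) and math.isfinite(x_b)):
        raise ValueError(f"non-finite performance scores for {outcome or 'outcome'}")
    if min(x_a, x_b) <= 0.0:
        if shift <= 0 or min(x_a, x_b) + shift <= 0.0:
            raise ValueError(
                f"non-positive performance score for {outcome or 'outcome'} "
                f"({x_a}, {x_b}): reciprocal/ratio standardization undefined; "
                "supply a positive shift")
        logger.warning(
            "non-positive performance score for %s (%g, %g): shifting both "
            "arms by +%g before standardization", outcome or "outcome",
            x_a, x_b, shift)
        x_a, x_b = x_a + shift, x_b + shift
    if direction is Direction.HIGHER_WORSE:
        x_a, x_b = 1.0 / x_a, 1.0 / x_b
    # same operation order as the vectorized Monte Carlo path, so a
    # zero-uncertainty sensitivity analysis reproduces this bit-for-bit
    norm = math.sqrt(x_a ** 2 + x_b ** 2)
    return x_a / norm, x_b / norm


@dataclass
class ValueScoreTable:
    """Standardized scores, weighted cells and overall values.

    ``standardized`` has one row per outcome with columns S_hcpc / S_uc;
    ``weighted_cells`` is outcome x (stakeholder, arm); ``overall`` is
    stakeholder x arm.
    """

    standardized: pd.DataFrame
    weighted_cells: pd.DataFrame
    overall: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def round(self, ndigits: int = 3) -> "ValueScoreTable":
        """Report-ready copy rounded half-to-even (as tables print)."""
        return ValueScoreTable(self.standardized.round(ndigits),
                               self.weighted_cells.round(ndigits),
                               self.overall.round(ndigits),
                               dict(self.metadata))


def standardize_performance(
    perf: pd.DataFrame, shift: float = 1.0,
) -> pd.DataFrame:
    """Standardize every row of a performance matrix.

    ``perf`` is indexed by outcome with columns ``mean_hcpc``,
    ``mean_uc`` and ``direction``.
    """
    rows = {}
    for outcome, row in perf.iterrows():
        s_h, s_u = standardize_pair(
            float(row["mean_hcpc"]), float(row["mean_uc"]),
            Direction(row["direction"]), shift=shift, outcome=str(outcome))
        rows[outcome] = {"S_hcpc": s_h, "S_uc": s_u}
    return pd.DataFrame.from_dict(rows, orient="index")


def value_scores(
    perf: pd.DataFrame,
    weight_sets: Sequence[StakeholderWeights] | Mapping[object, StakeholderWeights],
    shift: float = 1.0,
) -> ValueScoreTable:
    """Overall value score per stakeholder and arm (additive model).

    Every outcome named in a stakeholder's weight vector must be present
    in the performance matrix.
    """
    if isinstance(weight_sets, Mapping):
        weight_sets = list(weight_sets.values())
    std = standardize_performance(perf, shift=shift)
    table = value_scores_from_standardized(std, weight_sets)
    table.metadata["shift"] = shift
    return table


def value_scores_from_standardized(
    std: pd.DataFrame,
    weight_sets: Sequence[StakeholderWeights] | Mapping[object, StakeholderWeights],
) -> ValueScoreTable:
    """Aggregate already-standardized scores into overall values.

    ``std`` is indexed by outcome with columns ``S_hcpc`` and ``S_uc``
    (e.g. standardized scores taken from a published value table);
    weights are applied exactly as given.
    """
    if isinstance(weight_sets, Mapping):
        weight_sets = list(weight_sets.values())

    cells: dict[tuple[str, str], pd.Series] = {}
    overall_rows = {}
    for ws in weight_sets:
        missing = [o for o in ws.outcome_names if o not in std.index]
        if missing:
            raise KeyError(
                f"weights for {ws.stakeholder.value!r} name outcomes absent "
                f"from the performance matrix: {missing}")
        label = ws.label or ws.stakeholder.value
        w = pd.Series(dict(ws.weights))
        for arm, col in (("HCPC", "S_hcpc"), ("UC", "S_uc")):
            weighted = w * std.loc[w.index, col]
            cells[(label, arm)] = weighted
            overall_rows.setdefault(label, {})[arm] = float(weighted.sum())

    weighted_cells = pd.DataFrame(cells)
    weighted_cells.columns = pd.MultiIndex.from_tuples(
        weighted_cells.columns, names=["stakeholder", "arm"])
    overall = pd.DataFrame.from_dict(overall_rows, orient="index")
    overall.index.name = "stakeholder"
    sources = {ws.source.value for ws in weight_sets}
    return ValueScoreTable(
        std, weighted_cells, overall,
        metadata={"standardization": "relative (ratio-preserving, 1/x for "
                                     "reverse-coded outcomes)",
                  "weight_source": sorted(sources)})
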