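"""Cohort data model: ingestion, validation, imputation and cohort rules.

The study design is a two-arm longitudinal cohort — an integrated-care
programme arm (HCPC) versus usual care (UC) — observed at baseline (T0)
and at 6-month follow-up (T1).  A cohort table is long over patient x time
with a wide block of outcome columns (one per instrument, see
:mod:`selfie_mcda.outcomes`) and a wide block of 3-month resource-use
counts.

Cohort rules applied before analysis:

* patients who responded at follow-up only, with no baseline record, are
  excluded;
* sporadic missing outcome values are mean-imputed within arm x time x
  outcome strata (missing covariates stay as explicit ``missing``
  categories and are never imputed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .outcomes import ALL_OUTCOMES, OutcomeSpec, outcome_registry

ARMS = ("HCPC", "UC")
TIMES = ("T0", "T1")

#: fixed identifier/covariate columns, in file order
STANDARD_COLUMNS = (
    "patient_id", "arm", "time", "age_years", "sex", "living_condition",
    "smoking", "multimorbid", "education",
)

CATEGORICAL_COVARIATES = ("sex", "living_condition", "smoking", "education")
MISSING_CATEGORY = "missing"


@dataclass(frozen=True)
class ValidationFinding:
    """One problem detected in a cohort table."""

    kind: str            # e.g. "range_violation", "duplicate_key"
    message: str
    patient_id: str | None = None
    column: str | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.message}"


@dataclass
class CohortTable:
    """Long-format patient x time cohort with outcome metadata.

    ``data`` holds one row per (patient_id, time); outcome columns are
    named after their :class:`OutcomeSpec`; any remaining columns are
    3-month resource-use counts.
    """

    data: pd.DataFrame
    outcome_specs: dict[str, OutcomeSpec] = field(
        default_factory=lambda: outcome_registry(ALL_OUTCOMES))

    @property
    def outcome_columns(self) -> list[str]:
        return [c for c in self.data.columns if c in self.outcome_specs]

    @property
    def resource_columns(self) -> list[str]:
        known = set(STANDARD_COLUMNS) | set(self.outcome_specs)
        return [c for c in self.data.columns if c not in known]

    @property
    def patients(self) -> pd.Index:
        return pd.Index(self.data["patient_id"].unique())

    def baseline(self) -> pd.DataFrame:
        return self.data[self.data["time"] == "T0"]

    def followup(self) -> pd.DataFrame:
        return self.data[self.data["time"] == "T1"]

    def arm_of(self) -> pd.Series:
        """patient_id -> arm (constant per patient)."""
        return self.data.groupby("patient_id")["arm"].first()

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), dict(self.outcome_specs))


def read_cohort_csv(
    path: str | Path,
    outcome_specs: Iterable[OutcomeSpec] = ALL_OUTCOMES,
) -> CohortTable:
    """Read a cohort from delimited text (comma-separated, header row).

    Empty fields are missing values.  Covariate missingness is recoded to
    the explicit ``missing`` category; outcome/resource missingness stays
    ``NaN`` for downstream imputation or zero-costing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise IOError(f"cannot read cohort file {path}: {exc}") from exc
    for col in CATEGORICAL_COVARIATES:
        if col in df.columns:
            df[col] = df[col].fillna(MISSING_CATEGORY).astype(str)
    return CohortTable(df, outcome_registry(tuple(outcome_specs)))


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def validate_cohort(table: CohortTable) -> list[ValidationFinding]:
    """Check a cohort table against the schema invariants.

    Returns an empty list iff the table is well-formed: required columns
    present, valid arm/time codes, unique (patient, time) keys, outcome
    values inside their instrument ranges, both arms populated, and no
    follow-up-only patients (those must be removed by
    :func:`apply_cohort_rules` before analysis).
    """
    findings: list[ValidationFinding] = []
    df = table.data

    missing_cols = [c for c in ("patient_id", "arm", "time", "age_years")
                    if c not in df.columns]
    if missing_cols:
        findings.append(ValidationFinding(
            "missing_column", f"required columns absent: {missing_cols}"))
        return findings

    bad_arm = sorted(set(df["arm"].dropna()) - set(ARMS))
    if bad_arm:
        findings.append(ValidationFinding(
            "invalid_arm", f"unknown arm codes {bad_arm}; expected {ARMS}"))
    bad_time = sorted(set(df["time"].dropna()) - set(TIMES))
    if bad_time:
        findings.append(ValidationFinding(
            "invalid_time", f"unknown time codes {bad_time}; expected {TIMES}"))

    dup = df.duplicated(subset=["patient_id", "time"], keep=False)
    for (pid, t), _ in df[dup].groupby(["patient_id", "time"]):
        findings.append(ValidationFinding(
            "duplicate_key", f"patient {pid} has multiple {t} records",
            patient_id=str(pid)))

    arms_per_patient = df.groupby("patient_id")["arm"].nunique()
    for pid in arms_per_patient[arms_per_patient > 1].index:
        findings.append(ValidationFinding(
            "inconsistent_arm", f"patient {pid} appears in more than one arm",
            patient_id=str(pid)))

    for name in table.outcome_columns:
        spec = table.outcome_specs[name]
        vals = pd.to_numeric(df[name], errors="coerce")
        out = df[(vals.notna())
                 & ((vals < spec.scale_min) | (vals > spec.scale_max))]
        for _, row in out.iterrows():
            findings.append(ValidationFinding(
                "range_violation",
                f"{name}={row[name]} outside [{spec.scale_min}, "
                f"{spec.scale_max}] ({spec.instrument}) for patient "
                f"{row['patient_id']} at {row['time']}",
                patient_id=str(row["patient_id"]), column=name))

    present_arms = set(df["arm"].dropna()) & set(ARMS)
    if len(present_arms) < 2:
        findings.append(ValidationFinding(
            "single_arm", f"cohort contains only arms {sorted(present_arms)}"))

    has_t0 = set(df.loc[df["time"] == "T0", "patient_id"])
    t1_only = sorted(set(df.loc[df["time"] == "T1", "patient_id"]) - has_t0)
    for pid in t1_only:
        findings.append(ValidationFinding(
            "followup_only",
            f"patient {pid} has a T1 record but no T0 record "
            "(remove via apply_cohort_rules)", patient_id=str(pid)))

    return findings


@dataclass(frozen=True)
class ImputationEntry:
    outcome: str
    arm: str
    time: str
    n_imputed: int
    imputed_value: float


def impute_outcomes_by_group(
    table: CohortTable,
    outcomes: Sequence[str] | None = None,
) -> tuple[CohortTable, list[ImputationEntry]]:
    """Mean-impute missing outcome values within arm x time strata.

    Each missing outcome value is replaced by the mean of the non-missing
    values of that outcome in the same arm and wave, which leaves every
    stratum mean unchanged.  Returns the imputed table and a log of what
    was filled where.

    Raises
    ------
    ValueError
        If a stratum that needs imputing has no observed value at all.
    """
    out = table.copy()
    df = out.data
    log: list[ImputationEntry] = []
    names = list(outcomes) if outcomes is not None else table.outcome_columns
    for name in names:
        for (arm, time), idx in df.groupby(["arm", "time"]).groups.items():
            block = df.loc[idx, name]
            n_missing = int(block.isna().sum())
            if n_missing == 0:
                continue
            observed = block.dropna()
            if observed.empty:
                raise ValueError(
                    f"cannot impute {name!r} in stratum arm={arm}, "
                    f"time={time}: all values missing")
            fill = float(observed.mean())
            df.loc[idx, name] = block.fillna(fill)
            log.append(ImputationEntry(name, str(arm), str(time),
                                       n_missing, fill))
    return out, log


def apply_cohort_rules(table: CohortTable) -> tuple[CohortTable, list[str]]:
    """Drop patients with a follow-up record but no baseline record.

    Follow-up-only respondents cannot contribute to a change estimate
    anchored at baseline, so they are excluded before any modelling.
    Returns the filtered table and the removed patient ids.  Idempotent.
    """
    df = table.data
    has_t0 = set(df.loc[df["time"] == "T0", "patient_id"])
    keep = df["patient_id"].isin(has_t0)
    removed = sorted(set(df.loc[~keep, "patient_id"].astype(str)))
    out = dataclasses.replace(table, data=df[keep].reset_index(drop=True))
    return out, removed
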