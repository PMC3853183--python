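"""Delimited-text readers/writers and cohort validation.

All tables are comma-separated UTF-8 with a header row and ``.`` as decimal
separator. Numeric values are stored at full precision; rounding happens only
in report rendering.

Schemas
-------
patients.csv   : patient_id,age,sex,phc_id,bct_id,acg_code,n_visits,n_episodes,cost
units.csv      : level,id,assigned_population,parent_phc
indicators.csv : unit_id,indicator_id,eligible,compliant,observed_cost
reference.csv  : acg_code,n_patients,mean_visits,mean_episodes,mean_cost
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import CohortValidationError, SchemaError, StructuralError

logger = logging.getLogger(__name__)

__all__ = [
    "PATIENT_COLUMNS", "UNIT_COLUMNS", "INDICATOR_COLUMNS", "REFERENCE_COLUMNS",
    "read_patients", "read_units", "read_indicators", "read_reference_table",
    "write_table", "validate_patients", "validate_cohort", "CohortReport",
]

PATIENT_COLUMNS = ["patient_id", "age", "sex", "phc_id", "bct_id",
                   "acg_code", "n_visits", "n_episodes", "cost"]
UNIT_COLUMNS = ["level", "id", "assigned_population", "parent_phc"]
INDICATOR_COLUMNS = ["unit_id", "indicator_id", "eligible", "compliant", "observed_cost"]
REFERENCE_COLUMNS = ["acg_code", "n_patients", "mean_visits", "mean_episodes", "mean_cost"]

_PATIENT_DTYPES = {"patient_id": str, "sex": str, "phc_id": str,
                   "bct_id": str, "acg_code": str}
_SEXES = {"female", "male"}


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s): {', '.join(missing)}")


def validate_patients(patients: pd.DataFrame) -> None:
    """Enforce per-row and structural invariants of a patient table.

    An attended patient has at least one visit and one episode (a visit records
    at least one diagnosis), is older than 14, has a valid sex label and a
    non-negative cost, and each basic care team (BCT) is nested within exactly
    one primary health care centre (PHC).
    """
    _require_columns(patients, PATIENT_COLUMNS, "patients")

    def rows(mask) -> str:
        idx = patients.index[mask][:10].tolist()
        return ", ".join(str(i) for i in idx)

    checks = [
        (patients["age"] <= 14, "age must be > 14"),
        (~patients["sex"].isin(_SEXES), "sex must be 'female' or 'male'"),
        (patients["n_visits"] < 1, "attended patient must have n_visits >= 1"),
        (patients["n_episodes"] < 1, "attended patient must have n_episodes >= 1"),
        (patients["cost"] < 0, "cost must be non-negative"),
    ]
    problems = []
    for mask, msg in checks:
        if mask.any():
            problems.append(f"{msg} (rows: {rows(mask)})")
    if problems:
        raise CohortValidationError("; ".join(problems))

    nesting = patients.groupby("bct_id")["phc_id"].nunique()
    bad = nesting[nesting > 1]
    if not bad.empty:
        raise StructuralError(
            "BCT(s) mapped to more than one PHC: " + ", ".join(bad.index[:10])
        )


def read_patients(path) -> pd.DataFrame:
    """Read and validate a patient-level table (one row per attended patient)."""
    df = pd.read_csv(path, dtype=_PATIENT_DTYPES)
    _require_columns(df, PATIENT_COLUMNS, "patients")
    df = df[PATIENT_COLUMNS]
    validate_patients(df)
    logger.info("read %d patient records from %s", len(df), path)
    return df


def read_units(path) -> pd.DataFrame:
    """Read a unit metadata table (PHC and BCT rows with assigned populations)."""
    df = pd.read_csv(path, dtype={"level": str, "id": str, "parent_phc": str})
    _require_columns(df, UNIT_COLUMNS[:3], "units")
    if "parent_phc" not in df.columns:
        df["parent_phc"] = pd.NA
    bad_level = ~df["level"].isin({"PHC", "BCT"})
    if bad_level.any():
        raise CohortValidationError(
            f"units: level must be 'PHC' or 'BCT' (rows: {df.index[bad_level][:10].tolist()})"
        )
    if (df["assigned_population"] <= 0).any():
        raise CohortValidationError("units: assigned_population must be positive")
    phcs = set(df.loc[df["level"] == "PHC", "id"])
    bct = df["level"] == "BCT"
    orphan = bct & ~df["parent_phc"].isin(phcs)
    if orphan.any():
        raise StructuralError(
            "units: BCT rows with unknown parent_phc: "
            + ", ".join(df.loc[orphan, "id"][:10])
        )
    return df[UNIT_COLUMNS]


def read_indicators(path) -> pd.DataFrame:
    """Read per-unit quality-indicator observations.

    Proportion indicators carry ``eligible``/``compliant`` counts; cost-per-DDD
    indicators carry ``observed_cost``. The unused fields are left missing.
    """
    df = pd.read_csv(path, dtype={"unit_id": str})
    _require_columns(df, INDICATOR_COLUMNS[:2], "indicators")
    for col in ("eligible", "compliant"):
        if col not in df.columns:
            df[col] = pd.NA
        df[col] = df[col].astype("Int64")
    if "observed_cost" not in df.columns:
        df["observed_cost"] = pd.NA
    both = df["eligible"].notna() & df["compliant"].notna()
    bad = both & (df["compliant"] > df["eligible"])
    if bad.any():
        raise CohortValidationError(
            f"indicators: compliant > eligible (rows: {df.index[bad][:10].tolist()})"
        )
    return df[INDICATOR_COLUMNS]


def read_reference_table(path) -> pd.DataFrame:
    """Read an external per-ACG reference profile table."""
    df = pd.read_csv(path, dtype={"acg_code": str})
    _require_columns(df, REFERENCE_COLUMNS, "reference")
    return df[REFERENCE_COLUMNS]


def write_table(rows: pd.DataFrame, path) -> None:
    """Write a tabular result as CSV with header, full float precision.

    Raises
    ------
    ValueError
        if ``rows`` is empty — silently writing an empty report hides
        upstream failures.
    """
    if rows is None or len(rows) == 0:
        raise ValueError(f"refusing to write empty table to {path}")
    rows.to_csv(path, index=False)


@dataclass
class CohortReport:
    """Result of :func:`validate_cohort` (inputs are never mutated)."""

    patients_per_unit: dict[str, int] = field(default_factory=dict)
    acg_codes: list[str] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_cohort(patients: pd.DataFrame, units: pd.DataFrame | None = None) -> CohortReport:
    """Cross-check a cohort against its unit metadata.

    Reports attended counts per unit, the observed ACG codes, and any
    invariant violations (row-level problems, attended counts exceeding the
    assigned population). Exclusion rules (out-of-region, transfers,
    orthodontics-only patients) are assumed applied upstream; only unit/ACG
    consistency is checked here.

    Raises
    ------
    StructuralError
        if a BCT is nested in more than one PHC.
    """
    report = CohortReport()

    nesting = patients.groupby("bct_id")["phc_id"].nunique()
    bad = nesting[nesting > 1]
    if not bad.empty:
        raise StructuralError(
            "BCT(s) mapped to more than one PHC: " + ", ".join(bad.index[:10])
        )

    try:
        validate_patients(patients)
    except CohortValidationError as exc:
        report.violations.append(str(exc))

    counts_phc = patients["phc_id"].value_counts().to_dict()
    counts_bct = patients["bct_id"].value_counts().to_dict()
    report.patients_per_unit = {**counts_phc, **counts_bct}
    report.acg_codes = sorted(patients["acg_code"].unique())

    if units is not None:
        for _, row in units.iterrows():
            attended = (counts_phc if row["level"] == "PHC" else counts_bct).get(row["id"], 0)
            if attended > row["assigned_population"]:
                report.violations.append(
                    f"unit {row['id']}: attended count {attended} exceeds "
                    f"assigned population {row['assigned_population']}"
                )
    return report
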