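"""Indirect standardization of provider utilization: the core computation.

Each attended patient carries an ACG morbidity category and a year's visits,
care episodes and direct cost. For a care unit (primary health care centre,
PHC, or basic care team, BCT) the *expected* mean of a quantity is obtained
by indirect standardization: the unit's patient count in each ACG is
multiplied by the reference population's per-ACG mean of that quantity, the
products are summed and divided by the unit's attended count. From these:

* efficiency index (EI), one per quantity:  ``EI = observed mean / expected
  mean``. EI < 1 means the unit used fewer resources than its case mix
  predicts (greater efficiency); EI is blind to case-mix differences by
  construction.
* risk index (RI): ``RI = expected mean visits / reference pooled mean
  visits``. RI > 1 means a more complex (higher morbidity burden) case mix;
  RI is blind to the unit's own utilization behaviour.

When the reference profile is built from the analyzed cohort itself, expected
totals conserve observed totals, so the pooled EIs and the attended-weighted
mean RI are identically 1 — a useful internal check that is asserted by the
model fit (and skipped for external references, where it need not hold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import round_half_away
from .catalog import AcgCatalogEntry, default_acg_catalog
from .exceptions import (
    CohortValidationError,
    MissingAcgError,
    UndefinedIndexError,
)
from .io import read_patients, read_reference_table, read_units

__all__ = [
    "QUANTITIES", "ReferenceProfile", "build_reference_profile",
    "expected_means", "efficiency_index", "risk_index", "coverage_ratio",
    "unit_index_table", "descriptive_summary", "acg_distribution_table",
    "AcgDistribution", "CaseMixProfile", "CaseMixProfileResults",
]

#: quantities subjected to indirect standardization, with their patient columns
QUANTITIES = {"visits": "n_visits", "episodes": "n_episodes", "cost": "cost"}

_LEVEL_COLUMN = {"phc": "phc_id", "bct": "bct_id"}


class ReferenceProfile:
    """Per-ACG reference means of visits, episodes and cost, plus pooled totals.

    Parameters
    ----------
    table : DataFrame
        One row per ACG code with columns ``acg_code``, ``n_patients``,
        ``mean_visits``, ``mean_episodes``, ``mean_cost``.
    """

    def __init__(self, table: pd.DataFrame):
        table = table.copy()
        required = {"acg_code", "n_patients", "mean_visits", "mean_episodes", "mean_cost"}
        missing = required - set(table.columns)
        if missing:
            raise CohortValidationError(f"reference profile missing columns: {missing}")
        if table["acg_code"].duplicated().any():
            raise CohortValidationError("reference profile has duplicated ACG codes")
        if (table[["mean_visits", "mean_episodes", "mean_cost"]] < 0).any().any():
            raise CohortValidationError("reference means must be non-negative")
        self.table = table.set_index("acg_code")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_cohort(cls, patients: pd.DataFrame) -> "ReferenceProfile":
        """Pool the analyzed cohort itself into a reference profile."""
        if len(patients) == 0:
            raise CohortValidationError("cannot build a reference profile from an empty cohort")
        g = patients.groupby("acg_code")
        table = pd.DataFrame({
            "n_patients": g.size(),
            "mean_visits": g["n_visits"].mean(),
            "mean_episodes": g["n_episodes"].mean(),
            "mean_cost": g["cost"].mean(),
        }).reset_index()
        return cls(table)

    @classmethod
    def from_catalog(cls, catalog: list[AcgCatalogEntry] | None = None) -> "ReferenceProfile":
        """Use the ACG catalog's own per-category means as the reference."""
        catalog = default_acg_catalog() if catalog is None else catalog
        table = pd.DataFrame({
            "acg_code": [e.acg_code for e in catalog],
            "n_patients": [e.n_patients for e in catalog],
            "mean_visits": [e.visits_mean for e in catalog],
            "mean_episodes": [e.episodes_mean for e in catalog],
            "mean_cost": [e.cost_mean for e in catalog],
        })
        return cls(table)

    @classmethod
    def from_csv(cls, path) -> "ReferenceProfile":
        return cls(read_reference_table(path))

    # -- pooled moments ---------------------------------------------------
    @property
    def n_total(self) -> int:
        return int(self.table["n_patients"].sum())

    def pooled_mean(self, quantity: str) -> float:
        """n-weighted average of the per-ACG means (= pooled cohort mean)."""
        w = self.table["n_patients"].to_numpy(dtype=float)
        m = self.table[f"mean_{quantity}"].to_numpy(dtype=float)
        return float(np.average(m, weights=w))

    def to_frame(self) -> pd.DataFrame:
        return self.table.reset_index()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<ReferenceProfile: {len(self.table)} ACG categories, "
                f"N={self.n_total}, mean visits {self.pooled_mean('visits'):.2f}>")


def build_reference_profile(patients: pd.DataFrame) -> ReferenceProfile:
    """Per-ACG arithmetic means over the pooled cohort (all centres)."""
    return ReferenceProfile.from_cohort(patients)


def _check_codes(patients: pd.DataFrame, reference: ReferenceProfile) -> None:
    missing = set(patients["acg_code"].unique()) - set(reference.table.index)
    if missing:
        raise MissingAcgError(missing)


def expected_means(unit_patients: pd.DataFrame, reference: ReferenceProfile) -> dict[str, float]:
    """Indirectly standardized expected means for one unit.

    ``expected total = sum over ACG (unit count in ACG x reference per-ACG
    mean)``; the expected mean divides by the unit's attended count. Computed
    identically for visits, episodes and cost.

    Raises
    ------
    MissingAcgError
        if the unit contains ACG codes absent from the reference (no silent
        fallback).
    """
    if len(unit_patients) == 0:
        raise CohortValidationError("expected_means: empty unit")
    _check_codes(unit_patients, reference)
    counts = unit_patients["acg_code"].value_counts()
    n = counts.sum()
    out = {}
    for quantity in QUANTITIES:
        ref = reference.table[f"mean_{quantity}"].reindex(counts.index)
        out[quantity] = float((counts * ref).sum() / n)
    return out


def efficiency_index(observed_mean: float, expected_mean: float) -> float:
    """Observed/expected ratio; < 1 indicates greater efficiency."""
    if expected_mean <= 0:
        raise UndefinedIndexError(
            f"efficiency index undefined for expected mean {expected_mean!r}")
    return float(observed_mean) / float(expected_mean)


def risk_index(expected_mean_visits: float, reference_mean_visits: float) -> float:
    """Expected visits relative to the reference pooled mean; > 1 = more complex."""
    if reference_mean_visits <= 0:
        raise UndefinedIndexError(
            f"risk index undefined for reference mean {reference_mean_visits!r}")
    return float(expected_mean_visits) / float(reference_mean_visits)


def coverage_ratio(n_attended: int, assigned_population: int) -> float:
    """Attended patients over assigned (catchment) population, in (0, 1]."""
    if n_attended <= 0:
        raise CohortValidationError("coverage undefined: no attended patients")
    if assigned_population < n_attended:
        raise CohortValidationError(
            f"assigned population {assigned_population} below attended count {n_attended}")
    return n_attended / assigned_population


def unit_index_table(
    patients: pd.DataFrame,
    units: pd.DataFrame | None = None,
    reference: ReferenceProfile | None = None,
    level: str = "phc",
) -> pd.DataFrame:
    """Observed/expected means, the three EIs, RI and coverage per unit.

    The same code path serves both aggregation levels; ``level`` selects the
    PHC or BCT identifier column. Coverage requires ``units`` metadata and is
    missing otherwise.
    """
    if level not in _LEVEL_COLUMN:
        raise ValueError(f"level must be one of {sorted(_LEVEL_COLUMN)}, got {level!r}")
    if len(patients) == 0:
        raise CohortValidationError("unit_index_table: empty cohort")
    if reference is None:
        reference = ReferenceProfile.from_cohort(patients)
    _check_codes(patients, reference)

    unit_col = _LEVEL_COLUMN[level]
    counts = pd.crosstab(patients[unit_col], patients["acg_code"])
    n_attended = counts.sum(axis=1)

    obs = patients.groupby(unit_col).agg(
        observed_mean_visits=("n_visits", "mean"),
        observed_mean_episodes=("n_episodes", "mean"),
        observed_mean_cost=("cost", "mean"),
    )

    out = pd.DataFrame({"unit_id": counts.index, "level": level.upper()})
    out = out.set_index("unit_id")
    out["n_attended"] = n_attended
    for quantity in QUANTITIES:
        ref = reference.table[f"mean_{quantity}"].reindex(counts.columns).to_numpy()
        expected_total = counts.to_numpy(dtype=float) @ ref
        out[f"expected_mean_{quantity}"] = expected_total / n_attended.to_numpy()
        out[f"observed_mean_{quantity}"] = obs[f"observed_mean_{quantity}"]
        ei_name = {"visits": "visits_EI", "episodes": "episodes_EI", "cost": "costs_EI"}[quantity]
        out[ei_name] = out[f"observed_mean_{quantity}"] / out[f"expected_mean_{quantity}"]
    out["RI"] = out["expected_mean_visits"] / reference.pooled_mean("visits")

    out["coverage"] = np.nan
    if units is not None:
        assigned = units.loc[units["level"] == level.upper()].set_index("id")["assigned_population"]
        for uid in out.index:
            if uid in assigned.index:
                out.loc[uid, "coverage"] = coverage_ratio(
                    int(out.loc[uid, "n_attended"]), int(assigned.loc[uid]))
    if level == "bct":
        out["phc_id"] = patients.groupby("bct_id")["phc_id"].first()
    return out.reset_index()


def descriptive_summary(patients: pd.DataFrame) -> pd.DataFrame:
    """Cohort descriptives: mean (SD), median [IQR] of utilization; composition.

    One row per statistic, with a pre-rendered ``display`` column in the
    ``mean (SD) ; median [q1-q3]`` convention of descriptive cohort tables.
    """
    if len(patients) == 0:
        raise CohortValidationError("descriptive_summary: empty cohort")
    rows = []
    n = len(patients)
    rows.append(("attended_population", n, None, None, None, None, f"{n}"))
    n65 = int((patients["age"] > 65).sum())
    rows.append(("attended_over_65", n65, 100 * n65 / n, None, None, None,
                 f"{n65} ({round_half_away(100 * n65 / n, 1):.1f})"))
    nf = int((patients["sex"] == "female").sum())
    rows.append(("attended_females", nf, 100 * nf / n, None, None, None,
                 f"{nf} ({round_half_away(100 * nf / n, 1):.1f})"))
    def _sd(x):
        s = x.std(ddof=1)
        return 0.0 if pd.isna(s) else float(s)  # single observation: no spread

    mean_age, sd_age = patients["age"].mean(), _sd(patients["age"])
    rows.append(("age_years", None, mean_age, sd_age, None, None,
                 f"{round_half_away(mean_age, 1):.1f} ({round_half_away(sd_age, 1):.1f})"))
    for quantity, col in QUANTITIES.items():
        x = patients[col]
        mean, sd = x.mean(), _sd(x)
        med = x.median()
        q1, q3 = x.quantile(0.25), x.quantile(0.75)
        disp = (f"{round_half_away(mean, 1):.1f} ({round_half_away(sd, 1):.1f}) ; "
                f"{round_half_away(med, 1):g} [{round_half_away(q1, 1):g}-{round_half_away(q3, 1):g}]")
        rows.append((f"{quantity}_per_patient", None, mean, sd, med, (q1, q3), disp))
    df = pd.DataFrame(rows, columns=["statistic", "n", "mean_or_pct", "sd",
                                     "median", "iqr", "display"])
    return df


@dataclass
class AcgDistribution:
    """Per-ACG distribution of a cohort with concentration summaries."""

    table: pd.DataFrame  # sorted by count descending
    rare_share_threshold: float
    n_rare: int  # categories below the share threshold

    def top_share(self, k: int) -> float:
        """Cumulative population share of the ``k`` most prevalent categories."""
        return float(self.table["share"].iloc[:k].sum())


def acg_distribution_table(
    patients: pd.DataFrame, rare_share_threshold: float = 0.005
) -> AcgDistribution:
    """Count, share and utilization moments per ACG, sorted by prevalence."""
    if len(patients) == 0:
        raise CohortValidationError("acg_distribution_table: empty cohort")
    g = patients.groupby("acg_code")
    n = len(patients)
    table = pd.DataFrame({
        "n": g.size(),
        "episodes_mean": g["n_episodes"].mean(),
        "episodes_sd": g["n_episodes"].std(ddof=1),
        "cost_mean": g["cost"].mean(),
        "cost_sd": g["cost"].std(ddof=1),
        "visits_mean": g["n_visits"].mean(),
        "visits_sd": g["n_visits"].std(ddof=1),
    })
    table["share"] = table["n"] / n
    table["pct"] = 100.0 * table["share"]
    table = table.sort_values("n", ascending=False)
    table["cumulative_pct"] = table["pct"].cumsum()
    n_rare = int((table["share"] < rare_share_threshold).sum())
    return AcgDistribution(table=table.reset_index(), rare_share_threshold=rare_share_threshold,
                           n_rare=n_rare)


# ---------------------------------------------------------------------------
# Model / Results API
# ---------------------------------------------------------------------------

class CaseMixProfile:
    """Case-mix standardization model for a patient-level cohort.

    Parameters
    ----------
    patients : DataFrame
        One row per attended patient (see :mod:`casemix.io` schema).
    units : DataFrame, optional
        Unit metadata with assigned populations (enables coverage).
    reference : ReferenceProfile, optional
        External reference; defaults to the pooled analyzed cohort, in which
        case conservation diagnostics apply.
    level : {'phc', 'bct'}
        Aggregation level of the fitted index table.

    Examples
    --------
    >>> model = CaseMixProfile(patients, units=units, level="phc")
    >>> res = model.fit()
    >>> res.unit_indices[["unit_id", "costs_EI", "RI"]]        # doctest: +SKIP
    """

    def __init__(self, patients, units=None, reference=None, level="phc"):
        if level not in _LEVEL_COLUMN:
            raise ValueError(f"level must be one of {sorted(_LEVEL_COLUMN)}")
        self.patients = patients
        self.units = units
        self.level = level
        self.reference = reference
        self.reference_is_internal = reference is None

    @classmethod
    def from_csv(cls, patients_path, units_path=None, reference_path=None, level="phc"):
        patients = read_patients(patients_path)
        units = read_units(units_path) if units_path else None
        reference = ReferenceProfile.from_csv(reference_path) if reference_path else None
        return cls(patients, units=units, reference=reference, level=level)

    def fit(self) -> "CaseMixProfileResults":
        reference = self.reference or ReferenceProfile.from_cohort(self.patients)
        table = unit_index_table(self.patients, self.units, reference, self.level)
        descriptives = descriptive_summary(self.patients)
        distribution = acg_distribution_table(self.patients)
        return CaseMixProfileResults(
            model=self, reference=reference, unit_indices=table,
            descriptives=descriptives, acg_distribution=distribution,
        )


@dataclass
class CaseMixProfileResults:
    """Fitted per-unit indices with descriptive and diagnostic accessors."""

    model: CaseMixProfile
    reference: ReferenceProfile
    unit_indices: pd.DataFrame
    descriptives: pd.DataFrame
    acg_distribution: AcgDistribution

    def conservation(self) -> dict[str, float]:
        """Pooled EIs and attended-weighted mean RI (all 1 for internal reference)."""
        t = self.unit_indices
        w = t["n_attended"].to_numpy(dtype=float)
        out = {}
        for quantity in QUANTITIES:
            obs = float(np.sum(w * t[f"observed_mean_{quantity}"]))
            exp = float(np.sum(w * t[f"expected_mean_{quantity}"]))
            out[f"pooled_{quantity}_EI"] = obs / exp
        out["weighted_mean_RI"] = float(np.average(t["RI"], weights=w))
        return out

    def summary(self, digits: int = 2) -> str:
        """Text report in the per-centre layout of provider-profiling tables."""
        t = self.unit_indices.set_index("unit_id")
        rows = [
            ("Expected costs/patient, EUR", "expected_mean_cost"),
            ("Observed costs/patient, EUR", "observed_mean_cost"),
            ("Cost efficiency index", "costs_EI"),
            ("Expected episodes/patient", "expected_mean_episodes"),
            ("Observed episodes/patient", "observed_mean_episodes"),
            ("Episodes efficiency index", "episodes_EI"),
            ("Expected visits/patient", "expected_mean_visits"),
            ("Observed visits/patient", "observed_mean_visits"),
            ("Visits efficiency index", "visits_EI"),
            ("Risk index", "RI"),
        ]
        width = max(len(label) for label, _ in rows)
        ids = list(t.index)
        colw = max(8, max(len(str(u)) for u in ids) + 1)
        lines = [
            f"Case-mix profile ({self.model.level.upper()} level, "
            f"{len(ids)} units, N={int(t['n_attended'].sum())})",
            "Reference: " + ("pooled analyzed cohort" if self.model.reference_is_internal
                             else "external profile"),
            "",
            " " * width + "".join(f"{str(u):>{colw}}" for u in ids),
        ]
        for label, col in rows:
            vals = "".join(
                f"{round_half_away(float(t.loc[u, col]), digits):>{colw}.{digits}f}"
                for u in ids)
            lines.append(f"{label:<{width}}" + vals)
        return "\n".join(lines)
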