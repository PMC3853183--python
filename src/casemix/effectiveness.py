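"""Composite clinical-effectiveness scoring: the synthetic index (SI).

Twenty primary-care process/outcome indicators are scored per unit on a
0-100 scale and aggregated into a single synthetic index. Fifteen are
compliance proportions where more is better (screenings, control targets,
vaccinations, generic prescribing), one is a proportion where less is better
(uptake of new drugs with limited added value), and four are average costs
per defined daily dose (DDD) of common drug classes, where lower cost
relative to a benchmark is better.

Scoring rules (a documented re-specification; the original composite's exact
construction is not public):

* proportion, higher better:  ``100 x compliant / eligible``
* proportion, lower better:   ``100 x (1 - compliant / eligible)``
* cost per DDD, lower better: ``100 x min(1, benchmark / observed)``

The SI is the weighted mean of the available (non-missing) scores with the
weights renormalized over those indicators; default weights are equal.
An indicator with no eligible patients is *missing*, not zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import CohortValidationError
from .io import read_indicators

__all__ = [
    "IndicatorDefinition", "IndicatorScore", "default_indicator_definitions",
    "definitions_frame", "read_definitions", "score_indicator", "score_table",
    "synthetic_index", "si_table", "EffectivenessIndex", "EffectivenessResults",
]

PROPORTION = "proportion"
COST_PER_DDD = "cost_per_ddd"
HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"


@dataclass(frozen=True)
class IndicatorDefinition:
    """Definition of one quality indicator."""

    indicator_id: int
    description: str
    kind: str  # proportion | cost_per_ddd
    direction: str  # higher_better | lower_better
    benchmark_cost: float | None = None  # EUR/DDD, cost_per_ddd kind only
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in (PROPORTION, COST_PER_DDD):
            raise ValueError(f"indicator {self.indicator_id}: unknown kind {self.kind!r}")
        if self.direction not in (HIGHER_BETTER, LOWER_BETTER):
            raise ValueError(f"indicator {self.indicator_id}: unknown direction {self.direction!r}")
        if self.kind == COST_PER_DDD and (self.benchmark_cost is None or self.benchmark_cost <= 0):
            raise ValueError(
                f"indicator {self.indicator_id}: cost_per_ddd needs a positive benchmark_cost")
        if self.weight <= 0:
            raise ValueError(f"indicator {self.indicator_id}: weight must be positive")


# Benchmark EUR/DDD values for the four drug-cost indicators are synthetic
# defaults of plausible magnitude; override via definitions for real analyses.
_DEFAULT_DEFS = [
    (1, "Acceptable blood pressure control (<140/90; <130/80 in diabetes)"),
    (2, "Acceptable diabetes control (HbA1c < 7%)"),
    (3, "Blood pressure screening"),
    (4, "Diabetes mellitus screening"),
    (5, "Cardiovascular risk calculated, age 35-74 with cholesterol > 200 mg/dl"),
    (6, "Alcohol consumption screening in adults"),
    (7, "Ex-smokers at one year"),
    (8, "Ischemic heart disease with adequate antiplatelet treatment"),
    (9, "Ischemic heart disease with LDL < 100 mg/dl"),
    (10, "Atrial fibrillation with anticoagulation treatment"),
    (11, "Population >74 attended, including home care"),
    (12, "Population >74 attended, including home care, with evaluation"),
    (13, "Flu vaccine administered, assigned population aged 60+"),
    (14, "COPD patients with pneumococcal vaccine"),
    (15, "Use of generic pharmaceutical specialties"),
    (16, "Use of new medications with limited added value"),
    (17, "Average cost per DDD of proton pump inhibitors", 0.40),
    (18, "Average cost per DDD of statins", 0.70),
    (19, "Average cost per DDD of ACE inhibitors / angiotensin II antagonists", 0.50),
    (20, "Average cost per DDD of SSRI and newer antidepressants", 0.90),
]


def default_indicator_definitions() -> list[IndicatorDefinition]:
    """The default 20-indicator battery.

    Indicators 1-15 are higher-better proportions, 16 is a lower-better
    proportion, and 17-20 are lower-better drug costs per DDD.
    """
    defs = []
    for row in _DEFAULT_DEFS:
        iid, desc = row[0], row[1]
        if iid <= 15:
            defs.append(IndicatorDefinition(iid, desc, PROPORTION, HIGHER_BETTER))
        elif iid == 16:
            defs.append(IndicatorDefinition(iid, desc, PROPORTION, LOWER_BETTER))
        else:
            defs.append(IndicatorDefinition(iid, desc, COST_PER_DDD, LOWER_BETTER,
                                            benchmark_cost=row[2]))
    return defs


def definitions_frame(definitions=None) -> pd.DataFrame:
    definitions = default_indicator_definitions() if definitions is None else definitions
    return pd.DataFrame([vars(d) for d in definitions])


def read_definitions(path) -> list[IndicatorDefinition]:
    """Load indicator definitions from CSV (id, description, kind, direction,
    benchmark_cost, weight)."""
    df = pd.read_csv(path)
    defs = []
    for _, r in df.iterrows():
        bench = r.get("benchmark_cost")
        defs.append(IndicatorDefinition(
            indicator_id=int(r["indicator_id"]),
            description=str(r.get("description", "")),
            kind=str(r["kind"]),
            direction=str(r["direction"]),
            benchmark_cost=None if pd.isna(bench) else float(bench),
            weight=float(r.get("weight", 1.0)),
        ))
    return defs


@dataclass
class IndicatorScore:
    """One unit's score on one indicator; ``score=None`` marks missing."""

    unit_id: str
    indicator_id: int
    score: float | None
    n_eligible: int | None = None

    @property
    def missing(self) -> bool:
        return self.score is None


def score_indicator(
    definition: IndicatorDefinition,
    eligible: int | None = None,
    compliant: int | None = None,
    observed_cost: float | None = None,
    unit_id: str = "",
) -> IndicatorScore:
    """Score a single observation against its definition (0-100 scale)."""
    if definition.kind == PROPORTION:
        if eligible is None or eligible == 0:
            return IndicatorScore(unit_id, definition.indicator_id, None, eligible)
        if compliant is None or compliant < 0 or compliant > eligible:
            raise CohortValidationError(
                f"indicator {definition.indicator_id}: compliant must be in [0, eligible]")
        frac = compliant / eligible
        score = 100.0 * frac if definition.direction == HIGHER_BETTER else 100.0 * (1.0 - frac)
        return IndicatorScore(unit_id, definition.indicator_id, score, int(eligible))
    # cost per DDD
    if observed_cost is None or (isinstance(observed_cost, float) and np.isnan(observed_cost)):
        return IndicatorScore(unit_id, definition.indicator_id, None)
    if observed_cost <= 0:
        raise CohortValidationError(
            f"indicator {definition.indicator_id}: observed_cost must be positive")
    score = 100.0 * min(1.0, definition.benchmark_cost / observed_cost)
    return IndicatorScore(unit_id, definition.indicator_id, score)


def score_table(observations: pd.DataFrame, definitions=None) -> pd.DataFrame:
    """Score every (unit, indicator) observation row; long format."""
    definitions = default_indicator_definitions() if definitions is None else definitions
    by_id = {d.indicator_id: d for d in definitions}
    records = []
    for _, r in observations.iterrows():
        d = by_id.get(int(r["indicator_id"]))
        if d is None:
            raise CohortValidationError(f"no definition for indicator {r['indicator_id']}")
        elig = None if pd.isna(r.get("eligible")) else int(r["eligible"])
        comp = None if pd.isna(r.get("compliant")) else int(r["compliant"])
        cost = None if pd.isna(r.get("observed_cost")) else float(r["observed_cost"])
        s = score_indicator(d, eligible=elig, compliant=comp, observed_cost=cost,
                            unit_id=str(r["unit_id"]))
        records.append({"unit_id": s.unit_id, "indicator_id": s.indicator_id,
                        "score": np.nan if s.score is None else s.score,
                        "n_eligible": s.n_eligible, "weight": d.weight})
    return pd.DataFrame(records)


def synthetic_index(scores, weights=None) -> tuple[float, int]:
    """Aggregate indicator scores into the SI.

    Parameters
    ----------
    scores : sequence of float (NaN/None = missing)
    weights : sequence of float, optional
        Same length as ``scores``; renormalized over available indicators.
        Defaults to equal weights.

    Returns
    -------
    (si, n_used) : the composite (0-100) and how many indicators entered it.
    """
    s = np.asarray([np.nan if v is None else v for v in scores], dtype=float)
    if weights is None:
        w = np.ones_like(s)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != s.shape:
            raise ValueError("weights must match scores in length")
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    ok = ~np.isnan(s)
    if not ok.any():
        raise CohortValidationError("synthetic index undefined: all indicator scores missing")
    si = float(np.average(s[ok], weights=w[ok]))
    return si, int(ok.sum())


def si_table(observations: pd.DataFrame, definitions=None, weights=None) -> pd.DataFrame:
    """Per-unit SI table (unit_id, SI, n_indicators_used).

    ``weights`` maps indicator_id -> weight and overrides definition weights.
    """
    definitions = default_indicator_definitions() if definitions is None else definitions
    scored = score_table(observations, definitions)
    if weights is not None:
        scored["weight"] = scored["indicator_id"].map(weights)
        if scored["weight"].isna().any():
            raise ValueError("weights must cover every observed indicator_id")
    rows = []
    for unit_id, grp in scored.groupby("unit_id", sort=True):
        si, n_used = synthetic_index(grp["score"].tolist(), grp["weight"].tolist())
        rows.append({"unit_id": unit_id, "SI": si, "n_indicators_used": n_used})
    return pd.DataFrame(rows)


class EffectivenessIndex:
    """Effectiveness model: indicator observations -> per-unit SI.

    Parameters
    ----------
    observations : DataFrame
        Long table (unit_id, indicator_id, eligible, compliant, observed_cost).
    definitions : list of IndicatorDefinition, optional
    weights : dict, optional
        indicator_id -> weight override.
    """

    def __init__(self, observations, definitions=None, weights=None):
        self.observations = observations
        self.definitions = default_indicator_definitions() if definitions is None else definitions
        self.weights = weights

    @classmethod
    def from_csv(cls, observations_path, definitions_path=None):
        obs = read_indicators(observations_path)
        defs = read_definitions(definitions_path) if definitions_path else None
        return cls(obs, definitions=defs)

    def fit(self) -> "EffectivenessResults":
        scores = score_table(self.observations, self.definitions)
        si = si_table(self.observations, self.definitions, self.weights)
        return EffectivenessResults(model=self, scores=scores, si=si)


@dataclass
class EffectivenessResults:
    model: EffectivenessIndex
    scores: pd.DataFrame
    si: pd.DataFrame

    def summary(self, digits: int = 2) -> str:
        t = self.si
        lines = [
            f"Synthetic effectiveness index ({len(t)} units)",
            f"SI range: {t['SI'].min():.{digits}f} - {t['SI'].max():.{digits}f}"
            f", median {t['SI'].median():.{digits}f}",
            "",
            t.round({"SI": digits}).to_string(index=False),
        ]
        return "\n".join(lines)
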