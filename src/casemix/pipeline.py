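"""End-to-end analysis pipeline: simulate/load -> indices -> SI -> correlations.

The pipeline either loads a cohort from CSV files or simulates one from a
named scenario, fits the case-mix profile at both aggregation levels, scores
the quality indicators into the SI, correlates the five indices across basic
care teams, and bundles every table with a run log. Each stage failure is
wrapped with the stage name; the bundle is byte-stable for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import IndexAssociation
from .effectiveness import EffectivenessIndex
from .exceptions import CasemixError, PipelineError
from .io import read_indicators, read_patients, read_units, write_table
from .simulate import (
    CohortSimulator,
    GeneratorConfig,
    make_units,
    plant_unit_effects,
)
from .standardization import CaseMixProfile, ReferenceProfile

__all__ = ["AnalysisConfig", "ReportBundle", "run_pipeline"]


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs; file inputs or a simulation scenario.

    Exactly one of (``patients_path``) or (``scenario``) must be set. When a
    scenario is given, ``n_units``/``n_attended``/``kappa`` size the synthetic
    study. ``digits`` controls report rounding only; stored values keep full
    precision. ``alpha`` is the (strict) significance level.
    """

    patients_path: str | None = None
    units_path: str | None = None
    indicators_path: str | None = None
    reference_path: str | None = None
    scenario: str | None = None
    n_units: int = 13
    n_attended: int = 2000
    kappa: float = 200.0
    digits: int = 2
    alpha: float = 0.05
    method: str = "pearson"
    holm: bool = False
    weights: dict | None = None
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.digits < 0:
            raise ValueError("digits must be >= 0")
        if (self.patients_path is None) == (self.scenario is None):
            raise ValueError("provide exactly one of patients_path or scenario")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ReportBundle:
    """All pipeline outputs plus the run log."""

    patients: pd.DataFrame
    units: pd.DataFrame | None
    reference: ReferenceProfile
    phc_indices: pd.DataFrame
    bct_indices: pd.DataFrame
    scores: pd.DataFrame | None
    si: pd.DataFrame | None
    correlations: pd.DataFrame | None
    summary_text: str
    log: dict = field(default_factory=dict)

    def save(self, out_dir, include_inputs: bool = False) -> list[str]:
        """Write every table (CSV), the summary (markdown) and the run log."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []

        def _write(df, name):
            if df is not None and len(df):
                write_table(df, out / name)
                written.append(name)

        _write(self.phc_indices, "unit_indices_phc.csv")
        _write(self.bct_indices, "unit_indices_bct.csv")
        _write(self.reference.to_frame(), "reference.csv")
        _write(self.si, "si.csv")
        _write(self.scores, "indicator_scores.csv")
        _write(self.correlations, "correlations.csv")
        if include_inputs:
            _write(self.patients, "patients.csv")
            _write(self.units, "units.csv")
        (out / "summary.md").write_text(self.summary_text, encoding="utf-8")
        written.append("summary.md")
        (out / "run.json").write_text(
            json.dumps(self.log, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        written.append("run.json")
        return written


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (CasemixError, OSError, ValueError) as exc:
                if isinstance(exc, PipelineError):
                    raise
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("inputs")
def _load_inputs(config: AnalysisConfig):
    if config.scenario is not None:
        gen = GeneratorConfig(units=make_units(config.n_units, config.n_attended),
                              kappa=config.kappa, seed=config.seed)
        gen = plant_unit_effects(gen, config.scenario)
        sim = CohortSimulator(gen)
        return sim.population(), sim.units(), sim.indicators()
    patients = read_patients(config.patients_path)
    units = read_units(config.units_path) if config.units_path else None
    indicators = (read_indicators(config.indicators_path)
                  if config.indicators_path else None)
    return patients, units, indicators


@_stage("indices")
def _fit_indices(config, patients, units):
    reference = (ReferenceProfile.from_csv(config.reference_path)
                 if config.reference_path else None)
    phc = CaseMixProfile(patients, units=units, reference=reference, level="phc").fit()
    bct = CaseMixProfile(patients, units=units, reference=reference, level="bct").fit()
    return phc, bct


@_stage("effectiveness")
def _fit_effectiveness(config, indicators):
    if indicators is None:
        return None
    return EffectivenessIndex(indicators, weights=config.weights).fit()


@_stage("correlate")
def _fit_association(config, bct_indices, si):
    table = bct_indices.merge(si, on="unit_id", how="inner")
    model = IndexAssociation(table, alpha=config.alpha,
                             method=config.method, holm=config.holm)
    return model.fit()


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Execute simulate/load -> indices -> effectiveness -> correlate."""
    patients, units, indicators = _load_inputs(config)
    phc_res, bct_res = _fit_indices(config, patients, units)
    eff = _fit_effectiveness(config, indicators)

    assoc = None
    if eff is not None:
        assoc = _fit_association(config, bct_res.unit_indices, eff.si)

    parts = [
        "# Case-mix profiling report", "",
        "## Cohort descriptives", "```",
        phc_res.descriptives[["statistic", "display"]].to_string(index=False),
        "```", "",
        "## Per-centre indices", "```", phc_res.summary(config.digits), "```",
    ]
    if eff is not None:
        parts += ["", "## Effectiveness", "```", eff.summary(config.digits), "```"]
    if assoc is not None:
        parts += ["", "## Index correlations (BCT level)", "```",
                  assoc.summary(), "```"]
    summary_text = "\n".join(parts) + "\n"

    log = {
        "casemix_version": __version__,
        "seed": config.seed,
        "scenario": config.scenario,
        "alpha": config.alpha,
        "n_patients": int(len(patients)),
        "n_phc": int(phc_res.unit_indices.shape[0]),
        "n_bct": int(bct_res.unit_indices.shape[0]),
        "n_indicator_rows": None if indicators is None else int(len(indicators)),
        "reference": "external" if config.reference_path else "pooled cohort",
    }
    return ReportBundle(
        patients=patients, units=units, reference=phc_res.reference,
        phc_indices=phc_res.unit_indices, bct_indices=bct_res.unit_indices,
        scores=None if eff is None else eff.scores,
        si=None if eff is None else eff.si,
        correlations=None if assoc is None else assoc.correlations,
        summary_text=summary_text, log=log,
    )
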