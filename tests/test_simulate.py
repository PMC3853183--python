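"""Synthetic-cohort generator: determinism, moment recovery, planted effects."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

from casemix.catalog import default_acg_catalog
from casemix.effectiveness import EffectivenessIndex
from casemix.exceptions import ConfigError
from casemix.simulate import (
    GeneratorConfig,
    UnitEffect,
    _sample_zt_counts,
    generate_indicator_observations,
    generate_population,
    make_units,
    match_zt_count,
    plant_unit_effects,
    study_units,
    tilted_shares,
)
from tests.conftest import MASTER_SEED


def _null_config(n_units=4, n_attended=500, seed=MASTER_SEED):
    return plant_unit_effects(
        GeneratorConfig(units=make_units(n_units, n_attended), seed=seed), "null")


# -- determinism ------------------------------------------------------------

def test_same_seed_gives_byte_identical_cohort():
    a = generate_population(_null_config()).to_csv(index=False)
    b = generate_population(_null_config()).to_csv(index=False)
    assert a == b


def test_different_seed_changes_cohort():
    a = generate_population(_null_config(seed=1))
    b = generate_population(_null_config(seed=2))
    assert not a["n_visits"].equals(b["n_visits"])


def test_indicator_observations_deterministic():
    a = generate_indicator_observations(_null_config()).to_csv(index=False)
    b = generate_indicator_observations(_null_config()).to_csv(index=False)
    assert a == b


# -- moment recovery --------------------------------------------------------

def test_acg_shares_recovered_at_scale():
    # 50,000 neutral patients: empirical shares within +-0.01 of the catalog
    cfg = _null_config(n_units=10, n_attended=5000)
    patients = generate_population(cfg)
    emp = patients["acg_code"].value_counts(normalize=True)
    for entry in cfg.catalog:
        assert abs(emp.get(entry.acg_code, 0.0) - entry.share) < 0.01


def test_pooled_mean_visits_within_three_se():
    cfg = _null_config(n_units=10, n_attended=5000)
    patients = generate_population(cfg)
    df = patients["n_visits"]
    target = sum(e.share * e.visits_mean for e in cfg.catalog)
    se = df.std(ddof=1) / math.sqrt(len(df))
    assert abs(df.mean() - target) < 3 * se


def test_truncated_sampler_hits_target_moments(rng):
    # overdispersed target -> zero-truncated NB matched on truncated mean/SD
    params = match_zt_count(7.0, 5.2)
    assert params[0] == "nb"
    x = _sample_zt_counts(rng, params, 60_000)
    assert x.min() >= 1
    assert x.mean() == pytest.approx(7.0, abs=3 * 5.2 / math.sqrt(60_000))
    assert x.std(ddof=1) == pytest.approx(5.2, rel=0.03)


def test_no_patient_has_zero_visits_or_episodes():
    patients = generate_population(_null_config(n_units=6, n_attended=1000))
    assert patients["n_visits"].min() >= 1
    assert patients["n_episodes"].min() >= 1
    assert (patients["cost"] > 0).all()


# -- zero-truncated matching edge cases -------------------------------------

def test_underdispersed_target_falls_back_to_poisson(caplog):
    import casemix.simulate as sim
    sim._FALLBACK_WARNED.clear()
    match_zt_count.cache_clear()
    with caplog.at_level(logging.WARNING, logger="casemix.simulate"):
        params = match_zt_count(3.456789, 0.5)  # SD^2 << mean
    assert params[0] == "poisson"
    assert any("zero-truncated Poisson" in r.message for r in caplog.records)


def test_mean_below_one_is_infeasible():
    with pytest.raises(ConfigError, match="mean"):
        match_zt_count(0.9, 1.0)


def test_degenerate_mean_one_gives_constant_ones(rng):
    assert (_sample_zt_counts(rng, match_zt_count(1.0, 0.0), 10) == 1).all()


# -- mix tilt ---------------------------------------------------------------

def test_complexity_tilt_monotone_in_expected_visit_burden():
    catalog = default_acg_catalog()
    m = np.array([e.visits_mean for e in catalog])
    burdens = [float(tilted_shares(catalog, s) @ m)
               for s in np.linspace(-0.6, 0.6, 9)]
    assert all(b2 > b1 for b1, b2 in zip(burdens, burdens[1:]))


def test_zero_tilt_returns_catalog_shares():
    catalog = default_acg_catalog()
    assert np.allclose(tilted_shares(catalog, 0.0),
                       [e.share for e in catalog], atol=1e-15)


# -- unit defaults and config validation ------------------------------------

def test_assigned_population_defaults_to_coverage_ratio():
    u = UnitEffect(unit_id="B1", phc_id="P1", n_attended=692)
    assert u.assigned_population == 1000


def test_study_units_layout():
    units = study_units()
    assert len(units) == 187
    assert sum(u.n_attended for u in units) == 196_593
    assert len({u.phc_id for u in units}) == 13


@pytest.mark.parametrize("kwargs", [
    {"efficiency_factor_visits": 0.0},
    {"quality_level": 1.5},
    {"n_attended": 500, "assigned_population": 400},
])
def test_invalid_unit_effect_rejected(kwargs):
    base = {"unit_id": "B1", "phc_id": "P1", "n_attended": 500}
    with pytest.raises(ConfigError):
        UnitEffect(**{**base, **kwargs})


def test_config_requires_two_units():
    with pytest.raises(ConfigError, match="2 units"):
        GeneratorConfig(units=make_units(2, 100)[:1])


# -- indicator observations -------------------------------------------------

def test_compliant_never_exceeds_eligible():
    obs = generate_indicator_observations(_null_config(n_units=6, n_attended=800))
    prop = obs.dropna(subset=["eligible"])
    assert (prop["compliant"] <= prop["eligible"]).all()


def test_zero_noise_perfect_quality_hits_benchmarks():
    cfg = _null_config(n_units=2, n_attended=500)
    for u in cfg.units:
        u.quality_level = 1.0
    cfg.noise = False
    obs = generate_indicator_observations(cfg)
    costs = obs.dropna(subset=["observed_cost"]).merge(
        pd.DataFrame([vars(d) for d in cfg.indicator_definitions]),
        on="indicator_id")
    assert np.allclose(costs["observed_cost"].astype(float),
                       costs["benchmark_cost"].astype(float))


def test_quality_gap_orders_synthetic_index():
    cfg = _null_config(n_units=2, n_attended=4000)
    cfg.units[0].quality_level = 0.2
    cfg.units[1].quality_level = 0.9
    si = EffectivenessIndex(generate_indicator_observations(cfg)).fit().si
    si = si.set_index("unit_id")["SI"]
    assert si[cfg.units[1].unit_id] > si[cfg.units[0].unit_id]


# -- scenarios --------------------------------------------------------------

def test_null_scenario_is_neutral():
    cfg = _null_config()
    assert all(u.efficiency_factor_visits == 1.0 and u.complexity_shift == 0.0
               for u in cfg.units)


def test_efficiency_gradient_plants_distinct_factors():
    cfg = plant_unit_effects(
        GeneratorConfig(units=make_units(13, 100)), "efficiency_gradient")
    factors = [u.efficiency_factor_visits for u in cfg.units]
    assert len(set(factors)) == 13
    assert min(factors) == pytest.approx(0.85)
    assert max(factors) == pytest.approx(1.20)


def test_coupled_scenario_plants_negative_cost_quality_association():
    cfg = plant_unit_effects(
        GeneratorConfig(units=make_units(20, 100)), "coupled_quality_efficiency")
    q = [u.quality_level for u in cfg.units]
    fc = [u.efficiency_factor_costs for u in cfg.units]
    fe = [u.efficiency_factor_episodes for u in cfg.units]
    assert np.corrcoef(q, fc)[0, 1] < -0.99
    assert np.corrcoef(q, fe)[0, 1] > 0.99


def test_unknown_scenario_rejected():
    with pytest.raises(ConfigError, match="unknown scenario"):
        plant_unit_effects(GeneratorConfig(units=make_units(3, 100)), "bogus")
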