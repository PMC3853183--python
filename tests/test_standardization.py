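"""Indirect standardization: reference profiles, EIs, RI, tables, invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from casemix._utils import round_half_away
from casemix.catalog import catalog_dataframe
from casemix.exceptions import (
    CohortValidationError,
    MissingAcgError,
    UndefinedIndexError,
)
from casemix.standardization import (
    CaseMixProfile,
    acg_distribution_table,
    build_reference_profile,
    coverage_ratio,
    descriptive_summary,
    efficiency_index,
    expected_means,
    risk_index,
    unit_index_table,
)
from tests.conftest import random_cohort


def _tiny(rows):
    cols = ["patient_id", "age", "sex", "phc_id", "bct_id", "acg_code",
            "n_visits", "n_episodes", "cost"]
    return pd.DataFrame(rows, columns=cols)


# -- reference profile ------------------------------------------------------

def test_per_acg_mean_is_arithmetic_mean():
    patients = _tiny([
        ["p1", 40, "female", "P1", "B1", "A", 2, 1, 10.0],
        ["p2", 50, "male", "P1", "B1", "A", 4, 3, 30.0],
    ])
    ref = build_reference_profile(patients)
    assert ref.table.loc["A", "mean_visits"] == pytest.approx(3.0)
    assert ref.table.loc["A", "mean_episodes"] == pytest.approx(2.0)
    assert ref.table.loc["A", "mean_cost"] == pytest.approx(20.0)


def test_pooled_mean_is_share_weighted_mean(small_cohort):
    ref = build_reference_profile(small_cohort)
    shares = ref.table["n_patients"] / ref.n_total
    assert ref.pooled_mean("visits") == pytest.approx(
        float((shares * ref.table["mean_visits"]).sum()), rel=1e-9)
    assert ref.pooled_mean("visits") == pytest.approx(
        small_cohort["n_visits"].mean(), rel=1e-12)


def test_reference_profile_matches_per_patient_loop(rng):
    patients = random_cohort(rng, 10_000)
    ref = build_reference_profile(patients)
    sums, counts = {}, {}
    for acg, v in zip(patients["acg_code"], patients["n_visits"]):
        sums[acg] = sums.get(acg, 0) + v
        counts[acg] = counts.get(acg, 0) + 1
    for acg in counts:
        assert ref.table.loc[acg, "mean_visits"] == pytest.approx(
            sums[acg] / counts[acg], rel=1e-12)


def test_empty_cohort_rejected():
    with pytest.raises(CohortValidationError):
        build_reference_profile(_tiny([]))


# -- expected means ---------------------------------------------------------

def test_unit_with_pooled_mix_has_pooled_expectation(rng):
    patients = random_cohort(rng, 2000)
    ref = build_reference_profile(patients)
    exp = expected_means(patients, ref)  # the whole cohort is "the unit"
    for quantity, col in [("visits", "n_visits"), ("episodes", "n_episodes"),
                          ("cost", "cost")]:
        assert exp[quantity] == pytest.approx(patients[col].mean(), rel=1e-12)


def test_expected_means_equal_per_patient_loop(rng):
    patients = random_cohort(rng, 3000)
    ref = build_reference_profile(patients)
    unit = patients[patients["phc_id"] == "PHC0"]
    exp = expected_means(unit, ref)
    loop = sum(ref.table.loc[a, "mean_visits"] for a in unit["acg_code"]) / len(unit)
    assert exp["visits"] == pytest.approx(loop, rel=1e-12)


def test_missing_acg_codes_are_listed(rng):
    patients = random_cohort(rng, 200)
    ref = build_reference_profile(patients[patients["acg_code"] != "B"])
    with pytest.raises(MissingAcgError, match="B") as exc:
        expected_means(patients, ref)
    assert exc.value.codes == ["B"]


# -- scalar indices ---------------------------------------------------------

@pytest.mark.parametrize("obs,exp,rounded", [
    (600.87, 752.71, 0.80),  # centre with markedly low cost use
    (807.85, 707.07, 1.14),  # centre overshooting its expected cost
    (9.87, 8.02, 1.23),      # visits over expectation
    (4.94, 4.61, 1.07),      # episodes over expectation
])
def test_efficiency_index_reproduces_printed_ratios(obs, exp, rounded):
    assert round_half_away(efficiency_index(obs, exp), 2) == pytest.approx(rounded)


def test_efficiency_index_identity_and_errors():
    assert efficiency_index(7.5, 7.5) == pytest.approx(1.0)
    with pytest.raises(UndefinedIndexError):
        efficiency_index(1.0, 0.0)


@pytest.mark.parametrize("exp,ref,rounded", [(6.93, 7.8, 0.89), (8.49, 7.8, 1.09)])
def test_risk_index_reproduces_printed_ratios(exp, ref, rounded):
    assert round_half_away(risk_index(exp, ref), 2) == pytest.approx(rounded)


def test_risk_index_is_one_for_pooled_mix(rng):
    patients = random_cohort(rng, 2000)
    ref = build_reference_profile(patients)
    exp = expected_means(patients, ref)
    assert risk_index(exp["visits"], ref.pooled_mean("visits")) == pytest.approx(1.0, rel=1e-12)


@given(obs=st.floats(0.01, 1e4), exp=st.floats(0.01, 1e4))
def test_efficiency_index_recovers_observed(obs, exp):
    assert efficiency_index(obs, exp) * exp == pytest.approx(obs, rel=1e-9)


def test_coverage_ratio_cases():
    assert round_half_away(100 * coverage_ratio(196_593, 284_013), 1) == pytest.approx(69.2)
    assert coverage_ratio(50, 50) == pytest.approx(1.0)
    assert coverage_ratio(1, 4) == pytest.approx(0.25)
    with pytest.raises(CohortValidationError):
        coverage_ratio(10, 9)


# -- unit index table -------------------------------------------------------

def test_unit_table_shape_and_internal_consistency(rng):
    patients = random_cohort(rng, 5000, n_phc=13, bct_per_phc=1)
    table = unit_index_table(patients, level="phc")
    assert len(table) == 13
    for _, row in table.iterrows():
        assert row["visits_EI"] == pytest.approx(
            row["observed_mean_visits"] / row["expected_mean_visits"], rel=1e-12)
        assert row["costs_EI"] == pytest.approx(
            row["observed_mean_cost"] / row["expected_mean_cost"], rel=1e-12)
        assert row["visits_EI"] > 0 and row["RI"] > 0


def test_conservation_under_internal_reference(rng):
    patients = random_cohort(rng, 4000)
    res = CaseMixProfile(patients, level="phc").fit()
    cons = res.conservation()
    for key, value in cons.items():
        assert value == pytest.approx(1.0, rel=1e-9), key


def test_adding_a_visit_raises_visits_ei_and_leaves_ri(rng):
    patients = random_cohort(rng, 1500)
    ref = build_reference_profile(patients)  # frozen external reference
    before = unit_index_table(patients, reference=ref, level="phc").set_index("unit_id")
    bumped = patients.copy()
    idx = bumped.index[bumped["phc_id"] == "PHC1"][0]
    bumped.loc[idx, "n_visits"] += 1
    after = unit_index_table(bumped, reference=ref, level="phc").set_index("unit_id")
    assert after.loc["PHC1", "visits_EI"] > before.loc["PHC1", "visits_EI"]
    assert after.loc["PHC1", "RI"] == pytest.approx(before.loc["PHC1", "RI"], rel=1e-12)
    assert after.loc["PHC0", "visits_EI"] == pytest.approx(
        before.loc["PHC0", "visits_EI"], rel=1e-12)


def test_cost_scale_equivariance(rng):
    patients = random_cohort(rng, 1500)
    t1 = unit_index_table(patients, level="phc").set_index("unit_id")
    scaled = patients.assign(cost=patients["cost"] * 3.7)
    t2 = unit_index_table(scaled, level="phc").set_index("unit_id")
    assert np.allclose(t1["costs_EI"], t2["costs_EI"], rtol=1e-12)


def test_bct_level_uses_same_code_path(rng):
    patients = random_cohort(rng, 2000, n_phc=3, bct_per_phc=3)
    table = unit_index_table(patients, level="bct")
    assert set(table["unit_id"]) == set(patients["bct_id"].unique())
    assert "phc_id" in table.columns


# -- descriptive tables -----------------------------------------------------

def test_descriptives_single_patient():
    patients = _tiny([["p1", 40, "female", "P1", "B1", "A", 5, 2, 10.0]])
    d = descriptive_summary(patients).set_index("statistic")
    row = d.loc["visits_per_patient"]
    assert row["mean_or_pct"] == pytest.approx(5.0)
    assert row["sd"] == pytest.approx(0.0)
    assert row["median"] == pytest.approx(5.0)


def test_descriptives_display_convention(small_cohort):
    d = descriptive_summary(small_cohort).set_index("statistic")
    disp = d.loc["visits_per_patient", "display"]
    assert "(" in disp and ";" in disp and "[" in disp and "-" in disp


def test_descriptives_match_two_pass_oracle(small_cohort):
    d = descriptive_summary(small_cohort).set_index("statistic")
    x = small_cohort["cost"].to_numpy()
    mean = float(np.sum(x)) / len(x)
    sd = np.sqrt(np.sum((x - mean) ** 2) / (len(x) - 1))
    assert d.loc["cost_per_patient", "mean_or_pct"] == pytest.approx(mean, abs=1e-10)
    assert d.loc["cost_per_patient", "sd"] == pytest.approx(sd, abs=1e-10)


# -- ACG distribution -------------------------------------------------------

def catalog_count_cohort():
    """A cohort whose ACG counts equal the catalog's attended counts.

    The pooled OTHER entry stands for 39 individually rare categories, so it
    is split into 39 synthetic codes of near-equal size; concentration
    summaries then rank categories the way the source population does.
    """
    df = catalog_dataframe()
    named = df[df["acg_code"] != "OTHER"]
    codes = [np.repeat(named["acg_code"].to_numpy(), named["n_patients"].to_numpy())]
    n_other = int(df.loc[df["acg_code"] == "OTHER", "n_patients"].iloc[0])
    base, extra = divmod(n_other, 39)
    codes += [np.repeat(f"R{i + 1:02d}", base + (1 if i < extra else 0))
              for i in range(39)]
    codes = np.concatenate(codes)
    n = len(codes)
    return pd.DataFrame({
        "patient_id": np.arange(n).astype(str), "age": 50, "sex": "female",
        "phc_id": "P1", "bct_id": "B1", "acg_code": codes,
        "n_visits": 1, "n_episodes": 1, "cost": 1.0,
    })


@pytest.fixture(scope="module")
def catalog_scale_cohort():
    return catalog_count_cohort()


def test_concentration_of_most_prevalent_categories(catalog_scale_cohort):
    dist = acg_distribution_table(catalog_scale_cohort)
    assert round_half_away(dist.table["pct"].iloc[0], 1) == pytest.approx(14.7)
    assert round_half_away(100 * dist.top_share(5), 1) == pytest.approx(44.5)
    assert round_half_away(100 * dist.top_share(11), 1) == pytest.approx(68.0)


def test_percentages_sum_to_hundred(small_cohort):
    dist = acg_distribution_table(small_cohort)
    assert dist.table["pct"].sum() == pytest.approx(100.0, abs=1e-9)


def test_rare_category_count_matches_filter(rng):
    patients = random_cohort(rng, 3000, acg_codes=tuple("ABCDEFGH"))
    dist = acg_distribution_table(patients, rare_share_threshold=0.13)
    brute = int((patients["acg_code"].value_counts(normalize=True) < 0.13).sum())
    assert dist.n_rare == brute
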