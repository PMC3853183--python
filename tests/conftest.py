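import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

MASTER_SEED = 1234


@pytest.fixture
def rng():
    return np.random.default_rng(MASTER_SEED)


def random_cohort(rng, n, n_phc=3, bct_per_phc=2, acg_codes=("A", "B", "C", "D")):
    """Small arbitrary cohort for oracle-equivalence and invariant tests."""
    phc = rng.integers(0, n_phc, n)
    bct = rng.integers(0, bct_per_phc, n)
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "age": rng.integers(15, 95, n),
        "sex": np.where(rng.random(n) < 0.55, "female", "male"),
        "phc_id": [f"PHC{i}" for i in phc],
        "bct_id": [f"PHC{i}-B{j}" for i, j in zip(phc, bct)],
        "acg_code": rng.choice(list(acg_codes), n),
        "n_visits": 1 + rng.poisson(4.0, n),
        "n_episodes": 1 + rng.poisson(2.0, n),
        "cost": rng.gamma(2.0, 300.0, n),
    })


@pytest.fixture
def small_cohort(rng):
    return random_cohort(rng, 400)
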