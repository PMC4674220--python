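import numpy as np
import pytest

import deerpop as dp

#: regional vital-rate point estimates used throughout the tests
MEDIAN_VITALS = dict(s1=0.76, s2=0.68, s3=0.45, m=0.53, r_f=0.86, K_f=27.12)


@pytest.fixture(scope="session")
def median_vitals() -> dp.VitalRates:
    return dp.VitalRates(**MEDIAN_VITALS)


@pytest.fixture(scope="session")
def small_dataset():
    """A 3-park, 6-year synthetic dataset with its truth record."""
    design = dp.scenario_presets("small_test")
    return dp.generate_dataset(design, np.random.default_rng(42))


def make_degenerate_draws(vitals: dp.VitalRates, n: int = 8) -> dp.PosteriorDraws:
    """PosteriorDraws with every draw at the same parameter point."""
    C, S, P, T = 1, n, 2, 3
    values = {
        "s": np.tile([vitals.s1, vitals.s2, vitals.s3], (C, S, P, 1)),
        "a": np.ones((C, S, 3)),
        "b": np.ones((C, S, 3)),
        "m": np.full((C, S), vitals.m),
        "r_f": np.full((C, S), vitals.r_f),
        "K_f": np.full((C, S), vitals.K_f),
        "sigma_p2": np.full((C, S), vitals.sigma_p2),
        "d1": np.full((C, S, P), 30.0),
        "gamma1": np.tile([0.3, 0.4, 0.3], (C, S, P, 1)),
        "logN": np.log(np.full((C, S, P, T, 3), 50.0)),
    }
    return dp.PosteriorDraws(
        values=values, park_ids=["A", "B"], years=np.arange(2001, 2001 + T),
        areas=np.array([10.0, 5.0]), seed=0,
        config=dp.McmcConfig(n_chains=C, n_burnin=1, n_samples=S),
    )


@pytest.fixture(scope="session")
def degenerate_draws_factory():
    return make_degenerate_draws


@pytest.fixture(scope="session")
def small_draws(small_dataset):
    """A short but real posterior fit on the small dataset, shared across tests."""
    data, _ = small_dataset
    cfg = dp.McmcConfig(n_chains=2, n_burnin=400, n_samples=400, seed=7)
    return dp.fit_mcmc(data, cfg)
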