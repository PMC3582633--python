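import numpy as np
import pytest

import lunarsea as ls


@pytest.fixture(scope="session")
def small_deployment():
    """One small synthetic deployment reused across modules (6 birds, 40 nights)."""
    spec = ls.SimulationSpec(
        n_birds=6,
        n_nights=40,
        seed=11,
        include_daytime=True,
        day_rest_rate=0.02,
    )
    records, covs, truth = ls.simulate_deployment(spec)
    return spec, records, covs, truth


@pytest.fixture(scope="session")
def small_dataset(small_deployment):
    _, records, covs, _ = small_deployment
    nights = ls.aggregate_nights(records)
    return ls.join_design(nights, covs)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A short but usable posterior fit of the small deployment."""
    config = ls.McmcConfig(n_iter=4_000, n_burn=500, seed=5)
    return ls.sample_posterior(small_dataset, ls.PriorSpec(), config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
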