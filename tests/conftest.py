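import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from dimnorms import (Config, GeneratorConfig, aggregate, generate_dataset,
                      make_profiles, simulate_ratings)


@pytest.fixture(scope="session")
def small_config():
    """Small but structurally faithful study: 4 lists, 2 rater cohorts."""
    return GeneratorConfig(n_items=120, n_concrete=20, n_lists=4,
                           raters_per_list=22, noise_sd=0.8, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        frame, meta, truth = generate_dataset(small_config)
    return frame, meta, truth


@pytest.fixture(scope="session")
def small_norms(small_dataset):
    frame, meta, _ = small_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return aggregate(frame, meta=meta)


@pytest.fixture(scope="session")
def noiseless_config():
    """Integer latent levels, zero noise: aggregation is exact."""
    return GeneratorConfig(n_items=48, n_concrete=8, n_lists=4,
                           raters_per_list=20, noise_sd=0.0,
                           integer_levels=True, seed=5)
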