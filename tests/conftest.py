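import dataclasses

import pytest

import leafheat as lh


@pytest.fixture(scope="session")
def config():
    """Default synthetic study conditions (12 species x 3 sites)."""
    return lh.default_config(random_seed=11)


@pytest.fixture(scope="session")
def noiseless_config(config):
    """Same study with all residual noise off; observations sit on the curve."""
    return dataclasses.replace(config, noise_sd=0.0, control_fvfm_sd=0.0)


@pytest.fixture(scope="session")
def small_config():
    """One species at one site, for fast per-group tests."""
    full = lh.default_config(random_seed=7)
    keep = ("Cme",)
    return dataclasses.replace(
        full,
        species_labels=keep,
        site_labels=("ME",),
        true_thetas={k: v for k, v in full.true_thetas.items() if k[0] in keep},
        leaf_temp_params={k: v for k, v in full.leaf_temp_params.items() if k[0] in keep},
    )


@pytest.fixture(scope="session")
def fluorescence(config):
    return lh.simulate_fluorescence_dataset(config)
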