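import numpy as np
import pytest

import intermed as im


@pytest.fixture(scope="session")
def small_config():
    """Calibrated config at a reduced two-site scale."""
    return im.default_config(seed=20, n_lima=200, n_saopaulo=320)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    frame = im.generate_trial(small_config, seed=20)
    return im.complete_case_filter(im.from_frame(frame))


@pytest.fixture(scope="session")
def confounders():
    return ["phq9_baseline", "medication", "bads_baseline", "site"]


@pytest.fixture(scope="session")
def fitted_models(small_dataset, confounders):
    return im.fit_mediator_models(small_dataset, confounders)


@pytest.fixture(scope="session")
def fitted_outcome(small_dataset, confounders):
    return im.fit_outcome_model(small_dataset, confounders)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
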