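import dataclasses

import pytest
from hypothesis import settings

from hospicost import default_study_config, generate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    """A few facilities per type: fast but exercises every centre kind."""
    return dataclasses.replace(
        default_study_config(seed=123), n_district=6, n_private=5, n_tertiary=4
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """Study-sized sample (27/16/11 facilities), shared across tests."""
    return generate_dataset(default_study_config(seed=7))
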