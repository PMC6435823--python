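import numpy as np
import pytest

from azquant import synthetic as syn


@pytest.fixture(scope="session")
def default_map():
    """A representative 100-AZ map under the default study conditions."""
    return syn.gen_az_map(100, seed=1)


@pytest.fixture(scope="session")
def noisy_image(default_map):
    return syn.render_puncta_image(default_map, noise={"gaussian_sd": 3.0}, seed=2)


@pytest.fixture(scope="session")
def clean_image(default_map):
    return syn.render_puncta_image(default_map, noise=None)
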