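import pytest
from hypothesis import settings

from seedprotdev.simulate import SimConfig, generate_bundle

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Small but fully structured study design for fast end-to-end tests."""
    return SimConfig(seed=11, n_spots=200, n_diff_spots=12, n_proteins=20)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, small_config):
    """A generated input bundle plus its ground truths."""
    out = tmp_path_factory.mktemp("bundle")
    truths = generate_bundle(small_config, out)
    return out, truths
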