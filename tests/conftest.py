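import pytest

from misinfodemic.profiles import build_profiles
from misinfodemic.synth import SynthConfig, generate_stream, make_catalog, truth_table


@pytest.fixture(scope="session")
def small_cfg():
    """A compact stream with bots, used by most integration-style tests."""
    return SynthConfig(n_users=80, n_days=30, n_bot_users=3, seed=11)


@pytest.fixture(scope="session")
def small_stream(small_cfg):
    return generate_stream(small_cfg)


@pytest.fixture(scope="session")
def small_catalog(small_cfg):
    return make_catalog(small_cfg)


@pytest.fixture(scope="session")
def small_truth(small_cfg):
    return truth_table(small_cfg)


@pytest.fixture(scope="session")
def small_profiles(small_stream, small_catalog):
    return build_profiles(small_stream, small_catalog, seed=5)
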