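import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A tiny (2-participant) simulated study written to disk, with EEG."""
    from flashsleep import SimConfig, simulate_study

    out = tmp_path_factory.mktemp("study") / "sim"
    cfg = simulate_study(SimConfig(seed=7, n_participants=2), out)
    return out, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
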