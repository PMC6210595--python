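import pytest

from prescvar import panel_io
from prescvar import synthetic_data as synth


@pytest.fixture(scope="session")
def small_sim():
    """60 practices over the full window, default generator conditions."""
    cfg = synth.SimConfig(n_practices=60, seed=42)
    return synth.simulate_panel(cfg)


@pytest.fixture(scope="session")
def small_share(small_sim):
    panel, _, _ = small_sim
    return panel_io.compute_share(panel)


@pytest.fixture(scope="session")
def small_profiles(small_sim):
    return small_sim[1]
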