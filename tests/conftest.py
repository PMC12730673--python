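import numpy as np
import pytest

from msdual import simulate as sim


@pytest.fixture(scope="session")
def canonical():
    """The built-in 32-channel archetype template set."""
    return sim.make_canonical_templates()


@pytest.fixture(scope="session")
def profiles():
    return sim.doc_group_profiles()


@pytest.fixture(scope="session")
def hc_profile(profiles):
    return profiles["HC"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_recording(canonical, hc_profile):
    """A 30-s noise-free recording with its ground truth (fs 250)."""
    cfg = sim.SimulationConfig(noise_level=0.0, seed=42)
    rec, truth = sim.simulate_recording(hc_profile, canonical, cfg, 30.0, seed=42)
    return rec, truth


@pytest.fixture(scope="session")
def noisy_recording(canonical, hc_profile):
    """A 60-s recording at noise level 0.25 (fs 250)."""
    cfg = sim.SimulationConfig(noise_level=0.25, seed=7)
    rec, truth = sim.simulate_recording(hc_profile, canonical, cfg, 60.0, seed=7)
    return rec, truth
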