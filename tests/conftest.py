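import numpy as np
import pytest

from microstates import SimulationSpec, TemplateSet, make_templates, simulate_microstate_eeg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_templates():
    """Four well-separated 16-electrode maps."""
    return make_templates(16, 4, min_separation=0.5, seed=7)


@pytest.fixture(scope="session")
def short_simulation(small_templates):
    """A 30-second noisy recording with planted dynamics plus its spec."""
    spec = SimulationSpec(
        n_electrodes=16,
        duration=30.0,
        templates=small_templates,
        mean_durations=(60.0, 80.0, 100.0, 120.0),
        snr=2.0,
        seed=42,
    )
    rec, truth = simulate_microstate_eeg(spec)
    return spec, rec, truth


@pytest.fixture(scope="session")
def clean_simulation(small_templates):
    """Noise-free counterpart of the short simulation."""
    spec = SimulationSpec(
        n_electrodes=16,
        duration=30.0,
        templates=small_templates,
        mean_durations=(60.0, 80.0, 100.0, 120.0),
        snr=np.inf,
        seed=42,
    )
    rec, truth = simulate_microstate_eeg(spec)
    return spec, rec, truth
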