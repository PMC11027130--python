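import numpy as np
import pytest

import smd


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale session used across tests (fast but structurally complete)."""
    return smd.SimulationConfig(
        n_trial_sets=3, trial_set_duration=8.0, inter_trial_interval=4.0,
        sampling_rate_track=250.0, sampling_rate_meg=250.0,
        n_sensors=32, grid_shape=(4, 4, 4), seed=7, device_lag=137,
        noise_sd=0.5, source_location=30,
    )


@pytest.fixture(scope="session")
def articulatory_session(small_config):
    return smd.simulate_articulatory_session(small_config)


@pytest.fixture(scope="session")
def leadfield(small_config):
    return smd.make_leadfield(small_config.n_sensors, small_config.grid_shape,
                              small_config.grid_spacing, seed=0)


@pytest.fixture(scope="session")
def meg_session(small_config, articulatory_session, leadfield):
    tracks, acoustic, truth = articulatory_session
    return smd.simulate_meg_session(small_config, leadfield, truth, acoustic)


def raised_cosine_signal(amplitude=10.0, duration=0.2, sfreq=1000.0,
                         n_cycles=1, baseline=2.0, pad=0.3):
    """Closed-form raised-cosine open/close cycle train (analytic oracle)."""
    period = 2 * duration
    total = n_cycles * period + 2 * pad
    t = np.arange(0.0, total, 1.0 / sfreq)
    x = np.full_like(t, baseline)
    for k in range(n_cycles):
        s = pad + k * period
        sel = (t >= s) & (t < s + duration)
        x[sel] = baseline + amplitude / 2 * (1 - np.cos(np.pi * (t[sel] - s) / duration))
        sel = (t >= s + duration) & (t < s + period)
        x[sel] = baseline + amplitude / 2 * (
            1 + np.cos(np.pi * (t[sel] - s - duration) / duration))
    return smd.GesturalSignal("BC", t, x)
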