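import numpy as np
import pytest

import as4dpm as m


@pytest.fixture(scope="session")
def schedule():
    """The standard 70 s, 1.5 deg/s, 0.3 deg rotational acquisition."""
    return m.build_schedule(1.5, 70, 0.3)


@pytest.fixture(scope="session")
def clean_case(schedule):
    """Noise-free synthetic acquisition (projection and trace noise off)."""
    params = m.BreathingParams(seed=0, noise_sd=0.0)
    projection = m.ProjectionParams(noise_sd=0.0)
    return m.simulate_case(params, schedule, projection=projection)


@pytest.fixture(scope="session")
def noisy_case(schedule):
    """Synthetic acquisition at the default moderate noise levels."""
    return m.simulate_case(m.BreathingParams(seed=1), schedule)


@pytest.fixture(scope="session")
def quasi_periodic_trace():
    """A clean quasi-periodic breathing trace for regression tests."""
    params = m.BreathingParams(seed=7, noise_sd=0.0)
    return m.simulate_breathing(params, 302, amplitude=3.0)
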