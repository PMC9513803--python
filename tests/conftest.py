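"""Shared fixtures: the standard 1 s stimulus and a few simulated units.

Everything is generated programmatically at fixed seeds; session scope keeps
the expensive decodes to one per suite run.
"""

import numpy as np
import pytest

from wnspike.signal import generate_wn_signal, standardize
from wnspike.simulate import SimulationConfig, simulate_unit


@pytest.fixture(scope="session")
def trace_raw():
    """The 0-1 scaled stimulus at the 6 kHz stimulation rate."""
    return generate_wn_signal(duration=1.0, fs=6000.0, tau=3.0, seed=7)


@pytest.fixture(scope="session")
def trace_z(trace_raw):
    """Standardized stimulus on the 2500 Hz analysis grid."""
    return standardize(trace_raw.resample(2500.0))


@pytest.fixture(scope="session")
def unit_locked(trace_z):
    """A strongly signal-locked unit (lambda1=100, sigma1=2 ms, no noise)."""
    cfg = SimulationConfig(lambda1=100.0, sigma1=2.0, seed=11)
    return simulate_unit(cfg, trace_z, unit_id="locked")


@pytest.fixture(scope="session")
def unit_noisy(trace_z):
    """A unit with heavy homogeneous noise (the long-timescale regime)."""
    cfg = SimulationConfig(lambda1=100.0, sigma1=10.0, lambda2=200.0, sigma2=60.0,
                           n_add=25, seed=13)
    return simulate_unit(cfg, trace_z, unit_id="noisy")


@pytest.fixture(scope="session")
def unit_poisson():
    """Trial-independent homogeneous Poisson spiking: no stimulus locking
    and no shared across-trial structure."""
    from wnspike.simulate import SpikeTrainSet

    rng = np.random.default_rng(17)
    trials = [np.sort(rng.uniform(0.0, 999.9, size=rng.poisson(30)))
              for _ in range(25)]
    return SpikeTrainSet(unit_id="poisson", trials=trials, duration_ms=1000.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
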