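import numpy as np
import pytest

from ecistools.core import DEFAULT_FREQUENCIES_HZ, ImpedanceTimeSeries
from ecistools.gk import CellModelParams, calibrate_naked_electrode
from ecistools.simulate import (
    GroupParams,
    PhaseSchedule,
    SimulationConfig,
    WoundSpec,
)


@pytest.fixture(scope="session")
def naked():
    """Default cell-free electrode, calibrated to 2600 Ohm at 4 kHz."""
    return calibrate_naked_electrode()


@pytest.fixture
def cell_params():
    return CellModelParams(alpha=7.8, rb=5.0, cm=1.0)


@pytest.fixture
def small_series(naked):
    """2 wells x 3 sweeps x 11 frequencies, physically plausible values."""
    times = np.array([0.0, 160.0, 320.0])
    freqs = np.asarray(DEFAULT_FREQUENCIES_HZ)
    rng = np.random.default_rng(7)
    z = np.empty((3, 2, 11), dtype=complex)
    for w in range(2):
        base = 1000.0 * (w + 1)
        z[:, w, :] = (base + rng.uniform(0, 50, (3, 11))
                      - 1j * (1e7 / freqs)[None, :])
    return ImpedanceTimeSeries(times, ["A1", "B2"], freqs, z)


def compressed_config(**overrides):
    """A short-schedule simulation config for fast tests."""
    kw = dict(
        seed=1,
        duration_h=36.0,
        schedule=PhaseSchedule(rise_h=2.0, peak_r4k=15000.0, decline_h=3.0,
                               plateau_r4k=8500.0, cellfree_r4k=2600.0),
        wells=(("A1", "control"),),
        groups={"control": GroupParams(alpha=6.5, front_speed_um_h=10.69)},
        wound=WoundSpec(time_h=8.0),
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture
def fast_config():
    return compressed_config()
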