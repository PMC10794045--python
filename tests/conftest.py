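"""Shared fixtures: short-axis synthetic acquisitions for fast tests.

Tests run on a 512-step axis (9.1 ns at the 17.857 ps gate step) instead of
the instrument's full 1400 steps: long enough to contain the pulses under
test, short enough to keep per-fit cost in the millisecond range.
"""

import numpy as np
import pytest

import tofdepth.simulate as sim
from tofdepth.core import GateTimeAxis


@pytest.fixture(scope="session")
def axis():
    return GateTimeAxis(n_steps=512)


@pytest.fixture(scope="session")
def irf(axis):
    return sim.make_irf(axis, pulse_fwhm_ps=120.0, amplitude=1.0)


@pytest.fixture(scope="session")
def superpixel_sensor():
    """Sensor model for an 8x8-binned superpixel: 64x the binary frames."""
    n = 256 * 64
    return sim.SensorResponse(frames_per_gate_sequence=n, linear_range_ceiling=n)


@pytest.fixture(scope="session")
def fluor():
    return sim.FluorophoreModel(tau_ns=0.7)


def make_fluo_profile(irf, delta_ps, sigma_ps, amplitude=96000.0, tau_ns=0.7):
    """Noise-free fluorescence profile with the given ground truth."""
    med = sim.MediumTransfer(A=amplitude, delta_tissue_ps=delta_ps, sigma_ps=sigma_ps)
    return sim.forward_profile(irf, med, sim.FluorophoreModel(tau_ns=tau_ns))


def make_refl_profile(irf, delta_ps, sigma_ps, amplitude=96000.0):
    med = sim.MediumTransfer(A=amplitude, delta_tissue_ps=delta_ps, sigma_ps=sigma_ps)
    return sim.forward_profile(irf, med, None)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
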