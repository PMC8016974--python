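"""Shared fixtures: default optics and session-scoped calibrations."""

from __future__ import annotations

import numpy as np
import pytest

from selfipsf import ImagingSystem, OpticsConfig, SubstrateStack
from selfipsf.calibration import build_calibration, simulate_feature_samples


@pytest.fixture(scope="session")
def optics() -> OpticsConfig:
    return OpticsConfig()


@pytest.fixture(scope="session")
def optics96() -> OpticsConfig:
    """Wider field for movie scenes (particles wander laterally)."""
    return OpticsConfig(field_px=96)


@pytest.fixture(scope="session")
def imaging(optics):
    return ImagingSystem.from_config(optics)


@pytest.fixture(scope="session")
def stack(optics):
    return SubstrateStack.from_config(optics)


@pytest.fixture(scope="session")
def calib_noiseless(optics):
    """Noiseless simulated calibration, 2 nm sampling over the working range."""
    z_values = np.arange(30.0, 500.01, 2.0)
    return build_calibration(simulate_feature_samples(optics, z_values))


@pytest.fixture(scope="session")
def calib_noisy(optics96):
    """Measurement-protocol calibration: noisy replicates at 1e4 photons."""
    samples = simulate_feature_samples(
        optics96, np.arange(30.0, 500.01, 4.0), photons=1e4, n_rep=6, seed=11
    )
    return build_calibration(samples, smoothing=None)
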