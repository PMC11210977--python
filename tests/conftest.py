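"""Shared fixtures: small, fast synthetic study conditions."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mpspec.particle import FieldWaveform, ParticleModel
from mpspec.simulate import AcquisitionConfig, DriftModel, InstrumentModel
from mpspec.transfer import TransferFunction

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tf() -> TransferFunction:
    """Default parametric receive chain (differentiator x 30 dB notch at f0)."""
    return TransferFunction.parametric()


@pytest.fixture(scope="session")
def differentiator() -> TransferFunction:
    """Pure unit-gain differentiator (no notch)."""
    return TransferFunction.parametric(gain=1.0, notch_frequency=None)


@pytest.fixture(scope="session")
def ideal_instrument(tf) -> InstrumentModel:
    return InstrumentModel.ideal(tf)


@pytest.fixture(scope="session")
def noisy_instrument(tf) -> InstrumentModel:
    return InstrumentModel(tf=tf)


@pytest.fixture(scope="session")
def short_config() -> AcquisitionConfig:
    """Spectroscopy timing with 100 drive periods per measurement (fast tests)."""
    return AcquisitionConfig.spectroscopy(n_drive_periods=100)


@pytest.fixture(scope="session")
def drive_period_waveform(short_config) -> FieldWaveform:
    """One 84-sample drive period at 10 mT."""
    cfg = short_config
    t = np.arange(cfg.samples_per_drive_period) * cfg.sample_interval
    h = cfg.drive_amplitude * np.cos(2 * np.pi * cfg.drive_frequency * t)
    return FieldWaveform(h, cfg.sample_interval, cfg.samples_per_drive_period)


@pytest.fixture(scope="session")
def debye_particle() -> ParticleModel:
    return ParticleModel(1e-6, 1.0, "debye", tau_eff=3e-6)


@pytest.fixture(scope="session")
def adiabatic_particle() -> ParticleModel:
    return ParticleModel(1e-6, 1.0)
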