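"""Synthetic instrument: timing, waveforms, receive chain, drift, and schedules.

This module emulates the benchtop spectrometer end to end so that every
analysis mode in the package can be exercised on data with known ground
truth.  The timing contract mirrors the hardware: 2 MHz sampling, a 42 us
drive period (84 samples, ~23.8 kHz), an 84 ms bias period, and hence
exactly 2000 drive periods per bias period.  All drive and bias frequencies
are commensurate with the sampling grid, so every period is sampled
identically and harmonic bins are leakage-free by construction.

The receive model is

    V(f) = TF_rx(f) * c_j * [M_sample(f) + M_feedthrough(f)] + noise,

where ``c_j`` is a slow per-measurement complex drift (magnitude and phase),
feedthrough is the residual drive coupling expressed as an equivalent
moment at f0 and 3 f0, and the noise is white and Gaussian at the stated
voltage density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .particle import FieldWaveform, ParticleModel, magnetization_response
from .transfer import TransferFunction

__all__ = [
    "AcquisitionConfig",
    "DriftModel",
    "InstrumentModel",
    "Measurement",
    "MeasurementSet",
    "SweepRecord",
    "make_drive_waveform",
    "make_bias_waveform",
    "synthesize_rx",
    "synthesize_in_out_run",
    "synthesize_quasistatic_run",
    "synthesize_calibration_sweep",
    "IN_OUT_PATTERN",
]

#: Measurement schedule of one in/out spectroscopy run: eleven sample-out,
#: eleven sample-in, cycled two and a half times so the run is anchored by
#: sample-out blocks at both ends.
IN_OUT_PATTERN: tuple[str, ...] = ("out",) * 11 + ("in",) * 11 + ("out",) * 11 + (
    "in",
) * 11 + ("out",) * 11


class ConfigError(ValueError):
    """Raised when acquisition parameters violate the timing contract."""


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing and field-amplitude contract of one acquisition.

    Defaults reproduce the device's spectroscopy mode: 2 MHz sampling,
    42 us drive period at 10 mT peak, bias off, one bias period (84 ms,
    2000 drive periods) of data per measurement.
    """

    sampling_rate: float = 2e6
    drive_period: float = 42e-6
    bias_period: float = 84e-3
    drive_periods_per_bias_period: int = 2000
    drive_amplitude: float = 10.0
    bias_amplitude: float = 0.0
    acquisition_length: float = 84e-3
    random_seed: int = 0

    def __post_init__(self) -> None:
        spp = self.sampling_rate * self.drive_period
        if abs(spp - round(spp)) > 1e-9 * max(spp, 1.0) or round(spp) < 2:
            raise ConfigError(
                f"sampling_rate * drive_period = {spp} must be an integer >= 2"
            )
        if not math.isclose(
            self.drive_periods_per_bias_period * self.drive_period,
            self.bias_period,
            rel_tol=1e-9,
        ):
            raise ConfigError(
                "drive_periods_per_bias_period * drive_period must equal bias_period"
            )
        n_per = self.acquisition_length / self.drive_period
        if abs(n_per - round(n_per)) > 1e-6 or round(n_per) < 1:
            raise ConfigError(
                "acquisition_length must be a positive integer number of drive periods"
            )

    # -- derived timing ----------------------------------------------------
    @property
    def sample_interval(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def samples_per_drive_period(self) -> int:
        return round(self.sampling_rate * self.drive_period)

    @property
    def samples_per_bias_period(self) -> int:
        return self.samples_per_drive_period * self.drive_periods_per_bias_period

    @property
    def drive_frequency(self) -> float:
        return 1.0 / self.drive_period

    @property
    def bias_frequency(self) -> float:
        return 1.0 / self.bias_period

    @property
    def n_drive_periods(self) -> int:
        return round(self.acquisition_length / self.drive_period)

    @property
    def n_samples(self) -> int:
        return self.samples_per_drive_period * self.n_drive_periods

    def with_(self, **kwargs) -> "AcquisitionConfig":
        return replace(self, **kwargs)

    # -- mode presets ------------------------------------------------------
    @classmethod
    def spectroscopy(cls, n_drive_periods: int = 2000, **kwargs) -> "AcquisitionConfig":
        """10 mT drive, no bias; ``n_drive_periods`` of data per measurement."""
        return cls(acquisition_length=n_drive_periods * 42e-6, **kwargs)

    @classmethod
    def magnetometry(cls, n_bias_periods: int = 24, **kwargs) -> "AcquisitionConfig":
        """1 mT drive probing field, 50 mT bias, ~2 s of data (24 bias periods)."""
        kwargs.setdefault("drive_amplitude", 1.0)
        kwargs.setdefault("bias_amplitude", 50.0)
        return cls(acquisition_length=n_bias_periods * 84e-3, **kwargs)

    @classmethod
    def system_matrix(cls, n_bias_periods: int = 24, **kwargs) -> "AcquisitionConfig":
        """Imaging-amplitude drive (10 mT) with the 50 mT bias sweep."""
        kwargs.setdefault("drive_amplitude", 10.0)
        kwargs.setdefault("bias_amplitude", 50.0)
        return cls(acquisition_length=n_bias_periods * 84e-3, **kwargs)


@dataclass(frozen=True)
class DriftModel:
    """Slow per-measurement instability of the drive/receive chain.

    The hardware's stability target is a 0.1% magnitude drift and 1 mrad
    phase drift per 100 measurements; those are the defaults, expressed per
    measurement.  Measurement ``j`` scales the coherent (moment +
    feedthrough) signal content by ``(1 + a j) exp(i p j)``.
    """

    amplitude_drift_rate: float = 1e-5
    phase_drift_rate: float = 1e-5
    additive_baseline: np.ndarray | None = None

    def scale(self, index: int) -> complex:
        return (1.0 + self.amplitude_drift_rate * index) * np.exp(
            1j * self.phase_drift_rate * index
        )

    @classmethod
    def none(cls) -> "DriftModel":
        return cls(0.0, 0.0, None)


@dataclass(frozen=True)
class InstrumentModel:
    """Receive chain and parasitics: everything between moment and recorded volts.

    Parameters
    ----------
    tf : TransferFunction
        Moment-to-voltage response of the receive chain.
    drift : DriftModel
        Per-measurement complex drift of the coherent signal content.
    noise_density : float
        White voltage-noise density at the recorded output, V/sqrt(Hz).
    feedthrough_moment : float
        Equivalent moment of the residual drive feedthrough at 10 mT drive,
        Am^2; scaled linearly with the actual drive amplitude.
    feedthrough_third_dbc : float
        Drive third-harmonic contamination relative to the fundamental
        (amplitude dB; the device's measured purity is about -108 dBc).
    drive_coil_sensitivity : float
        Drive field per unit drive current, mT/A (drive-monitor channel).
    bias_coil_sensitivity : float
        Bias field per unit bias current, mT/A (bias-monitor channel).
    bmon_gain : float
        Field-monitor coil gain, V per (mT/s): the BMon channel records
        ``bmon_gain * dB/dt`` of the total applied field.
    """

    tf: TransferFunction
    drift: DriftModel = field(default_factory=DriftModel)
    noise_density: float = 3.3e-9
    feedthrough_moment: float = 7.5e-5
    feedthrough_third_dbc: float = -108.0
    drive_coil_sensitivity: float = 0.5
    bias_coil_sensitivity: float = 9.36
    bmon_gain: float = 9e-7

    @classmethod
    def ideal(cls, tf: TransferFunction | None = None) -> "InstrumentModel":
        """Noiseless, drift-free, feedthrough-free chain (round-trip testing)."""
        return cls(
            tf=tf if tf is not None else TransferFunction.parametric(),
            drift=DriftModel.none(),
            noise_density=0.0,
            feedthrough_moment=0.0,
        )


@dataclass
class Measurement:
    """One recorded acquisition: all channels plus its schedule annotations."""

    rx_voltage: np.ndarray
    drive_monitor: np.ndarray
    bias_monitor: np.ndarray
    bmon: np.ndarray
    sample_state: str
    index: int

    def __post_init__(self) -> None:
        if self.sample_state not in ("in", "out"):
            raise ValueError("sample_state must be 'in' or 'out'")
        n = self.rx_voltage.size
        for name in ("drive_monitor", "bias_monitor", "bmon"):
            if getattr(self, name).size != n:
                raise ValueError("all channels must share the same length")


@dataclass
class MeasurementSet:
    """Ordered measurements sharing one acquisition config and receive chain."""

    config: AcquisitionConfig
    instrument: InstrumentModel
    measurements: list[Measurement]
    seed: int
    particle: ParticleModel | None = None

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def sample_states(self) -> list[str]:
        return [m.sample_state for m in self.measurements]


@dataclass(frozen=True)
class SweepRecord:
    """One calibration-sweep point: test-coil current and resulting voltage."""

    frequency: float
    current: np.ndarray
    rx_voltage: np.ndarray
    sample_interval: float
    n_cycles: int
    turns: int
    area: float


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------

def make_drive_waveform(
    config: AcquisitionConfig,
    *,
    contamination_dbc: float | None = None,
) -> FieldWaveform:
    """Drive-field waveform: cosine at the drive frequency, mT.

    Phase is zero at t=0 (field at its positive peak).  If
    ``contamination_dbc`` is given, a third-harmonic component at that
    amplitude level (dB relative to the fundamental) is added, emulating
    residual drive distortion.
    """
    n = config.n_samples
    t = np.arange(n) * config.sample_interval
    w0 = 2.0 * np.pi * config.drive_frequency
    samples = config.drive_amplitude * np.cos(w0 * t)
    if contamination_dbc is not None and config.drive_amplitude > 0:
        samples = samples + (
            config.drive_amplitude * 10.0 ** (contamination_dbc / 20.0)
        ) * np.cos(3.0 * w0 * t)
    return FieldWaveform(samples, config.sample_interval, config.samples_per_drive_period)


def make_bias_waveform(config: AcquisitionConfig) -> FieldWaveform:
    """Bias-field waveform: sine at the bias frequency, mT.

    A sine (zero at t=0) keeps the first recorded samples near zero bias,
    mirroring the AC-coupled bias amplifier spinning up from rest.
    """
    n = config.n_samples
    t = np.arange(n) * config.sample_interval
    samples = config.bias_amplitude * np.sin(2.0 * np.pi * config.bias_frequency * t)
    periodicity = min(config.samples_per_bias_period, n)
    if n % periodicity != 0:
        periodicity = config.samples_per_drive_period
    return FieldWaveform(samples, config.sample_interval, periodicity)


def total_field_waveform(config: AcquisitionConfig, **drive_kwargs) -> FieldWaveform:
    """Drive plus bias field on the shared sampling grid, mT."""
    drive = make_drive_waveform(config, **drive_kwargs)
    if config.bias_amplitude == 0.0:
        return drive
    bias = make_bias_waveform(config)
    periodicity = max(drive.periodicity, bias.periodicity)
    if drive.samples.size % periodicity != 0:
        periodicity = drive.periodicity
    return FieldWaveform(drive.samples + bias.samples, config.sample_interval, periodicity)


# ---------------------------------------------------------------------------
# receive synthesis
# ---------------------------------------------------------------------------

def _noise(rng: np.random.Generator | None, density: float, fs: float, n: int) -> np.ndarray:
    if rng is None or density == 0.0:
        return np.zeros(n)
    sigma = density * np.sqrt(fs / 2.0)
    return rng.normal(0.0, sigma, n)


def _feedthrough_moment_waveform(
    config: AcquisitionConfig, instrument: InstrumentModel
) -> np.ndarray:
    """Residual drive coupling expressed as an equivalent moment series, Am^2."""
    amp = instrument.feedthrough_moment * (config.drive_amplitude / 10.0)
    if amp == 0.0:
        return np.zeros(config.n_samples)
    t = np.arange(config.n_samples) * config.sample_interval
    w0 = 2.0 * np.pi * config.drive_frequency
    third = amp * 10.0 ** (instrument.feedthrough_third_dbc / 20.0)
    return amp * np.cos(w0 * t) + third * np.cos(3.0 * w0 * t)


def synthesize_rx(
    moment: np.ndarray,
    tf: TransferFunction,
    *,
    sampling_rate: float,
    drift_scale: complex = 1.0 + 0.0j,
    noise_density: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Receive voltage induced by a moment waveform, V.

    Applies the transfer function spectrally (exact for the periodic,
    band-limited signals this instrument produces), scales the coherent
    content by ``drift_scale`` (magnitude drift and common phase rotation),
    and adds white Gaussian voltage noise.
    """
    m = np.asarray(moment, dtype=float)
    n = m.size
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    spectrum = np.fft.rfft(m) * tf(freqs) * drift_scale
    v = np.fft.irfft(spectrum, n=n)
    return v + _noise(rng, noise_density, sampling_rate, n)


def _measurement(
    config: AcquisitionConfig,
    instrument: InstrumentModel,
    moment: np.ndarray,
    state: str,
    index: int,
    rng: np.random.Generator | None,
    field_total: np.ndarray,
    drive_field: np.ndarray,
    bias_field: np.ndarray,
) -> Measurement:
    total_moment = moment + _feedthrough_moment_waveform(config, instrument)
    rx = synthesize_rx(
        total_moment,
        instrument.tf,
        sampling_rate=config.sampling_rate,
        drift_scale=instrument.drift.scale(index),
        noise_density=instrument.noise_density,
        rng=rng,
    )
    dbdt = np.gradient(field_total, config.sample_interval)
    return Measurement(
        rx_voltage=rx,
        drive_monitor=drive_field / instrument.drive_coil_sensitivity,
        bias_monitor=bias_field / instrument.bias_coil_sensitivity,
        bmon=instrument.bmon_gain * dbdt,
        sample_state=state,
        index=index,
    )


def synthesize_in_out_run(
    particle: ParticleModel,
    config: AcquisitionConfig,
    instrument: InstrumentModel,
    *,
    seed: int | None = None,
    pattern: tuple[str, ...] = IN_OUT_PATTERN,
) -> MeasurementSet:
    """Full in/out spectroscopy run: the 55-measurement out/in schedule.

    Sample-in measurements contain the particle's steady-state response;
    every measurement contains feedthrough, drift (advancing monotonically
    across the run), and noise.  Each measurement draws from its own
    deterministic random stream derived from ``seed`` and its index, so any
    single measurement can be regenerated without replaying the run.
    """
    if seed is None:
        seed = config.random_seed
    drive = make_drive_waveform(config)
    bias = make_bias_waveform(config) if config.bias_amplitude else None
    field_total = drive.samples + (bias.samples if bias is not None else 0.0)
    moment_in = magnetization_response(drive, particle)
    zeros = np.zeros_like(moment_in)
    bias_field = bias.samples if bias is not None else zeros
    measurements = []
    for j, state in enumerate(pattern):
        rng = np.random.default_rng([seed, j]) if instrument.noise_density else None
        moment = moment_in if state == "in" else zeros
        measurements.append(
            _measurement(
                config, instrument, moment, state, j, rng,
                field_total, drive.samples, bias_field,
            )
        )
    return MeasurementSet(config, instrument, measurements, seed, particle)


def synthesize_quasistatic_run(
    particle: ParticleModel,
    config: AcquisitionConfig,
    instrument: InstrumentModel,
    *,
    seed: int | None = None,
    include_baseline: bool = True,
) -> MeasurementSet:
    """Magnetometry / system-matrix run: drive plus slow bias sweep.

    Returns one long sample-in measurement (and, by default, a matched
    sample-out baseline measurement first) covering an integer number of
    bias periods, so the simulated response is the exact periodic steady
    state of the biased drive.
    """
    if seed is None:
        seed = config.random_seed
    fw = total_field_waveform(config)
    drive = make_drive_waveform(config)
    bias = make_bias_waveform(config)
    moment = magnetization_response(fw, particle, max_support_periods=None)
    measurements = []
    if include_baseline:
        rng = np.random.default_rng([seed, 0]) if instrument.noise_density else None
        measurements.append(
            _measurement(
                config, instrument, np.zeros_like(moment), "out", 0, rng,
                fw.samples, drive.samples, bias.samples,
            )
        )
    rng = np.random.default_rng([seed, 1]) if instrument.noise_density else None
    measurements.append(
        _measurement(
            config, instrument, moment, "in", len(measurements), rng,
            fw.samples, drive.samples, bias.samples,
        )
    )
    return MeasurementSet(config, instrument, measurements, seed, particle)


def synthesize_calibration_sweep(
    tf: TransferFunction,
    frequencies,
    *,
    turns: int = 15,
    diameter: float = 5e-3,
    current_amplitude: float = 1.0,
    sampling_rate: float = 2e6,
    n_cycles: int = 50,
    noise_density: float = 0.0,
    seed: int = 0,
) -> list[SweepRecord]:
    """Frequency sweep of a known test coil through the receive chain.

    At each requested frequency (snapped to the nearest value giving an
    integer number of samples over ``n_cycles`` cycles) a sinusoidal current
    of known amplitude drives a small coil of known turns and area; the
    moment N I(t) A is pushed through the transfer function to produce the
    voltage record.  Feeding these records to ``preprocess.measure_tf``
    recovers the transfer function at the swept bins.
    """
    area = np.pi * (diameter / 2.0) ** 2
    records = []
    for i, f_req in enumerate(np.atleast_1d(frequencies)):
        n = int(round(sampling_rate * n_cycles / f_req))
        if n < 2 * n_cycles:
            raise ConfigError(f"frequency {f_req} too close to Nyquist")
        f = sampling_rate * n_cycles / n
        t = np.arange(n) / sampling_rate
        current = current_amplitude * np.cos(2.0 * np.pi * f * t)
        moment = turns * area * current
        rng = np.random.default_rng([seed, i]) if noise_density else None
        rx = synthesize_rx(
            moment, tf, sampling_rate=sampling_rate,
            noise_density=noise_density, rng=rng,
        )
        records.append(SweepRecord(f, current, rx, 1.0 / sampling_rate, n_cycles, turns, area))
    return records
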