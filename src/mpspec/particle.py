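"""Nanoparticle magnetization physics.

A superparamagnetic nanoparticle ensemble driven well below its anisotropy
barrier follows an equilibrium (adiabatic) Langevin magnetization curve; the
finite response time of the magnetic moments is folded in afterwards by
convolving that adiabatic response with a causal relaxation kernel —
either a single-time-constant exponential (Debye) or a two-pole
biexponential.  This module implements

* the Langevin function and adiabatic magnetization,
* discrete relaxation kernels with exact unit DC gain,
* the periodic steady-state convolution response,
* exact-bin harmonic spectra of periodic moment waveforms.

Fields are expressed in mT throughout (the instrument's native unit) and
moments in Am^2; the Langevin steepness ``beta`` therefore carries units of
1/mT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FieldWaveform",
    "ParticleModel",
    "langevin",
    "adiabatic_magnetization",
    "relaxation_kernel",
    "magnetization_response",
    "harmonic_spectrum",
]


class KernelSupportError(ValueError):
    """Relaxation kernel rings for longer than the physically sensible limit."""


@dataclass(frozen=True)
class FieldWaveform:
    """Uniformly sampled applied-field waveform, periodic over ``periodicity`` samples.

    samples are in mT; ``sample_interval`` in seconds; ``periodicity`` is the
    number of samples in one fundamental period and must divide the record
    length, so that every period is sampled identically (no spectral leakage
    at the harmonic bins).
    """

    samples: np.ndarray
    sample_interval: float
    periodicity: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.periodicity <= 0:
            raise ValueError("periodicity must be a positive integer")
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if samples.size % self.periodicity != 0:
            raise ValueError(
                "record length must be an integer multiple of the periodicity"
            )

    @property
    def n_periods(self) -> int:
        return self.samples.size // self.periodicity

    @property
    def fundamental_frequency(self) -> float:
        """Frequency of the fundamental period, Hz."""
        return 1.0 / (self.periodicity * self.sample_interval)

    @property
    def duration(self) -> float:
        return self.samples.size * self.sample_interval

    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.sample_interval


@dataclass(frozen=True)
class ParticleModel:
    """Langevin particle with an optional relaxation kernel.

    Parameters
    ----------
    saturation_moment : float
        Total saturation moment of the sample, Am^2.
    beta : float
        Langevin steepness applied to the field in mT: m_ad = M_sat L(beta H).
    kernel : {"none", "debye", "two_pole"}
        Relaxation kernel family.
    tau_eff : float
        Debye effective time constant, seconds.
    tau1, tau2 : float
        Two-pole time constants, seconds (must differ).
    """

    saturation_moment: float
    beta: float
    kernel: str = "none"
    tau_eff: float | None = None
    tau1: float | None = None
    tau2: float | None = None

    def __post_init__(self) -> None:
        if self.saturation_moment < 0:
            raise ValueError("saturation_moment must be non-negative")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.kernel not in ("none", "debye", "two_pole"):
            raise ValueError(f"unknown kernel family: {self.kernel!r}")
        if self.kernel == "debye":
            if self.tau_eff is None or self.tau_eff <= 0:
                raise ValueError("debye kernel requires tau_eff > 0")
        if self.kernel == "two_pole":
            if self.tau1 is None or self.tau2 is None:
                raise ValueError("two_pole kernel requires tau1 and tau2")
            if self.tau1 <= 0 or self.tau2 <= 0:
                raise ValueError("two_pole time constants must be positive")
            if self.tau1 == self.tau2:
                raise ValueError("two_pole time constants must differ")

    def replace(self, **kwargs) -> "ParticleModel":
        from dataclasses import replace

        return replace(self, **kwargs)


def langevin(x):
    """Langevin function L(x) = coth(x) - 1/x.

    Odd, bounded in (-1, 1), with the removable singularity at zero handled
    by the series L(x) = x/3 - x^3/45 + O(x^5) for |x| < 1e-4 (the switch
    point keeps the truncation error below double-precision roundoff).
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = xs / 3.0 - xs**3 / 45.0
    xl = x[~small]
    out[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
    if out.ndim == 0:
        return float(out)
    return out


def adiabatic_magnetization(field: FieldWaveform, particle: ParticleModel) -> np.ndarray:
    """Relaxation-free moment waveform M_ad(t) = M_sat L(beta H(t)), Am^2."""
    return particle.saturation_moment * langevin(particle.beta * field.samples)


def _kernel_samples(particle: ParticleModel, time_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(time_grid, dtype=float)
    if particle.kernel == "debye":
        tau = particle.tau_eff
        k = np.exp(-t / tau) / tau
        # causal trapezoid: the jump at t=0 carries half weight, which keeps
        # the discrete frequency response second-order accurate in dt
        if t.size and t[0] == 0.0:
            k[0] *= 0.5
        return k
    if particle.kernel == "two_pole":
        t1, t2 = particle.tau1, particle.tau2
        return (np.exp(-t / t1) - np.exp(-t / t2)) / (t1 - t2)
    raise ValueError("particle has no relaxation kernel")


def kernel_support(particle: ParticleModel, rtol: float = 1e-12) -> float:
    """Duration after which the kernel amplitude has decayed below rtol, seconds."""
    if particle.kernel == "debye":
        return particle.tau_eff * np.log(1.0 / rtol)
    if particle.kernel == "two_pole":
        return max(particle.tau1, particle.tau2) * np.log(1.0 / rtol)
    return 0.0


def relaxation_kernel(particle: ParticleModel, time_grid) -> np.ndarray:
    """Discrete causal relaxation kernel on ``time_grid``, renormalized to unit DC gain.

    The continuous kernels integrate to one; after sampling, the samples are
    rescaled so that ``sum(kernel) * dt == 1`` exactly, which preserves the
    static magnetization at any sampling interval.  The two-pole kernel is
    the normalized biexponential difference
    ``(exp(-t/tau1) - exp(-t/tau2)) / (tau1 - tau2)``, whose limit for
    tau2 -> tau1 is the critically damped shape ``t exp(-t/tau) / tau^2``.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise ValueError("time_grid must be a 1-D array with at least two samples")
    dt = t[1] - t[0]
    min_tau = {
        "debye": particle.tau_eff,
        "two_pole": min(particle.tau1, particle.tau2) if particle.kernel == "two_pole" else None,
    }.get(particle.kernel)
    if min_tau is None:
        raise ValueError("particle has no relaxation kernel")
    if dt > min_tau / 5.0:
        warnings.warn(
            f"kernel under-resolved: dt={dt:.3g}s exceeds tau/5={min_tau / 5:.3g}s",
            RuntimeWarning,
            stacklevel=2,
        )
    k = _kernel_samples(particle, t)
    total = k.sum() * dt
    if total <= 0:
        raise ValueError("kernel has non-positive integral on this grid")
    return k / total


def magnetization_response(
    field: FieldWaveform,
    particle: ParticleModel,
    *,
    max_support_periods: float | None = 10.0,
) -> np.ndarray:
    """Periodic steady-state moment response M(t) = (M_ad * r)(t), Am^2.

    The record is treated as one period of an infinitely repeating waveform,
    so the convolution with the relaxation kernel is evaluated circularly:
    the kernel (truncated where it has decayed to 1e-12 of its peak) is
    folded into the record length and applied by FFT.  For a truly periodic
    drive this *is* the steady-state response — no transient settling is
    simulated or discarded.

    ``max_support_periods`` guards against kernels that ring for many drive
    periods (unphysical for the MPI regime); pass ``None`` to disable when
    deliberately probing slow kernels.
    """
    m_ad = adiabatic_magnetization(field, particle)
    if particle.kernel == "none":
        return m_ad
    dt = field.sample_interval
    support = kernel_support(particle)
    if max_support_periods is not None:
        period = field.periodicity * dt
        if support > max_support_periods * period:
            raise KernelSupportError(
                f"kernel support {support:.3g}s exceeds {max_support_periods} "
                f"drive periods ({max_support_periods * period:.3g}s)"
            )
    n = m_ad.size
    n_k = int(np.ceil(support / dt)) + 1
    t_k = np.arange(n_k) * dt
    k = relaxation_kernel(particle, t_k) if n_k >= 2 else np.array([1.0 / dt])
    # fold the kernel into the record length: exact for periodic input
    k_folded = np.zeros(n)
    np.add.at(k_folded, np.arange(n_k) % n, k)
    spectrum = np.fft.rfft(m_ad) * np.fft.rfft(k_folded) * dt
    return np.fft.irfft(spectrum, n=n)


def harmonic_spectrum(moment, periodicity: int, n_harmonics: int | None = None) -> np.ndarray:
    """Complex amplitudes of a periodic waveform at its harmonics k f0, k = 1..K.

    Scaled so a unit-amplitude cosine at harmonic k reports amplitude 1 + 0j
    (and a unit sine reports -1j).  The record must contain an integer number
    of periods; off-harmonic content then falls on other DFT bins and cannot
    leak into the reported values.
    """
    m = np.asarray(moment, dtype=float)
    if m.ndim != 1:
        raise ValueError("moment must be a 1-D array")
    if periodicity <= 0 or m.size % periodicity != 0:
        raise ValueError("record length must be an integer multiple of the periodicity")
    n_periods = m.size // periodicity
    nyquist_harmonic = periodicity // 2
    if n_harmonics is None:
        n_harmonics = nyquist_harmonic
    if n_harmonics > nyquist_harmonic:
        raise ValueError(
            f"harmonic {n_harmonics} exceeds the Nyquist harmonic {nyquist_harmonic}"
        )
    spectrum = np.fft.rfft(m)
    bins = n_periods * np.arange(1, n_harmonics + 1)
    return 2.0 * spectrum[bins] / m.size


def harmonic_ratio(moment, periodicity: int, k_num: int = 3, k_den: int = 1) -> float:
    """Magnitude ratio of harmonic ``k_num`` to harmonic ``k_den`` (e.g. S_3/1)."""
    spec = harmonic_spectrum(moment, periodicity, max(k_num, k_den))
    return abs(spec[k_num - 1]) / abs(spec[k_den - 1])
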