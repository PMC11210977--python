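"""Receive-chain transfer function: magnetic moment in, preamp voltage out.

An inductive receive chain is, to first order, a differentiator (Faraday's
law), shaped by whatever filtering sits between coil and digitizer — here a
deliberately weak notch at the drive frequency that knocks the enormous
feedthrough component down before amplification.  The transfer function
TF(f) has units of volts per Am^2 and is what converts between the recorded
voltage and the sample's magnetic moment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TransferFunction"]


@dataclass(frozen=True)
class TransferFunction:
    """Complex receive response sampled on a frequency grid, V per Am^2.

    Evaluation between grid points interpolates linearly in the real and
    imaginary parts separately; negative frequencies return the complex
    conjugate so that correcting a real signal yields a real signal.
    """

    frequency_grid: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequency_grid, dtype=float)
        r = np.asarray(self.response, dtype=complex)
        if f.ndim != 1 or f.size != r.size or f.size < 2:
            raise ValueError("frequency grid and response must be matching 1-D arrays")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if f[0] < 0:
            raise ValueError("grid must cover non-negative frequencies only")
        object.__setattr__(self, "frequency_grid", f)
        object.__setattr__(self, "response", r)

    @classmethod
    def parametric(
        cls,
        *,
        gain: float = 5e-4,
        notch_frequency: float | None = 1.0 / 42e-6,
        notch_depth_db: float = 30.0,
        notch_q: float = 5.0,
        max_frequency: float = 1e6,
        n_points: int = 8193,
    ) -> "TransferFunction":
        """Idealized receive chain: flat-gain differentiator times a notch.

        ``gain`` is in V s per Am^2 (so the response magnitude at frequency f
        away from the notch is ``gain * 2 pi f``).  The notch is a
        second-order band-stop of finite depth ``notch_depth_db`` (amplitude
        dB) centred on the drive frequency; pass ``notch_frequency=None`` for
        a pure differentiator.
        """
        f = np.linspace(0.0, max_frequency, n_points)
        response = gain * (2j * np.pi * f)
        if notch_frequency is not None:
            depth = 10.0 ** (-notch_depth_db / 20.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                x = f / notch_frequency - notch_frequency / np.where(f > 0, f, np.inf)
            response = response * (depth + 1j * notch_q * x) / (1.0 + 1j * notch_q * x)
        return cls(f, response)

    def __call__(self, frequencies) -> np.ndarray:
        """Evaluate the response at arbitrary frequencies (conjugate-symmetric)."""
        f = np.atleast_1d(np.asarray(frequencies, dtype=float))
        af = np.abs(f)
        if np.any(af > self.frequency_grid[-1] * (1 + 1e-12)):
            raise ValueError("frequency outside the calibrated grid")
        re = np.interp(af, self.frequency_grid, self.response.real)
        im = np.interp(af, self.frequency_grid, self.response.imag)
        out = re + 1j * np.sign(f) * im
        # sign(0) = 0 would null a purely real DC response; restore it
        out = np.where(f == 0, re + 0j, out)
        return out if np.ndim(frequencies) else out[0]

    def valid_at(self, frequencies, rel_threshold: float = 1e-9) -> np.ndarray:
        """Boolean mask of bins where the response is usable for correction.

        A bin is invalid where the response magnitude is below
        ``rel_threshold`` times the grid maximum (e.g. DC for a
        differentiator); correction zeroes such bins instead of dividing.
        """
        mag = np.abs(self(np.atleast_1d(frequencies)))
        return mag > rel_threshold * np.abs(self.response).max()
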