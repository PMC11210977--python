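"""Quasistatic modes: spectrogram magnetometry and 1-D system-matrix extraction.

With a weak drive tone probing the sample while a slow bias field sweeps its
operating point, the short-time amplitude of the drive-frequency line is the
differential susceptibility chi(H) = dM/dH at the instantaneous bias; its
integral (with a zero-mean-magnetization boundary condition) is the
quasistatic magnetization curve.  Run at full imaging drive amplitude and
keep all harmonic lines instead of just the fundamental, and the same
machinery yields the 1-D MPI system matrix: harmonic response versus bias
field, i.e. versus emulated position in an imaging gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import curve_fit
from scipy.signal.windows import hann

from .particle import langevin

__all__ = [
    "SpectrogramLines",
    "SusceptibilityCurve",
    "SystemMatrix1D",
    "spectrogram_lines",
    "fold_lines_by_bias",
    "susceptibility_vs_bias",
    "integrate_susceptibility",
    "fwhm",
    "estimate_langevin",
    "system_matrix",
]


@dataclass
class SpectrogramLines:
    """Time-resolved complex amplitude at selected drive harmonics.

    ``values`` has shape (n_frames, n_harmonics); ``frame_times`` marks each
    window center in seconds.  Amplitudes are normalized so a stationary
    unit-amplitude cosine at a harmonic reports magnitude 1.
    """

    frame_times: np.ndarray
    values: np.ndarray
    harmonics: np.ndarray
    hop: int
    sample_interval: float
    frame_starts: np.ndarray
    window: np.ndarray


def spectrogram_lines(
    series: np.ndarray,
    samples_per_drive_period: int,
    *,
    sample_interval: float,
    window_periods: int = 4,
    harmonics=(1,),
    overlap: float = 0.5,
) -> SpectrogramLines:
    """Short-time Fourier amplitudes at drive harmonics (Hanning window).

    The window spans ``window_periods`` drive periods (default 4) with 50%
    overlap, so each harmonic falls on an exact window bin and the hop is a
    whole number of drive periods — every frame sees the drive at the same
    phase, which keeps the complex frames directly comparable.
    """
    x = np.asarray(series, dtype=float)
    p = samples_per_drive_period
    length = window_periods * p
    if length > x.size:
        raise ValueError("window longer than the record")
    hop = int(round(length * (1.0 - overlap)))
    if hop % p != 0:
        raise ValueError("overlap must place hops on whole drive periods")
    harmonics = np.asarray(harmonics, dtype=int)
    if np.any(harmonics < 1) or np.any(harmonics * window_periods >= length // 2 + 1):
        raise ValueError("harmonic outside the window band")
    win = hann(length, sym=False)
    n_frames = (x.size - length) // hop + 1
    starts = hop * np.arange(n_frames)
    frames = np.lib.stride_tricks.sliding_window_view(x, length)[starts]
    spectra = np.fft.rfft(frames * win, axis=1)
    bins = harmonics * window_periods
    values = 2.0 * spectra[:, bins] / win.sum()
    frame_times = (starts + length / 2.0) * sample_interval
    return SpectrogramLines(frame_times, values, harmonics, hop, sample_interval, starts, win)


def fold_lines_by_bias(
    lines: SpectrogramLines,
    bias_field: np.ndarray,
    *,
    bias_period: float,
    discard_bias_periods: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Crop, fold by bias period, and average the spectrogram lines.

    The first ``discard_bias_periods`` bias periods are dropped (particle
    and electronics settling); the remaining complete periods are folded
    onto one bias cycle and averaged.  Returns ``(bias_per_frame, values)``
    where both cover exactly one bias cycle.
    """
    frames_per_bias = bias_period / (lines.hop * lines.sample_interval)
    if abs(frames_per_bias - round(frames_per_bias)) > 1e-9:
        raise ValueError("bias period must be a whole number of frame hops")
    fpb = round(frames_per_bias)
    # window-weighted mean bias per frame: the field each frame's amplitude
    # estimate actually averages over, not just the centre value
    w = lines.window / lines.window.sum()
    bias_frames = np.lib.stride_tricks.sliding_window_view(
        np.asarray(bias_field, dtype=float), lines.window.size
    )[lines.frame_starts]
    bias_at_frames = bias_frames @ w
    start = int(np.searchsorted(lines.frame_times, discard_bias_periods * bias_period))
    n_cycles = (lines.values.shape[0] - start) // fpb
    if n_cycles < 2:
        raise ValueError(
            f"only {n_cycles} complete bias periods remain after discarding "
            f"{discard_bias_periods}; need at least 2"
        )
    stop = start + n_cycles * fpb
    values = lines.values[start:stop].reshape(n_cycles, fpb, -1).mean(axis=0)
    bias = bias_at_frames[start:stop].reshape(n_cycles, fpb).mean(axis=0)
    return bias, values


def _bin_by_bias(
    bias: np.ndarray, values: np.ndarray, n_bins: int, bias_amplitude: float
) -> tuple[np.ndarray, np.ndarray]:
    """Average folded cycle points into uniform bias-field bins (merges half-cycles)."""
    edges = np.linspace(-bias_amplitude, bias_amplitude, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(bias, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    out = np.empty((n_bins, values.shape[1]), dtype=complex)
    for c in range(values.shape[1]):
        sums = np.bincount(idx, weights=values[:, c].real, minlength=n_bins).astype(
            complex
        )
        sums += 1j * np.bincount(idx, weights=values[:, c].imag, minlength=n_bins)
        out[:, c] = sums
    good = counts > 0
    out[good] /= counts[good, None]
    return centers[good], out[good]


@dataclass
class SusceptibilityCurve:
    """Differential susceptibility versus bias field.

    ``susceptibility`` is complex, in Am^2 per mT (per kg Fe if
    ``per_mass``); the grid is ascending in bias field with the rising and
    falling bias half-cycles merged.
    """

    bias_field: np.ndarray
    susceptibility: np.ndarray
    drive_amplitude: float
    per_mass: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "H_mT": self.bias_field,
                "chi_real": self.susceptibility.real,
                "chi_imag": self.susceptibility.imag,
            }
        )


def susceptibility_vs_bias(
    lines: SpectrogramLines,
    bias_field: np.ndarray,
    *,
    bias_period: float,
    drive_amplitude: float,
    discard_bias_periods: int = 10,
    n_bins: int = 101,
    average_half_cycles: bool = True,
) -> SusceptibilityCurve:
    """Susceptibility curve chi(H) from the drive-frequency spectrogram line.

    The fundamental-line amplitude divided by the drive amplitude is the
    differential susceptibility at the instantaneous bias field.  With
    ``average_half_cycles`` the rising and falling bias branches are merged
    into shared field bins (set False to expose quasistatic hysteresis: the
    branches are then binned separately and concatenated in time order).
    """
    bias_amp = float(np.max(np.abs(bias_field)))
    bias, values = fold_lines_by_bias(
        lines, bias_field, bias_period=bias_period,
        discard_bias_periods=discard_bias_periods,
    )
    fundamental = values[:, [int(np.argmax(lines.harmonics == 1))]]
    if average_half_cycles:
        grid, binned = _bin_by_bias(bias, fundamental, n_bins, bias_amp)
        chi = binned[:, 0] / drive_amplitude
        return SusceptibilityCurve(grid, chi, drive_amplitude)
    half = bias.size // 2
    parts = []
    for sl in (slice(0, half), slice(half, None)):
        grid, binned = _bin_by_bias(bias[sl], fundamental[sl], n_bins, bias_amp)
        parts.append((grid, binned[:, 0] / drive_amplitude))
    grid = np.concatenate([p[0] for p in parts])
    chi = np.concatenate([p[1] for p in parts])
    return SusceptibilityCurve(grid, chi, drive_amplitude)


def integrate_susceptibility(curve: SusceptibilityCurve) -> pd.DataFrame:
    """Quasistatic magnetization curve m(H): cumulative integral of chi over H.

    Integrates the in-phase (real) susceptibility with the boundary
    condition that the mean magnetization over the swept field range is
    zero — the absolute level is unobservable through an inductive chain.
    Returns a DataFrame with columns ``H_mT`` and ``m_Am2``.
    """
    h = curve.bias_field
    order = np.argsort(h)
    h = h[order]
    chi = curve.susceptibility.real[order]
    m = cumulative_trapezoid(chi, h, initial=0.0)
    m = m - np.trapezoid(m, h) / (h[-1] - h[0])
    return pd.DataFrame({"H_mT": h, "m_Am2": m})


def fwhm(curve: SusceptibilityCurve) -> float:
    """Full width at half maximum of |chi|(H), mT, by linear interpolation.

    Requires a unimodal magnitude curve whose peak is interior to the swept
    range; raises with diagnostics otherwise.
    """
    h = curve.bias_field
    mag = np.abs(curve.susceptibility)
    i_pk = int(np.argmax(mag))
    if i_pk in (0, mag.size - 1):
        raise ValueError(f"peak at the edge of the bias range (H = {h[i_pk]:.3g} mT)")
    half = mag[i_pk] / 2.0
    left = np.flatnonzero(mag[:i_pk] < half)
    right = np.flatnonzero(mag[i_pk:] < half)
    if left.size == 0 or right.size == 0:
        raise ValueError("curve does not fall below half maximum on both sides")
    iL = left[-1]
    hL = np.interp(half, [mag[iL], mag[iL + 1]], [h[iL], h[iL + 1]])
    iR = i_pk + right[0]
    hR = np.interp(half, [mag[iR], mag[iR - 1]], [h[iR], h[iR - 1]])
    if np.any(mag[:iL] > half) or np.any(mag[iR + 1 :] > half):
        raise ValueError("magnitude curve is not unimodal (re-crosses half maximum)")
    return float(hR - hL)


def estimate_langevin(mh: pd.DataFrame) -> tuple[float, float]:
    """Fit M_sat L(beta H) to a magnetization curve; returns (msat, beta).

    The integrated curve is zero-mean rather than zero at H=0, so a free
    offset is included in the fit and discarded.
    """
    h = mh["H_mT"].to_numpy()
    m = mh["m_Am2"].to_numpy()

    def model(hh, msat, beta, offset):
        return msat * langevin(beta * hh) + offset

    msat0 = float(np.max(np.abs(m))) or 1.0
    beta0 = 2.0 / max(np.max(np.abs(h)), 1e-6)
    popt, _ = curve_fit(model, h, m, p0=[msat0, beta0, 0.0], maxfev=20000)
    return float(popt[0]), float(abs(popt[1]))


@dataclass
class SystemMatrix1D:
    """Complex harmonic response versus bias field: the 1-D MPI system matrix.

    ``matrix`` has shape (n_bias, n_harmonics) with harmonic k in column
    k-1; ``magnitude`` and ``unwrapped_phase`` (unwrapped along the bias
    axis) are the conventional display views.
    """

    bias_field: np.ndarray
    matrix: np.ndarray
    harmonics: np.ndarray
    drive_amplitude: float

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.matrix)

    @property
    def unwrapped_phase(self) -> np.ndarray:
        return np.unwrap(np.angle(self.matrix), axis=0)

    def harmonic_row(self, k: int) -> np.ndarray:
        return self.matrix[:, int(np.argmax(self.harmonics == k))]


def system_matrix(
    lines: SpectrogramLines,
    bias_field: np.ndarray,
    *,
    bias_period: float,
    drive_amplitude: float,
    discard_bias_periods: int = 10,
    n_bins: int = 101,
) -> SystemMatrix1D:
    """Fold every harmonic spectrogram line into a bias-field grid.

    Identical processing to the magnetometry mode except that all requested
    harmonic lines are kept; each matrix column is that harmonic's complex
    response as a function of the (quasistatic) bias field.
    """
    bias_amp = float(np.max(np.abs(bias_field)))
    bias, values = fold_lines_by_bias(
        lines, bias_field, bias_period=bias_period,
        discard_bias_periods=discard_bias_periods,
    )
    grid, binned = _bin_by_bias(bias, values, n_bins, bias_amp)
    return SystemMatrix1D(grid, binned, lines.harmonics.copy(), drive_amplitude)
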