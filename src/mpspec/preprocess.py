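"""Receive-signal conditioning: baseline, transfer-function correction, masking.

The raw record is a preamp voltage.  Before any mode-specific analysis it is
(i) baseline-subtracted against a matched sample-out acquisition, (ii)
divided by the receive transfer function in the frequency domain — turning
volts into a real-valued magnetic moment series, not its derivative — and,
where the analysis works on harmonics only, (iii) stripped of all
non-harmonic bins.  The drive field itself is recovered from the inductive
field-monitor (BMon) channel by cumulative trapezoidal integration.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .simulate import SweepRecord
from .transfer import TransferFunction

__all__ = [
    "MomentSeries",
    "measure_tf",
    "subtract_baseline",
    "tf_correct",
    "zero_nonharmonics",
    "integrate_bmon",
]


class MomentSeries(np.ndarray):
    """Moment time series produced by ``tf_correct`` (tagged to prevent double correction)."""

    tf_corrected = True

    def __array_finalize__(self, obj):  # keep the tag through views
        pass


def measure_tf(records: list[SweepRecord]) -> TransferFunction:
    """Transfer function from a calibration sweep: TF(f) = V(f) / (N I(f) A).

    For each sweep record, the complex amplitudes of voltage and current at
    the record's own frequency bin are extracted by exact-bin DFT and
    ratioed.  Records with vanishing current are rejected.
    """
    if len(records) < 2:
        raise ValueError("need at least two sweep frequencies")
    freqs, responses = [], []
    for rec in records:
        n = rec.current.size
        k = rec.n_cycles
        i_bin = 2.0 * np.fft.rfft(rec.current)[k] / n
        v_bin = 2.0 * np.fft.rfft(rec.rx_voltage)[k] / n
        if abs(i_bin) == 0.0:
            raise ValueError(f"zero current at {rec.frequency} Hz: bin invalid")
        freqs.append(rec.frequency)
        responses.append(v_bin / (rec.turns * i_bin * rec.area))
    order = np.argsort(freqs)
    return TransferFunction(np.asarray(freqs)[order], np.asarray(responses)[order])


def subtract_baseline(rx: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Pointwise subtraction of a matched sample-out acquisition."""
    rx = np.asarray(rx, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if rx.shape != baseline.shape:
        raise ValueError("rx and baseline must have the same shape")
    return rx - baseline


def tf_correct(
    voltage: np.ndarray,
    tf: TransferFunction,
    *,
    sampling_rate: float,
    occupied_rel: float = 1e-9,
) -> MomentSeries:
    """Convert a voltage record to a magnetic-moment record, Am^2.

    Divides the one-sided spectrum by TF(f); bins where the transfer
    function is unusable (DC for an inductive chain) are zeroed, so the
    moment's mean is not recoverable — consistent with the zero-mean
    boundary condition used throughout.  Conjugate symmetry is preserved by
    construction, so the output is exactly real.

    Raises if the transfer function vanishes on a bin that actually carries
    signal, and if handed an already-corrected series.
    """
    if getattr(voltage, "tf_corrected", False):
        raise ValueError("series is already TF-corrected; refusing to correct twice")
    v = np.asarray(voltage, dtype=float)
    n = v.size
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    spectrum = np.fft.rfft(v)
    valid = tf.valid_at(freqs)
    occupied = np.abs(spectrum) > occupied_rel * np.abs(spectrum).max()
    bad = occupied & ~valid & (freqs > 0)
    if np.any(bad):
        raise ValueError(
            f"transfer function vanishes on {bad.sum()} occupied bins "
            f"(first at {freqs[bad][0]:.6g} Hz)"
        )
    corrected = np.zeros_like(spectrum)
    corrected[valid] = spectrum[valid] / tf(freqs[valid])
    moment = np.fft.irfft(corrected, n=n)
    return moment.view(MomentSeries)


def zero_nonharmonics(
    series: np.ndarray,
    periodicity: int,
    *,
    keep: int = 39,
) -> np.ndarray:
    """Keep only the exact drive-harmonic bins k f0, k = 1..keep; zero the rest.

    The record must hold an integer number of drive periods so the harmonic
    bins are exact.  This is an orthogonal projection (idempotent), and for
    white noise it discards all power off the harmonic comb.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if periodicity <= 0 or n % periodicity != 0:
        raise ValueError("record length must be an integer multiple of the periodicity")
    n_periods = n // periodicity
    spectrum = np.fft.rfft(x)
    k_max = min(keep, periodicity // 2)
    mask = np.zeros(spectrum.size, dtype=bool)
    mask[n_periods * np.arange(1, k_max + 1)] = True
    spectrum[~mask] = 0.0
    out = np.fft.irfft(spectrum, n=n)
    return out.view(MomentSeries) if getattr(series, "tf_corrected", False) else out


def integrate_bmon(
    bmon: np.ndarray,
    *,
    sample_interval: float,
    calibration: float,
    detrend: bool = False,
) -> np.ndarray:
    """Recover the applied field (mT) from the dB/dt field-monitor channel.

    Cumulative trapezoidal integration, scaled by ``calibration`` (mT per
    integrated volt-second), then mean-removed: the drive field has no DC
    component over whole periods, which pins the integration constant.  A DC
    offset on the monitor channel integrates to a linear ramp; ``detrend``
    additionally removes the best-fit line for that case.
    """
    b = np.asarray(bmon, dtype=float)
    field = cumulative_trapezoid(b, dx=sample_interval, initial=0.0) * calibration
    if detrend:
        t = np.arange(field.size, dtype=float)
        coef = np.polynomial.polynomial.polyfit(t, field, 1)
        field = field - np.polynomial.polynomial.polyval(t, coef)
    return field - field.mean()
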