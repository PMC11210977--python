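"""Matplotlib views of the standard analysis products."""

from __future__ import annotations

import numpy as np


def plot_loop(loop, ax=None, **kwargs):
    """Hysteresis loop m(H); closes the trace for display."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    h = np.r_[loop.field, loop.field[:1]]
    m = np.r_[loop.moment, loop.moment[:1]]
    ax.plot(h, m, **kwargs)
    ax.set_xlabel("H (mT)")
    ax.set_ylabel("m (Am$^2$)")
    return ax


def plot_spectrum(glm_result, ax=None, harmonic_offset: int = 1):
    """Per-harmonic recovered amplitude with noise level, log scale."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    k = np.arange(harmonic_offset, harmonic_offset + glm_result.n_harmonics)
    ax.semilogy(k, np.abs(glm_result.signal_amplitude), "o", label="signal")
    ax.semilogy(k, glm_result.residual_sd, "s", label="noise (out residual sd)")
    ax.set_xlabel("harmonic")
    ax.set_ylabel("moment amplitude (Am$^2$)")
    ax.legend()
    return ax


def plot_susceptibility(curve, ax=None, **kwargs):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.bias_field, np.abs(curve.susceptibility), **kwargs)
    ax.set_xlabel("bias field (mT)")
    ax.set_ylabel(r"$|\chi|$ (Am$^2$/mT)")
    return ax


def plot_system_matrix(matrix, n_columns: int = 7, figsize=(14, 8)):
    """Grid of per-harmonic magnitude rows versus bias field."""
    import matplotlib.pyplot as plt

    n = matrix.harmonics.size
    n_rows = int(np.ceil(n / n_columns))
    fig, axes = plt.subplots(n_rows, n_columns, figsize=figsize, squeeze=False)
    mag = matrix.magnitude
    for i, k in enumerate(matrix.harmonics):
        ax = axes[i // n_columns][i % n_columns]
        ax.plot(matrix.bias_field, mag[:, i])
        ax.set_title(f"{k}f$_0$", fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    for j in range(n, n_rows * n_columns):
        axes[j // n_columns][j % n_columns].axis("off")
    fig.tight_layout()
    return fig
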