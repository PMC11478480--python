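"""Plotting helpers: stride-normalized loading curves, training history,
and estimated-versus-true phase traces."""

from __future__ import annotations

import numpy as np

from .signal_io import CHANNEL_NAMES


def plot_stride_curves(curves_by_wc: dict, channels=None, ax=None):
    """Mean ± SD stride-normalized curves per walking condition.

    ``curves_by_wc`` is the output of :func:`phase_features.stride_normalize`.
    """
    import matplotlib.pyplot as plt

    if channels is None:
        channels = ["R_heel", "R_cuboid", "R_meta1", "R_toe"]
    idx = [CHANNEL_NAMES.index(c) for c in channels]
    fig, axes = plt.subplots(
        len(channels), len(curves_by_wc), sharex=True, sharey=True,
        figsize=(3 * len(curves_by_wc), 2 * len(channels)), squeeze=False,
    )
    grid = None
    for col, (wc, arr) in enumerate(sorted(curves_by_wc.items())):
        grid = np.linspace(0, 100, arr.shape[1])
        mean, sd = arr.mean(axis=0), arr.std(axis=0)
        for row, j in enumerate(idx):
            a = axes[row][col]
            a.plot(grid, mean[:, j])
            a.fill_between(grid, mean[:, j] - sd[:, j], mean[:, j] + sd[:, j], alpha=0.3)
            if row == 0:
                a.set_title(wc)
            if col == 0:
                a.set_ylabel(channels[row])
    axes[-1][0].set_xlabel("gait phase (%)")
    return fig


def plot_training_history(history: list, ax=None):
    """Train/validation loss curves from a fit history."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    epochs = [h["epoch"] for h in history]
    ax.plot(epochs, [h["train_loss"] for h in history], label="train")
    ax.plot(epochs, [h["val_loss"] for h in history], label="validation")
    ax.set_xlabel("epoch")
    ax.set_ylabel("loss")
    ax.legend()
    return ax


def plot_phase_trace(time, true_phase, est_phase, valid=None, ax=None):
    """Estimated phase (points) over the ground-truth sawtooth (line)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(time, true_phase, lw=1, label="ground truth")
    est = np.asarray(est_phase, float)
    if valid is not None:
        est = np.where(valid, est, np.nan)
    ax.plot(time, est, ".", ms=2, label="estimate")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("gait phase (%)")
    ax.legend(loc="upper right")
    return ax
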