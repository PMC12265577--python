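"""Matplotlib views of training metrics, spectra and evaluation reports."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_training", "plot_psd", "plot_ablation_bars"]


def plot_training(episodes: pd.DataFrame, baseline: pd.DataFrame | None = None,
                  ax=None):
    """Per-episode mean beta power and cumulative reward curves."""
    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 3.2), constrained_layout=True)
    for df, label in ((episodes, "SEA-DBS"), (baseline, "Baseline")):
        if df is None:
            continue
        ax[0].plot(df["episode"], 1000.0 * df["mean_beta"], label=label)
        ax[1].plot(df["episode"], df["cumulative_reward"], label=label)
    ax[0].set_xlabel("episode"); ax[0].set_ylabel("beta PSD (x1000)")
    ax[1].set_xlabel("episode"); ax[1].set_ylabel("episode reward")
    ax[0].legend(frameon=False)
    return ax


def plot_psd(psd, band=(13.0, 35.0), fmax=120.0, ax=None):
    """Neuron-averaged PSD with the beta band shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2), constrained_layout=True)
    power = np.atleast_2d(psd.power).mean(axis=0)
    sel = psd.freqs <= fmax
    ax.plot(psd.freqs[sel], power[sel])
    ax.axvspan(band[0], band[1], alpha=0.15, color="tab:red")
    ax.set_xlabel("frequency (Hz)"); ax.set_ylabel("PSD")
    return ax


def plot_ablation_bars(final_betas: dict, ax=None):
    """Final mean beta power per ablation arm."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2), constrained_layout=True)
    names = list(final_betas)
    ax.bar(names, [1000.0 * final_betas[k] for k in names])
    ax.set_ylabel("final beta PSD (x1000)")
    ax.tick_params(axis="x", rotation=30)
    return ax
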