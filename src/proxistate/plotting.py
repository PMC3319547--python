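"""Minimal matplotlib views of the pipeline's summary objects."""

from __future__ import annotations

import numpy as np


def plot_interval_profile(profile, prox_bins, ax=None):
    """Whisker-box style view of a feature's per-interval distribution:
    median line, quartile band, min/max whiskers over kept intervals."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tab = profile.table
    kept = tab[tab["kept"] & (tab["count"] > 0)]
    x = prox_bins.midpoints[kept["bin"].to_numpy()]
    ax.fill_between(x, kept["q1"], kept["q3"], alpha=0.3, label="quartiles")
    ax.plot(x, kept["median"], "o-", label="median")
    ax.vlines(x, kept["min"], kept["max"], lw=0.5, color="gray")
    ax.set_xlabel("spatial proximity")
    ax.set_ylabel(profile.feature)
    ax.set_title(f"rho = {profile.rho_medians:.2f}"
                 f" (p = {profile.p_medians:.2g})")
    ax.legend()
    return ax


def plot_rmse_curve(*selection_results, baseline=None, ax=None):
    """RMSE against model size for one or more selection strategies."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for res in selection_results:
        ax.errorbar(res.curve["n_features"], res.curve["rmse_mean"],
                    yerr=res.curve["rmse_sd"], label=res.method, capsize=2)
    if baseline is not None:
        ax.axhline(baseline, ls="--", color="k", label="train-mean baseline")
    ax.set_xlabel("number of features")
    ax.set_ylabel("test RMSE")
    ax.legend()
    return ax


def plot_chimera_profile(profile, control=None, prox_bins=None, ax=None):
    """Normalized chimera fraction per kept proximity interval."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tab = profile.table.dropna(subset=["normalized_fraction"])
    x = (prox_bins.midpoints[tab["bin"].to_numpy()] if prox_bins is not None
         else np.asarray(tab["bin"]))
    ax.plot(x, tab["normalized_fraction"], "^-",
            label=f"observed (rho={profile.rho:.2f})")
    if control is not None:
        tc = control.table.dropna(subset=["normalized_fraction"])
        xc = (prox_bins.midpoints[tc["bin"].to_numpy()]
              if prox_bins is not None else np.asarray(tc["bin"]))
        ax.plot(xc, tc["normalized_fraction"], "s--",
                label=f"re-paired control (rho={control.rho:.2f})")
    ax.set_xlabel("spatial proximity")
    ax.set_ylabel("normalized chimera fraction")
    ax.legend()
    return ax
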