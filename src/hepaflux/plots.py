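"""Matplotlib views of the main results: volcano, sweep curves, clustered
heatmaps and structure-function scatter fits.  Plotting is optional; every
function returns the Axes so callers can compose figures."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["volcano", "sweep_curves", "clustered_heatmap", "regression_panel"]

_CLASS_COLORS = {"up": "tab:blue", "down": "tab:red", "sub-threshold": "gold", "ns": "lightgray"}


def volcano(differential: pd.DataFrame, ax=None):
    """log2 fold change vs -log10 adjusted p, colored by volcano class."""
    ax = ax or plt.gca()
    y = -np.log10(np.maximum(differential["p_adj"], 1e-300))
    for klass, color in _CLASS_COLORS.items():
        m = differential["class"] == klass
        ax.scatter(differential.loc[m, "log2fc"], y[m], s=6, c=color, label=klass)
    ax.axhline(-np.log10(0.05), ls="--", lw=0.5, c="k")
    for x in (-1, 1):
        ax.axvline(x, ls="--", lw=0.5, c="k")
    ax.set_xlabel("log2 fold change (case / control)")
    ax.set_ylabel("-log10 adjusted p")
    ax.legend(frameon=False, fontsize=7)
    return ax


def sweep_curves(sweeps: dict[str, pd.DataFrame], readout: str = "glucose_exchange", ax=None):
    """Overlay a sweep readout for several samples/groups."""
    ax = ax or plt.gca()
    for label, sweep in sweeps.items():
        ax.plot(sweep["glucose"], sweep[readout], label=label)
    ax.axhline(0, lw=0.5, c="k")
    ax.set_xlabel("plasma glucose (mM)")
    ax.set_ylabel(f"{readout} (µmol/h/g)")
    ax.legend(frameon=False, fontsize=7)
    return ax


def clustered_heatmap(result, ax=None):
    """Heatmap of a clustergram result in dendrogram leaf order."""
    ax = ax or plt.gca()
    z = result.standardized.loc[result.row_order, result.col_order]
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(len(z.columns)))
    ax.set_xticklabels(z.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    plt.colorbar(im, ax=ax, label="z-score")
    return ax


def regression_panel(records: pd.DataFrame, funcs: pd.DataFrame, pairs, axes=None):
    """Scatter + OLS line for (property, function) pairs on pooled samples."""
    from scipy import stats as sps

    if axes is None:
        _, axes = plt.subplots(1, len(pairs), figsize=(3.2 * len(pairs), 3))
        axes = np.atleast_1d(axes)
    for ax, (prop, fn) in zip(axes, pairs):
        x = records[prop].to_numpy(dtype=float)
        y = funcs.loc[records.index, fn].to_numpy(dtype=float)
        fit = sps.linregress(x, y)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.scatter(x, y, s=14)
        ax.plot(xs, fit.intercept + fit.slope * xs, c="tab:red")
        ax.set_xlabel(prop)
        ax.set_ylabel(fn)
        ax.set_title(f"p={fit.pvalue:.3g}, R²={fit.rvalue ** 2:.2f}", fontsize=8)
    return axes
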