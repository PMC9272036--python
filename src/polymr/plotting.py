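"""Plots of estimated causal curves and replicate-study metrics.

Matplotlib is imported lazily so the core package works without it.
"""

from __future__ import annotations

import numpy as np

from .evaluate import ReplicateSummary
from .model import CausalCurve

__all__ = ["plot_causal_curve", "plot_replicate_summary"]


def _get_axes(ax):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    return ax


def plot_causal_curve(curve: CausalCurve, truth=None, ax=None, label="PolyMR"):
    """Estimated causal function with its 95% confidence hull.

    ``truth``, if given, is a callable evaluated on the grid and anchored to
    0 at the grid's anchor (the mean exposure).
    """
    ax = _get_axes(ax)
    ax.fill_between(
        curve.grid, curve.lower95, curve.upper95, alpha=0.25, lw=0, label="95% hull"
    )
    ax.plot(curve.grid, curve.estimate, lw=1.8, label=label)
    if truth is not None:
        t = np.asarray(truth(curve.grid), dtype=float)
        ax.plot(curve.grid, t - t[len(t) // 2], ls="--", lw=1.2, label="truth")
    ax.axhline(0.0, color="0.7", lw=0.6)
    ax.set_xlabel("exposure")
    ax.set_ylabel("outcome relative to mean exposure")
    ax.legend(frameon=False)
    return ax


def plot_replicate_summary(summary: ReplicateSummary, ax=None):
    """Per-percentile bias band and, when available, CI-width calibration."""
    ax = _get_axes(ax)
    ax.plot(summary.grid, summary.mean_bias, lw=1.5, label="mean bias")
    ax.plot(summary.grid, summary.rmse, lw=1.2, ls=":", label="RMSE")
    if summary.predicted_ci_width is not None:
        ax.plot(
            summary.grid, summary.predicted_ci_width, lw=1.0, ls="--",
            label="predicted 95% width",
        )
        ax.plot(
            summary.grid, summary.empirical_ci_width, lw=1.0, ls="-.",
            label="empirical 95% width",
        )
    ax.axhline(0.0, color="0.7", lw=0.6)
    ax.set_xlabel("exposure (percentile grid)")
    ax.set_title(f"{summary.scenario_id} ({summary.method}, {summary.n_replicates} reps)")
    ax.legend(frameon=False, fontsize=8)
    return ax
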