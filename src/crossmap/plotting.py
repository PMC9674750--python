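"""Plotting helpers for mapping-performance results."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_condition_summary(summary: pd.DataFrame, ax=None):
    """Point-and-interval plot of per-condition mapping performance
    (output of :func:`crossmap.analysis.condition_summary`), with the 0.5
    chance line dashed."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(summary))
    ax.errorbar(
        x,
        summary["performance"],
        yerr=[
            summary["performance"] - summary["ci_lower"],
            summary["ci_upper"] - summary["performance"],
        ],
        fmt="o",
        capsize=4,
    )
    ax.axhline(0.5, linestyle="--", color="grey")
    ax.set_xticks(x)
    ax.set_xticklabels(summary.iloc[:, 0], rotation=30, ha="right")
    ax.set_ylabel("mapping performance")
    ax.set_ylim(0, 1)
    return ax


def plot_performance_curve(results, trials: pd.DataFrame, covariate: str, ax=None, n_grid: int = 50):
    """Predicted mapping performance as a function of one continuous
    covariate, with a Wald 0.95 confidence band, other covariates at zero.

    ``results`` is a fitted :class:`crossmap.glmm.MixedLogitResults` whose
    design contains an Intercept and ``covariate``.
    """
    import matplotlib.pyplot as plt
    from scipy.special import expit

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    grid = np.linspace(trials[covariate].min(), trials[covariate].max(), n_grid)
    names = list(results.params.index)
    X = np.zeros((n_grid, len(names)))
    X[:, names.index("Intercept")] = 1.0
    X[:, names.index(covariate)] = grid
    eta = X @ results.params.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, results.cov_params.to_numpy(), X))
    ax.plot(grid, expit(eta))
    ax.fill_between(grid, expit(eta - 1.96 * se), expit(eta + 1.96 * se), alpha=0.25)
    ax.axhline(0.5, linestyle="--", color="grey")
    ax.set_xlabel(covariate)
    ax.set_ylabel("predicted mapping performance")
    ax.set_ylim(0, 1)
    return ax
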