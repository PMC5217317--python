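"""Figures mirroring the study's calibration/discrimination panels."""

from __future__ import annotations

import pandas as pd

REFERENCE_LINES = {"cal_intercept": 0.0, "cal_slope": 1.0}


def plot_metric_grid(tidy: pd.DataFrame, metric: str, methods=None):
    """Metric vs n_train, one panel per sigma, error bars = 1.96 SE.

    ``tidy`` is the long table written by ``write_results`` /
    ``ScenarioResult.summaries()`` (columns sigma, n_train, method, metric,
    mean, se).  Returns the matplotlib Figure.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    sub = tidy[tidy["metric"] == metric]
    if sub.empty:
        raise ValueError(f"metric {metric!r} not present")
    sigmas = sorted(sub["sigma"].unique())
    methods = methods or sorted(sub["method"].unique())
    fig, axes = plt.subplots(1, len(sigmas), figsize=(3.2 * len(sigmas), 3.2),
                             sharey=True, squeeze=False)
    for ax, sigma in zip(axes[0], sigmas):
        panel = sub[sub["sigma"] == sigma]
        for method in methods:
            g = panel[panel["method"] == method].sort_values("n_train")
            ax.errorbar(g["n_train"], g["mean"], yerr=1.96 * g["se"],
                        marker="o", capsize=2, label=method)
        if metric in REFERENCE_LINES:
            ax.axhline(REFERENCE_LINES[metric], color="grey", lw=0.8, ls="--")
        ax.set_xscale("log")
        ax.set_title(f"sigma = {sigma:g}")
        ax.set_xlabel("n_train")
    axes[0][0].set_ylabel(metric)
    axes[0][-1].legend(fontsize=8)
    fig.tight_layout()
    return fig
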