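"""Grouped-bar summaries of the benchmark grid (one panel per sample size)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_metric_bars"]

_METHOD_COLORS = {
    "pm": "tab:blue",
    "sam": "tab:gray",
    "tsbp": "tab:red",
    "pbp": "tab:orange",
    "tsbb": "tab:green",
    "pbb": "tab:purple",
}


def plot_metric_bars(summary: pd.DataFrame, metric: str, out_path, title: str | None = None):
    """Bar chart of a summary metric, grouped by DE fraction, one panel per n.

    ``summary`` is the output of :func:`rbm.simulate.summarize` for a
    single distribution.
    """
    if metric not in summary.columns:
        raise ValueError(f"metric {metric!r} not in summary columns")
    ns = sorted(summary["n"].unique())
    methods = [m for m in _METHOD_COLORS if m in set(summary["method"])]
    fig, axes = plt.subplots(1, len(ns), figsize=(4 * len(ns), 3.2), sharey=True, squeeze=False)
    for ax, n in zip(axes[0], ns):
        sub = summary[summary["n"] == n]
        pi1s = sorted(sub["pi1"].unique())
        width = 0.8 / max(len(methods), 1)
        for k, method in enumerate(methods):
            vals = [
                float(sub[(sub["pi1"] == p) & (sub["method"] == method)][metric].mean())
                for p in pi1s
            ]
            xs = [i + k * width for i in range(len(pi1s))]
            ax.bar(xs, vals, width=width, label=method.upper(), color=_METHOD_COLORS[method])
        ax.set_xticks([i + 0.4 - width / 2 for i in range(len(pi1s))])
        ax.set_xticklabels([f"{p:g}" for p in pi1s])
        ax.set_xlabel("DE fraction")
        ax.set_title(f"n = {n}")
    axes[0][0].set_ylabel(metric)
    axes[0][-1].legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
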