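"""Minimal figures for threshold sweeps and decade-binned compositions."""

from __future__ import annotations

import math

from .thresholds import BinnedDistribution, ThresholdSweep


def plot_sweep(sweep: ThresholdSweep, ax=None):
    """Group proportions and the cumulative significant fraction versus
    E-value threshold (log x-axis, stringent to loose)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    order = sorted(range(len(sweep.thresholds)),
                   key=lambda i: sweep.thresholds[i])
    xs = [sweep.thresholds[i] for i in order]
    for group in sweep.groups:
        ax.plot(xs, [sweep.proportions[i].get(group, 0.0) for i in order],
                marker="o", label=group)
    ax.plot(xs, [sweep.cumulative_fraction[i] for i in order],
            color="black", label="cumulative significant")
    ax.set_xscale("log")
    ax.set_xlabel("E-value threshold")
    ax.set_ylabel("proportion")
    ax.legend(fontsize="small")
    return ax


def plot_bins(bins: BinnedDistribution, ax=None):
    """Stacked per-decade category proportions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    labels = [f"1e{int(round(math.log10(lo)))}" for lo, _ in bins.bins]
    categories = sorted({c for props in bins.proportions for c in props})
    bottoms = [0.0] * len(bins.bins)
    for cat in categories:
        heights = [props.get(cat, 0.0) for props in bins.proportions]
        ax.bar(range(len(heights)), heights, bottom=bottoms, label=cat)
        bottoms = [b + h for b, h in zip(bottoms, heights)]
    ax.set_xticks(range(len(labels)), labels, rotation=45, fontsize="small")
    ax.set_ylabel("proportion of top hits")
    ax.legend(fontsize="x-small")
    return ax
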