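"""Plain matplotlib exports: scan curve, category histograms, correlation
dot-matrix, and forest plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .associate import LogisticFit
from .correlate import CorrelationMatrix
from .threshold import ThresholdScan

__all__ = ["plot_scan", "plot_category_histograms", "plot_correlation", "plot_forest"]


def plot_scan(scan: ThresholdScan, path) -> None:
    """P-value vs candidate threshold for both scores (log p axis),
    with the significance level and the selected threshold marked."""
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, pvals, label in (
        (axes[0], scan.p_faced, "FACED"),
        (axes[1], scan.p_efaced, "EFACED"),
    ):
        ax.plot(scan.grid, pvals, lw=1.2, color="tab:blue")
        ax.axhline(scan.alpha, color="red", lw=1, label=f"p = {scan.alpha}")
        if scan.selected is not None:
            ax.axvline(scan.selected, color="gold", ls="--", lw=1.5, label="selected")
        ax.set_yscale("log")
        ax.set_xlabel("neutrophil threshold (cells/µL)")
        ax.set_title(label)
        ax.legend(fontsize=8)
    axes[0].set_ylabel("Mann-Whitney p (two-sided)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_category_histograms(histograms: dict, path) -> None:
    fig, axes = plt.subplots(1, len(histograms), figsize=(4 * len(histograms), 3.5))
    if len(histograms) == 1:
        axes = [axes]
    width = 0.38
    for ax, (scale, hist) in zip(axes, histograms.items()):
        cats = list(hist.proportions.columns)
        x = np.arange(len(cats))
        ax.bar(x - width / 2, hist.proportions.loc["below"], width, label="below")
        ax.bar(x + width / 2, hist.proportions.loc["above"], width, label="above")
        ax.set_xticks(x, cats)
        ax.set_ylabel("proportion of cluster")
        ax.set_title(f"{scale} {hist.stars}")
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlation(cm: CorrelationMatrix, path, alpha: float = 0.05) -> None:
    """Dot matrix: colour/size proportional to r, crossed when p > alpha."""
    k = len(cm.variables)
    fig, ax = plt.subplots(figsize=(1 + 0.6 * k, 1 + 0.6 * k))
    mask = cm.nonsignificant_mask(alpha).to_numpy()
    r = cm.r.to_numpy()
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            color = plt.cm.RdBu(0.5 * (1 - r[i, j]))
            ax.scatter(j, k - 1 - i, s=400 * abs(r[i, j]) + 5, color=color)
            if mask[i, j]:
                ax.plot(j, k - 1 - i, marker="x", color="black", ms=8, mew=1.5)
    ax.set_xticks(range(k), cm.variables, rotation=90, fontsize=7)
    ax.set_yticks(range(k), list(cm.variables)[::-1], fontsize=7)
    ax.set_xlim(-0.5, k - 0.5)
    ax.set_ylim(-0.5, k - 0.5)
    ax.set_title(f"Pearson r ({cm.subset})", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_forest(fit: LogisticFit, path, title: str = "") -> None:
    """OR with 95 % CI per term, reference line at OR = 1 (log axis)."""
    s = fit.summary()
    s = s[s["term"] != "intercept"]
    y = np.arange(len(s))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(s) + 1.5))
    ax.errorbar(
        s["or"],
        y,
        xerr=[s["or"] - s["ci_low"], s["ci_high"] - s["or"]],
        fmt="o",
        color="black",
        ecolor="gray",
        capsize=3,
    )
    ax.axvline(1.0, color="red", lw=1)
    ax.set_yticks(y, s["term"], fontsize=8)
    ax.set_xscale("log")
    ax.set_xlabel("odds ratio (95% CI)")
    ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
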