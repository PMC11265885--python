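"""Plotting helpers: consensus forest plots, belief-change and correlation views."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .beliefs import BeliefSummary
from .instrument import Instrument
from .model import ConsensusSummary

__all__ = ["forest_plot", "belief_plot", "correlation_plot"]


def forest_plot(
    summary: ConsensusSummary,
    instrument: Instrument,
    path: str | Path | None = None,
    title: str | None = None,
):
    """Item consensus medians with 95% CIs against the category thresholds.

    Items sit on the y axis, the latent evaluation continuum on the x
    axis; shaded vertical bands mark the response categories delimited by
    the posterior-median thresholds, and the open marker at the bottom
    shows the overall subscale consensus.
    """
    I = len(summary.item_ids)
    thr = summary.thresholds
    fig, ax = plt.subplots(figsize=(7, 0.5 * I + 2))

    lo = min(summary.item_ci[:, 0].min(), thr[0]) - 0.6
    hi = max(summary.item_ci[:, 1].max(), thr[-1]) + 0.6
    edges = np.concatenate(([lo], thr, [hi]))
    cmap = plt.get_cmap("RdYlGn")
    # category labels in coded order from the first item of the subscale
    labels = instrument[summary.item_ids[0]].coded_labels()
    for c in range(len(edges) - 1):
        ax.axvspan(edges[c], edges[c + 1],
                   color=cmap(c / max(len(edges) - 2, 1)), alpha=0.18)
        ax.text((edges[c] + edges[c + 1]) / 2, I + 0.35, labels[c],
                ha="center", va="bottom", fontsize=7, rotation=0)

    ypos = np.arange(I)[::-1]
    ax.errorbar(
        summary.item_median, ypos,
        xerr=[summary.item_median - summary.item_ci[:, 0],
              summary.item_ci[:, 1] - summary.item_median],
        fmt="o", color="black", capsize=2, lw=1.2,
    )
    olo, ohi = summary.overall_ci
    ax.errorbar([summary.overall_median], [-1],
                xerr=[[summary.overall_median - olo], [ohi - summary.overall_median]],
                fmt="o", mfc="white", mec="black", color="black", capsize=2)
    names = [f"{i} [{instrument[i].label}]" for i in summary.item_ids]
    ax.set_yticks(list(ypos) + [-1], names + ["Overall"])
    ax.set_xlabel("latent consensus")
    ax.set_ylim(-1.8, I + 1.2)
    ax.set_title(title or f"Consensus: {summary.subscale}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def belief_plot(prior, final, summary: BeliefSummary,
                path: str | Path | None = None):
    """Slope plot of per-team prior -> final plausibility plus agreement bars."""
    prior = np.asarray(prior, dtype=float)
    final = np.asarray(final, dtype=float)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 4))
    rng = np.random.default_rng(0)
    jit = rng.uniform(-0.08, 0.08, size=prior.size)
    for p, f, j in zip(prior, final, jit):
        ax1.plot([0, 1], [p + j, f + j], "-o", color="grey", alpha=0.5, ms=3)
    ax1.set_xticks([0, 1], ["prior", "final"])
    ax1.set_yticks([1, 2, 3, 4])
    ax1.set_ylabel("plausibility (1..4)")
    ax1.set_title(
        f"{summary.prop_increased:.0%} up / {summary.prop_decreased:.0%} down "
        f"/ {summary.prop_unchanged:.0%} same"
    )
    for k, (vals, lab) in enumerate(((prior, "prior"), (final, "final"))):
        counts = [np.sum(vals == c) for c in (1, 2, 3, 4)]
        ax2.bar(np.arange(4) + k * 0.4, counts, width=0.38, label=lab)
    ax2.set_xticks(np.arange(4) + 0.2, ["1", "2", "3", "4"])
    ax2.legend()
    ax2.set_title(
        f"agree: {summary.pct_agree_prior:.2f}% -> {summary.pct_agree_final:.2f}%"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig


def correlation_plot(x, y, result, path: str | Path | None = None,
                     xlabel: str = "x", ylabel: str = "effect size"):
    """Scatter with jitter and the posterior correlation summary in the title."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    rng = np.random.default_rng(0)
    ax.plot(x + rng.uniform(-0.05, 0.05, x.size), y, "o", alpha=0.6)
    ax.axhline(0, ls="--", color="grey", lw=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(
        f"{result.method}: est={result.estimate:.2f} "
        f"[{result.ci95[0]:.2f}, {result.ci95[1]:.2f}], "
        f"BF+0={result.bf_plus0:.2f}"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
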