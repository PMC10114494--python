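"""Figures for reader-variability and risk analyses (matplotlib, Agg)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["reader_pair_panel", "prediction_scatter", "odds_ratio_bars"]


def reader_pair_panel(scores_a, scores_b, name_a: str, name_b: str,
                      path: str | None = None):
    """Scatter of one reader's scores against the other, with the two score
    histograms underneath — the standard view of a pair's distribution
    differences."""
    scores_a = np.asarray(scores_a, float)
    scores_b = np.asarray(scores_b, float)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(4.5, 7))
    ax1.scatter(scores_a, scores_b, s=6, alpha=0.5)
    ax1.plot([0, 100], [0, 100], "k--", lw=0.8)
    ax1.set_xlabel(f"{name_a} score")
    ax1.set_ylabel(f"{name_b} score")
    bins = np.linspace(0, 100, 26)
    ax2.hist(scores_a, bins=bins, alpha=0.5, label=name_a)
    ax2.hist(scores_b, bins=bins, alpha=0.5, label=name_b)
    ax2.set_xlabel("VAS density score")
    ax2.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def prediction_scatter(pred_x, pred_y, label_x: str, label_y: str,
                       path: str | None = None):
    """Model-vs-model (or model-vs-reader) prediction scatter."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(np.asarray(pred_x, float), np.asarray(pred_y, float),
               s=6, alpha=0.5)
    ax.plot([0, 100], [0, 100], "k--", lw=0.8)
    ax.set_xlabel(label_x)
    ax.set_ylabel(label_y)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def odds_ratio_bars(results: dict, path: str | None = None):
    """Bar chart of top-vs-bottom quintile odds ratios with CIs.

    ``results`` maps a model/subset name to an
    :class:`~densvar.evaluation.OddsRatioResult`.
    """
    names = list(results)
    ors = np.array([results[n].odds_ratio for n in names])
    lows = np.array([results[n].ci_low for n in names])
    highs = np.array([results[n].ci_high for n in names])
    fig, ax = plt.subplots(figsize=(max(4.0, 0.6 * len(names)), 4.0))
    x = np.arange(len(names))
    ax.bar(x, ors, yerr=[ors - lows, highs - ors], capsize=3)
    ax.axhline(1.0, color="k", lw=0.8, ls="--")
    ax.set_xticks(x)
    ax.set_xticklabels(names, rotation=45, ha="right")
    ax.set_ylabel("odds ratio (top vs bottom quintile)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
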