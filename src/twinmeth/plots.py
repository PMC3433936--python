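"""Scatter plots of within-pair discordance against age or shared time apart."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_statistic_vs_age", "plot_distance_vs_s"]

_MARKERS = {"M": "s", "F": "^"}  # squares for male pairs, triangles for female


def plot_statistic_vs_age(
    pair_stats: pd.DataFrame,
    amplicon: str,
    statistic: str = "correlation",
    sexes: pd.Series | None = None,
    path: str | Path | None = None,
    threshold_age: float = 60.0,
):
    """Per-pair statistic vs pair age for one amplicon, threshold marked."""
    col = {"correlation": "pearson_r", "distance": "euclidean_d"}[statistic]
    sub = pair_stats[pair_stats["amplicon"] == amplicon].dropna(subset=[col])
    fig, ax = plt.subplots(figsize=(5, 4))
    if sexes is not None:
        for sex, marker in _MARKERS.items():
            pick = sub["pair_id"].map(sexes) == sex
            ax.scatter(sub.loc[pick, "age"], sub.loc[pick, col],
                       marker=marker, label=sex, alpha=0.8)
        ax.legend(title="sex")
    else:
        ax.scatter(sub["age"], sub[col], alpha=0.8)
    ax.axvline(threshold_age, ls="--", color="grey", lw=1)
    ax.set_xlabel("pair age (years)")
    ax.set_ylabel("intra-couple Pearson r" if statistic == "correlation"
                  else "within-pair Euclidean distance")
    ax.set_title(amplicon)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_distance_vs_s(
    records: pd.DataFrame,
    amplicon: str,
    s_threshold: float = 35.0,
    discordant: pd.DataFrame | None = None,
    path: str | Path | None = None,
):
    """Within-pair distance vs S, highlighting discordant cohabiters."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(records["S"], records["euclidean_d"], alpha=0.8)
    if discordant is not None and len(discordant):
        ax.scatter(discordant["S"], discordant["euclidean_d"],
                   facecolors="none", edgecolors="red", s=120,
                   label="discordant cohabiters")
        ax.legend()
    ax.axvline(s_threshold, ls="--", color="grey", lw=1)
    ax.set_xlabel("S (% of lifetime lived apart)")
    ax.set_ylabel("within-pair Euclidean distance")
    ax.set_title(amplicon)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
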