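"""Figure helpers: methylation landscape along a replicon and efficiency bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_methylation_landscape(sites: pd.DataFrame, length: int, ax_pair=None,
                               highlight: tuple[int, int] | None = None):
    """Strand-split scatter of per-site methylation along the replicon.

    Forward strand on top, reverse below; an optional interval (e.g. the
    repeat-spacer array) is shaded.
    """
    if ax_pair is None:
        _, ax_pair = plt.subplots(2, 1, sharex=True, figsize=(10, 5))
    for ax, strand, color in zip(ax_pair, "+-", ("tab:blue", "tab:red")):
        sel = sites[(sites["strand"] == strand) & sites["fraction"].notna()]
        ax.scatter(sel["position"], 100 * sel["fraction"], s=8, color=color)
        ax.set_ylabel(f"% methylation ({strand})")
        ax.set_ylim(-5, 105)
        if highlight:
            ax.axvspan(*highlight, color="0.85", zorder=0)
    ax_pair[-1].set_xlabel("position (nt)")
    ax_pair[-1].set_xlim(1, length)
    return ax_pair


def plot_efficiency(summary: pd.DataFrame, ax=None):
    """Bar plot of normalised conjugation efficiencies with SE bars."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    labels = [f"{r.strain}\n{r.plasmid}:{r.pam}" for r in summary.itertuples()]
    ax.bar(range(len(summary)), summary["mean_efficiency"],
           yerr=summary["se"].fillna(0), capsize=3, color="tab:blue")
    ax.set_xticks(range(len(summary)))
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel("normalised conjugation efficiency")
    ax.axhline(1.0, ls="--", color="0.5", lw=0.8)
    return ax
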