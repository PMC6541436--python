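"""Plot helpers: uptake time courses and TMT enrichment scatters."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_uptake", "plot_enrichment_rank", "plot_timepoint_scatter"]


def plot_uptake(timecourses, path) -> None:
    """Median captured-probe fluorescence versus time, one line per condition."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for tc in timecourses:
        ax.plot(tc.times, tc.values, marker="o", ms=3, label=tc.condition)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("median uptake (a.u., background-subtracted)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_enrichment_rank(log2_table: pd.DataFrame, ranks: pd.Series, calls,
                         path, threshold: float = 0.5) -> None:
    """Mean log2 WT/KO ratio versus abundance rank, enrichment calls colored."""
    klass = {c.protein: c.klass for c in calls}
    mean_log2 = log2_table.mean(axis=1)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    colors = {"none": "0.7", "partial": "tab:blue", "full": "tab:red"}
    for k in ("none", "partial", "full"):
        ids = [p for p in mean_log2.index if klass.get(p, "none") == k and p in ranks]
        ax.scatter(ranks[ids], mean_log2[ids], s=6 if k == "none" else 16,
                   c=colors[k], label=k, zorder=2 if k == "none" else 3)
    ax.axhline(threshold, color="k", lw=0.5, ls="--")
    ax.set_xlabel("abundance rank (1 = most abundant)")
    ax.set_ylabel("mean log2 WT/KO ratio")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_timepoint_scatter(pairs: pd.DataFrame, path,
                           threshold: float = 0.5) -> None:
    """Per-protein log2 ratios at two time points, discordant points marked."""
    fig, ax = plt.subplots(figsize=(4, 4))
    disc = pairs["discordant"]
    ax.scatter(pairs.loc[~disc, "log2_x"], pairs.loc[~disc, "log2_y"], s=6, c="0.7")
    ax.scatter(pairs.loc[disc, "log2_x"], pairs.loc[disc, "log2_y"], s=16,
               c="tab:red", label="discordant")
    lim = float(np.nanmax(np.abs(pairs[["log2_x", "log2_y"]].to_numpy()))) * 1.1 + 0.1
    ax.plot([-lim, lim], [-lim, lim], color="k", lw=0.5)
    for v in (threshold, -threshold):
        ax.axhline(v, color="k", lw=0.5, ls="--")
        ax.axvline(v, color="k", lw=0.5, ls="--")
    ax.set_xlim(-lim, lim), ax.set_ylim(-lim, lim)
    ax.set_xlabel("log2 WT/KO (t = 0)")
    ax.set_ylabel("log2 WT/KO (t = 60)")
    if disc.any():
        ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
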