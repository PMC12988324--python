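"""Quick-look plots for RFD tracks, distance profiles and gene metaplots."""

from __future__ import annotations

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from traelseq.repliprofile import MetaplotResult


def plot_rfd_track(track: pd.DataFrame, chrom: str, ax=None):
    """RFD along one chromosome, positive and negative values in two colours
    (the conventional display: positive = forks moving left to right)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    sub = track[(track["chrom"] == chrom) & track["rfd"].notna()]
    x = (sub["start"] + sub["end"]) / 2 / 1e6
    pos = sub["rfd"].clip(lower=0)
    neg = sub["rfd"].clip(upper=0)
    ax.fill_between(x, 0, pos, color="tab:red", step="mid", label="rightward")
    ax.fill_between(x, 0, neg, color="tab:blue", step="mid", label="leftward")
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel(f"{chrom} position (Mb)")
    ax.set_ylabel("RFD")
    ax.legend(loc="upper right", frameon=False, fontsize=8)
    return ax


def plot_distance_profile(profile: pd.DataFrame, ax=None, label=None, color=None):
    """Mean read count vs distance from feature centres with the CI band."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    x = (profile["bin_start"] + profile["bin_end"]) / 2 / 1e6
    ax.plot(x, profile["mean"], label=label, color=color)
    ci = profile["ci_half"].fillna(0.0)
    ax.fill_between(x, profile["mean"] - ci, profile["mean"] + ci, alpha=0.25, color=color)
    ax.set_xlabel("distance from IZ centre (Mb)")
    ax.set_ylabel("mean read count per window")
    if label:
        ax.legend(frameon=False, fontsize=8)
    return ax


def plot_metaplot(result: MetaplotResult, ax=None):
    """Per-stratum normalized read density over gene bodies and flanks."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    f, b = result.flank_bins, result.body_bins
    for label, prof in result.profiles.items():
        ax.plot(np.arange(len(prof)), prof, label=f"{label} (n={result.n_genes[label]})")
    for edge in (f - 0.5, f + b - 0.5):
        ax.axvline(edge, color="grey", lw=0.5, ls="--")
    ax.set_xticks([f / 2, f + b / 2, f + b + f / 2])
    ax.set_xticklabels([f"-{result.flank // 1000} kb", "gene body", f"+{result.flank // 1000} kb"])
    ax.set_ylabel("normalized read density")
    ax.legend(frameon=False, fontsize=8)
    return ax
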