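"""Headless-safe figures: lick-rate traces, latency histogram, learning curves."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from . import stats


def plot_lick_rate(trials: pd.DataFrame, path, bin_width: float = 0.1) -> None:
    """Per-cage lick-rate traces, tone trials solid, catch trials dotted."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for cage_id, df in trials.groupby("cage_id"):
        for filt, ls in (("tone", "-"), ("catch", ":")):
            try:
                tr = stats.lick_rate_trace(df, bin_width=bin_width, trial_filter=filt)
            except ValueError:
                continue
            mid = (tr.bin_edges[:-1] + tr.bin_edges[1:]) / 2
            ax.plot(mid, tr.p_lick, ls, label=f"cage {cage_id} {filt}")
    ax.set_xlabel("time in trial (s)")
    ax.set_ylabel("P(lick)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_latency_hist(trials: pd.DataFrame, path, bin_width: float = 0.1) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    try:
        fls = stats.first_lick_stats(trials, bin_width=bin_width)
    except ValueError:
        plt.close(fig)
        return
    ax.hist(fls.latencies, bins=int(max(1, fls.latencies.max() / bin_width)))
    ax.axvline(fls.peak, color="k", ls="--", label=f"peak {fls.peak:.2f} s")
    ax.set_xlabel("first-lick latency (s)")
    ax.set_ylabel("trials")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_learning_curve(curve: pd.DataFrame, path) -> None:
    """Daily peak latency and required delay (top), rates (bottom)."""
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    ax1.plot(curve["day_index"], curve["peak_latency"], "k.-", label="peak latency")
    ax1.plot(curve["day_index"], curve["delay"], "b.-", label="required delay")
    ax1.set_ylabel("seconds")
    ax1.legend()
    for col, color, label in (
        ("hit_rate", "r", "hit"),
        ("early_rate", "g", "early"),
        ("fa_rate", "b", "false alarm"),
    ):
        ax2.plot(curve["day_index"], 100 * curve[col], f"{color}.-", label=label)
    ax2.set_xlabel("training day")
    ax2.set_ylabel("rate (%)")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
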