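"""Optional matplotlib figures mirroring the study pipeline's reports.

Plotting is never required for any analysis; these helpers exist so a study
directory can be turned into the usual three figures (per-center dot plot,
AP-vs-threshold curves, agreement bars) in one call each.
"""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_per_center_panel(table: pd.DataFrame, path: str) -> None:
    """Dot plot of each metric per center (rows with center_id != 'all')."""
    metrics = [c for c in ("sensitivity", "ppv", "f1", "f2", "ap@0.5",
                           "ap@0.75", "ap@0.5:0.95") if c in table]
    per_center = table[table["center_id"] != "all"]
    fig, ax = plt.subplots(figsize=(1.2 * len(metrics) + 2, 4))
    for i, m in enumerate(metrics):
        vals = per_center[m].dropna()
        ax.scatter([i] * len(vals), vals, alpha=0.7)
    ax.set_xticks(range(len(metrics)), metrics, rotation=30, ha="right")
    ax.set_ylim(0, 1.02)
    ax.set_ylabel("value (one dot per center)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_threshold_sweep(sweeps: Mapping[str, Mapping[float, float]], path: str) -> None:
    """AP against IoU threshold, one curve per overlap criterion kind."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for kind, curve in sweeps.items():
        ts = sorted(curve)
        ax.plot(ts, [curve[t] for t in ts], marker="o", ms=3, label=kind)
    ax.set_xlabel("IoU threshold")
    ax.set_ylabel("AP")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_agreement(table: pd.DataFrame, path: str) -> None:
    """Paired bars of agreement with 'useful' and 'not useful' ratings."""
    fig, ax = plt.subplots(figsize=(1.0 * len(table) + 2, 4))
    x = range(len(table))
    ax.bar([i - 0.2 for i in x], table["frac_useful_accepted"], width=0.4,
           label="useful accepted")
    ax.bar([i + 0.2 for i in x], table["frac_not_useful_rejected"], width=0.4,
           label="not useful rejected")
    ax.set_xticks(list(x), table["criterion"], rotation=30, ha="right")
    ax.set_ylim(0, 1.05)
    ax.set_ylabel("fraction of ratings in agreement")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
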