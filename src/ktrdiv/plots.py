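"""Diagnostic plots: QC traces for division review, class box/strip plots,
ERK-vs-Akt scatter, and median time courses with spread ribbons."""

from __future__ import annotations

import os

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_qc_traces", "plot_feature_boxes", "plot_feature_scatter",
           "plot_median_timecourses"]


def plot_qc_traces(traces: pd.DataFrame, calls: dict, out_dir: str,
                   channel: str = "akt", max_cells: int = 50) -> list[str]:
    """One PNG per flagged or called cell, marking the detected drop frame."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    flagged = [cid for cid, c in calls.items() if c is not None][:max_cells]
    for cid in flagged:
        sub = traces[(traces["cell_id"] == cid) & (traces["channel"] == channel)]
        fig, ax = plt.subplots(figsize=(5, 2.5))
        ax.plot(sub["time_h"], sub["cn_ratio"], lw=0.8)
        call = calls[cid]
        t_peak = sub["time_h"].iloc[0] + call.peak_frame * (
            sub["time_h"].diff().median() or 0.25)
        ax.axvline(t_peak, color="r", ls="--", lw=0.8)
        flags = ",".join(sorted(call.qc_flags)) or "accepted"
        ax.set_title(f"cell {cid} ({flags})", fontsize=8)
        ax.set_xlabel("time (h)")
        ax.set_ylabel(f"{channel} C/N")
        p = os.path.join(out_dir, f"cell_{cid:05d}.png")
        fig.savefig(p, dpi=90, bbox_inches="tight")
        plt.close(fig)
        paths.append(p)
    return paths


def plot_feature_boxes(features: pd.DataFrame, path: str) -> str:
    channels = [c.removeprefix("median_") for c in features.columns
                if c.startswith("median_")]
    fig, axes = plt.subplots(1, len(channels), figsize=(3 * len(channels), 3),
                             squeeze=False)
    rng = np.random.default_rng(0)
    for ax, ch in zip(axes[0], channels):
        col = f"median_{ch}"
        groups = [features.loc[features["divided"], col].dropna(),
                  features.loc[~features["divided"], col].dropna()]
        ax.boxplot(groups, tick_labels=["D", "ND"], showfliers=False)
        for i, g in enumerate(groups, start=1):
            ax.plot(i + rng.uniform(-0.12, 0.12, len(g)), g, ".", ms=3,
                    alpha=0.5)
        ax.set_title(ch.upper())
        ax.set_ylabel("median C/N (8.5-40 h)")
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_feature_scatter(features: pd.DataFrame, path: str) -> str:
    fig, ax = plt.subplots(figsize=(3.5, 3.5))
    for flag, color, lab in [(True, "tab:blue", "dividing"),
                             (False, "tab:red", "non-dividing")]:
        sub = features[features["divided"] == flag]
        ax.plot(sub["median_erk"], sub["median_akt"], ".", color=color,
                ms=4, alpha=0.6, label=lab)
    ax.set_xlabel("median ERK C/N")
    ax.set_ylabel("median Akt C/N")
    ax.legend(fontsize=7)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_median_timecourses(traces: pd.DataFrame, fates: pd.DataFrame,
                            path: str) -> str:
    fate_by_id = fates.set_index("cell_id")["fate"].to_dict()
    channels = sorted(traces["channel"].unique())
    fig, axes = plt.subplots(1, len(channels), figsize=(4 * len(channels), 3),
                             squeeze=False)
    for ax, ch in zip(axes[0], channels):
        sub = traces[traces["channel"] == ch].copy()
        sub["fate"] = sub["cell_id"].map(fate_by_id)
        for cls, color in [("dividing", "tab:blue"),
                           ("non-dividing", "tab:red")]:
            g = sub[sub["fate"] == cls].groupby("time_h")["cn_ratio"]
            med, sd = g.median(), g.std()
            ax.plot(med.index, med, color=color, label=cls)
            ax.fill_between(med.index, med - sd, med + sd, color=color,
                            alpha=0.2, lw=0)
        ax.set_title(ch.upper())
        ax.set_xlabel("time (h)")
        ax.set_ylabel("C/N")
        ax.legend(fontsize=7)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
    return path
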