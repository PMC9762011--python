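"""Figure helpers: condition bar plots, workspace maps, recommendation grids.

All functions write an image file and return the path; they are thin
matplotlib wrappers over the tidy structures produced by the evaluation
module.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_condition_bars(results: pd.DataFrame, path, arm: str = "left"):
    """Mean paretic-arm RE (+/- sd across seeds) per therapy condition."""
    col = f"mean_re_{arm}"
    keys = ["stage", "lesion_size", "complexity", "hand_mode", "plasticity"]
    agg = results.groupby(keys)[col].agg(["mean", "std"]).reset_index()
    labels = [
        f"{r.stage[:2]} n={r.lesion_size} {r.complexity[:6]}/{r.hand_mode}/{r.plasticity[:1]}"
        for r in agg.itertuples()
    ]
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(agg)), 4))
    ax.bar(range(len(agg)), agg["mean"], yerr=agg["std"].fillna(0.0), capsize=3)
    ax.set_xticks(range(len(agg)))
    ax.set_xticklabels(labels, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel(f"mean RE ({arm} arm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_workspace_map(result, dataset, path, arm: str = "left", threshold: float | None = None):
    """3D scatter of the test targets coloured by the arm's reaching error."""
    ds = dataset.without_rest_mode()
    active = ds.hsp[:, 0] == 1 if arm == "left" else ds.hsp[:, 1] == 1
    re = (result.re_left if arm == "left" else result.re_right)[active]
    req = (ds.required_left if arm == "left" else ds.required_right)[active]
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    sc = ax.scatter(req[:, 0], req[:, 1], req[:, 2], c=re, s=8, cmap="viridis")
    fig.colorbar(sc, label="reaching error", shrink=0.7)
    if threshold is not None:
        ax.set_title(f"{arm} arm: {int((re > threshold).sum())}/{len(re)} targets above {threshold}")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    ax.set_zlabel("z")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_recommendation_map(recommendations: pd.DataFrame, path):
    """Lesion-size x CC-integrity grid of recommended plasticity per stage."""
    stages = list(recommendations["stage"].unique())
    fig, axes = plt.subplots(1, len(stages), figsize=(4.5 * len(stages), 3.5), squeeze=False)
    for ax, stage in zip(axes[0], stages):
        sub = recommendations[recommendations["stage"] == stage]
        sizes = sorted(sub["lesion_size"].unique())
        integ = sorted(sub["cc_integrity"].unique())
        grid = np.zeros((len(integ), len(sizes)))
        for _, row in sub.iterrows():
            i = integ.index(row["cc_integrity"])
            j = sizes.index(row["lesion_size"])
            grid[i, j] = 1.0 if row["recommended_plasticity"] == "global" else 0.0
        im = ax.imshow(grid, cmap="coolwarm", vmin=0, vmax=1, origin="lower", aspect="auto")
        ax.set_xticks(range(len(sizes)), sizes)
        ax.set_yticks(range(len(integ)), integ)
        ax.set_xlabel("lesion size (nodes)")
        ax.set_ylabel("CC integrity")
        ax.set_title(f"{stage} (red = global, blue = local)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
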