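"""Figures for the fire-safety matrix: rankings, quadrant scatter,
dendrogram with cut line, and the jittered sensitivity plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse
from scipy.cluster import hierarchy

from .config import QuadrantRule
from .reconcile import ClusterTree, ellipse_params, quadrant_thresholds


def ranked_bar(summary: pd.DataFrame, which: str, path: Path) -> Path:
    """Horizontal bars of mean scores with low/high ranges, best-ranked on top."""
    mean, lo, hi = f"{which}_mean", f"{which}_low", f"{which}_high"
    df = summary.sort_values([mean, "type_id"], ascending=[True, False])
    fig, ax = plt.subplots(figsize=(7, 0.28 * len(df) + 1.2))
    y = np.arange(len(df))
    ax.barh(y, df[mean], color="#86b6d9", label="mean of variants")
    err_lo = df[mean] - df[[lo, hi]].min(axis=1)
    err_hi = df[[lo, hi]].max(axis=1) - df[mean]
    ax.errorbar(df[mean], y, xerr=[err_lo, err_hi], fmt="none", ecolor="#333333",
                capsize=2, label="low/high range")
    ax.set_yticks(y, df["type_id"])
    ax.set_xlabel(f"{which} score (1-5 scale)")
    ax.set_xlim(0, 5.2)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def scatter_with_ellipses(summary: pd.DataFrame, path: Path,
                          rule: QuadrantRule = QuadrantRule.midrange) -> Path:
    """Injury x exposure scatter; range ellipses and quadrant threshold lines."""
    fig, ax = plt.subplots(figsize=(8, 7))
    x_thr, y_thr = quadrant_thresholds(summary, rule)
    for _, row in summary.iterrows():
        g = ellipse_params(row)
        ax.add_patch(
            Ellipse(g.center, width=max(2 * g.semi_axis_x, 1e-3),
                    height=max(2 * g.semi_axis_y, 1e-3),
                    alpha=0.25, facecolor="#86b6d9", edgecolor="none")
        )
        ax.annotate(row["type_id"], g.center, fontsize=6, ha="center")
    ax.scatter(summary["injury_mean"], summary["exposure_mean"], s=10, color="#1f4e79")
    ax.axvline(x_thr, color="grey", linestyle="--", linewidth=1)
    ax.axhline(y_thr, color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("fire risk (injury), mean of variants")
    ax.set_ylabel("CFR exposure potential, mean of variants")
    ax.set_xlim(0.8, 5.2)
    ax.set_ylim(0.8, 5.2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def dendrogram_figure(tree: ClusterTree, cut_height: float, path: Path) -> Path:
    fig, ax = plt.subplots(figsize=(10, 5))
    hierarchy.dendrogram(tree.merges, labels=list(tree.labels), ax=ax,
                         color_threshold=cut_height, leaf_rotation=90, leaf_font_size=7)
    ax.axhline(cut_height, color="red", linestyle="--", linewidth=1)
    ax.set_ylabel("merge height (Euclidean distance)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def sensitivity_jitter_plot(sweep: pd.DataFrame, path: Path) -> Path:
    """Jittered injury scores per imputed contact-error delta."""
    fig, ax = plt.subplots(figsize=(7, 5))
    ax.scatter(sweep["jitter_x"], sweep["jitter_y"], s=8, alpha=0.5, color="#1f4e79")
    ax.set_xlabel("imputed contact-score error (points)")
    ax.set_ylabel("injury risk score")
    ax.set_xticks(sorted(sweep["delta"].unique()))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
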