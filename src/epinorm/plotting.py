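"""SVG figures for the standard reports: flag radar, WCSS elbow, PCA overlap."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def radar_plot(prevalence: pd.DataFrame, path, title: str = "Abnormality flags (%)") -> Path:
    """Radar of per-feature flag percentages, patients vs controls."""
    feats = prevalence.index.tolist()
    angles = np.linspace(0, 2 * np.pi, len(feats), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    for col, color in (("patient_pct", "tab:blue"), ("control_pct", "black")):
        vals = prevalence[col].to_numpy(float)
        ax.plot(np.r_[angles, angles[:1]], np.r_[vals, vals[:1]],
                color=color, label=col.split("_")[0])
        ax.fill(np.r_[angles, angles[:1]], np.r_[vals, vals[:1]], color=color, alpha=0.1)
    ax.set_xticks(angles)
    ax.set_xticklabels(feats, fontsize=7)
    ax.set_title(title)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.05))
    return _save(fig, path)


def elbow_plot(wcss_curve: dict, path, suggested_k: int | None = None) -> Path:
    """Within-cluster sum of squares against k with the elbow suggestion."""
    ks = sorted(wcss_curve)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(ks, [wcss_curve[k] for k in ks], "o-")
    if suggested_k is not None and suggested_k in wcss_curve:
        ax.axvline(suggested_k, ls="--", color="tab:red",
                   label=f"elbow suggestion k={suggested_k}")
        ax.legend()
    ax.set_xlabel("k")
    ax.set_ylabel("WCSS")
    ax.set_title("Elbow method")
    return _save(fig, path)


def pca_plot(coords: pd.DataFrame, labels: pd.Series, explained, path) -> Path:
    """Cluster overlap in the first two principal components."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for lab in sorted(labels.unique()):
        pts = coords.loc[labels[labels == lab].index]
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], s=18, label=f"profile {lab}")
    ax.set_xlabel(f"PC1 ({100 * explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * explained[1]:.1f}%)")
    ax.set_title("Cluster overlap (PCA)")
    ax.legend()
    return _save(fig, path)


def _save(fig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, format="svg", bbox_inches="tight")
    plt.close(fig)
    return path
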