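"""Figure helpers: barcode heat strips, protection profiles, dot plots.

All writers are deterministic for fixed input: SVG output uses a fixed hash
salt and omits date metadata so repeated runs are byte-identical.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .md import BarcodeMatrix

plt.rcParams["svg.hashsalt"] = "enhancerkit"
_SAVEFIG_KW = {"metadata": {"Date": None}}


def _save(fig, path):
    kw = _SAVEFIG_KW if str(path).endswith(".svg") else {}
    fig.savefig(path, bbox_inches="tight", **kw)
    plt.close(fig)


def barcode_plot(barcode: BarcodeMatrix, path) -> None:
    """Heat strip of motif-to-origin distance frequency over [-R, +R]."""
    fig, ax = plt.subplots(figsize=(6, 1.2))
    ax.imshow(
        barcode.normalized()[None, :],
        aspect="auto",
        cmap="Greys",
        extent=[barcode.bin_edges[0], barcode.bin_edges[-1], 0, 1],
    )
    ax.set_yticks([])
    ax.set_xlabel("distance to nearest origin (bp)")
    ax.set_title(barcode.motif_id, fontsize=9)
    _save(fig, path)


def mnase_plot(protection: pd.DataFrame, path) -> None:
    """Line plot with error bars of relative MNase protection along the tile."""
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.errorbar(
        protection["midpoint"],
        protection["protection_mean"],
        yerr=protection["protection_sd"],
        marker="o",
        capsize=3,
    )
    ax.axhline(1.0, ls="--", lw=0.8, color="grey")
    ax.set_xlabel("amplicon midpoint (bp)")
    ax.set_ylabel("relative protection")
    _save(fig, path)


def sn_dotplot(table: pd.DataFrame, features: list[str], path, group_variable: str = "disease") -> None:
    """Dot plot: per cell type x group, dot size = fraction of nuclei with any
    counts of the feature, color = mean depth-normalized count."""
    rows = []
    for (cell_type, group), grp in table.groupby(["cell_type", group_variable]):
        for feat in features:
            frac = float((grp[feat] > 0).mean())
            mean_norm = float((grp[feat] / grp["total_counts"] * 1e4).mean())
            rows.append((f"{cell_type} ({group})", feat, frac, mean_norm))
    summary = pd.DataFrame(rows, columns=["row", "feature", "frac", "mean_norm"])
    row_labels = sorted(summary["row"].unique())
    fig, ax = plt.subplots(figsize=(1.2 * len(features) + 3, 0.5 * len(row_labels) + 2))
    sc = ax.scatter(
        [features.index(f) for f in summary["feature"]],
        [row_labels.index(r) for r in summary["row"]],
        s=20 + 300 * summary["frac"],
        c=summary["mean_norm"],
        cmap="viridis",
    )
    ax.set_xticks(range(len(features)), features)
    ax.set_yticks(range(len(row_labels)), row_labels)
    fig.colorbar(sc, ax=ax, label="mean counts per 10$^4$ total")
    _save(fig, path)
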