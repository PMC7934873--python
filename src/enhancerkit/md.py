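"""Motif displacement (MD) scoring around eRNA origins.

For one motif, the MD score is the proportion of its genomic instances lying
within a small radius r (default 150 bp) of the nearest eRNA origin, among
those within a large radius R (default 1500 bp): md = h/H. Under uniform
placement md converges to r/R = 0.1; co-localization of a motif with
transcription initiation pulls it up. Two conditions are compared per motif
with a two-proportion z-test on (h, H) pairs; the significance threshold
follows the analysis convention alpha = 1e-4. Barcode matrices bin the signed
instance-to-origin distances over [-R, +R] for heat-strip display.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_R_SMALL = 150
DEFAULT_R_LARGE = 1500
DEFAULT_ALPHA = 1e-4


@dataclass
class MDResult:
    """Per-motif co-localization proportion h/H within radii (r, R)."""

    motif_id: str
    h: int
    H: int
    md: float  # NaN when undefined (H == 0)
    r: int = DEFAULT_R_SMALL
    R: int = DEFAULT_R_LARGE

    @property
    def defined(self) -> bool:
        return self.H > 0


@dataclass
class DiffMDResult:
    """Two-proportion z-test comparing one motif's MD between two conditions."""

    motif_id: str
    md_a: float
    md_b: float
    h_a: int
    H_a: int
    h_b: int
    H_b: int
    z: float
    p: float
    significant: bool
    degenerate: bool = False
    alpha: float = DEFAULT_ALPHA


@dataclass
class BarcodeMatrix:
    """Histogram of signed motif-to-origin distances over [-R, +R]."""

    motif_id: str
    bin_edges: np.ndarray
    counts: np.ndarray

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.astype(float)


def motif_distances(
    instances: pd.DataFrame,
    origins: pd.DataFrame,
    R: int = DEFAULT_R_LARGE,
) -> dict[str, np.ndarray]:
    """Signed distance from each motif instance midpoint to its nearest origin.

    The instance position is ``floor((start + end) / 2)``; the distance is
    midpoint minus origin, with equidistant ties resolved toward the smaller
    origin coordinate. Instances farther than R from every origin are dropped;
    each instance contributes at most once. Returns ``{motif_id: distances}``.

    Raises if an instance (or origin) chromosome is unknown to the other
    input, unless the origin set is empty, in which case all lists are empty.
    """
    result: dict[str, list] = {m: [] for m in instances["motif_id"].unique()}
    if len(origins) == 0:
        return {m: np.array(d) for m, d in result.items()}

    origin_by_chrom = {
        chrom: np.sort(grp["origin"].to_numpy()) for chrom, grp in origins.groupby("chrom")
    }
    unknown = set(instances["chrom"].unique()) - set(origin_by_chrom)
    if unknown:
        raise ValueError(
            f"instance chromosomes {sorted(unknown)} absent from the origin set"
        )

    for chrom, grp in instances.groupby("chrom"):
        oc = origin_by_chrom[chrom]
        mid = ((grp["start"].to_numpy() + grp["end"].to_numpy()) // 2).astype(np.int64)
        idx = np.searchsorted(oc, mid)
        left = oc[np.clip(idx - 1, 0, len(oc) - 1)]
        right = oc[np.clip(idx, 0, len(oc) - 1)]
        d_left = np.abs(mid - left)
        d_right = np.abs(mid - right)
        # tie (equidistant) resolves toward the smaller origin coordinate
        nearest = np.where(d_left <= d_right, left, right)
        dist = mid - nearest
        keep = np.abs(dist) <= R
        for m, d in zip(grp["motif_id"].to_numpy()[keep], dist[keep]):
            result[m].append(int(d))
    return {m: np.array(sorted(d), dtype=np.int64) for m, d in result.items()}


def compute_md(
    distances: np.ndarray,
    r: int = DEFAULT_R_SMALL,
    R: int = DEFAULT_R_LARGE,
    motif_id: str = "motif",
) -> MDResult:
    """MD score from signed distances; radii are inclusive (|d| <= r, |d| <= R)."""
    if r >= R:
        raise ValueError(f"r ({r}) must be smaller than R ({R})")
    d = np.abs(np.asarray(distances, dtype=float))
    H = int((d <= R).sum())
    h = int((d <= r).sum())
    md = h / H if H > 0 else float("nan")
    return MDResult(motif_id=motif_id, h=h, H=H, md=md, r=r, R=R)


def diff_md(a: MDResult, b: MDResult, alpha: float = DEFAULT_ALPHA) -> DiffMDResult:
    """Two-proportion z-test of md_a vs md_b with pooled variance.

    z = (md_a - md_b) / sqrt(p(1-p)(1/H_a + 1/H_b)) with the pooled
    proportion p = (h_a + h_b)/(H_a + H_b); p-value is the two-sided
    standard-normal tail. A pooled proportion of exactly 0 or 1 has no
    variance: the result is flagged degenerate with p = 1, not significant.
    """
    if a.H == 0 or b.H == 0:
        raise ValueError("diff_md requires H > 0 in both conditions")
    pooled = (a.h + b.h) / (a.H + b.H)
    if pooled in (0.0, 1.0):
        return DiffMDResult(
            motif_id=a.motif_id, md_a=a.md, md_b=b.md,
            h_a=a.h, H_a=a.H, h_b=b.h, H_b=b.H,
            z=float("nan"), p=1.0, significant=False, degenerate=True, alpha=alpha,
        )
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / a.H + 1.0 / b.H))
    z = (a.md - b.md) / se
    p = 2.0 * norm.sf(abs(z))
    return DiffMDResult(
        motif_id=a.motif_id, md_a=a.md, md_b=b.md,
        h_a=a.h, H_a=a.H, h_b=b.h, H_b=b.H,
        z=z, p=p, significant=p <= alpha, alpha=alpha,
    )


def barcode_matrix(
    distances: np.ndarray,
    R: int = DEFAULT_R_LARGE,
    n_bins: int = 100,
    motif_id: str = "motif",
) -> BarcodeMatrix:
    """Equal-width histogram of signed distances over [-R, +R].

    *n_bins* must be even so 0 falls on a bin edge. Bins are half-open
    [edge_i, edge_{i+1}) except the last, which includes +R; a distance of
    exactly 0 therefore lands in the right-central bin. The counts sum to H.
    """
    if n_bins % 2 != 0:
        raise ValueError("n_bins must be even (keeps 0 on a bin edge)")
    edges = np.linspace(-R, R, n_bins + 1)
    counts, _ = np.histogram(np.asarray(distances, dtype=float), bins=edges)
    return BarcodeMatrix(motif_id=motif_id, bin_edges=edges, counts=counts)


# ---------------------------------------------------------------------------
# Tabular conveniences over many motifs


def md_table(
    instances: pd.DataFrame,
    origins: pd.DataFrame,
    r: int = DEFAULT_R_SMALL,
    R: int = DEFAULT_R_LARGE,
) -> pd.DataFrame:
    """MD scores for every motif_id in *instances*: columns motif_id, h, H, md."""
    dists = motif_distances(instances, origins, R=R)
    rows = []
    for motif_id in sorted(dists):
        res = compute_md(dists[motif_id], r=r, R=R, motif_id=motif_id)
        rows.append((motif_id, res.h, res.H, res.md))
    return pd.DataFrame(rows, columns=["motif_id", "h", "H", "md"])


def diff_md_table(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    r: int = DEFAULT_R_SMALL,
    R: int = DEFAULT_R_LARGE,
) -> pd.DataFrame:
    """Per-motif differential MD between two condition tables.

    Motifs with H = 0 on either side carry no test statistic; they are
    reported with NaN z/p and excluded from significance accounting.
    """
    merged = table_a.merge(table_b, on="motif_id", suffixes=("_a", "_b"))
    rows = []
    for row in merged.itertuples(index=False):
        if row.H_a == 0 or row.H_b == 0:
            rows.append((row.motif_id, row.md_a, row.md_b, row.h_a, row.H_a,
                         row.h_b, row.H_b, float("nan"), float("nan"), False, True))
            continue
        res = diff_md(
            MDResult(row.motif_id, row.h_a, row.H_a, row.md_a, r, R),
            MDResult(row.motif_id, row.h_b, row.H_b, row.md_b, r, R),
            alpha=alpha,
        )
        rows.append((res.motif_id, res.md_a, res.md_b, res.h_a, res.H_a,
                     res.h_b, res.H_b, res.z, res.p, res.significant, res.degenerate))
    return pd.DataFrame(
        rows,
        columns=["motif_id", "md_a", "md_b", "h_a", "H_a", "h_b", "H_b",
                 "z", "p", "significant", "degenerate"],
    )


def significant_motifs(diff_table: pd.DataFrame) -> set[str]:
    """Motif ids flagged significant; intersect sets across comparisons to
    reproduce a multi-condition candidate list."""
    return set(diff_table.loc[diff_table["significant"], "motif_id"])


def write_barcode_tsv(barcodes: Mapping[str, BarcodeMatrix] | BarcodeMatrix, path) -> None:
    if isinstance(barcodes, BarcodeMatrix):
        barcodes = {barcodes.motif_id: barcodes}
    rows = {}
    edges = None
    for motif_id, bc in barcodes.items():
        rows[motif_id] = bc.counts
        edges = bc.bin_edges
    centers = (edges[:-1] + edges[1:]) / 2
    df = pd.DataFrame(rows, index=centers).T
    df.index.name = "motif_id"
    df.to_csv(path, sep="\t")
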