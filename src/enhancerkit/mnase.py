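"""Relative nucleosome protection from tiled MNase-qPCR Ct values.

Chromatin wrapped in a nucleosome resists micrococcal nuclease digestion, so
template survives and amplifies earlier (lower Ct); open chromatin is
digested and amplifies later. With amplification efficiency 2, protection is
estimated per amplicon by the delta-delta-Ct model against a reference
amplicon: protection_i = 2^-(dCt_i - dCt_ref), dCt = Ct_digested -
Ct_undigested. Values are relative to the reference (protection 1 there by
construction) and are reported as mean +/- SD across replicates, ordered
along the tile.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

CT_COLUMNS = ["amplicon_id", "midpoint", "ct_digested", "ct_undigested", "replicate"]


def validate_ct_table(table: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    for col in ("ct_digested", "ct_undigested"):
        vals = table[col].dropna()
        if ((vals <= 0) | (vals >= 45)).any():
            raise ValueError(f"{col} values must lie in (0, 45) cycles")
    mids = table.groupby("amplicon_id")["midpoint"].nunique()
    if (mids > 1).any():
        bad = mids[mids > 1].index.tolist()
        raise ValueError(f"amplicon(s) {bad} have inconsistent midpoints")


def read_ct_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    validate_ct_table(table)
    return table


def write_ct_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def relative_protection(table: pd.DataFrame, reference_amplicon_id: str) -> pd.DataFrame:
    """Per-amplicon relative protection, mean +/- SD across replicates.

    Within each replicate, dCt_i = Ct_digested_i - Ct_undigested_i and
    protection_i = 2^-(dCt_i - dCt_ref). The reference amplicon must be
    present in every replicate. Amplicons missing from some replicate are
    kept and flagged ``incomplete`` rather than silently dropped.

    Returns a DataFrame ordered by midpoint with columns amplicon_id,
    midpoint, protection_mean, protection_sd, n_replicates, incomplete.
    """
    validate_ct_table(table)
    if reference_amplicon_id not in set(table["amplicon_id"]):
        raise ValueError(f"reference amplicon {reference_amplicon_id!r} not in table")

    replicates = sorted(table["replicate"].unique())
    ref_rows = table[table["amplicon_id"] == reference_amplicon_id]
    ref_by_rep = {}
    for rep in replicates:
        sub = ref_rows[ref_rows["replicate"] == rep]
        if len(sub) == 0:
            raise ValueError(
                f"reference amplicon {reference_amplicon_id!r} missing in replicate {rep}"
            )
        ref_by_rep[rep] = float(
            (sub["ct_digested"] - sub["ct_undigested"]).mean()
        )

    rows = []
    for amp, grp in table.groupby("amplicon_id"):
        values = []
        for rep, rep_grp in grp.groupby("replicate"):
            dct = float((rep_grp["ct_digested"] - rep_grp["ct_undigested"]).mean())
            values.append(2.0 ** (-(dct - ref_by_rep[rep])))
        values = np.array(values)
        rows.append(
            (
                amp,
                float(grp["midpoint"].iloc[0]),
                float(values.mean()),
                float(values.std(ddof=1)) if len(values) > 1 else 0.0,
                len(values),
                len(values) < len(replicates),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "amplicon_id", "midpoint", "protection_mean", "protection_sd",
            "n_replicates", "incomplete",
        ],
    )
    return out.sort_values("midpoint", kind="stable").reset_index(drop=True)
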