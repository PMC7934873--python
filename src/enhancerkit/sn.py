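"""Pseudo-bulk single-nucleus contrasts of accessibility and expression.

Nuclei arrive already labeled (sample, disease group, genotype, cell type)
with a total sequencing depth and per-feature counts. Accessibility at a
locus is contrasted between two groups with logistic regression on the
binarized response (any fragment in the region), adjusting for log depth;
expression is contrasted with negative binomial regression with a log-depth
offset. Both tests are likelihood-ratio tests of the group term; p-values
are Bonferroni-adjusted over the number of contrasts actually run.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

REQUIRED_COLUMNS = [
    "nucleus_id",
    "sample_id",
    "disease",
    "genotype",
    "cell_type",
    "total_counts",
]

#: pseudo-offset (counts per 10^4 total) added to a group mean only when it is
#: exactly zero, to keep the fold change finite; flagged degenerate
ZERO_MEAN_OFFSET = 1.0


@dataclass
class RegressionResult:
    """One feature/contrast regression outcome.

    ``fold_change`` is the headline value: for accessibility the ratio of
    depth-normalized group means (counts per 10^4 total), for expression
    exp(group coefficient). ``coef_fold_change`` always carries exp(beta) and
    ``mean_ratio`` the normalized mean ratio, so both conventions are
    available. ``p`` is the likelihood-ratio p-value of the group term.
    """

    feature: str
    contrast: str
    group_a: str
    group_b: str
    fold_change: float
    mean_ratio: float
    coef_fold_change: float
    p: float
    n_a: int
    n_b: int
    method: str
    p_adj: float | None = None
    flags: list[str] = field(default_factory=list)


def validate_nucleus_table(table: pd.DataFrame, features: list[str] | None = None) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"nucleus table missing required columns: {missing}")
    if (table["total_counts"] <= 0).any():
        raise ValueError("total_counts must be positive")
    for feat in features or []:
        if feat not in table.columns:
            raise ValueError(f"feature column {feat!r} not in table")
        if (table[feat] < 0).any() or (table[feat] > table["total_counts"]).any():
            raise ValueError(f"feature {feat!r} counts must satisfy 0 <= count <= total_counts")


def read_nucleus_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    validate_nucleus_table(table)
    return table


def write_nucleus_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def select_nuclei(
    table: pd.DataFrame,
    cell_types=None,
    disease=None,
    genotype=None,
) -> pd.DataFrame:
    """Subset nuclei matching every provided filter.

    Each filter is a label or list of labels; unknown labels raise with the
    available ones listed. An empty subset is allowed (downstream operations
    flag it).
    """
    validate_nucleus_table(table)
    out = table
    for column, wanted in (("cell_type", cell_types), ("disease", disease), ("genotype", genotype)):
        if wanted is None:
            continue
        if isinstance(wanted, str):
            wanted = [wanted]
        available = sorted(table[column].unique())
        unknown = sorted(set(wanted) - set(available))
        if unknown:
            raise ValueError(
                f"unknown {column} label(s) {unknown}; available: {available}"
            )
        out = out[out[column].isin(wanted)]
    return out.reset_index(drop=True)


def _group_split(table: pd.DataFrame, group_variable: str, groups):
    if group_variable not in table.columns:
        raise ValueError(f"unknown group variable {group_variable!r}")
    present = sorted(table[group_variable].unique())
    if groups is None:
        groups = present
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    a, b = groups
    for g in (a, b):
        if g not in present:
            raise ValueError(f"group {g!r} absent; available: {present}")
    mask = table[group_variable].isin([a, b])
    sub = table[mask]
    g = (sub[group_variable] == b).to_numpy(dtype=float)
    n_a, n_b = int((g == 0).sum()), int((g == 1).sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be nonempty")
    return sub, g, str(a), str(b), n_a, n_b


def _normalized_mean_ratio(counts, total, g):
    """Ratio of group means of depth-normalized counts (per 10^4 total)."""
    norm = counts / total * 1e4
    mean_a = float(norm[g == 0].mean())
    mean_b = float(norm[g == 1].mean())
    flags = []
    if mean_a == 0.0 or mean_b == 0.0:
        mean_a += ZERO_MEAN_OFFSET
        mean_b += ZERO_MEAN_OFFSET
        flags.append("zero_group_mean_offset")
    return mean_b / mean_a, flags


def diff_accessibility(
    table: pd.DataFrame,
    feature: str,
    group_variable: str = "disease",
    groups=None,
) -> RegressionResult:
    """Logistic-regression accessibility contrast of *feature* between two groups.

    Response: indicator(feature count > 0). Model: logit(P) = b0 + b1*group +
    b2*log(total_counts); p from the likelihood-ratio test of b1 = 0. The
    headline fold change is the ratio of depth-normalized group mean counts;
    exp(b1) is also reported. Complete separation falls back to an
    L2-penalized fit, flagged.
    """
    validate_nucleus_table(table, [feature])
    sub, g, a, b, n_a, n_b = _group_split(table, group_variable, groups)
    counts = sub[feature].to_numpy(dtype=float)
    total = sub["total_counts"].to_numpy(dtype=float)
    y = (counts > 0).astype(float)
    logd = np.log(total)
    X_full = np.column_stack([np.ones_like(g), g, logd])
    X_red = np.column_stack([np.ones_like(g), logd])

    flags: list[str] = []
    method = "logistic_lrt"
    try:
        with np.errstate(all="ignore"):
            full = sm.Logit(y, X_full).fit(disp=0, maxiter=200)
            red = sm.Logit(y, X_red).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(full.params)) or not np.isfinite(full.llf):
            raise ValueError("non-finite logistic fit")
        beta = float(full.params[1])
        lr = max(2.0 * (full.llf - red.llf), 0.0)
    except Exception:
        # complete separation or failed convergence: small-ridge fallback
        with np.errstate(all="ignore"):
            full = sm.Logit(y, X_full).fit_regularized(alpha=1e-4, L1_wt=0.0, disp=0)
            red = sm.Logit(y, X_red).fit_regularized(alpha=1e-4, L1_wt=0.0, disp=0)
        beta = float(full.params[1])
        lr = max(2.0 * (full.llf - red.llf), 0.0)
        flags.append("separation_penalized")
        method = "logistic_penalized_lrt"
    p = float(chi2.sf(lr, 1))

    mean_ratio, mr_flags = _normalized_mean_ratio(counts, total, g)
    flags.extend(mr_flags)
    return RegressionResult(
        feature=feature,
        contrast=f"{group_variable}:{b} vs {a}",
        group_a=a,
        group_b=b,
        fold_change=mean_ratio,
        mean_ratio=mean_ratio,
        coef_fold_change=float(np.exp(beta)),
        p=p,
        n_a=n_a,
        n_b=n_b,
        method=method,
        flags=flags,
    )


def diff_expression(
    table: pd.DataFrame,
    gene: str,
    group_variable: str = "disease",
    groups=None,
) -> RegressionResult:
    """Negative-binomial expression contrast of *gene* between two groups.

    Model: count ~ NB(mu, alpha) with log mu = b0 + b1*group + log(total)
    offset; the dispersion alpha is estimated by maximum likelihood jointly
    with the coefficients, in both the full and the reduced model, and the
    group term is tested by likelihood ratio. fold_change = exp(b1).
    Nonconvergence falls back to Poisson regression, flagged.
    """
    validate_nucleus_table(table, [gene])
    sub, g, a, b, n_a, n_b = _group_split(table, group_variable, groups)
    y = sub[gene].to_numpy(dtype=float)
    total = sub["total_counts"].to_numpy(dtype=float)
    offset = np.log(total)
    X_full = np.column_stack([np.ones_like(g), g])
    X_red = np.ones((len(g), 1))

    flags: list[str] = []
    method = "negative_binomial_lrt"
    try:
        with np.errstate(all="ignore"):
            pois_full = sm.Poisson(y, X_full, offset=offset).fit(disp=0)
            pois_red = sm.Poisson(y, X_red, offset=offset).fit(disp=0)
            full = sm.NegativeBinomial(y, X_full, offset=offset).fit(
                start_params=np.append(pois_full.params, 0.5), disp=0, maxiter=200
            )
            red = sm.NegativeBinomial(y, X_red, offset=offset).fit(
                start_params=np.append(pois_red.params, 0.5), disp=0, maxiter=200
            )
        converged = full.mle_retvals.get("converged", True) and red.mle_retvals.get(
            "converged", True
        )
        if not converged or not np.all(np.isfinite(full.params)):
            raise ValueError("NB fit did not converge")
        beta = float(full.params[1])
        lr = max(2.0 * (full.llf - red.llf), 0.0)
    except Exception:
        with np.errstate(all="ignore"):
            full = sm.Poisson(y, X_full, offset=offset).fit(disp=0)
            red = sm.Poisson(y, X_red, offset=offset).fit(disp=0)
        beta = float(full.params[1])
        lr = max(2.0 * (full.llf - red.llf), 0.0)
        flags.append("poisson_fallback")
        method = "poisson_lrt"
    p = float(chi2.sf(lr, 1))

    mean_ratio, mr_flags = _normalized_mean_ratio(y, total, g)
    flags.extend(mr_flags)
    return RegressionResult(
        feature=gene,
        contrast=f"{group_variable}:{b} vs {a}",
        group_a=a,
        group_b=b,
        fold_change=float(np.exp(beta)),
        mean_ratio=mean_ratio,
        coef_fold_change=float(np.exp(beta)),
        p=p,
        n_a=n_a,
        n_b=n_b,
        method=method,
        flags=flags,
    )


def adjust_bonferroni(
    results: list[RegressionResult], n_tests: int | None = None
) -> list[RegressionResult]:
    """Set p_adj = min(1, p * n_tests) on each result, order preserved.

    *n_tests* defaults to the number of results and may not be smaller.
    """
    if n_tests is None:
        n_tests = len(results)
    if n_tests < len(results):
        raise ValueError("n_tests must be at least the number of results")
    for res in results:
        res.p_adj = min(1.0, res.p * n_tests)
    return results


def results_table(results: list[RegressionResult]) -> pd.DataFrame:
    rows = [
        (
            r.feature, r.contrast, r.group_a, r.group_b, r.fold_change,
            r.mean_ratio, r.coef_fold_change, r.p, r.p_adj, r.n_a, r.n_b,
            r.method, ";".join(r.flags),
        )
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "feature", "contrast", "group_a", "group_b", "fold_change",
            "mean_ratio", "coef_fold_change", "p", "p_adj", "n_a", "n_b",
            "method", "flags",
        ],
    )


# ---------------------------------------------------------------------------
# Pseudo-bulk coverage


@dataclass
class PseudobulkTrack:
    """Per-base fragment coverage aggregated over a nucleus subset."""

    chrom: str
    start: int
    end: int
    raw: np.ndarray
    normalized: np.ndarray  # per 10^4 nuclei
    n_nuclei: int
    empty: bool


def pseudobulk_profile(
    subset: pd.DataFrame,
    fragments: pd.DataFrame,
    region: tuple[str, int, int],
    chrom_sizes: dict[str, int] | None = None,
) -> PseudobulkTrack:
    """Sum per-base fragment overlap over the nuclei in *subset*.

    *fragments* is BED-like with columns nucleus_id, chrom, start, end.
    The normalized track is scaled to 10^4 nuclei; an empty subset yields a
    zero track flagged ``empty``.
    """
    chrom, start, end = region
    if start < 0 or end <= start:
        raise ValueError("invalid region coordinates")
    if chrom_sizes is not None:
        if chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if end > chrom_sizes[chrom]:
            raise ValueError(f"region end {end} beyond {chrom} length {chrom_sizes[chrom]}")

    n = len(subset)
    raw = np.zeros(end - start)
    if n > 0 and len(fragments) > 0:
        nuclei = set(subset["nucleus_id"])
        sel = fragments[
            (fragments["chrom"] == chrom)
            & fragments["nucleus_id"].isin(nuclei)
            & (fragments["end"] > start)
            & (fragments["start"] < end)
        ]
        diff = np.zeros(end - start + 1)
        s = np.clip(sel["start"].to_numpy() - start, 0, end - start)
        e = np.clip(sel["end"].to_numpy() - start, 0, end - start)
        np.add.at(diff, s, 1.0)
        np.add.at(diff, e, -1.0)
        raw = np.cumsum(diff[:-1])
    normalized = raw * (1e4 / n) if n > 0 else raw.copy()
    return PseudobulkTrack(
        chrom=chrom, start=start, end=end, raw=raw, normalized=normalized,
        n_nuclei=n, empty=n == 0,
    )
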