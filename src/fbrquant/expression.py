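"""Expression-side arithmetic: sample QC, normalization, DEG filtering,
variable-gene selection, PCA and qPCR relative quantification.

Sample QC keeps samples whose RNA integrity number (RIN) is strictly above
3. Sequencing depth is equalized by median-of-ratios size factors. The
differential-expression test here is a per-gene Welch t-test on
log2(normalized + 1) — a deliberately simple stand-in whose contract is
calibrated type-I error on simulated nulls — feeding the study-style DEG
filter: at least a twofold change, base expression above three normalized
counts, and Benjamini-Hochberg adjusted p below 0.01. qPCR fold changes use
the relative-quantification (RQ = 2^-ddCt) method with the strict two-fold
significance rule (RQ > 2 or < 0.5).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_samples_by_rin",
    "size_factors",
    "normalize_counts",
    "de_test",
    "deg_filter",
    "top_k_variable_genes",
    "pca_scores",
    "compute_rq",
]


def filter_samples_by_rin(metadata: pd.DataFrame, threshold: float = 3.0) -> list[str]:
    """Sample ids with RIN strictly above the threshold.

    Samples with missing RIN are excluded with a warning.
    """
    if "RIN" not in metadata.columns:
        raise ValueError("metadata must have a 'RIN' column")
    rin = pd.to_numeric(metadata["RIN"], errors="coerce")
    missing = metadata.index[rin.isna()]
    if len(missing):
        warnings.warn(f"samples without RIN excluded: {list(missing)}", stacklevel=2)
    return list(metadata.index[rin > threshold])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, sf_j is the median over genes (restricted to genes
    with a positive count in every sample, i.e. a finite log geometric
    mean) of count_gj / geometric_mean_g. Factors are reported with
    geometric mean 1, which leaves every between-sample ratio untouched
    and makes normalization idempotent: the size factors of an already
    normalized matrix are all exactly 1.
    """
    c = counts.to_numpy(dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    with np.errstate(divide="ignore"):
        logc = np.log(c)
    log_geomean = logc.mean(axis=1)
    usable = np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; size factors are undefined "
            "(filter all-zero genes or provide deeper coverage)"
        )
    log_ratios = logc[usable] - log_geomean[usable, None]
    log_sf = np.median(log_ratios, axis=0)
    sf = np.exp(log_sf - log_sf.mean())  # geometric mean 1
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, sf: pd.Series | None = None) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if sf is None:
        sf = size_factors(counts)
    return counts / sf


def de_test(
    normalized: pd.DataFrame,
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-gene Welch t-test on log2(normalized + 1) between two groups.

    log2 fold change is the difference of group means on the transformed
    scale (group_b minus group_a); p-values are BH-adjusted across genes.
    Genes with zero variance in both groups get p = 1 (test undefined).
    Returns a frame with gene, base_mean, log2_fold_change, p_value,
    adjusted_p.
    """
    groups = groups.reindex(normalized.columns)
    a_cols = groups.index[groups == group_a]
    b_cols = groups.index[groups == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need at least 2 samples per group")

    log_a = np.log2(normalized[a_cols].to_numpy(dtype=float) + 1.0)
    log_b = np.log2(normalized[b_cols].to_numpy(dtype=float) + 1.0)
    lfc = log_b.mean(axis=1) - log_a.mean(axis=1)
    base_mean = normalized[list(a_cols) + list(b_cols)].mean(axis=1).to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
    zero_var = (log_a.var(axis=1) == 0) & (log_b.var(axis=1) == 0)
    p = np.where(zero_var | ~np.isfinite(p), 1.0, p)
    adj = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene": normalized.index,
            "base_mean": base_mean,
            "log2_fold_change": lfc,
            "p_value": p,
            "adjusted_p": adj,
        }
    ).set_index("gene")


def deg_filter(
    records: pd.DataFrame,
    fc_min: float = 2.0,
    base_min: float = 3.0,
    padj_max: float = 0.01,
    fc_inclusive: bool = True,
) -> pd.Index:
    """Genes passing the differential-expression filter.

    Keeps genes with at least an ``fc_min``-fold change (|log2FC| >=
    log2(fc_min), inclusive by default), base expression strictly above
    ``base_min`` normalized counts, and adjusted p strictly below
    ``padj_max``.
    """
    lfc_min = np.log2(fc_min)
    abs_lfc = records["log2_fold_change"].abs()
    fc_ok = abs_lfc >= lfc_min if fc_inclusive else abs_lfc > lfc_min
    keep = fc_ok & (records["base_mean"] > base_min) & (records["adjusted_p"] < padj_max)
    return records.index[keep]


def top_k_variable_genes(normalized: pd.DataFrame, k: int = 500) -> pd.Index:
    """Top k genes by across-sample variance of log2(normalized + 1).

    Ties are broken by gene id order, so the selection is deterministic.
    """
    if k > len(normalized):
        raise ValueError(f"k={k} exceeds the number of genes ({len(normalized)})")
    logx = np.log2(normalized.to_numpy(dtype=float) + 1.0)
    var = pd.Series(logx.var(axis=1, ddof=1), index=normalized.index)
    order = var.to_frame("var").sort_index().sort_values("var", ascending=False, kind="stable")
    return order.index[:k]


def pca_scores(matrix: pd.DataFrame, n_components: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of a genes x samples matrix; samples are observations.

    Returns (scores, explained_variance_fractions). Scores columns are
    orthogonal; fractions are non-increasing and sum to at most 1.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x genes
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0)
    total_var = (Xc**2).sum()
    if total_var == 0:
        raise ValueError("matrix has zero variance across samples")
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, len(s))
    scores = U[:, :n_components] * s[:n_components]
    frac = (s**2 / total_var)[:n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=matrix.columns, columns=cols), frac


def compute_rq(
    ct_table: pd.DataFrame,
    housekeeping_gene: str,
    reference_group: str,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Relative quantification (RQ = 2^-ddCt) per gene and group.

    dCt = Ct_gene - Ct_housekeeping within each sample; dCt is averaged
    within group before differencing against the reference group's mean.
    The significance flag follows the strict two-fold rule: RQ strictly
    greater than ``fold_threshold`` or strictly less than its reciprocal.
    Samples lacking a housekeeping Ct are dropped with a warning.
    """
    for col in ("sample", "group", "gene", "ct"):
        if col not in ct_table.columns:
            raise ValueError(f"Ct table missing column {col!r}")
    hk = ct_table[ct_table["gene"] == housekeeping_gene].set_index("sample")["ct"]
    if hk.empty:
        raise ValueError(f"housekeeping gene {housekeeping_gene!r} not found")
    goi = ct_table[ct_table["gene"] != housekeeping_gene].copy()
    no_hk = set(goi["sample"]) - set(hk.index)
    if no_hk:
        warnings.warn(f"samples dropped (no housekeeping Ct): {sorted(no_hk)}", stacklevel=2)
        goi = goi[~goi["sample"].isin(no_hk)]
    goi["dct"] = goi["ct"] - goi["sample"].map(hk)

    mean_dct = goi.groupby(["gene", "group"])["dct"].mean()
    ref = mean_dct.xs(reference_group, level="group")
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} not found")

    rows = []
    for (gene, group), dct in mean_dct.items():
        if gene not in ref.index:
            continue
        ddct = dct - ref[gene]
        rq = 2.0 ** (-ddct)
        rows.append(
            {
                "gene": gene,
                "group": group,
                "rq": rq,
                "significant": bool(rq > fold_threshold or rq < 1.0 / fold_threshold),
            }
        )
    return pd.DataFrame(rows)
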