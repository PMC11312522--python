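"""Group-wise differential abundance, z-scoring and hierarchical clustering.

Testing is a two-sided independent two-sample t-test per metabolite on
the threshold-imputed intensity matrix (pooled-variance Student by
default, Welch optional), with raw p < alpha (0.05) as the significance
rule. Benjamini-Hochberg q-values are reported alongside but do not
drive the flag. Fold changes whose group means include imputed cells are
flagged as bounds (``fc_is_bound``), since threshold imputation caps the
ratio. Heatmap ordering uses row z-scores (sample standard deviation)
and agglomerative clustering with Euclidean distance / complete linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _scistats
from scipy.cluster.hierarchy import ClusterWarning, leaves_list, linkage
from statsmodels.stats.multitest import multipletests

__all__ = ["ClusterResult", "ttest_groups", "zscore_rows", "hierarchical_cluster", "volcano_table"]


def ttest_groups(
    imputed: pd.DataFrame,
    samples: pd.DataFrame,
    group_a: str,
    group_b: str,
    alpha: float = 0.05,
    variant: str = "student",
    detected: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-metabolite two-sided t-test of group B vs group A.

    Returns a table with columns metabolite, mean_A, mean_B, log2fc, t,
    p, q, significant, fc_is_bound. log2fc = log2(mean_B / mean_A) on the
    imputed matrix (imputation guarantees positive means when thresholds
    are positive). Zero variance in both groups with equal means yields
    p = 1 by convention. ``detected`` (flags aligned with ``imputed``)
    marks fold changes that rest on imputed cells as bounds.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"test variant must be 'student' or 'welch', got {variant!r}")
    a_cols = [s for s in imputed.columns if samples.loc[s, "group"] == group_a]
    b_cols = [s for s in imputed.columns if samples.loc[s, "group"] == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            f"each group needs >= 2 samples, got {group_a}: {len(a_cols)}, {group_b}: {len(b_cols)}"
        )
    if set(a_cols) & set(b_cols):
        raise ValueError("groups must be disjoint")

    a = imputed[a_cols].to_numpy(dtype=float)
    b = imputed[b_cols].to_numpy(dtype=float)
    with warnings.catch_warnings():
        # zero-variance rows warn about precision; they are resolved by the
        # degenerate-row convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p_val = _scistats.ttest_ind(a, b, axis=1, equal_var=(variant == "student"))
    t_stat = np.asarray(t_stat, dtype=float)
    p_val = np.asarray(p_val, dtype=float)

    # degenerate rows: zero variance in both groups -> NaN from the test
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    t_stat = np.where(degenerate, 0.0, t_stat)
    p_val = np.where(degenerate & equal_means, 1.0, np.where(degenerate & ~equal_means, 0.0, p_val))

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(divide="ignore"):
        log2fc = np.log2(mean_b / mean_a)
    q = multipletests(p_val, method="fdr_bh")[1]
    if detected is not None:
        fc_is_bound = ~detected[a_cols + b_cols].all(axis=1).to_numpy()
    else:
        fc_is_bound = np.zeros(len(imputed), dtype=bool)
    return pd.DataFrame(
        {
            "metabolite": imputed.index,
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2fc": log2fc,
            "t": t_stat,
            "p": p_val,
            "q": q,
            "significant": p_val < alpha,
            "fc_is_bound": fc_is_bound,
        }
    ).reset_index(drop=True)


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores with sample (n-1) standard deviation; constant
    rows map to all zeros."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True) if values.shape[1] > 1 else np.zeros_like(mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (values - mean) / sd, 0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


@dataclass
class ClusterResult:
    """Deterministic two-way clustering of a z-scored matrix."""

    row_order: list[str]
    col_order: list[str]
    z: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None


def hierarchical_cluster(
    z: pd.DataFrame, metric: str = "euclidean", method: str = "complete"
) -> ClusterResult:
    """Agglomerative clustering of rows (and columns when >= 2) of a
    z-scored matrix; emits leaf orders for heatmap layout."""
    if z.isna().to_numpy().any():
        raise ValueError("matrix contains NaN; z-score and impute before clustering")
    if len(z.index) < 2:
        raise ValueError("clustering needs >= 2 rows")
    with warnings.catch_warnings():
        # square observation matrices trip scipy's distance-matrix heuristic
        warnings.simplefilter("ignore", ClusterWarning)
        row_link = linkage(z.to_numpy(), method=method, metric=metric)
        row_order = [z.index[i] for i in leaves_list(row_link)]
        col_link = None
        col_order = list(z.columns)
        if len(z.columns) >= 2:
            col_link = linkage(z.to_numpy().T, method=method, metric=metric)
            col_order = [z.columns[i] for i in leaves_list(col_link)]
    return ClusterResult(row_order, col_order, z, row_link, col_link)


def volcano_table(comparisons: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready coordinates: log2fc vs -log10 p with the significance flag."""
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(comparisons["p"].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "metabolite": comparisons["metabolite"],
            "log2fc": comparisons["log2fc"],
            "neg_log10_p": neg_log10_p,
            "significant": comparisons["significant"],
        }
    )
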