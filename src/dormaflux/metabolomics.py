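"""Metabolite-table preprocessing and volcano analysis.

The stage mirrors a standard targeted-metabolomics workflow: missing values
are imputed with a K-nearest-neighbor rule in metabolite (feature) space,
abundances are normalized by log Pareto scaling (log10, mean-center, divide
by the square root of the SD), samples far outside the 95% Hotelling T^2
ellipse of the first two principal components are removed, and two-group
comparisons are displayed as a volcano where significance requires BOTH
|log2 fold-change| > 1 and a two-sided t-test p < 0.05.

Note: the volcano filter applies no multiple-testing correction — the
significance gate is the conjunction of the raw p-value and the fold-change
threshold.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .synthetic import MetaboliteTable

__all__ = [
    "knn_impute",
    "log_pareto_scale",
    "detect_outliers",
    "volcano",
    "count_significant_by_class",
]


def knn_impute(table: MetaboliteTable, k: int = 10) -> MetaboliteTable:
    """Impute missing cells from the k nearest metabolites.

    Distance between two metabolites is the Euclidean distance over the
    samples where both are observed; a missing cell is replaced by the mean
    of that sample's observed values across the k nearest metabolites.
    Observed cells are preserved bit-exactly.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = table.abundances
    if k >= X.shape[1]:
        raise ValueError(f"k={k} must be smaller than the metabolite count {X.shape[1]}")
    all_missing = X.columns[X.isna().all(axis=0)]
    if len(all_missing):
        raise ValueError(
            f"metabolite(s) with no observed values: {list(all_missing)}"
        )
    values = X.to_numpy(dtype=float)
    mask = np.isnan(values)
    if not mask.any():
        out = table.copy()
        out.provenance.append("knn_impute: no missing values")
        return out

    n_samples, n_mets = values.shape
    imputed = values.copy()
    # pairwise distances over mutually observed samples
    obs = ~mask
    dist = np.full((n_mets, n_mets), np.inf)
    for j in range(n_mets):
        both = obs[:, j][:, None] & obs
        diff = np.where(both, values[:, j][:, None] - np.where(mask, 0, values), 0.0)
        counts = both.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.sqrt((diff**2).sum(axis=0))
        d[counts == 0] = np.inf
        dist[j] = d
    np.fill_diagonal(dist, np.inf)

    order = np.argsort(dist, axis=1)
    for j in range(n_mets):
        missing_rows = np.flatnonzero(mask[:, j])
        if missing_rows.size == 0:
            continue
        neighbors = order[j][np.isfinite(dist[j][order[j]])][:k]
        for i in missing_rows:
            donor = neighbors[obs[i, neighbors]]
            if donor.size == 0:
                # fall back to the metabolite's own observed mean
                imputed[i, j] = values[obs[:, j], j].mean()
            else:
                imputed[i, j] = values[i, donor].mean()

    out = table.copy()
    out.abundances = pd.DataFrame(imputed, index=X.index, columns=X.columns)
    out.provenance.append(f"knn_impute(k={k}): {int(mask.sum())} cells imputed")
    return out


def log_pareto_scale(table: MetaboliteTable) -> MetaboliteTable:
    """log10 transform, then per metabolite (x - mean) / sqrt(sd).

    Zero-variance metabolites scale to all zeros with a warning.
    """
    X = table.abundances
    if X.isna().any().any():
        raise ValueError("impute missing values before scaling")
    if (X <= 0).any().any():
        raise ValueError("abundances must be > 0 for a log transform")
    logged = np.log10(X.to_numpy(dtype=float))
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    flat = sd < 1e-12  # tolerance: identical values leave ~1 ulp of jitter
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance metabolite(s) scaled to 0",
            stacklevel=2,
        )
    denom = np.where(flat, 1.0, np.sqrt(sd))
    scaled = (logged - mean) / denom
    scaled[:, flat] = 0.0
    out = table.copy()
    out.abundances = pd.DataFrame(scaled, index=X.index, columns=X.columns)
    out.provenance.append("log_pareto_scale")
    return out


def detect_outliers(
    table: MetaboliteTable, *, n_components: int = 2, alpha: float = 0.05
) -> list[str]:
    """Flag samples outside the (1 - alpha) Hotelling T^2 ellipse of the
    first ``n_components`` principal-component scores of the scaled table.

    Returns the flagged sample names (callers drop them before testing).
    """
    X = table.abundances.to_numpy(dtype=float)
    n = X.shape[0]
    if n <= n_components + 1:
        raise ValueError(
            f"need more than {n_components + 1} samples for {n_components}-component "
            "outlier detection"
        )
    scores = PCA(n_components=n_components).fit_transform(X)
    var = scores.var(axis=0, ddof=1)
    t2 = (scores**2 / var).sum(axis=1)
    p = n_components
    # exact null for *internally* studentized T^2 (the scores come from a
    # PCA of the same samples): T^2 * n / (n-1)^2 ~ Beta(p/2, (n-p-1)/2).
    # The F-form limit applies to external observations only and exceeds the
    # largest attainable internal T^2 at small n, masking every outlier.
    limit = (n - 1) ** 2 / n * sps.beta.ppf(1.0 - alpha, p / 2.0, (n - p - 1) / 2.0)
    flagged = table.abundances.index[t2 > limit]
    return list(flagged)


def volcano(
    table_raw_imputed: MetaboliteTable,
    table_scaled: MetaboliteTable | None,
    group_a: str,
    group_b: str,
    *,
    exclude_samples: list[str] | None = None,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Two-group volcano: log2(mean_A / mean_B) on imputed raw abundances,
    two-sided t-test on log-transformed values, significance by the
    conjunction |log2FC| > ``fc_threshold`` AND p < ``p_threshold``.

    Returns a DataFrame indexed by metabolite with columns
    class, log2fc, p_value, significant, direction.
    """
    X = table_raw_imputed.abundances
    if X.isna().any().any():
        raise ValueError("volcano requires an imputed (complete) table")
    groups = table_raw_imputed.group
    keep = X.index.difference(exclude_samples or [])
    X = X.loc[keep]
    groups = groups.loc[keep]
    idx_a = groups[groups == group_a].index
    idx_b = groups[groups == group_b].index
    if len(idx_a) < 3 or len(idx_b) < 3:
        raise ValueError(
            f"both groups need >= 3 samples after outlier removal "
            f"(got {len(idx_a)} vs {len(idx_b)})"
        )
    a = X.loc[idx_a].to_numpy(dtype=float)
    b = X.loc[idx_b].to_numpy(dtype=float)
    log2fc = np.log2(a.mean(axis=0) / b.mean(axis=0))
    _, p = sps.ttest_ind(np.log10(a), np.log10(b), axis=0, equal_var=False)
    significant = (np.abs(log2fc) > fc_threshold) & (p < p_threshold)
    direction = np.where(log2fc > 0, "increased", "decreased")
    return pd.DataFrame(
        {
            "class": table_raw_imputed.metabolite_class.reindex(X.columns).values,
            "log2fc": log2fc,
            "p_value": p,
            "significant": significant,
            "direction": direction,
        },
        index=X.columns.rename("metabolite"),
    )


def count_significant_by_class(
    volcano_result: pd.DataFrame, metabolite_class: str, direction: str
) -> int:
    """Count metabolites of one class passing the filter in one direction."""
    if metabolite_class not in set(volcano_result["class"]):
        raise ValueError(f"unknown metabolite class {metabolite_class!r}")
    if direction not in {"increased", "decreased"}:
        raise ValueError("direction must be 'increased' or 'decreased'")
    sub = volcano_result
    return int(
        (
            (sub["class"] == metabolite_class)
            & sub["significant"]
            & (sub["direction"] == direction)
        ).sum()
    )
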