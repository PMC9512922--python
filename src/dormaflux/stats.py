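"""Pixel-distribution statistics.

Calibrated images from several mice at one timepoint are pooled pixel-wise;
group comparisons use the two-sample Kolmogorov–Smirnov statistic with a
*blocked* permutation null in which whole mice — not pixels — are
exchanged between groups.  Pixels within a mouse are strongly correlated
(they share illumination, probe dose and tumor physiology), so the mouse is
the exchangeable unit; permuting pixels directly wildly inflates the type-I
error.  Group-mean comparisons (log2 fold-change with Welch t-test, one-way
ANOVA with Tukey HSD) operate on per-mouse mean intensities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .correction import CalibratedImage

__all__ = [
    "PixelPool",
    "PDFCurve",
    "BlockedKSResult",
    "FoldChangeResult",
    "pool_pixels",
    "compute_pdf",
    "ks_statistic",
    "blocked_permutation_test",
    "naive_permutation_test",
    "log2_fold_change",
    "anova_tukey",
]


@dataclass
class PixelPool:
    """Pooled calibrated pixels with a mouse label per pixel."""

    values: np.ndarray
    mouse_ids: np.ndarray
    group: str = ""
    probe: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mouse_ids = np.asarray(self.mouse_ids)
        if self.values.shape != self.mouse_ids.shape:
            raise ValueError("values and mouse_ids must align")
        if self.values.size and (
            not np.all(np.isfinite(self.values)) or np.any(self.values < 0)
        ):
            raise ValueError("pool values must be finite and >= 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def mice(self) -> list:
        return list(dict.fromkeys(self.mouse_ids.tolist()))  # stable order

    def by_mouse(self) -> dict:
        return {m: self.values[self.mouse_ids == m] for m in self.mice}

    def mouse_means(self) -> np.ndarray:
        return np.array([v.mean() for v in self.by_mouse().values()])


def pool_pixels(
    images: list[CalibratedImage], *, group: str = "", timepoint: str | None = None
) -> PixelPool:
    """Concatenate valid pixels across mice at one probe/timepoint."""
    if not images:
        raise ValueError("no images to pool")
    probes = {im.probe for im in images}
    if len(probes) != 1:
        raise ValueError(f"cannot pool across probes: {sorted(probes)}")
    timepoints = {im.timepoint for im in images}
    if timepoint is None:
        if len(timepoints) != 1:
            raise ValueError(f"cannot pool across timepoints: {sorted(timepoints)}")
        timepoint = timepoints.pop()
    values, mouse_ids = [], []
    for im in images:
        v = im.valid_pixels
        values.append(v)
        mouse_ids.append(np.full(v.size, im.mouse_id, dtype=object))
    return PixelPool(
        values=np.concatenate(values),
        mouse_ids=np.concatenate(mouse_ids),
        group=group,
        probe=probes.pop(),
        timepoint=timepoint,
    )


@dataclass
class PDFCurve:
    """Density-normalized histogram plus the pooled mean (the vertical line
    superimposed on ridgeline plots)."""

    bin_edges: np.ndarray
    densities: np.ndarray
    group_mean: float
    group: str = ""

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def compute_pdf(pool: PixelPool, n_bins: int = 100, *, vmax: float | None = None) -> PDFCurve:
    """Histogram the pooled pixels over [0, max] as a probability density.

    Binning is presentation only; all testing happens on the raw values.
    """
    if len(pool) == 0:
        raise ValueError("empty pixel pool")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    top = float(pool.values.max() if vmax is None else vmax)
    if top < 1e-12:  # empty-range guard: all-zero (or subnormal) pools
        top = 1.0
    edges = np.linspace(0.0, top, n_bins + 1)
    densities, edges = np.histogram(pool.values, bins=edges, density=True)
    return PDFCurve(
        bin_edges=edges,
        densities=densities,
        group_mean=float(pool.values.mean()),
        group=pool.group,
    )


def ks_statistic(values_a, values_b) -> float:
    """D = sup |ECDF_A - ECDF_B| on raw (unbinned) values."""
    a = np.sort(np.asarray(values_a, dtype=float).ravel())
    b = np.sort(np.asarray(values_b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


@dataclass
class BlockedKSResult:
    """Blocked-permutation KS test outcome."""

    D_obs: float
    p_empirical: float
    n_permutations: int
    permutation_Ds: np.ndarray = field(repr=False, default=None)
    exhaustive: bool = False


def _mouse_blocks(pool_a: PixelPool, pool_b: PixelPool):
    blocks = list(pool_a.by_mouse().values()) + list(pool_b.by_mouse().values())
    n_a = len(pool_a.mice)
    n_b = len(pool_b.mice)
    if n_a < 2 or n_b < 2:
        raise ValueError(
            "each group needs >= 2 mice for a valid blocked permutation null"
        )
    return blocks, n_a, n_b


def blocked_permutation_test(
    pool_a: PixelPool,
    pool_b: PixelPool,
    n_perm: int = 1000,
    seed: int | None = None,
    *,
    exhaustive: bool | None = None,
) -> BlockedKSResult:
    """KS test with a mouse-blocked permutation null.

    Each permutation reassigns whole mice (with all their pixels) between the
    two group labels, preserving the group sizes in mice, and recomputes D on
    the re-pooled pixels.  When the number of distinct reassignments is at
    most ``n_perm`` the null is enumerated exhaustively and the exact
    fraction is reported; otherwise ``n_perm`` random reassignments are drawn
    and the add-one estimator p = (1 + #{D_perm >= D_obs}) / (n_perm + 1)
    is used.  ``exhaustive`` forces either mode (True fails if enumeration
    exceeds ``n_perm``; False always samples).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    blocks, n_a, n_b = _mouse_blocks(pool_a, pool_b)
    d_obs = ks_statistic(pool_a.values, pool_b.values)
    n_total = n_a + n_b
    n_distinct = math.comb(n_total, n_a)

    def d_for(assignment_a: tuple[int, ...]) -> float:
        in_a = np.zeros(n_total, dtype=bool)
        in_a[list(assignment_a)] = True
        va = np.concatenate([blocks[i] for i in range(n_total) if in_a[i]])
        vb = np.concatenate([blocks[i] for i in range(n_total) if not in_a[i]])
        return ks_statistic(va, vb)

    if exhaustive is True and n_distinct > n_perm:
        raise ValueError(
            f"{n_distinct} distinct reassignments exceed n_perm={n_perm}; "
            "cannot enumerate exhaustively"
        )
    if exhaustive is not False and n_distinct <= n_perm:
        ds = np.array([d_for(c) for c in combinations(range(n_total), n_a)])
        # exact permutation p: fraction of the full null reaching D_obs
        # (the identity assignment is part of the enumeration, so p > 0)
        p = float(np.count_nonzero(ds >= d_obs - 1e-12) / n_distinct)
        return BlockedKSResult(d_obs, p, n_distinct, ds, exhaustive=True)

    rng = np.random.default_rng(seed)
    ds = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(n_total)
        ds[k] = d_for(tuple(perm[:n_a]))
    p = float((1 + np.count_nonzero(ds >= d_obs - 1e-12)) / (n_perm + 1))
    return BlockedKSResult(d_obs, p, n_perm, ds, exhaustive=False)


def naive_permutation_test(
    pool_a: PixelPool,
    pool_b: PixelPool,
    n_perm: int = 1000,
    seed: int | None = None,
) -> BlockedKSResult:
    """Pixel-level permutation KS test (ignores mouse blocks).

    Provided as the invalid comparator: with within-mouse correlation its
    type-I error is grossly inflated.  Same add-one p estimator.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d_obs = ks_statistic(pool_a.values, pool_b.values)
    pooled = np.concatenate([pool_a.values, pool_b.values])
    n_a = pool_a.values.size
    rng = np.random.default_rng(seed)
    ds = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(pooled.size)
        ds[k] = ks_statistic(pooled[perm[:n_a]], pooled[perm[n_a:]])
    p = float((1 + np.count_nonzero(ds >= d_obs - 1e-12)) / (n_perm + 1))
    return BlockedKSResult(d_obs, p, n_perm, ds, exhaustive=False)


@dataclass(frozen=True)
class FoldChangeResult:
    """Log2 ratio of group means with a Welch t-test on per-mouse means."""

    log2fc: float
    mean_a: float
    mean_b: float
    t_stat: float
    p_value: float


def log2_fold_change(means_a, means_b) -> FoldChangeResult:
    """log2(mean_A / mean_B) of per-mouse means; Welch two-sided t-test."""
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 per-mouse means")
    ma, mb = float(a.mean()), float(b.mean())
    if ma <= 0 or mb <= 0:
        raise ValueError("group means must be positive for a log fold-change")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return FoldChangeResult(
        log2fc=math.log2(ma / mb), mean_a=ma, mean_b=mb,
        t_stat=float(t), p_value=float(p),
    )


def anova_tukey(groups: list, labels: list[str] | None = None):
    """One-way fixed-effects ANOVA followed by Tukey HSD pairwise comparisons.

    Returns ``(F, p, pairwise)`` where ``pairwise`` maps (label_i, label_j)
    to the studentized-range adjusted p-value.  When every observation is
    identical the comparison is degenerate and reported as F=0, p=1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs >= 2 values")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    concat = np.concatenate(groups)
    if np.ptp(concat) == 0:
        warnings.warn("all observations identical; ANOVA degenerate", stacklevel=2)
        pairs = {
            (labels[i], labels[j]): 1.0
            for i, j in combinations(range(len(groups)), 2)
        }
        return 0.0, 1.0, pairs
    F, p = sps.f_oneway(*groups)
    codes = np.concatenate([[lab] * g.size for lab, g in zip(labels, groups)])
    tukey = pairwise_tukeyhsd(concat, codes)
    pairwise = {}
    summary = tukey.summary()
    for row, padj in zip(summary.data[1:], tukey.pvalues):
        pairwise[(str(row[0]), str(row[1]))] = float(padj)
    return float(F), float(p), pairwise
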