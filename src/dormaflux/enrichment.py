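"""Rank-based gene-set enrichment with a KS running-sum statistic.

Expression is first scaled per gene by its maximum, genes are ranked by the
log2 fold-change of group means (descending), and a gene set's enrichment
score (ES) is the signed extremum of the classic unweighted
Kolmogorov–Smirnov running sum over the ranked list — the deviation of the
member-rank ECDF from the uniform ECDF over all ranks (+1/|S| - 1/N at
members, -1/N elsewhere).  Nominal p-values come from a gene-label
permutation null (random same-size sets), compared on |ES|; NES is the
observed ES divided by the mean |ES| under that null.

Gene-label permutation (rather than phenotype permutation) is used because
the designs of interest have ~5 samples per group, which admits too few
distinct phenotype relabelings for a stable null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RankedGeneList",
    "EnrichmentResult",
    "normalize_expression",
    "rank_by_fold_change",
    "enrichment_score",
    "permutation_pvalue",
]

PSEUDOCOUNT = 1e-6  # guards log2 fold-change against zero group means


@dataclass
class RankedGeneList:
    """Genes ordered by ranking metric, descending; ties broken by gene id."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate gene ids in ranked list")
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != self.metric.size:
            raise ValueError("genes and metric must align")

    def __len__(self) -> int:
        return len(self.genes)


def normalize_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each gene's values by that gene's maximum (range (0, 1]).

    All-zero genes cannot be scaled and are dropped with a warning.
    """
    matrix = matrix.astype(float)
    gene_max = matrix.max(axis=1)
    zero = gene_max <= 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} gene(s) with no expression", stacklevel=2
        )
        matrix = matrix.loc[~zero]
        gene_max = gene_max[~zero]
    return matrix.div(gene_max, axis=0)


def rank_by_fold_change(
    matrix: pd.DataFrame, sample_groups: pd.Series, group_a: str, group_b: str
) -> RankedGeneList:
    """Rank genes by log2(mean_A / mean_B) of max-normalized expression.

    Descending order; exact ties broken lexicographically by gene id.
    """
    idx_a = sample_groups[sample_groups == group_a].index
    idx_b = sample_groups[sample_groups == group_b].index
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    norm = normalize_expression(matrix)
    mean_a = norm[idx_a].mean(axis=1) + PSEUDOCOUNT
    mean_b = norm[idx_b].mean(axis=1) + PSEUDOCOUNT
    metric = np.log2(mean_a / mean_b)
    order = sorted(norm.index, key=lambda g: (-metric[g], g))
    return RankedGeneList(genes=order, metric=metric[order].to_numpy())


def _es_from_positions(positions: np.ndarray, N: int) -> float:
    """KS running-sum extremum given sorted 0-based member positions.

    One-sample KS convention: the deviation tracked is the member-rank ECDF
    against the uniform ECDF over all N ranks — the sum gains 1/|S| at each
    member and drifts down by 1/N at every position, ending at 0.  Members
    occupying the top k of N therefore score 1 - k/N and a single member at
    the very top scores 1 - 1/N.  The sum is piecewise linear between hits,
    so only the 2k values just before/after each member are candidates for
    the extremum.
    """
    k = positions.size
    i = np.arange(1, k + 1, dtype=float)
    after_hit = i / k - (positions + 1) / N  # value just after hit i
    before_hit = (i - 1) / k - positions / N  # value just before hit i
    candidates = np.concatenate([after_hit, before_hit, [0.0]])
    return float(candidates[np.argmax(np.abs(candidates))])


def enrichment_score(
    ranked: RankedGeneList, geneset, *, weighted: bool = False
) -> float:
    """Signed extremum of the KS running sum over the ranked list.

    Unweighted (classic one-sample KS) by default: walking the ranked list,
    the sum gains 1/|S| at members and loses 1/N at every gene, so it tracks
    the deviation of the member-rank ECDF from uniform and ends at 0; ES is
    the value of largest magnitude it attains.  ``weighted=True`` replaces
    the member increment with |metric|-weighted steps (GSEA p=1 variant).
    """
    members = set(geneset)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool)
    n_hit = int(hit.sum())
    N = len(ranked)
    if n_hit == 0:
        raise ValueError("gene set has no overlap with the ranked list")
    if n_hit == N:
        raise ValueError("gene set covers the entire ranked list")
    if weighted:
        w = np.abs(ranked.metric) * hit
        total = w.sum()
        if total == 0:
            w = hit.astype(float)
            total = float(n_hit)
        steps = np.where(hit, w / total, 0.0) - 1.0 / N
        running = np.cumsum(steps)
        return float(running[np.argmax(np.abs(running))])
    return _es_from_positions(np.flatnonzero(hit).astype(float), N)


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment score with permutation p-value and normalized score."""

    name: str
    ES: float
    NES: float
    p_nominal: float
    n_permutations: int
    overlap: int


def permutation_pvalue(
    ranked: RankedGeneList,
    geneset,
    n_perm: int = 1000,
    seed: int | None = None,
    *,
    name: str = "",
    weighted: bool = False,
) -> EnrichmentResult:
    """Gene-label permutation null for one gene set.

    Null ES values come from random same-size gene sets; the nominal p is the
    add-one one-sided fraction with |ES_perm| >= |ES_obs|, and
    NES = ES / mean(|ES_perm|).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    members = [g for g in set(geneset) if g in set(ranked.genes)]
    if not members:
        raise ValueError("gene set has no overlap with the ranked list")
    es_obs = enrichment_score(ranked, members, weighted=weighted)
    rng = np.random.default_rng(seed)
    genes = np.asarray(ranked.genes, dtype=object)
    size = len(members)
    N = len(ranked)
    null = np.empty(n_perm)
    for k in range(n_perm):
        if weighted:
            random_set = rng.choice(genes, size=size, replace=False)
            null[k] = enrichment_score(ranked, random_set, weighted=True)
        else:
            positions = np.sort(rng.choice(N, size=size, replace=False)).astype(float)
            null[k] = _es_from_positions(positions, N)
    p = float((1 + np.count_nonzero(np.abs(null) >= abs(es_obs) - 1e-12)) / (n_perm + 1))
    nes = es_obs / float(np.abs(null).mean())
    return EnrichmentResult(
        name=name,
        ES=es_obs,
        NES=float(nes),
        p_nominal=p,
        n_permutations=n_perm,
        overlap=size,
    )
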