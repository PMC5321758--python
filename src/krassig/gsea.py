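"""Preranked gene-set enrichment: ES, permutation significance, leading edge.

The enrichment score is the weighted Kolmogorov-Smirnov statistic: walking
down a list ranked by log2 fold change, member genes add
``|metric|^p / N_R`` and non-members subtract ``1/(N - N_H)``; the ES is
the signed maximum deviation of this running sum.  Significance comes from
a gene-resampling null (random same-size sets from the ranked list), which
is the only null available once the data are reduced to a ranked list.

The leading edge is the subset of the gene set at or before the extreme of
the running sum; the cross-cohort core signature keeps genes recurrent in
more than half of the leading edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diffexpr import DEResult
from .matrix import GeneSetCollection


class GseaError(ValueError):
    pass


@dataclass
class RankedList:
    """Genes ordered by descending metric; ties broken by ascending symbol."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise GseaError("ranked list contains duplicate genes")
        if self.metric.shape != (len(self.genes),):
            raise GseaError("metric length does not match genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    es: float
    running_sum: np.ndarray
    hit_ranks: np.ndarray                  # 0-based positions of set members
    nes: float = np.nan
    p_value: float = np.nan
    leading_edge: list[str] = field(default_factory=list)
    null_es: np.ndarray | None = None


def rank_by_logfc(de: DEResult) -> RankedList:
    """Rank genes by log2 fold change, descending; ties ascending by symbol."""
    if not de.genes:
        raise GseaError("empty DE result")
    order = sorted(range(len(de.genes)), key=lambda i: (-de.log2fc[i], de.genes[i]))
    return RankedList(
        genes=[de.genes[i] for i in order],
        metric=de.log2fc[np.array(order)],
    )


def _hit_mask(ranked: RankedList, gene_set: list[str]) -> np.ndarray:
    members = set(gene_set)
    return np.array([g in members for g in ranked.genes], dtype=bool)


def enrichment_score(
    ranked: RankedList, gene_set: list[str], weight_p: float = 1.0
) -> GseaResult:
    """Weighted KS running-sum enrichment score for one (list, set) pair."""
    hits = _hit_mask(ranked, gene_set)
    n = len(ranked)
    n_h = int(hits.sum())
    if n_h == 0:
        raise GseaError("gene set not represented in the ranked list")
    if n_h == n:
        raise GseaError("gene set covers the entire ranked list; P_miss undefined")
    weights = np.abs(ranked.metric) ** weight_p
    w_hit = np.where(hits, weights, 0.0)
    n_r = w_hit.sum()
    if n_r == 0:  # all member metrics are zero: fall back to equal weights
        w_hit = hits.astype(float)
        n_r = w_hit.sum()
    p_hit = np.cumsum(w_hit) / n_r
    p_miss = np.cumsum(~hits) / (n - n_h)
    running = p_hit - p_miss
    peak = int(np.argmax(np.abs(running)))
    return GseaResult(
        es=float(running[peak]),
        running_sum=running,
        hit_ranks=np.flatnonzero(hits),
    )


def leading_edge(result: GseaResult, ranked: RankedList, gene_set: list[str]) -> list[str]:
    """Set members at or before (positive ES) / at or after (negative ES) the running-sum extreme."""
    running = result.running_sum
    if result.es >= 0:
        peak = int(np.argmax(np.abs(running)))
        keep = result.hit_ranks[result.hit_ranks <= peak]
    else:
        trough = int(np.argmax(np.abs(running)))
        keep = result.hit_ranks[result.hit_ranks >= trough]
    return [ranked.genes[i] for i in keep]


def _null_es(
    metric: np.ndarray, n_h: int, n_perm: int, weight_p: float, rng: np.random.Generator
) -> np.ndarray:
    """ES of ``n_perm`` random same-size gene sets, vectorised.

    The running-sum extreme always occurs immediately at a hit (positive
    deviation) or immediately before one (negative), so only 2*n_h candidate
    deviations per permutation need evaluating.
    """
    n = len(metric)
    weights = np.abs(metric) ** weight_p
    # random n_h positions per permutation, sorted ascending
    pos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n_h]
    pos.sort(axis=1)
    w = weights[pos]                                   # (n_perm, n_h)
    cumw = np.cumsum(w, axis=1)
    n_r = cumw[:, -1:]
    degenerate = n_r[:, 0] == 0
    if np.any(degenerate):                             # all-zero weights: equal weighting
        w[degenerate] = 1.0
        cumw[degenerate] = np.arange(1, n_h + 1)
        n_r = np.where(n_r == 0, n_h, n_r)
    j = np.arange(n_h)
    denom = n - n_h
    dev_at = cumw / n_r - (pos - j) / denom            # just after each hit
    dev_before = (cumw - w) / n_r - (pos - j) / denom  # just before each hit
    cand = np.concatenate([dev_at, dev_before], axis=1)
    idx = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(n_perm), idx]


def gsea_permutation(
    ranked: RankedList,
    gene_set: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> GseaResult:
    """Full preranked GSEA: ES, gene-resampling NES/p, and the leading edge.

    p is one-sided among same-sign null scores with a +1 pseudo-count; the
    NES divides the ES by the mean magnitude of same-sign null scores.
    """
    result = enrichment_score(ranked, gene_set, weight_p)
    rng = np.random.default_rng(seed)
    null = _null_es(ranked.metric, len(result.hit_ranks), n_perm, weight_p, rng)
    same_sign = null * result.es >= 0
    n_same = int(same_sign.sum())
    n_extreme = int(np.sum(np.abs(null[same_sign]) >= abs(result.es)))
    result.p_value = (1 + n_extreme) / (1 + n_same)
    mean_mag = float(np.mean(np.abs(null[same_sign]))) if n_same else np.nan
    result.nes = result.es / mean_mag if mean_mag else np.nan
    result.null_es = null
    result.leading_edge = leading_edge(result, ranked, gene_set)
    return result


def leading_edge_recurrence(
    edges: list[list[str]],
    min_fraction: float = 0.5,
    set_name: str = "core_signature",
) -> GeneSetCollection:
    """Genes present in strictly more than ``min_fraction`` of the leading edges."""
    if len(edges) < 2:
        raise GseaError("recurrence filtering needs at least 2 leading edges")
    counts: dict[str, int] = {}
    order: list[str] = []
    for edge in edges:
        for gene in set(edge):
            if gene not in counts:
                order.append(gene)
            counts[gene] = counts.get(gene, 0) + 1
    n = len(edges)
    selected = [g for g in order if counts[g] / n > min_fraction]
    collection = GeneSetCollection()
    if selected:
        collection.add(set_name, sorted(selected), f"recurrent in >{min_fraction:.0%} of {n} leading edges")
    return collection
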