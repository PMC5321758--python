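"""Empirical-Bayes moderated differential expression and selection rules.

Stage 1 of the discovery workflow.  Each gene gets a two-group log2 fold
change (mutant minus wild type), a moderated t-statistic whose residual
variance is shrunk toward a prior estimated by moment matching on the
log-variances, and a B statistic: the log posterior odds that the gene is
differentially expressed under a two-component hierarchical model.

Candidate genes are those with ``B > 0 and logFC > 1`` in at least two of
the discovery systems; knockdown signatures use ``FC < 0.5 and B > 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrix import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

_VAR_FLOOR = np.finfo(float).eps


class DegenerateFitError(ValueError):
    pass


@dataclass
class DEResult:
    """Per-gene moderated differential-expression statistics.

    ``b_stat`` is the log-odds of differential expression; ``hyperparams``
    records the empirical-Bayes fit: prior df ``d0``, prior variance
    ``s0_sq``, prior proportion differential ``p_prior`` and prior effect
    variance ``v0`` (on the unscaled-coefficient scale).
    """

    genes: list[str]
    log2fc: np.ndarray
    t_mod: np.ndarray
    df_total: float
    p_value: np.ndarray
    b_stat: np.ndarray
    hyperparams: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "log2fc": self.log2fc,
                "t_mod": self.t_mod,
                "p_value": self.p_value,
                "b_stat": self.b_stat,
            },
            index=self.genes,
        )


def filter_low_expression(
    matrix: ExpressionMatrix, floor: float = 5.0, max_low_fraction: float = 0.5
) -> ExpressionMatrix:
    """Drop genes with expression below ``floor`` in more than ``max_low_fraction`` of samples.

    The boundary is strict: a gene low in exactly half of the samples (at
    the default fraction 0.5) is retained.  Gene order is preserved.
    """
    if not 0 < max_low_fraction <= 1:
        raise ValueError("max_low_fraction must be in (0,1]")
    low_frac = (matrix.values < floor).mean(axis=1)
    keep = low_frac <= max_low_fraction
    kept = [g for g, k in zip(matrix.gene_ids, keep) if k]
    if not kept:
        logger.warning("expression floor filter removed every gene")
    return ExpressionMatrix(
        gene_ids=kept,
        sample_ids=list(matrix.sample_ids),
        values=matrix.values[keep, :] if kept else np.empty((0, matrix.n_samples)),
        phenotype=dict(matrix.phenotype),
    )


def _trigamma_inverse(x: float) -> float:
    """Solve psi'(y) = x for y by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif / y) < 1e-10:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log s^2 under the scaled chi-square model.

    With s^2 ~ s0^2 * chi^2_d / d * (chi^2_d0 / d0)^-1 marginally, the log
    variances satisfy E[z] = log s0^2 + psi(d/2) - psi(d0/2) - log(d/d0) and
    Var[z] = psi'(d/2) + psi'(d0/2); solving the second for d0 and the
    first for s0^2 gives the prior.  If the observed spread of log s^2 does
    not exceed the chi-square noise, d0 is infinite and all genes share s0^2.
    """
    z = np.log(s2)
    e = z - special.digamma(d / 2) + np.log(d / 2)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    excess = e_var - special.polygamma(1, d / 2)
    if excess <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0_sq


def _estimate_v0(
    t_mod: np.ndarray, log2fc: np.ndarray, s2_post: np.ndarray, v_unscaled: float
) -> float:
    """Prior variance of the true effect, from the top 10% genes by |t|.

    For a differentially expressed gene, E[logfc^2] = v0 + v * sigma^2; a
    moment estimate averages max(0, logfc^2 - v*s2_post) over the genes most
    likely to be differential.
    """
    n_top = max(1, int(np.ceil(0.10 * len(t_mod))))
    top = np.argsort(-np.abs(t_mod))[:n_top]
    v0 = float(np.mean(np.maximum(log2fc[top] ** 2 - v_unscaled * s2_post[top], 0.0)))
    # keep the prior proper: a differential gene must have extra variance
    return max(v0, v_unscaled * float(np.median(s2_post)))


def moderated_de(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    p_prior: float = 0.01,
    d0_override: float | None = None,
) -> DEResult:
    """Two-group moderated differential expression (group_a minus group_b).

    ``d0_override`` forces the prior degrees of freedom (0 recovers the
    ordinary pooled t-test; ``inf`` fully shrinks every gene to the common
    variance); by default the prior is estimated from the data.
    """
    cols_a = matrix.group_columns(group_a)
    cols_b = matrix.group_columns(group_b)
    n_a, n_b = len(cols_a), len(cols_b)
    if n_a < 2 or n_b < 2:
        raise ValueError("need >=2 samples per group")
    a = matrix.values[:, cols_a]
    b = matrix.values[:, cols_b]
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    d = float(n_a + n_b - 2)
    s2 = (a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)) / d
    n_zero = int(np.sum(s2 <= 0))
    if n_zero == len(s2):
        raise DegenerateFitError("zero residual variance for every gene")
    if n_zero:
        logger.warning("%d genes with zero residual variance floored to eps", n_zero)
        s2 = np.maximum(s2, _VAR_FLOOR)

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_sq = _fit_variance_prior(s2, d)
    else:
        d0, s0_sq = _fit_variance_prior(s2, d)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s2_post = s2
    else:
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
    df_total = d0 + d

    v = 1.0 / n_a + 1.0 / n_b  # unscaled variance of the mean difference
    t_mod = log2fc / np.sqrt(s2_post * v)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)

    v0 = _estimate_v0(t_mod, log2fc, s2_post, v)
    b_stat = _b_statistic(t_mod, df_total, v, v0, p_prior)

    return DEResult(
        genes=list(matrix.gene_ids),
        log2fc=log2fc,
        t_mod=t_mod,
        df_total=df_total,
        p_value=p,
        b_stat=b_stat,
        hyperparams={"d0": d0, "s0_sq": s0_sq, "p_prior": p_prior, "v0": v0},
    )


def _b_statistic(
    t_mod: np.ndarray, df_total: float, v: float, v0: float, p_prior: float
) -> np.ndarray:
    """Log posterior odds of differential expression.

    Under the hierarchical model the moderated t follows a t distribution
    with df_total df for a null gene and the same t scaled by
    sqrt((v+v0)/v) for a differential gene; B is the log odds
    log(p/(1-p)) - log(r)/2 + (1+df)/2 * log((t^2+df)/(t^2/r+df)) with
    r = (v+v0)/v (normal kernel in the infinite-df limit).
    """
    r = (v + v0) / v
    t2 = t_mod**2
    if np.isinf(df_total):
        kernel = t2 * (1.0 - 1.0 / r) / 2.0
    else:
        kernel = (1.0 + df_total) / 2.0 * np.log((t2 + df_total) / (t2 / r + df_total))
    return np.log(p_prior / (1.0 - p_prior)) - 0.5 * np.log(r) + kernel


def select_cross_system_candidates(
    results: list[DEResult],
    logfc_min: float = 1.0,
    b_min: float = 0.0,
    min_systems: int = 2,
    set_name: str = "candidates",
) -> GeneSetCollection:
    """Genes up-regulated (B > b_min and log2FC > logfc_min, strict) in >= min_systems results.

    Genes absent from a system count as not passing there.  Returns a
    one-set collection; the set may be empty, in which case an empty
    collection is returned and the caller decides how to proceed.
    """
    if len(results) < min_systems:
        raise ValueError(f"need at least min_systems={min_systems} results")
    counts: dict[str, int] = {}
    order: list[str] = []
    for res in results:
        passing = (res.b_stat > b_min) & (res.log2fc > logfc_min)
        for gene, ok in zip(res.genes, passing):
            if ok:
                if gene not in counts:
                    order.append(gene)
                counts[gene] = counts.get(gene, 0) + 1
    selected = [g for g in order if counts[g] >= min_systems]
    collection = GeneSetCollection()
    if selected:
        collection.add(set_name, selected, f"B>{b_min} & logFC>{logfc_min} in >={min_systems} systems")
    return collection


def select_knockdown_signature(
    result: DEResult,
    fc_max: float = 0.5,
    b_min: float = 0.0,
    set_name: str = "knockdown_signature",
) -> GeneSetCollection:
    """Genes down-regulated on knockdown: linear FC < fc_max and B > b_min."""
    log2_cut = np.log2(fc_max)
    passing = (result.log2fc < log2_cut) & (result.b_stat > b_min)
    selected = [g for g, ok in zip(result.genes, passing) if ok]
    collection = GeneSetCollection()
    if selected:
        collection.add(set_name, selected, f"FC<{fc_max} & B>{b_min}")
    return collection
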