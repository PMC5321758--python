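"""Standardized-mean-difference meta-analysis and hypergeometric enrichment.

Per-study effects are Hedges' g (Cohen's d with the small-sample J
correction); pooling uses inverse-variance weights, either fixed-effect or
DerSimonian-Laird random-effects.  Gene-category over-representation uses
the hypergeometric upper tail with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import GeneSetCollection


class MetaError(ValueError):
    pass


@dataclass
class StudyEffect:
    study_id: str
    g: float          # Hedges' standardized mean difference
    var_g: float      # sampling variance of g
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if self.var_g <= 0:
            raise MetaError(f"{self.study_id}: var_g must be positive")
        if self.n_case < 2 or self.n_control < 2:
            raise MetaError(f"{self.study_id}: need >=2 per arm")


def hedges_g(
    mean_case: float,
    sd_case: float,
    n_case: int,
    mean_control: float,
    sd_control: float,
    n_control: int,
    study_id: str = "study",
    correct: bool = True,
) -> StudyEffect:
    """Hedges' g with sampling variance.

    d = (mean_case - mean_control)/s_pooled; g = J*d with
    J = 1 - 3/(4(n1+n2-2)-1); var_g = J^2 * [(n1+n2)/(n1*n2) + d^2/(2(n1+n2))].
    With ``correct=False`` J = 1 (Cohen's d).
    """
    if sd_case <= 0 or sd_control <= 0:
        raise MetaError("standard deviations must be positive")
    if n_case < 2 or n_control < 2:
        raise MetaError("need >=2 per arm")
    n1, n2 = n_case, n_control
    s_pooled = np.sqrt(((n1 - 1) * sd_case**2 + (n2 - 1) * sd_control**2) / (n1 + n2 - 2))
    d = (mean_case - mean_control) / s_pooled
    j = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0) if correct else 1.0
    g = j * d
    var_g = j**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    return StudyEffect(study_id=study_id, g=float(g), var_g=float(var_g), n_case=n1, n_control=n2)


@dataclass
class PooledEffect:
    g: float
    se: float
    ci_lower: float
    ci_upper: float
    q: float          # Cochran heterogeneity statistic
    tau_sq: float     # between-study variance (0 for fixed)
    model: str
    p_value: float
    n_studies: int


def pool_smd(effects: list[StudyEffect], model: str = "random") -> PooledEffect:
    """Inverse-variance pooling of standardized mean differences.

    ``fixed``: weights 1/var_g.  ``random``: DerSimonian-Laird
    tau^2 = max(0, (Q - df)/C) added to every study variance before
    reweighting.  CI = pooled +/- 1.96*se in both models.
    """
    if len(effects) < 2:
        raise MetaError("need at least 2 studies")
    if model not in ("fixed", "random"):
        raise MetaError(f"unknown model {model!r}")
    g = np.array([e.g for e in effects])
    v = np.array([e.var_g for e in effects])
    w = 1.0 / v
    g_fixed = float(np.sum(w * g) / np.sum(w))
    q = float(np.sum(w * (g - g_fixed) ** 2))
    df = len(effects) - 1
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau_sq = max(0.0, (q - df) / c) if model == "random" else 0.0
    w_star = 1.0 / (v + tau_sq)
    pooled = float(np.sum(w_star * g) / np.sum(w_star))
    se = float(np.sqrt(1.0 / np.sum(w_star)))
    z = pooled / se
    return PooledEffect(
        g=pooled,
        se=se,
        ci_lower=pooled - 1.96 * se,
        ci_upper=pooled + 1.96 * se,
        q=q,
        tau_sq=tau_sq,
        model=model,
        p_value=float(2 * stats.norm.sf(abs(z))),
        n_studies=len(effects),
    )


@dataclass
class EnrichmentRow:
    category: str
    k: int            # query genes in the category
    K: int            # category size within the universe
    n: int            # query size
    N: int            # universe size
    p_value: float
    q_value: float = np.nan


def hypergeom_enrich(
    query: list[str], categories: GeneSetCollection, universe: list[str]
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric over-representation of ``query`` in each category.

    p = P(X >= k) for X ~ Hypergeom(N, K, n), with categories intersected
    with the universe first; rows come back sorted by p with BH q-values.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise MetaError("empty universe")
    uni_set = set(uni)
    query_set = set(query)
    outside = query_set - uni_set
    if outside:
        raise MetaError(f"query genes outside the universe: {sorted(outside)[:5]}")
    n = len(query_set)
    N = len(uni)
    rows = []
    for name, (_, genes) in categories.sets.items():
        cat = set(genes) & uni_set
        if not cat:
            continue
        K = len(cat)
        k = len(cat & query_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(EnrichmentRow(category=name, k=k, K=K, n=n, N=N, p_value=p))
    rows.sort(key=lambda r: r.p_value)
    qvals = bh_adjust([r.p_value for r in rows])
    for row, q in zip(rows, qvals):
        row.q_value = q
    return rows


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order preserved."""
    if not len(pvals):
        return []
    arr = np.asarray(pvals, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise MetaError("p-values must lie in [0,1]")
    return multipletests(arr, method="fdr_bh")[1].tolist()


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"category": r.category, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
             "p": r.p_value, "q": r.q_value}
            for r in rows
        ]
    )
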