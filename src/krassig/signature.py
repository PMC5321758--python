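"""Per-sample signature scores, group tests, status classifier and ROC.

Two scores are provided: the geometric mean of the signature genes'
linear-scale expression (an arithmetic mean on the log2 scale) and the
z-sum, the per-sample sum of per-gene standardized expression.  A
single-feature logistic regression on the score serves as the mutation
status predictor, evaluated by ROC/AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


class SignatureError(ValueError):
    pass


@dataclass
class ScoreTable:
    scores: dict[str, float]
    method: str                 # "geometric_mean" | "zsum"
    signature_name: str
    genes_used: list[str]

    def values_for(self, sample_ids: list[str]) -> np.ndarray:
        return np.array([self.scores[s] for s in sample_ids], dtype=float)


def _present_genes(
    matrix: ExpressionMatrix, genes: list[str], min_coverage: float
) -> list[str]:
    idx = matrix.gene_index()
    present = [g for g in genes if g in idx]
    if not present:
        raise SignatureError("no signature gene present in the matrix")
    missing = [g for g in genes if g not in idx]
    if missing:
        logger.warning("signature genes absent from matrix, renormalizing: %s", missing)
    if len(present) < min_coverage * len(genes):
        raise SignatureError(
            f"only {len(present)}/{len(genes)} signature genes present "
            f"(minimum coverage {min_coverage:.0%})"
        )
    return present


def geometric_mean_score(
    matrix: ExpressionMatrix,
    genes: list[str],
    signature_name: str = "signature",
    min_coverage: float = 0.75,
) -> ScoreTable:
    """Geometric mean of linear-scale expression over the signature genes.

    Computed as 2^(mean of log2 values), which is exactly the geometric
    mean of the linear values; missing genes are dropped with the exponent
    renormalized over the genes present.
    """
    present = _present_genes(matrix, genes, min_coverage)
    sub = matrix.subset_genes(present)
    scores = np.exp2(sub.values.mean(axis=0))
    return ScoreTable(
        scores=dict(zip(matrix.sample_ids, scores.astype(float))),
        method="geometric_mean",
        signature_name=signature_name,
        genes_used=present,
    )


def zsum_score(
    matrix: ExpressionMatrix,
    genes: list[str],
    signature_name: str = "signature",
    min_coverage: float = 0.75,
) -> ScoreTable:
    """Sum of per-gene standardized expression (mean 0, sd 1 across samples)."""
    if matrix.n_samples < 2:
        raise SignatureError("z-sum score needs >=2 samples for standardization")
    present = _present_genes(matrix, genes, min_coverage)
    sub = matrix.subset_genes(present)
    sd = sub.values.std(axis=1, ddof=1)
    usable = sd > 0
    if not np.all(usable):
        logger.warning(
            "zero-variance signature genes excluded: %s",
            [g for g, u in zip(sub.gene_ids, usable) if not u],
        )
    if not np.any(usable):
        raise SignatureError("all signature genes have zero variance")
    vals = sub.values[usable]
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[usable, None]
    scores = z.sum(axis=0)
    return ScoreTable(
        scores=dict(zip(matrix.sample_ids, scores.astype(float))),
        method="zsum",
        signature_name=signature_name,
        genes_used=[g for g, u in zip(sub.gene_ids, usable) if u],
    )


def score_signature(
    matrix: ExpressionMatrix, genes: list[str], method: str = "zsum", **kwargs
) -> ScoreTable:
    if method == "zsum":
        return zsum_score(matrix, genes, **kwargs)
    if method in ("geometric_mean", "geomean"):
        return geometric_mean_score(matrix, genes, **kwargs)
    raise ValueError(f"unknown scoring method {method!r}")


def _split_by_label(
    scores: ScoreTable, labels: dict[str, str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    levels = sorted(set(labels.values()))
    if len(levels) != 2:
        raise SignatureError(f"need exactly 2 label levels, got {levels}")
    groups = []
    for level in levels:
        ids = [s for s in scores.scores if labels.get(s) == level]
        if not ids:
            raise SignatureError(f"group {level!r} is empty")
        groups.append(scores.values_for(ids))
    return groups[0], groups[1], levels


def score_group_ttest(
    scores: ScoreTable, labels: dict[str, str]
) -> tuple[float, float, dict[str, float]]:
    """Two-sided pooled-variance two-sample t-test on the scores."""
    a, b, levels = _split_by_label(scores, labels)
    if len(a) < 2 or len(b) < 2:
        raise SignatureError("need >=2 samples per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(p):  # zero pooled variance with equal means
        t, p = 0.0, 1.0
    return float(t), float(p), {levels[0]: float(a.mean()), levels[1]: float(b.mean())}


@dataclass
class LogisticFit:
    intercept: float
    slope: float
    fitted: dict[str, float]          # sample -> P(label == positive)
    positive_label: str
    converged: bool
    separated: bool
    n_iter: int
    slope_se: float = np.nan
    wald_p: float = np.nan


def fit_status_classifier(
    scores: ScoreTable,
    labels: dict[str, str],
    positive_label: str | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Single-feature logistic regression fit by IRLS.

    Complete separation (the slope diverging) is detected and flagged on
    the returned fit rather than raised.
    """
    sample_ids = list(scores.scores)
    x = scores.values_for(sample_ids)
    lab = [labels[s] for s in sample_ids]
    levels = sorted(set(lab))
    if len(levels) != 2:
        raise SignatureError(f"need exactly 2 classes, got {levels}")
    if positive_label is None:
        positive_label = levels[1]
    y = np.array([1.0 if lb == positive_label else 0.0 for lb in lab])

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if np.all(w < 1e-10) or abs(beta[1]) > 30:
            separated = True
            break
        XtW = X.T * w
        try:
            delta = np.linalg.solve(XtW @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    if abs(beta[1]) > 30:
        separated = True

    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    slope_se = np.nan
    wald_p = np.nan
    if not separated:
        w = mu * (1.0 - mu)
        cov = np.linalg.inv((X.T * w) @ X)
        slope_se = float(np.sqrt(cov[1, 1]))
        wald_p = float(2 * stats.norm.sf(abs(beta[1]) / slope_se)) if slope_se > 0 else np.nan
    return LogisticFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        fitted=dict(zip(sample_ids, mu.astype(float))),
        positive_label=positive_label,
        converged=converged,
        separated=separated,
        n_iter=it,
        slope_se=slope_se,
        wald_p=wald_p,
    )


def roc_auc(
    scores: ScoreTable, labels: dict[str, str], positive_label: str | None = None
) -> tuple[float, np.ndarray]:
    """AUC via the rank (Mann-Whitney) formulation, ties counting 1/2.

    Returns (auc, roc_points) with roc_points an array of (fpr, tpr) rows
    from a threshold sweep over the unique scores.
    """
    sample_ids = list(scores.scores)
    x = scores.values_for(sample_ids)
    lab = [labels[s] for s in sample_ids]
    levels = sorted(set(lab))
    if len(levels) != 2:
        raise SignatureError(f"need exactly 2 classes, got {levels}")
    if positive_label is None:
        positive_label = levels[1]
    y = np.array([1 if lb == positive_label else 0 for lb in lab])
    if len(np.unique(x)) == 1:
        # degenerate sweep: a single threshold, chance-level discrimination
        return 0.5, np.array([[0.0, 0.0], [1.0, 1.0]])
    # rank formulation: exactly the count of concordant pairs with ties at 1/2
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(x)
    auc = float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
    fpr, tpr, _ = roc_curve(y, x)
    return auc, np.column_stack([fpr, tpr])
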