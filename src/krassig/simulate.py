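"""Synthetic data with the statistical structure the pipeline assumes.

The multi-cohort generator plants a set of genotype-associated genes that
are shifted upward in mutant samples across several discovery "systems"
(cell lines, mouse tumours) and validation cohorts (patient datasets, with
the effect attenuated to emulate cross-dataset heterogeneity).  Survival
times follow an exponential hazard multiplied by exp(beta * centered
score); dose-response curves come from the median-effect equation with
optional Gaussian noise on the logit of the fraction affected.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .matrix import ExpressionMatrix
from .survival import SurvivalTable
from .synergy import DoseResponse

MUT_LABEL = "KRAS_mut"
WT_LABEL = "KRAS_wt"


@dataclass(frozen=True)
class SimulationParams:
    """Defaults: 2000 genes, 20 planted at +1.5 log2 units, sd 0.5, 10/group.

    ``cohort_effect_attenuation`` multiplies the planted effect in the
    validation cohorts (cross-dataset heterogeneity); ``baseline_mean`` is
    the log2 expression level around which genes are centred, high enough
    that the default expression floor of 5 removes nothing by construction.
    """

    n_genes: int = 2000
    n_planted: int = 20
    planted_log2fc: float = 1.5
    noise_sd: float = 0.5
    n_per_group: int = 10
    n_systems: int = 3
    n_cohorts: int = 4
    cohort_effect_attenuation: float = 0.8
    baseline_mean: float = 8.0
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted cannot exceed n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_per_group < 2:
            raise ValueError("need n_per_group >= 2")


def _gene_names(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"G{idx:0{width}d}" for idx in range(n)]


def _simulate_two_group(
    rng: np.random.Generator,
    params: SimulationParams,
    effect: float,
    prefix: str,
    labels: tuple[str, str] = (MUT_LABEL, WT_LABEL),
) -> ExpressionMatrix:
    n = params.n_per_group
    genes = _gene_names(params.n_genes)
    # per-gene baseline shared by both groups within a dataset
    baseline = params.baseline_mean + rng.normal(0.0, 1.0, size=params.n_genes)
    values = baseline[:, None] + rng.normal(0.0, params.noise_sd, size=(params.n_genes, 2 * n))
    values[: params.n_planted, :n] += effect
    sample_ids = [f"{prefix}_mut{i}" for i in range(n)] + [f"{prefix}_wt{i}" for i in range(n)]
    phenotype = {s: labels[0] for s in sample_ids[:n]}
    phenotype.update({s: labels[1] for s in sample_ids[n:]})
    return ExpressionMatrix(gene_ids=genes, sample_ids=sample_ids, values=values, phenotype=phenotype)


def simulate_multi_cohort(
    params: SimulationParams,
) -> tuple[list[ExpressionMatrix], list[ExpressionMatrix], list[str]]:
    """Discovery systems, validation cohorts and the planted-gene truth list.

    The first ``n_planted`` genes are shifted by ``planted_log2fc`` in the
    mutant group of every system and by the attenuated effect in every
    cohort; all matrices share the same gene names.
    """
    rng = np.random.default_rng(params.seed)
    systems = [
        _simulate_two_group(rng, params, params.planted_log2fc, f"sys{k}")
        for k in range(params.n_systems)
    ]
    cohort_effect = params.planted_log2fc * params.cohort_effect_attenuation
    cohorts = [
        _simulate_two_group(rng, params, cohort_effect, f"coh{k}")
        for k in range(params.n_cohorts)
    ]
    truth = _gene_names(params.n_genes)[: params.n_planted]
    return systems, cohorts, truth


def simulate_knockdown_experiment(
    params: SimulationParams, n_down: int = 20, down_log2fc: float = -1.5
) -> tuple[ExpressionMatrix, list[str]]:
    """Two-group knockdown-vs-control matrix with ``n_down`` genes shifted down."""
    if down_log2fc > 0:
        raise ValueError("down_log2fc must be nonpositive")
    rng = np.random.default_rng(params.seed)
    kd_params = replace(params, n_planted=n_down)
    matrix = _simulate_two_group(
        rng, kd_params, down_log2fc, "kd", labels=("sh_target", "sh_control")
    )
    truth = _gene_names(params.n_genes)[:n_down]
    return matrix, truth


def simulate_survival(
    scores: np.ndarray | list[float],
    beta: float,
    baseline_rate: float = 0.1,
    censor_rate: float = 0.02,
    seed: int = 0,
    sample_ids: list[str] | None = None,
    status: np.ndarray | None = None,
) -> SurvivalTable:
    """Exponential survival with hazard baseline_rate * exp(beta * centered score).

    Censoring is an independent exponential clock; event = 1 iff the event
    time precedes the censor time.  ``status`` labels, if given, are carried
    through to the output table.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if censor_rate < 0:
        raise ValueError("censor_rate must be nonnegative")
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    rng = np.random.default_rng(seed)
    hazard = baseline_rate * np.exp(beta * (scores - scores.mean()))
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, size=n)
    else:
        censor_time = np.full(n, np.inf)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    if sample_ids is None:
        sample_ids = [f"P{i}" for i in range(n)]
    return SurvivalTable(
        sample_ids=list(sample_ids),
        time=np.maximum(time, 1e-9),
        event=event,
        status=None if status is None else np.asarray(status, dtype=object),
        score=scores,
    )


def simulate_dose_response(
    m: float,
    dm: float,
    doses: np.ndarray | list[float],
    fa_noise_sd: float = 0.0,
    seed: int = 0,
    drug_id: str = "drug",
) -> DoseResponse:
    """Median-effect curve fa/(1-fa) = (D/Dm)^m with logit-scale Gaussian noise.

    Noisy fractions are clamped to (0.001, 0.999) so every point stays
    usable by the fitter.
    """
    doses = np.asarray(doses, dtype=float)
    if m <= 0 or dm <= 0 or np.any(doses <= 0):
        raise ValueError("m, dm and doses must be strictly positive")
    logit = m * (np.log10(doses) - np.log10(dm))
    if fa_noise_sd > 0:
        rng = np.random.default_rng(seed)
        logit = logit + rng.normal(0.0, fa_noise_sd, size=len(doses))
    ratio = 10.0**logit
    fa = ratio / (1.0 + ratio)
    if fa_noise_sd > 0:
        fa = np.clip(fa, 0.001, 0.999)
    return DoseResponse(drug_id=drug_id, doses=doses, fa=fa)
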