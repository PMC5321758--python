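"""The discovery orchestrator: systems -> candidates -> cohorts -> core signature.

Stage 1 runs moderated differential expression on each discovery system
and intersects the per-system hits (B>0 and logFC>1) across systems.
Stage 2 ranks each validation cohort by log2 fold change, runs preranked
GSEA of the candidate set and filters for genes recurrent in more than
half of the leading edges.  Stage 3 scores every cohort sample with the
resulting core signature.  Empty intermediate sets halt the pipeline with
an explicit status so partial reports remain usable.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np
from dataclasses import dataclass, field
from pathlib import Path

from .config import PipelineConfig
from .diffexpr import DEResult, filter_low_expression, moderated_de, select_cross_system_candidates
from .gsea import GseaResult, gsea_permutation, rank_by_logfc
from .matrix import ExpressionMatrix
from .signature import ScoreTable, score_signature
from .simulate import MUT_LABEL, WT_LABEL

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_UNSATISFIABLE = "intersection rule unsatisfiable"
STATUS_NO_CANDIDATES = "no cross-system candidates"
STATUS_NO_RECURRENT = "no recurrent leading-edge genes"


@dataclass
class DiscoveryReport:
    status: str
    config: PipelineConfig
    system_de: list[DEResult] = field(default_factory=list)
    candidates: list[str] = field(default_factory=list)
    cohort_gsea: list[GseaResult] = field(default_factory=list)
    core_signature: list[str] = field(default_factory=list)
    cohort_scores: list[ScoreTable] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "status": self.status,
            "config": dataclasses.asdict(self.config),
            "candidates": self.candidates,
            "core_signature": self.core_signature,
            "cohort_gsea": [
                {
                    "es": g.es,
                    "nes": g.nes,
                    "p_value": g.p_value,
                    "leading_edge": g.leading_edge,
                }
                for g in self.cohort_gsea
            ],
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "discovery_report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)
        for k, de in enumerate(self.system_de):
            de.to_frame().to_csv(out / f"system{k}_de.tsv", sep="\t")
        for k, st in enumerate(self.cohort_scores):
            with open(out / f"cohort{k}_scores.tsv", "w") as fh:
                fh.write("sample_id\tscore\n")
                for sid, sc in st.scores.items():
                    fh.write(f"{sid}\t{sc:.17g}\n")


def run_discovery(
    config: PipelineConfig,
    systems: list[ExpressionMatrix],
    cohorts: list[ExpressionMatrix],
    group_a: str = MUT_LABEL,
    group_b: str = WT_LABEL,
) -> DiscoveryReport:
    """Run the three-stage cross-cohort signature discovery workflow."""
    if not systems or not cohorts:
        raise ValueError("need at least one discovery system and one validation cohort")
    report = DiscoveryReport(status=STATUS_OK, config=config)

    if len(systems) < config.min_systems:
        logger.warning(
            "only %d systems for min_systems=%d", len(systems), config.min_systems
        )
        report.status = STATUS_UNSATISFIABLE
        return report

    # stage 1: per-system moderated DE + intersection rule
    for k, system in enumerate(systems):
        filtered = filter_low_expression(system, config.expression_floor, config.floor_fraction)
        de = moderated_de(filtered, group_a, group_b, p_prior=config.p_prior)
        logger.info("system %d: %d genes after floor filter", k, len(de.genes))
        report.system_de.append(de)
    candidates = select_cross_system_candidates(
        report.system_de,
        logfc_min=config.logfc_min,
        b_min=config.b_min,
        min_systems=config.min_systems,
    )
    if "candidates" not in candidates:
        report.status = STATUS_NO_CANDIDATES
        return report
    report.candidates = candidates.genes("candidates")
    logger.info("stage 1: %d cross-system candidates", len(report.candidates))

    # stage 2: per-cohort preranked GSEA of the candidate set + recurrence
    edges: list[list[str]] = []
    for k, cohort in enumerate(cohorts):
        filtered = filter_low_expression(cohort, config.expression_floor, config.floor_fraction)
        de = moderated_de(filtered, group_a, group_b, p_prior=config.p_prior)
        ranked = rank_by_logfc(de)
        present = [g for g in report.candidates if g in set(ranked.genes)]
        if not present:
            edges.append([])
            report.cohort_gsea.append(
                GseaResult(es=0.0, running_sum=ranked.metric * 0.0, hit_ranks=np.array([], dtype=int))
            )
            continue
        result = gsea_permutation(
            ranked,
            present,
            n_perm=config.n_perm,
            seed=config.seed + k,
            weight_p=config.gsea_weight,
        )
        report.cohort_gsea.append(result)
        edges.append(result.leading_edge)
        logger.info("cohort %d: ES=%.3f p=%.4g |LE|=%d", k, result.es, result.p_value, len(result.leading_edge))
    n_cohorts = len(edges)
    counts: dict[str, int] = {}
    for edge in edges:
        for gene in set(edge):
            counts[gene] = counts.get(gene, 0) + 1
    core = sorted(g for g, c in counts.items() if c / n_cohorts > config.recurrence_fraction)
    if not core:
        report.status = STATUS_NO_RECURRENT
        return report
    report.core_signature = core
    logger.info("stage 2: core signature of %d genes", len(core))

    # stage 3: per-cohort signature scores
    for cohort in cohorts:
        report.cohort_scores.append(
            score_signature(cohort, core, method=config.scoring_method)
        )
    return report
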