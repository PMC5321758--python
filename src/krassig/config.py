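"""Pipeline configuration: every printed cutoff of the workflow in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and settings for the discovery workflow.

    The defaults are the workflow's published cutoffs: expression floor 5
    (log2 units) in more than 50% of samples, candidates with B>0 and
    logFC>1 in at least 2 systems, and a core signature recurrent in more
    than 50% of the cohort leading edges.
    """

    expression_floor: float = 5.0
    floor_fraction: float = 0.5
    logfc_min: float = 1.0
    b_min: float = 0.0
    min_systems: int = 2
    recurrence_fraction: float = 0.5
    gsea_weight: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    scoring_method: str = "zsum"      # "zsum" | "geometric_mean"
    survival_quantile: float = 0.5
    p_prior: float = 0.01
    out_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("floor_fraction", "recurrence_fraction"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ValueError(f"{name} must be in (0,1], got {value}")
        if not 0 < self.survival_quantile < 1:
            raise ValueError("survival_quantile must be in (0,1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.seed is None:
            raise ValueError("a seed is required for the permutation stages")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
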