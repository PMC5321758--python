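"""Core in-memory containers for the expression pipeline.

An :class:`ExpressionMatrix` holds a log2-scale genes x samples matrix
together with a per-sample phenotype label (e.g. ``KRAS_mut`` vs
``KRAS_wt``), which is the two-group contrast driving every stage of the
analysis.  A :class:`GeneSetCollection` holds named gene sets as read from
a GMT file or produced by the selection rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class ExpressionMatrix:
    """Log2-scale genes x samples expression matrix with phenotype labels.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per matrix row.
    sample_ids
        Unique sample names, one per matrix column.
    values
        Numeric matrix of shape ``(len(gene_ids), len(sample_ids))`` on the
        log2 scale; all entries must be finite.
    phenotype
        Map ``sample_id -> group label``; every key must be a sample id.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    phenotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValidationError("matrix contains non-finite values")
        unknown = set(self.phenotype) - set(self.sample_ids)
        if unknown:
            raise ValidationError(f"phenotype keys not in sample_ids: {sorted(unknown)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def group_columns(self, label: str) -> np.ndarray:
        """Column indices of the samples carrying phenotype ``label``."""
        return np.array(
            [j for j, s in enumerate(self.sample_ids) if self.phenotype.get(s) == label],
            dtype=int,
        )

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index()
        keep = [g for g in genes if g in idx]
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(
            gene_ids=keep,
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :] if rows else np.empty((0, self.n_samples)),
            phenotype=dict(self.phenotype),
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, phenotype: dict[str, str] | None = None
    ) -> "ExpressionMatrix":
        return cls(
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            values=frame.to_numpy(dtype=float),
            phenotype=dict(phenotype or {}),
        )


@dataclass
class GeneSetCollection:
    """Named gene sets: ``set_name -> (description, [gene symbols])``."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def genes(self, name: str) -> list[str]:
        return list(self.sets[name][1])

    def add(self, name: str, genes: list[str], description: str = "na") -> None:
        if name in self.sets:
            raise ValidationError(f"duplicate gene set name {name!r}")
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            logger.warning("gene set %s: %d duplicate genes removed", name, len(genes) - len(deduped))
        if not deduped:
            raise ValidationError(f"gene set {name!r} is empty")
        self.sets[name] = (description, deduped)
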