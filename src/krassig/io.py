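"""Readers and writers for the standard formats the pipeline touches.

Supported formats: expression matrices as plain TSV (gene ids in the first
column) or GCT 1.2; gene sets as GMT; phenotype labels as CLS or two-column
TSV; clinical tables as TSV.  Gene symbols are uppercased on ingest so that
mouse and human symbols match by case-folded equality (an explicit
two-column mapping table can override this, see :func:`apply_symbol_map`).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, GeneSetCollection, ValidationError
from .survival import SurvivalTable

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised on a malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def _collapse_duplicate_genes(frame: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate gene rows, keeping the row with the highest mean.

    This is the common probe-collapse convention: when a symbol appears more
    than once, retain the most highly expressed row.
    """
    if frame.index.is_unique:
        return frame
    n_dup = len(frame) - frame.index.nunique()
    logger.warning("collapsing %d duplicate gene rows by max mean expression", n_dup)
    means = frame.mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    deduped = frame.iloc[order]
    deduped = deduped[~deduped.index.duplicated(keep="first")]
    # restore first-occurrence order of the surviving symbols
    return deduped.loc[frame.index.drop_duplicates()]


def _finalize_expression(frame: pd.DataFrame, phenotype: dict[str, str] | None) -> ExpressionMatrix:
    frame.index = frame.index.astype(str).str.upper()
    frame = _collapse_duplicate_genes(frame)
    if not np.issubdtype(frame.to_numpy().dtype, np.number):
        for col in frame.columns:
            bad = pd.to_numeric(frame[col], errors="coerce")
            rows = frame.index[bad.isna() & frame[col].notna()]
            if len(rows):
                raise FormatError(f"non-numeric value at gene {rows[0]!r}, sample {col!r}")
        frame = frame.astype(float)
    return ExpressionMatrix.from_frame(frame, phenotype)


def read_expression(
    path: str | Path,
    format: str = "tsv",
    phenotype: dict[str, str] | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from ``tsv`` or ``gct`` (version 1.2).

    TSV: gene ids in the first column, sample ids in the header row.
    GCT 1.2: ``#1.2`` header, a dimensions line, then Name/Description
    columns followed by one column per sample.
    """
    path = Path(path)
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        return _finalize_expression(frame, phenotype)
    if format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: line 1: expected GCT version '#1.2', got {version!r}")
            dims = fh.readline().split()
            if len(dims) != 2:
                raise FormatError(f"{path}: line 2: expected '<n_genes>\\t<n_samples>'")
            n_genes, n_samples = int(dims[0]), int(dims[1])
            frame = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
        if "Description" not in frame.columns:
            raise FormatError(f"{path}: line 3: missing 'Description' column")
        frame = frame.drop(columns="Description")
        if frame.shape != (n_genes, n_samples):
            raise FormatError(
                f"{path}: dimensions line declares {n_genes}x{n_samples} "
                f"but data block is {frame.shape[0]}x{frame.shape[1]}"
            )
        return _finalize_expression(frame, phenotype)
    raise ValueError(f"unknown expression format {format!r}")


def write_expression(matrix: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    frame = matrix.to_frame()
    if format == "tsv":
        frame.to_csv(path, sep="\t", float_format="%.17g")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
            out = frame.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t", float_format="%.17g")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, ``name TAB description TAB genes...``."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 tab-separated fields")
            name, description = fields[0], fields[1]
            genes = [g.strip().upper() for g in fields[2:] if g.strip()]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no genes")
            collection.add(name, genes, description)
    return collection


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (description, genes) in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# phenotype labels (CLS / TSV)
# ---------------------------------------------------------------------------


def read_cls(path: str | Path, sample_ids: list[str]) -> dict[str, str]:
    """Read a categorical CLS phenotype file, mapping labels onto ``sample_ids``."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 3:
        raise FormatError(f"{path}: CLS requires 3 lines (counts, names, labels)")
    counts = lines[0].split()
    n_samples, n_classes = int(counts[0]), int(counts[1])
    if not lines[1].startswith("#"):
        raise FormatError(f"{path}: line 2: class-name line must start with '#'")
    class_names = lines[1].lstrip("#").split()
    if len(class_names) != n_classes:
        raise FormatError(f"{path}: line 2: expected {n_classes} class names")
    tokens = lines[2].split()
    if len(tokens) != n_samples or n_samples != len(sample_ids):
        raise FormatError(
            f"{path}: line 3: expected {len(sample_ids)} labels, got {len(tokens)}"
        )
    # tokens may be numeric class indices or the class names themselves
    labels: list[str] = []
    for tok in tokens:
        if tok in class_names:
            labels.append(tok)
        else:
            try:
                labels.append(class_names[int(tok)])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: line 3: unknown class token {tok!r}") from exc
    return dict(zip(sample_ids, labels))


def read_phenotype_tsv(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: phenotype TSV needs sample_id and label columns")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def write_cls(phenotype: dict[str, str], sample_ids: list[str], path: str | Path) -> None:
    labels = [phenotype[s] for s in sample_ids]
    class_names = list(dict.fromkeys(labels))
    with open(path, "w") as fh:
        fh.write(f"{len(sample_ids)} {len(class_names)} 1\n")
        fh.write("# " + " ".join(class_names) + "\n")
        fh.write(" ".join(str(class_names.index(lb)) for lb in labels) + "\n")


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

_OPTIONAL_CLINICAL = ("age", "sex", "stage", "status", "score")


def read_clinical(path: str | Path) -> SurvivalTable:
    """Read a clinical TSV with columns sample_id, time, event (+ optional covariates)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    bad_time = frame.index[frame["time"] <= 0].tolist()
    if bad_time:
        raise ValidationError(f"{path}: non-positive time at rows {bad_time}")
    bad_event = frame.index[~frame["event"].isin([0, 1])].tolist()
    if bad_event:
        raise ValidationError(f"{path}: event not in {{0,1}} at rows {bad_event}")
    kwargs = {}
    for col in _OPTIONAL_CLINICAL:
        if col in frame.columns:
            kwargs[col] = frame[col].to_numpy()
    return SurvivalTable(
        sample_ids=[str(s) for s in frame["sample_id"]],
        time=frame["time"].to_numpy(dtype=float),
        event=frame["event"].to_numpy(dtype=int),
        **kwargs,
    )


def write_clinical(table: SurvivalTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# symbol mapping hook
# ---------------------------------------------------------------------------


def apply_symbol_map(matrix: ExpressionMatrix, mapping_path: str | Path | None) -> ExpressionMatrix:
    """Map gene symbols through a two-column TSV (from TAB to).

    With no mapping table the identity is case-folded symbol equality, which
    ingest already enforces by uppercasing; this hook covers organisms whose
    orthologs do not share symbols.  Unmapped symbols are kept unchanged;
    collisions introduced by the map are collapsed by max mean expression.
    """
    if mapping_path is None:
        return matrix
    pairs = pd.read_csv(mapping_path, sep="\t", header=None, dtype=str)
    mapping = {a.upper(): b.upper() for a, b in zip(pairs.iloc[:, 0], pairs.iloc[:, 1])}
    frame = matrix.to_frame()
    frame.index = [mapping.get(g, g) for g in frame.index]
    frame = _collapse_duplicate_genes(frame)
    return ExpressionMatrix.from_frame(frame, matrix.phenotype)
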