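"""Readers and writers for the text formats the pipeline touches.

GCT 1.2 is the tab-separated expression-matrix interchange format used for
L1000 data releases; GMT carries named gene-set libraries (one set per
line); plain TSV covers generic matrices and sample metadata tables.
All round trips are bit-exact on values and order-preserving on
identifiers (floats are serialized with ``repr`` precision).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix, GeneSetLibrary, SampleMetadata

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


# ---------------------------------------------------------------------------
# GCT 1.2
# ---------------------------------------------------------------------------

def read_gct(path: str | Path, space: str = "full", scale: str = "log2") -> ExpressionMatrix:
    """Read a GCT 1.2 text file.

    Layout: a ``#1.2`` version line, a ``<n_genes>\\t<n_samples>`` dimension
    line, a header row (``Name``, ``Description``, sample ids) and one row
    per gene. The declared dimensions must match the data exactly.
    """
    path = Path(path)
    with path.open("r") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "#1.2":
        raise FormatError(f"{path}: line 1: expected GCT version line '#1.2', "
                          f"got {lines[0]!r}" if lines else f"{path}: empty file")
    try:
        dims = lines[1].split("\t")
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: line 2: malformed dimension line") from exc
    header = lines[2].split("\t")
    if len(header) != 2 + n_samples:
        raise FormatError(
            f"{path}: line 3: header has {len(header) - 2} sample columns, "
            f"dimension line declares {n_samples}"
        )
    sample_ids = header[2:]
    data_lines = [ln for ln in lines[3:] if ln.strip()]
    if len(data_lines) != n_genes:
        raise FormatError(
            f"{path}: dimension line declares {n_genes} genes but file has "
            f"{len(data_lines)} data rows"
        )
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for offset, line in enumerate(data_lines, start=4):
        fields = line.split("\t")
        if len(fields) != 2 + n_samples:
            raise FormatError(f"{path}: line {offset}: expected "
                              f"{2 + n_samples} fields, got {len(fields)}")
        gene_ids.append(fields[0])
        try:
            rows.append([float(v) for v in fields[2:]])
        except ValueError as exc:
            raise FormatError(f"{path}: line {offset}: non-numeric value") from exc
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError(f"{path}: duplicate gene identifiers")
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}: duplicate sample identifiers")
    return ExpressionMatrix(values=rows, gene_ids=gene_ids,
                            sample_ids=sample_ids, space=space, scale=scale)


def write_gct(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write a GCT 1.2 text file (Description column repeats the symbol)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, gene in enumerate(matrix.gene_ids):
            vals = "\t".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{gene}\t{gene}\t{vals}\n")


# ---------------------------------------------------------------------------
# TSV expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path, space: str = "full",
                        scale: str = "log2") -> ExpressionMatrix:
    """Read a TSV with gene symbols in the first column, sample ids in the header."""
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    frame.index = frame.index.map(str)
    return ExpressionMatrix.from_frame(frame, space=space, scale=scale)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, gene in enumerate(matrix.gene_ids):
            vals = "\t".join(repr(float(v)) for v in matrix.values[i])
            fh.write(f"{gene}\t{vals}\n")


# ---------------------------------------------------------------------------
# GMT gene-set libraries
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a GMT library: set name, description, then gene symbols per line.

    Duplicate symbols within a set are collapsed; a line with fewer than
    three fields is a format error (a set must contain at least one gene).
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with path.open("r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, description, genes), got {len(fields)}"
                )
            name = fields[0]
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"{path}: line {lineno}: set {name!r} has no genes")
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = genes
    return GeneSetLibrary(sets=sets)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name in library.names():
            genes = sorted(library[name])
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ["sample_id", "perturbagen", "batch", "cell_line", "role"]


def read_metadata_tsv(path: str | Path) -> list[SampleMetadata]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    return [
        SampleMetadata(
            sample_id=row["sample_id"],
            perturbagen=row["perturbagen"],
            batch=row["batch"],
            cell_line=row["cell_line"],
            role=row["role"] or "unknown",
        )
        for _, row in frame.iterrows()
    ]


def write_metadata_tsv(rows: list[SampleMetadata], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(METADATA_COLUMNS) + "\n")
        for r in rows:
            fh.write("\t".join([r.sample_id, r.perturbagen, r.batch,
                                r.cell_line, r.role]) + "\n")
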