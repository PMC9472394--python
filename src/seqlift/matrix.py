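"""Core in-memory containers for expression data.

The universal currency of the pipeline is the :class:`ExpressionMatrix`:
a genes-by-samples real matrix with ordered identifiers, a *space* tag
(landmark / full / common gene space) and a *scale* tag (raw counts or
log2 expression). Everything else — translator, extrapolator, metrics,
signatures — consumes and produces these.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPACES = ("landmark", "full", "common")
SCALES = ("counts", "log2")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix with ordered identifiers.

    Parameters
    ----------
    values
        Real matrix of shape ``(n_genes, n_samples)``. Stored as float64.
    gene_ids
        Ordered, unique gene symbols (one per row).
    sample_ids
        Ordered, unique sample identifiers (one per column).
    space
        Gene-space tag: ``"landmark"``, ``"full"`` or ``"common"``.
    scale
        Value-scale tag: ``"counts"`` (nonnegative raw counts) or ``"log2"``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    space: str = "full"
    scale: str = "log2"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = list(map(str, self.gene_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix (genes x samples)")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.space not in SPACES:
            raise ValueError(f"space must be one of {SPACES}, got {self.space!r}")
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.scale == "counts" and np.any(self.values < 0):
            raise ValueError("counts matrix contains negative values")

    # -- basic introspection -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        """Return a genes-by-samples :class:`pandas.DataFrame` view (copy)."""
        return pd.DataFrame(
            self.values.copy(), index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, space: str = "full", scale: str = "log2"
    ) -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=np.float64),
            gene_ids=[str(g) for g in frame.index],
            sample_ids=[str(s) for s in frame.columns],
            space=space,
            scale=scale,
        )

    # -- subsetting ----------------------------------------------------------

    def subset_genes(self, gene_ids: list[str], space: str | None = None) -> "ExpressionMatrix":
        """Restrict to ``gene_ids`` in the given order."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:10]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            values=self.values[rows, :],
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            space=space or self.space,
            scale=self.scale,
        )

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"samples not present in matrix: {missing[:10]}")
        cols = [index[s] for s in sample_ids]
        return ExpressionMatrix(
            values=self.values[:, cols],
            gene_ids=list(self.gene_ids),
            sample_ids=list(sample_ids),
            space=self.space,
            scale=self.scale,
        )

    def with_values(self, values: np.ndarray, scale: str | None = None) -> "ExpressionMatrix":
        """Same identifiers, new values (and optionally a new scale tag)."""
        return replace(self, values=np.asarray(values, dtype=np.float64),
                       scale=scale or self.scale)


def intersect_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to their shared genes, in ``a``'s order.

    Symbols present in one matrix only are dropped with a logged warning —
    cross-platform gene universes rarely coincide exactly.
    """
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    dropped = (set(a.gene_ids) | set(b.gene_ids)) - set(shared)
    if not shared:
        raise ValueError("gene intersection is empty")
    if dropped:
        logger.warning(
            "dropping %d genes absent from one matrix (e.g. %s)",
            len(dropped), sorted(dropped)[:5],
        )
    return a.subset_genes(shared), b.subset_genes(shared)


@dataclass
class SampleMetadata:
    """Per-sample annotations used for batch-wise signature computation."""

    sample_id: str
    perturbagen: str = ""
    batch: str = ""
    cell_line: str = ""
    role: str = "unknown"  # treatment | control | unknown

    def __post_init__(self) -> None:
        if self.role not in ("treatment", "control", "unknown"):
            raise ValueError(f"invalid role {self.role!r}")


def metadata_to_frame(rows: list[SampleMetadata]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "perturbagen": r.perturbagen,
                "batch": r.batch,
                "cell_line": r.cell_line,
                "role": r.role,
            }
            for r in rows
        ]
    )


def validate_metadata(rows: list[SampleMetadata], matrix: ExpressionMatrix) -> None:
    """Every metadata row must reference a sample in the companion matrix."""
    known = set(matrix.sample_ids)
    unknown = [r.sample_id for r in rows if r.sample_id not in known]
    if unknown:
        raise ValueError(f"metadata references unknown samples: {unknown[:10]}")


@dataclass
class GeneSetLibrary:
    """Named gene sets (e.g. ChIP-seq-derived transcription-factor targets)."""

    sets: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = set(map(str, genes))

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)
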