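"""Preprocessing of bulk RNA-seq count matrices.

The pipeline expects its RNA-seq domain on a common scale: lowly expressed
genes are removed (a gene must reach a minimum count in a minimum fraction
of samples), counts are log2(x+1) transformed, and samples are quantile
normalized so every profile shares one reference distribution. The
quantile-normalization reference learned at training time can be persisted
and re-applied to new samples so that inference-time profiles are
normalized consistently.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


def filter_low_expressed(
    counts: ExpressionMatrix,
    min_count: int = 10,
    min_sample_fraction: float = 0.02,
) -> ExpressionMatrix:
    """Drop genes that never reach ``min_count`` in enough samples.

    A gene is retained when its count is at least ``min_count`` in at least
    ``max(1, ceil(min_sample_fraction * n_samples))`` samples. Samples are
    never removed and gene order is preserved.
    """
    if counts.scale != "counts":
        raise ValueError("filter_low_expressed expects a counts matrix")
    if not (0 < min_sample_fraction <= 1):
        raise ValueError("min_sample_fraction must be in (0, 1]")
    if counts.n_samples == 0:
        raise ValueError("matrix has zero samples")
    threshold = max(1, math.ceil(min_sample_fraction * counts.n_samples))
    n_passing = (counts.values >= min_count).sum(axis=1)
    keep = n_passing >= threshold
    kept_ids = [g for g, k in zip(counts.gene_ids, keep) if k]
    logger.info(
        "low-expression filter: kept %d / %d genes (count >= %d in >= %d samples)",
        len(kept_ids), counts.n_genes, min_count, threshold,
    )
    return ExpressionMatrix(
        values=counts.values[keep, :],
        gene_ids=kept_ids,
        sample_ids=list(counts.sample_ids),
        space=counts.space,
        scale="counts",
    )


def log2_transform(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(count + 1); returns a log2-scale matrix."""
    if np.any(counts.values < 0):
        raise ValueError("log2_transform requires nonnegative values")
    return counts.with_values(np.log2(counts.values + 1.0), scale="log2")


def quantile_normalize(
    m: ExpressionMatrix,
    reference: np.ndarray | None = None,
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Quantile-normalize samples onto a shared reference distribution.

    Without a ``reference``, the reference is the across-sample mean of the
    within-sample sorted values, and every output column has exactly that
    sorted vector. With a ``reference`` (ascending, one entry per gene) each
    column's ranks are mapped onto it — the path used to normalize new
    samples consistently with a training corpus. Tied values receive the
    mean of the reference entries their ranks span, so the result does not
    depend on the input order of tied entries.

    Returns the normalized matrix and the reference used.
    """
    values = m.values
    n_genes = values.shape[0]
    if reference is None:
        sorted_cols = np.sort(values, axis=0)
        # Columns that already share one value multiset pass through
        # untouched (their common sorted vector IS the mean reference);
        # checked before averaging so repeated normalization is bit-exact
        # rather than merely close.
        if all(np.array_equal(sorted_cols[:, j], sorted_cols[:, 0])
               for j in range(1, values.shape[1])):
            return m.with_values(values.copy()), sorted_cols[:, 0].copy()
        reference = sorted_cols.mean(axis=1)
    else:
        reference = np.asarray(reference, dtype=np.float64)
        if reference.shape != (n_genes,):
            raise ValueError(
                f"reference length {reference.shape} does not match "
                f"{n_genes} genes"
            )
        reference = np.sort(reference)

    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[:, j] = _map_column_to_reference(values[:, j], reference)
    return m.with_values(out), reference


def _map_column_to_reference(column: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace a column's values by reference quantiles, averaging over ties."""
    order = np.argsort(column, kind="mergesort")
    ranked = column[order]
    result = np.empty_like(column)
    n = len(column)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ranked[j + 1] == ranked[i]:
            j += 1
        if j == i:
            fill = reference[i]
        else:
            span = reference[i : j + 1]
            # identical reference entries: keep them bit-exact, no averaging
            fill = span[0] if np.all(span == span[0]) else span.mean()
        result[order[i : j + 1]] = fill
        i = j + 1
    return result
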