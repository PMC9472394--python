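"""Benchmarking metrics: paired PCC/SCC/RMSE, random-pairing nulls, PCA.

Predicted and real profiles are compared either *sample-wise* (one metric
per matched sample, computed across genes) or *gene-wise* (one metric per
gene, computed across samples). A random-pairing control — the same
metrics after a seeded derangement of the second matrix's samples —
quantifies how much of the agreement is generic expression structure
rather than sample-specific signal. A 2-D PCA embedding of several
labeled matrices on their common genes supports visual domain comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

AXES = ("sample_wise", "gene_wise")


@dataclass
class MetricsReport:
    """Per-unit metric vectors plus their summary statistics.

    Undefined correlations (constant vectors) are stored as NaN, excluded
    from the summaries, and counted in ``n_undefined``.
    """

    axis: str
    unit_ids: list[str]
    pcc: np.ndarray
    scc: np.ndarray
    rmse: np.ndarray
    comparison_label: str = ""
    n_undefined: int = 0

    @property
    def summary(self) -> dict[str, float]:
        out = {}
        for name, vec in (("pcc", self.pcc), ("scc", self.scc), ("rmse", self.rmse)):
            valid = vec[np.isfinite(vec)]
            out[f"{name}_mean"] = float(valid.mean()) if valid.size else float("nan")
            out[f"{name}_sd"] = float(valid.std(ddof=0)) if valid.size else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"unit_id": self.unit_ids, "pcc": self.pcc,
                             "scc": self.scc, "rmse": self.rmse})


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        return float("nan")
    return float(stats.pearsonr(u, v).statistic)


def _spearman(u: np.ndarray, v: np.ndarray) -> float:
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        return float("nan")
    return float(stats.spearmanr(u, v).statistic)


def paired_metrics(a: ExpressionMatrix, b: ExpressionMatrix, axis: str,
                   comparison_label: str = "") -> MetricsReport:
    """PCC, SCC and RMSE per matched sample (or per matched gene).

    ``a`` and ``b`` must share identifiers in identical order; RMSE is the
    root mean squared difference over the compared vector.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    if list(a.gene_ids) != list(b.gene_ids) or list(a.sample_ids) != list(b.sample_ids):
        raise ValueError("matrices must share gene_ids and sample_ids in order")
    if axis == "sample_wise":
        va, vb = a.values.T, b.values.T
        unit_ids = list(a.sample_ids)
    else:
        va, vb = a.values, b.values
        unit_ids = list(a.gene_ids)
    n = len(unit_ids)
    pcc = np.empty(n)
    scc = np.empty(n)
    rmse = np.empty(n)
    for i in range(n):
        pcc[i] = _pearson(va[i], vb[i])
        scc[i] = _spearman(va[i], vb[i])
        rmse[i] = float(np.sqrt(np.mean((va[i] - vb[i]) ** 2)))
    n_undef = int(np.sum(~np.isfinite(pcc)))
    if n_undef:
        logger.info("%d units had undefined correlation (constant vectors)", n_undef)
    return MetricsReport(axis=axis, unit_ids=unit_ids, pcc=pcc, scc=scc,
                         rmse=rmse, comparison_label=comparison_label,
                         n_undefined=n_undef)


def _derangement(n: int, rng: np.random.Generator, max_tries: int = 1000) -> np.ndarray:
    """Seeded permutation of 0..n-1 with no fixed point (n > 1)."""
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm
    return np.roll(np.arange(n), 1)  # deterministic fallback, never hit in practice


def random_pairing_metrics(a: ExpressionMatrix, b: ExpressionMatrix, axis: str,
                           seed: int, n_permutations: int = 1) -> MetricsReport:
    """Metrics after randomly re-pairing ``b``'s samples against ``a``'s.

    Uses a seeded derangement so no sample is compared with itself. With
    ``n_permutations > 1`` the per-unit metric vectors are averaged over
    independent derangements.
    """
    if a.n_samples < 2:
        raise ValueError("random pairing needs at least 2 samples")
    if list(a.gene_ids) != list(b.gene_ids):
        raise ValueError("matrices must share gene_ids in order")
    if a.n_samples != b.n_samples:
        raise ValueError("matrices must have the same number of samples")
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(n_permutations):
        perm = _derangement(a.n_samples, rng)
        b_perm = ExpressionMatrix(values=b.values[:, perm],
                                  gene_ids=list(b.gene_ids),
                                  sample_ids=list(a.sample_ids),
                                  space=b.space, scale=b.scale)
        reports.append(paired_metrics(a, b_perm, axis,
                                      comparison_label="predicted_vs_random"))
    if n_permutations == 1:
        return reports[0]
    return MetricsReport(
        axis=axis, unit_ids=reports[0].unit_ids,
        pcc=np.nanmean([r.pcc for r in reports], axis=0),
        scc=np.nanmean([r.scc for r in reports], axis=0),
        rmse=np.mean([r.rmse for r in reports], axis=0),
        comparison_label="predicted_vs_random",
        n_undefined=max(r.n_undefined for r in reports),
    )


def pca_embedding(groups: list[tuple[str, ExpressionMatrix]],
                  scale: bool = False) -> pd.DataFrame:
    """Project labeled matrices into a shared 2-D PCA space.

    Matrices are restricted to their common genes, concatenated
    sample-wise, gene-mean centered (variance scaling optional) and
    projected on the top two principal axes. Returns a frame with columns
    ``label, sample_id, pc1, pc2`` and explained-variance ratios in
    ``attrs["explained_variance_ratio"]``.
    """
    from sklearn.decomposition import PCA

    if not groups:
        raise ValueError("no input matrices")
    common = [g for g in groups[0][1].gene_ids
              if all(g in set(m.gene_ids) for _, m in groups[1:])]
    if len(common) < 2:
        raise ValueError("fewer than 2 common genes across groups")
    blocks, labels, sample_ids = [], [], []
    for label, m in groups:
        sub = m.subset_genes(common)
        blocks.append(sub.values.T)
        labels.extend([label] * sub.n_samples)
        sample_ids.extend(sub.sample_ids)
    data = np.vstack(blocks)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 samples total")
    data = data - data.mean(axis=0)
    if scale:
        sd = data.std(axis=0)
        data = data / np.where(sd == 0, 1.0, sd)
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(data)
    frame = pd.DataFrame({"label": labels, "sample_id": sample_ids,
                          "pc1": coords[:, 0], "pc2": coords[:, 1]})
    frame.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    return frame
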