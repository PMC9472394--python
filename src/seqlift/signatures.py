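"""Differential-expression signatures, bridge walks and reverse search.

A *signature* contrasts treatment against control samples within one
experimental batch and records, per gene, a characteristic-direction (CD)
coefficient and a log2 fold change. The CD is a regularized linear
discriminant direction in gene space: a unit vector

    b  ∝  (gamma * Sigma_pooled + (1 - gamma) * I)^(-1) (mu_t - mu_c)

whose large-|coefficient| genes move most consistently between the
groups; with ``gamma = 0`` it reduces to the normalized mean-difference.
For p >> n the inverse is evaluated in the span of the data (Woodbury
identity), so the computation stays well-posed at genome scale.

Gene-set enrichment near the top of a signature's ranking is measured
with a *bridge walk*: a running sum over the ranked genes that rises by
1/m at each of the m set genes and falls by 1/(N-m) otherwise, returning
to zero at the end; its peak (in [0, 1]) is high when set genes crowd
the top ranks. A seeded permutation null turns the peak into an
empirical p-value.

``reverse_search`` inverts the signature collection: given one query
gene, it ranks the signatures that most up- or down-regulate that gene
by combining fold change, CD coefficient and within-signature rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class Signature:
    """Per-gene differential-expression record for one batch contrast."""

    signature_id: str
    gene_ids: list[str]
    cd_coefficients: np.ndarray | None
    log2_fold_changes: np.ndarray
    n_treatment: int
    n_control: int
    perturbagen: str = ""
    batch: str = ""
    cell_line: str = ""
    method: str = "cd"  # ranking method: cd | fold_change

    def __post_init__(self) -> None:
        self.log2_fold_changes = np.asarray(self.log2_fold_changes, dtype=np.float64)
        if self.cd_coefficients is not None:
            self.cd_coefficients = np.asarray(self.cd_coefficients, dtype=np.float64)
            if abs(np.linalg.norm(self.cd_coefficients) - 1.0) > 1e-8:
                raise ValueError("cd_coefficients must have unit Euclidean norm")
            if len(self.cd_coefficients) != len(self.gene_ids):
                raise ValueError("cd_coefficients length mismatch")
        if len(self.log2_fold_changes) != len(self.gene_ids):
            raise ValueError("log2_fold_changes length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids in signature")

    def ranking_values(self) -> np.ndarray:
        if self.method == "cd" and self.cd_coefficients is not None:
            return self.cd_coefficients
        return self.log2_fold_changes

    def ranked_genes(self) -> list[str]:
        """Genes sorted by descending differential-expression value.

        Ties break lexicographically on the gene symbol, so rankings are
        deterministic.
        """
        vals = self.ranking_values()
        order = sorted(range(len(self.gene_ids)),
                       key=lambda i: (-vals[i], self.gene_ids[i]))
        return [self.gene_ids[i] for i in order]

    def gene_rank(self, gene: str) -> int:
        """1-based rank of ``gene`` in the descending ranking."""
        return self.ranked_genes().index(gene) + 1

    def to_frame(self) -> pd.DataFrame:
        ranks = {g: r for r, g in enumerate(self.ranked_genes(), start=1)}
        return pd.DataFrame({
            "gene": self.gene_ids,
            "cd_coefficient": (self.cd_coefficients if self.cd_coefficients
                               is not None else np.full(len(self.gene_ids), np.nan)),
            "log2fc": self.log2_fold_changes,
            "rank": [ranks[g] for g in self.gene_ids],
        })


# ---------------------------------------------------------------------------
# characteristic direction & fold change
# ---------------------------------------------------------------------------

def characteristic_direction(controls: ExpressionMatrix,
                             treatments: ExpressionMatrix,
                             gamma: float = 0.5) -> np.ndarray:
    """Unit characteristic-direction vector over the shared genes.

    ``gamma`` in [0, 1] shrinks the pooled covariance toward the identity;
    with fewer than 2 samples in either group the covariance cannot be
    estimated and gamma is forced to 0 (mean-difference direction). The
    sign convention makes the gene with the largest |coefficient| carry
    the sign of its mean difference.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must be in [0, 1]")
    if list(controls.gene_ids) != list(treatments.gene_ids):
        raise ValueError("groups must share gene_ids in the same order")
    mu_c = controls.values.mean(axis=1)
    mu_t = treatments.values.mean(axis=1)
    delta = mu_t - mu_c
    if np.allclose(delta, 0.0):
        raise ValueError("no differential signal: zero mean-difference vector")
    n_c, n_t = controls.n_samples, treatments.n_samples
    if min(n_c, n_t) < 2:
        gamma = 0.0

    if gamma == 0.0:
        b = delta
    else:
        centered = np.hstack([controls.values - mu_c[:, None],
                              treatments.values - mu_t[:, None]])
        dof = max(1, n_c + n_t - 2)
        p = len(delta)
        if p <= max(n_c + n_t, 512):
            sigma = (centered @ centered.T) / dof
            m = gamma * sigma + (1.0 - gamma) * np.eye(p)
            try:
                b = np.linalg.solve(m, delta)
            except np.linalg.LinAlgError:
                b = np.linalg.pinv(m) @ delta
        else:
            b = _shrunk_inverse_apply(centered, dof, gamma, delta)

    sign_gene = int(np.argmax(np.abs(b)))
    if b[sign_gene] * delta[sign_gene] < 0:
        b = -b
    return b / np.linalg.norm(b)


def _shrunk_inverse_apply(centered: np.ndarray, dof: int, gamma: float,
                          delta: np.ndarray) -> np.ndarray:
    """(gamma*Sigma + (1-gamma)*I)^(-1) delta via the data-span (Woodbury).

    Sigma = V diag(d) V^T with V the left singular vectors of the centered
    data; the inverse acts as a scaled identity off the span.
    """
    a = 1.0 - gamma
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    d = (s ** 2) / dof
    keep = d > 1e-12
    u, d = u[:, keep], d[keep]
    shrink = (gamma * d) / (a + gamma * d)
    proj = u.T @ delta
    return (delta - u @ (shrink * proj)) / a


def fold_change_signature(controls: ExpressionMatrix,
                          treatments: ExpressionMatrix) -> np.ndarray:
    """Per-gene log2 fold change: mean(treatment) - mean(control)."""
    if controls.n_samples == 0 or treatments.n_samples == 0:
        raise ValueError("both groups must be non-empty")
    if list(controls.gene_ids) != list(treatments.gene_ids):
        raise ValueError("groups must share gene_ids in the same order")
    return treatments.values.mean(axis=1) - controls.values.mean(axis=1)


def batch_signatures(profiles: ExpressionMatrix,
                     metadata: list[SampleMetadata],
                     perturbagen: str,
                     method: str = "cd",
                     gamma: float = 0.5) -> list[Signature]:
    """One signature per batch: perturbagen samples vs the rest of the batch.

    Batches lacking either treatment or control samples are skipped with a
    logged reason. Both the fold change and (when at least one sample per
    side exists) the CD coefficients are stored on every signature; the
    ``method`` tag selects which one drives gene ranking.
    """
    if method not in ("cd", "fold_change"):
        raise ValueError("method must be 'cd' or 'fold_change'")
    by_sample = {r.sample_id: r for r in metadata}
    missing = [s for s in profiles.sample_ids if s not in by_sample]
    if missing:
        raise ValueError(f"metadata missing for samples: {missing[:10]}")
    if not any(r.perturbagen == perturbagen for r in metadata):
        raise ValueError(f"perturbagen {perturbagen!r} absent from metadata")

    batches: dict[str, list[str]] = {}
    for s in profiles.sample_ids:
        batches.setdefault(by_sample[s].batch, []).append(s)

    signatures = []
    for batch, samples in batches.items():
        treat = [s for s in samples if by_sample[s].perturbagen == perturbagen]
        ctrl = [s for s in samples if by_sample[s].perturbagen != perturbagen]
        if not treat or not ctrl:
            logger.info("batch %r skipped: needs both treated and control "
                        "samples (%d treated, %d control)", batch,
                        len(treat), len(ctrl))
            continue
        t_mat = profiles.subset_samples(treat)
        c_mat = profiles.subset_samples(ctrl)
        fc = fold_change_signature(c_mat, t_mat)
        try:
            cd = characteristic_direction(c_mat, t_mat, gamma=gamma)
        except ValueError:
            cd = None
        cell_lines = {by_sample[s].cell_line for s in treat}
        signatures.append(Signature(
            signature_id=f"{perturbagen}_{batch}",
            gene_ids=list(profiles.gene_ids),
            cd_coefficients=cd,
            log2_fold_changes=fc,
            n_treatment=len(treat),
            n_control=len(ctrl),
            perturbagen=perturbagen,
            batch=batch,
            cell_line=cell_lines.pop() if len(cell_lines) == 1 else "",
            method=method,
        ))
    return signatures


# ---------------------------------------------------------------------------
# bridge walks
# ---------------------------------------------------------------------------

@dataclass
class BridgeResult:
    """Running-sum walk over a gene ranking against one gene set."""

    running_sum: np.ndarray
    peak: float
    peak_rank: int
    n_set_in_ranking: int
    permutation_mean_peak: float | None = None
    p_value: float | None = None


def bridge_walk(ranked_genes: list[str], gene_set,
                weights: np.ndarray | None = None) -> BridgeResult:
    """Balanced running-sum walk down a ranked gene list.

    Unweighted: +1/m at each of the m set genes, -1/(N-m) otherwise, so
    the walk ends at exactly 0 and its peak lies in [0, 1]. The running
    sum is evaluated as cumulative-count ratios
    (hits_so_far/m - misses_so_far/(N-m)), so a set occupying the top m
    ranks peaks at exactly 1.0 and every walk ends at exactly 0.
    Weighted: the supplied per-gene nonnegative weights (absolute
    differential-expression values) are first rescaled into [0, 1] by
    their maximum, then the up-step at a set gene g is w_g / sum of
    rescaled weights over the set; down-steps are unchanged, so the
    weighted walk is also a bridge.
    """
    ranked_genes = list(ranked_genes)
    n = len(ranked_genes)
    if len(set(ranked_genes)) != n:
        raise ValueError("ranked_genes must be unique")
    members = np.array([g in set(gene_set) for g in ranked_genes])
    m = int(members.sum())
    if m == 0 or m == n:
        raise ValueError("degenerate gene set: no overlap or full overlap "
                         "with the ranking")
    cum_miss = np.cumsum(~members)
    if weights is None:
        up = np.cumsum(members) / m
    else:
        weights = np.asarray(weights, dtype=np.float64)
        if weights.shape != (n,):
            raise ValueError("weights must align with ranked_genes")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        w_max = weights.max()
        scaled = weights / w_max if w_max > 0 else np.full(n, 1.0)
        set_total = scaled[members].sum()
        if set_total == 0:
            up = np.cumsum(members) / m  # weightless set: flat up-steps
        else:
            contrib = np.where(members, scaled, 0.0)
            up = np.cumsum(contrib) / set_total
    running = up - cum_miss / (n - m)
    peak = float(running.max())
    return BridgeResult(running_sum=running, peak=peak,
                        peak_rank=int(np.argmax(running)) + 1,
                        n_set_in_ranking=m)


def bridge_null(ranked_genes: list[str], gene_set,
                n_permutations: int, seed: int,
                weights: np.ndarray | None = None) -> BridgeResult:
    """Permutation null for the bridge peak.

    The ranking is shuffled ``n_permutations`` times with a seeded
    generator (weights stay positional, so the null preserves the weight
    profile of the ranking); the empirical p-value is
    ``(1 + #{null peak >= observed}) / (n_permutations + 1)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    observed = bridge_walk(ranked_genes, gene_set, weights)
    rng = np.random.default_rng(seed)
    genes = np.asarray(ranked_genes, dtype=object)
    null_peaks = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(len(genes))
        null_peaks[i] = bridge_walk(list(genes[perm]), gene_set, weights).peak
    observed.permutation_mean_peak = float(null_peaks.mean())
    observed.p_value = float((1 + np.sum(null_peaks >= observed.peak))
                             / (n_permutations + 1))
    return observed


# ---------------------------------------------------------------------------
# gene-centric reverse search
# ---------------------------------------------------------------------------

def reverse_search(query_gene: str, signatures: list[Signature],
                   cell_line: str | None = None,
                   top_k: int = 100) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Find the signatures that most up- or down-regulate one gene.

    For every signature containing the query gene, its log2 fold change,
    CD coefficient and within-signature rank are extracted; signatures are
    ordered by a rank-sum over the three criteria (descending fold change,
    descending CD and ascending rank for the up-search; mirrored for the
    down-search). Returns ``(up_table, down_table, volcano)`` where the
    volcano frame carries ``x = log2 fold change`` and
    ``y = |CD coefficient|`` per signature, with a ``discordant`` flag for
    signatures whose fold change and CD disagree in sign (a gene can move
    inconsistently across replicates).
    """
    pool = signatures
    if cell_line is not None:
        pool = [s for s in pool if s.cell_line == cell_line]
        if not pool:
            logger.warning("cell-line filter %r excluded every signature", cell_line)
            empty = _empty_search_frame()
            return empty, empty.copy(), empty.copy()
    rows = []
    for sig in pool:
        if query_gene not in set(sig.gene_ids):
            continue
        i = sig.gene_ids.index(query_gene)
        fc = float(sig.log2_fold_changes[i])
        cd = (float(sig.cd_coefficients[i])
              if sig.cd_coefficients is not None else float("nan"))
        rows.append({
            "signature_id": sig.signature_id, "perturbagen": sig.perturbagen,
            "batch": sig.batch, "cell_line": sig.cell_line,
            "log2fc": fc, "cd_coefficient": cd,
            "rank": sig.gene_rank(query_gene),
            "discordant": bool(np.isfinite(cd) and fc * cd < 0),
        })
    if not rows:
        raise ValueError(f"gene {query_gene!r} absent from every signature")
    table = pd.DataFrame(rows)

    cd_for_rank = table["cd_coefficient"].fillna(0.0)
    up_score = (table["log2fc"].rank(ascending=False)
                + cd_for_rank.rank(ascending=False)
                + table["rank"].rank(ascending=True))
    down_score = (table["log2fc"].rank(ascending=True)
                  + cd_for_rank.rank(ascending=True)
                  + table["rank"].rank(ascending=False))
    up = table.assign(score=up_score).sort_values(
        ["score", "signature_id"]).head(top_k).reset_index(drop=True)
    down = table.assign(score=down_score).sort_values(
        ["score", "signature_id"]).head(top_k).reset_index(drop=True)
    volcano = table[["signature_id", "log2fc", "cd_coefficient", "discordant"]].copy()
    volcano["abs_cd"] = volcano["cd_coefficient"].abs()
    return up, down, volcano


def _empty_search_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["signature_id", "perturbagen", "batch",
                                 "cell_line", "log2fc", "cd_coefficient",
                                 "rank", "discordant", "score"])
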