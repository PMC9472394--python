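"""Step 2 — extrapolating landmark-space profiles to the full gene space.

A fully connected network takes RNA-seq-like landmark profiles and
predicts the expression of every other modeled gene; full profiles are
assembled as the input landmarks plus the predicted targets. Training
minimizes mean squared error with Adam, a seeded validation split, and
early stopping (training halts once the validation loss has failed to
improve for ``patience`` consecutive epochs, and the best-epoch weights
are restored). The final layer is rectified so predicted expression is
never negative.

Two reference baselines accompany the networks: per-gene ratio scaling
(for step 1: each gene rescaled by the ratio of domain means) and a
landmark→target linear regression (for step 2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import MLP, Adam, load_mlp, save_mlp
from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class ExtrapolatorConfig:
    """Hyper-parameters of the landmark→genome network.

    ``layer_units = None`` derives hidden widths from the landmark count in
    the same proportions as the full-scale architecture
    (962 → 2048 → 8162 → 23,614), i.e. roughly 1 : 2.1 : 8.5 relative to
    the input.
    """

    layer_units: list[int] | None = None
    learning_rate: float = 2e-4
    batch_size: int = 100
    patience: int = 3
    max_epochs: int = 200
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("batch_size, patience and max_epochs must be >= 1")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.layer_units is not None and any(u < 1 for u in self.layer_units):
            raise ValueError("all layer_units must be >= 1")


@dataclass
class ExtrapolatorModel:
    """Trained landmark→target network plus the gene partition it models.

    The network operates on standardized values (per-gene mean/sd learned
    from the training corpus); predictions are de-standardized and then
    rectified, so the model's output is nonnegative for any input.
    """

    E: MLP
    landmark_ids: list[str]
    target_ids: list[str]       # the predicted (non-landmark) genes
    full_gene_order: list[str]  # landmarks ∪ targets, original matrix order
    x_mean: np.ndarray = None
    x_sd: np.ndarray = None
    y_mean: np.ndarray = None
    y_sd: np.ndarray = None
    history: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict_targets(self, landmark_values: np.ndarray) -> np.ndarray:
        """Predict target-gene values for a ``samples x landmarks`` batch.

        Applies the stored standardization, the network, the inverse
        transform and a final rectification (output >= 0).
        """
        xs = (np.asarray(landmark_values, dtype=np.float64) - self.x_mean) / self.x_sd
        raw = self.E.predict(xs)
        return np.maximum(raw * self.y_sd + self.y_mean, 0.0)


def _default_units(n_in: int, n_out: int) -> list[int]:
    h1 = max(8, round(n_in * 2048 / 962))
    h2 = max(8, round(n_in * 8162 / 962))
    return [n_in, h1, h2, n_out]


def train_extrapolator(rnaseq_full: ExpressionMatrix, landmark_ids: list[str],
                       config: ExtrapolatorConfig | None = None) -> ExtrapolatorModel:
    """Fit the extrapolation network on full-genome RNA-seq profiles.

    Landmark rows are the inputs; all remaining genes are the regression
    targets. The sample-wise validation split, the initialization and the
    batch order are all driven by ``config.seed``.
    """
    config = config or ExtrapolatorConfig()
    missing = [g for g in landmark_ids if g not in set(rnaseq_full.gene_ids)]
    if missing:
        raise ValueError(f"landmark genes missing from matrix: {missing[:10]}")
    landmark_ids = list(landmark_ids)
    target_ids = [g for g in rnaseq_full.gene_ids if g not in set(landmark_ids)]
    if not target_ids:
        raise ValueError("no target genes left after removing landmarks")

    x_all = rnaseq_full.subset_genes(landmark_ids).values.T   # samples x landmarks
    y_all = rnaseq_full.subset_genes(target_ids).values.T     # samples x targets
    # per-gene standardization: the network trains in z-score space, which
    # conditions the optimization far better than raw log2 magnitudes
    x_mean, x_sd = x_all.mean(axis=0), x_all.std(axis=0)
    y_mean, y_sd = y_all.mean(axis=0), y_all.std(axis=0)
    x_sd = np.where(x_sd == 0, 1.0, x_sd)
    y_sd = np.where(y_sd == 0, 1.0, y_sd)
    x_all = (x_all - x_mean) / x_sd
    y_all = (y_all - y_mean) / y_sd
    n = len(x_all)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training samples")
    val_idx, train_idx = order[:n_val], order[n_val:]
    x_tr, y_tr = x_all[train_idx], y_all[train_idx]
    x_va, y_va = x_all[val_idx], y_all[val_idx]

    units = config.layer_units or _default_units(len(landmark_ids), len(target_ids))
    if units[0] != len(landmark_ids) or units[-1] != len(target_ids):
        raise ValueError(
            f"layer_units {units} incompatible with {len(landmark_ids)} "
            f"landmarks / {len(target_ids)} targets"
        )
    # linear output in standardized space; rectification happens after the
    # inverse transform in predict_targets
    net = MLP(units, relu_output=False, rng=rng)
    opt = Adam([net], lr=config.learning_rate)

    best_val = np.inf
    best_state = net.get_state()
    best_epoch = -1
    since_best = 0
    records = []
    n_batches = max(1, len(x_tr) // config.batch_size)

    for epoch in range(config.max_epochs):
        perm = rng.permutation(len(x_tr))
        train_loss = 0.0
        for b in range(n_batches):
            idx = perm[b * config.batch_size : (b + 1) * config.batch_size]
            if len(idx) == 0:
                continue
            xb, yb = x_tr[idx], y_tr[idx]
            out, cache = net.forward(xb)
            diff = out - yb
            loss = float(np.mean(diff ** 2))
            net.zero_grad()
            net.backward(cache, 2.0 * diff / diff.size)
            opt.step()
            train_loss += loss
        train_loss /= n_batches
        val_loss = float(np.mean((net.predict(x_va) - y_va) ** 2))
        records.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss})
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.get_state()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                logger.info("early stop at epoch %d (best epoch %d, val %.5f)",
                            epoch, best_epoch, best_val)
                break

    net.set_state(best_state)
    history = pd.DataFrame(records, columns=["epoch", "train_loss", "val_loss"])
    history.attrs["best_epoch"] = best_epoch
    return ExtrapolatorModel(E=net, landmark_ids=landmark_ids,
                             target_ids=target_ids,
                             full_gene_order=list(rnaseq_full.gene_ids),
                             x_mean=x_mean, x_sd=x_sd,
                             y_mean=y_mean, y_sd=y_sd,
                             history=history)


def extrapolate(model: ExtrapolatorModel,
                landmark_profiles: ExpressionMatrix) -> ExpressionMatrix:
    """Predict full-genome profiles from landmark profiles.

    Returns a full-space matrix in the model's original gene order: the
    landmark rows are the inputs passed through, the remaining rows are
    the network predictions. Deterministic; all values >= 0 when the input
    is nonnegative.
    """
    present = set(landmark_profiles.gene_ids) & set(model.landmark_ids)
    if not present:
        raise ValueError("no overlap between input genes and model landmarks")
    missing = [g for g in model.landmark_ids
               if g not in set(landmark_profiles.gene_ids)]
    if missing:
        raise ValueError(f"input missing model landmark genes: {missing[:10]}")
    x = landmark_profiles.subset_genes(list(model.landmark_ids))
    predicted = model.predict_targets(x.values.T).T   # targets x samples

    lm_index = {g: i for i, g in enumerate(model.landmark_ids)}
    tg_index = {g: i for i, g in enumerate(model.target_ids)}
    full = np.empty((len(model.full_gene_order), x.n_samples))
    for row, gene in enumerate(model.full_gene_order):
        if gene in lm_index:
            full[row] = x.values[lm_index[gene]]
        else:
            full[row] = predicted[tg_index[gene]]
    return ExpressionMatrix(values=full, gene_ids=list(model.full_gene_order),
                            sample_ids=list(landmark_profiles.sample_ids),
                            space="full", scale="log2")


def save_extrapolator(model: ExtrapolatorModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"landmark_ids": model.landmark_ids,
                "target_ids": model.target_ids,
                "full_gene_order": model.full_gene_order,
                "x_mean": [v.hex() for v in model.x_mean],
                "x_sd": [v.hex() for v in model.x_sd],
                "y_mean": [v.hex() for v in model.y_mean],
                "y_sd": [v.hex() for v in model.y_sd]}
    (directory / "extrapolator.json").write_text(json.dumps(manifest, indent=1))
    save_mlp(model.E, directory, "E")
    model.history.to_csv(directory / "history.tsv", sep="\t", index=False)


def load_extrapolator(directory: str | Path) -> ExtrapolatorModel:
    directory = Path(directory)
    manifest = json.loads((directory / "extrapolator.json").read_text())
    def _arr(key):
        return np.array([float.fromhex(v) for v in manifest[key]])
    return ExtrapolatorModel(E=load_mlp(directory, "E"),
                             landmark_ids=manifest["landmark_ids"],
                             target_ids=manifest["target_ids"],
                             full_gene_order=manifest["full_gene_order"],
                             x_mean=_arr("x_mean"), x_sd=_arr("x_sd"),
                             y_mean=_arr("y_mean"), y_sd=_arr("y_sd"),
                             history=pd.read_csv(directory / "history.tsv", sep="\t", float_precision="round_trip"))


# ---------------------------------------------------------------------------
# ratio-scaling baseline (step-1 reference)
# ---------------------------------------------------------------------------

@dataclass
class RatioBaseline:
    """Per-gene scaling by the ratio of domain means."""

    gene_ids: list[str]
    scale_factors: np.ndarray

    def __post_init__(self) -> None:
        self.scale_factors = np.asarray(self.scale_factors, dtype=np.float64)
        if self.scale_factors.shape != (len(self.gene_ids),):
            raise ValueError("one scale factor per gene required")
        if not np.all(np.isfinite(self.scale_factors)):
            raise ValueError("scale factors must be finite")


def fit_ratio_baseline(x_pool: ExpressionMatrix,
                       y_pool: ExpressionMatrix,
                       eps: float = 1e-8) -> RatioBaseline:
    """Per-gene factor ``mean_y / mean_x`` over (possibly unpaired) pools.

    Genes whose domain-X mean is ~0 get factor 1 with a warning — scaling
    an all-zero gene is ill-defined.
    """
    if x_pool.n_samples == 0 or y_pool.n_samples == 0:
        raise ValueError("pools must be non-empty")
    if list(x_pool.gene_ids) != list(y_pool.gene_ids):
        raise ValueError("pools must share gene_ids in the same order")
    mean_x = x_pool.values.mean(axis=1)
    mean_y = y_pool.values.mean(axis=1)
    degenerate = mean_x <= eps
    factors = np.ones_like(mean_x)
    np.divide(mean_y, mean_x, out=factors, where=~degenerate)
    if degenerate.any():
        logger.warning("ratio baseline: %d genes with near-zero domain-X mean "
                       "given factor 1", int(degenerate.sum()))
    return RatioBaseline(gene_ids=list(x_pool.gene_ids), scale_factors=factors)


def apply_ratio_baseline(b: RatioBaseline, x: ExpressionMatrix) -> ExpressionMatrix:
    x_ord = x.subset_genes(b.gene_ids)
    return x_ord.with_values(x_ord.values * b.scale_factors[:, None])


# ---------------------------------------------------------------------------
# linear-regression baseline (step-2 reference)
# ---------------------------------------------------------------------------

@dataclass
class LinearBaseline:
    """Per-target OLS regression on the landmark genes (intercept included)."""

    landmark_ids: list[str]
    target_ids: list[str]
    coefficients: np.ndarray  # targets x (landmarks + 1); last column = intercept
    full_gene_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        expected = (len(self.target_ids), len(self.landmark_ids) + 1)
        if self.coefficients.shape != expected:
            raise ValueError(f"coefficients must have shape {expected}")


def fit_linear_baseline(rnaseq_full: ExpressionMatrix, landmark_ids: list[str],
                        ridge: float = 0.0) -> LinearBaseline:
    """Jointly solve OLS for every target gene given the landmark genes.

    Rank-deficient designs fall back to the minimum-norm least-squares
    solution (with a warning); ``ridge > 0`` adds an L2 penalty on the
    slopes for ill-conditioned inputs.
    """
    missing = [g for g in landmark_ids if g not in set(rnaseq_full.gene_ids)]
    if missing:
        raise ValueError(f"landmark genes missing from matrix: {missing[:10]}")
    target_ids = [g for g in rnaseq_full.gene_ids if g not in set(landmark_ids)]
    X = rnaseq_full.subset_genes(list(landmark_ids)).values.T
    Y = rnaseq_full.subset_genes(target_ids).values.T
    n, p = X.shape
    design = np.hstack([X, np.ones((n, 1))])
    if ridge > 0:
        penalty = ridge * np.eye(p + 1)
        penalty[-1, -1] = 0.0  # never shrink the intercept
        coef = np.linalg.solve(design.T @ design + penalty, design.T @ Y)
    else:
        if n <= p or np.linalg.matrix_rank(design) < p + 1:
            logger.warning("rank-deficient design: using minimum-norm solution")
        coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return LinearBaseline(landmark_ids=list(landmark_ids), target_ids=target_ids,
                          coefficients=coef.T,
                          full_gene_order=list(rnaseq_full.gene_ids))


def apply_linear_baseline(b: LinearBaseline,
                          landmark_profiles: ExpressionMatrix) -> ExpressionMatrix:
    """Predict full profiles (landmarks passed through, targets regressed)."""
    x = landmark_profiles.subset_genes(list(b.landmark_ids))
    design = np.hstack([x.values.T, np.ones((x.n_samples, 1))])
    predicted = (design @ b.coefficients.T).T  # targets x samples
    order = b.full_gene_order or (list(b.landmark_ids) + list(b.target_ids))
    lm = {g: i for i, g in enumerate(b.landmark_ids)}
    tg = {g: i for i, g in enumerate(b.target_ids)}
    full = np.empty((len(order), x.n_samples))
    for row, gene in enumerate(order):
        full[row] = x.values[lm[gene]] if gene in lm else predicted[tg[gene]]
    return ExpressionMatrix(values=full, gene_ids=list(order),
                            sample_ids=list(landmark_profiles.sample_ids),
                            space="full", scale="log2")
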