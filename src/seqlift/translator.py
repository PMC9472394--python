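"""Step 1 — unpaired cross-platform translation in the landmark gene space.

A modified CycleGAN maps expression profiles between two platform domains:
X (L1000-like landmark profiles) and Y (RNA-seq-like profiles on the same
genes). Two generators ``G: X→Y`` and ``F: Y→X`` are trained against two
least-squares discriminators ``D_X``, ``D_Y`` on *unpaired* pools, under a
cycle-consistency penalty (a profile translated out and back must return
to itself), and an identity penalty (a generator fed a profile already in
its output domain should leave it alone — platforms share most expression
structure). Generator outputs pass through a final ReLU so translated
profiles are never negative, matching the nonnegative log2 scale.

The full objective is

    L = L_GAN(G, D_Y) + L_GAN(F, D_X) + lambda_cyc * L_cyc + lambda_identity * L_identity

with both weights defaulting to 10 and least-squares adversarial terms
(discriminator target 1 on real profiles, 0 on generated ones).
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
class CycleGANConfig:
    """Hyper-parameters of the translator.

    ``hidden_units = None`` selects ``min(1024, 4 * n_genes)`` at training
    time — capacity comparable to the input dimension without requiring a
    GPU. ``n_hidden_layers`` applies to all four networks (generators and
    discriminators alike).

    ``identity_init`` starts both generators near the identity map (exactly
    representable with ReLU units on nonnegative inputs, plus small
    symmetry-breaking noise). The two platforms share most expression
    structure, so the cycle and identity penalties then start near zero and
    the adversarial term only has to learn the per-gene platform
    correction; this stabilizes training dramatically at small sample
    counts.
    """

    hidden_units: int | None = None
    learning_rate: float = 2e-4
    lambda_cyc: float = 10.0
    lambda_identity: float = 10.0
    epochs: int = 100
    batch_size: int = 100
    n_hidden_layers: int = 2
    identity_init: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.lambda_cyc < 0 or self.lambda_identity < 0:
            raise ValueError("loss weights must be >= 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_hidden_layers < 1:
            raise ValueError("n_hidden_layers must be >= 1")


@dataclass
class TranslatorModel:
    """Trained (or freshly initialized) CycleGAN translator."""

    G: MLP
    F: MLP
    D_X: MLP
    D_Y: MLP
    gene_ids: list[str]
    config: CycleGANConfig
    history: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# loss functions (pure; also used during training)
# ---------------------------------------------------------------------------

def adversarial_loss(d_real_outputs: np.ndarray,
                     d_fake_outputs: np.ndarray) -> tuple[float, float]:
    """Least-squares adversarial losses.

    ``d_loss = mean((d_real - 1)^2) + mean(d_fake^2)`` — the discriminator
    pushes real scores to 1 and fake scores to 0;
    ``g_loss = mean((1 - d_fake)^2)`` — the generator pushes its fakes'
    scores to 1.
    """
    d_real = np.asarray(d_real_outputs, dtype=np.float64).ravel()
    d_fake = np.asarray(d_fake_outputs, dtype=np.float64).ravel()
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("discriminator output vectors must be non-empty")
    if not (np.all(np.isfinite(d_real)) and np.all(np.isfinite(d_fake))):
        raise ValueError("discriminator outputs must be finite")
    d_loss = float(np.mean((d_real - 1.0) ** 2) + np.mean(d_fake ** 2))
    g_loss = float(np.mean((1.0 - d_fake) ** 2))
    return d_loss, g_loss


def cycle_consistency_loss(x: np.ndarray, y: np.ndarray, G, F) -> float:
    """``mean((F(G(x)) - x)^2) + mean((G(F(y)) - y)^2)`` over all entries."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    x_rec = _apply(F, _apply(G, x))
    y_rec = _apply(G, _apply(F, y))
    if x_rec.shape != x.shape or y_rec.shape != y.shape:
        raise ValueError("generator output dimension mismatch")
    return float(np.mean((x_rec - x) ** 2) + np.mean((y_rec - y) ** 2))


def identity_loss(x: np.ndarray, y: np.ndarray, G, F) -> float:
    """``mean((F(x) - x)^2) + mean((G(y) - y)^2)`` over all entries."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    fx = _apply(F, x)
    gy = _apply(G, y)
    if fx.shape != x.shape or gy.shape != y.shape:
        raise ValueError("generator output dimension mismatch")
    return float(np.mean((fx - x) ** 2) + np.mean((gy - y) ** 2))


def total_objective(gan_G: float, gan_F: float, cyc: float, ident: float,
                    config: CycleGANConfig) -> float:
    """Weighted sum of the four loss components (bit-exact arithmetic)."""
    for v in (gan_G, gan_F, cyc, ident):
        if not np.isfinite(v):
            raise ValueError("loss components must be finite")
    return gan_G + gan_F + config.lambda_cyc * cyc + config.lambda_identity * ident


def _apply(net, batch: np.ndarray) -> np.ndarray:
    if isinstance(net, MLP):
        return net.predict(batch)
    return np.asarray(net(batch), dtype=np.float64)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _build_networks(n_genes: int, config: CycleGANConfig,
                    rng: np.random.Generator) -> tuple[MLP, MLP, MLP, MLP]:
    width = config.hidden_units or min(1024, 4 * n_genes)
    gen_units = [n_genes] + [width] * config.n_hidden_layers + [n_genes]
    dis_units = [n_genes] + [width] * config.n_hidden_layers + [1]
    G = MLP(gen_units, relu_output=True, rng=rng)
    F = MLP(gen_units, relu_output=True, rng=rng)
    if config.identity_init:
        _near_identity(G, rng)
        _near_identity(F, rng)
    # discriminators end in a single linear unit (least-squares GAN)
    D_X = MLP(dis_units, relu_output=False, rng=rng)
    D_Y = MLP(dis_units, relu_output=False, rng=rng)
    return G, F, D_X, D_Y


def _near_identity(net: MLP, rng: np.random.Generator,
                   noise_scale: float = 0.01) -> None:
    """Reset a ReLU generator to (identity map + small noise).

    With nonnegative inputs the composition of per-layer partial identity
    matrices passes the signal through every ReLU unchanged, so the
    network starts as x -> x exactly up to the injected noise.
    """
    for i, w in enumerate(net.weights):
        fan_in, fan_out = w.shape
        eye = np.zeros_like(w)
        d = min(fan_in, fan_out)
        eye[np.arange(d), np.arange(d)] = 1.0
        net.weights[i] = eye + rng.normal(0.0, noise_scale, size=w.shape)
        net.biases[i] = np.zeros(fan_out)


def train_translator(x_pool: ExpressionMatrix, y_pool: ExpressionMatrix,
                     config: CycleGANConfig | None = None) -> TranslatorModel:
    """Train the CycleGAN on unpaired landmark-space pools.

    Each mini-batch performs one discriminator update (both ``D_X`` and
    ``D_Y``) followed by one joint generator update (``G`` and ``F``
    against frozen discriminators). Epochs iterate over the larger pool;
    batches from the smaller pool are resampled. Fully deterministic for
    a fixed seed and platform.
    """
    config = config or CycleGANConfig()
    if list(x_pool.gene_ids) != list(y_pool.gene_ids):
        raise ValueError("x_pool and y_pool must share gene_ids in the same order")
    n_genes = x_pool.n_genes
    rng = np.random.default_rng(config.seed)
    G, F, D_X, D_Y = _build_networks(n_genes, config, rng)

    x_data = x_pool.values.T  # samples x genes
    y_data = y_pool.values.T
    opt_g = Adam([G, F], lr=config.learning_rate)
    opt_d = Adam([D_X, D_Y], lr=config.learning_rate)

    lam_c, lam_i = config.lambda_cyc, config.lambda_identity
    records = []
    n_major = max(len(x_data), len(y_data))
    n_batches = max(1, n_major // config.batch_size)

    for epoch in range(config.epochs):
        x_order = rng.permutation(len(x_data))
        y_order = rng.permutation(len(y_data))
        ep = {"gan_G": 0.0, "gan_F": 0.0, "cyc": 0.0, "ident": 0.0, "d_loss": 0.0}
        for b in range(n_batches):
            xb = x_data[_batch_idx(x_order, b, config.batch_size, rng)]
            yb = y_data[_batch_idx(y_order, b, config.batch_size, rng)]
            stats = _train_step(xb, yb, G, F, D_X, D_Y, opt_g, opt_d, lam_c, lam_i)
            for k in ep:
                ep[k] += stats[k]
        for k in ep:
            ep[k] /= n_batches
        g_loss = total_objective(ep["gan_G"], ep["gan_F"], ep["cyc"], ep["ident"], config)
        records.append({"epoch": epoch, "g_loss": g_loss, "d_loss": ep["d_loss"],
                        "cyc_loss": ep["cyc"], "id_loss": ep["ident"],
                        "gan_G": ep["gan_G"], "gan_F": ep["gan_F"]})
        if epoch % 10 == 0 or epoch == config.epochs - 1:
            logger.info("epoch %d: g_loss=%.4f d_loss=%.4f cyc=%.4f id=%.4f",
                        epoch, g_loss, ep["d_loss"], ep["cyc"], ep["ident"])

    history = pd.DataFrame(records, columns=["epoch", "g_loss", "d_loss",
                                             "cyc_loss", "id_loss", "gan_G", "gan_F"])
    return TranslatorModel(G=G, F=F, D_X=D_X, D_Y=D_Y,
                           gene_ids=list(x_pool.gene_ids),
                           config=config, history=history)


def _batch_idx(order: np.ndarray, b: int, size: int,
               rng: np.random.Generator) -> np.ndarray:
    start = b * size
    if start + size <= len(order):
        return order[start : start + size]
    # smaller pool exhausted: resample uniformly
    return rng.integers(0, len(order), size=size)


def _train_step(xb, yb, G, F, D_X, D_Y, opt_g: Adam, opt_d: Adam,
                lam_c: float, lam_i: float) -> dict:
    n = len(xb)
    d_in = xb.shape[1]
    elems = n * d_in

    # ---- discriminator update (generators frozen) ----
    fake_y = G.predict(xb)
    fake_x = F.predict(yb)
    for net in (D_X, D_Y):
        net.zero_grad()
    ry, c_ry = D_Y.forward(yb)
    fy, c_fy = D_Y.forward(fake_y)
    rx, c_rx = D_X.forward(xb)
    fx, c_fx = D_X.forward(fake_x)
    d_loss_y, _ = adversarial_loss(ry, fy)
    d_loss_x, _ = adversarial_loss(rx, fx)
    D_Y.backward(c_ry, 2.0 * (ry - 1.0) / n)
    D_Y.backward(c_fy, 2.0 * fy / n)
    D_X.backward(c_rx, 2.0 * (rx - 1.0) / n)
    D_X.backward(c_fx, 2.0 * fx / n)
    opt_d.step()

    # ---- joint generator update (discriminators frozen) ----
    for net in (G, F, D_X, D_Y):
        net.zero_grad()
    gy, c_g1 = G.forward(xb)            # G(x)
    dy, c_dy = D_Y.forward(gy)
    x_rec, c_f1 = F.forward(gy)         # F(G(x))
    fx_out, c_f2 = F.forward(yb)        # F(y)
    dx, c_dx = D_X.forward(fx_out)
    y_rec, c_g2 = G.forward(fx_out)     # G(F(y))
    id_x, c_f3 = F.forward(xb)          # F(x)
    id_y, c_g3 = G.forward(yb)          # G(y)

    gan_G = float(np.mean((1.0 - dy) ** 2))
    gan_F = float(np.mean((1.0 - dx) ** 2))
    cyc = float(np.mean((x_rec - xb) ** 2) + np.mean((y_rec - yb) ** 2))
    ident = float(np.mean((id_x - xb) ** 2) + np.mean((id_y - yb) ** 2))

    g_fy_adv = D_Y.backward(c_dy, -2.0 * (1.0 - dy) / n)
    g_fy_cyc = F.backward(c_f1, lam_c * 2.0 * (x_rec - xb) / elems)
    G.backward(c_g1, g_fy_adv + g_fy_cyc)

    g_fx_adv = D_X.backward(c_dx, -2.0 * (1.0 - dx) / n)
    g_fx_cyc = G.backward(c_g2, lam_c * 2.0 * (y_rec - yb) / elems)
    F.backward(c_f2, g_fx_adv + g_fx_cyc)

    F.backward(c_f3, lam_i * 2.0 * (id_x - xb) / elems)
    G.backward(c_g3, lam_i * 2.0 * (id_y - yb) / elems)

    # discriminators accumulated pass-through gradients; drop them
    D_X.zero_grad()
    D_Y.zero_grad()
    opt_g.step()

    return {"gan_G": gan_G, "gan_F": gan_F, "cyc": cyc, "ident": ident,
            "d_loss": d_loss_x + d_loss_y}


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def translate(model: TranslatorModel, x: ExpressionMatrix) -> ExpressionMatrix:
    """Apply ``G`` to landmark profiles; deterministic, output >= 0.

    ``x`` must contain every gene the model was trained on; extra genes are
    dropped with a warning.
    """
    model_genes = set(model.gene_ids)
    present = [g for g in x.gene_ids if g in model_genes]
    if not present:
        raise ValueError("no overlap between input genes and model genes")
    missing = [g for g in model.gene_ids if g not in set(x.gene_ids)]
    if missing:
        raise ValueError(f"input is missing model genes: {missing[:10]}")
    if len(present) != x.n_genes:
        logger.warning("dropping %d input genes unknown to the model",
                       x.n_genes - len(present))
    x_ord = x.subset_genes(list(model.gene_ids))
    out = model.G.predict(x_ord.values.T).T
    return ExpressionMatrix(values=out, gene_ids=list(model.gene_ids),
                            sample_ids=list(x.sample_ids),
                            space=x.space, scale="log2")


def translate_back(model: TranslatorModel, y: ExpressionMatrix) -> ExpressionMatrix:
    """Apply ``F`` (RNA-seq-like → L1000-like); the reverse direction."""
    y_ord = y.subset_genes(list(model.gene_ids))
    out = model.F.predict(y_ord.values.T).T
    return ExpressionMatrix(values=out, gene_ids=list(model.gene_ids),
                            sample_ids=list(y.sample_ids),
                            space=y.space, scale="log2")


# ---------------------------------------------------------------------------
# persistence: JSON manifest + hex-float text arrays + history TSV
# ---------------------------------------------------------------------------

def save_translator(model: TranslatorModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = model.config
    manifest = {
        "gene_ids": model.gene_ids,
        "config": {
            "hidden_units": cfg.hidden_units, "learning_rate": cfg.learning_rate,
            "lambda_cyc": cfg.lambda_cyc, "lambda_identity": cfg.lambda_identity,
            "epochs": cfg.epochs, "batch_size": cfg.batch_size,
            "n_hidden_layers": cfg.n_hidden_layers, "seed": cfg.seed,
        },
    }
    (directory / "translator.json").write_text(json.dumps(manifest, indent=1))
    for name, net in (("G", model.G), ("F", model.F),
                      ("D_X", model.D_X), ("D_Y", model.D_Y)):
        save_mlp(net, directory, name)
    model.history.to_csv(directory / "history.tsv", sep="\t", index=False)


def load_translator(directory: str | Path) -> TranslatorModel:
    directory = Path(directory)
    manifest = json.loads((directory / "translator.json").read_text())
    config = CycleGANConfig(**manifest["config"])
    nets = {name: load_mlp(directory, name) for name in ("G", "F", "D_X", "D_Y")}
    history = pd.read_csv(directory / "history.tsv", sep="\t", float_precision="round_trip")
    return TranslatorModel(G=nets["G"], F=nets["F"], D_X=nets["D_X"],
                           D_Y=nets["D_Y"], gene_ids=manifest["gene_ids"],
                           config=config, history=history)
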