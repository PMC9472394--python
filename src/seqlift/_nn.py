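"""Minimal feed-forward neural-network engine on numpy.

Implements exactly what the translator and extrapolator need: fully
connected layers, ReLU activations (optionally on the output layer),
reverse-mode gradients via cached forward passes, and the Adam update.
Networks here are tiny (hundreds of units), so explicit matrix backprop
on the CPU is fast and — given a seeded initializer and a fixed batch
order — bit-reproducible.

Gradients accumulate across multiple forward/backward calls (a generator
appears in several loss terms per step), and are cleared explicitly with
``zero_grad``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


class MLP:
    """Fully connected network with ReLU hidden activations.

    Parameters
    ----------
    layer_units
        Unit counts including input and output, e.g. ``[50, 128, 128, 50]``
        is a two-hidden-layer network.
    relu_output
        Apply ReLU to the final layer (used by the generators and the
        extrapolator to keep expression predictions nonnegative).
    rng
        Seeded generator for He-scaled initialization.
    """

    def __init__(self, layer_units: list[int], relu_output: bool,
                 rng: np.random.Generator):
        if len(layer_units) < 2 or any(u < 1 for u in layer_units):
            raise ValueError("layer_units must list >= 2 positive unit counts")
        self.layer_units = list(layer_units)
        self.relu_output = bool(relu_output)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(layer_units[:-1], layer_units[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))
        self.grad_w = [np.zeros_like(w) for w in self.weights]
        self.grad_b = [np.zeros_like(b) for b in self.biases]

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list]:
        """Run a batch ``(n, d_in)`` forward; returns output and a cache.

        The cache carries the layer inputs and pre-activations needed for a
        later :meth:`backward` call; separate forward calls get independent
        caches, so one network may appear in several loss terms per step.
        """
        x = np.asarray(x, dtype=np.float64)
        cache = []
        h = x
        last = self.n_layers - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            apply_relu = i < last or self.relu_output
            out = np.maximum(z, 0.0) if apply_relu else z
            cache.append((h, z, apply_relu))
            h = out
        return h, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]

    def backward(self, cache: list, grad_out: np.ndarray) -> np.ndarray:
        """Backpropagate ``dL/d_out`` through a cached forward pass.

        Accumulates parameter gradients in ``grad_w`` / ``grad_b`` and
        returns ``dL/d_in``.
        """
        g = np.asarray(grad_out, dtype=np.float64)
        for i in range(self.n_layers - 1, -1, -1):
            h, z, applied_relu = cache[i]
            if applied_relu:
                g = g * (z > 0.0)
            self.grad_w[i] += h.T @ g
            self.grad_b[i] += g.sum(axis=0)
            g = g @ self.weights[i].T
        return g

    def zero_grad(self) -> None:
        for gw in self.grad_w:
            gw.fill(0.0)
        for gb in self.grad_b:
            gb.fill(0.0)

    # -- (de)serialization ---------------------------------------------------

    def get_state(self) -> dict:
        return {
            "layer_units": self.layer_units,
            "relu_output": self.relu_output,
            "weights": [w.copy() for w in self.weights],
            "biases": [b.copy() for b in self.biases],
        }

    def set_state(self, state: dict) -> None:
        self.weights = [np.asarray(w, dtype=np.float64).copy() for w in state["weights"]]
        self.biases = [np.asarray(b, dtype=np.float64).copy() for b in state["biases"]]
        self.grad_w = [np.zeros_like(w) for w in self.weights]
        self.grad_b = [np.zeros_like(b) for b in self.biases]


class Adam:
    """Adam optimizer over one or more MLPs (decoupled per-parameter state)."""

    def __init__(self, nets: list[MLP], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.nets = nets
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in net.weights + net.biases] for net in nets]
        self.v = [[np.zeros_like(p) for p in net.weights + net.biases] for net in nets]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, net in enumerate(self.nets):
            params = net.weights + net.biases
            grads = net.grad_w + net.grad_b
            for i, (p, g) in enumerate(zip(params, grads)):
                m = self.m[k][i]
                v = self.v[k][i]
                m *= self.beta1
                m += (1.0 - self.beta1) * g
                v *= self.beta2
                v += (1.0 - self.beta2) * g * g
                p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# portable weight container: JSON manifest + one text array file per matrix
# ---------------------------------------------------------------------------

def save_mlp(net: MLP, directory: str | Path, name: str) -> None:
    """Save one network under ``directory`` as text files (round-trips bit-exactly)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "layer_units": net.layer_units,
        "relu_output": net.relu_output,
        "n_layers": net.n_layers,
    }
    (directory / f"{name}.json").write_text(json.dumps(manifest, indent=1))
    for i, (w, b) in enumerate(zip(net.weights, net.biases)):
        _save_array(w, directory / f"{name}_w{i}.tsv")
        _save_array(b.reshape(1, -1), directory / f"{name}_b{i}.tsv")


def load_mlp(directory: str | Path, name: str) -> MLP:
    directory = Path(directory)
    manifest = json.loads((directory / f"{name}.json").read_text())
    net = MLP(manifest["layer_units"], manifest["relu_output"],
              rng=np.random.default_rng(0))
    weights, biases = [], []
    for i in range(manifest["n_layers"]):
        weights.append(_load_array(directory / f"{name}_w{i}.tsv"))
        biases.append(_load_array(directory / f"{name}_b{i}.tsv").ravel())
    net.set_state({"weights": weights, "biases": biases})
    return net


def _save_array(a: np.ndarray, path: Path) -> None:
    with path.open("w") as fh:
        for row in np.atleast_2d(a):
            fh.write("\t".join(float(v).hex() for v in row) + "\n")


def _load_array(path: Path) -> np.ndarray:
    rows = []
    with path.open("r") as fh:
        for line in fh:
            rows.append([float.fromhex(v) for v in line.split()])
    return np.asarray(rows, dtype=np.float64)
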