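"""Parameter containers, layers and the Adam optimizer.

Parameters live in flat ``dict[str, Tensor]`` namespaces so that the
encoder, projection head and feed-forward classifier can share one
optimizer and one checkpoint format.
"""

from __future__ import annotations

import json

import numpy as np

from .tensor import Tensor, concat, relu

__all__ = ["glorot", "linear_params", "linear", "mlp_params", "mlp",
           "dropout_mask", "Adam", "save_params", "load_params"]

CHECKPOINT_SCHEMA_VERSION = 1


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization."""
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


def linear_params(rng: np.random.Generator, d_in: int, d_out: int,
                  prefix: str) -> dict[str, Tensor]:
    return {
        f"{prefix}.W": Tensor(glorot(rng, d_in, d_out), requires_grad=True),
        f"{prefix}.b": Tensor(np.zeros(d_out), requires_grad=True),
    }


def linear(params: dict[str, Tensor], prefix: str, x: Tensor) -> Tensor:
    return x @ params[f"{prefix}.W"] + params[f"{prefix}.b"]


def mlp_params(rng: np.random.Generator, dims: list[int],
               prefix: str) -> dict[str, Tensor]:
    """Parameters for a rectifier MLP with layer widths ``dims``."""
    params: dict[str, Tensor] = {}
    for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
        params.update(linear_params(rng, a, b, f"{prefix}.{i}"))
    return params


def mlp(params: dict[str, Tensor], prefix: str, x: Tensor, n_layers: int,
        dropout: float = 0.0,
        rng: np.random.Generator | None = None) -> Tensor:
    """Apply an MLP: ReLU between layers, no nonlinearity on the output."""
    for i in range(n_layers):
        x = linear(params, f"{prefix}.{i}", x)
        if i < n_layers - 1:
            x = relu(x)
            if dropout > 0.0 and rng is not None:
                x = x * dropout_mask(rng, x.shape, dropout)
    return x


def dropout_mask(rng: np.random.Generator, shape: tuple[int, ...],
                 p: float) -> Tensor:
    """Inverted-dropout mask (scaled by 1/(1-p)); constant w.r.t. the tape."""
    keep = (rng.random(shape) >= p).astype(np.float64) / (1.0 - p)
    return Tensor(keep)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def save_params(path, params: dict[str, Tensor],
                meta: dict | None = None) -> None:
    """Persist a parameter dict as ``.npz`` with a JSON metadata record."""
    arrays = {k: v.data for k, v in params.items()}
    header = json.dumps({"schema_version": CHECKPOINT_SCHEMA_VERSION,
                         "meta": meta or {}})
    np.savez(path, __meta__=np.frombuffer(header.encode(), dtype=np.uint8),
             **arrays)


def load_params(path) -> tuple[dict[str, Tensor], dict]:
    """Load a checkpoint written by :func:`save_params`."""
    with np.load(path) as npz:
        header = json.loads(npz["__meta__"].tobytes().decode())
        if header.get("schema_version") != CHECKPOINT_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported checkpoint schema: {header.get('schema_version')}")
        params = {k: Tensor(npz[k], requires_grad=True)
                  for k in npz.files if k != "__meta__"}
    return params, header["meta"]
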