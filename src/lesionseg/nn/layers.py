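"""Parameterised layers built on the autograd tape.

Initialisation follows common ReLU-network practice: He-uniform for
convolutional/dense weights, zeros for biases, uniform(-0.05, 0.05) for
embedding tables.  Every layer draws from a caller-supplied Generator so
model construction is fully seeded.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: anything with trainable tensors, discoverable recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            params.extend(_collect(value))
        return params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state length mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state shape mismatch")
            p.data = a.copy()


def _collect(value) -> list[Tensor]:
    if isinstance(value, Tensor):
        return [value] if value.requires_grad else []
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    return []


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Conv2d(Module):
    """Stride-1 k×k convolution with 'same' zero padding by default."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.k = k
        self.pad = (k - 1) // 2 if pad is None else pad
        fan_in = c_in * k * k
        self.w = Tensor(_he_uniform(rng, (c_out, c_in, k, k), fan_in), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.w, self.b, pad=self.pad)


class ConvTranspose2d(Module):
    """2×2 stride-2 transposed convolution (spatial doubling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * 4
        self.w = Tensor(_he_uniform(rng, (c_in, c_out, 2, 2), fan_in), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d(x, self.w, self.b)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.w = Tensor(_he_uniform(rng, (n_in, n_out), n_in), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.matmul(x, self.w) + self.b


class Embedding(Module):
    """Per-group categorical embedding table."""

    def __init__(self, vocab: int, dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.table = Tensor(rng.uniform(-0.05, 0.05, size=(vocab, dim)), requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return ag.embedding(self.table, indices)
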