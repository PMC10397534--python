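"""Neural-network layers and the Adam optimiser on top of :mod:`combosyn.autodiff`.

Initialisation draws from a :class:`numpy.random.Generator` passed in by the
caller, so a model built twice from the same seed has identical weights.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, concat, take_rows


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class with recursive parameter discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> Iterator[Parameter]:
        seen: set[int] = set()
        for value in self.__dict__.values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Parameter) and id(item) not in seen:
                    seen.add(id(item))
                    yield item
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            yield p

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for value in self.__dict__.values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Module):
                    item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = list(self.parameters())
        if len(params) != len(state):
            raise ValueError("parameter count mismatch")
        for p, arr in zip(params, state):
            p.data = np.array(arr, dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (d_in + d_out))  # Glorot uniform
        self.weight = Parameter(rng.uniform(-bound, bound, size=(d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.02, size=(num_embeddings, dim)))

    def forward(self, indices: np.ndarray) -> Tensor:
        return take_rows(self.weight, indices)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; the rng is stored so training runs are replayable."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * mask


class MLP(Module):
    """Stack of Linear layers with ReLU between them (none after the last)."""

    def __init__(self, dims: list[int], rng: np.random.Generator, dropout: Dropout | None = None):
        super().__init__()
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.dropout = dropout

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
                if self.dropout is not None:
                    x = self.dropout(x)
        return x


class MultiheadAttention(Module):
    """Scaled dot-product attention over (B, S, d_model) inputs.

    ``key_padding_mask`` is a boolean (B, S) array, True at padded positions;
    masked keys receive zero attention weight.
    """

    def __init__(self, d_model: int, num_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % num_heads != 0:
            raise ValueError("d_model must be divisible by num_heads")
        self.d_model = d_model
        self.num_heads = num_heads
        self.d_head = d_model // num_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.last_attention: np.ndarray | None = None

    def _split(self, x: Tensor, B: int, S: int) -> Tensor:
        # (B, S, d_model) -> (B, H, S, d_head)
        return x.reshape(B, S, self.num_heads, self.d_head).transpose(0, 2, 1, 3)

    def forward(self, x: Tensor, key_padding_mask: np.ndarray | None = None) -> Tensor:
        B, S, _ = x.shape
        q = self._split(self.wq(x), B, S)
        k = self._split(self.wk(x), B, S)
        v = self._split(self.wv(x), B, S)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        if key_padding_mask is not None:
            mask = key_padding_mask[:, None, None, :]  # broadcast over heads/queries
            scores = scores.masked_fill(np.broadcast_to(mask, scores.shape), -1e30)
        attn = scores.softmax(axis=-1)
        self.last_attention = attn.data
        out = attn @ v  # (B, H, S, d_head)
        out = out.transpose(0, 2, 1, 3).reshape(B, S, self.d_model)
        return self.wo(out)


class Adam:
    """Adam with bias correction; operates on a fixed parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
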