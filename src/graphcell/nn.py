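"""Neural-network building blocks on the numpy autodiff engine.

Layers follow standard transformer conventions: BERT-style N(0, 0.02)
initialization for embeddings and projections, pre-norm residual blocks,
GELU activations. Initialization draws from an explicit numpy Generator so
every model build is seed-reproducible.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, concat, embedding

INIT_STD = 0.02


class Module:
    """Container with recursive parameter discovery."""

    def parameters(self):
        params = []
        seen = set()
        stack = [self]
        while stack:
            obj = stack.pop()
            for value in vars(obj).values():
                if isinstance(value, Tensor) and value.requires_grad:
                    if id(value) not in seen:
                        seen.add(id(value))
                        params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    for item in value:
                        if isinstance(item, Module):
                            stack.append(item)
                        elif isinstance(item, Tensor) and item.requires_grad:
                            if id(item) not in seen:
                                seen.add(id(item))
                                params.append(item)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        """Named parameter arrays, keyed by attribute path."""
        out = {}

        def walk(obj, prefix):
            for name, value in vars(obj).items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor) and value.requires_grad:
                    out[key] = value.data.copy()
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                        elif isinstance(item, Tensor) and item.requires_grad:
                            out[f"{key}.{i}"] = item.data.copy()

        walk(self, "")
        return out

    def load_state_dict(self, state: dict):
        def walk(obj, prefix):
            for name, value in vars(obj).items():
                key = f"{prefix}{name}"
                if isinstance(value, Tensor) and value.requires_grad:
                    value.data = np.asarray(state[key], dtype=np.float64).copy()
                elif isinstance(value, Module):
                    walk(value, key + ".")
                elif isinstance(value, (list, tuple)):
                    for i, item in enumerate(value):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                        elif isinstance(item, Tensor) and item.requires_grad:
                            item.data = np.asarray(state[f"{key}.{i}"], dtype=np.float64).copy()

        walk(self, "")


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = parameter(rng.normal(0.0, INIT_STD, size=(d_in, d_out)))
        self.bias = parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, n_rows: int, d: int, rng: np.random.Generator,
                 std: float = INIT_STD):
        self.weight = parameter(rng.normal(0.0, std, size=(n_rows, d)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding(self.weight, idx)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = parameter(np.ones(d))
        self.beta = parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class MLP(Module):
    """Two-layer GELU feed-forward."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shift by a detached max: softmax is shift-invariant, so gradients are exact
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e * (e.sum(axis=axis, keepdims=True) ** -1.0)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def dropout(x: Tensor, p: float, rng: np.random.Generator | None, training: bool) -> Tensor:
    if not training or p <= 0.0 or rng is None:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


class MultiHeadSelfAttention(Module):
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d // n_heads
        self.qkv = Linear(d, 3 * d, rng)
        self.proj = Linear(d, d, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray) -> Tensor:
        """x: (B, L, d); pad_mask: (B, L) boolean, True on real slots."""
        B, L, d = x.shape
        h, dh = self.n_heads, self.d_head
        qkv = self.qkv(x)  # (B, L, 3d)
        qkv = qkv.reshape(B, L, 3, h, dh).transpose(2, 0, 3, 1, 4)  # (3, B, h, L, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (dh ** -0.5)  # (B, h, L, L)
        bias = np.where(pad_mask[:, None, None, :], 0.0, -1e9)  # mask pad keys
        attn = softmax(scores + Tensor(bias), axis=-1)
        out = attn @ v  # (B, h, L, dh)
        out = out.transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.proj(out)


class TransformerBlock(Module):
    """Pre-norm encoder block without positional encoding (order-free)."""

    def __init__(self, d: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(d, n_heads, rng)
        self.ln2 = LayerNorm(d)
        self.mlp = MLP(d, d_ff, d, rng)

    def __call__(self, x: Tensor, pad_mask: np.ndarray,
                 p_drop: float = 0.0, rng=None, training: bool = False) -> Tensor:
        x = x + dropout(self.attn(self.ln1(x), pad_mask), p_drop, rng, training)
        x = x + dropout(self.mlp(self.ln2(x)), p_drop, rng, training)
        return x


class Adam:
    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, warmup_steps: int = 0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.warmup_steps = warmup_steps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self) -> float:
        if self.warmup_steps and self.t < self.warmup_steps:
            return self.lr * (self.t + 1) / self.warmup_steps
        return self.lr

    def step(self):
        lr = self.current_lr()
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
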