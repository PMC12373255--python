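"""Neural-network building blocks on top of the autograd engine.

Initialisation draws from a caller-supplied ``numpy.random.Generator`` so
that model construction is fully reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module", "Linear", "Embedding", "LayerNorm", "MultiHeadSelfAttention",
    "TransformerBlock", "Dropout", "Conv1d", "BatchNorm1d",
]


class Module:
    """Minimal module base: parameter collection and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            out.extend(_collect(v))
        return out

    def _submodules(self):
        for v in self.__dict__.values():
            yield from _collect_modules(v)

    def train(self):
        self.training = True
        for m in self._submodules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self._submodules():
            m.training = False
        return self

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model expects {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64)


def _collect(v):
    if isinstance(v, Tensor) and v.requires_grad:
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for x in v:
            out.extend(_collect(x))
        return out
    return []


def _collect_modules(v):
    if isinstance(v, Module):
        yield v
        yield from v._submodules()
    elif isinstance(v, (list, tuple)):
        for x in v:
            yield from _collect_modules(x)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.W = Tensor(rng.uniform(-bound, bound, size=(d_in, d_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Embedding(Module):
    def __init__(self, n: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Tensor(rng.normal(0.0, 0.02, size=(n, dim)),
                             requires_grad=True)

    def __call__(self, idx) -> Tensor:
        return self.weight.take(np.asarray(idx, dtype=np.intp), axis=0)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; a no-op in eval mode or at rate 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = float(rate)
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate <= 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.binomial(1, keep, size=x.shape) / keep
        return x * Tensor(mask)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - x.max_detached(axis=axis, keepdims=True)
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadSelfAttention(Module):
    def __init__(self, width: int, heads: int, rng: np.random.Generator):
        super().__init__()
        if width % heads:
            raise ValueError("width must be divisible by heads")
        self.h = heads
        self.dk = width // heads
        self.wq = Linear(width, width, rng)
        self.wk = Linear(width, width, rng)
        self.wv = Linear(width, width, rng)
        self.wo = Linear(width, width, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (batch, tokens, width)
        b, t, w = x.shape
        def split(z):  # -> (batch, heads, tokens, dk)
            return z.reshape(b, t, self.h, self.dk).transpose(0, 2, 1, 3)
        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        att = softmax((q @ k.transpose(0, 1, 3, 2)) * (self.dk ** -0.5), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, t, w)
        return self.wo(out)


class TransformerBlock(Module):
    """Pre-LayerNorm transformer block with a 2x-width feed-forward."""

    def __init__(self, width: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(width)
        self.att = MultiHeadSelfAttention(width, heads, rng)
        self.ln2 = LayerNorm(width)
        self.ff1 = Linear(width, 2 * width, rng)
        self.ff2 = Linear(2 * width, width, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.att(self.ln1(x))
        return x + self.ff2(self.ff1(self.ln2(x)).relu())


class Conv1d(Module):
    """1-D convolution via gather + matmul (stride/padding, no dilation)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.padding = kernel // 2 if padding is None else padding
        bound = np.sqrt(6.0 / (c_in * kernel + c_out))
        self.W = Tensor(rng.uniform(-bound, bound, size=(c_in * kernel, c_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (batch, length, c_in) -> (batch, out_length, c_out)
        b, n, c = x.shape
        p = self.padding
        if p:
            pad = Tensor(np.zeros((b, p, c)))
            x = concat([pad, x, pad], axis=1)
            n = n + 2 * p
        starts = np.arange(0, n - self.kernel + 1, self.stride)
        # gather k shifted views and stack along a new patch axis
        cols = [x.take(starts + j, axis=1) for j in range(self.kernel)]
        patches = concat(cols, axis=2)  # (b, out_len, kernel*c) in j-major order
        # reorder weight rows to match (j, c) layout of `patches`
        return patches @ self._w_jmajor() + self.b

    def _w_jmajor(self) -> Tensor:
        # stored as (c_in*kernel, c_out) with c-major rows; permute to j-major
        c_in = self.W.shape[0] // self.kernel
        perm = np.arange(self.W.shape[0]).reshape(c_in, self.kernel).T.reshape(-1)
        return self.W.take(perm, axis=0)


class BatchNorm1d(Module):
    """Batch normalisation over (batch, length) for channel-last tensors."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 1), keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(1, 1, -1))
            var = Tensor(self.running_var.reshape(1, 1, -1))
            xc = x - mu
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta
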