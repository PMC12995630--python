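"""Minimal numpy neural-network core.

Layers implement explicit ``forward``/``backward`` passes with cached
activations; every trainable array is a :class:`Parameter` so optimizers and
parameter counting can treat the model as a flat list. All convolutions are
stride-1 with "same" zero padding, and support dilation — the dilated kernel is
never materialized, taps are applied as shifted slices of the padded input.

Shapes follow the channels-first convention: ``(N, C, L)`` for 1-D,
``(N, C, H, W)`` for 2-D and ``(N, C, B, H, W)`` for 3-D signals.
"""

from __future__ import annotations

import itertools

import numpy as np

#: float dtype for parameters and activations. float32 keeps the memory
#: traffic of the conv branches manageable; switch to float64 for
#: finite-difference gradient checking.
DTYPE = np.float32


def set_dtype(dtype) -> None:
    global DTYPE
    DTYPE = np.dtype(dtype)

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "ConvNd",
    "DepthwiseConv2d",
    "BatchNorm",
    "LayerNorm",
    "ReLU",
    "Dropout",
    "MultiHeadSelfAttention",
    "softmax",
    "cross_entropy",
    "Adam",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Parameter({self.name!r}, shape={self.data.shape})"


class Module:
    """Base class: tracks parameters and sub-modules for recursive traversal."""

    def __init__(self) -> None:
        self._params: list[Parameter] = []
        self._children: list[Module] = []

    def add_param(self, data: np.ndarray, name: str = "") -> Parameter:
        p = Parameter(data, name)
        self._params.append(p)
        return p

    def add_child(self, module: "Module") -> "Module":
        self._children.append(module)
        return module

    def parameters(self) -> list[Parameter]:
        out = list(self._params)
        for child in self._children:
            out.extend(child.parameters())
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        """Snapshot of all parameter arrays (used for checkpointing)."""
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError("state length mismatch")
        for p, arr in zip(params, state):
            p.data[...] = arr


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    """Affine map on the trailing axis: ``y = x @ W + b``."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 bias: bool = True, name: str = "linear") -> None:
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        scale = 1.0 / np.sqrt(in_dim)
        self.W = self.add_param(rng.uniform(-scale, scale, size=(in_dim, out_dim)),
                                f"{name}.W")
        self.b = self.add_param(np.zeros(out_dim), f"{name}.b") if bias else None
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        y = x @ self.W.data
        if self.b is not None:
            y = y + self.b.data
        return y

    def backward(self, g: np.ndarray) -> np.ndarray:
        x = self._x
        x2 = x.reshape(-1, self.in_dim)
        g2 = g.reshape(-1, self.out_dim)
        self.W.grad += x2.T @ g2
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        return g @ self.W.data.T


class ConvNd(Module):
    """Stride-1 "same"-padded dilated convolution over 1, 2 or 3 spatial axes.

    Weight shape is ``(C_out, C_in, k, ..., k)``. Dilation inserts ``d - 1``
    zeros between kernel taps; the effective kernel extent per axis is
    ``(k - 1) * d + 1`` and padding splits it as evenly as possible, so the
    output spatial shape equals the input's.
    """

    def __init__(self, ndim: int, c_in: int, c_out: int, kernel: int,
                 dilation: int, rng: np.random.Generator, bias: bool = True,
                 name: str = "conv") -> None:
        super().__init__()
        if ndim not in (1, 2, 3):
            raise ValueError("ndim must be 1, 2 or 3")
        if kernel < 1 or dilation < 1:
            raise ValueError("kernel and dilation must be >= 1")
        self.ndim, self.c_in, self.c_out = ndim, c_in, c_out
        self.kernel, self.dilation = kernel, dilation
        fan_in = c_in * kernel ** ndim
        self.W = self.add_param(
            _he_init(rng, (c_out, c_in) + (kernel,) * ndim, fan_in), f"{name}.W")
        self.b = self.add_param(np.zeros(c_out), f"{name}.b") if bias else None
        self._cols: np.ndarray | None = None
        self._spatial: tuple[int, ...] = ()

    @property
    def effective_kernel(self) -> int:
        return (self.kernel - 1) * self.dilation + 1

    def _pads(self) -> tuple[int, int]:
        total = self.effective_kernel - 1
        left = total // 2
        return left, total - left

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != self.ndim + 2 or x.shape[1] != self.c_in:
            raise ValueError(
                f"expected (N, {self.c_in}, {'x'.join('S' * self.ndim)}) input, got {x.shape}")
        left, right = self._pads()
        pad = [(0, 0), (0, 0)] + [(left, right)] * self.ndim
        xp = np.pad(x, pad)
        spatial = x.shape[2:]
        self._spatial = spatial
        n = x.shape[0]
        size = int(np.prod(spatial))
        d, k = self.dilation, self.kernel
        n_taps = k ** self.ndim
        # im2col: one gather pass, then a single matmul against the flat kernel
        cols = np.empty((n, self.c_in, n_taps, size), dtype=xp.dtype)
        for t_idx, taps in enumerate(itertools.product(range(k), repeat=self.ndim)):
            sl = (slice(None), slice(None)) + tuple(
                slice(t * d, t * d + s) for t, s in zip(taps, spatial))
            cols[:, :, t_idx, :] = xp[sl].reshape(n, self.c_in, size)
        cols = cols.reshape(n, self.c_in * n_taps, size)
        self._cols = cols
        out = self.W.data.reshape(self.c_out, -1) @ cols
        if self.b is not None:
            out += self.b.data[None, :, None]
        return out.reshape((n, self.c_out) + spatial)

    def backward(self, g: np.ndarray) -> np.ndarray:
        cols = self._cols
        spatial = self._spatial
        n = g.shape[0]
        size = int(np.prod(spatial))
        g2 = g.reshape(n, self.c_out, size)
        self.W.grad += np.tensordot(g2, cols, axes=([0, 2], [0, 2])).reshape(
            self.W.data.shape)
        if self.b is not None:
            self.b.grad += g2.sum(axis=(0, 2))
        gcols = (self.W.data.reshape(self.c_out, -1).T @ g2).reshape(
            n, self.c_in, -1, size)
        left, right = self._pads()
        gxp = np.zeros((n, self.c_in) + tuple(s + left + right for s in spatial),
                       dtype=g.dtype)
        d, k = self.dilation, self.kernel
        for t_idx, taps in enumerate(itertools.product(range(k), repeat=self.ndim)):
            sl = (slice(None), slice(None)) + tuple(
                slice(t * d, t * d + s) for t, s in zip(taps, spatial))
            gxp[sl] += gcols[:, :, t_idx, :].reshape((n, self.c_in) + spatial)
        crop = (slice(None), slice(None)) + tuple(
            slice(left, left + s) for s in spatial)
        return gxp[crop]


class DepthwiseConv2d(Module):
    """Per-channel 2-D convolution (grouped conv with groups = channels)."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True, name: str = "dwconv") -> None:
        super().__init__()
        self.channels, self.kernel = channels, kernel
        self.W = self.add_param(_he_init(rng, (channels, kernel, kernel), kernel ** 2),
                                f"{name}.W")
        self.b = self.add_param(np.zeros(channels), f"{name}.b") if bias else None
        # LIFO cache: the layer may run several times per pass (one call per
        # spatial segment); backward must pop in reverse call order
        self._stack: list[tuple[np.ndarray, tuple[int, int]]] = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.kernel
        left = (k - 1) // 2
        right = k - 1 - left
        xp = np.pad(x, [(0, 0), (0, 0), (left, right), (left, right)])
        h, w = x.shape[2:]
        self._stack.append((xp, (h, w)))
        out = np.zeros_like(x)
        for i in range(k):
            for j in range(k):
                out += xp[:, :, i:i + h, j:j + w] * self.W.data[None, :, i, j, None, None]
        if self.b is not None:
            out += self.b.data[None, :, None, None]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp, (h, w) = self._stack.pop()
        k = self.kernel
        gxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                xs = xp[:, :, i:i + h, j:j + w]
                self.W.grad[:, i, j] += np.einsum("nchw,nchw->c", g, xs)
                gxp[:, :, i:i + h, j:j + w] += g * self.W.data[None, :, i, j, None, None]
        if self.b is not None:
            self.b.grad += g.sum(axis=(0, 2, 3))
        left = (k - 1) // 2
        return gxp[:, :, left:left + h, left:left + w]


class BatchNorm(Module):
    """Batch normalization over all axes except channel (axis 1)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        super().__init__()
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.gamma = self.add_param(np.ones(channels), f"{name}.gamma")
        self.beta = self.add_param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None

    def _bshape(self, ndim: int) -> tuple[int, ...]:
        return (1, self.channels) + (1,) * (ndim - 2)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x.ndim)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, axes, shape, train, x.shape)
        return self.gamma.data.reshape(shape) * xhat + self.beta.data.reshape(shape)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape, train, xshape = self._cache
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gxhat = g * self.gamma.data.reshape(shape)
        if not train:
            return gxhat * inv.reshape(shape)
        m = np.prod([xshape[a] for a in axes])
        term = (gxhat - gxhat.mean(axis=axes).reshape(shape)
                - xhat * (gxhat * xhat).mean(axis=axes).reshape(shape))
        return term * inv.reshape(shape)


class LayerNorm(Module):
    """Normalization over the trailing feature axis."""

    def __init__(self, dim: int, eps: float = 1e-5, name: str = "ln") -> None:
        super().__init__()
        self.dim, self.eps = dim, eps
        self.gamma = self.add_param(np.ones(dim), f"{name}.gamma")
        self.beta = self.add_param(np.zeros(dim), f"{name}.beta")
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        red = tuple(range(g.ndim - 1))
        self.gamma.grad += (g * xhat).sum(axis=red)
        self.beta.grad += g.sum(axis=red)
        gxhat = g * self.gamma.data
        return (gxhat - gxhat.mean(axis=-1, keepdims=True)
                - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True)) * inv


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.p = p
        self.rng = rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p <= 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g * self._mask


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _softmax_backward(p: np.ndarray, g: np.ndarray, axis: int = -1) -> np.ndarray:
    return p * (g - (g * p).sum(axis=axis, keepdims=True))


class MultiHeadSelfAttention(Module):
    """softmax(QK^T / sqrt(d_k)) V per head, heads concatenated then projected."""

    def __init__(self, dim: int, n_heads: int, dropout: float,
                 rng: np.random.Generator, name: str = "mhsa") -> None:
        super().__init__()
        if dim % n_heads != 0:
            raise ValueError(f"token dim {dim} not divisible by {n_heads} heads")
        self.dim, self.n_heads = dim, n_heads
        self.d_k = dim // n_heads
        self.q = self.add_child(Linear(dim, dim, rng, name=f"{name}.q"))
        self.k = self.add_child(Linear(dim, dim, rng, name=f"{name}.k"))
        self.v = self.add_child(Linear(dim, dim, rng, name=f"{name}.v"))
        self.out = self.add_child(Linear(dim, dim, rng, name=f"{name}.out"))
        self.drop = self.add_child(Dropout(dropout, rng))
        self._cache: tuple | None = None
        self.last_attention: np.ndarray | None = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        n, t, _ = x.shape
        return x.reshape(n, t, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        n, h, t, d = x.shape
        return x.transpose(0, 2, 1, 3).reshape(n, t, h * d)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        q = self._split(self.q.forward(x))
        k = self._split(self.k.forward(x))
        v = self._split(self.v.forward(x))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.d_k)
        attn = softmax(scores, axis=-1)
        self.last_attention = attn
        ctx = attn @ v
        merged = self._merge(ctx)
        y = self.out.forward(merged)
        self._cache = (q, k, v, attn)
        return self.drop.forward(y, train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        g = self.drop.backward(g)
        gmerged = self.out.backward(g)
        gctx = self._split(gmerged)
        gattn = gctx @ v.transpose(0, 1, 3, 2)
        gv = attn.transpose(0, 1, 3, 2) @ gctx
        gscores = _softmax_backward(attn, gattn, axis=-1) / np.sqrt(self.d_k)
        gq = gscores @ k
        gk = gscores.transpose(0, 1, 3, 2) @ q
        gx = self.q.backward(self._merge(gq))
        gx += self.k.backward(self._merge(gk))
        gx += self.v.backward(self._merge(gv))
        return gx


def cross_entropy(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), targets].mean()
    grad = np.exp(logp)
    grad[np.arange(n), targets] -= 1.0
    return float(loss), grad / n


class Adam:
    """Adam with bias correction; deterministic given the parameter order."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1 - b1) * (p.grad - m)
            v += (1 - b2) * (p.grad ** 2 - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
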