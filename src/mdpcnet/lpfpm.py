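"""Linear-projection feature pyramid.

The branch outputs are flattened into one position sequence (branch-major
order: 1-D spectral positions as a 1-pixel-wide strip, then the 2-D grid, then
the spectrally-pooled 3-D grid), projected channel-wise to the pyramid width,
split into equal channel groups bound one-to-one to three receptive scales
(original / downsampled / upsampled), passed through shared depthwise
convolutions per group, re-concatenated, and fused by a pointwise (1x1)
convolution back to the model dimension.

Resampling operators are fixed (parameter-free): average-pool down by 2 with
edge padding on odd extents, nearest-neighbor back up; bilinear up by 2,
average-pool back down. Their backwards are exact transposes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .nn import DepthwiseConv2d, Linear, Module

__all__ = ["SegmentLayout", "FusedTensor", "split_groups", "concat_groups",
           "Lpfpm", "PlainFusion", "avg_pool2", "avg_pool2_backward",
           "nearest_up2", "nearest_up2_backward", "bilinear_up2",
           "bilinear_up2_backward"]


@dataclass(frozen=True)
class SegmentLayout:
    """Spatial interpretation of consecutive slices of the position sequence."""

    kinds: tuple[str, ...]          # per segment: "strip" or "grid"
    shapes: tuple[tuple[int, int], ...]

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(h * w for h, w in self.shapes)

    @property
    def total(self) -> int:
        return sum(self.lengths)

    def offsets(self) -> list[tuple[int, int]]:
        out, pos = [], 0
        for n in self.lengths:
            out.append((pos, pos + n))
            pos += n
        return out


@dataclass
class FusedTensor:
    """Position sequence after fusion (``x``) and after projection (``x_proj``)."""

    x: np.ndarray          # (N, S, C) branch-concatenated features
    x_proj: np.ndarray     # (N, S, D) after the linear projection
    layout: SegmentLayout


def split_groups(x: np.ndarray, n_groups: int) -> list[np.ndarray]:
    """Contiguous equal channel slices; concatenation restores the input."""
    dim = x.shape[-1]
    if dim % n_groups != 0:
        raise ValueError(f"feature dim {dim} not divisible by {n_groups} groups")
    width = dim // n_groups
    return [x[..., i * width:(i + 1) * width] for i in range(n_groups)]


def concat_groups(groups: list[np.ndarray]) -> np.ndarray:
    return np.concatenate(groups, axis=-1)


# ---------------------------------------------------------------------------
# fixed resampling operators on (N, C, H, W) with exact transposed backwards

def _pad_even_idx(n: int) -> np.ndarray:
    """Source index per padded position (edge-replicates odd extents)."""
    m = n + (n % 2)
    idx = np.arange(m)
    idx[idx >= n] = n - 1
    return idx


def avg_pool2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    ri, ci = _pad_even_idx(h), _pad_even_idx(w)
    xp = x[:, :, ri][:, :, :, ci]
    return xp.reshape(n, c, len(ri) // 2, 2, len(ci) // 2, 2).mean(axis=(3, 5))


def avg_pool2_backward(g: np.ndarray, in_shape: tuple[int, ...]) -> np.ndarray:
    n, c, h, w = in_shape
    ri, ci = _pad_even_idx(h), _pad_even_idx(w)
    gp = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
    gx = np.zeros(in_shape, dtype=g.dtype)
    np.add.at(gx, (slice(None), slice(None), ri[:, None], ci[None, :]),
              gp)
    return gx


def nearest_up2(y: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    h, w = out_hw
    ri = np.minimum(np.arange(h) // 2, y.shape[2] - 1)
    ci = np.minimum(np.arange(w) // 2, y.shape[3] - 1)
    return y[:, :, ri][:, :, :, ci]


def nearest_up2_backward(g: np.ndarray, in_shape: tuple[int, ...]) -> np.ndarray:
    h, w = g.shape[2:]
    ri = np.minimum(np.arange(h) // 2, in_shape[2] - 1)
    ci = np.minimum(np.arange(w) // 2, in_shape[3] - 1)
    gy = np.zeros(in_shape, dtype=g.dtype)
    np.add.at(gy, (slice(None), slice(None), ri[:, None], ci[None, :]), g)
    return gy


def _bilinear_axis(n_out: int, n_in: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index pairs and weights for exact-2x bilinear interpolation."""
    src = (np.arange(n_out) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    i1 = np.clip(i0 + 1, 0, n_in - 1)
    frac = np.clip(src - np.floor(src), 0.0, 1.0)
    frac[src < 0] = 0.0
    frac[src > n_in - 1] = 0.0
    return i0, i1, frac


def bilinear_up2(x: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    r0, r1, rf = _bilinear_axis(2 * h, h)
    c0, c1, cf = _bilinear_axis(2 * w, w)
    xr = x[:, :, r0] * (1 - rf)[None, None, :, None] + x[:, :, r1] * rf[None, None, :, None]
    return (xr[:, :, :, c0] * (1 - cf)[None, None, None, :]
            + xr[:, :, :, c1] * cf[None, None, None, :])


def bilinear_up2_backward(g: np.ndarray, in_shape: tuple[int, ...]) -> np.ndarray:
    n, c, h, w = in_shape
    r0, r1, rf = _bilinear_axis(2 * h, h)
    c0, c1, cf = _bilinear_axis(2 * w, w)
    gr = np.zeros((g.shape[0], g.shape[1], 2 * h, w), dtype=g.dtype)
    np.add.at(gr, (slice(None), slice(None), slice(None), c0),
              g * (1 - cf)[None, None, None, :])
    np.add.at(gr, (slice(None), slice(None), slice(None), c1),
              g * cf[None, None, None, :])
    gx = np.zeros(in_shape, dtype=g.dtype)
    np.add.at(gx, (slice(None), slice(None), r0),
              gr * (1 - rf)[None, None, :, None])
    np.add.at(gx, (slice(None), slice(None), r1),
              gr * rf[None, None, :, None])
    return gx


# ---------------------------------------------------------------------------

class _ScaleGroup(Module):
    """One channel group processed at one receptive scale, per segment."""

    def __init__(self, channels: int, kernel: int, scale: str,
                 rng: np.random.Generator, name: str) -> None:
        super().__init__()
        if scale not in ("original", "down", "up"):
            raise ValueError(f"unknown scale tag {scale!r}")
        self.scale = scale
        self.dw = self.add_child(DepthwiseConv2d(channels, kernel, rng,
                                                 name=f"{name}.dw"))
        self._cache: list[tuple] = []

    def forward_segment(self, x: np.ndarray, train: bool) -> np.ndarray:
        """x: (N, C, h, w) one segment grid."""
        if self.scale == "original":
            self._cache.append(("orig", x.shape))
            return self.dw.forward(x, train)
        if self.scale == "down":
            if min(x.shape[2:]) < 1:
                raise ValueError("downsampling path needs spatial extent >= 1")
            pooled = avg_pool2(x)
            y = self.dw.forward(pooled, train)
            self._cache.append(("down", x.shape, pooled.shape))
            return nearest_up2(y, x.shape[2:])
        up = bilinear_up2(x)
        y = self.dw.forward(up, train)
        self._cache.append(("up", x.shape, up.shape))
        return avg_pool2(y)

    def backward_segment(self, g: np.ndarray) -> np.ndarray:
        info = self._cache.pop()
        if info[0] == "orig":
            return self.dw.backward(g)
        if info[0] == "down":
            _, x_shape, pooled_shape = info
            gy = nearest_up2_backward(g, (g.shape[0], g.shape[1]) + pooled_shape[2:])
            gp = self.dw.backward(gy)
            return avg_pool2_backward(gp, x_shape)
        _, x_shape, up_shape = info
        gy = avg_pool2_backward(g, (g.shape[0], g.shape[1]) + up_shape[2:])
        gu = self.dw.backward(gy)
        return bilinear_up2_backward(gu, x_shape)


_SCALES = ("original", "down", "up")


class Lpfpm(Module):
    """Project -> split -> multi-scale depthwise -> concat -> pointwise fuse."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.cfg = cfg
        in_dim = cfg.branch_channels
        self.proj = self.add_child(Linear(in_dim, cfg.pyramid_width, rng,
                                          name="lpfpm.proj"))
        gw = cfg.pyramid_width // cfg.n_groups
        self.groups = [
            self.add_child(_ScaleGroup(gw, cfg.mrfp_kernel,
                                       _SCALES[i % len(_SCALES)], rng,
                                       f"lpfpm.group{i}"))
            for i in range(cfg.n_groups)
        ]
        self.pointwise = self.add_child(Linear(cfg.pyramid_width, cfg.model_dim,
                                               rng, name="lpfpm.pointwise"))
        self._layout: SegmentLayout | None = None

    def forward(self, x: np.ndarray, layout: SegmentLayout,
                train: bool = False) -> np.ndarray:
        """x: (N, S, 4w) position sequence -> (N, S, model_dim)."""
        self._layout = layout
        for grp in self.groups:  # drop stale caches from backward-free passes
            grp._cache.clear()
            grp.dw._stack.clear()
        z = self.proj.forward(x)
        parts = split_groups(z, self.cfg.n_groups)
        outs = []
        for grp, part in zip(self.groups, parts):
            seg_out = np.empty_like(part)
            for (lo, hi), shape in zip(layout.offsets(), layout.shapes):
                seg = part[:, lo:hi, :]
                n = seg.shape[0]
                grid = seg.transpose(0, 2, 1).reshape(n, seg.shape[2], *shape)
                res = grp.forward_segment(grid, train)
                seg_out[:, lo:hi, :] = res.reshape(n, seg.shape[2], hi - lo
                                                   ).transpose(0, 2, 1)
            outs.append(seg_out)
        fused = concat_groups(outs)
        return self.pointwise.forward(fused)

    def backward(self, g: np.ndarray) -> np.ndarray:
        layout = self._layout
        gf = self.pointwise.backward(g)
        parts = split_groups(gf, self.cfg.n_groups)
        gz = []
        for grp, part in zip(self.groups, parts):
            seg_grad = np.empty_like(part)
            # segments were cached in forward order; pop in reverse
            for (lo, hi), shape in reversed(list(zip(layout.offsets(),
                                                     layout.shapes))):
                seg = part[:, lo:hi, :]
                n = seg.shape[0]
                grid = seg.transpose(0, 2, 1).reshape(n, seg.shape[2], *shape)
                res = grp.backward_segment(grid)
                seg_grad[:, lo:hi, :] = res.reshape(n, seg.shape[2], hi - lo
                                                    ).transpose(0, 2, 1)
            gz.append(seg_grad)
        return self.proj.backward(concat_groups(gz))


class PlainFusion(Module):
    """Ablation fusion: flatten-concat followed by a single linear map."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.proj = self.add_child(Linear(cfg.branch_channels, cfg.model_dim,
                                          rng, name="plain.proj"))

    def forward(self, x: np.ndarray, layout: SegmentLayout,
                train: bool = False) -> np.ndarray:
        return self.proj.forward(x)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.proj.backward(g)
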