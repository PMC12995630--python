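"""Multi-dimensional feature extraction backbone.

Three parallel branches process each patch: a 1-D branch convolving the
center-pixel spectrum, a 2-D branch convolving spatially with the bands as
input channels, and a 3-D branch convolving the full spectral-spatial volume.
Each branch applies its dilation stages *in parallel* to the branch input —
base kernel 3, dilation factors (1, 2, 3, 6) from the printed inserted-zero
rates (0, 1, 2, 5) — and concatenates the stage outputs along the channel
axis, so the branch output carries ``n_stages * stage_width`` channels and the
stages together form a strict receptive-field pyramid. Every convolution is
stride-1 with "same" zero padding and is followed by batch normalization and
ReLU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .nn import BatchNorm, ConvNd, Module, ReLU

def _grad_dtype(g):
    for arr in (g.x1d, g.x2d, g.x3d):
        if arr is not None:
            return arr.dtype
    return np.float64


__all__ = ["DilationStep", "ConvLayerSpec", "effective_kernel_size",
           "receptive_field", "FeatureTriple", "Mdfem", "BranchStage"]


def effective_kernel_size(l: int, d: int) -> int:
    """Effective extent of a kernel of ``l`` taps at dilation factor ``d``."""
    if l < 1 or d < 1:
        raise ValueError(f"kernel size and dilation factor must be >= 1, got ({l}, {d})")
    return l + (l - 1) * (d - 1)


@dataclass(frozen=True)
class DilationStep:
    l: int
    d: int

    @property
    def L(self) -> int:
        return effective_kernel_size(self.l, self.d)


@dataclass(frozen=True)
class ConvLayerSpec:
    kernel: int
    dilation: int = 1
    stride: int = 1
    c_in: int = 1
    c_out: int = 1

    def __post_init__(self) -> None:
        if min(self.kernel, self.dilation, self.stride, self.c_in, self.c_out) < 1:
            raise ValueError("all ConvLayerSpec fields must be >= 1")

    @property
    def effective_kernel(self) -> int:
        return effective_kernel_size(self.kernel, self.dilation)


def receptive_field(layers: list[ConvLayerSpec]) -> list[int]:
    """Receptive field after each layer of a stack.

    ``R_1 = L_1`` and ``R_{m+1} = R_m + (L_{m+1} - 1) * prod(S_1..S_m)``.
    """
    if not layers:
        raise ValueError("receptive_field needs at least one layer")
    fields: list[int] = []
    stride_prod = 1
    for i, layer in enumerate(layers):
        if i == 0:
            fields.append(layer.effective_kernel)
        else:
            fields.append(fields[-1] + (layer.effective_kernel - 1) * stride_prod)
        stride_prod *= layer.stride
    return fields


@dataclass
class FeatureTriple:
    """Per-branch stage-concatenated feature maps (None when branch disabled)."""

    x1d: np.ndarray | None  # (N, 4w, B)
    x2d: np.ndarray | None  # (N, 4w, s, s)
    x3d: np.ndarray | None  # (N, 4w, B, s, s)


class BranchStage(Module):
    """One dilated conv stage: conv -> batch norm -> ReLU."""

    def __init__(self, ndim: int, c_in: int, width: int, kernel: int,
                 dilation: int, rng: np.random.Generator, name: str) -> None:
        super().__init__()
        self.conv = self.add_child(ConvNd(ndim, c_in, width, kernel, dilation,
                                          rng, name=f"{name}.conv"))
        self.bn = self.add_child(BatchNorm(width, name=f"{name}.bn"))
        self.act = self.add_child(ReLU())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.act.forward(self.bn.forward(self.conv.forward(x), train))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.act.backward(g)))


class _Branch(Module):
    """Parallel dilation stages over one branch input, concatenated on channels."""

    def __init__(self, ndim: int, c_in: int, cfg: ModelConfig,
                 rng: np.random.Generator, name: str) -> None:
        super().__init__()
        self.width = cfg.stage_width
        self.stages = [
            self.add_child(BranchStage(ndim, c_in, cfg.stage_width,
                                       cfg.schedule.base_kernel, d, rng,
                                       f"{name}.stage_d{d}"))
            for d in cfg.schedule.factors
        ]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.concatenate([s.forward(x, train) for s in self.stages], axis=1)

    def backward(self, g: np.ndarray) -> np.ndarray:
        w = self.width
        gx = None
        for i, stage in enumerate(self.stages):
            gi = stage.backward(g[:, i * w:(i + 1) * w])
            gx = gi if gx is None else gx + gi
        return gx


class Mdfem(Module):
    """The three-branch backbone; disabled branches are simply absent."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.cfg = cfg
        if cfg.patch_size % 2 == 0:
            raise ValueError("patch size must be odd")
        self.branch_1d = (self.add_child(_Branch(1, 1, cfg, rng, "b1d"))
                          if cfg.use_1d else None)
        self.branch_2d = (self.add_child(_Branch(2, cfg.n_bands, cfg, rng, "b2d"))
                          if cfg.use_2d else None)
        self.branch_3d = (self.add_child(_Branch(3, 1, cfg, rng, "b3d"))
                          if cfg.use_3d else None)
        # effective kernels larger than the padded axis are legal ("same" zero
        # padding covers them) but worth surfacing when introspecting a build
        self.build_log = [
            f"stage d={d}: effective kernel "
            f"{effective_kernel_size(cfg.schedule.base_kernel, d)} on "
            f"{cfg.patch_size}-pixel axis"
            for d in cfg.schedule.factors
            if effective_kernel_size(cfg.schedule.base_kernel, d) > cfg.patch_size
        ]
        self._shapes: dict[str, tuple] = {}

    def forward(self, patches: np.ndarray, train: bool = False) -> FeatureTriple:
        """``patches``: (N, s, s, B) batch in scene layout (band axis last)."""
        n, s1, s2, bands = patches.shape
        if (s1, s2) != (self.cfg.patch_size,) * 2 or bands != self.cfg.n_bands:
            raise ValueError(
                f"patch batch {patches.shape[1:]} does not match build "
                f"({self.cfg.patch_size}, {self.cfg.patch_size}, {self.cfg.n_bands})")
        half = self.cfg.patch_size // 2
        x1d = x2d = x3d = None
        if self.branch_1d is not None:
            spec = patches[:, half, half, :][:, None, :]  # (N, 1, B)
            x1d = self.branch_1d.forward(spec, train)
        if self.branch_2d is not None:
            img = np.ascontiguousarray(patches.transpose(0, 3, 1, 2))  # (N, B, s, s)
            x2d = self.branch_2d.forward(img, train)
        if self.branch_3d is not None:
            vol = np.ascontiguousarray(patches.transpose(0, 3, 1, 2))[:, None]
            x3d = self.branch_3d.forward(vol, train)
        self._shapes["in"] = patches.shape
        return FeatureTriple(x1d=x1d, x2d=x2d, x3d=x3d)

    def backward(self, g: FeatureTriple) -> np.ndarray:
        """Accumulate branch gradients back onto the patch batch."""
        n, s1, s2, bands = self._shapes["in"]
        gp = np.zeros((n, s1, s2, bands), dtype=_grad_dtype(g))
        half = self.cfg.patch_size // 2
        if self.branch_1d is not None and g.x1d is not None:
            gs = self.branch_1d.backward(g.x1d)[:, 0, :]  # (N, B)
            gp[:, half, half, :] += gs
        if self.branch_2d is not None and g.x2d is not None:
            gp += self.branch_2d.backward(g.x2d).transpose(0, 2, 3, 1)
        if self.branch_3d is not None and g.x3d is not None:
            gv = self.branch_3d.backward(g.x3d)[:, 0]  # (N, B, s, s)
            gp += gv.transpose(0, 2, 3, 1)
        return gp
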