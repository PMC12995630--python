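"""Full classifier: backbone -> feature pyramid -> Transformer head.

The patch batch flows through the enabled backbone branches; branch outputs
are flattened into one position sequence (1-D spectral strip, 2-D grid,
spectrally-pooled 3-D grid, in that order), fused (feature pyramid or the
plain concat+linear ablation), tokenized and classified.
"""

from __future__ import annotations

import numpy as np

from .config import ModelConfig
from .lpfpm import FusedTensor, Lpfpm, PlainFusion, SegmentLayout
from .mdfem import FeatureTriple, Mdfem
from . import nn as _nn
from .nn import Module
from .transformer import (AttentionConfig, MlpConfig, TokenizerConfig,
                          TransformerHead)

__all__ = ["MdpcNet", "build_model", "sequence_layout"]


def nn_dtype() -> np.dtype:
    return np.dtype(_nn.DTYPE)


def sequence_layout(cfg: ModelConfig) -> SegmentLayout:
    """Position-sequence segments produced by the enabled branches."""
    kinds: list[str] = []
    shapes: list[tuple[int, int]] = []
    s = cfg.patch_size
    if cfg.use_1d:
        kinds.append("strip")
        shapes.append((1, cfg.n_bands))
    if cfg.use_2d:
        kinds.append("grid")
        shapes.append((s, s))
    if cfg.use_3d:
        kinds.append("grid")
        shapes.append((s, s))
    return SegmentLayout(kinds=tuple(kinds), shapes=tuple(shapes))


class MdpcNet(Module):
    """The complete network; ablation flags prune branches or the pyramid."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.cfg = cfg
        self.layout = sequence_layout(cfg)
        self.backbone = self.add_child(Mdfem(cfg, rng))
        fusion_cls = Lpfpm if cfg.fusion == "lpfpm" else PlainFusion
        self.fusion = self.add_child(fusion_cls(cfg, rng))
        self.head = self.add_child(TransformerHead(
            cfg.model_dim, cfg.n_classes,
            TokenizerConfig(cfg.n_tokens, cfg.model_dim, cfg.use_cls_token),
            AttentionConfig(cfg.n_heads, cfg.model_dim, cfg.dropout),
            MlpConfig(cfg.mlp_hidden, cfg.model_dim), rng))
        self._bands = cfg.n_bands
        self._triple_shapes: dict[str, tuple] = {}

    # -- sequence assembly ---------------------------------------------------

    def _to_sequence(self, triple: FeatureTriple) -> np.ndarray:
        parts = []
        if triple.x1d is not None:
            parts.append(triple.x1d.transpose(0, 2, 1))          # (N, B, 4w)
            self._triple_shapes["x1d"] = triple.x1d.shape
        if triple.x2d is not None:
            n, c, h, w = triple.x2d.shape
            parts.append(triple.x2d.reshape(n, c, h * w).transpose(0, 2, 1))
            self._triple_shapes["x2d"] = triple.x2d.shape
        if triple.x3d is not None:
            pooled = triple.x3d.mean(axis=2)                     # collapse bands
            n, c, h, w = pooled.shape
            parts.append(pooled.reshape(n, c, h * w).transpose(0, 2, 1))
            self._triple_shapes["x3d"] = triple.x3d.shape
        return np.concatenate(parts, axis=1)

    def _sequence_backward(self, g: np.ndarray) -> FeatureTriple:
        g1 = g2 = g3 = None
        pos = 0
        if "x1d" in self._triple_shapes:
            n, c, b = self._triple_shapes["x1d"]
            g1 = g[:, pos:pos + b, :].transpose(0, 2, 1)
            pos += b
        if "x2d" in self._triple_shapes:
            n, c, h, w = self._triple_shapes["x2d"]
            g2 = g[:, pos:pos + h * w, :].transpose(0, 2, 1).reshape(n, c, h, w)
            pos += h * w
        if "x3d" in self._triple_shapes:
            n, c, b, h, w = self._triple_shapes["x3d"]
            gp = g[:, pos:pos + h * w, :].transpose(0, 2, 1).reshape(n, c, h, w)
            g3 = np.broadcast_to(gp[:, :, None] / b, (n, c, b, h, w)).copy()
        return FeatureTriple(x1d=g1, x2d=g2, x3d=g3)

    # -- public API ----------------------------------------------------------

    def fuse_and_project(self, triple: FeatureTriple,
                         train: bool = False) -> FusedTensor:
        """Assemble the position sequence and apply the fusion projection."""
        seq = self._to_sequence(triple)
        out = self.fusion.forward(seq, self.layout, train)
        return FusedTensor(x=seq, x_proj=out, layout=self.layout)

    def forward(self, patches: np.ndarray, train: bool = False) -> np.ndarray:
        """patches: (N, s, s, B) -> logits (N, n_classes)."""
        if patches.shape[3] != self._bands:
            raise ValueError(
                f"band count {patches.shape[3]} does not match build {self._bands}")
        patches = np.asarray(patches, dtype=nn_dtype())
        triple = self.backbone.forward(patches, train)
        fused = self.fuse_and_project(triple, train)
        return self.head.forward(fused.x_proj, train)

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        gseq_proj = self.head.backward(glogits)
        gseq = self.fusion.backward(gseq_proj)
        gtriple = self._sequence_backward(gseq)
        return self.backbone.backward(gtriple)

    def predict(self, patches: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Deterministic evaluation-mode class predictions (1-based labels)."""
        out = []
        for lo in range(0, len(patches), batch_size):
            logits = self.forward(patches[lo:lo + batch_size], train=False)
            out.append(np.argmax(logits, axis=1) + 1)
        return np.concatenate(out) if out else np.empty(0, dtype=int)


def build_model(cfg: ModelConfig, seed: int = 0) -> MdpcNet:
    return MdpcNet(cfg, np.random.default_rng(seed))
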