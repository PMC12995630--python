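"""Tokenization, depth-1 pre-norm Transformer encoder, classification head.

The tokenizer compresses the position sequence into a fixed number of tokens
via two learned projections: matrix A maps positions to tokens through a
softmax over positions (so each token is a convex mixture of positions) and
matrix B maps the feature axis to the token dimension. A learnable class token
is prepended; the classifier reads only that token after the encoder block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Dropout, LayerNorm, Linear, Module, MultiHeadSelfAttention,
                 ReLU, softmax)

__all__ = ["TokenizerConfig", "AttentionConfig", "MlpConfig", "Tokenizer",
           "MlpBlock", "EncoderBlock", "TransformerHead"]


@dataclass(frozen=True)
class TokenizerConfig:
    n_tokens: int = 4
    token_dim: int = 64
    use_cls_token: bool = True

    def __post_init__(self) -> None:
        if self.n_tokens < 1 or self.token_dim < 1:
            raise ValueError("n_tokens and token_dim must be >= 1")


@dataclass(frozen=True)
class AttentionConfig:
    n_heads: int = 8
    token_dim: int = 64
    dropout: float = 0.1

    def __post_init__(self) -> None:
        if self.token_dim % self.n_heads != 0:
            raise ValueError(
                f"token_dim {self.token_dim} not divisible by {self.n_heads} heads")

    @property
    def head_dim(self) -> int:
        return self.token_dim // self.n_heads


@dataclass(frozen=True)
class MlpConfig:
    hidden_dim: int = 8
    token_dim: int = 64

    def __post_init__(self) -> None:
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")


class Tokenizer(Module):
    """Position-softmax token pooling with a prepended class token."""

    def __init__(self, feature_dim: int, cfg: TokenizerConfig,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.cfg = cfg
        self.a_proj = self.add_child(Linear(feature_dim, cfg.n_tokens, rng,
                                            bias=False, name="tok.A"))
        self.b_proj = self.add_child(Linear(feature_dim, cfg.token_dim, rng,
                                            name="tok.B"))
        self.cls = (self.add_param(rng.normal(0, 0.02, size=(cfg.token_dim,)),
                                   "tok.cls")
                    if cfg.use_cls_token else None)
        self._cache: tuple | None = None
        self.last_attention: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, S, F) -> tokens (N, T(+1), token_dim)."""
        logits = self.a_proj.forward(x)            # (N, S, T)
        attn = softmax(logits, axis=1)             # normalized over positions
        self.last_attention = attn
        proj = self.b_proj.forward(x)              # (N, S, D)
        tokens = np.einsum("nst,nsd->ntd", attn, proj)
        self._cache = (attn, proj)
        if self.cls is not None:
            n = x.shape[0]
            cls = np.broadcast_to(self.cls.data, (n, 1, self.cfg.token_dim))
            tokens = np.concatenate([cls, tokens], axis=1)
        return tokens

    def backward(self, g: np.ndarray) -> np.ndarray:
        attn, proj = self._cache
        if self.cls is not None:
            self.cls.grad += g[:, 0, :].sum(axis=0)
            g = g[:, 1:, :]
        gattn = np.einsum("ntd,nsd->nst", g, proj)
        gproj = np.einsum("nst,ntd->nsd", attn, g)
        glogits = attn * (gattn - (gattn * attn).sum(axis=1, keepdims=True))
        return self.a_proj.backward(glogits) + self.b_proj.backward(gproj)


class MlpBlock(Module):
    """Position-wise two-layer perceptron with ReLU between the affine maps."""

    def __init__(self, cfg: MlpConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.fc1 = self.add_child(Linear(cfg.token_dim, cfg.hidden_dim, rng,
                                         name="mlp.fc1"))
        self.act = self.add_child(ReLU())
        self.fc2 = self.add_child(Linear(cfg.hidden_dim, cfg.token_dim, rng,
                                         name="mlp.fc2"))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.fc2.forward(self.act.forward(self.fc1.forward(x)))

    def backward(self, g: np.ndarray) -> np.ndarray:
        return self.fc1.backward(self.act.backward(self.fc2.backward(g)))


class EncoderBlock(Module):
    """Pre-norm residual block: x + MHSA(LN(x)), then x + MLP(LN(x))."""

    def __init__(self, attn_cfg: AttentionConfig, mlp_cfg: MlpConfig,
                 rng: np.random.Generator) -> None:
        super().__init__()
        dim = attn_cfg.token_dim
        self.ln1 = self.add_child(LayerNorm(dim, name="enc.ln1"))
        self.mhsa = self.add_child(MultiHeadSelfAttention(
            dim, attn_cfg.n_heads, attn_cfg.dropout, rng, name="enc.mhsa"))
        self.ln2 = self.add_child(LayerNorm(dim, name="enc.ln2"))
        self.mlp = self.add_child(MlpBlock(mlp_cfg, rng))
        self.drop = self.add_child(Dropout(attn_cfg.dropout, rng))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x + self.mhsa.forward(self.ln1.forward(x), train)
        return h + self.drop.forward(self.mlp.forward(self.ln2.forward(h)), train)

    def backward(self, g: np.ndarray) -> np.ndarray:
        gh = g + self.ln2.backward(self.mlp.backward(self.drop.backward(g)))
        return gh + self.ln1.backward(self.mhsa.backward(gh))


class TransformerHead(Module):
    """Tokenizer + single encoder block + class-token readout."""

    def __init__(self, feature_dim: int, n_classes: int,
                 tok_cfg: TokenizerConfig, attn_cfg: AttentionConfig,
                 mlp_cfg: MlpConfig, rng: np.random.Generator) -> None:
        super().__init__()
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.tokenizer = self.add_child(Tokenizer(feature_dim, tok_cfg, rng))
        self.encoder = self.add_child(EncoderBlock(attn_cfg, mlp_cfg, rng))
        self.ln_final = self.add_child(LayerNorm(tok_cfg.token_dim, name="head.ln"))
        self.head = self.add_child(Linear(tok_cfg.token_dim, n_classes, rng,
                                          name="head.fc"))
        self.use_cls = tok_cfg.use_cls_token
        self._n_tokens_out: int = 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        tokens = self.tokenizer.forward(x, train)
        enc = self.encoder.forward(tokens, train)
        self._n_tokens_out = enc.shape[1]
        readout = enc[:, 0, :] if self.use_cls else enc.mean(axis=1)
        return self.head.forward(self.ln_final.forward(readout))

    def backward(self, g: np.ndarray) -> np.ndarray:
        gread = self.ln_final.backward(self.head.backward(g))
        n, d = gread.shape
        genc = np.zeros((n, self._n_tokens_out, d))
        if self.use_cls:
            genc[:, 0, :] = gread
        else:
            genc += gread[:, None, :] / self._n_tokens_out
        gtok = self.encoder.backward(genc)
        return self.tokenizer.backward(gtok)
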