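"""Configuration dataclasses shared across the pipeline.

Defaults encode the reference protocol constants: 11x11 patches, dilation-rate
sequence [0, 1, 2, 5], a 64-dimensional token space with 4 learned tokens plus
a class token, a depth-1 / 8-head / hidden-8 Transformer with dropout 0.1,
500 epochs at learning rate 1e-4, and five 20(or 100)/300 per-class split
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = ["PdcSchedule", "ModelConfig", "TrainConfig"]


@dataclass(frozen=True)
class PdcSchedule:
    """Progressive-dilation schedule.

    ``printed_rates`` are inserted-zero counts (the conventional way these
    schedules are quoted); ``factors`` are the corresponding dilation factors
    ``rate + 1`` used by the convolutions, strictly increasing so the stages
    form a receptive-field pyramid.
    """

    printed_rates: tuple[int, ...] = (0, 1, 2, 5)
    base_kernel: int = 3

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.printed_rates):
            raise ValueError("printed rates must be >= 0")
        f = self.factors
        if any(b <= a for a, b in zip(f, f[1:])):
            raise ValueError(f"dilation factors must be strictly increasing, got {f}")
        if self.base_kernel < 1:
            raise ValueError("base_kernel must be >= 1")

    @property
    def factors(self) -> tuple[int, ...]:
        return tuple(r + 1 for r in self.printed_rates)

    @property
    def n_stages(self) -> int:
        return len(self.printed_rates)


@dataclass(frozen=True)
class ModelConfig:
    """Every architectural knob of the classifier.

    ``stage_width`` is the shared per-stage channel width of the three
    backbone branches; ``pyramid_width`` the internal channel width of the
    feature pyramid (split into ``n_groups`` scale groups before the pointwise
    fusion back to ``model_dim``). The reference widths are fixed by the
    complexity calibration, not guessed per layer.
    """

    n_bands: int
    n_classes: int
    patch_size: int = 11
    schedule: PdcSchedule = field(default_factory=PdcSchedule)
    stage_width: int = 8
    pyramid_width: int = 48
    model_dim: int = 64
    n_groups: int = 3
    n_tokens: int = 4
    n_heads: int = 8
    mlp_hidden: int = 8
    dropout: float = 0.1
    use_cls_token: bool = True
    use_positional_embedding: bool = False
    use_1d: bool = True
    use_2d: bool = True
    use_3d: bool = True
    fusion: str = "lpfpm"  # or "plain_concat_linear"
    mrfp_kernel: int = 3

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0 or self.patch_size < 1:
            raise ValueError(f"patch_size must be odd, got {self.patch_size}")
        if self.n_bands < 1 or self.n_classes < 2:
            raise ValueError("need n_bands >= 1 and n_classes >= 2")
        if self.pyramid_width % self.n_groups != 0:
            raise ValueError(
                f"pyramid_width {self.pyramid_width} not divisible by "
                f"n_groups {self.n_groups}")
        if self.model_dim % self.n_heads != 0:
            raise ValueError(
                f"model_dim {self.model_dim} not divisible by n_heads {self.n_heads}")
        if not (self.use_1d or self.use_2d or self.use_3d):
            raise ValueError("at least one branch must be enabled")
        if self.fusion not in ("lpfpm", "plain_concat_linear"):
            raise ValueError(f"unknown fusion {self.fusion!r}")
        if self.stage_width < 1 or self.pyramid_width < 1:
            raise ValueError("widths must be positive")

    @property
    def branch_channels(self) -> int:
        """Channels of each branch output: one width per dilation stage."""
        return self.schedule.n_stages * self.stage_width

    def variant(self, **kwargs: Any) -> "ModelConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 500
    learning_rate: float = 1e-4
    batch_size: int = 64
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0
    model_selection: str = "best_val_oa"  # or "final"
    eval_every: int = 1

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ValueError(f"unsupported loss {self.loss!r}")
        if self.model_selection not in ("final", "best_val_oa"):
            raise ValueError(f"unknown model_selection {self.model_selection!r}")


# ---------------------------------------------------------------------------
# YAML round-trip helpers

def _to_plain(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def dump_config(cfg: Any, path: Path | str) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))
    return path


def model_config_from_dict(d: dict) -> ModelConfig:
    d = dict(d)
    sched = d.pop("schedule", None)
    if sched is not None:
        sched = PdcSchedule(printed_rates=tuple(sched["printed_rates"]),
                            base_kernel=sched.get("base_kernel", 3))
        d["schedule"] = sched
    return ModelConfig(**d)


def load_model_config(path: Path | str) -> ModelConfig:
    return model_config_from_dict(yaml.safe_load(Path(path).read_text()))
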