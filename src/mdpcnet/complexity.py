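"""Closed-form cost model and model-level parameter/FLOP accounting.

Two layers of accounting live here:

* the textbook per-layer costs of standard vs depthwise-pointwise
  convolution — ``cost_standard``, ``cost_dpc`` and their ratio
  ``1/C_out + 1/K**2`` (the H, W and C_in factors cancel);
* an analytic walk of the full architecture that lists every trainable layer
  with its parameter count and forward multiply-accumulate (MAC) count for a
  single patch. FLOPs are reported as ``flops_per_mac * MACs`` (default 2:
  one multiply plus one add); normalization, activation and softmax
  arithmetic is excluded, and the convention is recorded in every report.

The budget calibration searches the stage width / pyramid width plane for the
configuration that reproduces printed parameter budgets across several
dataset shapes simultaneously (printed token geometry held fixed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

from .config import ModelConfig, PdcSchedule

__all__ = ["CostQuery", "CostReport", "cost_standard", "cost_dpc", "cost_ratio",
           "layer_costs", "count_params", "count_macs", "count_flops",
           "BudgetSpec", "CalibrationError", "CalibrationResult",
           "calibrate_reference_config", "DEFAULT_BUDGETS",
           "reference_model_config"]

FLOPS_PER_MAC = 2


@dataclass(frozen=True)
class CostQuery:
    K: int
    H: int
    W: int
    C_in: int
    C_out: int

    def __post_init__(self) -> None:
        if min(self.K, self.H, self.W, self.C_in, self.C_out) < 1:
            raise ValueError("all cost query fields must be >= 1")


@dataclass(frozen=True)
class CostReport:
    omega_s: int
    omega_dpc: int

    @property
    def omega_delta(self) -> float:
        return self.omega_dpc / self.omega_s


def cost_standard(q: CostQuery) -> int:
    """MACs of a standard KxK convolution: K^2 * H * W * C_in * C_out."""
    return q.K * q.K * q.H * q.W * q.C_in * q.C_out


def cost_dpc(q: CostQuery) -> int:
    """MACs of the depthwise-pointwise pair: (K^2 + C_out) * H * W * C_in."""
    depthwise = q.K * q.K * q.H * q.W * q.C_in
    pointwise = q.H * q.W * q.C_in * q.C_out
    return depthwise + pointwise


def cost_ratio(K: int, C_out: int) -> float:
    """cost_dpc / cost_standard = 1/C_out + 1/K^2 (H, W, C_in cancel)."""
    if K < 1 or C_out < 1:
        raise ValueError("K and C_out must be >= 1")
    return 1.0 / C_out + 1.0 / (K * K)


# ---------------------------------------------------------------------------
# analytic architecture walk

def layer_costs(cfg: ModelConfig) -> list[tuple[str, int, int]]:
    """(layer name, trainable params, forward MACs per patch) for the build.

    Mirrors the constructed network exactly: disabled branches and the plain
    fusion ablation change the listing the same way they change the model.
    """
    k = cfg.schedule.base_kernel
    w = cfg.stage_width
    b, s = cfg.n_bands, cfg.patch_size
    s2 = s * s
    rows: list[tuple[str, int, int]] = []

    for d in cfg.schedule.factors:
        if cfg.use_1d:
            rows.append((f"b1d.stage_d{d}.conv", k * 1 * w + w, k * 1 * w * b))
            rows.append((f"b1d.stage_d{d}.bn", 2 * w, 0))
        if cfg.use_2d:
            rows.append((f"b2d.stage_d{d}.conv", k * k * b * w + w,
                         k * k * b * w * s2))
            rows.append((f"b2d.stage_d{d}.bn", 2 * w, 0))
        if cfg.use_3d:
            rows.append((f"b3d.stage_d{d}.conv", k ** 3 * w + w,
                         k ** 3 * w * b * s2))
            rows.append((f"b3d.stage_d{d}.bn", 2 * w, 0))

    segments = []
    if cfg.use_1d:
        segments.append((1, b))
    if cfg.use_2d:
        segments.append((s, s))
    if cfg.use_3d:
        segments.append((s, s))
    seq = sum(h * wd for h, wd in segments)
    bc = cfg.branch_channels
    d_model, p = cfg.model_dim, cfg.pyramid_width

    if cfg.fusion == "lpfpm":
        rows.append(("lpfpm.proj", bc * p + p, seq * bc * p))
        gw = p // cfg.n_groups
        m = cfg.mrfp_kernel
        scale_positions = {
            "original": sum(h * wd for h, wd in segments),
            "down": sum(math.ceil(h / 2) * math.ceil(wd / 2) for h, wd in segments),
            "up": sum(4 * h * wd for h, wd in segments),
        }
        scales = ("original", "down", "up")
        for i in range(cfg.n_groups):
            scale = scales[i % 3]
            rows.append((f"lpfpm.group{i}.dw[{scale}]", m * m * gw + gw,
                         m * m * gw * scale_positions[scale]))
        rows.append(("lpfpm.pointwise", p * d_model + d_model, seq * p * d_model))
    else:
        rows.append(("plain.proj", bc * d_model + d_model, seq * bc * d_model))

    t = cfg.n_tokens
    rows.append(("tok.A", d_model * t, seq * d_model * t + t * seq * d_model))
    rows.append(("tok.B", d_model * d_model + d_model, seq * d_model * d_model))
    if cfg.use_cls_token:
        rows.append(("tok.cls", d_model, 0))

    tt = t + (1 if cfg.use_cls_token else 0)
    rows.append(("enc.ln1", 2 * d_model, 0))
    for name in ("q", "k", "v", "out"):
        rows.append((f"enc.mhsa.{name}", d_model * d_model + d_model,
                     tt * d_model * d_model))
    rows.append(("enc.mhsa.attention", 0, 2 * tt * tt * d_model))
    rows.append(("enc.ln2", 2 * d_model, 0))
    h = cfg.mlp_hidden
    rows.append(("enc.mlp.fc1", d_model * h + h, tt * d_model * h))
    rows.append(("enc.mlp.fc2", h * d_model + d_model, tt * h * d_model))
    rows.append(("head.ln", 2 * d_model, 0))
    rows.append(("head.fc", d_model * cfg.n_classes + cfg.n_classes,
                 d_model * cfg.n_classes))
    return rows


def count_params(cfg: ModelConfig) -> int:
    """Exact trainable-scalar count of the configured build."""
    return sum(p for _, p, _ in layer_costs(cfg))


def count_macs(cfg: ModelConfig) -> int:
    return sum(m for _, _, m in layer_costs(cfg))


def count_flops(cfg: ModelConfig, flops_per_mac: int = FLOPS_PER_MAC) -> int:
    """Analytic forward-pass FLOPs for one patch under the stated convention."""
    return flops_per_mac * count_macs(cfg)


# ---------------------------------------------------------------------------
# budget calibration

@dataclass(frozen=True)
class DatasetShape:
    name: str
    n_bands: int
    n_classes: int
    params_M: float
    flops_M: float


DEFAULT_BUDGETS: tuple[DatasetShape, ...] = (
    DatasetShape("matiwan", 256, 16, 0.295, 33.506),
    DatasetShape("honghu", 270, 19, 0.306, 34.807),
    DatasetShape("longkou", 270, 7, 0.305, 34.806),
)


@dataclass(frozen=True)
class BudgetSpec:
    shapes: tuple[DatasetShape, ...] = DEFAULT_BUDGETS
    patch_size: int = 11
    tolerance_params_M: float = 0.0005

    def __post_init__(self) -> None:
        if self.tolerance_params_M <= 0:
            raise ValueError("tolerance must be > 0")
        if not self.shapes:
            raise ValueError("need at least one dataset shape")


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationResult:
    stage_width: int
    pyramid_width: int
    max_abs_dev_M: float
    per_dataset: dict
    flops_per_mac: int = FLOPS_PER_MAC

    def model_config(self, n_bands: int, n_classes: int,
                     patch_size: int = 11) -> ModelConfig:
        return ModelConfig(n_bands=n_bands, n_classes=n_classes,
                           patch_size=patch_size, stage_width=self.stage_width,
                           pyramid_width=self.pyramid_width)

    def to_json(self, path: Path | str | None = None) -> str:
        payload = {
            "stage_width": self.stage_width,
            "pyramid_width": self.pyramid_width,
            "max_abs_dev_M": self.max_abs_dev_M,
            "flops_convention": f"{self.flops_per_mac} FLOPs per MAC; "
                                "norm/activation ops excluded",
            "per_dataset": self.per_dataset,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _shape_config(w: int, p: int, shape: DatasetShape,
                  patch_size: int) -> ModelConfig:
    return ModelConfig(n_bands=shape.n_bands, n_classes=shape.n_classes,
                       patch_size=patch_size, stage_width=w, pyramid_width=p)


def calibrate_reference_config(
        budgets: BudgetSpec | None = None,
        stage_widths: range | list[int] | None = None,
        pyramid_widths: range | list[int] | None = None,
        n_groups: int = 3) -> CalibrationResult:
    """Pin the unpublished widths to the printed parameter budgets.

    Minimizes the maximum absolute parameter deviation (in M) across all
    dataset shapes simultaneously; fails loudly, reporting the best miss, if
    no candidate lands within tolerance.
    """
    budgets = budgets or BudgetSpec()
    widths = list(stage_widths if stage_widths is not None else range(4, 41))
    pyramids = list(pyramid_widths if pyramid_widths is not None
                    else range(n_groups, 901, n_groups))
    if not widths or not pyramids:
        raise CalibrationError("empty search space")

    best: tuple[float, int, int] | None = None
    for w in widths:
        for p in pyramids:
            dev = max(
                abs(count_params(_shape_config(w, p, shape, budgets.patch_size))
                    / 1e6 - shape.params_M)
                for shape in budgets.shapes)
            if best is None or dev < best[0]:
                best = (dev, w, p)
    dev, w, p = best
    if dev > budgets.tolerance_params_M:
        raise CalibrationError(
            f"no configuration within ±{budgets.tolerance_params_M} M params; "
            f"best miss {dev:.6f} M at stage_width={w}, pyramid_width={p}")

    per_dataset = {}
    for shape in budgets.shapes:
        cfg = _shape_config(w, p, shape, budgets.patch_size)
        params = count_params(cfg)
        flops = count_flops(cfg)
        per_dataset[shape.name] = {
            "n_bands": shape.n_bands,
            "n_classes": shape.n_classes,
            "params": params,
            "params_M": round(params / 1e6, 3),
            "printed_params_M": shape.params_M,
            "flops": flops,
            "flops_M": round(flops / 1e6, 3),
            "printed_flops_M": shape.flops_M,
        }
    return CalibrationResult(stage_width=w, pyramid_width=p, max_abs_dev_M=dev,
                             per_dataset=per_dataset)


def reference_model_config(n_bands: int, n_classes: int,
                           result: CalibrationResult | None = None) -> ModelConfig:
    """Calibrated reference configuration instantiated for one dataset shape."""
    if result is None:
        result = calibrate_reference_config()
    return result.model_config(n_bands, n_classes)


def complexity_report(cfg: ModelConfig, flops_per_mac: int = FLOPS_PER_MAC) -> dict:
    rows = layer_costs(cfg)
    return {
        "flops_convention": f"{flops_per_mac} FLOPs per MAC; norm/activation "
                            "ops excluded",
        "layers": [{"name": n, "params": p, "macs": m} for n, p, m in rows],
        "total_params": sum(p for _, p, _ in rows),
        "total_params_M": round(sum(p for _, p, _ in rows) / 1e6, 3),
        "total_flops": flops_per_mac * sum(m for _, _, m in rows),
        "total_flops_M": round(flops_per_mac * sum(m for _, _, m in rows) / 1e6, 3),
    }
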