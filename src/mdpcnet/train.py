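"""Training loop, prediction, multi-run aggregation and ablation variants.

Training optimizes cross-entropy with Adam over seeded mini-batches of
patches; the per-epoch train loss and validation overall accuracy are
recorded, and either the final or the best-validation checkpoint is returned.
Everything (initialization, data order, dropout) is driven by the configured
seeds, so identical configurations reproduce identical histories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ModelConfig, TrainConfig
from .metrics import MetricsReport, aggregate_runs, compute_metrics
from .model import MdpcNet
from .nn import Adam, cross_entropy
from .sampling import SampleGroup, extract_patches
from .scene import HsiScene, save_label_png

__all__ = ["TrainHistory", "AblationVariant", "train_model", "predict_labels",
           "predict_map", "evaluate_group", "run_ablation", "render_map",
           "ABLATION_ROWS"]


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_epoch: list[int] = field(default_factory=list)
    val_oa: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_oa: float = float("-inf")


@dataclass(frozen=True)
class AblationVariant:
    backbone: str = "mdfem"  # single_1d | single_2d | single_3d | mdfem
    fusion: str = "lpfpm"    # plain_concat_linear | lpfpm

    def __post_init__(self) -> None:
        if self.backbone not in ("single_1d", "single_2d", "single_3d", "mdfem"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.fusion not in ("plain_concat_linear", "lpfpm"):
            raise ValueError(f"unknown fusion {self.fusion!r}")

    def apply(self, cfg: ModelConfig) -> ModelConfig:
        flags = {
            "mdfem": dict(use_1d=True, use_2d=True, use_3d=True),
            "single_1d": dict(use_1d=True, use_2d=False, use_3d=False),
            "single_2d": dict(use_1d=False, use_2d=True, use_3d=False),
            "single_3d": dict(use_1d=False, use_2d=False, use_3d=True),
        }[self.backbone]
        return cfg.variant(fusion=self.fusion, **flags)


# rows of the standard three-row ablation table: per-branch extractors with the
# pyramid, the three-branch backbone without it, and the full model
ABLATION_ROWS: list[tuple[str, list[AblationVariant]]] = [
    ("single_branch+lpfpm", [AblationVariant(f"single_{d}", "lpfpm")
                             for d in ("1d", "2d", "3d")]),
    ("mdfem+plain", [AblationVariant("mdfem", "plain_concat_linear")]),
    ("mdfem+lpfpm", [AblationVariant("mdfem", "lpfpm")]),
]


def _epoch_val_oa(model: MdpcNet, patches: np.ndarray, labels: np.ndarray,
                  batch_size: int) -> float:
    pred = model.predict(patches, batch_size=batch_size)
    return float((pred == labels).mean() * 100.0)


def train_model(scene: HsiScene, group: SampleGroup, model_cfg: ModelConfig,
                train_cfg: TrainConfig) -> tuple[MdpcNet, TrainHistory]:
    """Fit the model on one split group's training pixels."""
    tr_coords, tr_labels = group.coords_and_labels("train")
    va_coords, va_labels = group.coords_and_labels("val")
    present = np.unique(tr_labels)
    expected = np.arange(1, model_cfg.n_classes + 1)
    missing = np.setdiff1d(expected, present)
    if missing.size:
        raise ValueError(f"class(es) {missing.tolist()} absent from the training set")

    train_set = extract_patches(scene, tr_coords, model_cfg.patch_size,
                                labels=tr_labels, group=group)
    val_set = extract_patches(scene, va_coords, model_cfg.patch_size,
                              labels=va_labels, group=group)

    rng = np.random.default_rng(train_cfg.seed)
    model = MdpcNet(model_cfg, rng)
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    history = TrainHistory()
    best_state = model.state()
    n = len(train_set.patches)
    targets0 = train_set.labels - 1  # 0-based for the loss

    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, train_cfg.batch_size):
            idx = order[lo:lo + train_cfg.batch_size]
            model.zero_grad()
            logits = model.forward(train_set.patches[idx], train=True)
            loss, glogits = cross_entropy(logits, targets0[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss!r} "
                    f"(lr={train_cfg.learning_rate}, batch={len(idx)})")
            model.backward(glogits)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))
        if (epoch + 1) % train_cfg.eval_every == 0 or epoch == train_cfg.epochs - 1:
            oa = _epoch_val_oa(model, val_set.patches, val_set.labels,
                               train_cfg.batch_size)
            history.val_epoch.append(epoch)
            history.val_oa.append(oa)
            if oa > history.best_val_oa:
                history.best_val_oa = oa
                history.best_epoch = epoch
                if train_cfg.model_selection == "best_val_oa":
                    best_state = model.state()

    if train_cfg.model_selection == "best_val_oa":
        model.load_state(best_state)
    return model, history


def predict_labels(model: MdpcNet, scene: HsiScene, coords: np.ndarray,
                   group: SampleGroup | None = None,
                   batch_size: int = 32) -> np.ndarray:
    patch_set = extract_patches(scene, coords, model.cfg.patch_size, group=group)
    return model.predict(patch_set.patches, batch_size=batch_size)


def predict_map(model: MdpcNet, scene: HsiScene,
                group: SampleGroup | None = None,
                labeled_only: bool = True, batch_size: int = 32) -> np.ndarray:
    """Class map over the scene: 0 on pixels left unpredicted (unlabeled)."""
    if scene.shape[2] != model.cfg.n_bands:
        raise ValueError(
            f"scene has {scene.shape[2]} bands, model built for {model.cfg.n_bands}")
    coords = (scene.labeled_coords() if labeled_only
              else np.argwhere(np.ones_like(scene.labels, dtype=bool)))
    out = np.zeros_like(scene.labels)
    if len(coords):
        pred = predict_labels(model, scene, coords, group, batch_size)
        out[coords[:, 0], coords[:, 1]] = pred
    return out


def evaluate_group(model: MdpcNet, scene: HsiScene, group: SampleGroup,
                   part: str = "test", batch_size: int = 32) -> MetricsReport:
    coords, labels = group.coords_and_labels(part)
    pred = predict_labels(model, scene, coords, group, batch_size)
    return compute_metrics(labels, pred, model.cfg.n_classes,
                           group_index=group.group_index)


def run_ablation(scene: HsiScene, groups: list[SampleGroup],
                 variants: list[AblationVariant], model_cfg: ModelConfig,
                 train_cfg: TrainConfig) -> dict:
    """One aggregated metrics row per variant, averaged over split groups."""
    rows = {}
    for variant in variants:
        cfg = variant.apply(model_cfg)
        reports: list[MetricsReport] = []
        for group in groups:
            seeded = TrainConfig(**{**train_cfg.__dict__,
                                    "seed": train_cfg.seed + group.group_index})
            model, _ = train_model(scene, group, cfg, seeded)
            reports.append(evaluate_group(model, scene, group))
        key = f"{variant.backbone}+{variant.fusion}"
        rows[key] = aggregate_runs(reports)
    return rows


def ablation_table(rows: dict) -> "object":
    """Rows as a pandas DataFrame with OA/AA/Kappa mean ± std columns."""
    import pandas as pd

    records = []
    for key, agg in rows.items():
        records.append({
            "variant": key,
            "OA": agg["oa"]["formatted"],
            "AA": agg["aa"]["formatted"],
            "Kappa": agg["kappa"]["formatted"],
        })
    return pd.DataFrame.from_records(records).set_index("variant")


def render_map(label_map: np.ndarray, class_colors: list[tuple[int, int, int]],
               path: Path | str) -> Path:
    """Paletted PNG plus a legend JSON sidecar; unlabeled pixels black."""
    path = Path(path)
    out = save_label_png(label_map, class_colors, path)
    legend = {str(i + 1): list(rgb) for i, rgb in enumerate(class_colors)}
    legend["0"] = [0, 0, 0]
    Path(str(path.with_suffix("")) + "_legend.json").write_text(
        json.dumps(legend, indent=2, sort_keys=True))
    return out
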