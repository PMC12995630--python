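"""Limited-sample split protocol and patch extraction.

Splits follow the repeated per-class random draw protocol: for each of
``n_groups`` repetitions, draw ``train_per_class`` and ``val_per_class``
labeled pixels per class without replacement (group ``g`` uses seed
``base_seed + g``), and assign every remaining labeled pixel of that class to
the test set. Classifier inputs are odd-sized square patches centered on the
labeled pixel, with reflect padding at scene borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scene import HsiScene

__all__ = ["SplitSpec", "SampleGroup", "PatchSet", "draw_split_groups",
           "extract_patches"]


@dataclass(frozen=True)
class SplitSpec:
    train_per_class: int = 20
    val_per_class: int = 300
    n_groups: int = 5
    base_seed: int = 0
    standardize: bool = True
    exclude_classes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.train_per_class < 1 or self.val_per_class < 1 or self.n_groups < 1:
            raise ValueError("train_per_class, val_per_class and n_groups must be positive")


@dataclass
class SampleGroup:
    """One repetition's per-class train/val/test pixel index sets."""

    group_index: int
    seed: int
    train_idx: dict[int, np.ndarray]  # class id -> (n, 2) array of (row, col)
    val_idx: dict[int, np.ndarray]
    test_idx: dict[int, np.ndarray]
    band_mean: np.ndarray | None = None  # per-band stats from train pixels
    band_sd: np.ndarray | None = None

    def coords_and_labels(self, part: str) -> tuple[np.ndarray, np.ndarray]:
        """Stack one partition into (coords, labels) arrays, class-ordered."""
        idx = {"train": self.train_idx, "val": self.val_idx,
               "test": self.test_idx}[part]
        coords = [v for _, v in sorted(idx.items())]
        labels = [np.full(len(v), c) for c, v in sorted(idx.items())]
        return (np.concatenate(coords), np.concatenate(labels))


@dataclass
class PatchSet:
    patches: np.ndarray  # (n, s, s, B)
    labels: np.ndarray  # (n,), values in 1..C
    coords: np.ndarray  # (n, 2)


def draw_split_groups(scene: HsiScene, spec: SplitSpec) -> list[SampleGroup]:
    """Draw the seeded repetition groups; errors name any too-small class."""
    need = spec.train_per_class + spec.val_per_class
    class_ids = [c for c in range(1, scene.n_classes + 1)
                 if c not in spec.exclude_classes]
    per_class = {c: scene.labeled_coords(c) for c in class_ids}
    for c, coords in per_class.items():
        if len(coords) < need + 1:
            raise ValueError(
                f"class {c} ({scene.class_names[c - 1]!r}) has {len(coords)} labeled "
                f"pixels; needs > {need} for a {spec.train_per_class}/"
                f"{spec.val_per_class} split with a non-empty test set")
    groups: list[SampleGroup] = []
    for g in range(spec.n_groups):
        seed = spec.base_seed + g
        rng = np.random.default_rng(seed)
        train, val, test = {}, {}, {}
        for c in class_ids:
            coords = per_class[c]
            perm = rng.permutation(len(coords))
            train[c] = coords[perm[:spec.train_per_class]]
            val[c] = coords[perm[spec.train_per_class:need]]
            test[c] = coords[perm[need:]]
        group = SampleGroup(group_index=g, seed=seed, train_idx=train,
                            val_idx=val, test_idx=test)
        if spec.standardize:
            tr_coords, _ = group.coords_and_labels("train")
            spectra = scene.cube[tr_coords[:, 0], tr_coords[:, 1], :]
            group.band_mean = spectra.mean(axis=0)
            group.band_sd = np.maximum(spectra.std(axis=0), 1e-8)
        groups.append(group)
    return groups


def extract_patches(scene: HsiScene, coords: np.ndarray, patch_size: int,
                    labels: np.ndarray | None = None,
                    group: SampleGroup | None = None) -> PatchSet:
    """Cut the s x s x B window around each pixel (reflect padding at borders).

    When ``group`` carries training-pixel band statistics, each band is
    centered and scaled by them (statistics are never recomputed here, so the
    test set cannot leak into them).
    """
    if patch_size % 2 == 0 or patch_size < 1:
        raise ValueError(f"patch_size must be a positive odd integer, got {patch_size}")
    coords = np.asarray(coords)
    rows, cols, _ = scene.shape
    if coords.size and (coords.min() < 0 or coords[:, 0].max() >= rows
                        or coords[:, 1].max() >= cols):
        raise IndexError("coordinate outside the image")
    half = patch_size // 2
    cube = scene.cube
    if group is not None and group.band_mean is not None:
        cube = (cube - group.band_mean) / group.band_sd
    padded = np.pad(cube, [(half, half), (half, half), (0, 0)], mode="reflect") \
        if half > 0 else cube
    n = len(coords)
    bands = cube.shape[2]
    patches = np.empty((n, patch_size, patch_size, bands))
    for i, (r, c) in enumerate(coords):
        patches[i] = padded[r:r + patch_size, c:c + patch_size, :]
    if labels is None:
        labels = scene.labels[coords[:, 0], coords[:, 1]] if n else np.empty(0, int)
    return PatchSet(patches=patches, labels=np.asarray(labels), coords=coords)
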