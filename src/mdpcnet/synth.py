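"""Synthetic parcel-structured hyperspectral scene generator.

Emulates agricultural UAV/airborne scenes of the kind used for limited-sample
crop classification: an irregular patchwork of fields (Voronoi parcels), smooth
per-class reflectance signatures built from Gaussian bumps over the band axis,
multiplicative per-pixel illumination/growth variability (the "same object,
different spectra" phenomenon), optional near-identical class pairs ("different
objects, same spectrum"), mixed pixels along parcel boundaries, and additive
sensor noise.

Everything is deterministic for a fixed recipe seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .scene import HsiScene, default_colors

__all__ = ["SceneRecipe", "ClassSignatureSet", "make_signatures", "render_scene",
           "easy_recipe"]


@dataclass(frozen=True)
class SceneRecipe:
    """Full description of a synthetic scene draw.

    ``separation`` is the target mean spectral L2 distance between class
    signatures (reflectance units); ``intra_class_cv`` the coefficient of
    variation of the per-pixel lognormal illumination factor; ``noise_sd`` the
    additive Gaussian sensor noise; ``boundary_mix_width`` the pixel distance
    from a parcel edge within which spectra are convex mixtures of the two
    adjacent classes (labels keep the Voronoi owner).
    """

    rows: int = 64
    cols: int = 64
    n_bands: int = 40
    n_classes: int = 4
    n_parcels: int = 24
    seed: int = 0
    signature_bumps: int = 5
    separation: float = 1.0
    intra_class_cv: float = 0.1
    confusable_pairs: tuple[tuple[int, int], ...] = ()
    boundary_mix_width: int = 1
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.n_parcels < self.n_classes:
            raise ValueError("n_parcels must be >= n_classes")
        if self.n_parcels > self.rows * self.cols:
            raise ValueError("n_parcels exceeds pixel count")
        if min(self.separation, self.intra_class_cv, self.noise_sd) < 0:
            raise ValueError("separation, intra_class_cv, noise_sd must be >= 0")
        if self.boundary_mix_width < 0:
            raise ValueError("boundary_mix_width must be >= 0")
        if self.n_bands < self.signature_bumps:
            raise ValueError("n_bands must be >= signature_bumps")
        for a, b in self.confusable_pairs:
            if not (1 <= a <= self.n_classes and 1 <= b <= self.n_classes) or a == b:
                raise ValueError(f"invalid confusable pair ({a}, {b})")


def easy_recipe(seed: int = 0) -> SceneRecipe:
    """High-separation, low-noise recipe used for behavioral floors.

    30x30 pixels, 40 bands, 4 classes — small enough that a full train/predict
    cycle runs in seconds, easy enough that a sound classifier should recover
    the parcels almost perfectly from 20 training pixels per class.
    """
    return SceneRecipe(rows=30, cols=30, n_bands=40, n_classes=4, n_parcels=12,
                      seed=seed, separation=1.5, intra_class_cv=0.05,
                      confusable_pairs=(), boundary_mix_width=1, noise_sd=0.01)


@dataclass(frozen=True)
class ClassSignatureSet:
    signatures: np.ndarray  # (n_classes, n_bands), non-negative reflectance
    seed: int


def _bump_signature(rng: np.random.Generator, n_bands: int, n_bumps: int,
                    amplitude: float) -> np.ndarray:
    """Smooth non-negative spectrum: baseline plus Gaussian bumps over bands."""
    x = np.linspace(0.0, 1.0, n_bands)
    sig = 0.15 + 0.1 * x * rng.uniform(0.5, 1.5)  # gentle sloping baseline
    centers = rng.uniform(0.0, 1.0, size=n_bumps)
    widths = rng.uniform(0.03, 0.2, size=n_bumps)
    heights = rng.uniform(0.3, 1.0, size=n_bumps) * amplitude
    for c, w, h in zip(centers, widths, heights):
        sig = sig + h * np.exp(-0.5 * ((x - c) / w) ** 2)
    return sig


def make_signatures(recipe: SceneRecipe) -> ClassSignatureSet:
    """Draw per-class signatures with the requested confusability structure.

    Mean pairwise distance is rescaled to ``separation``; classes listed in
    ``confusable_pairs`` differ only by a perturbation of magnitude
    ``separation / 10``.
    """
    rng = np.random.default_rng(recipe.seed)
    # amplitude in rough proportion to the requested separation so the rescale
    # below is mild; degenerate separation = 0 collapses everything later
    amp = max(recipe.separation, 1e-3)
    sigs = np.stack([
        _bump_signature(rng, recipe.n_bands, recipe.signature_bumps, amp)
        for _ in range(recipe.n_classes)
    ])
    mean = sigs.mean(axis=0, keepdims=True)
    centered = sigs - mean
    dists = [np.linalg.norm(centered[i] - centered[j])
             for i in range(recipe.n_classes) for j in range(i + 1, recipe.n_classes)]
    mean_dist = float(np.mean(dists))
    scale = recipe.separation / mean_dist if mean_dist > 0 else 0.0
    sigs = mean + centered * scale
    for a, b in recipe.confusable_pairs:
        bump = _bump_signature(rng, recipe.n_bands, recipe.signature_bumps, 1.0)
        bump = bump / max(np.linalg.norm(bump), 1e-12)
        sigs[b - 1] = sigs[a - 1] + bump * (recipe.separation / 10.0)
    sigs = np.clip(sigs, 0.0, None)
    return ClassSignatureSet(signatures=sigs, seed=recipe.seed)


def _voronoi_labels(recipe: SceneRecipe, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parcel map from seeded points; returns (labels, owner distance gap, runner-up class)."""
    n_px = recipe.rows * recipe.cols
    sites = rng.choice(n_px, size=recipe.n_parcels, replace=False)
    sr, sc = np.divmod(sites, recipe.cols)
    # round-robin class assignment then shuffled: every class appears >= once
    parcel_class = np.arange(recipe.n_parcels) % recipe.n_classes + 1
    rng.shuffle(parcel_class)
    rr, cc = np.meshgrid(np.arange(recipe.rows), np.arange(recipe.cols), indexing="ij")
    d2 = ((rr[..., None] - sr) ** 2 + (cc[..., None] - sc) ** 2).astype(float)
    order = np.argsort(d2, axis=-1)
    nearest = order[..., 0]
    labels = parcel_class[nearest]
    # distance to the nearest parcel with a different class (for boundary mixing)
    own_d = np.sqrt(np.take_along_axis(d2, nearest[..., None], axis=-1)[..., 0])
    other_class = parcel_class[order]  # classes in increasing-distance order
    other_d = np.sqrt(np.take_along_axis(d2, order, axis=-1))
    diff = other_class != labels[..., None]
    first_diff = diff.argmax(axis=-1)
    runner_class = np.take_along_axis(other_class, first_diff[..., None], axis=-1)[..., 0]
    runner_d = np.take_along_axis(other_d, first_diff[..., None], axis=-1)[..., 0]
    gap = (runner_d - own_d) / 2.0  # approx. distance to the class boundary
    return labels, gap, runner_class


def render_scene(recipe: SceneRecipe) -> HsiScene:
    """Materialize a recipe into a validated :class:`HsiScene`."""
    rng = np.random.default_rng(recipe.seed)
    sigs = make_signatures(recipe).signatures
    labels, boundary_gap, runner = _voronoi_labels(recipe, rng)

    base = sigs[labels - 1]  # (rows, cols, bands)
    if recipe.boundary_mix_width > 0:
        w = recipe.boundary_mix_width
        # mixing weight rises towards the boundary; the label keeps the owner
        alpha = np.clip(0.5 * (1.0 - boundary_gap / w), 0.0, 0.5)
        base = (1.0 - alpha[..., None]) * base + alpha[..., None] * sigs[runner - 1]

    if recipe.intra_class_cv > 0:
        cv = recipe.intra_class_cv
        sigma2 = np.log(1.0 + cv ** 2)
        gain = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2),
                             size=labels.shape)
    else:
        gain = np.ones(labels.shape)
    cube = base * gain[..., None]
    if recipe.noise_sd > 0:
        cube = cube + rng.normal(0.0, recipe.noise_sd, size=cube.shape)

    names = [f"crop_{i}" for i in range(1, recipe.n_classes + 1)]
    return HsiScene(cube=cube, labels=labels, class_names=names,
                    class_colors=default_colors(recipe.n_classes),
                    provenance=f"synthetic:seed={recipe.seed}")


def with_seed(recipe: SceneRecipe, seed: int) -> SceneRecipe:
    """Same recipe, different random draw."""
    return replace(recipe, seed=seed)
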