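# mdpcnet

Limited-sample crop classification for hyperspectral imagery.

Mapping crops from airborne or UAV hyperspectral cubes runs into two
confusions at once: the same crop shows different spectra (illumination,
growth stage), and different crops show nearly the same spectrum (e.g.
morphologically close vegetables). With only tens of labeled pixels per class,
classifiers must exploit spectral *and* spatial context without overfitting.
`mdpcnet` implements MDPC-Net, a compact network for exactly this regime, plus
everything needed to study it reproducibly: the limited-sample split protocol,
OA/AA/kappa evaluation, closed-form complexity accounting, and a synthetic
parcel-scene generator so nothing depends on external downloads.

## The model

For each labeled pixel an `11 x 11 x B` patch is classified by:

1. **Three-branch dilated-convolution backbone** — a 1-D branch on the center
   spectrum, a 2-D spatial branch with bands as input channels, and a 3-D
   spectral–spatial branch. Each branch runs four parallel convolution stages
   with base kernel 3 and dilation factors (1, 2, 3, 6), producing receptive
   fields R = (3, 7, 13, 25) via R_{m+1} = R_m + (L_{m+1} − 1)·∏S_i with
   effective kernels L = l + (l − 1)(d − 1) — a multi-scale pyramid at no
   extra parameter cost.
2. **Linear-projection feature pyramid** — branch outputs are flattened into
   one position sequence, projected channel-wise, split into three channel
   groups processed by depthwise convolutions at three scales (original,
   downsampled, upsampled), and fused by a pointwise convolution. The
   depthwise–pointwise pair costs ω_DPC/ω_s = 1/C_out + 1/K² of a standard
   convolution.
3. **Compact Transformer head** — two learned projections compress the
   sequence to 4 tokens of dimension 64; a class token is prepended; one
   pre-norm encoder block (8 heads, MLP hidden 8, dropout 0.1) feeds a linear
   classifier on the class token.

Evaluation follows the limited-sample protocol: per class, 20 (or 100)
training and 300 validation pixels drawn at random, the rest as test, five
seeded repetitions, metrics reported as mean ± std of OA, AA and Cohen's
kappa = (OA/100 − p_e)/(1 − p_e) with p_e = Σ n_i·m_i / N².

The network is implemented directly in numpy (explicit forward/backward
passes, Adam), validated against finite-difference gradients; no deep-learning
framework is required.

## Worked example

```python
import numpy as np
from mdpcnet import (SceneRecipe, render_scene, SplitSpec, draw_split_groups,
                     ModelConfig, TrainConfig, train_model, evaluate_group,
                     scene_summary)

recipe = SceneRecipe(rows=24, cols=24, n_bands=24, n_classes=3, n_parcels=8,
                     seed=0, separation=1.2, intra_class_cv=0.05,
                     noise_sd=0.02, boundary_mix_width=1)
scene = render_scene(recipe)
print("counts:", scene_summary(scene).per_class_pixel_counts)

spec = SplitSpec(train_per_class=20, val_per_class=30, n_groups=1, base_seed=0)
group = draw_split_groups(scene, spec)[0]

cfg = ModelConfig(n_bands=24, n_classes=3, patch_size=11,
                  stage_width=4, pyramid_width=24)
tcfg = TrainConfig(epochs=40, learning_rate=1e-3, batch_size=32, seed=0,
                   eval_every=10)
model, history = train_model(scene, group, cfg, tcfg)
report = evaluate_group(model, scene, group)
print(f"test OA {report.oa:.2f}%  AA {report.aa:.2f}%  kappa {report.kappa:.4f}")
```

prints (about a minute on one CPU):

```
counts: [162, 248, 166]
test OA 87.56%  AA 89.13%  kappa 0.8088
```

The scene has three crops on eight Voronoi parcels with mixed boundary pixels
and 5% multiplicative spectral variability; trained on 20 pixels per class,
the model classifies the ~500 held-out pixels with 87.6% overall accuracy,
89.1% mean per-class accuracy, and chance-corrected agreement 0.81. Easier
recipes (higher separation, less mixing) reach well above 90% — the test
suite's recovery study asserts OA ≥ 90 on `easy_recipe()` with 100 epochs.

The same pipeline is scriptable from the shell:

```bash
mdpcnet generate recipe.yaml --out scene.npz
mdpcnet split scene.npz split.yaml --out splits.json
mdpcnet train scene.npz --model-config model.yaml --out-dir run/
mdpcnet ablate scene.npz --train-config quick.yaml --out-dir ablation/
mdpcnet complexity model.yaml
mdpcnet calibrate
```

Scenes are read from ENVI (hdr + raw, any interleave), GeoTIFF, MAT
containers, or the package's lossless `.npz` archive; label maps render to
paletted PNG with a JSON legend.

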