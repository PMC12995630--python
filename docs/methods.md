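# Methods

`mdpcnet` implements a patch-based spectral–spatial classifier for
hyperspectral cropland imagery under limited-sample conditions, together with
the evaluation protocol, complexity accounting and a synthetic scene generator
that the tests and examples run on. This note records the model, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Model

The classification unit is the `s x s x B` reflectance patch centered on a
labeled pixel (default `s = 11`); the label belongs to the center pixel.

**Backbone (three-branch progressive dilated convolution).** Three parallel
branches extract features of different dimensionality:

* a 1-D branch convolving the center pixel's spectrum (length `B`, one input
  channel);
* a 2-D branch convolving the patch spatially with the `B` bands as input
  channels;
* a 3-D branch convolving the full `1 x B x s x s` volume jointly.

Each branch applies four dilated convolution stages *in parallel* to the
branch input and concatenates their outputs along the channel axis. The
dilation schedule is quoted as inserted-zero counts `[0, 1, 2, 5]` and
implemented as dilation factors `[1, 2, 3, 6]` with base kernel 3, so the
effective kernel extents are 3, 5, 7 and 13 and the receptive fields of the
stage sequence form the strict pyramid 3, 7, 13, 25 (by the standard
receptive-field recursion at stride 1). A rate of 0 taken literally in the
effective-kernel formula would collapse the kernel to a single tap; the
inserted-zero reading keeps four distinct scales and is the conventional way
such schedules are quoted. Dilation adds no parameters: a dilated stage has
exactly the parameter count of its undilated counterpart, which the tests
assert.

Every convolution is stride-1, "same" zero-padded, and followed by batch
normalization and ReLU. With the factor-6 stage the effective kernel (13)
exceeds an 11-pixel axis; this is legal under "same" padding and is surfaced
in the build log rather than treated as an error.

**Sequence assembly.** Branch outputs are flattened into one position
sequence in branch-major order: the 1-D branch contributes `B` spectral
positions laid out as a 1-pixel-wide strip, the 2-D branch its `s x s` grid,
and the 3-D branch its `s x s` grid after mean-pooling over the spectral
axis. Every position carries the same channel count (4 stages x stage width
`w`), which is what makes a single channel-wise fusion map well defined. The
spectral pooling of the 3-D branch is a design choice: it gives the 3-D
branch the same flattened length as the 2-D branch (e.g. 3872 elements at
`w = 8`, `s = 11`) so the three branches contribute comparably sized feature
blocks rather than the 3-D branch dominating by a factor of `B`.

**Feature pyramid (linear projection + multi-scale depthwise fusion).** The
sequence is projected channel-wise (`4w -> P`, the pyramid width), split into
`N = 3` equal channel groups bound one-to-one to three receptive scales:

* group 1: depthwise 3x3 at the original resolution;
* group 2: average-pool down by 2 (edge padding on odd extents), depthwise,
  nearest-neighbor upsample back;
* group 3: bilinear upsample by 2, depthwise, average-pool back.

The groups are re-concatenated and fused by a pointwise (1x1) convolution to
the model dimension `D = 64`. Depthwise kernels are shared across the three
spatial segments of the sequence (the strip and the two grids), each of which
is reshaped to its own 2-D layout before the spatial operators run. Three
groups are used because exactly three scales are named; identifying the split
count with the scale count avoids a free parameter. The resampling operators
are fixed (parameter-free) and their backward passes are exact transposes.

The ablation alternative `plain_concat_linear` replaces the pyramid by a
single channel-wise linear map `4w -> D` on the same sequence.

**Transformer head.** Two learned projections tokenize the sequence: matrix A
(`D -> 4`, softmax-normalized over positions) mixes positions into 4 tokens,
matrix B (`D -> D`) maps features to the token dimension; a learnable class
token is prepended, giving 5 tokens of dimension 64. One pre-norm encoder
block follows — `x + MHSA(LN(x))` then `x + MLP(LN(x))` — with 8 attention
heads (head dim 8), MLP hidden width 8 with ReLU, and dropout 0.1 active only
in training mode. Logits are an affine map of the class token after a final
layer normalization. No positional embedding is used: the tokens are global
learned mixtures of positions, not spatial patches (a config flag reserves
the option). Residual connections are assumed around both sub-blocks, the
standard arrangement for a pre-norm encoder.

## Training protocol

Splits follow the limited-sample protocol: per class, draw `train_per_class`
(20 or 100) and `val_per_class` (300) pixels without replacement, the
remainder is the test set; five repetition groups by default, group `g`
seeded with `base_seed + g` so each repetition is individually reproducible.
Repetitions redraw both the sample groups and the network initialization.
Per-band standardization uses training pixels only and is applied to every
patch, preventing test leakage; it is toggleable. Patches crossing the scene
edge are completed by reflect padding, which avoids injecting zero spectra
(spurious class evidence) at borders. The background label 0 is excluded from
all splits and metrics; an explicitly annotated "others" class is sampled
like any crop class, with a flag to exclude it.

Training uses Adam (default learning rate 1e-4, 500 epochs, batch 64,
cross-entropy) — the optimizer, batch size and loss are standard choices for
this model family; epochs and learning rate follow the published protocol.
Model selection keeps the checkpoint with the best validation overall
accuracy (configurable to `final`). All randomness (initialization, batch
order, dropout) comes from the configured seeds, so identical configurations
produce identical loss histories and metric files.

Metrics are the field's standard trio: overall accuracy, average (per-class
mean) accuracy, and Cohen's kappa computed from the confusion matrix with the
chance-agreement term `p_e = sum_i n_i m_i / N^2`. Aggregates over repetition
groups report mean ± population standard deviation (population, not sample,
so the formatted tables are deterministic functions of the runs).

## Complexity accounting and calibration

`complexity.layer_costs` walks the architecture analytically and lists every
trainable layer with its parameter count and forward multiply–accumulate
(MAC) count for one patch; the analytic parameter count is asserted equal to
exhaustive enumeration of built models. FLOPs are reported as
`2 x MACs` (one multiply plus one add; the factor is switchable), with
normalization, activation and softmax arithmetic excluded. The closed-form
costs of standard vs depthwise-pointwise convolution and their ratio
`1/C_out + 1/K^2` are implemented and cross-checked in exact rational
arithmetic. The depthwise–pointwise cost is implemented in the form whose
ratio simplification is exact; the alternative printed expansion
`(K + C_out) * K * H * W * C_in` is inconsistent with that simplification and
is treated as a typographical slip.

The published record gives parameter/FLOP budgets for three dataset shapes
but not the layer widths. The calibration search recovers them: it scans the
stage-width / pyramid-width grid and minimizes the maximum absolute parameter
deviation across the three shapes simultaneously (token geometry held at its
printed values). The dataset differences identify the configuration
essentially uniquely — only the 2-D branch's first convolution has
band-dependent parameters (36·w per band at kernel 3), so the printed
+14-band budget delta forces `w = 21`, and the absolute level then fixes the
pyramid width `P = 468`. The calibrated builds reproduce all three printed
parameter budgets at three-decimal precision in millions (0.295 / 0.306 /
0.305 M).

The printed FLOP budgets, however, are not reproducible under any counting
convention consistent with those parameter budgets: at `w = 21` the 2-D and
3-D convolution branches alone cost ≈ 99 M MACs per 11x11x270 patch, an
order of magnitude above the printed ≈ 35 M FLOPs, and no width choice can
satisfy both the parameter deltas and the FLOP level for this architecture.
The package reports its honestly computed value (≈ 281 M FLOPs at 2
FLOPs/MAC for the 270-band build) and records the convention in every
report; the corresponding acceptance check is expected to fail and is left
failing rather than fitted.

## Synthetic scene generator

The generator emulates the agricultural scenes this classifier family is
evaluated on: an irregular patchwork of fields (Voronoi tessellation of
seeded points, classes assigned round-robin then shuffled so every class
appears), smooth per-class reflectance signatures (Gaussian bumps over the
band index plus a sloping baseline, rescaled so the mean pairwise signature
distance equals `separation`), multiplicative lognormal per-pixel gain with
coefficient of variation `intra_class_cv` (illumination/growth-stage
variability — "same object, different spectra"), optional near-identical
signature pairs differing by `separation/10` ("different objects, same
spectrum"), convex spectral mixing within `boundary_mix_width` pixels of a
parcel edge (labels keep the Voronoi owner: mixing corrupts features, not
annotations, as in real mixed pixels), and additive Gaussian sensor noise.
Lognormal gain keeps spectra non-negative; Voronoi parcels reproduce
irregular field geometry at negligible cost. Everything is deterministic for
a fixed recipe seed, and a centroid-classifier difficulty check (accuracy
non-increasing in noise, non-decreasing in separation, averaged over five
seeds) is part of the test suite.

What the generator does *not* emulate: physically based radiative transfer,
real crop spectral libraries, sensor artifacts (striping, saturation, band
noise correlation), cloud occlusion, or spatially correlated label noise.
Passing the synthetic-recovery tests therefore demonstrates that the
pipeline learns and evaluates correctly end to end under controlled
confusability — not that field-scale accuracies on real UAV benchmarks are
reproduced; those require the external benchmark scenes and multi-hour
training, which are out of scope here.

## Desk-scale study sizes

The network core is pure numpy (layers with explicit forward/backward passes
validated against central finite differences in float64; float32 is the
default activation dtype). The packaged experiments are sized for a single
CPU: the synthetic-recovery study uses a 30x30x40 scene with 4 classes,
20 training / 30 validation pixels per class, a compact width configuration
(`stage_width = 4`, `pyramid_width = 24`) and 100 training epochs at learning
rate 1e-3, batch 32; the ablation ordering (full backbone vs the mean of the
three single-branch variants, with the pyramid fusion) is evaluated over
three seeded repetition groups at 50 epochs. The calibrated reference widths
(`w = 21`, `P = 468`) are used for complexity accounting, where only
construction and counting — not training — is required.

## Degenerate inputs and tie-breaks

* `separation = 0` with all pairs confusable collapses all signatures to a
  common spectrum (the degenerate limit tests rely on this).
* Class prediction ties resolve to the lowest class index (argmax).
* Band standardization floors the per-band standard deviation at 1e-8.
* Kappa is defined as 1 when the chance-agreement term reaches 1 (perfect
  agreement is the only way to get there).
* A class whose labeled pixel count cannot fill train + validation + at least
  one test pixel aborts the split with the class named; there is no silent
  fallback.
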