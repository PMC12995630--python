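"""Backbone: receptive-field arithmetic and the dilation/zero-stuffing identity."""

import numpy as np
import pytest
from scipy import ndimage

from mdpcnet.config import ModelConfig
from mdpcnet.mdfem import (ConvLayerSpec, DilationStep, Mdfem,
                           effective_kernel_size, receptive_field)
from mdpcnet.nn import ConvNd


class TestEffectiveKernel:
    @pytest.mark.parametrize("l,d,expected", [
        (3, 1, 3),   # no dilation: identity
        (3, 2, 5),
        (1, 6, 1),   # pointwise kernel unaffected
        (3, 6, 13),
        (5, 3, 13),
    ])
    def test_values(self, l, d, expected):
        assert effective_kernel_size(l, d) == expected
        assert DilationStep(l, d).L == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            effective_kernel_size(0, 1)
        with pytest.raises(ValueError):
            effective_kernel_size(3, 0)


class TestReceptiveField:
    def test_single_layer(self):
        assert receptive_field([ConvLayerSpec(kernel=3)]) == [3]

    def test_two_stride1_layers(self):
        layers = [ConvLayerSpec(kernel=3, dilation=1),
                  ConvLayerSpec(kernel=3, dilation=2)]
        assert receptive_field(layers) == [3, 7]

    def test_default_schedule_pyramid(self):
        # iterating R_{m+1} = R_m + (L_{m+1}-1) * prod(S) by hand for the
        # factor schedule (1, 2, 3, 6) at stride 1 gives 3, 7, 13, 25
        layers = [ConvLayerSpec(kernel=3, dilation=d) for d in (1, 2, 3, 6)]
        fields = receptive_field(layers)
        assert fields == [3, 7, 13, 25]
        assert all(b > a for a, b in zip(fields, fields[1:]))

    def test_stride_multiplies_growth(self):
        layers = [ConvLayerSpec(kernel=3, stride=2), ConvLayerSpec(kernel=3)]
        assert receptive_field(layers) == [3, 3 + 2 * 2]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            receptive_field([])


def stuffed_kernel(w: np.ndarray, d: int) -> np.ndarray:
    """Insert d-1 zeros between kernel taps along every axis."""
    out = w
    for axis in range(w.ndim):
        shape = list(out.shape)
        shape[axis] = (shape[axis] - 1) * d + 1
        stuffed = np.zeros(shape, dtype=out.dtype)
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(None, None, d)
        stuffed[tuple(sl)] = out
        out = stuffed
    return out


class TestZeroStuffingEquivalence:
    """A dilated stage equals standard convolution with a zero-stuffed kernel."""

    @pytest.mark.parametrize("ndim,shape", [
        (1, (6,)), (2, (5, 5)), (3, (6, 5, 5)),
    ])
    @pytest.mark.parametrize("dilation", [2, 3])
    def test_equivalence(self, float64_nn, ndim, shape, dilation):
        rng = np.random.default_rng(ndim * 10 + dilation)
        conv = ConvNd(ndim, c_in=2, c_out=3, kernel=3, dilation=dilation,
                      rng=rng, bias=False)
        x = rng.normal(size=(1, 2) + shape)
        got = conv.forward(x)[0]
        expected = np.zeros_like(got)
        for o in range(3):
            acc = np.zeros(shape)
            for c in range(2):
                k = stuffed_kernel(conv.W.data[o, c], dilation)
                acc += ndimage.correlate(x[0, c], k, mode="constant", cval=0.0)
            expected[o] = acc
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_dilation_adds_no_parameters(self, rng):
        plain = ConvNd(2, 4, 8, 3, dilation=1, rng=rng)
        dilated = ConvNd(2, 4, 8, 3, dilation=6, rng=rng)
        assert plain.n_params() == dilated.n_params()


class TestMdfemContracts:
    def test_output_shapes(self, rng):
        cfg = ModelConfig(n_bands=20, n_classes=4, patch_size=11,
                          stage_width=8, pyramid_width=48)
        backbone = Mdfem(cfg, rng)
        patches = rng.normal(size=(3, 11, 11, 20))
        triple = backbone.forward(patches.astype(np.float32))
        assert triple.x1d.shape == (3, 32, 20)
        assert triple.x2d.shape == (3, 32, 11, 11)
        assert triple.x3d.shape == (3, 32, 20, 11, 11)

    def test_oversized_effective_kernel_logged_not_fatal(self, rng):
        # factor-6 stage: effective kernel 13 > 11-pixel axis, handled by
        # "same" zero padding and surfaced in the build log
        cfg = ModelConfig(n_bands=20, n_classes=4, patch_size=11,
                          stage_width=2, pyramid_width=6, model_dim=8,
                          n_heads=2)
        backbone = Mdfem(cfg, rng)
        assert any("effective kernel 13" in line for line in backbone.build_log)

    def test_zero_input_zero_biases_gives_zero_triple(self, rng):
        cfg = ModelConfig(n_bands=10, n_classes=3, patch_size=5,
                          stage_width=2, pyramid_width=6, model_dim=8,
                          n_heads=2)
        backbone = Mdfem(cfg, rng)
        # evaluation-mode BN with zero shift and unit running stats is the
        # identity, so ReLU(conv(0) + 0) = 0 everywhere
        triple = backbone.forward(np.zeros((2, 5, 5, 10), dtype=np.float32),
                                  train=False)
        for arr in (triple.x1d, triple.x2d, triple.x3d):
            np.testing.assert_array_equal(arr, 0.0)

    def test_band_mismatch_rejected(self, rng):
        cfg = ModelConfig(n_bands=10, n_classes=3, patch_size=5,
                          stage_width=2, pyramid_width=6, model_dim=8,
                          n_heads=2)
        backbone = Mdfem(cfg, rng)
        with pytest.raises(ValueError, match="does not match build"):
            backbone.forward(np.zeros((2, 5, 5, 9), dtype=np.float32))

    def test_batch_dimension_preserved(self, rng):
        cfg = ModelConfig(n_bands=6, n_classes=3, patch_size=5, stage_width=2,
                          pyramid_width=6, model_dim=8, n_heads=2)
        backbone = Mdfem(cfg, rng)
        triple = backbone.forward(
            rng.normal(size=(7, 5, 5, 6)).astype(np.float32))
        assert triple.x1d.shape[0] == triple.x2d.shape[0] == 7


class TestDilationProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.integers(1, 15), st.integers(1, 12))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_effective_kernel_bounds_and_monotonicity(self, l, d):
        L = effective_kernel_size(l, d)
        assert L >= l
        assert (L == l) == (d == 1 or l == 1)
        assert effective_kernel_size(l, d + 1) >= L

    @given(st.lists(st.integers(1, 6), min_size=1, max_size=6))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_receptive_field_non_decreasing(self, dilations):
        layers = [ConvLayerSpec(kernel=3, dilation=d) for d in dilations]
        fields = receptive_field(layers)
        assert all(b >= a for a, b in zip(fields, fields[1:]))
        assert fields[0] == layers[0].effective_kernel
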