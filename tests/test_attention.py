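"""Attention blocks, residual fusion and bilinear resize against oracles."""

import numpy as np
import pytest

from tscnna import autodiff as ad
from tscnna.attention import (
    ChannelAttentionParams,
    ResidualFusionParams,
    SpatialAttentionParams,
    apply_attention,
    apply_attention_t,
    bilinear_resize,
    channel_attention,
    channel_pools,
    combine,
    residual_fuse,
    residual_fuse_t,
    spatial_attention,
)
from tscnna.autodiff import Tensor


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _random_ca(rng, c, r):
    return ChannelAttentionParams(
        rng.normal(size=(c // r, c)), rng.normal(size=(c, c // r)), r
    )


def _random_sa(rng):
    return SpatialAttentionParams(rng.normal(size=(7, 7, 2, 1)) * 0.3, float(rng.normal()))


class TestChannelPools:
    def test_constant_channels(self):
        f = np.stack([np.full((3, 4), v) for v in (1.0, -2.0, 7.0)], axis=2)
        avg, mx = channel_pools(f)
        np.testing.assert_allclose(avg, [1.0, -2.0, 7.0])
        np.testing.assert_allclose(mx, [1.0, -2.0, 7.0])

    def test_single_channel_example(self):
        f = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        avg, mx = channel_pools(f)
        assert avg[0] == pytest.approx(2.5)
        assert mx[0] == 4.0

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            h, w, c = rng.integers(1, 8, size=3)
            f = rng.normal(size=(h, w, c))
            avg, mx = channel_pools(f)
            for ch in range(c):
                vals = [f[i, j, ch] for i in range(h) for j in range(w)]
                assert avg[ch] == pytest.approx(sum(vals) / len(vals), abs=1e-12)
                assert mx[ch] == max(vals)


class TestChannelAttention:
    def test_zero_weights_give_half(self, rng):
        c, r = 4, 2
        params = ChannelAttentionParams(np.zeros((c // r, c)), np.zeros((c, c // r)), r)
        out = channel_attention(rng.normal(size=(3, 3, c)), params)
        np.testing.assert_allclose(out, 0.5)

    def test_hand_worked_two_channel(self):
        # C=2, r=1: reduce/expand are 2×2; constant map makes avg == max
        reduce = np.array([[1.0, 0.0], [0.0, -1.0]])
        expand = np.array([[2.0, 1.0], [0.5, 0.0]])
        params = ChannelAttentionParams(reduce, expand, 1)
        f = np.stack([np.full((2, 2), 3.0), np.full((2, 2), -1.0)], axis=2)
        pooled = np.array([3.0, -1.0])  # avg == max
        hidden = np.maximum(reduce @ pooled, 0)
        want = _sigmoid(2 * (expand @ hidden))
        np.testing.assert_allclose(channel_attention(f, params), want, rtol=1e-12)

    def test_output_strictly_in_unit_interval(self, rng):
        # moderate magnitudes: float64 sigmoid saturates to exactly 0/1 beyond ~|37|
        for _ in range(20):
            c = int(rng.choice([2, 4, 8]))
            params = ChannelAttentionParams(
                rng.normal(size=(c // 2, c)) * 0.5, rng.normal(size=(c, c // 2)) * 0.5, 2
            )
            out = channel_attention(rng.normal(size=(5, 5, c)), params)
            assert ((out > 0) & (out < 1)).all()

    def test_shared_mlp_processes_both_pools(self, rng):
        """M_C = σ(MLP(avg) + MLP(max)) with the same weights for both."""
        c, r = 4, 2
        params = _random_ca(rng, c, r)
        f = rng.normal(size=(6, 5, c))
        avg, mx = channel_pools(f)

        def mlp(v):
            return params.expand @ np.maximum(params.reduce @ v, 0)

        np.testing.assert_allclose(
            channel_attention(f, params), _sigmoid(mlp(avg) + mlp(mx)), rtol=1e-10
        )


class TestSpatialAttention:
    def test_zero_kernel_gives_half(self, rng):
        params = SpatialAttentionParams(np.zeros((7, 7, 2, 1)), 0.0)
        out = spatial_attention(rng.normal(size=(5, 6, 3)), params)
        np.testing.assert_allclose(out, 0.5)

    def test_single_channel_mean_equals_max(self, rng):
        f = rng.normal(size=(9, 9, 1))
        params = _random_sa(rng)
        # with one channel, the cross-channel mean and max maps are both F
        stacked = np.concatenate([f, f], axis=2)
        want = _sigmoid(
            conv_same(stacked, params.kernel[:, :, :, 0]) + params.bias
        )
        np.testing.assert_allclose(spatial_attention(f, params), want, rtol=1e-10)

    def test_matches_loop_oracle(self, rng):
        for _ in range(30):
            h, w = rng.integers(2, 10, size=2)
            c = int(rng.integers(1, 5))
            f = rng.normal(size=(h, w, c))
            params = _random_sa(rng)
            mean_map = f.mean(axis=2)
            max_map = f.max(axis=2)
            stacked = np.stack([mean_map, max_map], axis=2)
            want = _sigmoid(conv_same(stacked, params.kernel[:, :, :, 0]) + params.bias)
            np.testing.assert_allclose(spatial_attention(f, params), want, rtol=1e-10)


def conv_same(x, kernel):
    """Direct same-padded correlation of H×W×C with a kh×kw×C kernel."""
    kh, kw, _ = kernel.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((ph, ph), (pw, pw), (0, 0)))
    h, w = x.shape[:2]
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = (xp[i : i + kh, j : j + kw, :] * kernel).sum()
    return out


class TestApplyAttention:
    def test_zero_weight_params_halve_the_map(self, rng):
        c = 4
        cp = ChannelAttentionParams(np.zeros((2, c)), np.zeros((c, 2)), 2)
        sp = SpatialAttentionParams(np.zeros((7, 7, 2, 1)), 0.0)
        f = rng.normal(size=(5, 5, c))
        f1, f2 = apply_attention(f, cp, sp)
        np.testing.assert_allclose(f1, 0.5 * f, rtol=1e-12)
        np.testing.assert_allclose(f2, 0.25 * f, rtol=1e-12)

    def test_zero_input_stays_zero(self, rng):
        c = 4
        f1, f2 = apply_attention(np.zeros((4, 4, c)), _random_ca(rng, c, 2), _random_sa(rng))
        assert (f1 == 0).all() and (f2 == 0).all()

    def test_composition_matches_individual_ops(self, rng):
        for _ in range(30):
            c = int(rng.choice([2, 4]))
            f = rng.normal(size=(rng.integers(2, 7), rng.integers(2, 7), c))
            cp, sp = _random_ca(rng, c, 2), _random_sa(rng)
            f1, f2 = apply_attention(f, cp, sp)
            mc = channel_attention(f, cp)
            want_f1 = f * mc[None, None, :]
            ms = spatial_attention(want_f1, sp)
            np.testing.assert_allclose(f1, want_f1, rtol=1e-10)
            np.testing.assert_allclose(f2, want_f1 * ms[:, :, None], rtol=1e-10)

    def test_never_amplifies_magnitudes(self, rng):
        c = 4
        f = rng.normal(size=(6, 6, c)) * 5
        f1, f2 = apply_attention(f, _random_ca(rng, c, 2), _random_sa(rng))
        assert (np.abs(f1) <= np.abs(f) + 1e-12).all()
        assert (np.abs(f2) <= np.abs(f1) + 1e-12).all()


class TestResidualFuse:
    def test_zero_inputs_give_constant_offset(self):
        out = residual_fuse(np.zeros((3, 4, 2)), np.zeros((3, 4, 2)))
        np.testing.assert_allclose(out, 0.0001)

    def test_hand_worked_elements(self):
        out = residual_fuse(np.array([[[1.0]]]), np.array([[[2.0]]]))
        assert out[0, 0, 0] == pytest.approx(5.0001)
        out = residual_fuse(np.array([[[-1.0]]]), np.array([[[3.0]]]))
        assert out[0, 0, 0] == pytest.approx(2.0001)

    def test_symmetry(self, rng):
        for _ in range(100):
            shape = tuple(rng.integers(1, 5, size=3))
            x, y = rng.normal(size=shape), rng.normal(size=shape)
            np.testing.assert_allclose(residual_fuse(x, y), residual_fuse(y, x), atol=1e-12)

    def test_matches_elementwise_oracle(self, rng):
        xi = 0.0001
        for _ in range(100):
            shape = tuple(rng.integers(1, 4, size=3))
            x, y = rng.normal(size=shape), rng.normal(size=shape)
            want = np.empty(shape)
            for idx in np.ndindex(shape):
                want[idx] = x[idx] + y[idx] + max(x[idx], 0) * max(y[idx], 0) + xi
            np.testing.assert_allclose(residual_fuse(x, y), want, atol=1e-12)

    def test_spatial_harmonization_by_resize(self, rng):
        x = rng.normal(size=(4, 4, 2))
        y_small = rng.normal(size=(2, 2, 2))
        out = residual_fuse(x, y_small)
        assert out.shape == (4, 4, 2)

    def test_channel_mismatch_without_projection_rejected(self, rng):
        with pytest.raises(ValueError, match="projection"):
            residual_fuse(rng.normal(size=(4, 4, 2)), rng.normal(size=(4, 4, 3)))

    def test_nonpositive_offset_rejected(self):
        with pytest.raises(ValueError):
            ResidualFusionParams(offset=0.0)


class TestCombine:
    def test_zero_cases(self, rng):
        f2 = rng.normal(size=(3, 3, 2))
        np.testing.assert_allclose(combine(f2, np.zeros_like(f2)), f2)
        np.testing.assert_allclose(combine(np.zeros_like(f2), f2), f2)

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            shape = tuple(rng.integers(1, 5, size=3))
            a, b = rng.normal(size=shape), rng.normal(size=shape)
            np.testing.assert_allclose(combine(a, b), a + b, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            combine(rng.normal(size=(2, 2, 1)), rng.normal(size=(3, 2, 1)))


class TestBilinearResize:
    def test_same_size_is_identity(self, rng):
        f = rng.normal(size=(5, 7, 3))
        np.testing.assert_allclose(bilinear_resize(f, 5, 7), f)

    def test_constant_stays_constant(self):
        f = np.full((3, 3, 2), 1.75)
        out = bilinear_resize(f, 8, 5)
        np.testing.assert_allclose(out, 1.75)

    def test_two_by_two_to_four_by_four_closed_form(self):
        f = np.array([[0.0, 1.0], [2.0, 3.0]])
        out = bilinear_resize(f, 4, 4)
        # source coords (align-corners-false): (i+0.5)/2 − 0.5 → [0,.25,.75,1] clamped
        src = np.clip((np.arange(4) + 0.5) * 0.5 - 0.5, 0, 1)
        want = src[:, None] * 2 + src[None, :]
        np.testing.assert_allclose(out, want, atol=1e-12)

    def test_matches_pointwise_oracle(self, rng):
        for _ in range(50):
            h, w = rng.integers(1, 7, size=2)
            oh, ow = rng.integers(1, 9, size=2)
            f = rng.normal(size=(h, w))
            out = bilinear_resize(f, oh, ow)
            for i in range(oh):
                for j in range(ow):
                    sy = min(max((i + 0.5) * h / oh - 0.5, 0), h - 1)
                    sx = min(max((j + 0.5) * w / ow - 0.5, 0), w - 1)
                    y0, x0 = int(np.floor(sy)), int(np.floor(sx))
                    y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
                    fy, fx = sy - y0, sx - x0
                    want = (
                        f[y0, x0] * (1 - fy) * (1 - fx) + f[y0, x1] * (1 - fy) * fx
                        + f[y1, x0] * fy * (1 - fx) + f[y1, x1] * fy * fx
                    )
                    assert out[i, j] == pytest.approx(want, abs=1e-10)

    def test_nonpositive_target_rejected(self, rng):
        with pytest.raises(ValueError):
            bilinear_resize(rng.normal(size=(3, 3, 1)), 0, 4)


class TestAttentionChainGradients:
    def test_finite_difference_through_attention_residual_combine(self, rng):
        """Gradient flow through apply_attention → residual_fuse → combine."""
        c, r = 2, 1
        x_data = rng.normal(size=(1, 8, 8, 3))
        conv_w = rng.normal(size=(3, 3, 3, c)) * 0.5
        names = {
            "conv_w": conv_w,
            "reduce": rng.normal(size=(c // r, c)),
            "expand": rng.normal(size=(c, c // r)),
            "kernel": rng.normal(size=(7, 7, 2, 1)) * 0.3,
            "bias": rng.normal(size=1),
            "conv4_w": rng.normal(size=(3, 3, c, c)) * 0.5,
        }

        def run(tensors):
            f = ad.relu(ad.conv2d(Tensor(x_data), tensors["conv_w"], padding="same"))
            f1, f2 = apply_attention_t(
                f, tensors["reduce"], tensors["expand"], tensors["kernel"], tensors["bias"]
            )
            xp = ad.relu(ad.conv2d(f2, tensors["conv4_w"], padding="same"))
            fused = residual_fuse_t(f, xp, 0.0001)
            out = ad.add(f2, fused)
            return ad.mul(out, out)

        tensors = {k: Tensor(v.copy(), requires_grad=True) for k, v in names.items()}
        out = run(tensors)
        out.backward()
        eps = 1e-6
        for name, t in tensors.items():
            for _ in range(3):
                idx = tuple(rng.integers(0, s) for s in t.data.shape)
                orig = t.data[idx]

                def value(v):
                    consts = {k: Tensor(tt.data) for k, tt in tensors.items()}
                    perturbed = t.data.copy()
                    perturbed[idx] = v
                    consts[name] = Tensor(perturbed)
                    return float(run(consts).data.sum())

                fd = (value(orig + eps) - value(orig - eps)) / (2 * eps)
                assert t.grad[idx] == pytest.approx(fd, rel=1e-4, abs=1e-6), name
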