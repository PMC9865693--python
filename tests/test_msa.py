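"""Pyramid pooling and dual attention: identities, normalisation, and a
brute-force recomputation of the attention equations."""

import numpy as np
import pytest

from laseg import nn
from laseg.autodiff import Tensor
from laseg.errors import ConfigurationError
from laseg.msa import MSA, ChannelAttention, PositionAttention, PyramidPool


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestPyramidPool:
    def test_doubles_channel_count(self):
        pool = PyramidPool(16, rng=_rng())
        out = pool(Tensor(_rng(1).random((2, 16, 12, 12), dtype=np.float32)))
        assert out.shape == (2, 32, 12, 12)

    def test_avg_and_max_grids_agree_on_constant_input(self):
        x = Tensor(np.full((1, 4, 8, 8), 3.25, dtype=np.float32))
        for g in (1, 2, 4, 6):
            a = nn.adaptive_avg_pool2d(x, g).data
            m = nn.adaptive_max_pool2d(x, g).data
            assert np.allclose(a, m)

    def test_spatial_size_below_largest_grid_rejected(self):
        pool = PyramidPool(64, rng=_rng())
        with pytest.raises(ConfigurationError, match="grid"):
            pool(Tensor(np.zeros((1, 64, 4, 4), dtype=np.float32)))

    def test_channels_must_divide_reduction(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            PyramidPool(6, rng=_rng())


class TestPositionAttention:
    def test_identity_at_initialisation(self):
        pa = PositionAttention(8, rng=_rng())
        x = _rng(2).normal(size=(2, 8, 6, 6)).astype(np.float32)
        out = pa(Tensor(x)).data
        assert np.abs(out - x).max() < 1e-6

    def test_rows_of_s_sum_to_one(self):
        pa = PositionAttention(8, rng=_rng())
        for seed in range(5):
            x = Tensor(_rng(seed).normal(size=(1, 8, 5, 5)).astype(np.float32))
            s = pa.attention_map(x).data
            assert np.abs(s.sum(axis=2) - 1.0).max() < 1e-5

    def test_equal_similarities_give_uniform_attention(self):
        pa = PositionAttention(4, rng=_rng())
        pa.query.weight.data[:] = 0          # all B.C dot products equal
        x = Tensor(_rng(3).normal(size=(1, 4, 1, 2)).astype(np.float32))
        s = pa.attention_map(x).data[0]
        assert np.allclose(s, [[0.5, 0.5], [0.5, 0.5]])

    def test_large_maps_are_downsampled_but_identity_preserved(self):
        pa = PositionAttention(4, max_grid=8, rng=_rng())
        x = _rng(4).normal(size=(1, 4, 32, 32)).astype(np.float32)
        assert np.abs(pa(Tensor(x)).data - x).max() < 1e-6


class TestChannelAttention:
    def test_identity_at_initialisation(self):
        ca = ChannelAttention()
        x = _rng(5).normal(size=(2, 6, 4, 4)).astype(np.float32)
        assert np.abs(ca(Tensor(x)).data - x).max() < 1e-6

    def test_rows_of_x_sum_to_one(self):
        ca = ChannelAttention()
        for seed in range(5):
            a = Tensor(_rng(seed).normal(size=(1, 6, 4, 4)).astype(np.float32))
            x = ca.attention_map(a).data
            assert np.abs(x.sum(axis=2) - 1.0).max() < 1e-5

    def test_identical_channels_hand_computation(self):
        # two identical channels: X is uniform and E'_j = beta * A_j + A_j
        base = _rng(6).normal(size=(2, 2)).astype(np.float32)
        a = np.stack([base, base])[None]          # (1, 2, 2, 2)
        ca = ChannelAttention()
        ca.beta.data[:] = 0.7
        xmap = ca.attention_map(Tensor(a)).data[0]
        assert np.allclose(xmap, [[0.5, 0.5], [0.5, 0.5]])
        out = ca(Tensor(a)).data
        assert np.allclose(out, 1.7 * a, atol=1e-6)

    def test_permutation_equivariance(self):
        ca = ChannelAttention()
        ca.beta.data[:] = 1.3
        x = _rng(7).normal(size=(1, 5, 4, 4)).astype(np.float32)
        perm = np.array([3, 0, 4, 1, 2])
        out = ca(Tensor(x)).data
        out_perm = ca(Tensor(x[:, perm])).data
        assert np.allclose(out[:, perm], out_perm, atol=1e-5)


class TestBruteForceOracle:
    """Recompute the attention outputs with explicit loops over positions
    and channels and compare against the vectorised implementation."""

    def test_position_attention_matches_double_loop(self):
        pa = PositionAttention(3, proj_ratio=1, rng=_rng(8))
        pa.alpha.data[:] = 0.6
        a = _rng(9).normal(size=(1, 3, 4, 4)).astype(np.float64)
        out = pa(Tensor(a)).data[0]

        def apply_1x1(conv, arr):
            w = conv.weight.data.astype(np.float64)[:, :, 0, 0]
            b = conv.bias.data.astype(np.float64)
            return np.einsum("oc,chw->ohw", w, arr) + b[:, None, None]

        b_map = apply_1x1(pa.query, a[0]).reshape(-1, 16)
        c_map = apply_1x1(pa.key, a[0]).reshape(-1, 16)
        d_map = apply_1x1(pa.value, a[0]).reshape(-1, 16)
        n_pix = 16
        s = np.zeros((n_pix, n_pix))
        for j in range(n_pix):
            e = np.array([np.exp(b_map[:, i] @ c_map[:, j])
                          for i in range(n_pix)])
            s[j] = e / e.sum()
        expected = np.zeros_like(d_map)
        for j in range(n_pix):
            for i in range(n_pix):
                expected[:, j] += s[j, i] * d_map[:, i]
        expected = 0.6 * expected.reshape(3, 4, 4) + a[0]
        assert np.abs(out - expected).max() < 1e-6

    def test_channel_attention_matches_double_loop(self):
        ca = ChannelAttention()
        ca.beta.data[:] = 0.9
        a = _rng(10).normal(size=(1, 3, 4, 4)).astype(np.float64)
        out = ca(Tensor(a)).data[0]

        flat = a[0].reshape(3, -1)
        x = np.zeros((3, 3))
        for j in range(3):
            e = np.array([np.exp(flat[i] @ flat[j]) for i in range(3)])
            x[j] = e / e.sum()
        expected = np.zeros_like(flat)
        for j in range(3):
            for i in range(3):
                expected[j] += x[j, i] * flat[i]
        expected = 0.9 * expected.reshape(3, 4, 4) + a[0]
        assert np.abs(out - expected).max() < 1e-6


class TestMSAModule:
    def test_shape_contract_restores_skip_channels(self):
        msa = MSA(16, max_grid=8, rng=_rng(11))
        out = msa(Tensor(_rng(12).random((1, 16, 16, 16), dtype=np.float32)))
        assert out.shape == (1, 16, 16, 16)

    def test_attention_at_init_reduces_to_projected_pool(self):
        msa = MSA(8, max_grid=8, rng=_rng(13))
        x = Tensor(_rng(14).random((1, 8, 8, 8), dtype=np.float32))
        full = msa(x).data
        expected = msa.project(msa.pool(x)).data
        assert np.abs(full - expected).max() < 1e-6

    def test_gradient_reaches_attention_scales(self):
        msa = MSA(8, max_grid=8, rng=_rng(15))
        x = Tensor(_rng(16).random((1, 8, 8, 8), dtype=np.float32))
        (msa(x) ** 2).sum().backward()
        assert msa.pos.alpha.grad is not None
        assert msa.chan.beta.grad is not None
        assert abs(float(msa.pos.alpha.grad[0])) > 0
        assert abs(float(msa.chan.beta.grad[0])) > 0
        opt = nn.SGD([msa.pos.alpha, msa.chan.beta], lr=0.1)
        opt.step()
        assert float(msa.pos.alpha.data[0]) != 0.0
        assert float(msa.chan.beta.data[0]) != 0.0
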