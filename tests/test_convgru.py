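"""ConvGRU cell and bidirectional wrapper: gate identities, a dense-GRU
oracle at scalar size, and direction symmetries."""

import numpy as np
import pytest

from laseg.autodiff import Tensor
from laseg.convgru import BiConvGRU, ConvGRUCell, run_direction
from laseg.errors import ValidationError


def _cell(in_ch=4, hid=4, kernel=3, seed=0, dtype=np.float32):
    return ConvGRUCell(in_ch, hid, kernel, rng=np.random.default_rng(seed),
                       dtype=dtype)


def _x(shape, seed=1, dtype=np.float32):
    return Tensor(np.random.default_rng(seed).normal(size=shape).astype(dtype))


class TestGruStep:
    def test_update_gate_saturated_high_keeps_candidate(self):
        cell = _cell()
        cell.wz.bias.data[:] = 50.0          # z -> 1 everywhere
        x, h = _x((1, 4, 6, 6)), _x((1, 4, 6, 6), seed=2)
        out = cell.step(x, h).data
        r = (cell.wr(x) + cell.ur(h)).sigmoid()
        cand = (cell.w(x) + cell.u(r * h)).tanh().data
        assert np.abs(out - cand).max() < 1e-6

    def test_update_gate_saturated_low_keeps_previous_state(self):
        cell = _cell()
        cell.wz.bias.data[:] = -50.0         # z -> 0 everywhere
        x, h = _x((1, 4, 6, 6)), _x((1, 4, 6, 6), seed=2)
        assert np.abs(cell.step(x, h).data - h.data).max() < 1e-6

    def test_all_zero_parameters_give_zero_state(self):
        # z = r = sigmoid(0) = 0.5, candidate = tanh(0) = 0,
        # h = 0.5 * 0 + 0.5 * 0 = 0
        cell = _cell()
        for p in cell.parameters():
            p.data[:] = 0.0
        x = _x((1, 4, 6, 6))
        h0 = cell.init_state(x)
        out = cell.step(x, h0).data
        assert np.abs(out).max() == 0.0

    def test_spatial_misalignment_rejected(self):
        cell = _cell()
        with pytest.raises(ValidationError):
            cell.step(_x((1, 4, 6, 6)), _x((1, 4, 5, 5)))

    def test_state_stays_inside_unit_band(self):
        # from h0 = 0, |h_t| < 1 by induction: h is a convex mix of the
        # previous state and a tanh-bounded candidate
        cell = _cell(seed=5)
        seq = [_x((2, 4, 5, 5), seed=s) * 3.0 for s in range(10)]
        states = run_direction(seq, cell)
        for st in states:
            assert np.abs(st.data).max() < 1.0


class TestScalarOracle:
    def test_matches_dense_gru_recurrence(self):
        """At 1x1 spatial size with 1x1 kernels the ConvGRU must reduce
        exactly to the textbook dense GRU, implemented independently."""
        rng = np.random.default_rng(42)
        cell = _cell(in_ch=1, hid=1, kernel=1, seed=7, dtype=np.float64)
        wz = float(cell.wz.weight.data.squeeze())
        uz = float(cell.uz.weight.data.squeeze())
        bz = float(cell.wz.bias.data.squeeze())
        wr = float(cell.wr.weight.data.squeeze())
        ur = float(cell.ur.weight.data.squeeze())
        br = float(cell.wr.bias.data.squeeze())
        w = float(cell.w.weight.data.squeeze())
        u = float(cell.u.weight.data.squeeze())
        b = float(cell.w.bias.data.squeeze())

        def sigmoid(v):
            return 1.0 / (1.0 + np.exp(-v))

        h_ref = 0.0
        h = cell.init_state(Tensor(np.zeros((1, 1, 1, 1))))
        for _ in range(20):
            xv = float(rng.normal())
            z = sigmoid(wz * xv + uz * h_ref + bz)
            r = sigmoid(wr * xv + ur * h_ref + br)
            cand = np.tanh(w * xv + u * (r * h_ref) + b)
            h_ref = (1 - z) * h_ref + z * cand
            h = cell.step(Tensor(np.full((1, 1, 1, 1), xv)), h)
            assert abs(float(h.data.squeeze()) - h_ref) < 1e-10


class TestRunDirection:
    def test_single_step_is_direction_independent(self):
        cell = _cell()
        seq = [_x((1, 4, 6, 6))]
        f = run_direction(seq, cell, reverse=False)[0].data
        b = run_direction(seq, cell, reverse=True)[0].data
        assert (f == b).all()

    def test_reverse_equals_forward_on_reversed_input(self):
        cell = _cell(seed=3)
        seq = [_x((1, 4, 5, 5), seed=s) for s in range(4)]
        rev = run_direction(seq, cell, reverse=True)
        fwd_on_flipped = run_direction(seq[::-1], cell, reverse=False)
        for a, b in zip(rev, fwd_on_flipped[::-1]):
            assert np.allclose(a.data, b.data)

    def test_constant_input_converges_towards_fixed_point(self):
        cell = _cell(seed=9)
        x = _x((1, 4, 5, 5), seed=11)
        states = run_direction([x] * 12, cell)
        diffs = [np.linalg.norm(states[t].data - states[t - 1].data)
                 for t in range(1, 12)]
        assert diffs[-1] < diffs[1]
        assert all(d2 <= d1 + 1e-9 for d1, d2 in zip(diffs[3:], diffs[4:]))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            run_direction([], _cell())


class TestBiConvGRU:
    def test_output_has_twice_hidden_channels(self):
        bi = BiConvGRU(4, 8, rng=np.random.default_rng(0))
        seq = [_x((2, 4, 6, 6), seed=s) for s in range(3)]
        out = bi(seq)
        assert len(out) == 3
        assert all(o.shape == (2, 16, 6, 6) for o in out)

    def test_reversing_input_and_swapping_cells_swaps_halves(self):
        rng = np.random.default_rng(1)
        bi = BiConvGRU(4, 4, rng=rng)
        seq = [_x((1, 4, 5, 5), seed=s) for s in range(4)]
        out = bi(seq)
        swapped = BiConvGRU(4, 4, rng=np.random.default_rng(99))
        swapped.fwd, swapped.bwd = bi.bwd, bi.fwd
        out_swapped = swapped(seq[::-1])
        for a, b in zip(out, out_swapped[::-1]):
            assert np.allclose(a.data[:, :4], b.data[:, 4:], atol=1e-6)
            assert np.allclose(a.data[:, 4:], b.data[:, :4], atol=1e-6)

    def test_palindrome_with_shared_cells_gives_symmetric_middle(self):
        bi = BiConvGRU(4, 4, rng=np.random.default_rng(2))
        bi.bwd.load_state_dict(bi.fwd.state_dict())
        a, b = _x((1, 4, 5, 5), seed=5), _x((1, 4, 5, 5), seed=6)
        out = bi([a, b, a])          # palindromic sequence, middle index 1
        mid = out[1].data
        assert np.allclose(mid[:, :4], mid[:, 4:], atol=1e-6)

    def test_tensor_interface_shape(self):
        bi = BiConvGRU(4, 4, rng=np.random.default_rng(3))
        x = _x((2, 3, 4, 6, 6))
        assert bi.forward_tensor(x).shape == (2, 3, 8, 6, 6)
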