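"""3-D convolutional LSTM: hand-computed steps, scalar-loop oracle, invariants."""

import numpy as np
import pytest

from voxrecon.autodiff import Tensor
from voxrecon.recurrence import ConvLSTM3D, GridState, LSTMConfig, input_transform


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def scalar_lstm_step(x, h, s, params, grid_n, hidden, k):
    """Brute-force per-unit reference: explicit loops over units and channels.

    x: (latent,); h, s: (hidden, N, N, N); params maps W_*/U_*/b_* to arrays.
    Convolution is same-size, zero-padded, stride 1.
    """
    latent = x.shape[0]
    n = grid_n
    pad = k // 2

    def gate(name):
        W, U, b = params[f"W_{name}"], params[f"U_{name}"], params[f"b_{name}"]
        out = np.zeros((hidden, n, n, n))
        wx = (x @ W).reshape(n, n, n, hidden)
        for i in range(n):
            for j in range(n):
                for l in range(n):
                    for c in range(hidden):
                        acc = wx[i, j, l, c] + b[c]
                        for ci in range(hidden):
                            for u in range(k):
                                for v in range(k):
                                    for w in range(k):
                                        ii, jj, ll = i + u - pad, j + v - pad, l + w - pad
                                        if 0 <= ii < n and 0 <= jj < n and 0 <= ll < n:
                                            acc += U[c, ci, u, v, w] * h[ci, ii, jj, ll]
                        out[c, i, j, l] = acc
        return out

    f = _sigmoid(gate("f"))
    i = _sigmoid(gate("i"))
    g = np.tanh(gate("s"))
    s_new = f * s + i * g
    return np.tanh(s_new), s_new


class TestInputTransform:
    def test_zero_latent_gives_zero_grid(self):
        W = Tensor(np.random.default_rng(0).normal(size=(4, 2**3 * 3)))
        out = input_transform(Tensor(np.zeros((1, 4))), W, 2, 3)
        assert out.shape == (1, 3, 2, 2, 2) and np.all(out.data == 0.0)

    def test_scalar_case(self):
        out = input_transform(Tensor(np.array([[1.5]])), Tensor(np.array([[2.0]])), 1, 1)
        assert np.allclose(out.data, 3.0)

    def test_zero_weight_gives_zero_grid(self):
        out = input_transform(Tensor(np.ones((1, 5))), Tensor(np.zeros((5, 8))), 2, 1)
        assert np.all(out.data == 0.0)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            input_transform(Tensor(np.ones((1, 3))), Tensor(np.zeros((5, 8))), 2, 1)


class TestStep:
    def test_zero_params_zero_state_is_fixed_point(self):
        m = ConvLSTM3D(LSTMConfig(grid_n=2, hidden=2, kernel=3, latent_dim=4))
        for p in m.parameters():
            p.data[:] = 0.0
        st = m.run_sequence(np.random.default_rng(0).normal(size=(5, 1, 4)))
        assert np.all(st.h.data == 0.0) and np.all(st.s.data == 0.0)

    def test_hand_computed_single_unit_step(self):
        m = ConvLSTM3D(LSTMConfig(grid_n=1, hidden=1, kernel=1, latent_dim=1))
        for g in "fis":
            m.params[f"W_{g}"].data[:] = 1.0
            m.params[f"U_{g}"].data[:] = 0.0
            m.params[f"b_{g}"].data[:] = 0.0
        st = m.step(Tensor(np.array([[1.0]])), m.zero_state())
        sig1 = _sigmoid(1.0)
        s_expected = sig1 * np.tanh(1.0)  # f*0 + i*tanh(Ws x)
        assert abs(st.s.data.ravel()[0] - s_expected) < 1e-6
        assert abs(st.h.data.ravel()[0] - np.tanh(s_expected)) < 1e-6

    @pytest.mark.parametrize("grid_n,hidden,kernel", [(1, 1, 1), (2, 1, 3), (2, 2, 3), (1, 2, 1)])
    def test_matches_scalar_loop_oracle(self, grid_n, hidden, kernel):
        rng = np.random.default_rng(grid_n * 100 + hidden * 10 + kernel)
        latent = 3
        m = ConvLSTM3D(LSTMConfig(grid_n=grid_n, hidden=hidden, kernel=kernel,
                                  latent_dim=latent, seed=0))
        params = {name: p.data for name, p in m.params.items()}
        h = rng.normal(size=(hidden, grid_n, grid_n, grid_n)) * 0.5
        s = rng.normal(size=(hidden, grid_n, grid_n, grid_n)) * 0.5
        x = rng.normal(size=latent)
        state = GridState(Tensor(h[None]), Tensor(s[None]))
        new = m.step(Tensor(x[None]), state)
        h_ref, s_ref = scalar_lstm_step(x, h, s, params, grid_n, hidden, kernel)
        assert np.allclose(new.h.data[0], h_ref, atol=1e-10)
        assert np.allclose(new.s.data[0], s_ref, atol=1e-10)

    def test_gate_and_state_ranges_on_random_steps(self):
        rng = np.random.default_rng(11)
        m = ConvLSTM3D(LSTMConfig(grid_n=2, hidden=2, kernel=3, latent_dim=6, seed=1))
        state = m.zero_state()
        for step in range(1000):
            if step % 100 == 0:  # refresh parameters to cover many regimes
                for p in m.parameters():
                    p.data[:] = rng.normal(size=p.data.shape)
            x = Tensor(rng.normal(size=(1, 6)) * 3.0)
            state = m.step(x, state)
            assert np.all(np.abs(state.h.data) < 1.0)  # h = tanh(s)
            assert np.all(np.isfinite(state.s.data))

    def test_non_finite_input_names_offending_gate(self):
        m = ConvLSTM3D(LSTMConfig(grid_n=1, hidden=1, kernel=1, latent_dim=1))
        with pytest.raises(FloatingPointError):
            m.step(Tensor(np.array([[np.inf]])), m.zero_state())


class TestSequence:
    def test_single_view_equals_one_step(self):
        rng = np.random.default_rng(4)
        m = ConvLSTM3D(LSTMConfig(grid_n=2, hidden=2, kernel=3, latent_dim=4, seed=2))
        x = rng.normal(size=(1, 4))
        seq = m.run_sequence([Tensor(x)])
        one = m.step(Tensor(x), m.zero_state())
        assert np.array_equal(seq.h.data, one.h.data)

    def test_empty_sequence_rejected(self):
        m = ConvLSTM3D(LSTMConfig(grid_n=1, hidden=1, latent_dim=2, kernel=1))
        with pytest.raises(ValueError):
            m.run_sequence([])

    def test_order_sensitivity_of_view_fusion(self):
        rng = np.random.default_rng(8)
        m = ConvLSTM3D(LSTMConfig(grid_n=2, hidden=3, kernel=3, latent_dim=5, seed=3))
        latents = rng.normal(size=(3, 1, 5))
        from itertools import permutations

        finals = []
        for perm in permutations(range(3)):
            finals.append(m.run_sequence([Tensor(latents[i]) for i in perm]).h.data.copy())
        assert any(not np.allclose(finals[0], f) for f in finals[1:])

    def test_cell_state_bounded_by_step_count(self):
        rng = np.random.default_rng(15)
        m = ConvLSTM3D(LSTMConfig(grid_n=2, hidden=2, kernel=3, latent_dim=4, seed=4))
        for p in m.parameters():
            p.data[:] = rng.normal(size=p.data.shape) * 2.0
        state = m.zero_state()
        for t in range(1, 12):
            prev = np.abs(state.s.data).copy()
            state = m.step(Tensor(rng.normal(size=(1, 4)) * 5), state)
            # |s_t| <= |s_{t-1}| + 1 elementwise since f, i in (0,1), |tanh|<=1
            assert np.all(np.abs(state.s.data) <= prev + 1.0 + 1e-12)
            assert np.abs(state.s.data).max() <= t + 1e-12
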