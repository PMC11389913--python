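import math

import numpy as np
import pytest

from gluforecast.autodiff import Tensor
from gluforecast.errors import ParameterError
from gluforecast.models import (
    GateActivations,
    HybridConfig,
    HybridForecaster,
    LSTMCellParams,
    LSTMCellState,
    MODEL_KINDS,
    TransformerEncoder,
    build_model,
    hybrid_forward,
    lstm_cell_step,
    lstm_forward,
    positional_encoding,
    transformer_encoder,
)

SMALL_CFG = HybridConfig(
    d_model=8, n_heads=2, n_encoder_layers=1, ffn_width=16,
    lstm_hidden=8, lstm_layers=1, dropout=0.1, lookback=12,
)


def scalar_lstm_step_oracle(x, h_prev, C_prev, p):
    """Element-wise scalar-loop oracle: no vectorized numpy."""
    hid, tot = p.W_f.shape
    z = list(h_prev) + list(x)
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))

    def gate(W, b, act):
        out = []
        for r in range(hid):
            acc = b[r]
            for c in range(tot):
                acc += W[r][c] * z[c]
            out.append(act(acc))
        return out

    f = gate(p.W_f, p.b_f, sig)
    i = gate(p.W_i, p.b_i, sig)
    Ct = gate(p.W_C, p.b_C, math.tanh)
    o = gate(p.W_O, p.b_O, sig)
    C = [f[r] * C_prev[r] + i[r] * Ct[r] for r in range(hid)]
    h = [o[r] * math.tanh(C[r]) for r in range(hid)]
    return h, C


class TestPositionalEncoding:
    def test_position_zero(self):
        np.testing.assert_array_equal(
            positional_encoding(1, 4)[0], [0.0, 1.0, 0.0, 1.0]
        )

    def test_position_one_closed_form(self):
        row = positional_encoding(2, 4)[1]
        expected = [math.sin(1), math.cos(1), math.sin(0.01), math.cos(0.01)]
        np.testing.assert_allclose(row, expected, rtol=1e-12)

    def test_rows_pairwise_distinct(self):
        table = positional_encoding(50, 8)
        for i in range(50):
            for j in range(i + 1, 50):
                assert not np.allclose(table[i], table[j])

    def test_entries_bounded(self):
        t = positional_encoding(100, 32)
        assert np.all(t >= -1.0) and np.all(t <= 1.0)

    def test_odd_d_model_rejected(self):
        with pytest.raises(ParameterError):
            positional_encoding(4, 5)


class TestLSTMCellStep:
    def test_hand_evaluated_zero_weights(self):
        p = LSTMCellParams(
            *(np.zeros((1, 2)),) * 4, *(np.zeros(1),) * 4
        )
        prev = LSTMCellState(np.zeros(1), np.ones(1))
        state, gates = lstm_cell_step(np.zeros(1), prev, p)
        # sigma(0)=0.5, tanh(0)=0 => C=0.5*1, h=0.5*tanh(0.5)
        np.testing.assert_allclose(gates.f_t, 0.5)
        np.testing.assert_allclose(gates.i_t, 0.5)
        np.testing.assert_allclose(gates.O_t, 0.5)
        np.testing.assert_allclose(gates.C_tilde, 0.0)
        np.testing.assert_allclose(state.C, 0.5)
        np.testing.assert_allclose(state.h, 0.5 * np.tanh(0.5), rtol=1e-12)

    def test_saturated_forget_gate_preserves_cell(self):
        p = LSTMCellParams(
            *(np.zeros((2, 3)),) * 4,
            np.full(2, 100.0),        # b_f huge -> f ~= 1
            np.full(2, -100.0),       # b_i huge negative -> i ~= 0
            np.zeros(2),
            np.zeros(2),
        )
        prev = LSTMCellState(np.zeros(2), np.array([0.7, -0.3]))
        state, _ = lstm_cell_step(np.zeros(1), prev, p)
        np.testing.assert_allclose(state.C, prev.C, atol=1e-10)

    def test_matches_scalar_loop_oracle_100_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            hid = int(rng.integers(1, 5))
            d = int(rng.integers(1, 4))
            p = LSTMCellParams.random(hid, d, rng)
            h0, C0 = rng.normal(size=hid), rng.normal(size=hid)
            x = rng.normal(size=d)
            state, _ = lstm_cell_step(x, LSTMCellState(h0, C0), p)
            h_ref, C_ref = scalar_lstm_step_oracle(
                list(x), list(h0), list(C0), p
            )
            np.testing.assert_allclose(state.h, h_ref, atol=1e-10)
            np.testing.assert_allclose(state.C, C_ref, atol=1e-10)

    def test_gate_ranges(self):
        rng = np.random.default_rng(1)
        p = LSTMCellParams.random(4, 3, rng)
        state, g = lstm_cell_step(
            rng.normal(size=3) * 5,
            LSTMCellState(rng.normal(size=4), rng.normal(size=4)),
            p,
        )
        for v in (g.f_t, g.i_t, g.O_t):
            assert np.all(v > 0) and np.all(v < 1)
        assert np.all(np.abs(g.C_tilde) < 1)
        assert np.all(np.abs(state.h) < 1)

    def test_shape_mismatch_rejected(self):
        p = LSTMCellParams.random(2, 2, np.random.default_rng(0))
        with pytest.raises(ParameterError):
            lstm_cell_step(np.zeros(3), LSTMCellState.zeros(2), p)


class TestLSTMForward:
    def test_single_step_equals_cell_step(self):
        rng = np.random.default_rng(2)
        p = LSTMCellParams.random(3, 2, rng)
        x = rng.normal(size=(1, 2))
        out = lstm_forward(x, p)
        state, _ = lstm_cell_step(x[0], LSTMCellState.zeros(3), p)
        np.testing.assert_allclose(out[0], state.h, rtol=1e-12)

    def test_four_step_fold_oracle(self):
        rng = np.random.default_rng(3)
        p = LSTMCellParams.random(3, 2, rng)
        x = rng.normal(size=(4, 2))
        out = lstm_forward(x, p)
        state = LSTMCellState.zeros(3)
        for t in range(4):
            state, _ = lstm_cell_step(x[t], state, p)
            np.testing.assert_allclose(out[t], state.h, rtol=1e-12)

    def test_hidden_magnitudes_below_one(self):
        rng = np.random.default_rng(4)
        p = LSTMCellParams.random(5, 2, rng)
        out = lstm_forward(rng.normal(size=(20, 2)) * 3, p)
        assert np.all(np.abs(out) < 1.0)

    def test_empty_sequence_rejected(self):
        p = LSTMCellParams.random(2, 2, np.random.default_rng(0))
        with pytest.raises(ParameterError):
            lstm_forward(np.zeros((0, 2)), p)


class TestTransformerEncoder:
    @pytest.mark.parametrize("L,d", [(4, 8), (12, 16)])
    def test_shape_preserved(self, L, d):
        cfg = HybridConfig(d_model=d, n_heads=2, n_encoder_layers=2,
                           ffn_width=2 * d, lookback=L)
        enc = TransformerEncoder(cfg, np.random.default_rng(0))
        out = transformer_encoder(np.random.default_rng(1).normal(size=(L, d)),
                                  cfg, enc)
        assert out.shape == (L, d)

    def test_permutation_equivariance_without_positions(self):
        cfg = HybridConfig(d_model=8, n_heads=2, n_encoder_layers=2,
                           ffn_width=16, lookback=6)
        enc = TransformerEncoder(cfg, np.random.default_rng(5))
        x = np.random.default_rng(6).normal(size=(6, 8))
        perm = np.random.default_rng(7).permutation(6)
        out = transformer_encoder(x, cfg, enc)
        out_perm = transformer_encoder(x[perm], cfg, enc)
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-10)

    def test_positional_encoding_breaks_order_invariance(self):
        cfg = HybridConfig(d_model=8, n_heads=2, n_encoder_layers=2,
                           ffn_width=16, lookback=6)
        enc = TransformerEncoder(cfg, np.random.default_rng(5))
        x = np.random.default_rng(6).normal(size=(6, 8))
        pe = positional_encoding(6, 8)
        perm = np.array([1, 0, 3, 2, 5, 4])
        # positions attach to slots, not samples: encoding a permuted
        # sequence is NOT the permutation of the encoded original
        out = transformer_encoder(x + pe, cfg, enc)
        out_perm = transformer_encoder(x[perm] + pe, cfg, enc)
        assert np.abs(out_perm - out[perm]).max() > 1e-3

    def test_bad_head_divisibility_rejected(self):
        with pytest.raises(ParameterError):
            HybridConfig(d_model=10, n_heads=4)


class TestHybridForward:
    def test_zero_head_outputs_bias(self):
        model = build_model("transformer_lstm", SMALL_CFG, seed=0)
        model.head.W.data[:] = 0.0
        model.head.b.data[:] = 3.25
        rng = np.random.default_rng(1)
        for _ in range(3):
            assert hybrid_forward(rng.normal(size=12), model) == pytest.approx(3.25)

    def test_eval_mode_deterministic(self):
        model = build_model("transformer_lstm", SMALL_CFG, seed=0)
        x = np.random.default_rng(2).normal(size=12)
        assert hybrid_forward(x, model) == hybrid_forward(x, model)

    def test_all_parameter_groups_receive_gradient(self):
        model = build_model("transformer_lstm", SMALL_CFG, seed=3)
        model.train()
        x = Tensor(np.random.default_rng(4).normal(size=(4, 12)))
        loss = (model(x) ** 2).mean()
        model.zero_grad()
        loss.backward()
        groups = {
            "embed": model.embed.parameters(),
            "encoder": model.encoder.parameters(),
            "lstm": [p for layer in model.lstm for p in layer.parameters()],
            "head": model.head.parameters(),
        }
        for name, params in groups.items():
            assert any(
                p.grad is not None and np.abs(p.grad).max() > 0 for p in params
            ), f"no gradient reached {name}"

    def test_gradient_matches_finite_differences_spot_check(self):
        model = build_model("transformer_lstm", SMALL_CFG, seed=5)
        model.eval()  # dropout off so the loss is deterministic
        x = np.random.default_rng(6).normal(size=(2, 12))

        def loss_value():
            return float((model(Tensor(x)) ** 2).mean().item())

        loss = (model(Tensor(x)) ** 2).mean()
        model.zero_grad()
        loss.backward()
        rng = np.random.default_rng(7)
        for p in (model.head.W, model.embed.W, model.lstm[0].Wf):
            flat_idx = tuple(rng.integers(0, s) for s in p.data.shape)
            orig = p.data[flat_idx]
            eps = 1e-6
            p.data[flat_idx] = orig + eps
            up = loss_value()
            p.data[flat_idx] = orig - eps
            down = loss_value()
            p.data[flat_idx] = orig
            num = (up - down) / (2 * eps)
            assert num == pytest.approx(p.grad[flat_idx], abs=1e-6)

    def test_window_length_mismatch_rejected(self):
        model = build_model("transformer_lstm", SMALL_CFG, seed=0)
        with pytest.raises(ParameterError):
            hybrid_forward(np.zeros(5), model)


class TestBuildModel:
    def test_seeded_init_reproducible(self):
        for kind in MODEL_KINDS:
            a = build_model(kind, SMALL_CFG, seed=11)
            b = build_model(kind, SMALL_CFG, seed=11)
            for pa, pb in zip(a.parameters(), b.parameters()):
                np.testing.assert_array_equal(pa.data, pb.data)

    def test_bilstm_head_width(self):
        m = build_model("bilstm", SMALL_CFG, seed=0)
        assert m.head.W.shape[0] == 2 * SMALL_CFG.lstm_hidden

    def test_stacked_lstm_has_two_layers(self):
        m = build_model("stacked_lstm", SMALL_CFG, seed=0)
        assert len(m.core) == 2

    @pytest.mark.parametrize("kind", MODEL_KINDS)
    def test_all_kinds_forward_smoke_and_eval_determinism(self, kind):
        m = build_model(kind, SMALL_CFG, seed=1)
        x = np.random.default_rng(0).normal(size=(7, 12))
        y1 = m.predict_batch(x)
        y2 = m.predict_batch(x)
        assert y1.shape == (7,)
        assert np.all(np.isfinite(y1))
        np.testing.assert_array_equal(y1, y2)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ParameterError, match="unknown model kind"):
            build_model("cnn", SMALL_CFG, seed=0)

    def test_module_lstm_matches_functional_primitives(self):
        m = build_model("lstm", SMALL_CFG, seed=2)
        x = np.random.default_rng(3).normal(size=(1, 12))
        # module path
        pred = m.predict_batch(x)
        # functional path through the same weights
        emb = x.reshape(12, 1) @ m.embed.W.data + m.embed.b.data
        h = lstm_forward(emb, m.core[0].cell_params())
        manual = h[-1] @ m.head.W.data[:, 0] + m.head.b.data[0]
        assert pred[0] == pytest.approx(float(manual), rel=1e-12)
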