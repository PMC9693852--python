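"""Classifier architectures: LSTM recurrence, sequence plumbing, models."""

import numpy as np
import pytest

from sleeptf.nets import (
    BackboneSpec,
    LSTMParams,
    LSTMState,
    SleepNetConfig,
    bilstm_forward,
    build_model,
    feature_sequence,
    lstm_step,
)
from sleeptf.nets.lstm import LSTMLayer, lstm_forward
from sleeptf.nets.layers import softmax, softmax_xent


def naive_lstm_step(x, h_prev, c_prev, params):
    """Scalar-loop reference: every gate element computed one by one."""
    H, D = params.hidden_size, params.input_size
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    h_new = np.zeros(H)
    c_new = np.zeros(H)
    for j in range(H):
        zf = params.b["f"][j] + sum(params.W["f"][j, d] * x[d] for d in range(D)) \
            + sum(params.U["f"][j, k] * h_prev[k] for k in range(H))
        zi = params.b["i"][j] + sum(params.W["i"][j, d] * x[d] for d in range(D)) \
            + sum(params.U["i"][j, k] * h_prev[k] for k in range(H))
        zc = params.b["c"][j] + sum(params.W["c"][j, d] * x[d] for d in range(D)) \
            + sum(params.U["c"][j, k] * h_prev[k] for k in range(H))
        zo = params.b["o"][j] + sum(params.W["o"][j, d] * x[d] for d in range(D)) \
            + sum(params.U["o"][j, k] * h_prev[k] for k in range(H))
        c_new[j] = sig(zf) * c_prev[j] + sig(zi) * np.tanh(zc)
        h_new[j] = sig(zo) * np.tanh(c_new[j])
    return h_new, c_new


class TestLSTMStep:
    def test_zero_parameters(self):
        p = LSTMParams.zeros(3, 2)
        st = lstm_step(np.array([1.0, -2.0, 0.5]), LSTMState.zeros(2), p)
        assert np.all(st.C == 0) and np.all(st.h == 0)

    def test_hand_computed_1d(self):
        """Open gates (bias +10), W_c = 1: C_1 = tanh(0.5) (up to the ~1
        gate saturation) and h_1 = tanh(C_1)."""
        g = lambda v: {k: np.full((1, 1), float(v)) for k in ("i", "f", "c", "o")}
        p = LSTMParams(
            W={"i": np.zeros((1, 1)), "f": np.zeros((1, 1)),
               "c": np.ones((1, 1)), "o": np.zeros((1, 1))},
            U={k: np.zeros((1, 1)) for k in ("i", "f", "c", "o")},
            b={"i": np.full(1, 10.0), "f": np.full(1, 10.0),
               "c": np.zeros(1), "o": np.full(1, 10.0)},
        )
        st = lstm_step(np.array([0.5]), LSTMState.zeros(1), p)
        gate = 1.0 / (1.0 + np.exp(-10.0))
        assert st.C[0] == pytest.approx(gate * np.tanh(0.5), abs=1e-12)
        assert st.h[0] == pytest.approx(gate * np.tanh(gate * np.tanh(0.5)), abs=1e-12)
        # to displayed precision these are tanh(0.5) and tanh(tanh(0.5))
        assert st.C[0] == pytest.approx(np.tanh(0.5), abs=1e-4)
        assert st.h[0] == pytest.approx(np.tanh(np.tanh(0.5)), abs=1e-4)

    def test_matches_naive_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = LSTMParams.random(2, 3, rng)
            x = rng.standard_normal(2)
            h0, c0 = rng.standard_normal(3), rng.standard_normal(3)
            st = lstm_step(x, LSTMState(h=h0, C=c0), p)
            h_ref, c_ref = naive_lstm_step(x, h0, c0, p)
            assert np.abs(st.h - h_ref).max() < 1e-12
            assert np.abs(st.C - c_ref).max() < 1e-12

    def test_dimension_mismatch(self):
        p = LSTMParams.zeros(3, 2)
        with pytest.raises(ValueError, match="shape"):
            lstm_step(np.zeros(5), LSTMState.zeros(2), p)


class TestBiLSTM:
    def test_zero_parameters_width(self):
        f = LSTMParams.zeros(3, 4)
        b = LSTMParams.zeros(3, 4)
        out = bilstm_forward(np.ones((6, 3)), f, b)
        assert out.shape == (6, 8)
        assert np.all(out == 0)

    def test_reversal_symmetry(self):
        """bilstm(reversed x; swapped params) is the time-reversed,
        half-swapped output of bilstm(x)."""
        rng = np.random.default_rng(1)
        f = LSTMParams.random(3, 4, rng)
        b = LSTMParams.random(3, 4, rng)
        x = rng.standard_normal((7, 3))
        out = bilstm_forward(x, f, b)
        out_rev = bilstm_forward(x[::-1], b, f)
        H = 4
        swapped = np.concatenate([out_rev[::-1, H:], out_rev[::-1, :H]], axis=1)
        assert np.abs(out - swapped).max() < 1e-12

    def test_length_one_reduces_to_steps(self):
        rng = np.random.default_rng(2)
        f = LSTMParams.random(3, 4, rng)
        b = LSTMParams.random(3, 4, rng)
        x = rng.standard_normal((1, 3))
        out = bilstm_forward(x, f, b)
        hf = lstm_step(x[0], LSTMState.zeros(4), f).h
        hb = lstm_step(x[0], LSTMState.zeros(4), b).h
        assert np.allclose(out[0], np.concatenate([hf, hb]), atol=1e-14)

    def test_empty_rejected(self):
        p = LSTMParams.zeros(3, 4)
        with pytest.raises(ValueError, match="nonempty"):
            bilstm_forward(np.empty((0, 3)), p, p)

    def test_fused_layer_matches_step_recurrence(self):
        rng = np.random.default_rng(3)
        layer = LSTMLayer(4, 3, rng)
        layer.params = {k: v.astype(np.float64) for k, v in layer.params.items()}
        p = LSTMParams.from_packed(layer.params["Wx"], layer.params["Wh"], layer.params["b"])
        x = rng.standard_normal((2, 6, 4))
        out = layer.forward(x)
        for n in range(2):
            assert np.abs(out[n] - lstm_forward(x[n], p)).max() < 1e-12


class TestFeatureSequence:
    def test_sequence_length_is_width(self):
        fm = np.zeros((7, 7, 64))
        assert feature_sequence(fm).shape == (7, 7 * 64)

    def test_one_hot_locality(self):
        fm = np.zeros((5, 7, 3))
        fm[2, 4, 1] = 1.0
        seq = feature_sequence(fm)
        nz = np.nonzero(seq)
        assert nz[0].tolist() == [4]                # only column 4 fires
        assert nz[1].tolist() == [2 * 3 + 1]        # frequency-major, then channel

    def test_round_trip(self):
        from sleeptf.nets.model import feature_map_from_sequence

        rng = np.random.default_rng(5)
        fm = rng.standard_normal((6, 9, 4))
        assert np.array_equal(feature_map_from_sequence(feature_sequence(fm), 6, 4), fm)


SMALL_BB = BackboneSpec(widths=(4, 8, 8, 8))


class TestSleepNet:
    def test_probability_rows(self):
        m = build_model(SleepNetConfig(variant="cnn", seed=0), SMALL_BB)
        x = np.random.default_rng(0).random((4, 224, 224, 3), dtype=np.float32)
        p = m.forward(x)
        assert p.shape == (4, 5)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_deterministic(self):
        m = build_model(SleepNetConfig(variant="cnn_rnn", hidden_sizes=(8, 8), seed=0), SMALL_BB)
        x = np.random.default_rng(1).random((3, 224, 224, 3), dtype=np.float32)
        assert np.array_equal(m.forward(x), m.forward(x))

    def test_backbone_shape_probe(self):
        m = build_model(SleepNetConfig(variant="cnn", seed=0), SMALL_BB)
        fm = m.backbone.forward(m._to_nchw(np.zeros((1, 224, 224, 3), dtype=np.float32)))
        N, C, H, W = fm.shape
        assert (H, W, C) == m.backbone.out_shape
        assert W >= 4

    def test_pretrained_adapter_unavailable(self):
        with pytest.raises(FileNotFoundError, match="compact"):
            build_model(SleepNetConfig(variant="cnn", seed=0),
                        BackboneSpec(kind="pretrained-adapter"))

    def test_softmax_shift_invariance(self):
        rng = np.random.default_rng(2)
        z = rng.standard_normal((6, 5))
        assert np.allclose(softmax(z), softmax(z + 123.4), atol=1e-12)

    def test_frozen_backbone_untouched_by_training(self):
        from sleeptf.train import TrainConfig, train_model

        m = build_model(
            SleepNetConfig(variant="cnn_rnn", hidden_sizes=(8, 8), freeze_backbone=True, seed=0),
            SMALL_BB,
        )
        before_bb = m.parameter_hash("backbone")
        before_head = m.parameter_hash("head")
        rng = np.random.default_rng(3)
        x = rng.random((12, 224, 224, 3), dtype=np.float32)
        y = rng.integers(0, 5, 12)
        train_model(m, x, y, TrainConfig(lr=0.05, max_epochs=1, batch_size=6,
                                         oversample=False, seed=0))
        assert m.parameter_hash("backbone") == before_bb
        assert m.parameter_hash("head") != before_head

    def test_checkpoint_round_trip(self, tmp_path):
        from sleeptf.nets import SleepNet

        m = build_model(SleepNetConfig(variant="cnn_rnn", hidden_sizes=(8, 8), seed=4), SMALL_BB)
        x = np.random.default_rng(5).random((2, 224, 224, 3), dtype=np.float32)
        p1 = m.forward(x)
        m.save(tmp_path / "ck.npz")
        m2 = SleepNet.load(tmp_path / "ck.npz")
        assert np.array_equal(p1, m2.forward(x))

    def test_gradients_match_numeric(self):
        """End-to-end backprop vs central differences on a tiny cnn_rnn."""
        m = build_model(SleepNetConfig(variant="cnn_rnn", hidden_sizes=(3, 3), seed=6),
                        BackboneSpec(widths=(2, 2, 2, 2)))
        # promote to float64 for the numeric check
        for group in m.parameter_groups().values():
            for layer, k in group:
                layer.params[k] = layer.params[k].astype(np.float64)
        rng = np.random.default_rng(7)
        x = rng.random((2, 224, 224, 3)).astype(np.float64)
        y = np.array([1, 3])

        def loss():
            return softmax_xent(m.logits(x), y)[0]

        l0, dl = softmax_xent(m.logits(x), y)
        m.backward(dl)
        checked = 0
        for gname, items in m.parameter_groups().items():
            for layer, key in items:
                arr = layer.params[key]
                g = layer.grads[key]
                idx = tuple(rng.integers(0, s) for s in arr.shape)
                eps = 1e-5
                old = arr[idx]
                arr[idx] = old + eps
                lp = loss()
                arr[idx] = old - eps
                lm = loss()
                arr[idx] = old
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(g[idx], rel=1e-3, abs=1e-7), (gname, key)
                checked += 1
        assert checked >= 10
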