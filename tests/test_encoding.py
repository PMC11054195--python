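"""Framing, LSTM cell arithmetic, stacked encoding, and attention pooling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protobeat import LabeledSequence, attend, encode, lstm_step, segment_series
from protobeat._network import init_params
from protobeat.encoding import LSTMCellParams, segment_batch
from protobeat.estimator import PrototypeSequenceClassifier


class TestSegmentSeries:
    @pytest.mark.parametrize(
        "length,T,n,covered",
        [(12, 3, 4, 12), (10, 3, 3, 9), (7, 1, 7, 7)],
    )
    def test_frame_widths_and_remainder_drop(self, length, T, n, covered):
        seq = LabeledSequence(np.arange(1.0, length + 1), 0, "s")
        frames = segment_series(seq, T)
        assert frames.shape == (T, n)
        np.testing.assert_array_equal(frames.ravel(), np.arange(1.0, covered + 1))

    def test_exact_division_example(self):
        frames = segment_series(np.arange(1.0, 13.0), 3)
        np.testing.assert_array_equal(frames[0], [1, 2, 3, 4])
        np.testing.assert_array_equal(frames[2], [9, 10, 11, 12])

    def test_too_many_frames_rejected(self):
        with pytest.raises(ValueError, match="length 5.*T=9"):
            segment_series(np.zeros(5), 9)

    def test_batch_framing_matches_per_series(self):
        X = np.arange(20.0).reshape(2, 10)
        batched = segment_batch(X, 3)
        for i in range(2):
            np.testing.assert_array_equal(batched[i], segment_series(X[i], 3))


class TestLSTMStep:
    def test_all_zero_weights_give_half_gates_and_zero_state(self):
        cell = LSTMCellParams(np.zeros((4, 1)), np.zeros((4, 1)), np.zeros(4))
        h, c = lstm_step([0.0], [0.0], [0.0], cell)
        assert h[0] == 0.0 and c[0] == 0.0

    def test_scalar_hand_evaluation(self):
        # unit weights, zero input/hidden, c_prev = 1: all gates sigmoid(0) = 0.5,
        # candidate tanh(0) = 0, so c = 0.5 and h = 0.5 * tanh(0.5)
        cell = LSTMCellParams.scalar(w=1.0)
        h, c = lstm_step([0.0], [0.0], [1.0], cell)
        assert c[0] == pytest.approx(0.5, abs=1e-12)
        assert h[0] == pytest.approx(0.5 * np.tanh(0.5), abs=1e-12)

    def test_matches_straight_line_reimplementation(self):
        rng = np.random.default_rng(7)
        H, n = 5, 4
        for _ in range(20):
            Wx = rng.normal(size=(4 * H, n))
            Wh = rng.normal(size=(4 * H, H))
            b = rng.normal(size=4 * H)
            cell = LSTMCellParams(Wx, Wh, b)
            x, hp, cp = rng.normal(size=n), rng.normal(size=H), rng.normal(size=H)
            h, c = lstm_step(x, hp, cp, cell)
            # independent formula-by-formula evaluation
            sig = lambda v: 1.0 / (1.0 + np.exp(-v))
            a = Wx @ x + Wh @ hp + b
            ig, fg = sig(a[:H]), sig(a[H:2 * H])
            cand, og = np.tanh(a[2 * H:3 * H]), sig(a[3 * H:])
            c_ref = fg * cp + ig * cand
            h_ref = og * np.tanh(c_ref)
            np.testing.assert_allclose(c, c_ref, atol=1e-6)
            np.testing.assert_allclose(h, h_ref, atol=1e-6)
            assert np.all(np.abs(h) < 1.0)

    def test_shape_mismatch_rejected(self):
        cell = LSTMCellParams.scalar()
        with pytest.raises(ValueError, match="shape mismatch"):
            lstm_step([0.0, 1.0], [0.0], [0.0], cell)


class TestEncode:
    def _params(self, rng, n_frame, hidden, layers, bi):
        return init_params(n_frame, hidden, layers, bi, 2, 2, 2, rng)

    def test_single_step_equals_lstm_step_per_direction(self):
        rng = np.random.default_rng(0)
        params = self._params(rng, 4, 3, 1, True)
        frame = rng.normal(size=(1, 4))
        H = encode(frame, params, 1, True)
        hf, _ = lstm_step(frame[0], np.zeros(3), np.zeros(3),
                          LSTMCellParams(params["enc0f_Wx"], params["enc0f_Wh"],
                                         params["enc0f_b"]))
        hb, _ = lstm_step(frame[0], np.zeros(3), np.zeros(3),
                          LSTMCellParams(params["enc0b_Wx"], params["enc0b_Wh"],
                                         params["enc0b_b"]))
        np.testing.assert_allclose(H[0], np.concatenate([hf, hb]), atol=1e-12)

    def test_unidirectional_reversal_changes_states(self):
        rng = np.random.default_rng(1)
        params = self._params(rng, 4, 3, 1, False)
        frames = rng.normal(size=(3, 4))
        assert not np.allclose(encode(frames, params, 1, False),
                               encode(frames[::-1], params, 1, False))

    def test_bidirectional_reversal_swaps_direction_blocks(self):
        # with shared directional weights, reversing the input time-reverses H
        # and swaps its forward/backward blocks
        rng = np.random.default_rng(2)
        params = self._params(rng, 4, 5, 1, True)
        for s in ("Wx", "Wh", "b"):
            params[f"enc0b_{s}"] = params[f"enc0f_{s}"].copy()
        frames = rng.normal(size=(3, 4))
        H = encode(frames, params, 1, True)
        Hr = encode(frames[::-1], params, 1, True)
        swapped = np.concatenate([Hr[:, 5:], Hr[:, :5]], axis=1)[::-1]
        np.testing.assert_allclose(H, swapped, atol=1e-12)

    def test_default_construction_is_three_layer_bidirectional_16(self):
        clf = PrototypeSequenceClassifier()
        assert (clf.n_layers, clf.hidden_size, clf.bidirectional) == (3, 16, True)
        assert clf.embedding_size_ == 32

    def test_hidden_states_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(3)
        params = self._params(rng, 4, 3, 2, True)
        frames = rng.normal(size=(10, 4)) * 50  # extreme inputs
        H = encode(frames, params, 2, True)
        assert np.all(np.abs(H) < 1.0)

    def test_deterministic(self):
        rng = np.random.default_rng(4)
        params = self._params(rng, 4, 3, 2, True)
        frames = rng.normal(size=(5, 4))
        a = encode(frames, params, 2, True)
        b = encode(frames, params, 2, True)
        assert np.array_equal(a, b)


class TestAttend:
    def test_singleton_softmax(self):
        h = np.array([[0.3, -0.2]])
        alpha, e = attend(h, np.eye(2), np.zeros(2), np.array([1.0, 0.0]))
        np.testing.assert_allclose(alpha, [1.0])
        np.testing.assert_allclose(e, h[0])

    def test_identical_states_give_uniform_weights(self):
        h = np.tile([[0.5, 0.1]], (4, 1))
        alpha, e = attend(h, np.eye(2), np.zeros(2), np.array([1.0, 2.0]))
        np.testing.assert_allclose(alpha, np.full(4, 0.25), atol=1e-12)
        np.testing.assert_allclose(e, h[0], atol=1e-12)

    def test_hand_evaluated_two_step_softmax(self):
        # scores (0, ln 3) -> alpha (1/4, 3/4), e = 0.75 * (ln 3, 0)
        h = np.array([[0.0, 0.0], [np.log(3.0), 0.0]])
        alpha, e = attend(h, np.eye(2), np.zeros(2), np.array([1.0, 0.0]))
        np.testing.assert_allclose(alpha, [0.25, 0.75], atol=1e-12)
        np.testing.assert_allclose(e, [0.75 * np.log(3.0), 0.0], atol=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            attend(np.zeros((0, 2)), np.eye(2), np.zeros(2), np.ones(2))

    def test_permuting_steps_leaves_embedding_unchanged(self):
        rng = np.random.default_rng(5)
        h = rng.normal(size=(6, 3))
        W, b, V = rng.normal(size=(3, 2)), rng.normal(size=2), rng.normal(size=2)
        perm = rng.permutation(6)
        alpha, e = attend(h, W, b, V)
        alpha_p, e_p = attend(h[perm], W, b, V)
        np.testing.assert_allclose(alpha_p, alpha[perm], atol=1e-12)
        np.testing.assert_allclose(e_p, e, atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_weights_are_convex_for_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        T, u, D = int(rng.integers(1, 9)), int(rng.integers(1, 6)), int(rng.integers(1, 5))
        h = rng.normal(size=(T, u)) * rng.uniform(0.1, 5)
        alpha, e = attend(h, rng.normal(size=(u, D)), rng.normal(size=D),
                          rng.normal(size=D))
        assert abs(alpha.sum() - 1.0) < 1e-6
        assert alpha.min() >= 0.0
        # e lies in the convex hull of the h_t, coordinate-wise
        assert np.all(e <= h.max(axis=0) + 1e-12)
        assert np.all(e >= h.min(axis=0) - 1e-12)

    def test_optional_tanh_score_changes_weights(self):
        rng = np.random.default_rng(6)
        h = rng.normal(size=(4, 3)) * 3
        args = (rng.normal(size=(3, 2)), rng.normal(size=2), rng.normal(size=2))
        a_plain, _ = attend(h, *args, use_tanh=False)
        a_tanh, _ = attend(h, *args, use_tanh=True)
        assert not np.allclose(a_plain, a_tanh)
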