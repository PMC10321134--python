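"""Base-learner contracts: fitting, probabilities, RBM energetics, LSTM algebra."""

import numpy as np
import pytest

from oedl import learners
from oedl.learners import (
    LSTMCell,
    LearnerSpec,
    RBMParams,
    TrainedLearner,
    _Dense,
    _Network,
    fit,
    lstm_forward,
    rbm_cd_step,
    rbm_energy,
    rbm_free_energy,
    rbm_partition,
    rbm_prob,
    softmax,
)

TEST_SPEC = dict(epochs=300, lr=1e-3)  # reduced-epoch profile


class TestSpecValidation:
    def test_neuron_bounds(self):
        with pytest.raises(ValueError):
            LearnerSpec(neurons=(0,), n_hidden_layers=1)
        with pytest.raises(ValueError):
            LearnerSpec(neurons=(101,), n_hidden_layers=1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            LearnerSpec(neurons=(10,), n_hidden_layers=2)

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            LearnerSpec(family="cnn")


class TestFit:
    @pytest.mark.parametrize("family", learners.FAMILIES)
    def test_separable_toy_high_training_accuracy(self, family, separable_toy):
        X, y = separable_toy
        model = fit(LearnerSpec(family=family, **TEST_SPEC), X, y, seed=1)
        assert (model.predict(X) == y).mean() >= 0.95

    @pytest.mark.parametrize("family", learners.FAMILIES)
    def test_shuffled_labels_near_chance_on_heldout(self, family, separable_toy):
        X, y = separable_toy
        rng = np.random.default_rng(0)
        y_shuf = rng.permutation(y)
        model = fit(LearnerSpec(family=family, epochs=150, lr=1e-3),
                    X[:100], y_shuf[:100], seed=1)
        acc = (model.predict(X[100:]) == y_shuf[100:]).mean()
        # majority rate ~1/3; binomial 3-sigma band at n=50
        assert acc < 1 / 3 + 3 * np.sqrt((1 / 3) * (2 / 3) / 50)

    @pytest.mark.parametrize("family", learners.FAMILIES)
    def test_seed_determinism(self, family, separable_toy):
        X, y = separable_toy
        spec = LearnerSpec(family=family, epochs=20, lr=1e-3)
        a = fit(spec, X, y, seed=3)
        b = fit(spec, X, y, seed=3)
        assert a.loss_history == b.loss_history

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            fit(LearnerSpec(epochs=1), X, np.array([0, 1]))


class TestPredictProba:
    def test_rows_sum_to_one_and_duplicates_agree(self, separable_toy):
        X, y = separable_toy
        model = fit(LearnerSpec(epochs=30, lr=1e-3), X, y, seed=0)
        Xq = np.vstack([X[:5], X[:5]])
        probs = model.predict_proba(Xq)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(probs[:5], probs[5:])
        assert (probs >= 0).all()

    def test_hand_set_weights_give_closed_form_softmax(self):
        W = np.array([[1.0, -1.0, 0.5], [0.0, 2.0, -0.5]])
        b = np.array([0.1, -0.2, 0.0])
        net = _Network([_Dense(np.random.default_rng(0), 2, 3, W=W.copy(), b=b.copy())])
        model = TrainedLearner(LearnerSpec(epochs=1), net)
        x = np.array([[2.0, -1.0]])
        expected = softmax(x @ W + b)
        np.testing.assert_allclose(model.predict_proba(x), expected, atol=1e-12)


class TestRBM:
    def test_zero_parameters_zero_energy(self):
        p = RBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        assert rbm_energy(p, np.array([1, 0, 1]), np.array([1, 1])) == 0.0

    def test_probabilities_normalize_by_enumeration(self):
        rng = np.random.default_rng(8)
        p = RBMParams(rng.normal(0, 1, (2, 2)), rng.normal(0, 1, 2), rng.normal(0, 1, 2))
        z = rbm_partition(p)
        total = 0.0
        for iv in range(4):
            v = np.array([iv & 1, (iv >> 1) & 1], dtype=float)
            for ih in range(4):
                h = np.array([ih & 1, (ih >> 1) & 1], dtype=float)
                total += rbm_prob(p, v, h, z)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_free_energy_marginalizes_hidden(self):
        rng = np.random.default_rng(2)
        p = RBMParams(rng.normal(0, 1, (3, 2)), rng.normal(0, 1, 3), rng.normal(0, 1, 2))
        v = np.array([1.0, 0.0, 1.0])
        direct = sum(
            np.exp(-rbm_energy(p, v, np.array([a, b], dtype=float)))
            for a in (0, 1) for b in (0, 1)
        )
        assert rbm_free_energy(p, v) == pytest.approx(-np.log(direct), abs=1e-10)

    def test_cd_training_reduces_reconstruction_error(self):
        rng = np.random.default_rng(5)
        patterns = np.array([[1, 0, 1, 0], [0, 1, 0, 1]] * 10, dtype=float)
        p = RBMParams(rng.normal(0, 0.01, (4, 3)), np.zeros(4), np.zeros(3))

        def recon_err(params):
            ph = 1 / (1 + np.exp(-(params.c + patterns @ params.W)))
            pv = 1 / (1 + np.exp(-(params.b + ph @ params.W.T)))
            return float(np.mean((patterns - pv) ** 2))

        before = recon_err(p)
        for _ in range(200):
            rbm_cd_step(p, patterns, lr=0.1, rng=rng)
        assert recon_err(p) < before

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            RBMParams(np.zeros((2, 2)), np.zeros(3), np.zeros(2))


class TestLSTM:
    def test_gating_algebra(self):
        # saturate gates with huge biases: sigmoid(+-1000) is exactly 1/0
        H, D = 2, 3
        big = 1000.0
        cell = LSTMCell(np.random.default_rng(0), D, H)
        cell.Wx[:] = 0.0
        cell.Wh[:] = 0.0
        x = np.ones((1, D))
        c_prev = np.array([[0.7, -0.3]])
        # forget=0, input=0 -> cell state zeroed
        cell.b[:] = np.array([-big] * H + [-big] * H + [0.0] * H + [0.0] * H)
        _, c_t = lstm_forward(cell, x, np.zeros((1, H)), c_prev)
        np.testing.assert_array_equal(c_t, np.zeros((1, H)))
        # forget=1, input=0 -> cell state carried through
        cell.b[:] = np.array([-big] * H + [big] * H + [0.0] * H + [0.0] * H)
        _, c_t = lstm_forward(cell, x, np.zeros((1, H)), c_prev)
        np.testing.assert_allclose(c_t, c_prev, atol=1e-12)

    def test_matches_hand_rolled_reference(self):
        rng = np.random.default_rng(9)
        D, H = 4, 3
        cell = LSTMCell(rng, D, H)
        x = rng.normal(0, 1, (1, D))
        h_prev = rng.normal(0, 1, (1, H))
        c_prev = rng.normal(0, 1, (1, H))
        h_t, c_t = lstm_forward(cell, x, h_prev, c_prev)

        def sig(z):
            return 1 / (1 + np.exp(-z))

        z = x @ cell.Wx + h_prev @ cell.Wh + cell.b
        i, f, g, o = sig(z[:, :H]), sig(z[:, H:2 * H]), np.tanh(z[:, 2 * H:3 * H]), sig(z[:, 3 * H:])
        c_ref = f * c_prev + i * g
        h_ref = o * np.tanh(c_ref)
        np.testing.assert_allclose(c_t, c_ref, atol=1e-10)
        np.testing.assert_allclose(h_t, h_ref, atol=1e-10)

    def test_features_as_timesteps_mode_trains(self, separable_toy):
        X, y = separable_toy
        spec = LearnerSpec(family="lstm_rnn", n_hidden_layers=1, neurons=(8,),
                           epochs=60, lr=1e-2, features_as_timesteps=True)
        model = fit(spec, X[:60], y[:60], seed=0)
        assert np.isfinite(model.loss_history).all()
        assert model.predict_proba(X[:5]).shape == (5, 3)
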