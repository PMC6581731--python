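"""LSTM+FC classifier: parameter counts, forward oracle, gradients, training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from saelstm import classify as cl


def tiny_spec(**kw):
    defaults = dict(input_dim=3, seq_len=4, lstm_hidden=3, fc_units=2,
                    dropout_lstm=0.0, dropout_fc=0.0)
    defaults.update(kw)
    return cl.ClassifierSpec(**defaults)


class TestCountClassifierParams:
    def test_default_architecture(self):
        assert cl.count_classifier_params(cl.ClassifierSpec()) == 2040376

    def test_all_ones_hand_count(self):
        spec = cl.ClassifierSpec(input_dim=1, seq_len=1, lstm_hidden=1, fc_units=1)
        assert cl.count_classifier_params(spec) == 16

    def test_fc_term_scales_linearly(self):
        base = cl.ClassifierSpec()
        doubled = cl.ClassifierSpec(fc_units=250)
        fc_term = lambda s: (s.seq_len * s.lstm_hidden) * s.fc_units + s.fc_units \
            + s.fc_units * s.output_units + s.output_units  # noqa: E731
        assert fc_term(doubled) - 1 == 2 * (fc_term(base) - 1)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            cl.ClassifierSpec(lstm_hidden=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(d=st.integers(1, 6), t=st.integers(1, 5), h=st.integers(1, 6),
           f=st.integers(1, 6))
    def test_closed_form_matches_enumeration(self, d, t, h, f):
        spec = cl.ClassifierSpec(input_dim=d, seq_len=t, lstm_hidden=h, fc_units=f)
        model = cl.TrainedClassifier(spec=spec, params=cl._init_params(spec, 0))
        assert model.n_params() == cl.count_classifier_params(spec)


def reference_lstm_forward(params, spec, x):
    """Independent step-by-step recurrence with per-gate slices, kept
    deliberately naive (scalar-style loops over time)."""
    H = spec.lstm_hidden
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))  # noqa: E731
    h = np.zeros(H)
    c = np.zeros(H)
    hs = []
    for t in range(spec.seq_len):
        z = params["W"] @ x[t] + params["U"] @ h + params["b"]
        i, f, g, o = z[:H], z[H:2*H], z[2*H:3*H], z[3*H:]
        i, f, o = sig(i), sig(f), sig(o)
        g = np.tanh(g)
        c = f * c + i * g
        h = o * np.tanh(c)
        hs.append(h.copy())
    flat = np.concatenate(hs)
    fc = np.tanh(params["W_fc"] @ flat + params["b_fc"])
    return sig(params["W_out"] @ fc + params["b_out"])[0]


class TestForward:
    def test_output_strictly_in_unit_interval(self, rng):
        spec = tiny_spec()
        model = cl.TrainedClassifier(spec=spec, params=cl._init_params(spec, 1))
        p = cl.forward(model, rng.standard_normal((4, 3)))
        assert 0.0 < p < 1.0

    def test_zero_parameters_give_half(self):
        spec = tiny_spec()
        params = {k: np.zeros_like(v) for k, v in cl._init_params(spec, 0).items()}
        model = cl.TrainedClassifier(spec=spec, params=params)
        assert cl.forward(model, np.ones((4, 3))) == pytest.approx(0.5)

    def test_matches_independent_recurrence_oracle(self, rng):
        spec = tiny_spec(input_dim=2, seq_len=3, lstm_hidden=3, fc_units=2)
        params = cl._init_params(spec, 7)
        # perturb so no structure (e.g. zero biases) hides an indexing bug
        for v in params.values():
            v += 0.1 * rng.standard_normal(v.shape)
        model = cl.TrainedClassifier(spec=spec, params=params)
        x = rng.standard_normal((3, 2))
        assert cl.forward(model, x) == pytest.approx(
            reference_lstm_forward(params, spec, x), abs=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        spec = tiny_spec()
        model = cl.TrainedClassifier(spec=spec, params=cl._init_params(spec, 0))
        with pytest.raises(ValueError):
            cl.forward(model, rng.standard_normal((5, 3)))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        spec = tiny_spec()
        params = cl._init_params(spec, 2)
        x = rng.standard_normal((5, 4, 3))
        y = rng.integers(0, 2, 5).astype(float)
        _, grads = cl.loss_and_grads(params, spec, x, y, l2_weight=1e-4)
        eps = 1e-6
        for k, v in params.items():
            it = np.nditer(v, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                v[i] += eps
                lp, _ = cl.loss_and_grads(params, spec, x, y, l2_weight=1e-4)
                v[i] -= 2 * eps
                lm, _ = cl.loss_and_grads(params, spec, x, y, l2_weight=1e-4)
                v[i] += eps
                num = (lp - lm) / (2 * eps)
                assert abs(num - grads[k][i]) <= 1e-5 * max(abs(num), 1e-3), k


def make_separable(n, seq_len=10, dim=4, seed=0, shift=2.0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, seq_len, dim))
    # class signal: late-half mean shift in feature 0, mimicking a band-power
    # contrast
    X[y == 1, seq_len // 2:, 0] += shift
    return X, y.astype(float)


class TestTraining:
    def test_loss_decreases_over_first_steps(self, rng):
        X, y = make_separable(32, seed=3)
        spec = cl.ClassifierSpec(input_dim=4, seq_len=10, lstm_hidden=8,
                                 fc_units=8, dropout_lstm=0, dropout_fc=0)
        params = cl._init_params(spec, 0)
        losses = []
        for _ in range(10):
            loss, grads = cl.loss_and_grads(params, spec, X, y)
            losses.append(loss)
            for k, g in grads.items():
                params[k] -= 1e-2 * g
        assert losses[-1] < losses[0]
        assert np.all(np.diff(losses) < 1e-6)

    def test_learns_separable_sequences(self):
        X, y = make_separable(80, seed=4, shift=3.0)
        spec = cl.ClassifierSpec(input_dim=4, seq_len=10, lstm_hidden=8,
                                 fc_units=8, dropout_lstm=0.1, dropout_fc=0.1)
        model = cl.train_classifier(X[:60], y[:60], spec=spec, seed=0,
                                    lr_high=0.05, lr_low=0.01, batch_size=8,
                                    switch_epoch=200, max_epochs=300)
        pred = (cl.forward(model, X[60:]) > 0.5).astype(float)
        assert np.mean(pred == y[60:]) >= 0.9

    def test_reproducible_without_dropout(self):
        X, y = make_separable(20, seed=5)
        spec = cl.ClassifierSpec(input_dim=4, seq_len=10, lstm_hidden=4,
                                 fc_units=4, dropout_lstm=0, dropout_fc=0)
        m1 = cl.train_classifier(X, y, spec=spec, seed=9, max_epochs=5)
        m2 = cl.train_classifier(X, y, spec=spec, seed=9, max_epochs=5)
        for k in m1.params:
            np.testing.assert_array_equal(m1.params[k], m2.params[k])

    def test_single_class_warns_but_proceeds(self):
        X, _ = make_separable(10, seed=6)
        spec = cl.ClassifierSpec(input_dim=4, seq_len=10, lstm_hidden=3, fc_units=3)
        with pytest.warns(UserWarning, match="single class"):
            model = cl.train_classifier(X, np.ones(10), spec=spec, max_epochs=2)
        assert model.trained

    def test_divergence_raises(self):
        X, y = make_separable(16, seed=7)
        spec = cl.ClassifierSpec(input_dim=4, seq_len=10, lstm_hidden=4, fc_units=4)
        with pytest.raises(cl.TrainingError):
            cl.train_classifier(X, y, spec=spec, lr_high=1e6, max_epochs=50,
                                l2_weight=1.0)


class TestPredictLabel:
    @pytest.fixture()
    def fixed_probability_model(self):
        """A model whose output is sigmoid(b_out) regardless of input."""
        spec = tiny_spec()
        params = {k: np.zeros_like(v) for k, v in cl._init_params(spec, 0).items()}
        params["b_out"] = np.array([np.log(0.7 / 0.3)])  # p = 0.7
        return cl.TrainedClassifier(spec=spec, params=params), np.zeros((4, 3))

    def test_probability_above_threshold_is_high(self, fixed_probability_model):
        model, x = fixed_probability_model
        assert cl.forward(model, x) == pytest.approx(0.7)
        assert cl.predict_label(model, x) == "High"

    def test_tie_at_threshold_is_low(self, fixed_probability_model):
        model, x = fixed_probability_model
        model.params["b_out"][:] = 0.0  # p = 0.5 exactly
        assert cl.predict_label(model, x, threshold=0.5) == "Low"

    def test_extreme_thresholds(self, fixed_probability_model):
        model, x = fixed_probability_model
        assert cl.predict_label(model, x, threshold=0.0) == "High"
        assert cl.predict_label(model, x, threshold=1.0) == "Low"
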