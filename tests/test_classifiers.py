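"""Per-decoder behaviour: closed forms, limits, symmetries, tie rule."""

import numpy as np
import pytest
from scipy import stats

from popdecode.classifiers import (
    DecoderSpec,
    ann_cost,
    fit_ann,
    fit_bayes,
    fit_r_ole,
    fit_reservoir,
    fit_svm,
    sign_pm,
    svm_kernel_expansion,
)


def _gaussian_clusters(rng, n_cells=5, n_per=30, sep=3.0, sd=1.0):
    mu = rng.standard_normal(n_cells)
    X = np.concatenate(
        [
            mu[:, None] - sep / 2 + sd * rng.standard_normal((n_cells, n_per)),
            mu[:, None] + sep / 2 + sd * rng.standard_normal((n_cells, n_per)),
        ],
        axis=1,
    )
    y = np.repeat([-1, 1], n_per)
    return X, y


class TestTieRule:
    def test_sign_convention(self):
        assert np.array_equal(sign_pm([0.3, -2.0, 0.0]), [1, -1, 1])


class TestSpecValidation:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            DecoderSpec("perceptron")

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError, match="spectral_radius"):
            DecoderSpec("reservoir", params={"spectral_radius": 0.9})


class TestROle:
    def test_vanishing_regularization_recovers_least_squares(self, rng):
        X, y = _gaussian_clusters(rng, n_cells=5, n_per=20)
        dec = fit_r_ole(X, y.astype(float), lambda_grid=(0.0,))
        design = np.column_stack([X.T, np.ones(X.shape[1])])
        coef = np.linalg.lstsq(design, y.astype(float), rcond=None)[0]
        assert dec.weights == pytest.approx(coef[:-1], abs=1e-8)
        assert dec.bias == pytest.approx(coef[-1], abs=1e-8)

    def test_infinite_regularization_collapses_to_bias(self, rng):
        X, y = _gaussian_clusters(rng)
        y = y.astype(float)
        y[:10] = 1.0  # majority class fixes the sign of the bias
        dec = fit_r_ole(X, y, lambda_grid=(1e12,))
        assert np.abs(dec.weights).max() < 1e-6
        assert np.all(dec.predict(X) == sign_pm(dec.bias))

    def test_label_flip_flips_predictions(self, rng):
        X, y = _gaussian_clusters(rng, sep=1.0)
        a = fit_r_ole(X, y, lambda_grid=(1.0,))
        b = fit_r_ole(X, -y, lambda_grid=(1.0,))
        assert np.array_equal(a.predict(X), -b.predict(X))

    def test_cell_order_permutation_invariance(self, rng):
        X, y = _gaussian_clusters(rng)
        perm = rng.permutation(X.shape[0])
        a = fit_r_ole(X, y, lambda_grid=(0.5,))
        b = fit_r_ole(X[perm], y, lambda_grid=(0.5,))
        assert b.weights == pytest.approx(a.weights[perm], abs=1e-9)

    def test_lambda_selected_from_grid(self, rng):
        X, y = _gaussian_clusters(rng, sep=1.5)
        dec = fit_r_ole(X, y, rng=rng)
        assert dec.lam in tuple(10.0 ** np.arange(-6, 4))


class TestAnn:
    def test_pure_mse_when_ratio_is_one(self, rng):
        X, y = _gaussian_clusters(rng, n_cells=3, n_per=10)
        theta = rng.standard_normal(4)
        out = np.tanh(theta[:3] @ ((X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)) + theta[3])
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        out = np.tanh(theta[:3] @ Z + theta[3])
        assert ann_cost(theta, Z, y.astype(float), 0, 1.0) == pytest.approx(
            np.mean((out - y) ** 2)
        )

    def test_gradient_matches_finite_differences(self, rng):
        from popdecode.classifiers import _ann_cost_grad

        Z = rng.standard_normal((4, 12))
        y = np.repeat([-1.0, 1.0], 6)
        for hidden in (0, 2):
            n_params = 5 if hidden == 0 else 2 * (4 + 2) + 1
            theta = 0.3 * rng.standard_normal(n_params)
            cost, grad = _ann_cost_grad(theta, Z, y, hidden, 0.5)
            eps = 1e-6
            for i in range(n_params):
                d = np.zeros(n_params)
                d[i] = eps
                num = (
                    _ann_cost_grad(theta + d, Z, y, hidden, 0.5)[0]
                    - _ann_cost_grad(theta - d, Z, y, hidden, 0.5)[0]
                ) / (2 * eps)
                assert grad[i] == pytest.approx(num, abs=1e-5)

    def test_linear_net_separates_clean_clusters(self, rng):
        X, y = _gaussian_clusters(rng, sep=6.0, sd=0.1)
        dec = fit_ann(X, y.astype(float), hidden_units=0, rng=rng)
        assert np.all(dec.predict(X) == y)

    def test_hidden_layer_solves_xor_where_linear_fails(self, rng):
        # two informative cells in an XOR arrangement + two noise cells
        centers = np.array([[0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        labels = np.array([-1, -1, 1, 1])
        reps = 30
        X = np.zeros((4, 4 * reps))
        y = np.zeros(4 * reps)
        rows = []
        for k, (c, lab) in enumerate(zip(centers, labels)):
            sl = slice(k * reps, (k + 1) * reps)
            X[:2, sl] = c[:, None] + 0.05 * rng.standard_normal((2, reps))
            X[2:, sl] = 0.05 * rng.standard_normal((2, reps))
            y[sl] = lab
        ole = fit_ann(X, y, hidden_units=0, rng=rng)
        nle = fit_ann(X, y, hidden_units=2, rng=rng, restarts=4)
        acc_ole = np.mean(ole.predict(X) == y)
        acc_nle = np.mean(nle.predict(X) == y)
        assert acc_ole <= 0.80
        assert acc_nle > acc_ole

    def test_invalid_hidden_count_rejected(self, rng):
        X, y = _gaussian_clusters(rng)
        with pytest.raises(ValueError):
            fit_ann(X, y.astype(float), hidden_units=4, rng=rng)


class TestBayes:
    def test_equal_variance_boundary_is_linear(self, rng):
        # two cells, class means (0,0) and (1,1), shared sigma: the decision
        # boundary is x1 + x2 = 1
        n = 4000
        X = np.concatenate(
            [rng.standard_normal((2, n)), 1 + rng.standard_normal((2, n))], axis=1
        )
        y = np.repeat([-1, 1], n)
        dec = fit_bayes(X, y)
        assert dec.predict(np.array([[0.4], [0.4]]))[0] == -1
        assert dec.predict(np.array([[0.7], [0.7]]))[0] == 1
        near = dec.decision_values(np.array([[0.5], [0.5]]))
        assert abs(near[0]) < 0.2

    def test_identical_classes_tie_breaks_positive(self):
        X = np.array([[1.0, 2.0, 1.0, 2.0]])
        y = np.array([-1, -1, 1, 1])
        dec = fit_bayes(X, y)
        assert dec.predict(np.array([[1.5]]))[0] == 1

    def test_log_posterior_matches_density_ratio_oracle(self, rng):
        X = np.array([[0.0, 0.4, -0.3, 2.0, 2.5, 3.1]])
        y = np.array([-1, -1, -1, 1, 1, 1])
        dec = fit_bayes(X, y)
        r = np.array([[1.2]])
        expected = stats.norm.logpdf(1.2, dec.mu[1, 0], dec.sd[1, 0]) - stats.norm.logpdf(
            1.2, dec.mu[0, 0], dec.sd[0, 0]
        )
        assert dec.decision_values(r)[0] == pytest.approx(expected, abs=1e-10)

    def test_label_flip_flips_predictions(self, rng):
        X, y = _gaussian_clusters(rng, sep=1.0)
        a = fit_bayes(X, y)
        b = fit_bayes(X, -y)
        assert np.array_equal(a.predict(X), -b.predict(X))

    def test_cell_order_permutation_invariance(self, rng):
        X, y = _gaussian_clusters(rng)
        perm = rng.permutation(X.shape[0])
        a = fit_bayes(X, y)
        b = fit_bayes(X[perm], y)
        assert np.array_equal(a.predict(X), b.predict(X[perm]))

    def test_degenerate_variance_floored(self):
        X = np.array([[1.0, 1.0, 2.0, 2.0], [0.1, 0.2, 0.3, 0.4]])
        y = np.array([-1, -1, 1, 1])
        dec = fit_bayes(X, y)
        assert np.all(dec.sd > 0)

    def test_single_trial_class_rejected(self):
        with pytest.raises(ValueError):
            fit_bayes(np.ones((2, 3)), np.array([-1, 1, 1]))


class TestReservoir:
    def _traces(self, rng, n_cells=6, m=40, T=120, sep=4.0):
        y = np.repeat([-1.0, 1.0], m // 2)
        base = rng.standard_normal((n_cells, m, T))
        signal = np.linspace(0, 1, T) * sep
        pref = np.where(np.arange(n_cells) % 2 == 0, 1, -1)
        for i in range(n_cells):
            base[i] += np.outer(y == pref[i], signal)
        return base, y

    def test_negative_time_constant_rejected(self, rng):
        traces, y = self._traces(rng)
        with pytest.raises(ValueError):
            fit_reservoir(traces, y, (50, 100), rng, tau=0.5)

    def test_leak_converges_geometrically_to_fixed_point(self, rng):
        traces = np.ones((3, 2, 80))
        dec = fit_reservoir(
            traces, np.array([-1.0, 1.0]), (0, 80), rng, tau=55.0,
            transfer="tanh", n_nodes=10, zscore=False, input_scale=0.1,
        )
        states = dec.states_over_time(traces, np.arange(80))
        target = np.tanh(dec.W_in @ np.ones(3))
        err = np.abs(states[:, 0, :] - target[:, None]).mean(axis=0)
        ratios = err[1:] / err[:-1]
        assert np.allclose(ratios, 1 - 1 / 55.0, atol=1e-6)

    def test_zero_input_predicts_positive_tie(self, rng):
        traces, y = self._traces(rng)
        dec = fit_reservoir(traces, y, (50, 100), rng, n_nodes=20, zscore=False)
        zeros = np.zeros((6, 3, 120))
        assert np.all(dec.predict_over_time(zeros, np.arange(10)) == 1)

    def test_separable_time_series_classified(self, rng):
        traces, y = self._traces(rng, sep=8.0)
        dec = fit_reservoir(traces, y, (90, 120), rng, n_nodes=50)
        preds = dec.predict_over_time(traces, np.array([110]))
        assert np.mean(preds[:, 0] == y) > 0.95


class TestSvm:
    def test_clean_clusters_fully_separated(self, rng):
        X, y = _gaussian_clusters(rng, sep=8.0, sd=0.2)
        dec = fit_svm(X, y, rng, c_grid=(1.0, 100.0), gamma_grid=(0.01, 0.1))
        assert np.all(dec.predict(X) == y)

    def test_decision_matches_kernel_expansion(self, rng):
        X, y = _gaussian_clusters(rng, sep=2.0)
        dec = fit_svm(X, y, rng, c_grid=(10.0,), gamma_grid=(0.05,))
        probe = rng.standard_normal((5, 20))
        assert svm_kernel_expansion(dec, probe) == pytest.approx(
            dec.decision_values(probe), abs=1e-6
        )

    def test_rbf_solves_concentric_rings(self, rng):
        n = 120
        angles = rng.uniform(0, 2 * np.pi, n)
        radii = np.concatenate([np.full(n // 2, 0.5), np.full(n // 2, 2.0)])
        radii = radii + 0.05 * rng.standard_normal(n)
        X = np.stack([radii * np.cos(angles), radii * np.sin(angles)])
        y = np.repeat([-1, 1], n // 2)
        linear = fit_r_ole(X, y.astype(float), lambda_grid=(1.0,))
        dec = fit_svm(X, y, rng, c_grid=(10.0, 1000.0), gamma_grid=(0.5, 2.0))
        assert np.mean(linear.predict(X) == y) < 0.7
        assert np.mean(dec.predict(X) == y) > 0.95

    def test_label_flip_flips_predictions(self, rng):
        X, y = _gaussian_clusters(rng, sep=1.5)
        a = fit_svm(X, y, np.random.default_rng(7), c_grid=(10.0,), gamma_grid=(0.05,))
        b = fit_svm(X, -y, np.random.default_rng(7), c_grid=(10.0,), gamma_grid=(0.05,))
        assert np.array_equal(a.predict(X), -b.predict(X))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_svm(np.ones((2, 10)), np.ones(10), rng)
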