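"""PLS and MLP calibration models."""

import numpy as np
import pytest

import voltacal as vc
from voltacal.calibration import CalibrationDataset, MLPCalibrator, PLSCalibrator


def _linear_dataset(rng, n=50, p=8, q=4, rank=None, noise=0.0):
    rank = p if rank is None else rank
    basis = rng.normal(size=(rank, p))
    X = rng.normal(size=(n, rank)) @ basis
    B = rng.normal(size=(p, q))
    Y = X @ B + noise * rng.normal(size=(n, q))
    return CalibrationDataset(X=X, Y=Y)


class TestPLS:
    def test_full_rank_noiseless_reproduces_targets(self, rng):
        data = _linear_dataset(rng, n=50, p=8)
        model = vc.pls_fit(data, n_components=8)
        assert np.allclose(model.predict(data.X), data.Y, atol=1e-8)

    def test_matches_ols_at_full_rank(self, rng):
        # independent oracle: multivariate least squares via lstsq
        data = _linear_dataset(rng, n=60, p=6, noise=0.1)
        model = vc.pls_fit(data, n_components=6)
        Xc = np.column_stack([np.ones(60), data.X])
        beta, *_ = np.linalg.lstsq(Xc, data.Y, rcond=None)
        ols_pred = Xc @ beta
        assert np.max(np.abs(model.predict(data.X) - ols_pred)) < 1e-6

    def test_first_weight_maximizes_covariance(self, rng):
        # oracle: dominant left singular vector of X'Y on a toy problem
        X = rng.normal(size=(20, 5))
        y = X[:, [0]] + 0.01 * rng.normal(size=(20, 1))
        model = PLSCalibrator(n_components=1).fit(X, y)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean(axis=0)
        u, *_ = np.linalg.svd(Xc.T @ yc)
        cosine = abs(float(u[:, 0] @ model.x_weights_[:, 0]))
        assert cosine > 0.999

    def test_mean_input_predicts_mean_output(self, rng):
        data = _linear_dataset(rng, noise=0.3)
        model = vc.pls_fit(data, n_components=4)
        pred = model.predict(data.X.mean(axis=0, keepdims=True))
        assert np.allclose(pred.ravel(), data.Y.mean(axis=0), atol=1e-10)

    def test_sample_order_invariance(self, rng):
        data = _linear_dataset(rng, noise=0.2)
        perm = rng.permutation(data.n_samples)
        m1 = vc.pls_fit(data, n_components=5)
        m2 = PLSCalibrator(n_components=5).fit(data.X[perm], data.Y[perm])
        probe = rng.normal(size=(7, data.X.shape[1]))
        assert np.allclose(m1.predict(probe), m2.predict(probe), atol=1e-8)

    def test_component_bound_enforced(self, rng):
        data = _linear_dataset(rng, n=10, p=8)
        with pytest.raises(ValueError, match="n_components"):
            vc.pls_fit(data, n_components=10)

    def test_zero_variance_column_flagged(self, rng):
        data = _linear_dataset(rng)
        X = data.X.copy()
        X[:, 0] = 5.0
        with pytest.warns(UserWarning, match="zero-variance"):
            PLSCalibrator(n_components=3).fit(X, data.Y)


class TestSelectComponents:
    def test_noiseless_low_rank_selects_at_most_rank(self, rng):
        data = _linear_dataset(rng, n=60, p=12, rank=4)
        assert vc.select_components(data, k_folds=5, max_components=10) <= 4

    def test_pure_noise_selects_minimum(self, rng):
        X = rng.normal(size=(60, 10))
        Y = rng.normal(size=(60, 4))
        data = CalibrationDataset(X=X, Y=Y)
        assert vc.select_components(data, k_folds=5, max_components=8) == 1

    def test_deterministic(self, rng):
        data = _linear_dataset(rng, n=60, p=12, rank=5, noise=0.5)
        picks = {vc.select_components(data, 5, 10) for _ in range(3)}
        assert len(picks) == 1


class TestMLP:
    def test_same_seed_identical_weights(self, rng):
        data = _linear_dataset(rng, n=30, p=6, q=2)
        kwargs = dict(hidden_layer_sizes=(5, 3), max_epochs=15, random_state=3)
        m1 = MLPCalibrator(**kwargs).fit(data.X, data.Y)
        m2 = MLPCalibrator(**kwargs).fit(data.X, data.Y)
        for W1, W2 in zip(m1.coefs_, m2.coefs_):
            assert np.array_equal(W1, W2)

    def test_sample_order_invariance_under_fixed_seed(self, rng):
        data = _linear_dataset(rng, n=30, p=6, q=2)
        perm = rng.permutation(30)
        kwargs = dict(hidden_layer_sizes=(5, 3), max_epochs=10, random_state=3)
        m1 = MLPCalibrator(**kwargs).fit(data.X, data.Y)
        m2 = MLPCalibrator(**kwargs).fit(data.X[perm], data.Y[perm])
        probe = rng.normal(size=(5, 6))
        assert np.allclose(m1.predict(probe), m2.predict(probe), atol=1e-4)

    def test_objective_never_increases_on_accepted_steps(self, rng):
        data = _linear_dataset(rng, n=30, p=6, q=2, noise=0.3)
        m = MLPCalibrator(hidden_layer_sizes=(5, 3), max_epochs=25).fit(
            data.X, data.Y
        )
        assert np.all(m.objective_improvements_ >= 0)

    def test_constant_inputs_predict_training_mean(self, rng):
        X = np.full((40, 6), 2.0)
        Y = rng.uniform(5, 50, size=(40, 3))
        m = MLPCalibrator(hidden_layer_sizes=(4, 3), max_epochs=60).fit(X, Y)
        pred = m.predict(np.full((3, 6), 2.0))
        assert np.allclose(pred, Y.mean(axis=0), rtol=0.1)

    def test_sgd_solver_reduces_error(self, rng):
        data = _linear_dataset(rng, n=40, p=6, q=2)
        m = MLPCalibrator(
            hidden_layer_sizes=(5, 3), solver="sgd", max_epochs=300, random_state=0
        ).fit(data.X, data.Y)
        assert m.objective_curve_[-1] < m.objective_curve_[0]

    def test_gradient_matches_finite_differences(self, rng):
        # Jacobian backprop against numerical differentiation
        m = MLPCalibrator(hidden_layer_sizes=(4, 3))
        shapes = m._shapes(5, 2)
        P = sum(o * i + o for o, i in shapes)
        w = rng.normal(scale=0.4, size=P)
        Z = rng.normal(size=(6, 5))
        Ws, bs = m._unpack(w, shapes)
        acts = m._forward(Z, Ws, bs)
        J = m._jacobian(acts, Ws)
        eps = 1e-6
        for pi in rng.choice(P, size=12, replace=False):
            dw = np.zeros(P)
            dw[pi] = eps
            Wp, bp = m._unpack(w + dw, shapes)
            Wm, bm = m._unpack(w - dw, shapes)
            num = (m._forward(Z, Wp, bp)[-1] - m._forward(Z, Wm, bm)[-1]) / (2 * eps)
            assert np.allclose(J[:, pi].reshape(6, 2), num, atol=1e-5)

    def test_training_performance_on_synthetic_calibration(self, seed1_pipeline):
        rep = seed1_pipeline.mlp_report
        for analyte in vc.ANALYTES:
            assert rep.per_analyte[analyte].training.R >= 0.97

    def test_single_sample_and_batch_prediction_agree(self, seed1_pipeline):
        mlp = seed1_pipeline.mlp
        X = seed1_pipeline.test.X
        batch = mlp.predict(X)
        singles = np.vstack([mlp.predict(X[i : i + 1]) for i in range(len(X))])
        assert np.allclose(batch, singles)

    def test_unknown_solver_rejected(self, rng):
        data = _linear_dataset(rng, n=10, p=4, q=2)
        with pytest.raises(ValueError, match="solver"):
            MLPCalibrator(solver="adam").fit(data.X, data.Y)

    def test_feature_count_checked_at_predict(self, rng):
        data = _linear_dataset(rng, n=20, p=6, q=2)
        m = MLPCalibrator(hidden_layer_sizes=(4, 3), max_epochs=5).fit(data.X, data.Y)
        with pytest.raises(ValueError, match="features"):
            m.predict(np.zeros((2, 5)))
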