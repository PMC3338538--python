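"""SVM, kernel and GP-EP classifier tests, each against an independent oracle."""

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.linalg import cholesky
from scipy.optimize import minimize
from scipy.special import ndtr

from mazemvpa.classifiers import (
    KernelSpec,
    center_kernel,
    center_test_kernel,
    gp_ep_train,
    gp_predict_prob,
    linear_kernel_inhom,
    sv_class_proportions,
    svm_predict,
    train_linear_svm,
)


class TestKernels:
    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        X1, X2 = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
        spec = KernelSpec(sigma=1.7, sigma0_sq=0.9, centering="none")
        K = linear_kernel_inhom(X1, X2, spec)
        for i in range(5):
            for j in range(4):
                oracle = 1.7**2 * sum(X1[i, d] * X2[j, d] for d in range(3)) + 0.9
                assert K[i, j] == pytest.approx(oracle, rel=1e-12)

    def test_orthonormal_rows_give_identity(self):
        X = np.eye(3)
        K = linear_kernel_inhom(X, X, KernelSpec(sigma=1.0, sigma0_sq=0.0))
        np.testing.assert_allclose(K, np.eye(3), atol=1e-12)

    def test_vanishing_sigma_leaves_bias_constant(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 2))
        K = linear_kernel_inhom(X, X, KernelSpec(sigma=1e-9, sigma0_sq=4.0))
        np.testing.assert_allclose(K, 4.0, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            linear_kernel_inhom(np.zeros((2, 3)), np.zeros((2, 4)))

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            KernelSpec(sigma=0.0)


class TestCentering:
    def test_centered_kernel_has_zero_means(self):
        rng = np.random.default_rng(2)
        K = center_kernel(rng.normal(size=(6, 6)))
        assert np.max(np.abs(K.mean(axis=0))) < 1e-10
        assert np.max(np.abs(K.mean(axis=1))) < 1e-10

    def test_centering_is_idempotent(self):
        rng = np.random.default_rng(3)
        K = rng.normal(size=(5, 5))
        np.testing.assert_allclose(center_kernel(center_kernel(K)), center_kernel(K))

    def test_square_centering_equals_projection_oracle(self):
        rng = np.random.default_rng(4)
        K = rng.normal(size=(7, 7))
        H = np.eye(7) - np.ones((7, 7)) / 7
        np.testing.assert_allclose(center_kernel(K), H @ K @ H, atol=1e-12)

    def test_train_mode_matches_feature_space_oracle(self):
        rng = np.random.default_rng(5)
        Xtr, Xte = rng.normal(size=(6, 4)), rng.normal(size=(3, 4))
        spec = KernelSpec(sigma=1.3, centering="train")
        K_tr = linear_kernel_inhom(Xtr, Xtr, spec)
        K_te = linear_kernel_inhom(Xte, Xtr, spec)
        centered = center_test_kernel(K_te, K_tr, mode="train")
        mu = Xtr.mean(axis=0)
        oracle = 1.3**2 * (Xte - mu) @ (Xtr - mu).T
        np.testing.assert_allclose(centered, oracle, atol=1e-10)


class TestSVM:
    def test_symmetric_pair_in_one_dimension(self):
        model = train_linear_svm(np.array([[-1.0], [1.0]]), np.array([-1, 1]))
        assert len(model.support) == 2
        assert model.b == pytest.approx(0.0, abs=1e-9)
        assert svm_predict(model, [[0.0]])[0] == 1  # boundary maps to +1
        assert list(svm_predict(model, [[-1.0], [1.0]])) == [-1, 1]

    def test_dual_objective_matches_qp_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(6, 2))
        y = np.array([1, 1, 1, -1, -1, -1])
        C = 1.0
        model = train_linear_svm(X, y, C=C)
        a_signed = np.zeros(6)
        a_signed[model.support] = model.dual_coef
        Q = X @ X.T
        obj_fit = np.sum(np.abs(a_signed)) - 0.5 * a_signed @ Q @ a_signed

        def neg_dual(a):
            s = a * y
            return -(a.sum() - 0.5 * s @ Q @ s)

        res = minimize(
            neg_dual,
            np.full(6, C / 2),
            bounds=[(0, C)] * 6,
            constraints=[{"type": "eq", "fun": lambda a: a @ y}],
            method="SLSQP",
            options={"ftol": 1e-14, "maxiter": 1000},
        )
        assert obj_fit == pytest.approx(-res.fun, abs=1e-6)

    def test_kkt_conditions_hold(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=30) > 0, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        model = train_linear_svm(X, y)
        alpha = np.abs(model.dual_coef)
        assert np.all(alpha >= -1e-9) and np.all(alpha <= 1.0 + 1e-9)
        assert np.sum(model.dual_coef) == pytest.approx(0.0, abs=1e-6)
        assert np.all(alpha > 0)  # support vectors are exactly the dual-active samples

    def test_duplicated_training_set_keeps_decision_function(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        m1 = train_linear_svm(X, y)
        m2 = train_linear_svm(np.vstack([X, X]), np.concatenate([y, y]), C=0.5)
        grid = rng.normal(size=(20, 3))
        # agreement is limited by the solver's working tolerance (1e-3)
        np.testing.assert_allclose(
            grid @ m1.w + m1.b, grid @ m2.w + m2.b, atol=2e-3
        )

    def test_predictions_match_explicit_loop(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(15, 4))
        y = np.where(X[:, 1] > 0, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        model = train_linear_svm(X, y)
        Xt = rng.normal(size=(5, 4))
        for i in range(5):
            score = sum(model.w[d] * Xt[i, d] for d in range(4)) + model.b
            assert svm_predict(model, Xt[i : i + 1])[0] == (1 if score >= 0 else -1)

    def test_sv_proportions_sum_to_one_and_balance_on_symmetric_data(self):
        model = train_linear_svm(np.array([[-1.0], [1.0]]), np.array([-1, 1]))
        props = sv_class_proportions(model)
        assert props == {-1: 0.5, 1: 0.5}
        assert sum(props.values()) == pytest.approx(1.0)

    def test_minority_class_overrepresented_among_support_vectors(self):
        # the mechanism behind SV-proportion diagnostics on imbalanced data
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.vstack(
                [rng.normal(0, 1, (90, 20)) + 0.3, rng.normal(0, 1, (30, 20)) - 0.3]
            )
            y = np.r_[np.ones(90, int), -np.ones(30, int)]
            props = sv_class_proportions(train_linear_svm(X, y))
            hits += props[-1] > 30 / 120
        assert hits >= 16


def _exact_log_marginal(K, y, n_nodes=50):
    """Tensor Gauss-Hermite quadrature of log integral N(f|0,K) prod Phi(y f)."""
    n = len(y)
    L = cholesky(K, lower=True)
    x, w = hermegauss(n_nodes)
    w = w / np.sqrt(2 * np.pi)
    grids = np.meshgrid(*([x] * n), indexing="ij")
    Z = np.stack([g.ravel() for g in grids])
    W = np.ones(Z.shape[1])
    for i in range(n):
        W *= w[np.searchsorted(x, Z[i])]
    F = L @ Z
    return float(np.log(np.sum(W * np.prod(ndtr(y[:, None] * F), axis=0))))


class TestGPEP:
    def test_mirror_symmetry_gives_half_probability(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0]])
        y = np.array([1, -1])
        model = gp_ep_train(
            X, y, spec=KernelSpec(sigma=1.0, centering="none"), optimize_sigma=False
        )
        p = gp_predict_prob(model, [[0.0, 0.0]])
        assert p[0] == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("trial", range(3))
    def test_log_marginal_matches_quadrature_oracle(self, trial):
        rng = np.random.default_rng(trial)
        X = rng.normal(size=(3, 2))
        y = np.array([1, -1, 1])
        model = gp_ep_train(
            X, y, spec=KernelSpec(sigma=1.5, centering="none"), optimize_sigma=False
        )
        exact = _exact_log_marginal(model.K - np.eye(3) * (model.jitter - 1e-10), y)
        assert model.log_marginal == pytest.approx(exact, abs=0.05)

    def test_label_flip_complements_probabilities(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(10, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        spec = KernelSpec(sigma=1.0, centering="none")
        m_pos = gp_ep_train(X, y, spec=spec, optimize_sigma=False)
        m_neg = gp_ep_train(X, -y, spec=spec, optimize_sigma=False)
        Xt = rng.normal(size=(6, 3))
        np.testing.assert_allclose(
            gp_predict_prob(m_pos, Xt), 1.0 - gp_predict_prob(m_neg, Xt), atol=1e-5
        )

    def test_confident_on_well_separated_point(self):
        # train-statistics centering here: independent centering removes the
        # test-block mean, which degenerates for a single test point
        rng = np.random.default_rng(11)
        X = np.vstack(
            [rng.normal(3, 0.3, (15, 2)), rng.normal(-3, 0.3, (15, 2))]
        )
        y = np.r_[np.ones(15, int), -np.ones(15, int)]
        model = gp_ep_train(X, y, spec=KernelSpec(centering="train"))
        p = gp_predict_prob(model, [[6.0, 6.0]])
        assert p[0] > 0.95

    def test_single_point_independent_centering_is_uninformative(self):
        # the convention of centering the test kernel block with its own
        # means zeroes a 1 x n block: one lone test point always gets 0.5
        rng = np.random.default_rng(14)
        X = np.vstack([rng.normal(2, 0.3, (10, 2)), rng.normal(-2, 0.3, (10, 2))])
        y = np.r_[np.ones(10, int), -np.ones(10, int)]
        model = gp_ep_train(X, y, optimize_sigma=False)
        assert gp_predict_prob(model, [[5.0, 5.0]])[0] == pytest.approx(0.5)

    def test_probabilities_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 4))
        y = np.where(X[:, 0] > 0, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        model = gp_ep_train(X, y, optimize_sigma=False)
        p = gp_predict_prob(model, rng.normal(size=(50, 4)) * 100)
        assert np.all(p > 0) and np.all(p < 1)

    def test_site_precisions_nonnegative_and_converged(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 5))
        y = np.where(X[:, 0] + 0.5 * rng.normal(size=20) > 0, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        model = gp_ep_train(X, y, optimize_sigma=False)
        assert np.all(model.tau_site >= 0)
        assert model.converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            gp_ep_train(np.zeros((4, 2)), np.ones(4, dtype=int))

    def test_binary_accuracy_on_separable_sampleset(self, separable_samples):
        s = separable_samples
        mask = np.isin(s.labels, ("faces", "buildings"))
        X, y = s.X[mask], np.where(s.labels[mask] == "faces", 1, -1)
        hold = s.blocks[mask] == s.blocks[mask].max()
        model = gp_ep_train(X[~hold], y[~hold])
        p = gp_predict_prob(model, X[hold])
        acc = np.mean((p > 0.5) == (y[hold] == 1))
        assert acc >= 0.95
        svm = train_linear_svm(X[~hold], y[~hold])
        assert np.mean(svm_predict(svm, X[hold]) == y[hold]) >= 0.95
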