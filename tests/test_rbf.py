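import math

import numpy as np
import pytest

from oxypond.errors import DegenerateCentersError
from oxypond.io import Normalizer, fit_normalizer
from oxypond.rbf import (
    RBFModel,
    compute_width,
    design_matrix,
    fit_rbf,
    fit_weights,
)


class TestWidth:
    def test_two_centers_distance_one(self):
        centers = np.array([[0, 0, 0, 0], [1, 0, 0, 0.0]])
        assert compute_width(centers) == pytest.approx(0.5)

    def test_eight_centers_dmax_four(self):
        # place 8 centers with max pairwise distance 4: sigma = 4/sqrt(16) = 1
        centers = np.zeros((8, 4))
        centers[:, 0] = np.linspace(0, 4, 8)
        assert compute_width(centers) == pytest.approx(4 / math.sqrt(16))

    def test_coincident_centers_rejected(self):
        with pytest.raises(DegenerateCentersError):
            compute_width(np.zeros((3, 4)))

    def test_single_center_rejected(self):
        with pytest.raises(DegenerateCentersError):
            compute_width(np.ones((1, 4)))


class TestDesignMatrix:
    def test_point_on_center_gives_one(self):
        c = np.array([[0.3, 0.1, 0.5, 0.9]])
        phi = design_matrix(c, c, sigma=0.7)
        assert phi[0, 0] == pytest.approx(1.0)

    def test_distance_sigma_sqrt2_gives_inverse_e(self):
        sigma = 0.4
        pts = np.array([[sigma * math.sqrt(2), 0, 0, 0.0]])
        centers = np.zeros((1, 4))
        phi = design_matrix(pts, centers, sigma)
        assert phi[0, 0] == pytest.approx(math.exp(-1), rel=1e-12)

    def test_entries_in_unit_interval_and_vanish_far_away(self):
        rng = np.random.default_rng(0)
        phi = design_matrix(rng.uniform(0, 1, (20, 4)),
                            rng.uniform(0, 1, (5, 4)), sigma=0.3)
        assert ((phi > 0) & (phi <= 1)).all()
        far = design_matrix(np.full((1, 4), 1e3), np.zeros((1, 4)), sigma=0.3)
        assert far[0, 0] == 0.0  # underflows to exactly 0 in float64


class TestWeights:
    def test_identity_design_returns_targets(self):
        y = np.array([1.0, -2.0, 3.0])
        np.testing.assert_allclose(fit_weights(np.eye(3), y), y)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        phi = design_matrix(rng.uniform(0, 1, (40, 4)),
                            rng.uniform(0, 1, (6, 4)), sigma=0.5)
        y = rng.normal(0, 1, 40)
        w = fit_weights(phi, y)
        oracle = np.linalg.solve(phi.T @ phi, phi.T @ y)
        np.testing.assert_allclose(w, oracle, atol=1e-8)

    def test_ridge_solution_matches_damped_normal_equations(self):
        rng = np.random.default_rng(9)
        phi = rng.uniform(0, 1, (15, 5))
        y = rng.normal(0, 1, 15)
        lam = 0.1
        w = fit_weights(phi, y, ridge=lam)
        oracle = np.linalg.solve(phi.T @ phi + lam * np.eye(5), phi.T @ y)
        np.testing.assert_allclose(w, oracle, rtol=1e-10)


class TestModel:
    def _exact_model(self, n=12, seed=4):
        rng = np.random.default_rng(seed)
        u = rng.uniform(0, 1, (n, 4))
        y = rng.uniform(1.5, 2.5, n)
        norm = Normalizer.identity()
        model = fit_rbf(u, y, u, norm)  # centers = training points
        return model, u, y

    def test_exact_interpolation_limit(self):
        model, u, y = self._exact_model()
        resid = model.predict(u) - y
        assert math.sqrt(float(np.mean(resid ** 2))) <= 1e-6

    def test_prediction_linear_in_weights(self):
        model, u, _ = self._exact_model()
        rng = np.random.default_rng(1)
        w1 = rng.normal(size=model.n_centers)
        w2 = rng.normal(size=model.n_centers)
        q = rng.uniform(0, 1, (5, 4))

        def predict_with(w):
            m = RBFModel(model.centers, model.sigma, w, model.normalizer)
            return m.predict(q)

        np.testing.assert_allclose(predict_with(w1 + w2),
                                   predict_with(w1) + predict_with(w2),
                                   rtol=1e-10)

    def test_unit_weight_at_center_predicts_one(self):
        model, u, _ = self._exact_model()
        w = np.zeros(model.n_centers)
        w[3] = 1.0
        m = RBFModel(model.centers, 1e-6, w, model.normalizer)
        assert m.predict(u[3]) == pytest.approx(1.0)

    def test_prediction_is_locally_lipschitz(self):
        model, u, _ = self._exact_model()
        q = np.full(4, 0.5)
        eps = 1e-7
        base = model.predict(q)
        for axis in range(4):
            dq = q.copy()
            dq[axis] += eps
            # Gaussian mixtures have bounded derivative ~ |w| d/sigma^2
            bound = np.abs(model.weights).sum() / model.sigma * math.exp(-0.5)
            assert abs(model.predict(dq) - base) <= (bound + 1) * eps

    def test_non_finite_query_rejected(self):
        model, _, _ = self._exact_model()
        with pytest.raises(ValueError):
            model.predict(np.array([np.nan, 0, 0, 0]))

    def test_fit_is_invariant_to_training_row_order(self, pond_survey):
        norm = fit_normalizer(pond_survey)
        u = norm.transform(pond_survey.X)
        y = pond_survey.y
        centers = u[::9][:8]
        m1 = fit_rbf(u, y, centers, norm)
        perm = np.random.default_rng(0).permutation(len(u))
        m2 = fit_rbf(u[perm], y[perm], centers, norm)
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-9)

    def test_save_load_round_trip_is_bit_exact(self, tmp_path):
        model, u, _ = self._exact_model()
        p = tmp_path / "model.json"
        model.save(p)
        again = RBFModel.load(p)
        assert again.sigma == model.sigma
        np.testing.assert_array_equal(again.centers, model.centers)
        np.testing.assert_array_equal(again.weights, model.weights)
        p2 = tmp_path / "model2.json"
        again.save(p2)
        assert p.read_bytes() == p2.read_bytes()
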