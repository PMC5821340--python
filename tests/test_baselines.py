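import numpy as np
import pytest

from oxypond.baselines import (
    VariogramModel,
    empirical_variogram,
    fit_variogram,
    idw_predict,
    kriging_predict,
    kriging_weights,
    standard_rbf_fit,
)
from oxypond.io import SampleSet


def toy_samples():
    """Five stations on a 1-D transect (x varies, y/z/t fixed)."""
    x = np.array([0.0, 25.0, 50.0, 80.0, 120.0])
    do = np.array([2.4, 2.2, 2.0, 1.9, 1.7])
    return SampleSet.from_arrays(np.zeros(5), x, np.full(5, 20.0),
                                 np.full(5, 1.0), do)


class TestStandardRBF:
    def test_k_equals_n_exact_interpolation(self, small_survey):
        model = standard_rbf_fit(small_survey, k=len(small_survey), seed=0)
        resid = model.predict(small_survey.X) - small_survey.y
        assert float(np.sqrt(np.mean(resid ** 2))) <= 1e-6

    def test_two_group_fixture_centers_at_group_means(self, two_groups):
        pts, means = two_groups
        data = SampleSet.from_arrays(pts[:, 0], pts[:, 1] * 100, pts[:, 2] * 40,
                                     pts[:, 3], np.full(10, 2.0))
        model = standard_rbf_fit(data, k=2, seed=123)
        # centers live in normalized space; compare against normalized means
        from oxypond.io import fit_normalizer
        u_means = fit_normalizer(data).transform(
            np.column_stack([means[:, 0], means[:, 1] * 100,
                             means[:, 2] * 40, means[:, 3]]))
        got = model.centers[np.argsort(model.centers[:, 0])]
        want = u_means[np.argsort(u_means[:, 0])]
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_same_seed_reproduces_model(self, small_survey):
        m1 = standard_rbf_fit(small_survey, k=5, seed=9)
        m2 = standard_rbf_fit(small_survey, k=5, seed=9)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.centers, m2.centers)

    def test_k_above_n_rejected(self, small_survey):
        with pytest.raises(ValueError):
            standard_rbf_fit(small_survey, k=len(small_survey) + 1, seed=0)


class TestIDW:
    def test_exact_at_sample_locations(self):
        data = toy_samples()
        np.testing.assert_allclose(idw_predict(data, data.X), data.y)

    def test_midpoint_of_two_equidistant_samples(self):
        data = SampleSet.from_arrays([0, 0], [0, 10], [0, 0], [1, 1], [2.0, 4.0])
        q = np.array([0.0, 5.0, 0.0, 1.0])
        assert idw_predict(data, q) == pytest.approx(3.0)

    def test_three_point_hand_case(self):
        # raw units, p=2: weights 1/d^2 with d = 1, 2, 4
        data = SampleSet.from_arrays([0, 0, 0], [1, 2, 4], [0, 0, 0],
                                     [0, 0, 0], [1.0, 2.0, 3.0])
        q = np.array([0.0, 0.0, 0.0, 0.0])
        w = np.array([1.0, 1 / 4, 1 / 16])
        expected = float((w * [1, 2, 3]).sum() / w.sum())
        assert idw_predict(data, q, normalize=False) == pytest.approx(expected)

    def test_bounded_by_sample_range(self, pond_survey):
        rng = np.random.default_rng(0)
        q = np.column_stack([rng.uniform(0, 40, 50), rng.uniform(0, 130, 50),
                             rng.uniform(0, 45, 50), rng.uniform(0, 1.6, 50)])
        pred = idw_predict(pond_survey, q)
        assert (pred >= pond_survey.y.min() - 1e-12).all()
        assert (pred <= pond_survey.y.max() + 1e-12).all()


class TestVariogram:
    def test_spherical_shape(self):
        v = VariogramModel(nugget=0.1, sill=1.0, range_=50.0)
        h = np.array([0.0, 25.0, 50.0, 200.0])
        g = v(h)
        assert g[0] == 0.0  # exact at zero lag
        assert g[3] == pytest.approx(1.0)  # sill beyond the range
        assert 0.1 < g[1] < g[2] <= 1.0

    def test_empirical_semivariance_hand_case(self):
        coords = np.array([[0, 0, 0], [10, 0, 0], [20, 0, 0.0]])
        values = np.array([1.0, 3.0, 2.0])
        h, gamma, counts = empirical_variogram(coords, values, lag=15.0, n_lags=2)
        # bin (0,15]: pairs (0,1) and (1,2): mean of {2, 0.5} = 1.25
        # bin (15,30]: pair (0,2): 0.5
        np.testing.assert_allclose(gamma, [1.25, 0.5])
        np.testing.assert_array_equal(counts, [2, 1])

    def test_fit_tracks_a_linear_transect(self):
        """For a pure linear profile, gamma(h) grows ~ h^2/2 at short lags;
        the fitted spherical curve must reproduce the binned semivariances
        it was fit to far better than a flat (pure-nugget) model would."""
        x = np.linspace(0, 120, 30)
        data = SampleSet.from_arrays(np.zeros(30), x, np.full(30, 20.0),
                                     np.full(30, 1.0), 2.4 - 0.005 * x)
        vgm = fit_variogram(data, lag=15.0, n_lags=8)
        h, gamma, _ = empirical_variogram(data.X[:, 1:4], data.y, 15.0, 8)
        fit_rss = float(((vgm(h) - gamma) ** 2).sum())
        flat_rss = float(((gamma.mean() - gamma) ** 2).sum())
        assert fit_rss < 0.2 * flat_rss


class TestKriging:
    def test_exact_at_samples_with_zero_nugget(self):
        data = toy_samples()
        vgm = VariogramModel(nugget=0.0, sill=0.2, range_=100.0)
        pred, var = kriging_predict(data, vgm, data.X)
        np.testing.assert_allclose(pred, data.y, atol=1e-8)
        np.testing.assert_allclose(var, 0.0, atol=1e-8)

    def test_weights_sum_to_one(self):
        data = toy_samples()
        vgm = VariogramModel(nugget=0.05, sill=0.3, range_=80.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            q = np.array([0.0, rng.uniform(0, 130), rng.uniform(0, 45),
                          rng.uniform(0, 1.6)])
            w = kriging_weights(data, vgm, q)
            assert w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_direct_solve(self):
        """Hand-assembled ordinary-kriging system solved independently."""
        data = toy_samples()
        vgm = VariogramModel(nugget=0.0, sill=0.25, range_=90.0)
        q = np.array([0.0, 60.0, 20.0, 1.0])

        coords = data.X[:, 1:4]
        n = len(coords)
        a = np.ones((n + 1, n + 1))
        a[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                a[i, j] = vgm(np.array([np.linalg.norm(coords[i] - coords[j])]))[0]
        b = np.ones(n + 1)
        for i in range(n):
            b[i] = vgm(np.array([np.linalg.norm(coords[i] - q[1:4])]))[0]
        sol = np.linalg.solve(a, b)
        expected = float(sol[:n] @ data.y)

        pred, _ = kriging_predict(data, vgm, q)
        assert pred == pytest.approx(expected, rel=1e-12)

    def test_duplicate_locations_averaged_with_warning(self):
        data = SampleSet.from_arrays([0, 0, 0, 0], [0, 0, 30, 60],
                                     [0, 0, 0, 0], [1, 1, 1, 1],
                                     [2.0, 3.0, 2.0, 1.8])
        vgm = VariogramModel(nugget=0.0, sill=0.2, range_=50.0)
        with pytest.warns(UserWarning, match="duplicate"):
            pred, _ = kriging_predict(data, vgm, np.array([0.0, 0.0, 0.0, 1.0]))
        assert pred == pytest.approx(2.5)  # mean of the duplicates

    def test_fit_variogram_on_survey_is_valid(self, pond_survey):
        vgm = fit_variogram(pond_survey, lag=10.0, n_lags=15)
        assert vgm.sill >= vgm.nugget >= 0
        assert vgm.range_ > 0
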