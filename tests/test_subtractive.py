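import math

import numpy as np
import pytest

from oxypond.errors import CalibrationError
from oxypond.subtractive import (
    ClusterConfig,
    DensityState,
    calibrate_alpha,
    compute_densities,
    revise_densities,
    subtractive_cluster,
)


def brute_force_sc(points, alpha, mu, delta):
    """Independent double-loop transcription of the density-selection rules.

    Used as the oracle: plain Python loops, no vectorization shared with
    the implementation.
    """
    pts = [np.asarray(p, dtype=float) for p in points]
    m = len(pts)
    dens = []
    for i in range(m):
        d = 0.0
        for j in range(m):
            d += math.exp(-float(np.sum((pts[i] - pts[j]) ** 2)) / (alpha / 2) ** 2)
        dens.append(d)
    beta = mu * alpha
    chosen = []
    d1 = None
    while len(chosen) < m:
        k = max(range(m), key=lambda i: (dens[i], -i))
        dk = dens[k]
        if d1 is None:
            d1 = dk
        elif dk / d1 < delta:
            break
        chosen.append(k)
        for i in range(m):
            dens[i] = max(
                dens[i] - dk * math.exp(
                    -float(np.sum((pts[i] - pts[k]) ** 2)) / (beta / 2) ** 2),
                0.0)
    return chosen


class TestDensities:
    def test_identical_points_have_density_m(self):
        pts = np.zeros((6, 4))
        np.testing.assert_allclose(compute_densities(pts, 0.5), 6.0)

    def test_single_point_density_is_one(self):
        np.testing.assert_allclose(compute_densities(np.zeros((1, 4)), 1.0), 1.0)

    def test_two_points_at_half_alpha(self):
        alpha = 0.8
        pts = np.array([[0, 0, 0, 0], [alpha / 2, 0, 0, 0.0]])
        expected = 1 + math.exp(-1)
        np.testing.assert_allclose(compute_densities(pts, alpha),
                                   [expected, expected], rtol=1e-12)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError):
            compute_densities(np.zeros((2, 4)), 0.0)


class TestRevision:
    def test_center_density_drops_to_zero(self):
        pts = np.array([[0, 0, 0, 0], [1, 0, 0, 0.0]])
        state = DensityState(densities=compute_densities(pts, 0.5))
        new = revise_densities(state, pts, 0, beta=0.75)
        assert new.densities[0] == 0.0

    def test_far_point_unchanged(self):
        pts = np.array([[0, 0, 0, 0], [1e6, 0, 0, 0.0]])
        state = DensityState(densities=np.array([2.0, 1.3]))
        new = revise_densities(state, pts, 0, beta=0.75)
        assert new.densities[1] == pytest.approx(1.3)

    def test_hand_value_at_beta_over_two(self):
        beta = 0.6
        pts = np.array([[0, 0, 0, 0], [beta / 2, 0, 0, 0.0]])
        state = DensityState(densities=np.array([2.0, 1.5]))
        new = revise_densities(state, pts, 0, beta=beta)
        assert new.densities[1] == pytest.approx(1.5 - 2 * math.exp(-1), abs=1e-6)

    def test_revision_floors_at_zero(self):
        pts = np.array([[0, 0, 0, 0], [0.01, 0, 0, 0.0]])
        state = DensityState(densities=np.array([5.0, 0.5]))
        new = revise_densities(state, pts, 0, beta=1.0)
        assert (new.densities >= 0).all()


class TestSelection:
    def test_two_groups_two_centers(self, two_groups):
        pts, means = two_groups
        centers, state = subtractive_cluster(
            pts, ClusterConfig(alpha=0.3, delta=0.15))
        assert len(centers) == 2
        # one center in each group
        labels = {int(np.linalg.norm(c - means[0]) > np.linalg.norm(c - means[1]))
                  for c in centers}
        assert labels == {0, 1}

    def test_identical_points_yield_single_center(self):
        centers, _ = subtractive_cluster(np.zeros((8, 4)), ClusterConfig())
        assert len(centers) == 1

    def test_selected_densities_non_increasing(self, pond_survey):
        from oxypond.io import fit_normalizer
        u = fit_normalizer(pond_survey).transform(pond_survey.X)
        _, state = subtractive_cluster(u, ClusterConfig(alpha=0.3))
        selected = [d for _, d in state.chosen]
        assert all(a >= b - 1e-12 for a, b in zip(selected, selected[1:]))

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        m = int(rng.integers(3, 51))
        pts = rng.uniform(0, 1, (m, 4))
        cfg = ClusterConfig(alpha=float(rng.uniform(0.2, 1.2)),
                            delta=float(rng.uniform(0.05, 0.5)))
        centers, state = subtractive_cluster(pts, cfg)
        oracle = brute_force_sc(pts, cfg.alpha, cfg.mu, cfg.delta)
        assert state.center_indices == oracle

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 1, (20, 4))
        cfg = ClusterConfig(alpha=0.4)
        _, state = subtractive_cluster(pts, cfg)
        perm = rng.permutation(20)
        _, state_p = subtractive_cluster(pts[perm], cfg)
        mapped = [int(np.where(perm == i)[0][0]) for i in state.center_indices]
        assert state_p.center_indices == mapped

    def test_small_alpha_limit_every_distinct_point_a_center(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 1, (12, 4))
        centers, _ = subtractive_cluster(
            pts, ClusterConfig(alpha=1e-4, delta=1 / 24))
        assert len(centers) == 12


class TestCalibration:
    def test_reproduces_requested_count(self, pond_survey):
        from oxypond.io import fit_normalizer
        u = fit_normalizer(pond_survey).transform(pond_survey.X)
        for target in (2, 10, 21):
            alpha = calibrate_alpha(u, target)
            centers, _ = subtractive_cluster(u, ClusterConfig(alpha=alpha))
            assert len(centers) == target

    def test_target_equal_to_distinct_points(self, two_groups):
        pts, _ = two_groups
        alpha = calibrate_alpha(pts, len(pts))
        centers, _ = subtractive_cluster(pts, ClusterConfig(alpha=alpha))
        assert len(centers) == len(pts)

    def test_target_zero_rejected(self, two_groups):
        pts, _ = two_groups
        with pytest.raises(ValueError):
            calibrate_alpha(pts, 0)

    def test_unreachable_target_reports_achievable(self):
        pts = np.zeros((5, 4))
        with pytest.raises(CalibrationError):
            calibrate_alpha(pts, 3)
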