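import numpy as np
import pytest

import _reference as ref
from pupilfcm.clustering import (
    FCMConfig,
    classical_fcm,
    objective,
    run_fcm,
    update_centers,
    update_memberships,
)
from pupilfcm.filtering import IntensityHistogram, gray_histogram


def _hist(counts_by_level: dict[int, int]) -> IntensityHistogram:
    counts = np.zeros(256, dtype=int)
    for level, n in counts_by_level.items():
        counts[level] = n
    return IntensityHistogram(counts=counts)


class TestObjective:
    def test_zero_when_single_level_sits_on_center(self):
        h = _hist({50: 10})
        u = np.ones((1, 1))
        assert objective(h, None, np.array([50.0]), u, 2.0) == 0.0

    def test_linear_in_counts(self):
        h1 = _hist({10: 3, 200: 7})
        h2 = _hist({10: 6, 200: 14})
        u = np.array([[0.8, 0.3], [0.2, 0.7]])
        c = np.array([30.0, 150.0])
        assert objective(h2, None, c, u, 2.0) == pytest.approx(
            2 * objective(h1, None, c, u, 2.0)
        )

    def test_matches_triple_loop(self):
        h = _hist({10: 4, 100: 6, 250: 2})
        levels = h.levels
        w = np.linspace(0.1, 0.4, 256)
        u = np.array([[0.9, 0.5, 0.1], [0.1, 0.5, 0.9]])
        c = np.array([20.0, 180.0])
        expected = ref.objective(
            levels.astype(float),
            h.counts[levels].astype(float),
            w[levels],
            u.tolist(),
            c,
            2.0,
        )
        assert objective(h, w, c, u, 2.0) == pytest.approx(expected, abs=1e-12)


class TestUpdateMemberships:
    def test_equidistant_level_splits_evenly(self):
        h = _hist({110: 5})
        u = update_memberships(h, None, np.array([20.0, 200.0]), 2.0)
        np.testing.assert_allclose(u[:, 0], [0.5, 0.5])

    def test_exact_hit_is_crisp(self):
        h = _hist({20: 5, 65: 3})
        u = update_memberships(h, None, np.array([20.0, 200.0]), 2.0)
        assert u[0, 0] == 1.0 and u[1, 0] == 0.0

    def test_matches_loop_and_prior_cancels(self):
        h = _hist({65: 3, 90: 2, 130: 4})
        centers = np.array([20.0, 200.0])
        u_uniform = update_memberships(h, None, centers, 2.0)
        u_prior = update_memberships(h, np.linspace(0.01, 0.9, 256), centers, 2.0)
        expected = np.array(ref.memberships(h.levels.astype(float), centers, 2.0))
        np.testing.assert_allclose(u_uniform, expected, atol=1e-12)
        # cluster-independent prior cancels row-wise in the normalization
        np.testing.assert_allclose(u_prior, u_uniform, atol=1e-15)

    def test_rows_sum_to_one(self, rng):
        h = _hist({int(l): int(n) for l, n in zip(rng.integers(0, 256, 30), rng.integers(1, 50, 30))})
        centers = np.sort(rng.uniform(0, 255, 4))
        u = update_memberships(h, None, centers, 2.0)
        np.testing.assert_allclose(u.sum(axis=0), 1.0, atol=1e-12)


class TestUpdateCenters:
    def test_single_level_attracts_all_centers(self):
        h = _hist({77: 9})
        u = np.array([[1.0], [1.0]])  # degenerate but normalized per level is moot here
        c = update_centers(h, None, u, 2.0)
        np.testing.assert_allclose(c, [77.0, 77.0])

    def test_uniform_prior_matches_loop(self):
        h = _hist({10: 4, 100: 6, 250: 2})
        u = np.array([[0.9, 0.4, 0.1], [0.1, 0.6, 0.9]])
        got = update_centers(h, None, u, 2.0)
        expected = ref.center_update(
            h.levels.astype(float),
            h.counts[h.levels].astype(float),
            [1.0] * 3,
            u.tolist(),
            2.0,
        )
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_concentrated_prior_pulls_centers(self):
        h = _hist({10: 5, 100: 5, 250: 5})
        w = np.full(256, 1e-9)
        w[100] = 1.0
        u = np.full((2, 3), 1 / 2)
        got = update_centers(h, w, u, 2.0)
        np.testing.assert_allclose(got, [100.0, 100.0], atol=1e-5)

    def test_empty_cluster_reseeded_at_far_level(self):
        h = _hist({10: 5, 250: 5})
        u = np.array([[1.0, 1.0], [0.0, 0.0]])  # cluster 1 has zero mass
        got = update_centers(h, None, u, 2.0)
        assert got[0] == pytest.approx(130.0)
        assert got[1] in (10.0, 250.0)


class TestRunFCM:
    def test_perfect_clusters_recovered(self):
        h = _hist({10: 20, 100: 20, 240: 20})
        state = run_fcm(h, None, FCMConfig(n_clusters=3))
        np.testing.assert_allclose(np.sort(state.centers), [10, 100, 240], atol=1e-6)

    def test_bimodal_centers(self):
        h = _hist({20: 50, 200: 50})
        state = run_fcm(h, None, FCMConfig(n_clusters=2))
        got = np.sort(state.centers)
        oracle = ref.pixel_fcm([20] * 50 + [200] * 50, 2)
        np.testing.assert_allclose(got, oracle, atol=1e-6)
        assert abs(got[0] - 20) < 0.5 and abs(got[1] - 200) < 0.5

    def test_objective_trace_non_increasing(self, rng):
        for _ in range(10):
            counts = rng.integers(0, 40, 256)
            h = IntensityHistogram(counts=counts)
            state = run_fcm(h, None, FCMConfig(max_iter=120))
            tr = state.objective_trace
            assert (np.diff(tr) <= 1e-9 * np.maximum(1.0, np.abs(tr[:-1]))).all()

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            run_fcm(IntensityHistogram(counts=np.zeros(256, int)))

    def test_deterministic_for_fixed_seed(self, rng):
        counts = rng.integers(0, 40, 256)
        h = IntensityHistogram(counts=counts)
        cfg = FCMConfig(init="random", seed=42)
        a = run_fcm(h, None, cfg)
        b = run_fcm(h, None, cfg)
        np.testing.assert_array_equal(a.centers, b.centers)
        assert a.n_iter == b.n_iter


class TestClassicalFCM:
    def test_identical_pixels_collapse(self):
        state = classical_fcm(np.full(30, 128.0), FCMConfig(n_clusters=2))
        np.testing.assert_allclose(state.centers, 128.0, atol=1e-3)

    def test_two_extreme_pixels(self):
        state = classical_fcm(np.array([0.0, 255.0]), FCMConfig(n_clusters=2))
        np.testing.assert_allclose(np.sort(state.centers), [0.0, 255.0], atol=0.5)

    def test_equivalent_to_histogram_fcm(self, rng):
        img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
        cfg = FCMConfig(n_clusters=4, max_iter=300)
        a = run_fcm(gray_histogram(img), None, cfg)
        b = classical_fcm(img.ravel(), cfg)
        np.testing.assert_allclose(np.sort(a.centers), np.sort(b.centers), atol=1e-4)
        assert a.n_iter == b.n_iter


class TestPriorScaleInvariance:
    def test_positive_rescaling_changes_nothing(self, rng):
        counts = rng.integers(0, 40, 256)
        h = IntensityHistogram(counts=counts)
        w = rng.uniform(0.01, 0.5, 256)
        cfg = FCMConfig(max_iter=150)
        for scale in (1e-6, 3.7, 1e6):
            a = run_fcm(h, w, cfg)
            b = run_fcm(h, w * scale, cfg)
            np.testing.assert_allclose(a.centers, b.centers, atol=1e-10)
            np.testing.assert_allclose(a.memberships, b.memberships, atol=1e-10)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_clusters": 1},
            {"fuzziness": 1.0},
            {"max_iter": 0},
            {"tol": 0.0},
            {"init": "bogus"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            FCMConfig(**kwargs)
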