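"""Slowness fitting, velocity, PCA and entropy of activation patterns."""

import numpy as np
import pytest

from pacemap.beats import cluster_beats
from pacemap.electrogram import ActivationEvent
from pacemap.spatial import (
    fit_slowness,
    interbeat_slowness_diff,
    pca_activation,
    slowness_entropy,
    slowness_to_velocity,
)


def normal_equations_fit(t, xy):
    """Independent closed-form OLS oracle."""
    X = np.column_stack([np.ones(len(t)), xy])
    beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(t, float))
    return beta  # [t0, s_x, s_y]


class TestSlownessFit:
    def test_identical_times_give_zero_slowness(self, layout_positions):
        sv = fit_slowness(np.full(12, 0.3), layout_positions)
        assert sv.norm == pytest.approx(0.0, abs=1e-12)

    def test_exact_planar_recovery(self, layout_positions):
        t = 0.005 + 0.0341 * layout_positions[:, 0]
        sv = fit_slowness(t, layout_positions)
        assert sv.s_x == pytest.approx(0.0341, abs=1e-12)
        assert sv.s_y == pytest.approx(0.0, abs=1e-12)
        assert sv.intercept == pytest.approx(0.005, abs=1e-12)
        assert sv.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, layout_positions, rng):
        for _ in range(20):
            t = rng.normal(0, 0.01, 12)
            sv = fit_slowness(t, layout_positions)
            beta = normal_equations_fit(t, layout_positions)
            np.testing.assert_allclose([sv.intercept, sv.s_x, sv.s_y], beta, atol=1e-12)

    def test_jittered_planar_recovery(self, layout_positions):
        """With 0.2 ms jitter the estimate stays within 3 SE of truth for
        nearly all of 500 draws."""
        rng = np.random.default_rng(7)
        true = np.array([0.02, -0.015])
        X = np.column_stack([np.ones(12), layout_positions])
        cov = np.linalg.inv(X.T @ X)
        se = 0.0002 * np.sqrt(np.diag(cov)[1:])
        hits = 0
        for _ in range(500):
            t = X @ np.array([0.001, *true]) + rng.normal(0, 0.0002, 12)
            sv = fit_slowness(t, layout_positions)
            if np.all(np.abs(np.array([sv.s_x, sv.s_y]) - true) < 3 * se):
                hits += 1
        assert hits > 480  # ~99.3% expected per component under normality

    def test_rotational_equivariance(self, layout_positions, rng):
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        s = np.array([0.02, 0.01])
        t = layout_positions @ s + 0.001
        sv0 = fit_slowness(t, layout_positions)
        t_rot = (layout_positions @ R.T) @ (R @ s) + 0.001
        sv1 = fit_slowness(t_rot, layout_positions @ R.T)
        np.testing.assert_allclose([sv1.s_x, sv1.s_y], R @ s, atol=1e-12)
        assert sv1.norm == pytest.approx(sv0.norm, abs=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_slowness([0, 1, 2], [[0, 0], [1, 0], [0, 1]])

    def test_collinear_layout_raises(self):
        xy = [[0, 0], [1, 0], [2, 0], [3, 0]]
        with pytest.raises(ValueError, match="collinear"):
            fit_slowness([0, 1, 2, 3], xy)


class TestVelocity:
    @pytest.mark.parametrize("norm,speed", [(0.0341, 29.3), (0.0334, 29.9)])
    def test_reported_speeds(self, norm, speed):
        v = slowness_to_velocity(np.array([norm, 0.0]))
        assert np.linalg.norm(v) == pytest.approx(speed, abs=0.05)

    def test_direction_preserved(self):
        s = np.array([0.03, 0.04])
        v = slowness_to_velocity(s)
        np.testing.assert_allclose(v / np.linalg.norm(v), s / np.linalg.norm(s))
        assert np.linalg.norm(v) == pytest.approx(1 / 0.05)

    def test_zero_slowness_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            slowness_to_velocity(np.zeros(2))


def beats_from_matrix(times_matrix, base=1.0):
    """Build a BeatSeries with one beat per row, electrodes 1..12."""
    events = []
    for i, row in enumerate(times_matrix):
        for j, t in enumerate(row):
            events.append(ActivationEvent(j + 1, base * i + t, 1.0))
    return cluster_beats(sorted(events, key=lambda e: e.time), gap=0.5)


class TestPCA:
    def test_rank_two_data_has_all_variance_in_two_components(self, layout):
        pos = layout[["x_cm", "y_cm"]].to_numpy()
        rng = np.random.default_rng(1)
        rows = []
        for _ in range(40):
            a, b = rng.normal(0, 0.02, 2)
            rows.append(a * pos[:, 0] + b * pos[:, 1])
        pca = pca_activation(beats_from_matrix(rows), layout)
        assert pca.cumulative_two == pytest.approx(1.0, abs=1e-10)

    def test_variance_fractions_sum_to_one_and_orthonormal(self, layout, rng):
        rows = rng.normal(0, 0.001, (30, 12))
        pca = pca_activation(beats_from_matrix(rows), layout)
        assert pca.variance_fractions.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(np.diff(pca.variance_fractions) <= 1e-12)
        G = pca.component_loadings @ pca.component_loadings.T
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-10)

    def test_matches_sklearn(self, layout, rng):
        from sklearn.decomposition import PCA

        rows = rng.normal(0, 0.001, (25, 12))
        ours = pca_activation(beats_from_matrix(rows), layout)
        ref = PCA().fit(rows - rows.mean(axis=1, keepdims=True))
        np.testing.assert_allclose(
            ours.variance_fractions, ref.explained_variance_ratio_, atol=1e-10
        )

    def test_pure_jitter_spreads_variance(self, layout, rng):
        rows = rng.normal(0, 0.0005, (200, 12))
        pca = pca_activation(beats_from_matrix(rows), layout)
        assert pca.cumulative_two < 0.5

    def test_too_few_complete_beats_raises(self, layout):
        with pytest.raises(ValueError, match="at least 3"):
            pca_activation(beats_from_matrix(np.zeros((2, 12))), layout)


class TestEntropy:
    def test_single_bin_zero_entropy(self):
        vecs = [np.array([0.0101, 0.0102])] * 9
        res = slowness_entropy(vecs)
        assert res.entropy == 0.0 and res.occupied_bins == 1

    def test_uniform_over_four_bins(self):
        vecs = [
            np.array([0.0025, 0.0025]),
            np.array([0.0075, 0.0025]),
            np.array([0.0025, 0.0075]),
            np.array([0.0075, 0.0075]),
        ] * 3
        res = slowness_entropy(vecs)
        assert res.entropy == pytest.approx(np.log(4), abs=1e-12)

    def test_weighted_three_bins(self):
        vecs = (
            [np.array([0.001, 0.001])] * 2
            + [np.array([0.006, 0.001])]
            + [np.array([0.001, 0.006])]
        )
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert slowness_entropy(vecs).entropy == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance_and_split_monotonicity(self, rng):
        vecs = [np.array(v) for v in rng.normal(0, 0.01, (50, 2))]
        e1 = slowness_entropy(vecs).entropy
        e2 = slowness_entropy(vecs[::-1]).entropy
        assert e1 == pytest.approx(e2, abs=1e-12)
        # splitting a cluster over more bins cannot lower the entropy
        finer = slowness_entropy(vecs, bin_size=0.0025).entropy
        assert finer >= e1 - 1e-12


class TestInterbeatDiff:
    def test_constant_slowness_zero_diff(self, layout_positions):
        sv = fit_slowness(layout_positions @ [0.03, 0.0] + 0.001, layout_positions)
        _, d = interbeat_slowness_diff([sv] * 5)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_alternating_orthogonal_vectors(self, layout_positions):
        a = fit_slowness(layout_positions @ [0.03, 0.0], layout_positions)
        b = fit_slowness(layout_positions @ [0.0, 0.03], layout_positions)
        _, d = interbeat_slowness_diff([a, b, a, b])
        np.testing.assert_allclose(d, 0.03 * np.sqrt(2), atol=1e-12)

    def test_ineligible_pairs_dropped(self, layout_positions):
        sv = fit_slowness(layout_positions @ [0.02, 0.01], layout_positions)
        idx, d = interbeat_slowness_diff([sv, None, sv, sv])
        assert idx.tolist() == [2]
        assert d.size == 1

    def test_diff_spikes_at_takeover(self, two_focus_truth, layout_positions):
        gt = two_focus_truth
        vecs = [fit_slowness(row, layout_positions) for row in gt.true_activation_times]
        idx, d = interbeat_slowness_diff(vecs)
        switch = np.diff(gt.firing_focus) != 0
        assert d[switch[idx]].min() > d[~switch[idx]].mean()
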