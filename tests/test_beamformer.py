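"""LCMV beamformer: subspace reduction, covariance pooling, orientation,
weights, and stationary/adaptive reconstruction."""

import numpy as np
import pytest

from hmmbeam import (
    LeadFieldSet,
    SensorDataset,
    SimConfig,
    StateSequence,
    build_leadfields,
    envelope_z,
    estimate_covariances,
    evaluate_reconstruction,
    lcmv_weights,
    line_grid_x,
    make_helmet_array,
    optimal_orientation,
    reconstruct,
    reduce_subspace,
    simulate_dataset,
    sliding_window_labels,
    source_std,
)
from hmmbeam.envelope import bandpass

from conftest import random_spd


def toy_leadfields(rng, V=3, N=6):
    return LeadFieldSet(
        voxels=np.arange(V * 3, dtype=float).reshape(V, 3),
        fields=rng.standard_normal((V, N, 3)),
    )


class TestReduceSubspace:
    def test_full_rank_projection_preserves_reconstruction(self, rng):
        N, T = 6, 800
        data = SensorDataset(rng.standard_normal((N, T)), fs=100.0)
        lf = toy_leadfields(rng, V=2, N=N)
        red, red_lf, P = reduce_subspace(data, lf, rank=N)
        covs = estimate_covariances(data, None)
        covs_r = estimate_covariances(red, None)
        est = reconstruct(data, lf, covs, None)
        est_r = reconstruct(red, red_lf, covs_r, None)
        np.testing.assert_allclose(est.mean, est_r.mean, atol=1e-8)
        np.testing.assert_allclose(est.std, est_r.std, atol=1e-8)

    def test_low_rank_data_variance_retained(self, rng):
        latent = rng.standard_normal((3, 2000))
        mix = rng.standard_normal((10, 3))
        data = SensorDataset(mix @ latent, fs=100.0)
        lf = toy_leadfields(rng, V=1, N=10)
        red, _, _ = reduce_subspace(data, lf, rank=3)
        assert red.data.var() * 3 / (data.data.var() * 10) > 0.999

    def test_rank_one_projector_is_dominant_eigenvector(self, rng):
        x = rng.standard_normal(5000)
        data = SensorDataset(np.vstack([x, -x + 0.01 * rng.standard_normal(5000)]), fs=1.0)
        lf = toy_leadfields(rng, V=1, N=2)
        _, _, P = reduce_subspace(data, lf, rank=1)
        expected = np.array([1.0, -1.0]) / np.sqrt(2)
        # sign convention: largest-magnitude component positive
        assert abs(abs(P[0] @ expected) - 1.0) < 1e-3
        assert P[0, np.argmax(np.abs(P[0]))] > 0

    def test_rank_out_of_range_rejected(self, rng):
        data = SensorDataset(rng.standard_normal((4, 100)), fs=1.0)
        with pytest.raises(ValueError, match="rank"):
            reduce_subspace(data, toy_leadfields(rng, N=4), rank=5)


class TestEstimateCovariances:
    def test_single_state_equals_full_exactly(self, rng):
        data = SensorDataset(rng.standard_normal((4, 500)), fs=1.0)
        u = StateSequence(np.ones(500, dtype=int), K=1, fs=1.0)
        covs = estimate_covariances(data, u)
        np.testing.assert_array_equal(covs.per_state[0], covs.full)

    def test_two_state_recovery_within_sampling_error(self, rng):
        T_k = 50_000
        y1 = rng.standard_normal((2, T_k))
        y2 = 3.0 * rng.standard_normal((2, T_k))
        data = SensorDataset(np.concatenate([y1, y2], axis=1), fs=1.0)
        labels = np.r_[np.ones(T_k, int), 2 * np.ones(T_k, int)]
        covs = estimate_covariances(data, StateSequence(labels, K=2, fs=1.0))
        # SE of a sample variance of N(0, s^2) is s^2 * sqrt(2/T)
        se1 = 1.0 * np.sqrt(2 / T_k)
        se2 = 9.0 * np.sqrt(2 / T_k)
        assert np.all(np.abs(np.diag(covs.per_state[0]) - 1.0) < 3 * se1)
        assert np.all(np.abs(np.diag(covs.per_state[1]) - 9.0) < 3 * se2)

    def test_rank_deficient_state_without_reg_rejected(self, rng):
        x = rng.standard_normal(300)
        data = SensorDataset(np.vstack([x, 2 * x]), fs=1.0)
        with pytest.raises(ValueError, match="reg"):
            estimate_covariances(data, None, reg=0.0)

    def test_undersampled_state_rejected(self, rng):
        data = SensorDataset(rng.standard_normal((8, 100)), fs=1.0)
        labels = np.ones(100, dtype=int)
        labels[:4] = 2
        with pytest.raises(ValueError, match="state 2"):
            estimate_covariances(data, StateSequence(labels, K=2, fs=1.0))

    def test_counts_sum_to_T(self, rng):
        data = SensorDataset(rng.standard_normal((2, 400)), fs=1.0)
        labels = rng.integers(1, 3, size=400)
        covs = estimate_covariances(data, StateSequence(labels, K=2, fs=1.0))
        assert covs.counts.sum() == 400


def brute_force_orientation(H3, C, n=20_000, seed=0):
    """Maximise the pseudo-Z objective by dense random search on the sphere."""
    rng = np.random.default_rng(seed)
    etas = rng.standard_normal((n, 3))
    etas /= np.linalg.norm(etas, axis=1, keepdims=True)
    Ci = np.linalg.inv(C)
    best, best_val = None, -np.inf
    for eta in etas:
        h = H3 @ eta
        val = (h @ Ci @ h) / (h @ Ci @ Ci @ h)
        if val > best_val:
            best, best_val = eta, val
    return best


class TestOptimalOrientation:
    def test_identity_covariance_prefers_strongest_column(self):
        """With white data the pseudo-Z is flat and the tie breaks to the
        largest forward gain: the norm-3 column."""
        H = np.diag([1.0, 2.0, 3.0])[np.r_[0, 1, 2, 2], :]  # 4x3, orthogonal cols
        eta = optimal_orientation(H[:3], np.eye(3))
        np.testing.assert_allclose(np.abs(eta), [0, 0, 1], atol=1e-10)

    def test_whitened_power_example(self):
        eta = optimal_orientation(np.eye(3), np.diag([1.0, 4.0, 9.0]))
        np.testing.assert_allclose(np.abs(eta), [0, 0, 1], atol=1e-10)

    def test_matches_brute_force_on_random_instances(self, rng):
        for i in range(3):
            H = rng.standard_normal((8, 3))
            C = random_spd(rng, 8)
            eta = optimal_orientation(H, C)
            ref = brute_force_orientation(H, C, seed=i)
            assert abs(eta @ ref) > 0.999

    def test_unit_norm(self, rng):
        for _ in range(5):
            eta = optimal_orientation(
                rng.standard_normal((6, 3)), random_spd(rng, 6)
            )
            assert abs(np.linalg.norm(eta) - 1.0) < 1e-12

    def test_rank_deficient_rejected(self, rng):
        H = np.zeros((5, 3))
        H[:, :2] = rng.standard_normal((5, 2))
        with pytest.raises(ValueError, match="rank deficient"):
            optimal_orientation(H, np.eye(5))


class TestLCMVWeights:
    def test_identity_case(self):
        W = lcmv_weights(np.array([1.0, 0.0]), np.eye(2))
        np.testing.assert_allclose(W, [1.0, 0.0])
        assert W @ np.array([1.0, 0.0]) == 1.0

    def test_closed_form_two_channel(self):
        W = lcmv_weights(np.array([1.0, 1.0]), np.diag([1.0, 2.0]))
        np.testing.assert_allclose(W, [2 / 3, 1 / 3], rtol=1e-12)

    def test_unit_gain_exact(self, rng):
        for _ in range(10):
            h = rng.standard_normal(5)
            C = random_spd(rng, 5)
            assert abs(lcmv_weights(h, C) @ h - 1.0) < 1e-12

    def test_minimum_variance_against_optimiser(self, rng):
        """Any unit-gain filter has at least the LCMV output variance;
        checked against a constrained optimiser."""
        from scipy.optimize import minimize

        for _ in range(3):
            N = 5
            h = rng.standard_normal(N)
            C = random_spd(rng, N)
            W = lcmv_weights(h, C)
            ours = W @ C @ W
            res = minimize(
                lambda w: w @ C @ w,
                x0=h / (h @ h),
                constraints=[{"type": "eq", "fun": lambda w: w @ h - 1.0}],
                method="SLSQP",
            )
            assert ours <= res.fun * (1 + 1e-6) + 1e-12

    def test_ill_conditioned_covariance_rejected(self):
        C = np.diag([1.0, 1e-14])
        with pytest.raises(ValueError, match="condition number"):
            lcmv_weights(np.array([1.0, 1.0]), C, cond_cap=1e10)


class TestSourceStd:
    def test_identity(self):
        assert source_std(np.array([1.0, 0.0]), np.eye(2)) == 1.0

    def test_direct_evaluation(self):
        val = source_std(np.array([2 / 3, 1 / 3]), np.diag([1.0, 2.0]))
        assert val == pytest.approx(np.sqrt(6) / 3)

    def test_homogeneity_in_covariance_scale(self, rng):
        W = rng.standard_normal(4)
        C = random_spd(rng, 4)
        assert source_std(W, 4.0 * C) == pytest.approx(2 * source_std(W, C))


class TestReconstruct:
    def test_single_state_adaptive_equals_stationary_bitwise(self, rng):
        data = SensorDataset(rng.standard_normal((6, 900)), fs=100.0)
        lf = toy_leadfields(rng, V=3, N=6)
        u = StateSequence(np.ones(900, dtype=int), K=1, fs=100.0)
        est_s = reconstruct(data, lf, estimate_covariances(data, None), None)
        est_a = reconstruct(data, lf, estimate_covariances(data, u), u)
        assert np.array_equal(est_s.mean, est_a.mean)
        assert np.array_equal(est_s.std, est_a.std)

    def test_noiseless_dipole_recovered_at_true_voxel(self):
        """A single simulated dipole with essentially no sensor noise is
        reconstructed with near-perfect in-band correlation."""
        cfg = SimConfig(duration_s=40.0, seed=5, confound_std=0.0)
        array = make_helmet_array(60)
        data, truth = simulate_dataset(cfg, array, snr=1e4)
        grid = np.array([[41.0, -25.0, 49.0]])
        lf = build_leadfields(array, grid)
        filt = bandpass(data, 13.0, 30.0)
        # diagonal loading: the near-noiseless covariance is almost rank-1
        covs = estimate_covariances(filt, None, reg=1e-2)
        est = reconstruct(filt, lf, covs, None)
        ref = bandpass(truth.signal_tc, 13.0, 30.0, fs=cfg.fs)
        r = np.corrcoef(est.mean[0], ref)[0, 1]
        assert abs(r) > 0.99

    def test_sliding_window_labels_drive_adaptive_path(self, rng):
        data = SensorDataset(rng.standard_normal((4, 1000)), fs=100.0)
        lf = toy_leadfields(rng, V=2, N=4)
        u = sliding_window_labels(1000, fs=100.0, window_s=2.5)
        assert u.K == 4
        covs = estimate_covariances(data, u)
        est = reconstruct(data, lf, covs, u)
        # std is block-constant: one value per (voxel, window)
        stds = est.std[0]
        for k in range(1, 5):
            block = stds[u.labels == k]
            assert np.all(block == block[0])

    def test_missing_state_covariance_rejected(self, rng):
        data = SensorDataset(rng.standard_normal((4, 400)), fs=1.0)
        lf = toy_leadfields(rng, V=1, N=4)
        covs = estimate_covariances(data, None)  # single matrix
        labels = np.r_[np.ones(200, int), 2 * np.ones(200, int)]
        with pytest.raises(ValueError, match="states"):
            reconstruct(data, lf, covs, StateSequence(labels, K=2, fs=1.0))

    def test_adaptive_std_positive_and_switching(self, rng):
        y1 = rng.standard_normal((4, 600))
        y2 = 5 * rng.standard_normal((4, 600))
        data = SensorDataset(np.concatenate([y1, y2], axis=1), fs=100.0)
        lf = toy_leadfields(rng, V=2, N=4)
        labels = np.r_[np.ones(600, int), 2 * np.ones(600, int)]
        u = StateSequence(labels, K=2, fs=100.0)
        est = reconstruct(data, lf, estimate_covariances(data, u), u)
        assert np.all(est.std > 0)
        assert est.std[0, 0] != est.std[0, -1]
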