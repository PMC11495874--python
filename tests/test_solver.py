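"""The alternating multi-view solver: fusion, beta/alpha updates, fits."""

import time
from dataclasses import replace

import numpy as np
import pytest

from mvhknn.data import FeatureDataset
from mvhknn.exceptions import ConfigurationError
from mvhknn.graphs import build_view_laplacians
from mvhknn.hknn import find_neighborhood, hknn_solve
from mvhknn.krp import KRPParams, lambda_diag, objective
from mvhknn.solver import (
    Hyperparameters,
    classify,
    fit_sample_class,
    fuse_laplacians,
    update_alpha,
    update_beta,
)
from mvhknn.synthetic import BlobConfig, generate_blobs


def _rand_psd(rng, k):
    M = rng.standard_normal((k, k))
    return M @ M.T


class TestFuseLaplacians:
    def test_single_view_is_identity_fusion(self, rng):
        L = _rand_psd(rng, 4)
        assert np.allclose(fuse_laplacians([L], [1.0], rho=2.0), L)

    def test_two_equal_weights_rho_two(self, rng):
        L1, L2 = _rand_psd(rng, 3), _rand_psd(rng, 3)
        fused = fuse_laplacians([L1, L2], [0.5, 0.5], rho=2.0)
        assert np.allclose(fused, 0.25 * (L1 + L2))

    def test_zero_laplacians_fuse_to_zero(self):
        Ls = [np.zeros((3, 3))] * 2
        assert np.all(fuse_laplacians(Ls, [0.5, 0.5], 2.0) == 0)


class TestUpdateBeta:
    def test_equal_traces_give_exact_uniform(self, rng):
        L = _rand_psd(rng, 4)
        alpha = rng.standard_normal(4)
        beta = update_beta(alpha, [L, L, L], rho=2.0)
        assert np.array_equal(beta, np.full(3, 1.0 / 3.0))

    def test_single_view_gets_all_weight(self, rng):
        beta = update_beta(rng.standard_normal(3), [_rand_psd(rng, 3)], rho=2.0)
        assert np.array_equal(beta, [1.0])

    def test_hand_computed_two_view_weights(self):
        # traces 1 and 4 with rho=2: tm = (1, 1/4) -> beta = (0.8, 0.2)
        L1 = np.eye(2)
        L2 = 4.0 * np.eye(2)
        alpha = np.array([1.0, 0.0])
        beta = update_beta(alpha, [L1, L2], rho=2.0)
        assert np.allclose(beta, [0.8, 0.2])

    def test_smoother_view_dominates_degenerate_trace(self, rng):
        # alpha in the null space of L1 -> view 1 maximally smooth
        L1 = np.diag([0.0, 1.0])
        L2 = np.eye(2)
        alpha = np.array([1.0, 0.0])
        beta = update_beta(alpha, [L1, L2], rho=2.0)
        assert beta[0] > 0.999
        assert np.isfinite(beta).all()
        assert beta.sum() == pytest.approx(1.0, abs=1e-12)

    def test_rho_must_exceed_one(self, rng):
        with pytest.raises(ConfigurationError):
            update_beta(np.ones(2), [np.eye(2)], rho=1.0)


class TestUpdateAlpha:
    def test_identity_lambda_reduces_to_ridge(self, rng):
        d, K = 9, 3
        V = rng.standard_normal((d, K))
        x = rng.standard_normal(d)
        got = update_alpha(x, V, np.ones(d), None, lambda1=0.5, lambda2=0.0)
        expected = np.linalg.solve(0.5 * np.eye(K) + V.T @ V, V.T @ x)
        assert np.allclose(got, expected)

    def test_unregularized_recovers_span_member(self, rng):
        d, K = 7, 3
        V = rng.standard_normal((d, K))
        alpha_true = rng.standard_normal(K)
        x = V @ alpha_true
        got = update_alpha(x, V, np.ones(d), None, 0.0, 0.0)
        assert np.linalg.norm(x - V @ got) <= 1e-8

    def test_fixed_point_is_stationary(self, rng):
        """Iterating the closed-form update to convergence yields a point
        that a further update moves by <= 1e-6, and the analytic gradient
        of the full objective vanishes there."""
        from mvhknn.krp import krp_loss_gradient

        d, K = 10, 3
        params = KRPParams()
        lam_r, mu = 0.05, 0.0
        lambda1 = 4 * params.sigma**2 * d * lam_r / params.p
        V = rng.standard_normal((d, K))
        x = rng.standard_normal(d)
        alpha = rng.standard_normal(K)
        for _ in range(200):
            Lam = lambda_diag(x - V @ alpha, params)
            alpha = update_alpha(x, V, Lam, None, lambda1, 0.0)
        Lam = lambda_diag(x - V @ alpha, params)
        alpha_next = update_alpha(x, V, Lam, None, lambda1, 0.0)
        assert np.linalg.norm(alpha_next - alpha) <= 1e-6
        grad = 2 * lam_r * alpha + krp_loss_gradient(x, V, alpha, params)
        assert np.linalg.norm(grad) <= 1e-6


class TestFitSampleClass:
    def test_large_sigma_limit_matches_ridge_hyperplane(self, small_blobs):
        """With a huge kernel bandwidth the reweighting matrix degenerates
        to the identity and one solver round reproduces the classical
        ridge hyperplane weights (ridge matched through lambda1)."""
        sigma = 1e6
        lam_r = 1e-15  # keeps lambda1 = 4 sigma^2 d lam_r / p moderate
        hp = Hyperparameters(
            lambda_r=lam_r,
            krp=KRPParams(sigma=sigma, lam=1.0, p=2.0),
            mu=0.0,
            K=5,
            iterations=1,
            views=("rbf",),
        )
        x = small_blobs.X[0] + 0.3
        state, _ = fit_sample_class(x, small_blobs, 0, hp)
        nb = find_neighborhood(x, small_blobs, 0, 5)
        lambda1, _ = hp.reparameterized(small_blobs.d)
        ridge_alpha = hknn_solve(x, nb, lambda1)
        assert np.allclose(state.alpha, ridge_alpha, atol=1e-3)

    def test_same_seed_gives_bitwise_identical_fit(self, small_blobs):
        hp = Hyperparameters(seed=42)
        x = small_blobs.X[7] + 0.1
        s1, o1 = fit_sample_class(x, small_blobs, 1, hp)
        s2, o2 = fit_sample_class(x, small_blobs, 1, hp)
        assert o1 == o2
        assert np.array_equal(s1.alpha, s2.alpha)
        assert s1.objective_trace == s2.objective_trace

    def test_d_not_exceeding_k_is_rejected_then_warned(self, rng):
        X = rng.standard_normal((20, 4))
        y = np.array([0] * 10 + [1] * 10)
        data = FeatureDataset([f"s{i}" for i in range(20)], X, y)
        hp = Hyperparameters(K=5)
        with pytest.raises(ConfigurationError, match="exceed"):
            fit_sample_class(rng.standard_normal(4), data, 0, hp)
        hp_soft = replace(hp, enforce_d_gt_K=False)
        with pytest.warns(UserWarning, match="exceed"):
            fit_sample_class(rng.standard_normal(4), data, 0, hp_soft)

    def test_beta_stays_on_simplex_every_iteration(self, small_blobs, rng):
        hp = Hyperparameters(iterations=4)
        for _ in range(10):
            x = rng.standard_normal(small_blobs.d) * 2
            state, _ = fit_sample_class(x, small_blobs, 0, hp)
            for beta in state.beta_trace:
                assert abs(beta.sum() - 1.0) <= 1e-12
                assert np.all((beta >= 0) & (beta <= 1))

    def test_objective_trace_mostly_descends(self, rng):
        """The alternation is not provably monotone; empirically the final
        objective is at or below the initial one nearly always."""
        data = generate_blobs(BlobConfig(n_per_class=20, d=12, separation=4.0, seed=5))
        hp = Hyperparameters(K=4)
        wins = 0
        trials = 200
        for t in range(trials):
            x = rng.standard_normal(12) + data.X[t % data.n]
            state, _ = fit_sample_class(x, data, t % 2, replace(hp, seed=t))
            if state.objective_trace[-1] <= state.objective_trace[0] + 1e-12:
                wins += 1
        assert wins / trials >= 0.95

    def test_query_on_training_point_beats_indicator_candidate(self, small_blobs):
        """When x coincides with a neighbour, the fitted objective cannot
        exceed the objective of the one-hot weight vector selecting it."""
        hp = Hyperparameters(lambda_r=1e-4, iterations=10)
        x = small_blobs.X[2].copy()
        state, obj = fit_sample_class(x, small_blobs, 0, hp)
        nb = state.neighborhood
        j = int(np.argmin(nb.distances))
        assert nb.distances[j] == 0.0
        e_j = np.zeros(hp.K)
        e_j[j] = 1.0
        candidate = objective(x, nb.V, e_j, state.L_star, hp.lambda_r, hp.mu, hp.krp)
        assert obj <= candidate + 1e-6


class TestClassify:
    def test_coincident_point_is_recovered(self, small_blobs):
        hp = Hyperparameters()
        lab, objs, score = classify(small_blobs.X[1], small_blobs, hp)
        assert lab == small_blobs.y[1] == 0
        assert objs[0] < objs[1]
        assert score == pytest.approx(objs[0] - objs[1])

    def test_perfectly_symmetric_tie_goes_to_class_zero(self):
        # mirror-image classes; the midpoint query ties exactly
        base = np.array(
            [[1.0, 0.0, 0.3, -0.2, 0.5], [2.0, 0.4, -0.1, 0.0, 0.1],
             [1.5, -0.3, 0.2, 0.6, -0.4], [2.5, 0.2, 0.0, -0.5, 0.3]]
        )
        X = np.vstack([base, -base])
        y = np.array([0] * 4 + [1] * 4)
        data = FeatureDataset([f"s{i}" for i in range(8)], X, y)
        hp = Hyperparameters(K=2, views=("rbf",))
        lab, objs, _ = classify(np.zeros(5), data, hp)
        assert objs[0] == pytest.approx(objs[1], rel=1e-9)
        assert lab == 0

    def test_single_view_equals_fusion_free_oracle(self, small_blobs, rng):
        """With one view, the full solver must match an independently
        coded single-Laplacian alternation (no fusion machinery)."""
        hp = Hyperparameters(views=("rbf",), seed=9)
        for _ in range(5):
            x = rng.standard_normal(small_blobs.d) * 2
            for c in (0, 1):
                state, obj = fit_sample_class(x, small_blobs, c, hp)
                obj_oracle, alpha_oracle = _single_view_oracle(x, small_blobs, c, hp)
                assert np.allclose(state.alpha, alpha_oracle, atol=1e-12)
                assert obj == pytest.approx(obj_oracle, abs=1e-12)

    def test_fit_time_scales_mildly_with_dimension(self):
        """Per-fit cost is near-linear in d at fixed K and n: doubling d
        should not triple the per-fit wall time (coarse check)."""
        times = {}
        for d in (200, 400):
            data = generate_blobs(BlobConfig(n_per_class=30, d=d, separation=6.0, seed=2))
            hp = Hyperparameters()
            x = data.X[0] + 0.1
            fit_sample_class(x, data, 0, hp)  # warm up
            t0 = time.perf_counter()
            for _ in range(30):
                fit_sample_class(x, data, 0, hp)
            times[d] = time.perf_counter() - t0
        assert times[400] / times[200] < 3.0


def _single_view_oracle(x, data, c, hp):
    """Test-local reimplementation of the alternating fit for m = 1."""
    nb = find_neighborhood(x, data, c, hp.K)
    pool = data.X[data.class_indices(c)]
    L = build_view_laplacians(nb, pool, hp.similarity_views(), hp.K,
                              hp.mutual_scope)[0].matrix
    rng = np.random.default_rng(hp.seed)
    alpha = rng.standard_normal(hp.K) / hp.K
    lambda1, lambda2 = hp.reparameterized(x.size)
    for _ in range(hp.iterations):
        Lam = lambda_diag(x - nb.V @ alpha, hp.krp)
        A = lambda1 * np.eye(hp.K) + nb.V.T @ (Lam[:, None] * nb.V) + lambda2 * L
        alpha = np.linalg.solve(A, nb.V.T @ (Lam * x))
    return objective(x, nb.V, alpha, L, hp.lambda_r, hp.mu, hp.krp), alpha
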