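"""Solver correctness: objective oracle, initialization, update rules, fit."""

import numpy as np
import pytest

from xintnmf.data_model import MultiOmicsDataset, OmicsLayer
from xintnmf.factorization import (
    FactorModel,
    Hyperparameters,
    _nn_lasso_columns,
    fit,
    init_H,
    init_W,
    objective,
    transform,
    update_H,
    update_W,
)
from xintnmf.network import assemble
from xintnmf.synthetic import SyntheticSpec, generate
from tests.conftest import make_layer


def naive_objective(dataset, L_dense, W, H, alpha, beta, gamma):
    """Independent four-term evaluation written from the objective definition,
    kept deliberately naive (explicit loops over layers/samples)."""
    recon = 0.0
    for layer, Wd in zip(dataset.layers, W):
        recon += 0.5 * np.linalg.norm(layer.values - Wd @ H, "fro") ** 2
    Wbar = np.vstack(W)
    net = 0.5 * alpha * np.trace(Wbar.T @ L_dense @ Wbar)
    w_l1 = sum(b * np.abs(Wd).sum() for b, Wd in zip(beta, W))
    h_l1 = sum(gamma[i] * np.abs(H[:, i]).sum() for i in range(H.shape[1]))
    return recon + net + w_l1 + h_l1


def grid_search_nn_lasso(Wbar, x, gamma, lo=0.0, hi=2.0, res=1e-3):
    """Exhaustive K=2 grid oracle for min_h>=0 1/2||x-Wh||^2 + gamma*||h||_1."""
    grid = np.arange(lo, hi + res, res)
    best, best_val = None, np.inf
    for h0 in grid:
        # inner coordinate closed over h1 evaluated on the grid too
        r = x - Wbar[:, 0] * h0
        vals = (
            0.5 * ((r[:, None] - np.outer(Wbar[:, 1], grid)) ** 2).sum(axis=0)
            + gamma * (h0 + grid)
        )
        j = int(np.argmin(vals))
        if vals[j] < best_val:
            best_val = vals[j]
            best = np.array([h0, grid[j]])
    return best, best_val


@pytest.fixture
def instance(rng, small_dataset):
    net = assemble(small_dataset, fallback_density=0.2)
    return small_dataset, net


class TestObjective:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, seed, small_dataset):
        rng = np.random.default_rng(seed)
        net = assemble(small_dataset, fallback_density=float(rng.uniform(0.1, 0.4)))
        K = 3
        W = [rng.random((l.n_features, K)) for l in small_dataset.layers]
        H = rng.random((K, small_dataset.n_samples))
        alpha, beta = float(rng.uniform(0, 5)), rng.uniform(0, 1, 2)
        gamma = rng.uniform(0, 1, small_dataset.n_samples)
        hp = Hyperparameters(K=K, alpha=alpha, beta=beta, gamma=gamma)
        got, terms = objective(small_dataset, net, W, H, hp)
        want = naive_objective(small_dataset, net.laplacian.toarray(), W, H, alpha, beta, gamma)
        assert got == pytest.approx(want, rel=1e-10)
        assert got == pytest.approx(sum(terms.values()), rel=1e-12)

    def test_perfect_reconstruction_zero(self, rng, small_dataset):
        K = 2
        W = [rng.random((l.n_features, K)) for l in small_dataset.layers]
        H = rng.random((K, small_dataset.n_samples))
        layers = [
            OmicsLayer(l.layer_id, l.feature_ids, l.sample_ids, Wd @ H)
            for l, Wd in zip(small_dataset.layers, W)
        ]
        exact = MultiOmicsDataset(layers)
        hp = Hyperparameters(K=K, alpha=0.0, beta=0.0, gamma=0.0)
        f, _ = objective(exact, None, W, H, hp)
        assert f == pytest.approx(0.0, abs=1e-18)

    def test_zero_H_gives_half_squared_norm(self, small_dataset):
        K = 2
        W = [np.ones((l.n_features, K)) for l in small_dataset.layers]
        H = np.zeros((K, small_dataset.n_samples))
        hp = Hyperparameters(K=K, alpha=0.0, beta=0.0, gamma=0.0)
        f, _ = objective(small_dataset, None, W, H, hp)
        want = 0.5 * sum((l.values**2).sum() for l in small_dataset.layers)
        assert f == pytest.approx(want, rel=1e-12)


class TestInitW:
    def test_rank1_recovers_leading_direction(self):
        rng = np.random.default_rng(0)
        u, v = rng.random(12) + 0.1, rng.random(9) + 0.1
        layer = OmicsLayer("a", [f"f{i}" for i in range(12)], [f"S{j}" for j in range(9)],
                           np.outer(u, v))
        ds = MultiOmicsDataset([layer])
        W = init_W(ds, K=1)[0]
        cos = W[:, 0] @ u / (np.linalg.norm(W[:, 0]) * np.linalg.norm(u))
        assert cos > 0.999

    def test_nonnegative_and_strictly_positive_after_epsilon(self, small_dataset):
        for Wd in init_W(small_dataset, K=3):
            assert (Wd > 0).all()

    def test_deterministic(self, small_dataset):
        A = init_W(small_dataset, K=3, seed=7)
        B = init_W(small_dataset, K=3, seed=7)
        for a, b in zip(A, B):
            np.testing.assert_array_equal(a, b)

    def test_infeasible_K_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="exceeds"):
            init_W(small_dataset, K=7)  # > min(m_d, N) = 5


class TestInitH:
    def test_unpenalized_limit_recovers_planted_h(self, rng):
        Wbar = rng.random((20, 3)) + 0.1
        h_star = rng.random((3, 4)) + 0.2
        X = Wbar @ h_star
        layer = OmicsLayer("a", [f"f{i}" for i in range(20)], [f"S{j}" for j in range(4)], X)
        ds = MultiOmicsDataset([layer])
        H, gamma = init_H(ds, [Wbar], gamma_mode=0.0)
        np.testing.assert_allclose(H, h_star, atol=1e-5)
        assert (gamma == 0).all()

    def test_large_gamma_shrinks_to_zero(self, rng, small_dataset):
        W = init_W(small_dataset, K=2)
        H, _ = init_H(small_dataset, W, gamma_mode=1e6)
        assert (H == 0).all()

    def test_all_zero_sample_column_warns(self, rng):
        vals = rng.random((6, 3)) + 0.1
        vals[:, 1] = 0.0
        layer = OmicsLayer("a", [f"f{i}" for i in range(6)], ["S0", "S1", "S2"], vals)
        ds = MultiOmicsDataset([layer])
        W = [rng.random((6, 2)) + 0.1]
        with pytest.warns(UserWarning, match="all-zero sample"):
            H, gamma = init_H(ds, W, gamma_mode="cv", seed=0)
        assert (H[:, 1] == 0).all() and gamma[1] == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_grid_oracle_K2(self, seed):
        rng = np.random.default_rng(seed)
        Wbar = rng.random((15, 2)) + 0.1
        x = rng.random(15)
        gamma = float(rng.uniform(0.0, 0.5))
        G, C = Wbar.T @ Wbar, (Wbar.T @ x)[:, None]
        h = _nn_lasso_columns(G, C, np.array([gamma]), tol=1e-10)[:, 0]
        h_grid, val_grid = grid_search_nn_lasso(Wbar, x, gamma)
        my_val = 0.5 * ((x - Wbar @ h) ** 2).sum() + gamma * h.sum()
        assert my_val <= val_grid + 1e-6
        np.testing.assert_allclose(h, h_grid, atol=2e-3)


class TestUpdateW:
    def test_fixed_point_at_exact_factorization(self, rng):
        K = 2
        W_true = [rng.random((6, K)) + 0.1, rng.random((4, K)) + 0.1]
        H = rng.random((K, 5)) + 0.1
        layers = [
            OmicsLayer("a", [f"a{i}" for i in range(6)], [f"S{j}" for j in range(5)], W_true[0] @ H),
            OmicsLayer("b", [f"b{i}" for i in range(4)], [f"S{j}" for j in range(5)], W_true[1] @ H),
        ]
        ds = MultiOmicsDataset(layers)
        hp = Hyperparameters(K=K, alpha=0.0, beta=0.0, gamma=0.0)
        W_new = update_W(ds, None, W_true, H, hp)
        for a, b in zip(W_true, W_new):
            np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_zero_stays_zero_without_epsilon(self, rng, small_dataset):
        K = 2
        W = [rng.random((l.n_features, K)) for l in small_dataset.layers]
        W[0][3, :] = 0.0
        H = rng.random((K, small_dataset.n_samples))
        hp = Hyperparameters(K=K, alpha=0.0, beta=0.0, gamma=0.0)
        W_new = update_W(small_dataset, None, W, H, hp)
        assert (W_new[0][3, :] == 0).all()

    @pytest.mark.parametrize("alpha,beta", [(0.0, 0.0), (0.5, 0.1), (5.0, 0.0)])
    def test_descent_over_seeds(self, alpha, beta, small_dataset):
        net = assemble(small_dataset, fallback_density=0.25)
        hp = Hyperparameters(K=3, alpha=alpha, beta=beta, gamma=0.0)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            W = [rng.random((l.n_features, 3)) + 0.05 for l in small_dataset.layers]
            H = rng.random((3, small_dataset.n_samples))
            f0, _ = objective(small_dataset, net, W, H, hp)
            W1 = update_W(small_dataset, net, W, H, hp)
            f1, _ = objective(small_dataset, net, W1, H, hp)
            assert f1 <= f0 + 1e-9


class TestUpdateH:
    def test_orthogonal_design_closed_form(self, rng):
        K, n = 3, 4
        Q = np.linalg.qr(rng.random((12, K)))[0]
        Wbar = np.abs(Q)  # not orthogonal after abs; build truly orthogonal nonneg
        Wbar = np.zeros((12, K))
        for k in range(K):
            Wbar[4 * k : 4 * (k + 1), k] = rng.random(4) + 0.2  # disjoint support
        X = rng.random((12, n))
        layer = OmicsLayer("a", [f"f{i}" for i in range(12)], [f"S{j}" for j in range(n)], X)
        ds = MultiOmicsDataset([layer])
        H0 = np.zeros((K, n))
        H = update_H(ds, [Wbar], H0, np.zeros(n))
        expect = np.maximum(0.0, (Wbar.T @ X) / (Wbar**2).sum(axis=0)[:, None])
        np.testing.assert_allclose(H, expect, atol=1e-8)

    def test_full_shrinkage_threshold(self, rng, small_dataset):
        W = init_W(small_dataset, K=2)
        Wbar = np.vstack(W)
        Xbar = small_dataset.stacked()
        gmax = (Wbar.T @ Xbar).max(axis=0)
        H = update_H(small_dataset, W, np.zeros((2, small_dataset.n_samples)), gmax + 1e-9)
        assert (H == 0).all()


class TestFit:
    def test_noiseless_recovery(self):
        spec = SyntheticSpec(noise_sd=0.0, seed=3)
        cohort = generate(spec)
        hp = Hyperparameters(K=spec.K_true, alpha=0.0, beta=0.0, gamma=0.0, max_iter=500)
        model = fit(cohort.dataset, None, hp)
        norm2 = sum((l.values**2).sum() for l in cohort.dataset.layers)
        recon = 2 * model.objective_trace[-1]  # alpha=beta=gamma=0: f = 1/2 error
        assert recon <= 1e-3 * norm2

    def test_max_iter_zero_returns_initialization(self, instance):
        ds, net = instance
        hp = Hyperparameters(K=2, alpha=1.0, beta=0.1, max_iter=0, seed=1)
        model = fit(ds, net, hp)
        assert model.n_iter == 0 and not model.converged
        assert len(model.objective_trace) == 1
        W0 = init_W(ds, K=2, seed=1)
        for a, b in zip(model.W, W0):
            np.testing.assert_array_equal(a, b)

    def test_deterministic_traces(self, instance):
        ds, net = instance
        hp = Hyperparameters(K=2, alpha=0.5, beta=0.05, max_iter=30, seed=11)
        m1 = fit(ds, net, hp)
        m2 = fit(ds, net, hp)
        assert m1.objective_trace == m2.objective_trace
        np.testing.assert_array_equal(m1.H, m2.H)

    def test_trace_monotone_nonincreasing(self, instance):
        ds, net = instance
        hp = Hyperparameters(K=3, alpha=2.0, beta=0.1, max_iter=100, seed=5)
        model = fit(ds, net, hp)
        diffs = np.diff(model.objective_trace)
        assert (diffs <= 1e-9).all()

    def test_alpha_zero_never_touches_network(self, small_dataset):
        class Tripwire:
            def __getattr__(self, name):
                raise AssertionError(f"network accessed ({name}) despite alpha=0")

        hp = Hyperparameters(K=2, alpha=0.0, beta=0.1, max_iter=5, seed=0)
        model = fit(small_dataset, Tripwire(), hp)
        assert model.n_iter == 5 or model.converged


class TestTransform:
    def test_training_sample_roundtrip(self, instance):
        ds, net = instance
        hp = Hyperparameters(K=2, alpha=0.5, beta=0.01, max_iter=60, seed=2)
        model = fit(ds, net, hp)
        H_again = transform(model, ds, gamma_mode=model.gamma)
        np.testing.assert_allclose(H_again, model.H, atol=1e-5)

    def test_all_zero_sample_maps_to_zero(self, instance, rng):
        ds, net = instance
        hp = Hyperparameters(K=2, alpha=0.0, beta=0.01, max_iter=30, seed=2)
        model = fit(ds, None, hp)
        layers = [
            OmicsLayer(l.layer_id, l.feature_ids, ["T0"], np.zeros((l.n_features, 1)))
            for l in ds.layers
        ]
        with pytest.warns(UserWarning, match="all-zero"):
            H_t = transform(model, MultiOmicsDataset(layers))
        assert (H_t == 0).all()

    def test_planted_test_sample_recovered(self, instance, rng):
        ds, net = instance
        hp = Hyperparameters(K=2, alpha=0.0, beta=0.0, gamma=0.0, max_iter=200, seed=2)
        model = fit(ds, None, hp)
        h_star = rng.random((2, 1)) + 0.5
        Xt = model.Wbar @ h_star
        off = 0
        layers = []
        for l, W in zip(ds.layers, model.W):
            layers.append(OmicsLayer(l.layer_id, l.feature_ids, ["T0"], Xt[off : off + W.shape[0]]))
            off += W.shape[0]
        H_t = transform(model, MultiOmicsDataset(layers), gamma_mode=0.0)
        np.testing.assert_allclose(H_t, h_star, rtol=1e-4)

    def test_feature_mismatch_lists_missing(self, instance):
        ds, net = instance
        hp = Hyperparameters(K=2, alpha=0.0, beta=0.0, max_iter=5)
        model = fit(ds, None, hp)
        bad = MultiOmicsDataset(
            [
                OmicsLayer(l.layer_id, [f + "_x" for f in l.feature_ids], l.sample_ids, l.values)
                for l in ds.layers
            ]
        )
        with pytest.raises(ValueError, match="feature mismatch"):
            transform(model, bad)


class TestAlphaScaleSanity:
    def test_network_penalty_nonincreasing_in_alpha(self):
        """Raising the network weight shrinks the fitted Laplacian quadratic:
        the penalty term value is non-increasing over an alpha grid, checked
        as a majority vote over seeds."""
        from xintnmf.network import laplacian_quadratic
        from xintnmf.synthetic import SyntheticSpec, generate

        votes = 0
        n_seeds = 5
        for seed in range(n_seeds):
            c = generate(SyntheticSpec(seed=seed, m=(20, 12), N=30))
            vals = []
            for a in (0.01, 0.1, 1.0, 10.0):
                m = fit(c.dataset, c.network,
                        Hyperparameters(K=3, alpha=a, beta=0.01, seed=seed, max_iter=150))
                vals.append(laplacian_quadratic(c.network, m.Wbar))
            votes += all(vals[i + 1] <= vals[i] + 1e-9 for i in range(len(vals) - 1))
        assert votes > n_seeds / 2
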