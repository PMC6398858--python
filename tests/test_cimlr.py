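import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import adjusted_rand_score

from plasmaclust import (
    Hyperparams,
    build_kernel_bank,
    embed_and_cluster,
    estimate_num_clusters,
    fit_cimlr,
    objective,
)
from plasmaclust.cimlr import project_rows_to_simplex


class TestSimplexProjection:
    def test_matches_fine_grid_search(self):
        rng = np.random.default_rng(0)
        t = rng.normal(0.3, 0.5, size=4)
        proj = project_rows_to_simplex(t[None, :])[0]
        best, best_d = None, np.inf
        step = 50
        for comp in itertools.product(range(step + 1), repeat=3):
            if sum(comp) > step:
                continue
            s = np.array([*comp, step - sum(comp)]) / step
            d = np.sum((s - t) ** 2)
            if d < best_d:
                best, best_d = s, d
        assert np.sum((proj - t) ** 2) <= best_d + 1e-12
        np.testing.assert_allclose(proj, best, atol=1.0 / step)

    @settings(max_examples=100, deadline=None)
    @given(arrays(np.float64, (3, 5), elements=st.floats(-5, 5)))
    def test_output_is_on_the_simplex_and_optimal(self, V):
        P = project_rows_to_simplex(V)
        assert (P >= 0).all()
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        # no feasible point is closer (spot-check with random candidates)
        rng = np.random.default_rng(0)
        for _ in range(10):
            cand = rng.dirichlet(np.ones(5))
            for row in range(3):
                assert (np.sum((P[row] - V[row]) ** 2)
                        <= np.sum((cand - V[row]) ** 2) + 1e-9)

    def test_shift_invariance(self, rng):
        V = rng.normal(size=(4, 6))
        np.testing.assert_allclose(
            project_rows_to_simplex(V), project_rows_to_simplex(V + 3.7), atol=1e-12)


class TestObjective:
    def hand_bank(self):
        column = np.array([0.1, 0.5, 0.9])
        return build_kernel_bank(column[:, None], k_grid=(1,), sigma_grid=(1.0,))

    def test_matches_loop_computation_on_three_subjects(self):
        bank = self.hand_bank()
        hp = Hyperparams(n_clusters=2, normalize_kernels=False)
        S = np.eye(3)  # each row a point mass on itself
        A = np.eye(3)[:, :2]
        w = np.array([1.0])
        gamma, mu, beta = 0.7, 1.3, 0.4
        got = objective(S, A, w, bank, hp, gamma=gamma, mu=mu, beta=beta)
        K = bank.kernels[0]
        kernel_term = -sum(w[0] * K[i, j] * S[i, j] for i in range(3) for j in range(3))
        lap = np.eye(3) - S
        trace_term = gamma * np.trace(A.T @ lap @ A)
        entropy_term = mu * w[0] * np.log(w[0])
        frob_term = beta * np.sum(S ** 2)
        assert got == pytest.approx(kernel_term + trace_term + entropy_term + frob_term)

    def test_frobenius_closed_form_for_uniform_similarity(self):
        bank = self.hand_bank()
        hp = Hyperparams(n_clusters=2, normalize_kernels=False)
        n = 3
        S = np.full((n, n), 1.0 / n)  # ||S||_F^2 = n^2 / n^2 = 1
        A = np.eye(n)[:, :2]
        w = np.array([1.0])
        beta = 0.9
        base = objective(S, A, w, bank, hp, gamma=1.0, mu=1.0, beta=beta)
        doubled = objective(S, A, w, bank, hp, gamma=1.0, mu=1.0, beta=2 * beta)
        assert doubled - base == pytest.approx(beta * 1.0)

    def test_entropy_closed_form_at_uniform_weights(self):
        column = np.linspace(0, 1, 6)
        bank = build_kernel_bank(column[:, None], k_grid=(2, 3), sigma_grid=(1.0, 2.0))
        q = bank.n_kernels
        hp = Hyperparams(n_clusters=2, normalize_kernels=False)
        S = np.eye(6)
        A = np.eye(6)[:, :2]
        w = np.full(q, 1.0 / q)
        mu = 2.5
        with_entropy = objective(S, A, w, bank, hp, gamma=1.0, mu=mu, beta=1.0)
        without = objective(S, A, w, bank, hp, gamma=1.0, mu=1e-300, beta=1.0)
        assert with_entropy - without == pytest.approx(mu * np.log(1.0 / q))

    def test_shape_mismatch_raises(self):
        bank = self.hand_bank()
        hp = Hyperparams(n_clusters=2)
        with pytest.raises(ValueError, match="S must be"):
            objective(np.eye(4), np.eye(3)[:, :2], np.array([1.0]), bank, hp,
                      gamma=1.0, mu=1.0, beta=1.0)


class TestFit:
    def test_constraints_hold_on_fitted_model(self, small_model):
        S, A, w = small_model.S, small_model.A, small_model.w
        assert (S >= -1e-12).all()
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-6)
        assert (w >= 0).all()
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(A.T @ A, np.eye(small_model.n_clusters), atol=1e-6)

    def test_objective_trace_non_increasing(self, small_model):
        tr = small_model.objective_trace
        slack = small_model.hyperparams.tol * np.abs(tr[:-1]) + 1e-9
        assert (np.diff(tr) <= slack).all()

    def test_recovers_planted_clusters(self, small_cohort, small_model):
        ari = adjusted_rand_score(small_cohort.true_cluster, small_model.labels)
        assert ari >= 0.9

    def test_single_cluster_data_converges_without_error(self, rng):
        X = rng.random((40, 6))  # no structure at all
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bank = build_kernel_bank(X)
        model = fit_cimlr(bank, Hyperparams(n_clusters=4, max_iter=20))
        assert np.isfinite(model.objective_trace).all()
        np.testing.assert_allclose(model.S.sum(axis=1), 1.0, atol=1e-6)

    def test_too_many_clusters_rejected(self, small_bank):
        with pytest.raises(ValueError, match="n_clusters"):
            fit_cimlr(small_bank, Hyperparams(n_clusters=90))

    def test_permutation_equivariance(self, small_cohort, small_scaled, small_model):
        rng = np.random.default_rng(5)
        perm = rng.permutation(small_scaled.values.shape[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bank_p = build_kernel_bank(small_scaled.values[perm])
        model_p = fit_cimlr(bank_p, Hyperparams(n_clusters=3))
        np.testing.assert_allclose(
            model_p.S, small_model.S[np.ix_(perm, perm)], atol=1e-8)
        embed_and_cluster(model_p, seed=0)
        assert adjusted_rand_score(small_model.labels[perm], model_p.labels) == 1.0


class TestEmbedAndCluster:
    def test_same_seed_identical_labels(self, small_bank):
        m1 = embed_and_cluster(fit_cimlr(small_bank, Hyperparams(n_clusters=3)), seed=7)
        m2 = embed_and_cluster(fit_cimlr(small_bank, Hyperparams(n_clusters=3)), seed=7)
        np.testing.assert_array_equal(m1.labels, m2.labels)
        np.testing.assert_allclose(m1.embedding, m2.embedding)

    def test_embedding_shape(self, small_model):
        assert small_model.embedding.shape == (90, 2)
        assert sorted(np.unique(small_model.labels)) == [0, 1, 2]


class TestEstimateNumClusters:
    def test_empty_or_out_of_range_c_rejected(self, small_model):
        with pytest.raises(ValueError, match="empty"):
            estimate_num_clusters(small_model.S, [])
        with pytest.raises(ValueError, match="within"):
            estimate_num_clusters(small_model.S, [60])

    def test_eigengap_finds_planted_three_clusters(self, small_model):
        sel = estimate_num_clusters(small_model.S, range(2, 7), seed=0)
        assert 3 in sel["eigengap_selected"]

    def test_elbow_finds_planted_three_clusters_in_embedding(self, small_model):
        sel = estimate_num_clusters(
            small_model.S, range(2, 7), seed=0, embedding=small_model.embedding)
        assert 3 in sel["elbow_selected"]
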