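"""Objective evaluation and multiplicative-update optimization."""

import numpy as np
import pytest

import cemodule as cm

from conftest import random_state


def term_by_term_objective(dataset, nets, hp, state):
    """Independent oracle: each of the nine summands computed separately
    with elementary operations (no shared code with the implementation)."""
    W, H1, H2, H3 = state.W, state.H1, state.H2, state.H3
    Xs = (dataset.lnc.values, dataset.mir.values, dataset.mrna.values)
    Hs = (H1, H2, H3)
    K = W.shape[1]

    def frob2(M):
        return sum(M[i, j] ** 2 for i in range(M.shape[0]) for j in range(M.shape[1]))

    def trace(M):
        return sum(M[i, i] for i in range(M.shape[0]))

    terms = []
    for X, H in zip(Xs, Hs):
        terms.append(frob2(X - W @ H.T))
        terms.append(0.5 * hp.alpha * frob2(H.T @ H - np.eye(K)))
    terms.append(-hp.lambda1 * trace(H2.T @ nets.A @ H1))
    terms.append(-hp.lambda2 * trace(H2.T @ nets.B @ H3))
    terms.append(-hp.lambda3 * trace(H3.T @ nets.C @ H3))
    terms.append(hp.gamma1 * frob2(W))
    terms.append(hp.gamma2 * sum(float(np.sum(np.abs(H))) for H in Hs))
    return float(sum(terms))


def tiny_instance(seed=0, S=4, n1=3, n2=2, n3=3):
    rng = np.random.default_rng(seed)
    ds = cm.TriOmicsDataset(
        lnc=cm.OmicsLayer("lncRNA", [f"l{i}" for i in range(n1)],
                          [f"s{i}" for i in range(S)], rng.random((S, n1))),
        mir=cm.OmicsLayer("miRNA", [f"m{i}" for i in range(n2)],
                          [f"s{i}" for i in range(S)], rng.random((S, n2))),
        mrna=cm.OmicsLayer("mRNA", [f"g{i}" for i in range(n3)],
                           [f"s{i}" for i in range(S)], rng.random((S, n3))),
    )
    A = (rng.random((n2, n1)) < 0.5).astype(float)
    B = (rng.random((n2, n3)) < 0.5).astype(float)
    C = np.triu(rng.random((n3, n3)) * (rng.random((n3, n3)) < 0.5), k=1)
    C = C + C.T
    nets = cm.InteractionData(A=A, B=B, C=C,
                              lnc_ids=ds.lnc.molecule_ids,
                              mir_ids=ds.mir.molecule_ids,
                              mrna_ids=ds.mrna.molecule_ids)
    return ds, nets


class TestObjective:
    def test_zero_factors_analytic_value(self):
        ds, nets = tiny_instance(0)
        K = 2
        hp = cm.Hyperparameters(K=K, alpha=1.7, lambda1=0.3, lambda2=0.4,
                                lambda3=0.5, gamma1=0.6, gamma2=0.7)
        state = cm.FactorizationResult(
            W=np.zeros((ds.n_samples, K)), H1=np.zeros((3, K)),
            H2=np.zeros((2, K)), H3=np.zeros((3, K)))
        expected = sum(
            float(np.sum(X.values ** 2)) for X in (ds.lnc, ds.mir, ds.mrna)
        ) + 1.5 * hp.alpha * K
        assert cm.objective(ds, nets, hp, state) == pytest.approx(expected, rel=1e-12)

    def test_penalty_free_reduces_to_joint_nmf_residual(self):
        ds, nets = tiny_instance(1)
        hp = cm.Hyperparameters(K=2, alpha=0, lambda1=0, lambda2=0, lambda3=0,
                                gamma1=0, gamma2=0)
        rng = np.random.default_rng(2)
        state = random_state(rng, ds.n_samples, 3, 2, 3, 2)
        expected = sum(
            float(np.linalg.norm(X.values - state.W @ H.T) ** 2)
            for X, H in zip((ds.lnc, ds.mir, ds.mrna), (state.H1, state.H2, state.H3))
        )
        assert cm.objective(ds, nets, hp, state) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_term_by_term_oracle(self, seed):
        ds, nets = tiny_instance(seed)
        rng = np.random.default_rng(100 + seed)
        hp = cm.Hyperparameters(K=2, alpha=rng.random(), lambda1=rng.random(),
                                lambda2=rng.random(), lambda3=rng.random(),
                                gamma1=rng.random(), gamma2=rng.random())
        state = random_state(rng, ds.n_samples, 3, 2, 3, 2, scale=2.0)
        got = cm.objective(ds, nets, hp, state)
        want = term_by_term_objective(ds, nets, hp, state)
        assert got == pytest.approx(want, rel=1e-10)

    def test_dimension_mismatch_rejected(self):
        ds, nets = tiny_instance(0)
        hp = cm.Hyperparameters(K=2)
        state = random_state(np.random.default_rng(0), ds.n_samples, 3, 2, 4, 2)
        with pytest.raises(cm.ValidationError):
            cm.objective(ds, nets, hp, state)


class TestUpdateStep:
    def test_exact_factorization_is_fixed_point(self):
        # noiseless planted data with all penalties zero makes every update
        # numerator equal its denominator at the generating factors
        spec = cm.SyntheticSpec(S=20, N1=20, N2=10, N3=20, K_true=2,
                                members_lnc=4, members_mir=2, members_mrna=4,
                                noise_sd=0.0, background_edge_prob=0.0, seed=3)
        ds, nets, _ = cm.generate(spec)
        hp = cm.Hyperparameters(K=2, alpha=0, lambda1=0, lambda2=0, lambda3=0,
                                gamma1=0, gamma2=0, seed=3)
        # recover the generating factors from the (exactly rank-2) data
        rng = np.random.default_rng(spec.seed)
        W = rng.uniform(0.0, 1.0, size=(spec.S, 2))
        H1 = np.linalg.lstsq(W, ds.lnc.values, rcond=None)[0].T
        H2 = np.linalg.lstsq(W, ds.mir.values, rcond=None)[0].T
        H3 = np.linalg.lstsq(W, ds.mrna.values, rcond=None)[0].T
        state = cm.FactorizationResult(W=W, H1=np.clip(H1, 0, None),
                                       H2=np.clip(H2, 0, None),
                                       H3=np.clip(H3, 0, None))
        out = cm.update_step(ds, nets, hp, state)
        for before, after in zip(state.factors(), out.factors()):
            np.testing.assert_allclose(after, before, rtol=1e-6, atol=1e-9)

    def test_zero_entries_stay_zero(self):
        ds, nets = tiny_instance(4)
        hp = cm.Hyperparameters(K=2)
        state = random_state(np.random.default_rng(5), ds.n_samples, 3, 2, 3, 2)
        state.W[1, 0] = 0.0
        state.H1[2, 1] = 0.0
        out = cm.update_step(ds, nets, hp, state)
        assert out.W[1, 0] == 0.0
        assert out.H1[2, 1] == 0.0

    def test_single_step_descends_objective(self):
        spec = cm.SyntheticSpec(S=6, N1=8, N2=4, N3=8, K_true=2,
                                members_lnc=2, members_mir=2, members_mrna=2, seed=6)
        ds, nets, _ = cm.generate(spec)
        hp = cm.Hyperparameters(K=2, alpha=0.5, lambda1=0.01, lambda2=0.01,
                                lambda3=0.01, gamma1=0.05, gamma2=0.05, seed=6)
        state = cm.initialize_factors(ds, hp)
        before = cm.objective(ds, nets, hp, state)
        after = cm.objective(ds, nets, hp, cm.update_step(ds, nets, hp, state))
        assert after <= before + 1e-8

    def test_nonnegativity_preserved_over_many_steps(self):
        ds, nets = tiny_instance(7)
        hp = cm.Hyperparameters(K=2, seed=7)
        state = cm.initialize_factors(ds, hp)
        for _ in range(50):
            state = cm.update_step(ds, nets, hp, state)
        assert min(f.min() for f in state.factors()) >= 0.0


class TestFit:
    def test_same_seed_bit_identical(self, small_instance):
        _, ds, nets, _ = small_instance
        hp = cm.Hyperparameters(K=3, seed=42, max_iter=30, tol=1e-15)
        with pytest.warns(RuntimeWarning):
            r1 = cm.fit(ds, nets, hp)
        with pytest.warns(RuntimeWarning):
            r2 = cm.fit(ds, nets, hp)
        assert r1.objective_trace == r2.objective_trace
        for a, b in zip(r1.factors(), r2.factors()):
            assert a.tobytes() == b.tobytes()

    def test_huge_tol_stops_immediately(self, small_instance):
        _, ds, nets, _ = small_instance
        hp = cm.Hyperparameters(K=3, seed=0, tol=1e30)
        result = cm.fit(ds, nets, hp)
        assert result.converged
        assert result.iterations_run == 1
        assert len(result.objective_trace) == 2

    def test_monotone_descent_across_penalty_grid(self):
        grids = [(0.5, 0.005), (1.0, 0.01), (2.0, 0.05)]
        gammas = [(0.01, 0.01), (0.1, 0.1), (0.5, 0.5)]
        for i, seed in enumerate(range(6)):
            alpha, lam = grids[i % 3]
            g1, g2 = gammas[i // 3 % 3]
            spec = cm.SyntheticSpec(S=20, N1=15, N2=9, N3=15, K_true=3,
                                    members_lnc=3, members_mir=2,
                                    members_mrna=3, seed=seed)
            ds, nets, _ = cm.generate(spec)
            hp = cm.Hyperparameters(K=3, alpha=alpha, lambda1=lam, lambda2=lam,
                                    lambda3=lam, gamma1=g1, gamma2=g2,
                                    seed=seed, max_iter=80, tol=1e-13)
            with pytest.warns(RuntimeWarning):
                result = cm.fit(ds, nets, hp)
            diffs = np.diff(result.objective_trace)
            assert diffs.max() <= 1e-8

    def test_planted_instance_residual_halves(self, fitted_small):
        ds, nets, _, hp, result = fitted_small

        def residual(state):
            return sum(
                float(np.linalg.norm(X.values - state.W @ H.T) ** 2)
                for X, H in zip((ds.lnc, ds.mir, ds.mrna),
                                (state.H1, state.H2, state.H3))
            )

        init = cm.initialize_factors(ds, hp)
        assert residual(result) <= 0.5 * residual(init)

    def test_orthogonality_pressure_reduces_gram_deviation(self):
        spec = cm.SyntheticSpec(S=20, N1=15, N2=9, N3=15, K_true=3,
                                members_lnc=3, members_mir=2, members_mrna=3,
                                seed=8)
        ds, nets, _ = cm.generate(spec)
        hp = cm.Hyperparameters(K=3, alpha=20.0, lambda1=0, lambda2=0,
                                lambda3=0, gamma1=0, gamma2=0, seed=8,
                                max_iter=400, tol=1e-10)
        init = cm.initialize_factors(ds, hp)
        result = cm.fit(ds, nets, hp, init=init)

        def gram_dev(state):
            return sum(
                float(np.linalg.norm(H.T @ H - np.eye(hp.K)))
                for H in (state.H1, state.H2, state.H3)
            )

        assert gram_dev(result) < gram_dev(init)

    def test_network_attraction_coloads_interacting_pairs(self):
        spec = cm.SyntheticSpec(seed=9, S=40, N1=40, N2=20, N3=40,
                                members_lnc=6, members_mir=3, members_mrna=6,
                                K_true=4)
        ds, nets, _ = cm.generate(spec)
        hp = cm.Hyperparameters(K=4, lambda1=1.0, seed=9, max_iter=600)
        result = cm.fit(ds, nets, hp)

        def row_corr(a, b):
            a = a - a.mean()
            b = b - b.mean()
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            return float(a @ b) / denom if denom > 0 else 0.0

        linked, unlinked = [], []
        for p in range(spec.N2):
            for j in range(spec.N1):
                corr = row_corr(result.H2[p], result.H1[j])
                (linked if nets.A[p, j] else unlinked).append(corr)
        assert np.mean(linked) > np.mean(unlinked)

    def test_k_exceeding_layer_size_rejected(self, small_instance):
        _, ds, nets, _ = small_instance
        with pytest.raises(cm.ValidationError):
            cm.fit(ds, nets, cm.Hyperparameters(K=16, seed=0))


class TestPlainNMFReduction:
    """With all penalties zero and two layers of width zero, the update
    rules must coincide with standard multiplicative-update NMF."""

    @staticmethod
    def plain_nmf_trace(X, W, H, n_iter):
        """Independent textbook NMF (min ||X - W H^T||_F^2) from given init."""
        eps = cm.EPSILON
        residuals = [float(np.linalg.norm(X - W @ H.T) ** 2)]
        for _ in range(n_iter):
            W = W * (X @ H) / (W @ (H.T @ H) + eps)
            H = H * (X.T @ W) / (H @ (W.T @ W) + eps)
            residuals.append(float(np.linalg.norm(X - W @ H.T) ** 2))
        return residuals

    def test_residuals_match_textbook_nmf_every_iteration(self):
        rng = np.random.default_rng(10)
        S, n1, K, n_iter = 12, 9, 3, 60
        X = rng.random((S, n1))
        ds = cm.TriOmicsDataset(
            lnc=cm.OmicsLayer("lncRNA", [f"l{i}" for i in range(n1)],
                              [f"s{i}" for i in range(S)], X),
            mir=cm.OmicsLayer("miRNA", [], [f"s{i}" for i in range(S)],
                              np.zeros((S, 0))),
            mrna=cm.OmicsLayer("mRNA", [], [f"s{i}" for i in range(S)],
                               np.zeros((S, 0))),
        )
        nets = cm.InteractionData(A=np.zeros((0, n1)), B=np.zeros((0, 0)),
                                  C=np.zeros((0, 0)), lnc_ids=ds.lnc.molecule_ids,
                                  mir_ids=[], mrna_ids=[])
        hp = cm.Hyperparameters(K=K, alpha=0, lambda1=0, lambda2=0, lambda3=0,
                                gamma1=0, gamma2=0, seed=10, max_iter=n_iter,
                                tol=1e-300)
        init = cm.initialize_factors(ds, hp)
        with pytest.warns(RuntimeWarning):
            result = cm.fit(ds, nets, hp, init=init)
        oracle = self.plain_nmf_trace(X, init.W.copy(), init.H1.copy(), n_iter)
        np.testing.assert_allclose(result.objective_trace, oracle, rtol=1e-6)
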