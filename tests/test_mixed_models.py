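"""Bivariate GCA model, single-step individual model, EM-REML, cross values."""

import numpy as np
import pytest

from rrgsim.mixed_models import (
    VarComps,
    estimate_varcomps_em,
    predict_cross_value,
    solve_gca_bivariate,
    solve_ssgblup_bivariate,
)


# ---------------------------------------------------------------------------
# Dense GLS oracle (independent of the MME implementation)
# ---------------------------------------------------------------------------

def gls_blup(y, X, terms, resid):
    """Generalized-least-squares BLUP with explicit covariance matrices.

    ``y`` is (n, 2) stacked trait-major; ``terms`` is a list of
    (Z, Sigma2x2, K); residuals independent across traits.
    """
    n = y.shape[0]
    yv = np.concatenate([y[:, 0], y[:, 1]])
    Xb = np.kron(np.eye(2), X)
    V = np.kron(np.diag(resid), np.eye(n))
    covs = []
    for Z, S, K in terms:
        Zb = np.kron(np.eye(2), Z)
        cov = S_kron = np.kron(S, K)
        V = V + Zb @ S_kron @ Zb.T
        covs.append((Zb, S_kron))
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(Xb.T @ Vi @ Xb, Xb.T @ Vi @ yv)
    resid_v = yv - Xb @ beta
    us = [S_kron @ Zb.T @ Vi @ resid_v for Zb, S_kron in covs]
    return beta, us


def toy_gca_data(rng, n_p1=3, n_p2=4, n_rec=60):
    i1 = rng.integers(0, n_p1, n_rec)
    i2 = rng.integers(0, n_p2, n_rec)
    S1 = np.array([[0.4, -0.2], [-0.2, 0.5]])
    S2 = np.array([[0.3, -0.1], [-0.1, 0.6]])
    K1 = np.eye(n_p1)
    K2 = np.eye(n_p2)
    u1 = rng.multivariate_normal([0, 0], S1, n_p1)
    u2 = rng.multivariate_normal([0, 0], S2, n_p2)
    resid = np.array([1.0, 2.0])
    y = np.stack(
        [
            10 + u1[i1, t] + u2[i2, t] + rng.normal(0, np.sqrt(resid[t]), n_rec)
            for t in range(2)
        ],
        axis=1,
    )
    vc = VarComps(terms={"pop1": S1, "pop2": S2}, resid=resid)
    return y, i1, i2, K1, K2, vc


class TestGcaModel:
    def test_zero_variance_collapses_to_trait_means(self, rng):
        y, i1, i2, K1, K2, _ = toy_gca_data(rng)
        vc0 = VarComps(
            terms={"pop1": np.zeros((2, 2)), "pop2": np.zeros((2, 2))},
            resid=np.array([1.0, 2.0]),
        )
        sol = solve_gca_bivariate(y, i1, i2, K1, K2, vc0)
        assert np.allclose(sol.means, y.mean(axis=0))
        assert np.allclose(sol.effects["pop1"], 0.0)
        assert np.allclose(sol.effects["pop2"], 0.0)

    def test_matches_dense_gls_oracle(self, rng):
        y, i1, i2, K1, K2, vc = toy_gca_data(rng)
        sol = solve_gca_bivariate(y, i1, i2, K1, K2, vc)
        n = y.shape[0]
        X = np.ones((n, 1))
        Z1 = np.zeros((n, 3))
        Z1[np.arange(n), i1] = 1
        Z2 = np.zeros((n, 4))
        Z2[np.arange(n), i2] = 1
        beta, us = gls_blup(
            y, X, [(Z1, vc.terms["pop1"], K1), (Z2, vc.terms["pop2"], K2)],
            vc.resid,
        )
        assert np.allclose(sol.means, beta, atol=1e-8)
        assert np.allclose(
            sol.effects["pop1"], us[0].reshape(2, 3).T, atol=1e-8
        )
        assert np.allclose(
            sol.effects["pop2"], us[1].reshape(2, 4).T, atol=1e-8
        )
        assert sol.residual_norm < 1e-8

    def test_correlated_kernels_against_oracle(self, rng):
        """Non-diagonal kernels (related parents) still match GLS."""
        y, i1, i2, _, _, vc = toy_gca_data(rng)
        L = rng.normal(size=(3, 3))
        K1 = L @ L.T / 3 + np.eye(3)
        L2 = rng.normal(size=(4, 4))
        K2 = L2 @ L2.T / 4 + np.eye(4)
        sol = solve_gca_bivariate(y, i1, i2, K1, K2, vc)
        n = y.shape[0]
        X = np.ones((n, 1))
        Z1 = np.zeros((n, 3))
        Z1[np.arange(n), i1] = 1
        Z2 = np.zeros((n, 4))
        Z2[np.arange(n), i2] = 1
        beta, us = gls_blup(
            y, X, [(Z1, vc.terms["pop1"], K1), (Z2, vc.terms["pop2"], K2)],
            vc.resid,
        )
        assert np.allclose(sol.means, beta, atol=1e-8)
        assert np.allclose(sol.effects["pop1"], us[0].reshape(2, 3).T, atol=1e-8)

    def test_uncorrelated_traits_equal_univariate_runs(self, rng):
        """With zero between-trait covariance the bivariate solution equals
        two independent univariate BLUPs (computed via the GLS oracle)."""
        y, i1, i2, K1, K2, _ = toy_gca_data(rng)
        S1 = np.diag([0.4, 0.5])
        S2 = np.diag([0.3, 0.6])
        vc = VarComps(terms={"pop1": S1, "pop2": S2}, resid=np.array([1.0, 2.0]))
        sol = solve_gca_bivariate(y, i1, i2, K1, K2, vc)
        n = y.shape[0]
        X = np.ones((n, 1))
        Z1 = np.zeros((n, 3))
        Z1[np.arange(n), i1] = 1
        Z2 = np.zeros((n, 4))
        Z2[np.arange(n), i2] = 1
        for t in range(2):
            V = (
                S1[t, t] * Z1 @ K1 @ Z1.T
                + S2[t, t] * Z2 @ K2 @ Z2.T
                + vc.resid[t] * np.eye(n)
            )
            Vi = np.linalg.inv(V)
            mu = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y[:, t]).item()
            u1 = S1[t, t] * K1 @ Z1.T @ Vi @ (y[:, t] - mu)
            assert sol.means[t] == pytest.approx(mu, abs=1e-8)
            assert np.allclose(sol.effects["pop1"][:, t], u1, atol=1e-8)

    def test_non_psd_varcomps_rejected(self):
        with pytest.raises(ValueError):
            VarComps(
                terms={"pop1": np.array([[1.0, 2.0], [2.0, 1.0]])},
                resid=np.array([1.0, 1.0]),
            )


class TestSsgblup:
    def test_identity_kernel_is_scalar_shrinkage(self, rng):
        """H = I, one record per individual, diagonal trait covariance:
        GEBV = h2-style shrinkage of the centered record, per trait."""
        n = 40
        S = np.diag([2.0, 3.0])
        resid = np.array([1.0, 1.5])
        y = rng.normal(12.0, 2.0, size=(n, 2))
        vc = VarComps(terms={"additive": S}, resid=resid)
        sol = solve_ssgblup_bivariate(y, np.arange(n), np.eye(n), vc)
        for t in range(2):
            lam = S[t, t] / (S[t, t] + resid[t])
            expected = lam * (y[:, t] - sol.means[t])
            assert np.allclose(sol.effects["additive"][:, t], expected, atol=1e-6)

    def test_zero_variance_gives_zero_gebv(self, rng):
        y = rng.normal(size=(10, 2))
        vc = VarComps(
            terms={"additive": np.zeros((2, 2))}, resid=np.array([1.0, 1.0])
        )
        sol = solve_ssgblup_bivariate(y, np.arange(10), np.eye(10), vc)
        assert np.allclose(sol.effects["additive"], 0.0)

    def test_toy_with_unrecorded_individuals_matches_gls(self, rng):
        """10 individuals, records on 6, dense H: solution matches the GLS
        oracle with the explicit H covariance, including GEBV of the four
        record-free individuals."""
        N, n = 10, 6
        L = rng.normal(size=(N, N))
        H = L @ L.T / N + np.eye(N)
        S = np.array([[1.0, -0.5], [-0.5, 2.0]])
        resid = np.array([1.0, 2.0])
        idx = rng.choice(N, n, replace=False)
        y = rng.normal(5.0, 1.5, size=(n, 2))
        vc = VarComps(terms={"additive": S}, resid=resid)
        sol = solve_ssgblup_bivariate(y, idx, np.linalg.inv(H), vc)
        X = np.ones((n, 1))
        Z = np.zeros((n, N))
        Z[np.arange(n), idx] = 1
        beta, us = gls_blup(y, X, [(Z, S, H)], resid)
        assert np.allclose(sol.means, beta, atol=1e-7)
        assert np.allclose(sol.effects["additive"], us[0].reshape(2, N).T,
                           atol=1e-7)

    def test_iterative_path_matches_dense_path(self, rng):
        """Forcing the conjugate-gradient branch reproduces the dense
        solution to solver tolerance."""
        N, n = 30, 25
        L = rng.normal(size=(N, N))
        H = L @ L.T / N + np.eye(N)
        S = np.array([[1.0, -0.6], [-0.6, 1.5]])
        resid = np.array([0.8, 1.2])
        idx = rng.choice(N, n, replace=False)
        y = rng.normal(0.0, 1.0, size=(n, 2))
        vc = VarComps(terms={"additive": S}, resid=resid)
        Hinv = np.linalg.inv(H)
        dense = solve_ssgblup_bivariate(y, idx, Hinv, vc, dense_threshold=1000)
        cg = solve_ssgblup_bivariate(y, idx, Hinv, vc, dense_threshold=1)
        assert cg.converged
        assert np.allclose(dense.effects["additive"], cg.effects["additive"],
                           atol=1e-5)


class TestEmReml:
    def test_parameter_recovery_on_simulated_data(self):
        """EM-REML recovers known components within Monte-Carlo error on a
        single-kernel bivariate model with replicated records."""
        rng = np.random.default_rng(8)
        q, reps = 150, 8
        n = q * reps
        S_true = np.array([[2.0, -1.2], [-1.2, 3.0]])
        resid_true = np.array([1.0, 1.5])
        u = rng.multivariate_normal([0, 0], S_true, q)
        Z = np.kron(np.eye(q), np.ones((reps, 1)))
        y = np.stack(
            [
                4.0 + Z @ u[:, t] + rng.normal(0, np.sqrt(resid_true[t]), n)
                for t in range(2)
            ],
            axis=1,
        )
        start = VarComps(
            terms={"g": np.array([[1.0, 0.0], [0.0, 1.0]])},
            resid=np.array([1.0, 1.0]),
        )
        est, converged, it = estimate_varcomps_em(
            y, {"g": Z}, {"g": np.eye(q)}, start, max_iter=300, tol=1e-7
        )
        assert converged
        # Tolerances ~4 standard errors of the Monte-Carlo sampling noise
        # (SE(resid) ~ resid * sqrt(2/(n-q)), SE(S) ~ S * sqrt(2/q)).
        assert np.allclose(est.terms["g"], S_true, atol=0.7)
        assert np.allclose(est.resid, resid_true, atol=0.25)

    def test_start_at_truth_stays_near_truth(self, rng):
        q, reps = 80, 6
        S_true = np.array([[1.5, 0.5], [0.5, 1.0]])
        resid_true = np.array([1.0, 1.0])
        u = rng.multivariate_normal([0, 0], S_true, q)
        Z = np.kron(np.eye(q), np.ones((reps, 1)))
        n = q * reps
        y = np.stack(
            [Z @ u[:, t] + rng.normal(0, 1.0, n) for t in range(2)], axis=1
        )
        start = VarComps(terms={"g": S_true}, resid=resid_true)
        est, _, _ = estimate_varcomps_em(
            y, {"g": Z}, {"g": np.eye(q)}, start, max_iter=50
        )
        assert np.allclose(est.terms["g"], S_true, atol=0.7)

    def test_zero_heritability_shrinks_to_boundary(self, rng):
        """Pure-noise data with replicated records: the additive components
        head toward the zero boundary (replicates are required; with one
        record per effect the split would be unidentifiable)."""
        q, reps = 60, 5
        Z = np.kron(np.eye(q), np.ones((reps, 1)))
        y = rng.normal(size=(q * reps, 2))  # pure noise
        start = VarComps(
            terms={"g": np.eye(2) * 0.5}, resid=np.array([0.5, 0.5])
        )
        est, _, _ = estimate_varcomps_em(
            y, {"g": Z}, {"g": np.eye(q)}, start, max_iter=400, tol=1e-8
        )
        assert est.terms["g"][0, 0] < 0.1
        assert est.terms["g"][1, 1] < 0.1


class TestCrossValue:
    def test_null_gca_gives_mean_product(self):
        assert predict_cross_value(
            np.zeros(2), np.zeros(2), np.array([15.0, 15.0])
        ) == pytest.approx(225.0)

    def test_ranking_matches_brute_force(self, rng):
        g1 = rng.normal(0, 1, size=(3, 2))
        g2 = rng.normal(0, 1, size=(3, 2))
        means = np.array([15.0, 15.0])
        scores = {}
        for i in range(3):
            for j in range(3):
                bw = means[0] + g1[i, 0] + g2[j, 0]
                bn = means[1] + g1[i, 1] + g2[j, 1]
                scores[(i, j)] = bw * bn
        for (i, j), expected in scores.items():
            assert predict_cross_value(g1[i], g2[j], means) == pytest.approx(expected)

    def test_monotone_in_gca_when_traits_positive(self, rng):
        means = np.array([15.0, 15.0])
        g1 = np.array([0.5, -0.3])
        g2 = np.array([0.1, 0.2])
        base = predict_cross_value(g1, g2, means)
        bumped = predict_cross_value(g1 + np.array([0.3, 0.0]), g2, means)
        assert bumped >= base
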