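"""Fuzzy factor extraction: weighted moments, classical limit, diagnostics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import smht
from smht.containers import ValidationError
from smht.fuzzy_efa import DegenerateWeightError


class TestFuzzyMoments:
    def test_uniform_weights_give_plain_mean(self, planted_sim):
        X = planted_sim.responses
        m = smht.fuzzy_mean(X, np.ones(X.n_respondents))
        assert np.allclose(m, X.values.mean(axis=0))

    def test_point_mass_selects_row(self, planted_sim):
        X = planted_sim.responses
        U = np.zeros(X.n_respondents)
        U[0] = 1.0
        assert np.allclose(smht.fuzzy_mean(X, U), X.values[0])

    def test_hand_weighted_average(self):
        X = np.array([[1.0, 5.0], [3.0, 3.0]])
        m = smht.fuzzy_mean(X, np.array([0.75, 0.25]))
        assert np.allclose(m, [1.5, 4.5])

    def test_uniform_weights_give_population_covariance(self, planted_sim):
        X = planted_sim.responses
        U = np.ones(X.n_respondents)
        cov = smht.fuzzy_covariance(X, U, smht.fuzzy_mean(X, U))
        assert np.allclose(cov, np.cov(X.values.T, ddof=0), atol=1e-10)

    def test_single_weight_gives_zero_dispersion(self):
        X = np.array([[1.0, 2.0], [4.0, 5.0], [2.0, 2.0]])
        U = np.array([0.0, 1.0, 0.0])
        cov = smht.fuzzy_covariance(X, U, smht.fuzzy_mean(X, U))
        assert np.allclose(cov, 0.0)

    def test_hand_covariance(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        U = np.ones(2)
        cov = smht.fuzzy_covariance(X, U, smht.fuzzy_mean(X, U))
        assert np.allclose(cov, [[1.0, 1.0], [1.0, 1.0]])

    def test_zero_weights_rejected(self):
        X = np.ones((3, 2))
        with pytest.raises(DegenerateWeightError):
            smht.fuzzy_mean(X, np.zeros(3))
        with pytest.raises(DegenerateWeightError):
            smht.fuzzy_covariance(X, np.zeros(3), np.ones(2))


class TestMembership:
    def test_known_distances(self):
        # rows at distances (0, 1, 3) from the mean; median distance 1
        X = np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]])
        U = smht.update_membership(X, np.zeros(2), item_sd=np.ones(2))
        assert np.allclose(U, [1.0, 0.5, 0.1])

    def test_identical_rows_get_unit_weights(self):
        X = np.tile([2.0, 3.0], (5, 1))
        U = smht.update_membership(X, np.array([2.0, 3.0]), item_sd=np.ones(2))
        assert np.allclose(U, 1.0)

    @given(st.lists(st.integers(1, 5000), min_size=3, max_size=20, unique=True))
    def test_strictly_decreasing_in_distance(self, dists):
        X = 0.01 * np.array(sorted(dists), dtype=float)[:, None]
        U = smht.update_membership(X, np.zeros(1), item_sd=np.ones(1))
        assert np.all(np.diff(U) < 0)


class TestFitFuzzyFA:
    def test_classical_limit_matches_eigendecomposition(self, planted_sim):
        X = planted_sim.responses
        model = smht.fit_fuzzy_fa(X, fuzzy=False)
        R = np.corrcoef(X.values.T)
        vals, vecs = np.linalg.eigh(R)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        assert np.allclose(model.eigenvalues, vals, atol=1e-8)
        k = model.retained_k
        oracle = vecs[:, :k] * np.sqrt(vals[:k])
        sign = np.sign((oracle * model.loadings).sum(axis=0))
        assert np.max(np.abs(model.loadings - oracle * sign)) < 1e-8

    def test_identity_correlation_retains_nothing(self):
        # two exactly uncorrelated Likert items
        X = smht.ResponseMatrix(np.array([[1, 1], [5, 1], [1, 5], [5, 5]]))
        model = smht.fit_fuzzy_fa(X, fuzzy=False)
        assert np.allclose(model.eigenvalues, 1.0, atol=1e-12)
        assert model.retained_k == 0

    def test_planted_structure_recovered(self, planted_sim):
        model = smht.fit_fuzzy_fa(planted_sim.responses)
        assert model.retained_k == 3
        rotated = smht.varimax(model.loadings)
        rmse = smht.aligned_loading_rmse(
            rotated, planted_sim.config.loading_pattern
        )
        assert rmse < 0.1

    def test_trace_conservation(self, planted_sim):
        model = smht.fit_fuzzy_fa(planted_sim.responses)
        assert model.eigenvalues.sum() == pytest.approx(
            planted_sim.responses.n_items, abs=1e-8
        )

    def test_outliers_get_lower_membership(self):
        cfg = smht.SimulationConfig(
            n_respondents=400, n_items=12, n_factors=2,
            loading_pattern=smht.simple_structure_loadings(12, 2, 0.7),
            uniqueness=1 - 0.49, outlier_fraction=0.05, outlier_magnitude=4.0,
            seed=42,
        )
        sim = smht.simulate_responses(cfg)
        model = smht.fit_fuzzy_fa(sim.responses)
        clean = np.setdiff1d(np.arange(400), sim.outlier_indices)
        assert (
            model.memberships[sim.outlier_indices].mean()
            < model.memberships[clean].mean()
        )

    def test_small_sample_warns(self):
        X = smht.ResponseMatrix(
            np.random.default_rng(0).integers(1, 6, size=(10, 12))
        )
        with pytest.warns(UserWarning, match="poorly determined"):
            smht.fit_fuzzy_fa(X, fuzzy=False)

    def test_non_convergence_flagged_not_silent(self, planted_sim):
        with pytest.warns(UserWarning, match="did not converge"):
            model = smht.fit_fuzzy_fa(planted_sim.responses, max_iter=1, tol=1e-15)
        assert not model.converged

    def test_constant_matrix_rejected(self):
        X = np.full((20, 4), 3)
        with pytest.raises(ValidationError):
            smht.fit_fuzzy_fa(X)


class TestFactorScores:
    def test_centered_input_scores_zero(self, planted_sim):
        model = smht.fit_fuzzy_fa(planted_sim.responses)
        scores = smht.factor_scores(model, model.fuzzy_mean[None, :])
        assert np.allclose(scores, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, planted_sim):
        model = smht.fit_fuzzy_fa(planted_sim.responses)
        X = planted_sim.responses.values[:25].astype(float)
        z = (X - model.fuzzy_mean) / model.fuzzy_sd
        oracle, *_ = np.linalg.lstsq(model.loadings, z.T, rcond=None)
        assert np.allclose(smht.factor_scores(model, X), oracle.T, atol=1e-10)

    def test_orthonormal_single_column_is_projection(self, planted_sim):
        model = smht.fit_fuzzy_fa(planted_sim.responses)
        L = np.zeros((18, 1))
        L[0, 0] = 1.0
        model.loadings = L
        model.retained_k = 1
        x = planted_sim.responses.values[:5].astype(float)
        z = (x - model.fuzzy_mean) / model.fuzzy_sd
        assert np.allclose(smht.factor_scores(model, x), z @ L, atol=1e-12)


class TestSamplingAdequacy:
    def test_kmo_two_items_is_half(self):
        for r in (0.2, -0.5, 0.9):
            R = np.array([[1.0, r], [r, 1.0]])
            assert smht.kmo_statistic(R) == pytest.approx(0.5, abs=1e-12)

    def test_kmo_matches_partial_correlation_oracle(self):
        # one-factor structure, p=6, off-diagonal r=0.7
        p = 6
        R = np.full((p, p), 0.7)
        np.fill_diagonal(R, 1.0)
        # oracle: partial correlations via regression residuals on exact data
        rng = np.random.default_rng(0)
        raw = rng.standard_normal((5000, p))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        data = q @ np.linalg.cholesky(R).T  # sample correlation exactly R
        partial2 = 0.0
        for i in range(p):
            for j in range(i + 1, p):
                rest = [k for k in range(p) if k not in (i, j)]
                A = data[:, rest]
                beta_i = np.linalg.lstsq(A, data[:, i], rcond=None)[0]
                beta_j = np.linalg.lstsq(A, data[:, j], rcond=None)[0]
                ri = data[:, i] - A @ beta_i
                rj = data[:, j] - A @ beta_j
                pr = ri @ rj / np.sqrt((ri @ ri) * (rj @ rj))
                partial2 += 2 * pr**2
        r2 = float((R**2).sum() - p)
        assert smht.kmo_statistic(R) == pytest.approx(r2 / (r2 + partial2), abs=1e-10)

    def test_kmo_singular_matrix_rejected(self):
        R = np.ones((3, 3))
        with pytest.raises(ValidationError, match="singular"):
            smht.kmo_statistic(R)

    def test_bartlett_identity_is_null(self):
        chi2, df, p = smht.bartlett_sphericity(np.eye(5), n=100)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_bartlett_scalar_oracle(self):
        R = np.array([[1.0, 0.5], [0.5, 1.0]])
        chi2, df, p = smht.bartlett_sphericity(R, n=100)
        assert chi2 == pytest.approx(-(100 - 1 - 9 / 6) * np.log(0.75), abs=1e-10)
        assert df == 1

    def test_bartlett_df(self):
        chi2, df, p = smht.bartlett_sphericity(np.eye(14), n=300)
        assert df == 91


class TestAlignment:
    def test_permutation_and_sign_recovered(self):
        rng = np.random.default_rng(3)
        ref = rng.standard_normal((10, 3))
        est = ref[:, [2, 0, 1]] * np.array([-1, 1, -1])
        assert smht.aligned_loading_rmse(est, ref) == pytest.approx(0.0, abs=1e-12)
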