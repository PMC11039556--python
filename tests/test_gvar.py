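import numpy as np
import pytest

from idionet.gvar import (
    GVARModel,
    SingularInformationError,
    _init_prior,
    _initial_params,
    _mstep_single,
    fit_gvar_lasso,
    fit_gvar_ml,
    loglik_gvar,
    n_free_params,
    pcc_from_precision,
)
from idionet.kalman import kalman_smoother
from idionet.series import StudyDesign
from idionet.simulate import (
    MissingnessSpec,
    generate_precision_matrix,
    simulate_series,
)

from conftest import bruteforce_joint_loglik, conditional_ml_oracle


class TestPartialCorrelations:
    def test_identity_precision_means_no_edges(self):
        assert np.array_equal(pcc_from_precision(np.eye(6)), np.eye(6))

    def test_two_by_two_closed_form(self):
        K = np.array([[2.0, -1.0], [-1.0, 2.0]])
        Omega = pcc_from_precision(K)
        assert Omega[0, 1] == pytest.approx(0.5)
        # independent route: partial correlation of a bivariate pair is its
        # correlation, recovered from the inverse of K
        S = np.linalg.inv(K)
        r = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
        assert Omega[0, 1] == pytest.approx(r)

    @pytest.mark.parametrize("seed", range(6))
    def test_partials_bounded_and_scale_invariant(self, seed):
        K = generate_precision_matrix(6, density=0.5, seed=seed)
        Omega = pcc_from_precision(K)
        off = Omega[~np.eye(6, dtype=bool)]
        assert np.all(np.abs(off) < 1.0)
        assert np.allclose(pcc_from_precision(3.7 * K), Omega)
        assert np.allclose(np.diag(Omega), 1.0)

    def test_non_spd_rejected(self):
        with pytest.raises(ValueError, match="positive definite"):
            pcc_from_precision(np.array([[1.0, 2.0], [2.0, 1.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            pcc_from_precision(np.array([[1.0, 0.5], [0.0, 1.0]]))


class TestLoglik:
    def test_single_standard_normal_observation_at_origin(self):
        model = GVARModel(mu=np.zeros(6), B=np.zeros((6, 6)), K=np.eye(6))
        Y = np.full((2, 6), np.nan)
        Y[0] = 0.0
        assert loglik_gvar(model, Y) == pytest.approx(-3.0 * np.log(2 * np.pi))

    def test_independence_doubles_the_loglik(self):
        model = GVARModel(mu=np.zeros(3), B=np.zeros((3, 3)), K=np.eye(3) * 2.0)
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((20, 3))
        ll = loglik_gvar(model, Y)
        assert loglik_gvar(model, np.vstack([Y, Y])) == pytest.approx(2 * ll)

    @pytest.mark.parametrize("seed,with_missing", [(0, False), (1, True), (2, True)])
    def test_matches_bruteforce_joint_gaussian(self, seed, with_missing):
        """T=10, p=2: the filter equals an explicit joint-normal density."""
        rng = np.random.default_rng(seed)
        B = np.array([[0.4, 0.1], [-0.2, 0.3]])
        K = np.array([[2.0, -0.5], [-0.5, 1.5]])
        mu = np.array([1.0, -2.0])
        model = GVARModel(mu=mu, B=B, K=K)
        Y = rng.standard_normal((10, 2)) + mu
        if with_missing:
            Y[3] = np.nan
            Y[7, 0] = np.nan
        ll_bf = bruteforce_joint_loglik(mu, B, model.Sigma, Y)
        assert loglik_gvar(model, Y) == pytest.approx(ll_bf, abs=1e-8)

    def test_nonstationary_model_rejected(self):
        model = GVARModel(mu=np.zeros(2), B=np.eye(2) * 0.5, K=np.eye(2))
        model.B = np.eye(2) * 1.05  # bypass constructor check
        with pytest.raises(ValueError, match="stationary"):
            loglik_gvar(model, np.zeros((5, 2)))

    def test_dimension_mismatch_rejected(self):
        model = GVARModel(mu=np.zeros(2), B=np.zeros((2, 2)), K=np.eye(2))
        with pytest.raises(ValueError, match="dimension"):
            loglik_gvar(model, np.zeros((5, 3)))


class TestMLFit:
    def test_complete_data_equals_conditional_ml_oracle(self, complete_series):
        model = fit_gvar_ml(complete_series)
        mu_o, B_o, Sigma_o, ll_o = conditional_ml_oracle(complete_series.values)
        assert model.loglik == pytest.approx(ll_o, abs=1e-4)
        assert np.allclose(model.B, B_o, atol=1e-4)
        assert np.allclose(model.mu, mu_o, atol=1e-4)
        assert np.allclose(model.Sigma, Sigma_o, atol=1e-4)

    def test_parameter_count(self, complete_series):
        model = fit_gvar_ml(complete_series)
        assert model.n_params == n_free_params(6) == 63

    def test_consistency_at_large_T(self, truth6):
        design = StudyDesign(n_days=1000, beeps_per_day=5)
        s = simulate_series(truth6, design, missing=MissingnessSpec(0.0), seed=21)
        model = fit_gvar_ml(s)
        assert np.max(np.abs(model.B - truth6.B)) < 0.05
        truth_omega = pcc_from_precision(truth6.K)
        assert np.max(np.abs(model.Omega - truth_omega)) < 0.05

    def test_constant_column_raises_singular_information(self, complete_series):
        Y = complete_series.values.copy()
        Y[:, 2] = 7.0
        with pytest.raises(SingularInformationError):
            fit_gvar_ml(Y)

    def test_too_few_completed_assessments_refused(self, truth6):
        s = simulate_series(truth6, missing=MissingnessSpec(0.0), seed=1)
        Y = s.values.copy()
        Y[29:] = np.nan
        with pytest.raises(ValueError, match="completed assessments"):
            fit_gvar_ml(Y)

    def test_below_recommended_length_warns(self, truth6):
        s = simulate_series(truth6, missing=MissingnessSpec(0.0), seed=2)
        Y = s.values.copy()
        Y[60:] = np.nan
        with pytest.warns(UserWarning, match="below the recommended"):
            fit_gvar_ml(Y)

    def test_fit_is_deterministic(self, missing_series):
        a = fit_gvar_ml(missing_series)
        b = fit_gvar_ml(missing_series)
        assert np.array_equal(a.B, b.B)
        assert np.array_equal(a.K, b.K)
        assert a.loglik == b.loglik

    def test_em_loglik_is_monotone_under_missing_data(self, missing_series):
        """The EM contract: the conditional loglik never decreases."""
        Y = missing_series.values
        c, B, Sigma = _initial_params(Y)
        lls = []
        for _ in range(25):
            m0, P0 = _init_prior(c, B, Sigma)
            sm = kalman_smoother(Y, c, B, Sigma, m0, P0, conditional=True)
            lls.append(sm.loglik)
            c, B, Sigma = _mstep_single(sm)
        assert np.all(np.diff(lls) >= -1e-8)

    def test_fiml_uses_partial_beeps(self, truth6):
        """Item-level missingness is marginalized, not listwise-deleted:
        adding back a partially observed beep changes the loglik."""
        s = simulate_series(truth6, missing=MissingnessSpec(0.0), seed=30)
        Y_full = s.values.copy()
        Y_full[10, :3] = np.nan  # partial beep
        Y_row_deleted = Y_full.copy()
        Y_row_deleted[10] = np.nan
        model = fit_gvar_ml(Y_full)
        assert loglik_gvar(model, Y_full) != pytest.approx(
            loglik_gvar(model, Y_row_deleted)
        )


class TestLassoFit:
    def test_small_penalty_approaches_ml(self, complete_series):
        ml = fit_gvar_ml(complete_series)
        path = fit_gvar_lasso(
            complete_series, lambdas_B=[1e-4], lambdas_K=[1e-6]
        )
        sel = path.selected_model
        assert np.max(np.abs(sel.B - ml.B)) < 1e-2
        assert np.max(np.abs(sel.Omega - ml.Omega)) < 1e-2

    def test_huge_penalty_gives_empty_networks(self, complete_series):
        path = fit_gvar_lasso(
            complete_series, lambdas_B=[1e6], lambdas_K=[1e3]
        )
        sel = path.selected_model
        assert np.all(sel.B == 0.0)
        assert np.allclose(sel.Omega, np.eye(6), atol=1e-6)

    def test_bic_selects_the_minimum(self, missing_series):
        path = fit_gvar_lasso(
            missing_series,
            lambdas_B=np.geomspace(50.0, 0.5, 4),
            lambdas_K=np.geomspace(0.5, 0.01, 3),
        )
        assert path.selected.bic == min(e.bic for e in path.entries)
        assert len(path.entries) == 12

    def test_support_recovery_beats_permuted_chance(self, truth6):
        """Selected temporal support overlaps the truth more than a random
        relabeling of the same number of edges would."""
        s = simulate_series(truth6, missing=MissingnessSpec(0.0), seed=33)
        path = fit_gvar_lasso(
            s, lambdas_B=np.geomspace(100.0, 1.0, 6), lambdas_K=[0.05]
        )
        est = np.abs(path.selected_model.B) > 1e-8
        true = truth6.B != 0.0

        def jaccard(a, b):
            return (a & b).sum() / max((a | b).sum(), 1)

        obs = jaccard(est, true)
        rng = np.random.default_rng(0)
        chance = []
        for _ in range(200):
            perm = np.zeros(36, dtype=bool)
            perm[rng.choice(36, est.sum(), replace=False)] = True
            chance.append(jaccard(perm.reshape(6, 6), true))
        assert obs > np.mean(chance)
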