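"""Estimation engine: discrepancy, fitting, robust corrections, score tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lava_frozen

import rshift as rs
from rshift import engine as eng
from rshift import model as ms
from rshift.errors import ConfigurationError


class TestImpliedMoments:
    def test_final_model_implied_variance_and_mean(self, model4, gen):
        """Implied Var(SF,t1) = 12.508^2 + 243.06 and implied mean(SF,t2)
        = 87.290 + 12.508 * (-0.165), straight arithmetic on the
        generating parameters."""
        Sigma, mu = rs.implied_moments(model4, gen.as_estimates())
        i_sf = ms.DEFAULT_SCALES.index("SF")
        assert Sigma[i_sf, i_sf] == pytest.approx(399.510064, abs=1e-6)
        assert mu[8 + i_sf] == pytest.approx(85.22618, abs=1e-6)
        assert np.allclose(Sigma, Sigma.T)

    def test_zero_loadings_give_theta_and_tau(self, toy_config):
        m = rs.build_model(toy_config)
        est = {}
        for i, s in enumerate(m.scales):
            est[ms.lam_id(s, "f", 1)] = 0.0
            est[ms.tau_id(s, 1)] = float(i)
            est[ms.theta_id(s, 1)] = 2.0 + i
        Sigma, mu = rs.implied_moments(m, est)
        assert np.allclose(Sigma, np.diag([2.0, 3.0, 4.0, 5.0]))
        assert np.allclose(mu, [0, 1, 2, 3])


class TestDiscrepancy:
    def test_saturation_gives_zero(self, pop_moments):
        F, T = rs.ml_discrepancy(pop_moments, pop_moments.S, pop_moments.m)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert T == pytest.approx(0.0, abs=1e-9)

    def test_univariate_hand_value(self):
        """p=1, S=2, Sigma=1, equal means: F = ln 1 + 2 - ln 2 - 1 = 1 - ln 2."""
        mom = rs.SampleMoments(S=[[2.0]], m=[0.0], n=50)
        F, T = rs.ml_discrepancy(mom, np.array([[1.0]]), np.array([0.0]))
        assert F == pytest.approx(1.0 - np.log(2.0), abs=1e-12)
        assert T == pytest.approx(49 * (1.0 - np.log(2.0)), abs=1e-9)

    def test_equals_log_likelihood_ratio_oracle(self, toy_data):
        """F computed from n-divisor moments equals 2/n * (saturated minus
        model log-likelihood), with the likelihoods evaluated through
        scipy's multivariate normal as an independent route."""
        Y = toy_data.to_numpy()
        n = len(Y)
        S_n = np.cov(Y, rowvar=False, ddof=0)
        ybar = Y.mean(axis=0)
        Sigma = S_n * 1.3 + 0.2 * np.eye(4)
        mu = ybar + 0.1
        mom = rs.SampleMoments(S=S_n, m=ybar, n=n)
        F, _ = rs.ml_discrepancy(mom, Sigma, mu)
        ll_sat = stats.multivariate_normal(ybar, S_n).logpdf(Y).sum()
        ll_mod = stats.multivariate_normal(mu, Sigma).logpdf(Y).sum()
        assert F == pytest.approx(2.0 * (ll_sat - ll_mod) / n, rel=1e-10)


class TestFit:
    def test_just_identified_closed_form(self):
        """1-factor, 3-indicator model is just identified: T = 0 and the
        loadings obey the classical closed-form solution
        lambda_1 = sqrt(s12 s13 / s23)."""
        cfg = {"scales": ["a", "b", "c"], "factors": {"f": ["a", "b", "c"]},
               "occasions": 1, "residual_covariances": []}
        m = rs.build_model(cfg)
        S = np.array([[2.0, 0.8, 0.9], [0.8, 1.5, 0.6], [0.9, 0.6, 1.8]])
        mom = rs.SampleMoments(S=S, m=[1.0, 2.0, 3.0], n=100)
        f = rs.fit(m, mom)
        assert ms.model_df(m) == 0
        assert f.T_ml == pytest.approx(0.0, abs=1e-8)
        lam1 = np.sqrt(S[0, 1] * S[0, 2] / S[1, 2])
        assert abs(f.estimates[ms.lam_id("a", "f", 1)]) == pytest.approx(
            lam1, abs=1e-6)
        assert f.estimates[ms.tau_id("a", 1)] == pytest.approx(1.0, abs=1e-6)

    def test_population_recovery_two_factor_toy(self):
        """Fitting a model to its own implied moments returns the
        generating parameter vector with T ~ 0."""
        cfg = {"scales": ["a", "b", "c", "d", "e"],
               "factors": {"F1": ["a", "b", "c"], "F2": ["d", "e"]},
               "occasions": 1, "residual_covariances": []}
        m = rs.build_model(cfg)
        truth = {}
        for i, s in enumerate(m.scales):
            fac = "F1" if s in "abc" else "F2"
            truth[ms.lam_id(s, fac, 1)] = 0.8 + 0.1 * i
            truth[ms.tau_id(s, 1)] = float(i)
            truth[ms.theta_id(s, 1)] = 0.5 + 0.1 * i
        truth[ms.rho_id("F1_t1", "F2_t1")] = 0.4
        Sigma, mu = rs.implied_moments(m, truth)
        f = rs.fit(m, rs.SampleMoments(S=Sigma, m=mu, n=500))
        assert f.T_ml < 1e-6
        for pid, v in truth.items():
            assert f.estimates[pid] == pytest.approx(v, abs=1e-5)

    def test_chisq_invariant_to_indicator_order(self, gen, model1):
        data = rs.simulate(gen, 300, seed=5)
        f_a = rs.fit(model1, data)
        shuffled = data[list(data.columns[::-1])]
        f_b = rs.fit(model1, shuffled)
        assert f_a.T_ml == pytest.approx(f_b.T_ml, rel=1e-8)

    def test_release_never_increases_chisq(self, gen, model1, model2):
        data = rs.simulate(gen, 250, seed=9)
        f2 = rs.fit(model2, data)
        f1 = rs.fit(model1, data, start=f2.estimates)
        assert f1.T_ml <= f2.T_ml + 1e-6
        rel = rs.release_constraint(model2, ms.theta_id("RP", 1))
        fr = rs.fit(rel, data, start=f2.estimates)
        assert fr.T_ml <= f2.T_ml + 1e-6

    def test_rejects_wrong_input_type(self, model1):
        with pytest.raises(ConfigurationError):
            rs.fit(model1, np.zeros((10, 16)))


class TestIndependentOracle:
    """Cross-checks against lava (an independent maximum-likelihood
    latent-variable implementation in R); see lava_frozen for the frozen
    coefficients and the likelihood-convention bridge."""

    @pytest.mark.parametrize("case", lava_frozen.ALL_CASES,
                             ids=["one_factor", "two_factor"])
    def test_estimates_and_chisq_match_lava(self, case):
        cfg, Y, frozen, T_frozen = case()
        f = rs.fit(rs.build_model(cfg), lava_frozen.ml_convention_moments(Y))
        for pid, v in frozen.items():
            assert f.estimates[pid] == pytest.approx(v, abs=1e-4)
        assert f.T_ml == pytest.approx(T_frozen, abs=1e-4)


class TestRobustCorrections:
    def test_normal_theory_gamma_gives_unit_scaling(self, model1, pop_moments):
        f1 = rs.fit(model1, pop_moments)
        Sigma, _ = rs.implied_moments(model1, f1.estimates)
        mom = rs.SampleMoments(S=pop_moments.S, m=pop_moments.m, n=203,
                               gamma=eng.normal_theory_gamma(Sigma))
        assert rs.mlr_scaling_factor(f1, mom) == pytest.approx(1.0, abs=1e-8)

    def test_heavy_tails_inflate_scaling(self, toy_config):
        m = rs.build_model(toy_config)
        rng = np.random.default_rng(11)
        n = 4000
        lam = np.array([1.0, 0.8, 1.2, 0.9])
        th = np.array([0.5, 0.7, 0.6, 0.8])
        w = rng.chisquare(5, n) / 5
        eps = (rng.standard_normal((n, 4)) * np.sqrt(th)
               / np.sqrt(w)[:, None] * np.sqrt(3 / 5))
        Y = pd.DataFrame(np.outer(rng.standard_normal(n), lam) + eps,
                         columns=[f"y{i}_t1" for i in range(1, 5)])
        f = rs.fit(m, Y, estimator="MLR")
        assert f.c > 1.2
        assert f.T_scaled == pytest.approx(f.T_ml / f.c)

    def test_saturated_model_scaling_undefined(self):
        cfg = {"scales": ["a", "b", "c"], "factors": {"f": ["a", "b", "c"]},
               "occasions": 1, "residual_covariances": []}
        m = rs.build_model(cfg)
        rng = np.random.default_rng(3)
        Y = pd.DataFrame(rng.standard_normal((200, 3)) + [1, 2, 3],
                         columns=["a_t1", "b_t1", "c_t1"])
        f = rs.fit(m, Y, estimator="ML")
        mom = rs.SampleMoments.from_data(Y, m.indicators, compute_gamma=True)
        with pytest.raises(ConfigurationError):
            rs.mlr_scaling_factor(f, mom)


class TestScaledDifferenceTest:
    def _stub(self, T, c, df):
        mom = rs.SampleMoments(S=np.eye(2), m=np.zeros(2), n=100)
        return eng.FittedModel(model=None, moments=mom, x=np.zeros(1),
                               estimates={}, F=T / 99, T_ml=T, df=df, c=c)

    def test_unscaled_reduction(self):
        dt = rs.sb_diff_test(self._stub(120.0, 1.0, 10), self._stub(100.0, 1.0, 8))
        assert dt.cd == 1.0
        assert dt.TRd == pytest.approx(20.0)

    def test_hand_worked_scaled_example(self):
        """T0=100, c0=1.2, df0=10 vs T1=80, c1=1.0, df1=8:
        cd = (12-8)/2 = 2, TRd = 10, p = P(chi2_2 > 10)."""
        dt = rs.sb_diff_test(self._stub(100.0, 1.2, 10), self._stub(80.0, 1.0, 8))
        assert dt.cd == pytest.approx(2.0)
        assert dt.TRd == pytest.approx(10.0)
        assert dt.df == 2
        assert dt.p == pytest.approx(stats.chi2.sf(10.0, 2))

    def test_negative_difference_not_rejected(self):
        dt = rs.sb_diff_test(self._stub(80.0, 1.0, 10), self._stub(90.0, 1.0, 8))
        assert dt.TRd < 0
        assert dt.p == 1.0
        assert dt.warning is not None

    def test_nesting_precondition(self):
        with pytest.raises(ConfigurationError):
            rs.sb_diff_test(self._stub(80.0, 1.0, 8), self._stub(70.0, 1.0, 10))


class TestModificationIndices:
    def test_free_parameter_has_zero_index(self, model2, pop_moments):
        f2 = rs.fit(model2, pop_moments)
        mi = rs.modification_indices(f2, [ms.tau_id("GH", 2),
                                          ms.kappa_id("GenPHYS", 2)])
        free_row = mi[mi.parameter == ms.kappa_id("GenPHYS", 2)]
        assert float(free_row.mi.iloc[0]) == pytest.approx(0.0, abs=1e-4)

    def test_planted_intercept_shift_ranks_first(self, gen_null, model2):
        params = rs.inject_rs(gen_null, "SF", "uniform recalibration", 7.241)
        f2 = rs.fit(model2, params.implied_moments(n=203))
        intercept_cands = [ms.tau_id(s, 2) for s in ms.DEFAULT_SCALES]
        mi = rs.modification_indices(f2, intercept_cands)
        assert mi.iloc[0]["parameter"] == ms.tau_id("SF", 2)

    def test_index_approximates_refit_drop(self, gen_null, model2):
        """For a small planted effect the score statistic approximates the
        actual chi-square drop from refitting with the release."""
        params = rs.inject_rs(gen_null, "SF", "uniform recalibration", 1.5)
        mom = params.implied_moments(n=203)
        f2 = rs.fit(model2, mom)
        mi = rs.modification_indices(f2, [ms.tau_id("SF", 2)])
        released = rs.release_constraint(model2, ms.tau_id("SF", 2))
        fr = rs.fit(released, mom, start=f2.estimates)
        drop = f2.T_ml - fr.T_ml
        assert float(mi.mi.iloc[0]) == pytest.approx(drop, rel=0.10)
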