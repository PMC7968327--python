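"""Synthetic-data generator: defaults, moment consistency, RS injection."""

import numpy as np
import pytest

import rshift as rs
from rshift import model as ms
from rshift.errors import ConfigurationError


class TestDefaults:
    def test_sf_intercept_shift(self, gen):
        i = ms.DEFAULT_SCALES.index("SF")
        assert gen.tau_t2[i] - gen.tau_t1[i] == pytest.approx(7.241)

    def test_occasion1_identification(self, gen):
        assert np.allclose(gen.factor_means[:2], 0.0)
        assert np.allclose(gen.factor_vars[:2], 1.0)

    def test_correlation_matrix_positive_definite(self, gen):
        assert np.linalg.eigvalsh(gen.factor_corr).min() > 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            rs.GeneratingParameters(theta_t1=np.zeros(8),
                                    theta_t2=np.ones(8))
        bad_corr = np.full((4, 4), 0.99)
        np.fill_diagonal(bad_corr, 1.0)
        bad_corr[0, 1] = bad_corr[1, 0] = -0.99
        with pytest.raises(ConfigurationError):
            rs.GeneratingParameters(factor_corr=bad_corr)


class TestSimulate:
    def test_seed_determinism(self, gen):
        a = rs.simulate(gen, 50, seed=123)
        b = rs.simulate(gen, 50, seed=123)
        assert a.equals(b)
        assert not a.equals(rs.simulate(gen, 50, seed=124))

    def test_large_sample_mean_matches_implied(self, gen):
        """Law of large numbers: mean of SF_t2 approaches
        87.290 + 12.508 * (-0.165) = 85.226."""
        data = rs.simulate(gen, 200_000, seed=42)
        assert data["SF_t2"].mean() == pytest.approx(85.22618, abs=0.15)

    def test_sample_cov_converges_to_implied(self, gen):
        mom = gen.implied_moments()
        d_small = rs.simulate(gen, 2_000, seed=7)
        d_big = rs.simulate(gen, 80_000, seed=7)
        err = [np.linalg.norm(np.cov(d.to_numpy(), rowvar=False) - mom.S)
               / np.linalg.norm(mom.S) for d in (d_small, d_big)]
        assert err[1] < err[0]
        assert err[1] < 0.02

    def test_scaled_t_keeps_moment_structure(self, gen):
        d = rs.simulate_scaled_t(gen, 60_000, seed=3, t_df=8)
        mom = gen.implied_moments()
        rel = np.linalg.norm(np.cov(d.to_numpy(), rowvar=False) - mom.S) \
            / np.linalg.norm(mom.S)
        assert rel < 0.05

    def test_n_must_be_positive(self, gen):
        with pytest.raises(ConfigurationError):
            rs.simulate(gen, 0, seed=1)


class TestInjectRs:
    def test_uniform_recalibration_reproduces_default_intercepts(self, gen_null):
        out = rs.inject_rs(gen_null, "SF", "uniform recalibration", 7.241)
        i = ms.DEFAULT_SCALES.index("SF")
        assert out.tau_t2[i] == pytest.approx(80.049 + 7.241)
        assert np.allclose(np.delete(out.tau_t2, i), np.delete(gen_null.tau_t2, i))

    def test_zero_magnitude_is_identity(self, gen_null):
        out = rs.inject_rs(gen_null, "PF", "reprioritization", 0.0)
        assert np.allclose(out.lambda_t2, gen_null.lambda_t2)
        assert np.allclose(out.tau_t2, gen_null.tau_t2)

    def test_reprioritization_is_local(self, gen_null):
        out = rs.inject_rs(gen_null, "PF", "reprioritization", 5.0)
        diff = out.lambda_t2 - gen_null.lambda_t2
        assert diff[ms.DEFAULT_SCALES.index("PF"), 0] == pytest.approx(5.0)
        assert np.count_nonzero(diff) == 1
        assert np.allclose(out.lambda_t1, gen_null.lambda_t1)

    def test_composable(self, gen_null):
        out = rs.inject_rs(gen_null, "SF", "uniform recalibration", 7.241)
        out = rs.inject_rs(out, "RP", "non-uniform recalibration", 414.5)
        assert out.tau_t2[ms.DEFAULT_SCALES.index("SF")] > 87.0
        assert out.theta_t2[ms.DEFAULT_SCALES.index("RP")] == pytest.approx(492.01)

    def test_unknown_type_and_scale_error(self, gen_null):
        with pytest.raises(ConfigurationError):
            rs.inject_rs(gen_null, "SF", "gestalt shift", 1.0)
        with pytest.raises(ConfigurationError):
            rs.inject_rs(gen_null, "XX", "uniform recalibration", 1.0)


class TestTruncate:
    def test_clamps_and_identity(self, gen):
        d = rs.simulate(gen, 500, seed=2)
        t = rs.truncate_to_scale_range(d)
        assert t.to_numpy().min() >= 0.0
        assert t.to_numpy().max() <= 100.0
        inside = d.clip(0, 100)
        assert t.equals(inside)
        assert rs.truncate_to_scale_range(inside).equals(inside)

    def test_bad_bounds_error(self, gen):
        d = rs.simulate(gen, 10, seed=2)
        with pytest.raises(ConfigurationError):
            rs.truncate_to_scale_range(d, lo=50, hi=50)


class TestFullPipelineRecovery:
    def test_monte_carlo_estimates_unbiased(self, gen, model4):
        """Across replicates at the study's sample size, the mean of the
        fitted estimates stays within 2 Monte-Carlo SEs of the generating
        values for a set of probe parameters."""
        probes = {ms.tau_id("SF", 2): 87.290,
                  ms.theta_id("RP", 2): 492.01,
                  ms.kappa_id("GenPHYS", 2): 0.234,
                  ms.psi_id("GenMENT", 2): 0.781,
                  ms.lam_id("SF", "GenMENT", 1): 12.508}
        truth = gen.as_estimates()
        reps = 60
        draws = {k: [] for k in probes}
        for r in range(reps):
            d = rs.simulate(gen, 203, seed=1000 + r)
            f = rs.fit(model4, d, start=truth, gtol=1e-6, compute_se=False)
            for k in probes:
                draws[k].append(f.estimates[k])
        for k, want in probes.items():
            v = np.asarray(draws[k])
            se = v.std(ddof=1) / np.sqrt(reps)
            assert abs(v.mean() - want) < 2.5 * se + 1e-3, k
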