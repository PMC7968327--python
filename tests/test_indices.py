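"""Fit indices and the acceptability gate."""

import numpy as np
import pytest

import rshift as rs
from rshift import indices as fi
from rshift import model as ms


class TestScalarFormulas:
    def test_perfect_fit_limits(self):
        assert fi.cfi(50.0, 50, 300.0, 120) == 1.0
        assert fi.rmsea(50.0, 50, 203) == 0.0
        assert fi.tli(50.0, 50, 300.0, 120) == 1.0

    def test_baseline_as_its_own_target_gives_zero_cfi(self):
        assert fi.cfi(300.0, 120, 300.0, 120) == 0.0

    def test_df_zero_undefined(self):
        assert fi.rmsea(0.0, 0, 203) is None
        assert fi.tli(0.0, 0, 300.0, 120) is None

    def test_formula_oracle_on_random_dataset(self, gen, model1, model2):
        """Indices from the engine agree with an independent re-coding of
        the standard formulas applied to the raw chi-squares."""
        data = rs.simulate(gen, 400, seed=21)
        f = rs.fit(model2, data)
        b = rs.fit(rs.independence_model(model2), data)
        out = rs.compute_indices(f, b)
        T, df, Tb, dfb, n = f.T_ml, f.df, b.T_ml, b.df, f.n
        assert out.chisq == pytest.approx(T)
        assert out.cfi == pytest.approx(
            1 - max(T - df, 0) / max(Tb - dfb, T - df, 0), abs=1e-8)
        assert out.tli == pytest.approx(
            ((Tb / dfb) - (T / df)) / ((Tb / dfb) - 1), abs=1e-8)
        assert out.rmsea == pytest.approx(
            np.sqrt(max(T - df, 0) / (df * (n - 1))), abs=1e-8)
        # SRMR from scratch: standardized covariance residuals
        Sigma, _ = rs.implied_moments(model2, f.estimates)
        S = f.moments.S
        d = np.sqrt(np.diag(S))
        R = (S - Sigma) / np.outer(d, d)
        i, j = np.tril_indices(16)
        assert out.srmr == pytest.approx(np.sqrt(np.mean(R[i, j] ** 2)), abs=1e-8)


class TestRmseaCI:
    def test_ci_brackets_point_estimate(self, gen, model2):
        data = rs.simulate(gen, 300, seed=4)
        f = rs.fit(model2, data)
        b = rs.fit(rs.independence_model(model2), data)
        out = rs.compute_indices(f, b)
        lo, hi = out.rmsea_ci90
        assert lo <= out.rmsea <= hi

    def test_ci_endpoints_monotone_in_statistic(self):
        df, n = 80, 203
        bounds = [fi._ncp_ci(T, df) for T in (90.0, 130.0, 200.0)]
        los = [b[0] for b in bounds]
        his = [b[1] for b in bounds]
        assert los == sorted(los)
        assert his == sorted(his)


class TestGate:
    def _make(self, **kw):
        base = dict(chisq=151.6, df=88, cfi=0.951, tli=0.934, rmsea=0.060,
                    rmsea_ci90=(0.043, 0.075), srmr=0.050)
        base.update(kw)
        return fi.FitIndices(**base)

    def test_published_model1_indices_pass(self):
        gate = rs.acceptability_gate(self._make())
        assert gate.passed and gate.reasons == []

    def test_low_cfi_fails_with_reason(self):
        gate = rs.acceptability_gate(self._make(cfi=0.89))
        assert not gate.passed
        assert gate.reasons == ["CFI"]

    def test_thresholds_are_strict(self):
        gate = rs.acceptability_gate(self._make(rmsea=0.08))
        assert not gate.passed
        assert "RMSEA" in gate.reasons
        gate = rs.acceptability_gate(self._make(cfi=0.9, tli=0.9))
        assert set(gate.reasons) == {"CFI", "TLI"}
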