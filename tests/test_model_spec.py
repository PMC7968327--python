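"""Constraint algebra and degrees-of-freedom bookkeeping."""

import pytest
import yaml
from hypothesis import given
from hypothesis import strategies as st

import rshift as rs
from rshift import model as ms
from rshift.errors import ConfigurationError, ConstraintError


class TestDfBookkeeping:
    def test_published_df_sequence(self, model1, model2, model3, model4):
        """The four nested longitudinal models have df 88/108/105/106."""
        assert ms.moment_count(model1) == 152
        assert ms.model_df(model1) == 88
        assert ms.model_df(model2) == 108
        assert ms.model_df(model3) == 105
        assert ms.model_df(model4) == 106

    def test_model1_free_parameter_count(self, model1):
        # 16 loadings + 16 intercepts + 16 residual variances
        # + 10 residual covariances + 6 factor correlations
        assert model1.n_free() == 64

    def test_independence_baseline_df(self, model1):
        base = rs.independence_model(model1)
        assert ms.model_df(base) == 152 - 32

    def test_one_occasion_toy_parameter_count(self):
        cfg = {"scales": ["a", "b", "c"], "factors": {"f": ["a", "b", "c"]},
               "occasions": 1, "residual_covariances": []}
        m = rs.build_model(cfg)
        # 3 loadings + 3 intercepts + 3 residual variances
        assert m.n_free() == 9
        assert ms.moment_count(m) == 9

    def test_moment_count_is_p_time_p_plus_3_halves(self):
        single = ms.MeasurementModel(scales=("a",), structure={}, n_occasions=1)
        assert ms.moment_count(single) == 2

    def test_invariance_class_variants(self, model1):
        assert ms.model_df(rs.apply_invariance(model1, ())) == 88
        # loadings only: +8 constraints, -2 freed occasion-2 factor variances
        assert ms.model_df(rs.apply_invariance(model1, {"loadings"})) == 94

    def test_factor_structure_constraints(self, model3):
        assert ms.model_df(rs.constrain_factor_structure(model3, ())) == 105
        all3 = rs.constrain_factor_structure(
            model3, {"factor_means", "factor_variances", "factor_correlations"})
        assert ms.model_df(all3) == 110


class TestConstraintAlgebra:
    def test_release_then_reapply_restores_df(self, model2):
        pid1, pid2 = ms.tau_id("SF", 1), ms.tau_id("SF", 2)
        released = rs.release_constraint(model2, pid1)
        assert ms.model_df(released) == 107
        restored = released.with_equality((pid1, pid2))
        assert ms.model_df(restored) == ms.model_df(model2)

    def test_release_unconstrained_pair_errors(self, model1):
        with pytest.raises(ConstraintError):
            rs.release_constraint(model1, ms.tau_id("SF", 1))

    def test_double_constraint_errors(self, model2):
        with pytest.raises(ConstraintError):
            rs.apply_invariance(model2, {"intercepts"})

    def test_fixed_parameter_cannot_join_equality(self, model1):
        with pytest.raises(ConstraintError):
            model1.with_equality((ms.kappa_id("GenPHYS", 1),
                                  ms.kappa_id("GenPHYS", 2)))


class TestConfiguration:
    def test_indicator_in_two_factors_errors(self):
        cfg = rs.model.default_config()
        cfg["factors"]["GenPHYS"] = list(cfg["factors"]["GenPHYS"]) + ["SF"]
        with pytest.raises(ConfigurationError):
            rs.build_fig1_model(cfg)

    def test_unknown_indicator_errors(self):
        cfg = rs.model.default_config()
        cfg["factors"]["GenPHYS"] = ["PF", "RP", "BP", "XX"]
        with pytest.raises(ConfigurationError):
            rs.build_fig1_model(cfg)

    def test_unassigned_indicator_errors(self):
        cfg = rs.model.default_config()
        cfg["factors"]["GenPHYS"] = ["PF", "RP", "BP"]  # RE dropped
        with pytest.raises(ConfigurationError):
            rs.build_fig1_model(cfg)

    def test_three_occasions_errors(self):
        cfg = rs.model.default_config()
        cfg["occasions"] = 3
        with pytest.raises(ConfigurationError):
            rs.build_fig1_model(cfg)

    def test_config_roundtrip_is_identity(self, model4):
        cfg = ms.to_config(model4)
        back = ms.from_config(yaml.safe_load(yaml.safe_dump(cfg)))
        assert back.scales == model4.scales
        assert back.structure == model4.structure
        assert back.fixed == model4.fixed
        assert set(back.equalities) == set(model4.equalities)
        assert back.residual_cov_pairs == model4.residual_cov_pairs
        assert ms.model_df(back) == ms.model_df(model4)
        assert ms.to_config(back) == cfg


@st.composite
def random_structure(draw):
    n_scales = draw(st.integers(3, 6))
    scales = [f"s{i}" for i in range(n_scales)]
    n_fac = draw(st.integers(1, 2))
    cut = draw(st.integers(1, n_scales - 1)) if n_fac == 2 else n_scales
    factors = {"F1": scales[:cut]}
    if n_fac == 2:
        factors["F2"] = scales[cut:]
    return {"scales": scales, "factors": factors, "occasions": 2,
            "residual_covariances": "auto"}


class TestProperties:
    @given(random_structure())
    def test_full_invariance_df_gain(self, cfg):
        """Constraining the 3 RS classes gains 3s - 2k df (s scales, k factors)."""
        m = rs.build_model(cfg)
        m2 = rs.apply_invariance(m)
        s, k = len(cfg["scales"]), len(cfg["factors"])
        assert ms.model_df(m2) - ms.model_df(m) == 3 * s - 2 * k

    @given(random_structure())
    def test_serialization_roundtrip(self, cfg):
        m = rs.apply_invariance(rs.build_model(cfg))
        back = ms.from_config(ms.to_config(m))
        assert ms.to_config(back) == ms.to_config(m)

    @given(random_structure(), st.integers(0, 10))
    def test_release_drops_one_df(self, cfg, pick):
        m = rs.apply_invariance(rs.build_model(cfg))
        classes = sorted(sorted(c) for c in m.equalities)
        cls = classes[pick % len(classes)]
        released = rs.release_constraint(m, cls[0])
        assert ms.model_df(m) - ms.model_df(released) == 1
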