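import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rshift as rs
from rshift import model as ms

settings.register_profile(
    "repro", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("repro")


@pytest.fixture(scope="session")
def gen():
    return rs.default_generating_model()


@pytest.fixture(scope="session")
def gen_null():
    return rs.rs_free_generating_model()


@pytest.fixture(scope="session")
def pop_moments(gen):
    return gen.implied_moments(n=203)


@pytest.fixture(scope="session")
def model1():
    return rs.build_fig1_model()


@pytest.fixture(scope="session")
def model2(model1):
    return rs.apply_invariance(model1)


@pytest.fixture(scope="session")
def model3(model2):
    m = model2
    for pid in (ms.tau_id("SF", 1), ms.theta_id("RP", 1), ms.theta_id("BP", 1)):
        m = rs.release_constraint(m, pid)
    return m


@pytest.fixture(scope="session")
def model4(model3):
    return rs.constrain_factor_structure(model3, {"factor_correlations"})


@pytest.fixture(scope="session")
def pop_fit4(model4, pop_moments):
    """Model 4 fitted to the population moments of the default generator."""
    return rs.fit(model4, pop_moments)


@pytest.fixture(scope="session")
def toy_config():
    """1-factor, 4-indicator, single-occasion structure."""
    return {"scales": ["y1", "y2", "y3", "y4"],
            "factors": {"f": ["y1", "y2", "y3", "y4"]},
            "occasions": 1, "residual_covariances": []}


@pytest.fixture(scope="session")
def toy_data():
    rng = np.random.default_rng(20260926)
    n = 150
    lam = np.array([1.0, 0.8, 1.3, 0.7])
    tau = np.array([2.0, -1.0, 0.5, 1.5])
    th = np.array([0.6, 0.9, 0.5, 1.1])
    eta = rng.standard_normal(n) * 1.2 + 0.3
    Y = tau + np.outer(eta, lam) + rng.standard_normal((n, 4)) * np.sqrt(th)
    import pandas as pd
    return pd.DataFrame(Y, columns=["y1_t1", "y2_t1", "y3_t1", "y4_t1"])
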