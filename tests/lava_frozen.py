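"""Frozen cross-check fixtures from the lava R package.

lava is an independent maximum-likelihood latent-variable implementation;
its coefficients and likelihood-ratio chi-squares for the two deterministic
datasets below were computed once and frozen here.  lava maximizes the
raw-data normal likelihood, which coincides with this package's moment
discrepancy when the n-divisor covariance matrix is supplied together with
an n+1 nominal sample size.
"""

import numpy as np

import rshift as rs


def ml_convention_moments(Y: np.ndarray) -> rs.SampleMoments:
    n = len(Y)
    S_n = np.cov(Y, rowvar=False, ddof=0)
    return rs.SampleMoments(S=S_n, m=Y.mean(axis=0), n=n + 1)


def one_factor_case():
    rng = np.random.default_rng(20260926)
    n = 150
    lam = np.array([1.0, 0.8, 1.3, 0.7])
    tau = np.array([2.0, -1.0, 0.5, 1.5])
    th = np.array([0.6, 0.9, 0.5, 1.1])
    eta = rng.standard_normal(n) * 1.2 + 0.3
    Y = tau + np.outer(eta, lam) + rng.standard_normal((n, 4)) * np.sqrt(th)
    cfg = {"scales": ["y1", "y2", "y3", "y4"],
           "factors": {"f": ["y1", "y2", "y3", "y4"]},
           "occasions": 1, "residual_covariances": []}
    frozen = {"lambda[y1,f,t1]": 1.2305016, "lambda[y2,f,t1]": 0.8690152,
              "lambda[y3,f,t1]": 1.6027418, "lambda[y4,f,t1]": 0.8918299,
              "tau[y1,t1]": 2.3422718, "tau[y2,t1]": -0.7228262,
              "tau[y3,t1]": 0.8406524, "tau[y4,t1]": 1.7087326,
              "theta[y1,t1]": 0.6858046, "theta[y2,t1]": 0.9641332,
              "theta[y3,t1]": 0.4443181, "theta[y4,t1]": 0.9432904}
    return cfg, Y, frozen, 0.71815


def two_factor_case():
    rng = np.random.default_rng(77)
    n = 200
    lamA = np.array([1.0, 0.7, 1.1])
    lamB = np.array([0.9, 1.2, 0.8])
    tau = np.array([1.0, 2.0, -0.5, 0.0, 3.0, 1.5])
    th = np.array([0.5, 0.8, 0.6, 0.9, 0.7, 0.6])
    eta = rng.multivariate_normal([0, 0], [[1, .5], [.5, 1]], size=n)
    Th = np.diag(th)
    Th[0, 3] = Th[3, 0] = 0.2
    eps = rng.multivariate_normal(np.zeros(6), Th, size=n)
    Y = tau + np.column_stack([np.outer(eta[:, 0], lamA),
                               np.outer(eta[:, 1], lamB)]) + eps
    cfg = {"scales": ["y1", "y2", "y3", "y4", "y5", "y6"],
           "factors": {"fA": ["y1", "y2", "y3"], "fB": ["y4", "y5", "y6"]},
           "occasions": 1,
           "residual_covariances": [[["y1", 1], ["y4", 1]]]}
    frozen = {"tau[y1,t1]": 1.0806127, "tau[y2,t1]": 2.0884845,
              "tau[y3,t1]": -0.3420391, "tau[y4,t1]": 0.0841072,
              "tau[y5,t1]": 2.9382129, "tau[y6,t1]": 1.5600414,
              "lambda[y1,fA,t1]": 1.0079141, "lambda[y2,fA,t1]": 0.7870801,
              "lambda[y3,fA,t1]": 1.0771611, "lambda[y4,fB,t1]": 0.8420741,
              "lambda[y5,fB,t1]": 1.3093695, "lambda[y6,fB,t1]": 0.8446970,
              "theta[y1,t1]": 0.4333238, "theta[y2,t1]": 0.7727943,
              "theta[y3,t1]": 0.6999810, "theta[y4,t1]": 1.0106436,
              "theta[y5,t1]": 0.6238062, "theta[y6,t1]": 0.5399209,
              "rho[fA_t1,fB_t1]": 0.3704768,
              "theta_cov[y1_t1,y4_t1]": 0.2435762}
    return cfg, Y, frozen, 2.64518


ALL_CASES = (one_factor_case, two_factor_case)
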