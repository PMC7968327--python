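"""Two-occasion SF-36-like scale-score simulator.

The generator reads the final response-shift model forward as a
data-generating process: latent general-physical and general-mental health
factors at baseline and follow-up are drawn from a 4-variate normal with
the published means, variances and correlations, and the eight scale
scores per occasion arise as ``tau + Lambda * factors + residuals``.

The default parameter set is the fitted final-model solution for the
hypertension disease-management cohort, which already embodies three
response-shift effects: a uniform recalibration of SF (intercept
80.049 -> 87.290), non-uniform recalibration of RP and BP (residual
variances 77.51 -> 492.01 and 255.96 -> 125.94), and true change in both
factor means (+0.234 physical, -0.165 mental) with unequal follow-up
factor variances (1.136, 0.781).  Residual covariances (each scale with
itself across occasions, RP-RE within occasions) are not published and
default to zero, though the fitted models keep them free.

Additional response-shift effects of any of the four types can be planted
with :func:`inject_rs`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model as ms
from .engine import SampleMoments
from .errors import ConfigurationError

SCALES = ms.DEFAULT_SCALES
FACTORS = ("GenPHYS", "GenMENT")

_LOADINGS = {"PF": 17.557, "RP": 29.074, "BP": 13.761, "RE": 18.159,
             "GH": 14.339, "SF": 12.508, "VT": 12.664, "MH": 13.713}
_INTERCEPTS_T1 = (74.214, 72.804, 78.853, 83.962, 54.656, 80.049, 55.038, 69.664)
_RESID_T1 = (236.00, 77.51, 255.96, 670.02, 141.12, 243.06, 169.46, 282.52)
_RESID_T2 = (236.00, 492.01, 125.94, 670.02, 141.12, 243.06, 169.46, 282.52)
# factor order: GenPHYS_t1, GenMENT_t1, GenPHYS_t2, GenMENT_t2
_FACTOR_MEANS = (0.0, 0.0, 0.234, -0.165)
_FACTOR_VARS = (1.0, 1.0, 1.136, 0.781)
_FACTOR_CORR = np.array([
    [1.000, 0.840, 0.871, 0.561],
    [0.840, 1.000, 0.685, 0.583],
    [0.871, 0.685, 1.000, 0.840],
    [0.561, 0.583, 0.840, 1.000],
])

RS_TYPES = ("uniform recalibration", "non-uniform recalibration",
            "reprioritization", "reconceptualization")


@dataclass
class GeneratingParameters:
    """Fully numeric two-occasion factor model used as a data generator.

    Loadings are stored per occasion as 8x2 matrices over (GenPHYS,
    GenMENT) so that occasion-specific changes (reprioritization,
    reconceptualization) can be represented; by default the two occasions
    share the published loadings.
    """

    scales: tuple = SCALES
    factors: tuple = FACTORS
    lambda_t1: np.ndarray = None
    lambda_t2: np.ndarray = None
    tau_t1: np.ndarray = None
    tau_t2: np.ndarray = None
    theta_t1: np.ndarray = None
    theta_t2: np.ndarray = None
    factor_means: np.ndarray = None
    factor_vars: np.ndarray = None
    factor_corr: np.ndarray = None
    residual_cross_cov: np.ndarray = None   # per scale, across occasions
    residual_rp_re_cov: tuple = (0.0, 0.0)  # RP-RE within each occasion

    def __post_init__(self):
        if self.lambda_t1 is None:
            lam = np.zeros((8, 2))
            for i, s in enumerate(SCALES):
                lam[i, 0 if s in ms.FIG_STRUCTURE["GenPHYS"] else 1] = _LOADINGS[s]
            self.lambda_t1 = lam
            self.lambda_t2 = lam.copy()
        if self.tau_t1 is None:
            self.tau_t1 = np.array(_INTERCEPTS_T1)
            self.tau_t2 = np.array(_INTERCEPTS_T1)
            self.tau_t2[SCALES.index("SF")] = 87.290
        if self.theta_t1 is None:
            self.theta_t1 = np.array(_RESID_T1)
            self.theta_t2 = np.array(_RESID_T2)
        if self.factor_means is None:
            self.factor_means = np.array(_FACTOR_MEANS)
        if self.factor_vars is None:
            self.factor_vars = np.array(_FACTOR_VARS)
        if self.factor_corr is None:
            self.factor_corr = _FACTOR_CORR.copy()
        if self.residual_cross_cov is None:
            self.residual_cross_cov = np.zeros(8)
        self.validate()

    def validate(self):
        if np.any(self.theta_t1 <= 0) or np.any(self.theta_t2 <= 0):
            raise ConfigurationError("residual variances must be positive")
        if np.linalg.eigvalsh(self.factor_corr).min() <= 0:
            raise ConfigurationError("factor correlation matrix must be "
                                     "positive definite")
        if np.any(self.factor_vars <= 0):
            raise ConfigurationError("factor variances must be positive")

    # -- implied structure --------------------------------------------------

    @property
    def factor_cov(self) -> np.ndarray:
        sd = np.sqrt(self.factor_vars)
        return self.factor_corr * np.outer(sd, sd)

    def full_lambda(self) -> np.ndarray:
        """16x4 loading matrix over (GP_t1, GM_t1, GP_t2, GM_t2)."""
        L = np.zeros((16, 4))
        L[:8, :2] = self.lambda_t1
        L[8:, 2:] = self.lambda_t2
        return L

    def full_theta(self) -> np.ndarray:
        Th = np.diag(np.concatenate([self.theta_t1, self.theta_t2]))
        for i in range(8):
            Th[i, 8 + i] = Th[8 + i, i] = self.residual_cross_cov[i]
        irp, ire = SCALES.index("RP"), SCALES.index("RE")
        Th[irp, ire] = Th[ire, irp] = self.residual_rp_re_cov[0]
        Th[8 + irp, 8 + ire] = Th[8 + ire, 8 + irp] = self.residual_rp_re_cov[1]
        return Th

    def full_tau(self) -> np.ndarray:
        return np.concatenate([self.tau_t1, self.tau_t2])

    def implied_moments(self, n: int = 203) -> SampleMoments:
        """Population covariance matrix and mean vector as SampleMoments."""
        L = self.full_lambda()
        Sigma = L @ self.factor_cov @ L.T + self.full_theta()
        mu = self.full_tau() + L @ self.factor_means
        names = tuple(ms.obs_name(s, o) for o in (1, 2) for s in SCALES)
        return SampleMoments(S=Sigma, m=mu, n=n, names=names)

    def as_estimates(self) -> dict:
        """Parameter-id -> value map matching the fitted-model naming."""
        est = {}
        for occ, lam in ((1, self.lambda_t1), (2, self.lambda_t2)):
            for i, s in enumerate(SCALES):
                for j, f in enumerate(FACTORS):
                    if lam[i, j] != 0.0:
                        est[ms.lam_id(s, f, occ)] = float(lam[i, j])
        for occ, tau in ((1, self.tau_t1), (2, self.tau_t2)):
            for i, s in enumerate(SCALES):
                est[ms.tau_id(s, occ)] = float(tau[i])
        for occ, th in ((1, self.theta_t1), (2, self.theta_t2)):
            for i, s in enumerate(SCALES):
                est[ms.theta_id(s, occ)] = float(th[i])
        for i in range(8):
            est[ms.theta_cov_id(ms.obs_name(SCALES[i], 1),
                                ms.obs_name(SCALES[i], 2))] = \
                float(self.residual_cross_cov[i])
        for occ in (1, 2):
            est[ms.theta_cov_id(ms.obs_name("RP", occ), ms.obs_name("RE", occ))] = \
                float(self.residual_rp_re_cov[occ - 1])
        fullfacs = [ms.factor_name(f, o) for o in (1, 2) for f in FACTORS]
        for i, (f, occ) in enumerate([(f, o) for o in (1, 2) for f in FACTORS]):
            est[ms.kappa_id(f, occ)] = float(self.factor_means[i])
            est[ms.psi_id(f, occ)] = float(self.factor_vars[i])
        for a in range(4):
            for b in range(a + 1, 4):
                est[ms.rho_id(fullfacs[a], fullfacs[b])] = \
                    float(self.factor_corr[a, b])
        return est


def default_generating_model() -> GeneratingParameters:
    """The published final-model parameter set as a generator."""
    return GeneratingParameters()


def rs_free_generating_model() -> GeneratingParameters:
    """A no-response-shift, no-change variant: occasion 2 mirrors occasion 1."""
    g = GeneratingParameters()
    g.tau_t2 = g.tau_t1.copy()
    g.theta_t2 = g.theta_t1.copy()
    g.lambda_t2 = g.lambda_t1.copy()
    g.factor_means = np.zeros(4)
    g.factor_vars = np.ones(4)
    return g


def simulate(params: GeneratingParameters, n: int, seed) -> pd.DataFrame:
    """Draw ``n`` respondents' scale scores at both occasions.

    Factor scores are 4-variate normal, residuals 16-variate normal with
    the generator's residual covariance structure; columns are named
    ``<SCALE>_t<occasion>``, occasion-1 block first.
    """
    if n < 1:
        raise ConfigurationError("n must be at least 1")
    rng = np.random.default_rng(seed)
    L = params.full_lambda()
    eta = rng.multivariate_normal(params.factor_means, params.factor_cov,
                                  size=n, method="cholesky")
    eps = rng.multivariate_normal(np.zeros(16), params.full_theta(),
                                  size=n, method="cholesky")
    Y = params.full_tau() + eta @ L.T + eps
    names = [ms.obs_name(s, o) for o in (1, 2) for s in params.scales]
    return pd.DataFrame(Y, columns=names)


def simulate_scaled_t(params: GeneratingParameters, n: int, seed,
                      t_df: float = 5.0) -> pd.DataFrame:
    """Like :func:`simulate` but with heavy-tailed (scaled-t) residuals.

    Residuals are multivariate-t draws rescaled to the same covariance, so
    the moment structure is unchanged while excess kurtosis exercises the
    robust (MLR) correction path.
    """
    if t_df <= 2:
        raise ConfigurationError("t_df must exceed 2 for finite variance")
    rng = np.random.default_rng(seed)
    L = params.full_lambda()
    eta = rng.multivariate_normal(params.factor_means, params.factor_cov,
                                  size=n, method="cholesky")
    z = rng.multivariate_normal(np.zeros(16), params.full_theta(), size=n,
                                method="cholesky")
    w = rng.chisquare(t_df, size=n) / t_df
    eps = z / np.sqrt(w)[:, None] * np.sqrt((t_df - 2.0) / t_df)
    Y = params.full_tau() + eta @ L.T + eps
    names = [ms.obs_name(s, o) for o in (1, 2) for s in params.scales]
    return pd.DataFrame(Y, columns=names)


def inject_rs(params: GeneratingParameters, scale: str, rs_type: str,
              magnitude: float, factor: str | None = None) -> GeneratingParameters:
    """Plant one response-shift effect at occasion 2; composable.

    * ``uniform recalibration`` adds ``magnitude`` to the occasion-2
      intercept of ``scale``;
    * ``non-uniform recalibration`` adds it to the occasion-2 residual
      variance;
    * ``reprioritization`` adds it to the occasion-2 loading on the
      scale's own factor;
    * ``reconceptualization`` sets an occasion-2 cross-loading of
      ``magnitude`` on ``factor`` (required).
    """
    if scale not in params.scales:
        raise ConfigurationError(f"unknown scale {scale!r}")
    if not np.isfinite(magnitude):
        raise ConfigurationError("magnitude must be finite")
    out = copy.deepcopy(params)
    i = params.scales.index(scale)
    if rs_type == "uniform recalibration":
        out.tau_t2 = out.tau_t2.copy()
        out.tau_t2[i] += magnitude
    elif rs_type == "non-uniform recalibration":
        out.theta_t2 = out.theta_t2.copy()
        out.theta_t2[i] += magnitude
        if out.theta_t2[i] <= 0:
            raise ConfigurationError("injected residual variance must stay positive")
    elif rs_type == "reprioritization":
        out.lambda_t2 = out.lambda_t2.copy()
        j = int(np.argmax(np.abs(out.lambda_t2[i])))
        out.lambda_t2[i, j] += magnitude
    elif rs_type == "reconceptualization":
        if factor is None:
            raise ConfigurationError("reconceptualization needs a target factor")
        j = params.factors.index(factor)
        out.lambda_t2 = out.lambda_t2.copy()
        out.lambda_t2[i, j] = magnitude
    else:
        raise ConfigurationError(f"unknown rs_type {rs_type!r}; "
                                 f"expected one of {RS_TYPES}")
    out.validate()
    return out


def truncate_to_scale_range(data: pd.DataFrame, lo: float = 0.0,
                            hi: float = 100.0) -> pd.DataFrame:
    """Clamp simulated scores into the instrument's 0-100 range.

    Off by default in the pipeline: clamping breaks the normality the ML
    fit assumes, so use it only for bounded-realism demonstrations.
    """
    if lo >= hi:
        raise ConfigurationError("lo must be below hi")
    return data.clip(lower=lo, upper=hi)
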