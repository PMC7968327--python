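"""Maximum-likelihood estimation of longitudinal factor models.

The engine fits a :class:`~rshift.model.MeasurementModel` to sample moments
(covariance matrix ``S``, mean vector ``m``, sample size ``n``) by
minimizing the normal-theory discrepancy with mean structure

    F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p + (m - mu)' Sigma^-1 (m - mu)

over the free parameters, where ``Sigma = Lam Phi Lam' + Theta`` and
``mu = tau + Lam kappa``.  The chi-square statistic uses the Wishart
convention ``T = (n - 1) F``.

Internal parameterization: residual variances are optimized on the log
scale (which keeps them positive and avoids Heywood crashes), factor
variances as log-standard-deviations, and factor correlations through the
inverse hyperbolic tangent.  Equality-constrained parameters share a single
free coordinate, so invariance constraints are exact, not penalized.

Robust (MLR-style) corrections use the distribution-free estimate of the
asymptotic covariance of the sample moments (``gamma``) together with the
normal-theory weight and model Jacobian to form the scaling factor
``c = tr(U gamma) / df``; scaled chi-square differences follow the
Satorra-Bentler construction.  Modification indices are 1-df score tests
computed from the analytic gradient and a finite-difference observed
information at the solution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats

from . import model as ms
from .errors import ConfigurationError, ConvergenceError, NumericalError

logger = logging.getLogger(__name__)

_PENALTY = 1e12


# ---------------------------------------------------------------------------
# transforms (internal optimizer scale <-> external reporting scale)

def _to_internal(kind: str, value: float) -> float:
    if kind == "resid_var":
        return float(np.log(value))
    if kind == "factor_var":
        return 0.5 * float(np.log(value))
    if kind == "factor_corr":
        return float(np.arctanh(value))
    return float(value)


def _to_external(kind: str, value: float) -> float:
    if kind == "resid_var":
        return float(np.exp(value))
    if kind == "factor_var":
        return float(np.exp(2.0 * value))
    if kind == "factor_corr":
        return float(np.tanh(value))
    return float(value)


def _dext_dint(kind: str, external: float) -> float:
    """Derivative of the external value w.r.t. the internal coordinate."""
    if kind == "resid_var":
        return external
    if kind == "factor_var":
        return 2.0 * external
    if kind == "factor_corr":
        return 1.0 - external * external
    return 1.0


# ---------------------------------------------------------------------------


@dataclass
class SampleMoments:
    """Observed moments: covariance ``S`` (n-1 divisor), means ``m``, size ``n``.

    ``gamma`` optionally holds the distribution-free asymptotic covariance
    of the sample moment vector (means then vech(S)), needed for robust
    scaling corrections.
    """

    S: np.ndarray
    m: np.ndarray
    n: int
    gamma: np.ndarray | None = None
    names: tuple | None = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ConfigurationError("S must be a square matrix")
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise ConfigurationError("S must be symmetric")
        if self.m.shape[0] != self.S.shape[0]:
            raise ConfigurationError("mean vector length must match S")
        if self.n < 2:
            raise ConfigurationError("sample size must be at least 2")
        ev = np.linalg.eigvalsh(self.S)
        if ev.min() < -1e-8 * max(1.0, ev.max()):
            raise ConfigurationError("S must be positive semi-definite")

    @property
    def p(self) -> int:
        return self.S.shape[0]

    @classmethod
    def from_data(cls, data: pd.DataFrame, names: Sequence[str] | None = None,
                  compute_gamma: bool = False) -> "SampleMoments":
        """Moments from raw data, columns aligned to ``names`` if given."""
        if names is not None:
            missing = [c for c in names if c not in data.columns]
            if missing:
                raise ConfigurationError(f"data lacks columns: {missing}")
            data = data.loc[:, list(names)]
        Y = np.asarray(data, dtype=float)
        if np.isnan(Y).any():
            raise ConfigurationError("data contain missing values; "
                                     "filter to complete cases first")
        n = Y.shape[0]
        S = np.cov(Y, rowvar=False, ddof=1)
        m = Y.mean(axis=0)
        gamma = sample_gamma(Y) if compute_gamma else None
        return cls(S=np.atleast_2d(S), m=m, n=n, gamma=gamma,
                   names=tuple(data.columns))


def vech(M: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(M.shape[0])
    return M[i, j]


def duplication_matrix(p: int) -> np.ndarray:
    """D with vec(M) = D vech(M) for symmetric M (column-major vec)."""
    rows_i, rows_j = np.tril_indices(p)
    D = np.zeros((p * p, len(rows_i)))
    for k, (i, j) in enumerate(zip(rows_i, rows_j)):
        D[i + j * p, k] = 1.0
        D[j + i * p, k] = 1.0
    return D


def sample_gamma(Y: np.ndarray) -> np.ndarray:
    """Distribution-free asymptotic covariance of (means, vech(S))."""
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    Z = Y - Y.mean(axis=0)
    i, j = np.tril_indices(p)
    d = np.concatenate([Y, Z[:, i] * Z[:, j]], axis=1)
    d = d - d.mean(axis=0)
    return d.T @ d / n


def normal_theory_gamma(Sigma: np.ndarray) -> np.ndarray:
    """Asymptotic moment covariance implied by multivariate normality."""
    p = Sigma.shape[0]
    D = duplication_matrix(p)
    Dplus = np.linalg.solve(D.T @ D, D.T)
    cov_block = 2.0 * Dplus @ np.kron(Sigma, Sigma) @ Dplus.T
    top = np.concatenate([Sigma, np.zeros((p, cov_block.shape[1]))], axis=1)
    bot = np.concatenate([np.zeros((cov_block.shape[0], p)), cov_block], axis=1)
    return np.concatenate([top, bot], axis=0)


# ---------------------------------------------------------------------------
# parameter layout


class ParamLayout:
    """Maps a model's parameters to a flat internal vector and free slots."""

    def __init__(self, model: ms.MeasurementModel):
        self.model = model
        self.params = model.parameters()
        self.N = len(self.params)
        self.pid_index = {p.pid: idx for idx, p in enumerate(self.params)}
        self.kinds = [p.kind for p in self.params]

        obs = model.indicators
        facs = model.factors
        self.p = len(obs)
        self.k = len(facs)
        obs_ix = {name: i for i, name in enumerate(obs)}
        fac_ix = {name: i for i, name in enumerate(facs)}

        # structural index arrays per kind
        li, lj, lt = [], [], []
        ti, tt = [], []
        hi, ht = [], []
        ci, cj, ct = [], [], []
        ki, kt = [], []
        vi, vt = [], []
        ra, rb, rt = [], [], []
        for idx, pr in enumerate(self.params):
            if pr.kind == "loading":
                s, f, occ = pr.meta
                li.append(obs_ix[ms.obs_name(s, occ)])
                lj.append(fac_ix[ms.factor_name(f, occ)])
                lt.append(idx)
            elif pr.kind == "intercept":
                s, occ = pr.meta
                ti.append(obs_ix[ms.obs_name(s, occ)])
                tt.append(idx)
            elif pr.kind == "resid_var":
                s, occ = pr.meta
                hi.append(obs_ix[ms.obs_name(s, occ)])
                ht.append(idx)
            elif pr.kind == "resid_cov":
                (s1, o1), (s2, o2) = pr.meta
                ci.append(obs_ix[ms.obs_name(s1, o1)])
                cj.append(obs_ix[ms.obs_name(s2, o2)])
                ct.append(idx)
            elif pr.kind == "factor_mean":
                f, occ = pr.meta
                ki.append(fac_ix[ms.factor_name(f, occ)])
                kt.append(idx)
            elif pr.kind == "factor_var":
                f, occ = pr.meta
                vi.append(fac_ix[ms.factor_name(f, occ)])
                vt.append(idx)
            elif pr.kind == "factor_corr":
                f1, f2 = pr.meta
                ra.append(fac_ix[f1])
                rb.append(fac_ix[f2])
                rt.append(idx)
        arr = lambda x: np.asarray(x, dtype=int)
        self.load_i, self.load_j, self.load_t = arr(li), arr(lj), arr(lt)
        self.tau_i, self.tau_t = arr(ti), arr(tt)
        self.th_i, self.th_t = arr(hi), arr(ht)
        self.cov_i, self.cov_j, self.cov_t = arr(ci), arr(cj), arr(ct)
        self.kap_i, self.kap_t = arr(ki), arr(kt)
        self.psi_i, self.psi_t = arr(vi), arr(vt)
        self.rho_a, self.rho_b, self.rho_t = arr(ra), arr(rb), arr(rt)

        # free-slot mapping honoring fixed values and equality classes
        self.slot_of = np.full(self.N, -1, dtype=int)
        self.fixed_internal = np.zeros(self.N)
        self.free_mask = np.ones(self.N, dtype=bool)
        class_slot: dict = {}
        slot_count = 0
        slot_rep = []
        for idx, pr in enumerate(self.params):
            if pr.pid in model.fixed:
                self.free_mask[idx] = False
                self.fixed_internal[idx] = _to_internal(pr.kind, model.fixed[pr.pid])
                continue
            cls = model.equality_class_of(pr.pid)
            if cls is not None:
                if cls in class_slot:
                    self.slot_of[idx] = class_slot[cls]
                    continue
                class_slot[cls] = slot_count
            self.slot_of[idx] = slot_count
            slot_rep.append(idx)
            slot_count += 1
        self.n_slots = slot_count
        self.slot_rep = np.asarray(slot_rep, dtype=int)

    # -- vector plumbing ----------------------------------------------------

    def t_from_x(self, x: np.ndarray) -> np.ndarray:
        t = self.fixed_internal.copy()
        t[self.free_mask] = x[self.slot_of[self.free_mask]]
        return t

    def grad_to_slots(self, g_full: np.ndarray) -> np.ndarray:
        g = np.zeros(self.n_slots)
        np.add.at(g, self.slot_of[self.free_mask], g_full[self.free_mask])
        return g

    def x_from_estimates(self, estimates: Mapping[str, float],
                         default: np.ndarray | None = None) -> np.ndarray:
        x = default.copy() if default is not None else np.zeros(self.n_slots)
        acc = np.zeros(self.n_slots)
        cnt = np.zeros(self.n_slots)
        for idx, pr in enumerate(self.params):
            if not self.free_mask[idx] or pr.pid not in estimates:
                continue
            acc[self.slot_of[idx]] += _to_internal(pr.kind, estimates[pr.pid])
            cnt[self.slot_of[idx]] += 1
        got = cnt > 0
        x[got] = acc[got] / cnt[got]
        return x

    def estimates_from_t(self, t: np.ndarray) -> dict:
        return {pr.pid: _to_external(pr.kind, t[idx])
                for idx, pr in enumerate(self.params)}

    # -- model matrices -----------------------------------------------------

    def matrices(self, t: np.ndarray):
        p, k = self.p, self.k
        Lam = np.zeros((p, k))
        Lam[self.load_i, self.load_j] = t[self.load_t]
        tau = np.zeros(p)
        tau[self.tau_i] = t[self.tau_t]
        Theta = np.zeros((p, p))
        Theta[self.th_i, self.th_i] = np.exp(t[self.th_t])
        Theta[self.cov_i, self.cov_j] += t[self.cov_t]
        Theta[self.cov_j, self.cov_i] += t[self.cov_t]
        kappa = np.zeros(k)
        kappa[self.kap_i] = t[self.kap_t]
        sd = np.ones(k)
        sd[self.psi_i] = np.exp(t[self.psi_t])
        R = np.eye(k)
        rho = np.tanh(t[self.rho_t])
        R[self.rho_a, self.rho_b] = rho
        R[self.rho_b, self.rho_a] = rho
        Phi = R * np.outer(sd, sd)
        return Lam, tau, Theta, kappa, sd, R, Phi

    def implied(self, t: np.ndarray):
        Lam, tau, Theta, kappa, sd, R, Phi = self.matrices(t)
        Sigma = Lam @ Phi @ Lam.T + Theta
        mu = tau + Lam @ kappa
        return Sigma, mu

    # -- discrepancy and analytic gradient ----------------------------------

    def F_and_grad_full(self, t, S, m, logdet_S):
        """Discrepancy F and its gradient w.r.t. the full internal vector."""
        Lam, tau, Theta, kappa, sd, R, Phi = self.matrices(t)
        Sigma = Lam @ Phi @ Lam.T + Theta
        mu = tau + Lam @ kappa
        try:
            cf = sla.cho_factor(Sigma, lower=True, check_finite=False)
        except sla.LinAlgError:
            return _PENALTY, np.zeros(self.N)
        logdet = 2.0 * np.log(np.diag(cf[0])).sum()
        Siginv = sla.cho_solve(cf, np.eye(self.p), check_finite=False)
        d = m - mu
        v = Siginv @ d
        F = (logdet + float(np.sum(Siginv * S)) - logdet_S - self.p
             + float(d @ v))
        A = S + np.outer(d, d)
        B = Siginv - Siginv @ A @ Siginv

        g = np.zeros(self.N)
        if self.load_t.size:
            G_lam = 2.0 * (B @ Lam @ Phi) - 2.0 * np.outer(v, kappa)
            g[self.load_t] = G_lam[self.load_i, self.load_j]
        g[self.tau_t] = -2.0 * v[self.tau_i]
        # residual variances on log scale: chain by theta_ii
        g[self.th_t] = np.diag(B)[self.th_i] * np.exp(t[self.th_t])
        if self.cov_t.size:
            g[self.cov_t] = 2.0 * B[self.cov_i, self.cov_j]
        if self.k:
            C = Lam.T @ B @ Lam
            g[self.kap_t] = (-2.0 * (Lam.T @ v))[self.kap_i]
            if self.psi_t.size:
                g[self.psi_t] = (2.0 * (C * Phi).sum(axis=1))[self.psi_i]
            if self.rho_t.size:
                rho = np.tanh(t[self.rho_t])
                g[self.rho_t] = (2.0 * C[self.rho_a, self.rho_b]
                                 * sd[self.rho_a] * sd[self.rho_b]
                                 * (1.0 - rho * rho))
        return F, g

    def objective(self, S, m):
        sign, logdet_S = np.linalg.slogdet(S)
        if sign <= 0:
            raise NumericalError("sample covariance matrix is singular")

        def fun(x):
            F, g = self.F_and_grad_full(self.t_from_x(x), S, m, logdet_S)
            return F, self.grad_to_slots(g)

        return fun, logdet_S

    # -- Jacobian of (mu, vech(Sigma)) w.r.t. free slots --------------------

    def moment_jacobian(self, t: np.ndarray) -> np.ndarray:
        Lam, tau, Theta, kappa, sd, R, Phi = self.matrices(t)
        p = self.p
        tri_i, tri_j = np.tril_indices(p)
        nmom = p + len(tri_i)
        Delta = np.zeros((nmom, self.n_slots))
        PhiLamT = Phi @ Lam.T if self.k else np.zeros((0, p))
        for idx, pr in enumerate(self.params):
            if not self.free_mask[idx]:
                continue
            dmu = np.zeros(p)
            dSig = np.zeros((p, p))
            kind = pr.kind
            if kind == "loading":
                pos = np.where(self.load_t == idx)[0][0]
                i, j = self.load_i[pos], self.load_j[pos]
                row = PhiLamT[j]
                dSig[i, :] += row
                dSig[:, i] += row
                dmu[i] = kappa[j]
            elif kind == "intercept":
                pos = np.where(self.tau_t == idx)[0][0]
                dmu[self.tau_i[pos]] = 1.0
            elif kind == "resid_var":
                pos = np.where(self.th_t == idx)[0][0]
                i = self.th_i[pos]
                dSig[i, i] = np.exp(t[idx])
            elif kind == "resid_cov":
                pos = np.where(self.cov_t == idx)[0][0]
                i, j = self.cov_i[pos], self.cov_j[pos]
                dSig[i, j] = dSig[j, i] = 1.0
            elif kind == "factor_mean":
                pos = np.where(self.kap_t == idx)[0][0]
                dmu = Lam[:, self.kap_i[pos]].copy()
            elif kind == "factor_var":
                pos = np.where(self.psi_t == idx)[0][0]
                j = self.psi_i[pos]
                dPhi = np.zeros((self.k, self.k))
                dPhi[j, :] += Phi[j, :]
                dPhi[:, j] += Phi[:, j]
                dSig = Lam @ dPhi @ Lam.T
            elif kind == "factor_corr":
                pos = np.where(self.rho_t == idx)[0][0]
                a, b = self.rho_a[pos], self.rho_b[pos]
                rho = np.tanh(t[idx])
                dPhi = np.zeros((self.k, self.k))
                dPhi[a, b] = dPhi[b, a] = sd[a] * sd[b] * (1.0 - rho * rho)
                dSig = Lam @ dPhi @ Lam.T
            col = np.concatenate([dmu, dSig[tri_i, tri_j]])
            Delta[:, self.slot_of[idx]] += col
        return Delta


# ---------------------------------------------------------------------------
# fitted-model container and public operations


@dataclass
class FittedModel:
    """Estimation result: estimates, chi-square statistics, diagnostics."""

    model: ms.MeasurementModel
    moments: SampleMoments
    x: np.ndarray
    estimates: dict
    F: float
    T_ml: float
    df: int
    c: float = 1.0
    se: dict | None = None
    converged: bool = True
    gradient_norm: float = np.nan
    layout: ParamLayout | None = field(default=None, repr=False)

    @property
    def T_scaled(self) -> float:
        return self.T_ml / self.c

    @property
    def n(self) -> int:
        return self.moments.n


def implied_moments(model: ms.MeasurementModel, estimates: Mapping[str, float]):
    """Model-implied covariance matrix and mean vector at given estimates.

    ``estimates`` must cover every free parameter (external scale); fixed
    values are substituted automatically.
    """
    layout = ParamLayout(model)
    t = layout.fixed_internal.copy()
    for idx, pr in enumerate(layout.params):
        if layout.free_mask[idx]:
            if pr.pid not in estimates:
                raise ConfigurationError(f"no estimate for free parameter {pr.pid!r}")
            t[idx] = _to_internal(pr.kind, estimates[pr.pid])
    Sigma, mu = layout.implied(t)
    if not np.all(np.isfinite(mu)):
        raise NumericalError("implied means are not finite")
    return Sigma, mu


def ml_discrepancy(moments: SampleMoments, Sigma: np.ndarray, mu: np.ndarray):
    """Normal-theory discrepancy F and chi-square T = (n-1) F."""
    S, m, p = moments.S, moments.m, moments.p
    sign_s, logdet_S = np.linalg.slogdet(S)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        raise NumericalError("Sigma is singular or not positive definite")
    Siginv = np.linalg.inv(Sigma)
    d = m - mu
    F = float(logdet + np.sum(Siginv * S) - logdet_S - p + d @ Siginv @ d)
    return F, (moments.n - 1) * F


def _default_start(layout: ParamLayout, S: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Documented starting values: loadings = indicator SD, intercepts =
    indicator mean, residual variances = half the indicator variance,
    correlations = 0.3, factor means 0 / variances 1."""
    x = np.zeros(layout.n_slots)
    sd_obs = np.sqrt(np.clip(np.diag(S), 1e-8, None))
    for slot, idx in enumerate(layout.slot_rep):
        kind = layout.kinds[idx]
        if kind == "loading":
            pos = np.where(layout.load_t == idx)[0][0]
            x[slot] = sd_obs[layout.load_i[pos]]
        elif kind == "intercept":
            pos = np.where(layout.tau_t == idx)[0][0]
            x[slot] = m[layout.tau_i[pos]]
        elif kind == "resid_var":
            pos = np.where(layout.th_t == idx)[0][0]
            x[slot] = np.log(0.5 * sd_obs[layout.th_i[pos]] ** 2)
        elif kind == "factor_corr":
            x[slot] = np.arctanh(0.3)
        # resid_cov, factor_mean, factor_var (log-sd) start at 0
    return x


def _fd_hessian(fun_grad, x: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian columns from an analytic gradient."""
    q = x.size
    H = np.zeros((q, q))
    for j in range(q):
        h = step * max(1.0, abs(x[j]))
        xp = x.copy(); xp[j] += h
        xm = x.copy(); xm[j] -= h
        H[:, j] = (fun_grad(xp) - fun_grad(xm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit(model: ms.MeasurementModel, data_or_moments, estimator: str = "ML",
        start: Mapping[str, float] | None = None, gtol: float = 1e-8,
        compute_se: bool = True, maxiter: int = 5000) -> FittedModel:
    """Fit a measurement model to raw data or sample moments.

    ``estimator`` is ``"ML"`` or ``"MLR"``; MLR additionally computes the
    chi-square scaling factor, which requires raw data (or moments carrying
    a fourth-moment ``gamma``).  ``start`` optionally warm-starts the
    optimizer from a pid -> value mapping on the external scale.
    """
    if isinstance(data_or_moments, SampleMoments):
        moments = data_or_moments
        if estimator == "MLR" and moments.gamma is None:
            logger.info("MLR requested but no fourth-moment matrix available; "
                        "falling back to c = 1 (normal-theory chi-square)")
    elif isinstance(data_or_moments, pd.DataFrame):
        moments = SampleMoments.from_data(data_or_moments, model.indicators,
                                          compute_gamma=(estimator == "MLR"))
    else:
        raise ConfigurationError(
            "expected a pandas DataFrame or SampleMoments, got "
            f"{type(data_or_moments).__name__}")
    if moments.p != len(model.indicators):
        raise ConfigurationError(
            f"model has {len(model.indicators)} indicators but moments have "
            f"{moments.p} variables")

    layout = ParamLayout(model)
    df = ms.model_df(model)
    fun, _ = layout.objective(moments.S, moments.m)

    x0 = _default_start(layout, moments.S, moments.m)
    if start is not None:
        x0 = layout.x_from_estimates(start, default=x0)

    grad_only = lambda z: fun(z)[1]

    def _minimize_from(x):
        F, g = fun(x)
        gnorm = float(np.max(np.abs(g))) if g.size else 0.0
        for _round in range(3):
            if gnorm <= gtol:
                break
            if _round > 0 or gnorm > 1.0 or not np.isfinite(F) or F >= _PENALTY / 2:
                # far from an optimum: let L-BFGS close most of the distance
                res = optimize.minimize(fun, x, jac=True, method="L-BFGS-B",
                                        options={"maxiter": maxiter,
                                                 "ftol": 1e-11,
                                                 "gtol": 1e-5, "maxcor": 20})
                if res.fun <= F:
                    x, F = res.x, res.fun
                F, g = fun(x)
                gnorm = float(np.max(np.abs(g)))
            # Newton polish to drive the gradient to the tolerance
            for _ in range(40):
                if gnorm <= gtol:
                    break
                H = _fd_hessian(grad_only, x)
                try:
                    step_dir = np.linalg.solve(H + 1e-10 * np.eye(len(x)), g)
                except np.linalg.LinAlgError:
                    step_dir = g
                if float(g @ step_dir) <= 0:
                    step_dir = g  # indefinite Hessian: fall back to descent
                if 0.5 * float(g @ step_dir) < 1e-15:
                    break  # expected decrease below floating-point resolution
                alpha = 1.0
                improved = False
                for _ in range(30):
                    x_new = x - alpha * step_dir
                    F_new, g_new = fun(x_new)
                    if F_new <= F + 1e-14:
                        x, F, g = x_new, F_new, g_new
                        improved = True
                        break
                    alpha *= 0.5
                if not improved:
                    break
                gnorm = float(np.max(np.abs(g)))
        return x, F, g, gnorm

    if layout.n_slots:
        x, F, g, gnorm = _minimize_from(x0)
        if gnorm > max(gtol, 1e-5) and start is not None:
            # a poor warm start can strand the search in a curved valley;
            # retry cold and keep whichever solution is better
            x2, F2, g2, gnorm2 = _minimize_from(
                _default_start(layout, moments.S, moments.m))
            if F2 < F:
                x, F, g, gnorm = x2, F2, g2, gnorm2
    else:
        x = x0
        F, g = fun(x)
        gnorm = 0.0
    H = None

    # a gradient below 1e-5 changes the chi-square by far less than any
    # reported digit; treat it as converged even when gtol is tighter
    converged = bool(gnorm <= max(gtol, 1e-5) or layout.n_slots == 0)
    if F >= _PENALTY / 2:
        raise ConvergenceError("optimizer stranded in a non-positive-definite "
                               "region; check the model or starting values")
    t = layout.t_from_x(x)
    estimates = layout.estimates_from_t(t)
    T_ml = max(0.0, (moments.n - 1) * F)

    se = None
    if compute_se and layout.n_slots:
        if H is None:
            H = _fd_hessian(grad_only, x)
        try:
            cov = 2.0 / (moments.n - 1) * np.linalg.inv(H)
            diag = np.diag(cov)
            se = {}
            for idx, pr in enumerate(layout.params):
                if not layout.free_mask[idx]:
                    continue
                var = diag[layout.slot_of[idx]]
                if var <= 0:
                    se[pr.pid] = float("nan")
                else:
                    se[pr.pid] = float(np.sqrt(var)
                                       * abs(_dext_dint(pr.kind, estimates[pr.pid])))
        except np.linalg.LinAlgError:
            warnings.warn("information matrix singular; standard errors skipped")
            se = None

    fitted = FittedModel(model=model, moments=moments, x=x, estimates=estimates,
                         F=F, T_ml=T_ml, df=df, se=se, converged=converged,
                         gradient_norm=gnorm, layout=layout)
    if estimator == "MLR" and moments.gamma is not None and df > 0:
        fitted.c = mlr_scaling_factor(fitted, moments)
    return fitted


def mlr_scaling_factor(fitted: FittedModel, moments: SampleMoments) -> float:
    """Chi-square scaling factor c = tr(U gamma) / df.

    ``U = W - W Delta (Delta' W Delta)^-1 Delta' W`` is the residual weight
    of the normal-theory ML estimator at the solution and ``gamma`` the
    distribution-free covariance of the sample moments.  Under exact
    multivariate normality c -> 1.
    """
    if fitted.df == 0:
        raise ConfigurationError("scaling factor undefined for a saturated "
                                 "model (df = 0)")
    if moments.gamma is None:
        raise ConfigurationError("moments carry no fourth-moment matrix; "
                                 "provide raw data to estimate gamma")
    layout = fitted.layout or ParamLayout(fitted.model)
    t = layout.t_from_x(fitted.x)
    Sigma, _ = layout.implied(t)
    p = layout.p
    Siginv = np.linalg.inv(Sigma)
    D = duplication_matrix(p)
    W_cov = 0.5 * D.T @ np.kron(Siginv, Siginv) @ D
    nmom = p + p * (p + 1) // 2
    W = np.zeros((nmom, nmom))
    W[:p, :p] = Siginv
    W[p:, p:] = W_cov
    Delta = layout.moment_jacobian(t)
    WD = W @ Delta
    M = Delta.T @ WD
    U = W - WD @ np.linalg.solve(M, WD.T)
    c = float(np.sum(U * moments.gamma.T) / fitted.df)
    if c <= 0:
        warnings.warn(f"non-positive scaling factor c={c:.4g}; check gamma")
    return c


@dataclass
class DiffTest:
    """Result of a (possibly scaled) chi-square difference test."""

    TRd: float
    df: int
    p: float
    cd: float = 1.0
    warning: str | None = None


def sb_diff_test(fit_restricted: FittedModel, fit_free: FittedModel) -> DiffTest:
    """Satorra-Bentler scaled chi-square difference test.

    ``cd = (df0 c0 - df1 c1) / (df0 - df1)``; ``TRd = (T0 - T1) / cd`` with
    the plain ML statistics, referred to a chi-square with ``df0 - df1``
    degrees of freedom.  With c0 = c1 = 1 this reduces to the ordinary
    difference test.  A negative difference is reported with a warning and
    p = 1 (do-not-reject convention); a non-positive ``cd`` flags a
    strict-correction failure.
    """
    df0, df1 = fit_restricted.df, fit_free.df
    if df0 <= df1:
        raise ConfigurationError(
            f"restricted model must have more df than free model "
            f"({df0} vs {df1})")
    if not (fit_restricted.converged and fit_free.converged):
        raise ConvergenceError("difference test refused: a model did not converge")
    df_diff = df0 - df1
    cd = (df0 * fit_restricted.c - df1 * fit_free.c) / df_diff
    if cd <= 0:
        return DiffTest(TRd=float("nan"), df=df_diff, p=float("nan"), cd=cd,
                        warning="strict-correction failure: cd <= 0")
    TRd = (fit_restricted.T_ml - fit_free.T_ml) / cd
    if TRd < 0:
        return DiffTest(TRd=TRd, df=df_diff, p=1.0, cd=cd,
                        warning="negative scaled chi-square difference; "
                                "reported but not rejected")
    return DiffTest(TRd=TRd, df=df_diff, p=float(stats.chi2.sf(TRd, df_diff)),
                    cd=cd)


def modification_indices(fitted: FittedModel,
                         candidates: Sequence[str]) -> pd.DataFrame:
    """1-df score-test statistics for releasing constrained parameters.

    Each candidate is a parameter id that is currently (a) a member of an
    across-occasion equality class (release the class), (b) fixed (free
    it), or (c) an absent loading written as ``lambda[scale,factor,tocc]``
    (add the cross-loading: a factor-pattern change).  Returns a DataFrame
    with columns ``parameter``, ``mi``, ``epc`` (expected parameter change,
    external scale), sorted by decreasing index.
    """
    model = fitted.model
    known = set(model.parameter_ids())
    ext_model = model
    for pid in candidates:
        if pid not in known:
            if not pid.startswith("lambda["):
                raise ConfigurationError(f"unknown candidate parameter {pid!r}")
            body = pid[len("lambda["):-1]
            s, f, tocc = body.split(",")
            ext_model = ext_model.with_extra_loading(s, f, int(tocc[1:]),
                                                     fixed_at=0.0)
    layout = ParamLayout(ext_model)
    t = np.array([_to_internal(pr.kind,
                               fitted.estimates.get(pr.pid,
                                                    ext_model.fixed.get(pr.pid, 0.0)))
                  for pr in layout.params])
    S, m = fitted.moments.S, fitted.moments.m
    sign, logdet_S = np.linalg.slogdet(S)
    grad_full = lambda tt: layout.F_and_grad_full(tt, S, m, logdet_S)[1]
    G = grad_full(t)
    H = _fd_hessian(grad_full, t, step=1e-5)

    free_idx = np.where(layout.free_mask)[0]
    slots = layout.slot_of[free_idx]
    A = np.zeros((layout.N, layout.n_slots))
    A[free_idx, slots] = 1.0
    M = A.T @ H @ A
    n1 = fitted.moments.n - 1

    rows = []
    for pid in candidates:
        idx = layout.pid_index[pid]
        cls = ext_model.equality_class_of(pid)
        if cls is not None and len(cls) >= 2:
            # releasing an equality: use the lexically-last member's direction
            idx = layout.pid_index[sorted(cls)[-1]]
        elif layout.free_mask[idx]:
            # already free: the score vanishes at the optimum
            rows.append((pid, 0.0, 0.0))
            continue
        u = H[:, idx]
        Au = A.T @ u
        try:
            denom = float(H[idx, idx] - Au @ np.linalg.solve(M, Au))
        except np.linalg.LinAlgError:
            warnings.warn(f"singular information for candidate {pid!r}; skipped")
            continue
        if denom <= 1e-12:
            warnings.warn(f"non-positive information for candidate {pid!r}; skipped")
            continue
        g_d = float(G[idx])
        mi = 0.5 * n1 * g_d * g_d / denom
        epc_int = -g_d / denom
        pr = layout.params[idx]
        ext_val = _to_external(pr.kind, t[idx])
        epc = epc_int * _dext_dint(pr.kind, ext_val)
        rows.append((pid, mi, epc))
    out = pd.DataFrame(rows, columns=["parameter", "mi", "epc"])
    return out.sort_values("mi", ascending=False, ignore_index=True)
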