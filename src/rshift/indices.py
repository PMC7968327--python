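"""Model-fit indices and the acceptability gate.

CFI and TLI compare the target model to an independence baseline (free
means and variances, zero covariances); RMSEA measures misfit per degree
of freedom with a 90% confidence interval obtained by inverting the
noncentral chi-square distribution in its noncentrality parameter; SRMR is
the root-mean-square standardized covariance residual (means excluded, the
conventional covariance-based variant).

The acceptability gate applies the usual strict thresholds: CFI > 0.9,
TLI > 0.9, SRMR < 0.1 and RMSEA < 0.08.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .engine import FittedModel, ParamLayout, SampleMoments
from .errors import ConfigurationError


@dataclass
class FitIndices:
    chisq: float
    df: int
    cfi: float
    tli: float | None
    rmsea: float | None
    rmsea_ci90: tuple | None
    srmr: float
    scaled: bool = False


@dataclass
class GateResult:
    passed: bool
    reasons: list
    thresholds: dict


DEFAULT_THRESHOLDS = {"cfi": 0.9, "tli": 0.9, "srmr": 0.1, "rmsea": 0.08}


def _ncp_ci(T: float, df: int, level: float = 0.90):
    """90% CI for the noncentrality parameter of a chi-square statistic."""
    lo_q, hi_q = (1 + level) / 2, (1 - level) / 2  # 0.95, 0.05

    def solve(q):
        # lambda such that P(chi2_{df, lambda} > T) = 1 - q, i.e. cdf = q
        if stats.ncx2.cdf(T, df, 1e-10) <= q:
            return 0.0
        hi = max(T * 2, df + 10.0)
        while stats.ncx2.cdf(T, df, hi) > q:
            hi *= 2
            if hi > 1e8:
                return hi
        return float(optimize.brentq(lambda l: stats.ncx2.cdf(T, df, l) - q,
                                     1e-10, hi, xtol=1e-8))

    return solve(lo_q), solve(hi_q)


def cfi(T: float, df: int, Tb: float, dfb: int) -> float:
    """Comparative fit index: 1 - max(T-df,0)/max(Tb-dfb, T-df, 0)."""
    num = max(T - df, 0.0)
    den = max(Tb - dfb, T - df, 0.0)
    if den <= 0:
        return 1.0
    return min(max(1.0 - num / den, 0.0), 1.0)


def tli(T: float, df: int, Tb: float, dfb: int) -> float | None:
    """Tucker-Lewis (non-normed) index; None when undefined."""
    if df == 0 or dfb == 0 or Tb / dfb <= 1.0:
        return None
    return min(((Tb / dfb) - (T / df)) / ((Tb / dfb) - 1.0), 1.0)


def rmsea(T: float, df: int, n: int) -> float | None:
    """Root-mean-square error of approximation; None when df = 0."""
    if df == 0:
        return None
    return float(np.sqrt(max(T - df, 0.0) / (df * (n - 1))))


def srmr(fitted: FittedModel, moments: SampleMoments | None = None) -> float:
    """Root-mean-square standardized covariance residual."""
    moments = moments or fitted.moments
    layout = fitted.layout or ParamLayout(fitted.model)
    Sigma, _ = layout.implied(layout.t_from_x(fitted.x))
    S = moments.S
    d = np.sqrt(np.diag(S))
    resid = (S - Sigma) / np.outer(d, d)
    i, j = np.tril_indices(S.shape[0])
    return float(np.sqrt(np.mean(resid[i, j] ** 2)))


def compute_indices(fitted: FittedModel, baseline: FittedModel,
                    moments: SampleMoments | None = None,
                    statistic: str = "auto") -> FitIndices:
    """Fit indices for ``fitted`` against an independence ``baseline``.

    ``statistic`` selects the chi-square entering CFI/TLI/RMSEA:
    ``"ml"`` (plain), ``"scaled"`` (T/c), or ``"auto"`` (scaled whenever a
    scaling factor differing from 1 is present).
    """
    moments = moments or fitted.moments
    if baseline.df <= fitted.df:
        raise ConfigurationError("baseline must have more df than the target model")
    use_scaled = (statistic == "scaled"
                  or (statistic == "auto" and (fitted.c != 1.0 or baseline.c != 1.0)))
    T = fitted.T_scaled if use_scaled else fitted.T_ml
    Tb = baseline.T_scaled if use_scaled else baseline.T_ml
    df, dfb = fitted.df, baseline.df
    n1 = moments.n - 1

    if df > 0:
        lo, hi = _ncp_ci(T, df)
        ci = (float(np.sqrt(lo / (df * n1))), float(np.sqrt(hi / (df * n1))))
    else:
        ci = None

    t = tli(T, df, Tb, dfb)
    return FitIndices(chisq=float(T), df=df, cfi=float(cfi(T, df, Tb, dfb)),
                      tli=None if t is None else float(t),
                      rmsea=rmsea(T, df, moments.n), rmsea_ci90=ci,
                      srmr=srmr(fitted, moments), scaled=use_scaled)


def acceptability_gate(fi: FitIndices,
                       thresholds: dict | None = None) -> GateResult:
    """Strict-inequality acceptability check on the fit indices.

    Pass requires CFI > 0.9, TLI > 0.9, SRMR < 0.1 and RMSEA < 0.08
    (thresholds overridable); the failing criteria are listed by name.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    reasons = []
    if not fi.cfi > th["cfi"]:
        reasons.append("CFI")
    if fi.tli is not None and not fi.tli > th["tli"]:
        reasons.append("TLI")
    if not fi.srmr < th["srmr"]:
        reasons.append("SRMR")
    if fi.rmsea is not None and not fi.rmsea < th["rmsea"]:
        reasons.append("RMSEA")
    return GateResult(passed=not reasons, reasons=reasons, thresholds=th)
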