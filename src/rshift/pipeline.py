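"""The 4-step response-shift detection procedure.

Step 1 establishes the unconstrained longitudinal measurement model
(Model 1) and requires acceptable fit (CFI/TLI > 0.9, SRMR < 0.1,
RMSEA < 0.08) before anything else runs.  Step 2 constrains all
RS-related parameters (loadings, intercepts, residual variances) equal
across occasions (Model 2, the no-RS model) and tests the overall
existence of response shift with a (scaled) chi-square difference test.
Step 3 releases untenable invariance constraints one at a time, guided by
modification indices, at a Bonferroni-adjusted alpha (0.05 divided by the
number of scales by default); each retained release is classified by
parameter class: factor pattern -> reconceptualization, loading ->
reprioritization, intercept -> uniform recalibration, residual variance ->
non-uniform recalibration.  Step 4 tests invariance of the common-factor
correlations, variances and means on the resulting Model 3; tenable
constraints form Model 4, whose factor-mean differences are the
response-shift-adjusted ("true") change.

Effect sizes standardize Model-4 parameter differences by the occasion-1
model-implied indicator standard deviation, so for every scale the
observed standardized change decomposes additively into a response-shift
component and the adjusted change.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import model as ms
from .engine import (DiffTest, FittedModel, SampleMoments, fit,
                     modification_indices, sb_diff_test)
from .errors import ConfigurationError, PipelineHalt
from .indices import FitIndices, acceptability_gate, compute_indices

logger = logging.getLogger(__name__)

#: parameter class -> response-shift type
RS_TYPE_OF = {
    "pattern": "reconceptualization",
    "loading": "reprioritization",
    "intercept": "uniform recalibration",
    "residual_variance": "non-uniform recalibration",
}

COHEN_ANCHORS = ((0.8, "large"), (0.5, "medium"), (0.2, "small"))


def cohen_label(d: float) -> str:
    for cut, name in COHEN_ANCHORS:
        if abs(d) >= cut:
            return name
    return "negligible"


@dataclass
class RSFinding:
    """One retained constraint release: a detected response-shift effect."""

    parameter_class: str
    scale: str
    rs_type: str
    chisq_diff: float
    df: int
    p: float
    release_order: int
    parameter: str


@dataclass
class FactorMeanChange:
    factor: str
    estimate: float
    p: float
    effect_size: float
    label: str


@dataclass
class EffectSizeRow:
    scale: str
    rs_type: str | None
    observed_change: float
    rs_effect: float
    adjusted_change: float
    label: str


@dataclass
class ModelRecord:
    name: str
    fitted: FittedModel
    indices: FitIndices


@dataclass
class RSReport:
    """Machine-readable result of the full 4-step procedure."""

    models: dict = field(default_factory=dict)  # name -> ModelRecord
    overall_test: DiffTest | None = None
    overall_rs_present: bool | None = None
    findings: list = field(default_factory=list)
    factor_mean_changes: list = field(default_factory=list)
    retained_step4: list = field(default_factory=list)
    effect_table: list = field(default_factory=list)
    log: list = field(default_factory=list)
    halted: str | None = None
    config: dict = field(default_factory=dict)
    seed: int | None = None
    config_hash: str | None = None


# ---------------------------------------------------------------------------


def _as_moments(data_or_moments, model, estimator):
    if isinstance(data_or_moments, SampleMoments):
        return data_or_moments
    if isinstance(data_or_moments, pd.DataFrame):
        return SampleMoments.from_data(data_or_moments, model.indicators,
                                       compute_gamma=(estimator == "MLR"))
    raise ConfigurationError("expected a DataFrame or SampleMoments")


def _fit(model, moments, config, start=None):
    return fit(model, moments, estimator=config.get("estimator", "ML"),
               start=start, gtol=config.get("fit_tol", 1e-8))


def _indices(fitted, baseline_fit, config):
    return compute_indices(fitted, baseline_fit)


def _baseline(moments, config):
    base = ms.independence_model(ms.build_fig1_model(config.get("model_config")))
    return _fit(base, moments, config)


def step1(data, config: Mapping | None = None):
    """Fit Model 1 and apply the acceptability gate.

    Returns ``(fitted_model1, fit_indices, baseline_fit)``; raises
    :class:`PipelineHalt` when the gate fails (further steps would be
    meaningless on a misfitting measurement model) and
    :class:`ConfigurationError` when fewer complete cases than the
    configured minimum (default 100) are supplied.
    """
    config = dict(config or {})
    model1 = ms.build_fig1_model(config.get("model_config"))
    if isinstance(data, pd.DataFrame):
        if len(data) < config.get("min_n", 100):
            raise ConfigurationError(
                f"need at least {config.get('min_n', 100)} complete cases, "
                f"got {len(data)}")
    moments = _as_moments(data, model1, config.get("estimator", "ML"))
    fitted = _fit(model1, moments, config)
    basefit = _baseline(moments, config)
    fi = compute_indices(fitted, basefit)
    gate = acceptability_gate(fi, config.get("fit_thresholds"))
    if not gate.passed:
        raise PipelineHalt(
            f"Model 1 failed the fit gate on: {', '.join(gate.reasons)}",
            partial={"model1": fitted, "indices": fi})
    return fitted, fi, basefit


def step2(model1_fit: FittedModel, config: Mapping | None = None):
    """Form the no-RS model (Model 2) and test overall response shift."""
    config = dict(config or {})
    model2 = ms.apply_invariance(model1_fit.model)
    if ms.model_df(model2) == ms.model_df(model1_fit.model):
        raise ConfigurationError("no invariance constraints were added; "
                                 "nothing to test")
    fitted2 = _fit(model2, model1_fit.moments, config,
                   start=model1_fit.estimates)
    overall = sb_diff_test(fitted2, model1_fit)
    return fitted2, overall


def _release_candidates(model: ms.MeasurementModel):
    """RS-related equality classes, keyed by their occasion-2 member pid."""
    out = []
    for cls in model.equalities:
        pids = sorted(cls)
        kinds = {pid.split("[")[0] for pid in pids}
        if kinds & {"lambda", "tau", "theta"}:
            kind = kinds.pop()
            if kind == "lambda":
                pclass = "loading"
                scale = pids[0][len("lambda["):].split(",")[0]
            elif kind == "tau":
                pclass = "intercept"
                scale = pids[0][len("tau["):].split(",")[0]
            else:
                pclass = "residual_variance"
                scale = pids[0][len("theta["):].split(",")[0]
            out.append((pids[-1], pclass, scale))
    return out


def _pattern_candidates(model: ms.MeasurementModel):
    """Occasion-2 cross-loadings absent from the pattern."""
    existing = set(model.loading_entries())
    out = []
    for s in model.scales:
        for f in model.structure:
            if (s, f, 2) not in existing:
                out.append((ms.lam_id(s, f, 2), "pattern", s))
    return out


def step3(model2_fit: FittedModel, alpha: float | None = None,
          config: Mapping | None = None):
    """Backward release of untenable RS-related invariance constraints.

    At each iteration the largest-modification-index candidate is released
    and the release is kept only if the (scaled) 1-df difference test beats
    the Bonferroni-adjusted ``alpha`` (default 0.05 / number of scales);
    otherwise the release is reverted and the phase stops.  Equality
    releases (loadings, intercepts, residual variances) are exhausted
    first; occasion-2 cross-loading additions (reconceptualization
    candidates) are then tested the same way.  A reverted candidate is
    never retried.
    """
    config = dict(config or {})
    if alpha is None:
        nscales = len(model2_fit.model.scales)
        alpha = config.get("alpha_overall", 0.05) / \
            config.get("bonferroni_denominator", nscales)
    findings: list = []
    tried: set = set()
    current = model2_fit
    order = 1
    for phase in ("release", "pattern"):
        while True:
            if phase == "release":
                cands = [(pid, pc, s) for pid, pc, s in
                         _release_candidates(current.model) if pid not in tried]
            else:
                cands = [(pid, pc, s) for pid, pc, s in
                         _pattern_candidates(current.model) if pid not in tried]
            if not cands:
                break
            info = {pid: (pc, s) for pid, pc, s in cands}
            mi = modification_indices(current, [pid for pid, _, _ in cands])
            if mi.empty:
                break
            top = mi.iloc[0]["parameter"]
            pclass, scale = info[top]
            start = dict(current.estimates)
            if pclass == "pattern":
                body = top[len("lambda["):-1]
                s, f, tocc = body.split(",")
                new_model = current.model.with_extra_loading(s, f, int(tocc[1:]))
                start[top] = 0.0  # the candidate loading enters at zero
            else:
                new_model = ms.release_constraint(current.model, top)
            new_fit = _fit(new_model, current.moments, config, start=start)
            dt = sb_diff_test(current, new_fit)
            tried.add(top)
            if np.isfinite(dt.p) and dt.p < alpha:
                findings.append(RSFinding(
                    parameter_class=pclass, scale=scale,
                    rs_type=RS_TYPE_OF[pclass], chisq_diff=float(dt.TRd),
                    df=dt.df, p=float(dt.p), release_order=order,
                    parameter=top))
                logger.info("step 3: released %s (%s, p=%.4g)", top,
                            RS_TYPE_OF[pclass], dt.p)
                current = new_fit
                order += 1
            else:
                logger.info("step 3: top candidate %s not significant "
                            "(p=%.4g >= %.4g); phase stops", top, dt.p, alpha)
                break
    return current, findings


def step4(model3_fit: FittedModel, config: Mapping | None = None):
    """Test factor-level invariance and assess the adjusted change.

    Correlation invariance is tested first (one within-occasion equality),
    then variance invariance jointly over the factors, then mean invariance
    per factor (whose tests double as the significance tests of adjusted
    change), each at the unadjusted step-4 alpha (default 0.05).  Tenable
    constraints accumulate into Model 4.  The factor-mean entries report the across-occasion change in
    each common factor after all response shift is accounted for, with the
    p-value of its invariance test and the change standardized by the
    occasion-1 factor SD.
    """
    config = dict(config or {})
    alpha = config.get("alpha_step4", 0.05)
    current = model3_fit
    retained = []
    mean_tests = {}
    tests = [("factor_correlations", None), ("factor_variances", None)]
    tests += [("factor_means", f) for f in model3_fit.model.factor_bases]
    for cls, fac in tests:
        try:
            cand = ms.constrain_factor_structure(
                current.model, {cls}, factors=None if fac is None else [fac])
        except Exception as exc:  # already tied (e.g. nothing to constrain)
            logger.info("step 4: skipping %s/%s (%s)", cls, fac, exc)
            continue
        cfit = _fit(cand, current.moments, config, start=current.estimates)
        dt = sb_diff_test(cfit, current)
        if cls == "factor_means":
            mean_tests[fac] = dt
        if np.isfinite(dt.p) and dt.p >= alpha:
            retained.append((cls, fac, dt))
            current = cfit
            logger.info("step 4: retained %s (%s), p=%.4g", cls, fac, dt.p)
        else:
            logger.info("step 4: rejected %s (%s), p=%.4g", cls, fac, dt.p)

    changes = []
    for f in model3_fit.model.factor_bases:
        k1 = current.model.fixed.get(ms.kappa_id(f, 1),
                                     current.estimates.get(ms.kappa_id(f, 1), 0.0))
        k2 = current.model.fixed.get(ms.kappa_id(f, 2),
                                     current.estimates.get(ms.kappa_id(f, 2)))
        psi1 = current.model.fixed.get(ms.psi_id(f, 1),
                                       current.estimates.get(ms.psi_id(f, 1), 1.0))
        delta = float(k2 - k1)
        es = delta / float(np.sqrt(psi1))
        dt = mean_tests.get(f)
        changes.append(FactorMeanChange(
            factor=f, estimate=delta,
            p=float(dt.p) if dt is not None else float("nan"),
            effect_size=es, label=cohen_label(es)))
    return current, changes, retained


def effect_size_table(model4_fit: FittedModel, findings=(),
                      config: Mapping | None = None):
    """Standardized decomposition: observed change = RS effect + adjusted change.

    For scale j with loading lambda_j on factor f:
    ``adjusted = lambda_j(t1) * d_kappa_f / SD_j`` and ``rs = (d_tau_j +
    d_lambda_j * kappa_f(t2)) / SD_j`` (zero when the intercept and loading
    are invariant; residual-variance changes have zero group-level mean
    effect).  ``SD_j`` is by default the occasion-1 model-implied indicator
    SD; ``sd_convention`` may also be ``"pooled"`` (average of the two
    occasions' implied variances) or ``"observed_t1"`` (sample SD).
    """
    config = dict(config or {})
    conv = config.get("sd_convention", "model_implied_t1")
    m = model4_fit.model
    est = dict(m.fixed)
    est.update(model4_fit.estimates)
    rs_type_of_scale = {f.scale: f.rs_type for f in findings}
    rows = []
    for i, s in enumerate(m.scales):
        f = m.factor_of(s)
        lam1 = est[ms.lam_id(s, f, 1)]
        lam2 = est[ms.lam_id(s, f, 2)]
        psi1 = est[ms.psi_id(f, 1)]
        psi2 = est[ms.psi_id(f, 2)]
        th1 = est[ms.theta_id(s, 1)]
        th2 = est[ms.theta_id(s, 2)]
        dkappa = est[ms.kappa_id(f, 2)] - est[ms.kappa_id(f, 1)]
        dtau = est[ms.tau_id(s, 2)] - est[ms.tau_id(s, 1)]
        if conv == "model_implied_t1":
            sd = np.sqrt(lam1 ** 2 * psi1 + th1)
        elif conv == "pooled":
            sd = np.sqrt(0.5 * (lam1 ** 2 * psi1 + th1 + lam2 ** 2 * psi2 + th2))
        elif conv == "observed_t1":
            j = m.indicators.index(ms.obs_name(s, 1))
            sd = np.sqrt(model4_fit.moments.S[j, j])
        else:
            raise ConfigurationError(f"unknown sd_convention {conv!r}")
        adjusted = lam1 * dkappa / sd
        rs = (dtau + (lam2 - lam1) * est[ms.kappa_id(f, 2)]) / sd
        observed = rs + adjusted
        rows.append(EffectSizeRow(
            scale=s, rs_type=rs_type_of_scale.get(s),
            observed_change=float(observed), rs_effect=float(rs),
            adjusted_change=float(adjusted), label=cohen_label(observed)))
    return rows


def run(data, config: Mapping | None = None, seed: int | None = None) -> RSReport:
    """Run the full 4-step procedure and return an :class:`RSReport`.

    A halted step (e.g. the step-1 fit gate) yields a partial report with
    the halt reason instead of raising.
    """
    config = dict(config or {})
    report = RSReport(config=config, seed=seed)
    report.config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
    if isinstance(data, pd.DataFrame) and data.empty:
        raise ConfigurationError("empty dataset")
    try:
        fit1, fi1, basefit = step1(data, config)
        report.models["model1"] = ModelRecord("model1", fit1, fi1)
        report.log.append(f"step 1: Model 1 df={fit1.df}, chisq={fit1.T_scaled:.2f}, "
                          "fit gate passed")
        fit2, overall = step2(fit1, config)
        report.models["model2"] = ModelRecord(
            "model2", fit2, compute_indices(fit2, basefit))
        report.overall_test = overall
        report.overall_rs_present = bool(overall.p < config.get("alpha_overall", 0.05))
        report.log.append(
            f"step 2: overall RS test chisq({overall.df})={overall.TRd:.2f}, "
            f"p={overall.p:.4g} -> RS {'present' if report.overall_rs_present else 'absent'}")
        fit3, findings = step3(fit2, config=config)
        report.findings = findings
        report.models["model3"] = ModelRecord(
            "model3", fit3, compute_indices(fit3, basefit))
        report.log.append(f"step 3: {len(findings)} release(s) retained")
        fit4, changes, retained = step4(fit3, config)
        report.models["model4"] = ModelRecord(
            "model4", fit4, compute_indices(fit4, basefit))
        report.factor_mean_changes = changes
        report.retained_step4 = [(cls, fac) for cls, fac, _ in retained]
        report.effect_table = effect_size_table(fit4, findings, config)
        report.log.append(
            "step 4: retained " + (", ".join(
                f"{cls}[{fac}]" if fac else cls
                for cls, fac in report.retained_step4) or "nothing"))
    except PipelineHalt as halt:
        report.halted = halt.reason
        report.log.append(f"halted: {halt.reason}")
        if halt.partial and "model1" in halt.partial:
            report.models["model1"] = ModelRecord(
                "model1", halt.partial["model1"], halt.partial.get("indices"))
    return report
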