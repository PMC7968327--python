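"""Dataset ingestion, analysis configuration, and report serialization.

The data contract is a wide CSV with a header row and one row per
respondent: 16 numeric columns named ``<SCALE>_t<occasion>`` for the eight
SF-36 scales (PF, RP, BP, RE, GH, SF, VT, MH) at two occasions, each
scored 0-100.  Incomplete rows are dropped (complete-case analysis) with
the exclusion tally logged; out-of-range values are retained with a
warning.

Reports serialize to JSON losslessly and render to Markdown tables
mirroring the goodness-of-fit / parameter-estimate / effect-size layout of
a standard response-shift analysis write-up.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import model as ms
from .errors import SchemaError
from .pipeline import (EffectSizeRow, FactorMeanChange, RSFinding, RSReport)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Analysis options with the published defaults.

    ``alpha_overall`` governs the step-2 overall test (0.05);
    ``bonferroni_denominator`` divides it for step-3 release tests (8, the
    number of scales, giving 0.05/8 = 0.00625); step-4 factor-level tests
    use the unadjusted ``alpha_step4``.
    """

    model_config: dict = field(default_factory=ms.default_config)
    alpha_overall: float = 0.05
    bonferroni_denominator: int = 8
    alpha_step4: float = 0.05
    sd_convention: str = "model_implied_t1"
    estimator: str = "ML"
    min_n: int = 100
    fit_tol: float = 1e-8
    fit_thresholds: dict | None = None
    seed: int | None = None

    def __post_init__(self):
        if not 0 < self.alpha_overall < 1 or not 0 < self.alpha_step4 < 1:
            raise SchemaError("alpha values must lie in (0, 1)")
        if self.bonferroni_denominator < 1:
            raise SchemaError("bonferroni_denominator must be >= 1")
        if self.estimator not in ("ML", "MLR"):
            raise SchemaError("estimator must be 'ML' or 'MLR'")

    @property
    def alpha_release(self) -> float:
        return self.alpha_overall / self.bonferroni_denominator

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def read_config(path) -> AnalysisConfig:
    """Load an analysis configuration from YAML or JSON."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise SchemaError(f"cannot read config {path}: {exc}") from exc
    try:
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise SchemaError(f"malformed config {path}: {exc}") from exc
    return AnalysisConfig.from_dict(data or {})


def write_config(config: AnalysisConfig, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def expected_columns(scales=ms.DEFAULT_SCALES, occasions: int = 2) -> list:
    return [ms.obs_name(s, o) for o in range(1, occasions + 1) for s in scales]


def read_dataset(path, scales=ms.DEFAULT_SCALES, occasions: int = 2,
                 lo: float = 0.0, hi: float = 100.0):
    """Read a wide two-occasion CSV; returns ``(complete_cases, n_excluded)``.

    Raises :class:`SchemaError` naming any missing column or the first
    non-numeric cell; values outside the score range are retained with a
    warning (the linear 0-100 transform admits only that range, but
    simulated data may exceed it).
    """
    cols = expected_columns(scales, occasions)
    try:
        raw = pd.read_csv(path)
    except OSError as exc:
        raise SchemaError(f"cannot read dataset {path}: {exc}") from exc
    missing = [c for c in cols if c not in raw.columns]
    if missing:
        raise SchemaError(f"dataset lacks required column(s): {missing}")
    raw = raw.loc[:, cols]
    for col in cols:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"non-numeric value {raw.loc[row, col]!r} in column {col!r}, "
                f"row {row}")
        raw[col] = coerced
    complete = raw.dropna()
    n_excluded = len(raw) - len(complete)
    if n_excluded:
        logger.info("excluded %d incomplete row(s); %d complete cases retained",
                    n_excluded, len(complete))
    out_of_range = ((complete < lo) | (complete > hi)).to_numpy().sum()
    if out_of_range:
        warnings.warn(f"{out_of_range} value(s) outside [{lo}, {hi}] retained")
    return complete.reset_index(drop=True), n_excluded


# ---------------------------------------------------------------------------
# report serialization


def _round_alpha(alpha: float) -> float:
    """Display convention for the Bonferroni-adjusted critical value."""
    return float(f"{alpha:.3f}")


def _fitted_to_dict(fitted) -> dict:
    return {
        "df": fitted.df,
        "T_ml": fitted.T_ml,
        "T_scaled": fitted.T_scaled,
        "c": fitted.c,
        "n": fitted.n,
        "converged": fitted.converged,
        "gradient_norm": fitted.gradient_norm,
        "estimates": dict(sorted(fitted.estimates.items())),
        "se": None if fitted.se is None else dict(sorted(fitted.se.items())),
        "model": ms.to_config(fitted.model),
    }


def report_to_dict(report: RSReport) -> dict:
    out = {
        "config": report.config,
        "config_hash": report.config_hash,
        "seed": report.seed,
        "halted": report.halted,
        "log": list(report.log),
        "models": {},
        "overall_test": None,
        "overall_rs_present": report.overall_rs_present,
        "findings": [dataclasses.asdict(f) for f in report.findings],
        "factor_mean_changes": [dataclasses.asdict(c)
                                for c in report.factor_mean_changes],
        "retained_step4": [list(r) for r in report.retained_step4],
        "effect_table": [dataclasses.asdict(r) for r in report.effect_table],
    }
    for name, rec in report.models.items():
        entry = {"fitted": _fitted_to_dict(rec.fitted)}
        if rec.indices is not None:
            entry["indices"] = dataclasses.asdict(rec.indices)
            entry["indices"]["rmsea_ci90"] = (
                None if rec.indices.rmsea_ci90 is None
                else list(rec.indices.rmsea_ci90))
        out["models"][name] = entry
    if report.overall_test is not None:
        out["overall_test"] = dataclasses.asdict(report.overall_test)
    return out


def write_report(report: RSReport, path) -> None:
    """Serialize a report to JSON (sorted keys, full float precision)."""
    path = Path(path)
    try:
        path.write_text(json.dumps(report_to_dict(report), indent=2,
                                   sort_keys=True, default=str) + "\n")
    except OSError as exc:
        raise SchemaError(f"cannot write report to {path}: {exc}") from exc


def read_report(path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise SchemaError(f"cannot read report {path}: {exc}") from exc


def report_markdown(report: RSReport) -> str:
    """Human-readable Markdown rendering of an RSReport."""
    lines = ["# Response-shift detection report", ""]
    if report.halted:
        lines += [f"**Pipeline halted:** {report.halted}", ""]
    if report.models:
        lines += ["## Goodness of fit", "",
                  "| Model | df | chisq | CFI | TLI | RMSEA (90% CI) | SRMR |",
                  "|---|---|---|---|---|---|---|"]
        for name in ("model1", "model2", "model3", "model4"):
            rec = report.models.get(name)
            if rec is None or rec.indices is None:
                continue
            fi = rec.indices
            ci = ("" if fi.rmsea_ci90 is None
                  else f" ({fi.rmsea_ci90[0]:.3f}, {fi.rmsea_ci90[1]:.3f})")
            lines.append(
                f"| {name} | {fi.df} | {fi.chisq:.1f} | {fi.cfi:.3f} | "
                f"{'' if fi.tli is None else format(fi.tli, '.3f')} | "
                f"{'' if fi.rmsea is None else format(fi.rmsea, '.3f')}{ci} | "
                f"{fi.srmr:.3f} |")
        lines.append("")
    if report.overall_test is not None:
        ot = report.overall_test
        lines += [f"**Overall RS test:** chisq({ot.df}) = {ot.TRd:.2f}, "
                  f"p = {ot.p:.4g} -> response shift "
                  f"{'present' if report.overall_rs_present else 'absent'}", ""]
    if report.findings:
        lines += ["## Detected response shifts", "",
                  "| Scale | Type | chisq(1) | p | order |", "|---|---|---|---|---|"]
        for f in report.findings:
            lines.append(f"| {f.scale} | {f.rs_type} | {f.chisq_diff:.2f} | "
                         f"{f.p:.4g} | {f.release_order} |")
        lines.append("")
    if report.factor_mean_changes:
        lines += ["## Adjusted change in common factors", "",
                  "| Factor | change | p | effect size | label |",
                  "|---|---|---|---|---|"]
        for c in report.factor_mean_changes:
            lines.append(f"| {c.factor} | {c.estimate:+.3f} | {c.p:.4g} | "
                         f"{c.effect_size:+.2f} | {c.label} |")
        lines.append("")
    if report.effect_table:
        lines += ["## Effect-size decomposition", "",
                  "| Scale | RS type | Observed | RS | Adjusted |",
                  "|---|---|---|---|---|"]
        for r in report.effect_table:
            lines.append(f"| {r.scale} | {r.rs_type or ''} | "
                         f"{r.observed_change:+.2f} | {r.rs_effect:+.2f} | "
                         f"{r.adjusted_change:+.2f} |")
        lines.append("")
    if report.log:
        lines += ["## Decision log", ""] + [f"- {entry}" for entry in report.log]
        lines.append("")
    return "\n".join(lines)
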