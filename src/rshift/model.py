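"""Symbolic two-occasion longitudinal factor models.

A :class:`MeasurementModel` describes a confirmatory factor model for
repeated administrations of a multi-scale questionnaire: which observed
scales load on which latent factors at each occasion, which parameters are
fixed for identification, and which parameter pairs are constrained equal
across occasions.  The default structure is the two-factor SF-36 model used
in response-shift detection: a general-physical-health factor (GenPHYS:
PF, RP, BP, RE) and a general-mental-health factor (GenMENT: GH, SF, VT,
MH), measured at baseline (t1) and follow-up (t2).

Parameters are addressed by stable string identifiers, e.g.
``lambda[SF,GenMENT,t1]`` (loading), ``tau[SF,t2]`` (intercept),
``theta[RP,t2]`` (residual variance), ``theta_cov[RP_t1,RP_t2]`` (residual
covariance), ``kappa[GenPHYS,t2]`` (factor mean), ``psi[GenMENT,t2]``
(factor variance) and ``rho[GenPHYS_t1,GenMENT_t1]`` (factor correlation).
The factor covariance matrix is parameterized as standard deviations plus
correlations, so equating correlations across occasions is a plain linear
parameter equality even when the factor variances differ.

Degrees of freedom follow the usual mean-and-covariance-structure
arithmetic: ``df = p(p+3)/2 - (number of free parameters)``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, ConstraintError, IdentificationError

DEFAULT_SCALES = ("PF", "RP", "BP", "RE", "GH", "SF", "VT", "MH")

#: Two-factor structure for the eight SF-36 scale scores.
FIG_STRUCTURE = {
    "GenPHYS": ("PF", "RP", "BP", "RE"),
    "GenMENT": ("GH", "SF", "VT", "MH"),
}

RS_CLASSES = ("loadings", "intercepts", "residual_variances")
FACTOR_CLASSES = ("factor_means", "factor_variances", "factor_correlations")


# ---------------------------------------------------------------------------
# parameter identifiers

def obs_name(scale: str, occ: int) -> str:
    return f"{scale}_t{occ}"


def factor_name(factor: str, occ: int) -> str:
    return f"{factor}_t{occ}"


def lam_id(scale: str, factor: str, occ: int) -> str:
    return f"lambda[{scale},{factor},t{occ}]"


def tau_id(scale: str, occ: int) -> str:
    return f"tau[{scale},t{occ}]"


def theta_id(scale: str, occ: int) -> str:
    return f"theta[{scale},t{occ}]"


def theta_cov_id(var1: str, var2: str) -> str:
    a, b = sorted((var1, var2))
    return f"theta_cov[{a},{b}]"


def kappa_id(factor: str, occ: int) -> str:
    return f"kappa[{factor},t{occ}]"


def psi_id(factor: str, occ: int) -> str:
    return f"psi[{factor},t{occ}]"


def rho_id(fo1: str, fo2: str) -> str:
    a, b = sorted((fo1, fo2))
    return f"rho[{a},{b}]"


@dataclass(frozen=True)
class ParamRef:
    """A parameter identifier with its structural role resolved."""

    pid: str
    kind: str  # loading | intercept | resid_var | resid_cov | factor_mean | factor_var | factor_corr
    meta: tuple = ()


# ---------------------------------------------------------------------------


@dataclass
class MeasurementModel:
    """Symbolic longitudinal factor model with constraint bookkeeping.

    ``structure`` maps each factor to the scales loading on it (identical
    pattern at every occasion); ``extra_loadings`` holds occasion-specific
    pattern additions, i.e. reconceptualization releases.
    """

    scales: tuple
    structure: dict
    n_occasions: int = 2
    extra_loadings: tuple = ()  # (scale, factor, occ)
    residual_cov_pairs: tuple = ()  # ((scale, occ), (scale, occ))
    fixed: dict = field(default_factory=dict)  # pid -> value
    equalities: tuple = ()  # tuple of frozensets of pids

    # -- structural views ---------------------------------------------------

    @property
    def indicators(self) -> list:
        return [obs_name(s, o) for o in range(1, self.n_occasions + 1)
                for s in self.scales]

    @property
    def factors(self) -> list:
        return [factor_name(f, o) for o in range(1, self.n_occasions + 1)
                for f in self.structure]

    @property
    def factor_bases(self) -> tuple:
        return tuple(self.structure)

    def loading_entries(self) -> list:
        """Ordered (scale, factor, occ) triples for every loading that exists."""
        out = []
        for occ in range(1, self.n_occasions + 1):
            for fac, members in self.structure.items():
                for s in members:
                    out.append((s, fac, occ))
        out.extend(self.extra_loadings)
        return out

    def factor_of(self, scale: str) -> str:
        for fac, members in self.structure.items():
            if scale in members:
                return fac
        raise ConfigurationError(f"scale {scale!r} loads on no factor")

    # -- parameter enumeration ---------------------------------------------

    def parameters(self) -> list:
        """Every model parameter (free, fixed, or constrained), in canonical order."""
        out = []
        for (s, f, occ) in self.loading_entries():
            out.append(ParamRef(lam_id(s, f, occ), "loading", (s, f, occ)))
        for occ in range(1, self.n_occasions + 1):
            for s in self.scales:
                out.append(ParamRef(tau_id(s, occ), "intercept", (s, occ)))
        for occ in range(1, self.n_occasions + 1):
            for s in self.scales:
                out.append(ParamRef(theta_id(s, occ), "resid_var", (s, occ)))
        for (s1, o1), (s2, o2) in self.residual_cov_pairs:
            v1, v2 = obs_name(s1, o1), obs_name(s2, o2)
            out.append(ParamRef(theta_cov_id(v1, v2), "resid_cov",
                                ((s1, o1), (s2, o2))))
        for occ in range(1, self.n_occasions + 1):
            for f in self.structure:
                out.append(ParamRef(kappa_id(f, occ), "factor_mean", (f, occ)))
        for occ in range(1, self.n_occasions + 1):
            for f in self.structure:
                out.append(ParamRef(psi_id(f, occ), "factor_var", (f, occ)))
        facs = self.factors
        for i in range(len(facs)):
            for j in range(i + 1, len(facs)):
                out.append(ParamRef(rho_id(facs[i], facs[j]), "factor_corr",
                                    (facs[i], facs[j])))
        return out

    def parameter_ids(self) -> list:
        return [p.pid for p in self.parameters()]

    def n_parameters(self) -> int:
        return len(self.parameters())

    def n_free(self) -> int:
        n = self.n_parameters() - len(self.fixed)
        for cls in self.equalities:
            n -= len(cls) - 1
        return n

    # -- constraint algebra -------------------------------------------------

    def _clone(self) -> "MeasurementModel":
        return copy.deepcopy(self)

    def equality_class_of(self, pid: str):
        for cls in self.equalities:
            if pid in cls:
                return cls
        return None

    def with_equality(self, pids: Iterable[str]) -> "MeasurementModel":
        """Return a copy with the given parameters placed in one equality class."""
        pids = tuple(pids)
        known = set(self.parameter_ids())
        for pid in pids:
            if pid not in known:
                raise ConstraintError(f"unknown parameter {pid!r}")
            if pid in self.fixed:
                raise ConstraintError(f"parameter {pid!r} is fixed; cannot equate")
            if self.equality_class_of(pid) is not None:
                raise ConstraintError(f"parameter {pid!r} is already constrained")
        if len(pids) < 2:
            raise ConstraintError("an equality class needs at least two members")
        m = self._clone()
        m.equalities = self.equalities + (frozenset(pids),)
        return m

    def with_fixed(self, pid: str, value: float) -> "MeasurementModel":
        if pid not in set(self.parameter_ids()):
            raise ConstraintError(f"unknown parameter {pid!r}")
        if pid in self.fixed:
            raise ConstraintError(f"parameter {pid!r} is already fixed")
        if self.equality_class_of(pid) is not None:
            raise ConstraintError(f"parameter {pid!r} is in an equality class")
        m = self._clone()
        m.fixed = dict(self.fixed)
        m.fixed[pid] = float(value)
        return m

    def with_freed(self, pid: str) -> "MeasurementModel":
        if pid not in self.fixed:
            raise ConstraintError(f"parameter {pid!r} is not fixed")
        m = self._clone()
        m.fixed = {k: v for k, v in self.fixed.items() if k != pid}
        return m

    def with_extra_loading(self, scale: str, factor: str, occ: int,
                           fixed_at: float | None = None) -> "MeasurementModel":
        if (scale, factor, occ) in set(self.loading_entries()):
            raise ConstraintError(
                f"loading of {scale} on {factor} at t{occ} already exists")
        m = self._clone()
        m.extra_loadings = self.extra_loadings + ((scale, factor, occ),)
        if fixed_at is not None:
            m.fixed = dict(m.fixed)
            m.fixed[lam_id(scale, factor, occ)] = float(fixed_at)
        return m


# ---------------------------------------------------------------------------
# module-level operations


def moment_count(model: MeasurementModel) -> int:
    """Number of distinct sample moments: p(p+3)/2 covariances-plus-means."""
    p = len(model.indicators)
    return p * (p + 3) // 2


def model_df(model: MeasurementModel) -> int:
    df = moment_count(model) - model.n_free()
    if df < 0:
        raise IdentificationError(
            f"model has negative degrees of freedom ({df}); "
            "more free parameters than sample moments")
    return df


def build_model(config: Mapping) -> MeasurementModel:
    """Build an unconstrained measurement model from a structure description.

    ``config`` requires keys ``scales`` (list of scale names) and
    ``factors`` (mapping factor name -> scales); optional keys ``occasions``
    (1 or 2, default 2), ``residual_covariances`` (list of
    [[scale, occ], [scale, occ]] pairs; the string ``"auto"`` declares the
    canonical set: each scale with itself across occasions), and
    ``within_occasion_residual_covariances`` (list of [scale, scale] pairs
    correlated at every occasion).

    Factor means are fixed at 0 and factor variances at 1 at *every*
    occasion (the occasion-2 identification transfer happens when loadings
    and intercepts are constrained invariant, see :func:`apply_invariance`).
    """
    try:
        scales = tuple(config["scales"])
        structure = {f: tuple(m) for f, m in dict(config["factors"]).items()}
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"config missing required section: {exc}") from exc
    n_occ = int(config.get("occasions", 2))
    if n_occ not in (1, 2):
        raise ConfigurationError(f"occasions must be 1 or 2, got {n_occ}")
    seen: dict = {}
    for fac, members in structure.items():
        for s in members:
            if s not in scales:
                raise ConfigurationError(f"unknown indicator {s!r} in factor {fac!r}")
            if s in seen:
                raise ConfigurationError(
                    f"indicator {s!r} assigned to both {seen[s]!r} and {fac!r}")
            seen[s] = fac
    missing = [s for s in scales if s not in seen]
    if missing:
        raise ConfigurationError(f"indicators assigned to no factor: {missing}")

    rc = config.get("residual_covariances", "auto")
    pairs: list = []
    if rc == "auto":
        if n_occ == 2:
            pairs = [((s, 1), (s, 2)) for s in scales]
    else:
        pairs = [((p[0][0], int(p[0][1])), (p[1][0], int(p[1][1]))) for p in rc]
    for a, b in config.get("within_occasion_residual_covariances", []):
        for occ in range(1, n_occ + 1):
            pairs.append(((a, occ), (b, occ)))

    fixed = {}
    for occ in range(1, n_occ + 1):
        for f in structure:
            fixed[kappa_id(f, occ)] = 0.0
            fixed[psi_id(f, occ)] = 1.0
    for pid, val in dict(config.get("fixed", {})).items():
        fixed[pid] = float(val)

    m = MeasurementModel(scales=scales, structure=structure, n_occasions=n_occ,
                         residual_cov_pairs=tuple(pairs), fixed=fixed)
    for cls in config.get("equalities", []):
        m = m.with_equality(cls)
    for (s, f, occ) in config.get("extra_loadings", []):
        m = m.with_extra_loading(s, f, int(occ))
    model_df(m)  # raises if over-parameterized
    return m


def default_config() -> dict:
    """Structure description of the two-factor, two-occasion SF-36 model."""
    return {
        "scales": list(DEFAULT_SCALES),
        "factors": {f: list(m) for f, m in FIG_STRUCTURE.items()},
        "occasions": 2,
        "residual_covariances": "auto",
        "within_occasion_residual_covariances": [["RP", "RE"]],
    }


def build_fig1_model(config: Mapping | None = None) -> MeasurementModel:
    """Build the unconstrained longitudinal measurement model (Model 1).

    All RS-related parameters (loadings, intercepts, residual variances)
    are free at each occasion; factor means/variances are fixed at 0/1 at
    both occasions; residual covariances link each scale with itself across
    occasions, plus RP-RE within each occasion (the two role-limitation
    scales share wording about social roles).
    """
    cfg = dict(config) if config is not None else default_config()
    return build_model(cfg)


def apply_invariance(model: MeasurementModel,
                     classes: Iterable[str] = RS_CLASSES) -> MeasurementModel:
    """Constrain RS-related parameters equal across occasions (the no-RS model).

    ``classes`` is a subset of ``{"loadings", "intercepts",
    "residual_variances"}``.  When loadings are constrained, occasion-2
    factor variances become free (identification transfers to the invariant
    loadings); when loadings *and* intercepts are constrained, occasion-2
    factor means become free as well.  With all three classes this turns a
    Model-1-style model into Model 2.
    """
    classes = set(classes)
    unknown = classes - set(RS_CLASSES)
    if unknown:
        raise ConstraintError(f"unknown invariance classes: {sorted(unknown)}")
    if model.n_occasions != 2:
        raise ConstraintError("across-occasion invariance needs 2 occasions")
    m = model
    if "loadings" in classes:
        for fac, members in model.structure.items():
            for s in members:
                m = m.with_equality((lam_id(s, fac, 1), lam_id(s, fac, 2)))
    if "intercepts" in classes:
        for s in model.scales:
            m = m.with_equality((tau_id(s, 1), tau_id(s, 2)))
    if "residual_variances" in classes:
        for s in model.scales:
            m = m.with_equality((theta_id(s, 1), theta_id(s, 2)))
    if "loadings" in classes:
        for f in model.structure:
            if psi_id(f, 2) in m.fixed:
                m = m.with_freed(psi_id(f, 2))
        if "intercepts" in classes:
            for f in model.structure:
                if kappa_id(f, 2) in m.fixed:
                    m = m.with_freed(kappa_id(f, 2))
    return m


def release_constraint(model: MeasurementModel, parameter_pair) -> MeasurementModel:
    """Remove the equality class containing the given parameter (or pair).

    The members become free per occasion and the model gains one degree of
    freedom per removed class member beyond the first.
    """
    if isinstance(parameter_pair, str):
        pid = parameter_pair
    else:
        pid = tuple(parameter_pair)[0]
    cls = model.equality_class_of(pid)
    if cls is None:
        raise ConstraintError(f"parameter {pid!r} is not in an equality class")
    m = model._clone()
    m.equalities = tuple(c for c in model.equalities if c != cls)
    return m


def constrain_factor_structure(model: MeasurementModel,
                               classes: Iterable[str],
                               factors: Sequence[str] | None = None,
                               ) -> MeasurementModel:
    """Apply across-occasion equality of factor means/variances/correlations.

    ``classes`` is a subset of ``{"factor_means", "factor_variances",
    "factor_correlations"}``; ``factors`` optionally restricts mean and
    variance constraints to a subset of factors.  When the occasion-1
    parameter is fixed (the identification convention), constraining its
    occasion-2 twin fixes the latter at the same value; otherwise an
    equality class is formed.  Correlation equality operates on the
    correlation scale: for each within-occasion factor pair, the t1 and t2
    correlations are equated.
    """
    classes = set(classes)
    unknown = classes - set(FACTOR_CLASSES)
    if unknown:
        raise ConstraintError(f"unknown factor classes: {sorted(unknown)}")
    if model.n_occasions != 2:
        raise ConstraintError("across-occasion invariance needs 2 occasions")
    facs = tuple(factors) if factors is not None else model.factor_bases
    m = model

    def _tie(pid1: str, pid2: str) -> "MeasurementModel":
        if pid1 in m.fixed:
            return m.with_fixed(pid2, m.fixed[pid1])
        return m.with_equality((pid1, pid2))

    if "factor_correlations" in classes:
        bases = model.factor_bases
        for i in range(len(bases)):
            for j in range(i + 1, len(bases)):
                p1 = rho_id(factor_name(bases[i], 1), factor_name(bases[j], 1))
                p2 = rho_id(factor_name(bases[i], 2), factor_name(bases[j], 2))
                m = m.with_equality((p1, p2))
    if "factor_variances" in classes:
        for f in facs:
            m = _tie(psi_id(f, 1), psi_id(f, 2))
    if "factor_means" in classes:
        for f in facs:
            m = _tie(kappa_id(f, 1), kappa_id(f, 2))
    return m


# ---------------------------------------------------------------------------
# config serialization (bit-exact round trip)


def to_config(model: MeasurementModel) -> dict:
    return {
        "scales": list(model.scales),
        "occasions": model.n_occasions,
        "factors": {f: list(mm) for f, mm in model.structure.items()},
        "extra_loadings": [list(e) for e in model.extra_loadings],
        "residual_covariances": [[list(a), list(b)]
                                 for a, b in model.residual_cov_pairs],
        "fixed": dict(model.fixed),
        "equalities": sorted(sorted(cls) for cls in model.equalities),
    }


def from_config(config: Mapping) -> MeasurementModel:
    m = MeasurementModel(
        scales=tuple(config["scales"]),
        structure={f: tuple(mm) for f, mm in dict(config["factors"]).items()},
        n_occasions=int(config.get("occasions", 2)),
        extra_loadings=tuple(tuple([e[0], e[1], int(e[2])])
                             for e in config.get("extra_loadings", [])),
        residual_cov_pairs=tuple(((a[0], int(a[1])), (b[0], int(b[1])))
                                 for a, b in config.get("residual_covariances", [])),
        fixed={k: float(v) for k, v in dict(config.get("fixed", {})).items()},
        equalities=tuple(frozenset(cls) for cls in config.get("equalities", [])),
    )
    model_df(m)
    return m


def independence_model(model: MeasurementModel) -> MeasurementModel:
    """Baseline model on the same indicators: free means and variances only."""
    return MeasurementModel(scales=model.scales, structure={},
                            n_occasions=model.n_occasions)
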