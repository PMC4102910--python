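"""Declarative description of two-level non-linear structural equation mixture models.

A model couples, on each level, a measurement model (indicators regressed on a
polynomial/spline expansion of the latent vector and of observed covariates), a
recursive structural model among the latents, and a multinomial-logit mixture
over unobserved classes.  Level-1 (within, individual) parameters may be tied to
level-2 (between, cluster) latent variables through a random-coefficient map,
which is how random intercepts and random slopes enter the framework.

The classes here hold both the *structure* (which entries are free) and a full
set of parameter *values*; the simulator treats the values as generating truth,
the estimator treats free entries as parameters to sample and fixed entries as
constraints.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import yaml

__all__ = [
    "Term",
    "FunctionSpec",
    "IndicatorSpec",
    "MeasurementSpec",
    "StructuralSpec",
    "MixtureSpec",
    "RandomCoefficient",
    "ModelSpec",
    "RuleResult",
    "ValidationReport",
    "check_disjoint_terms",
    "validate_identification",
    "parameter_index",
    "pack_parameters",
    "unpack_parameters",
    "spec_to_yaml",
    "spec_from_yaml",
]


# ---------------------------------------------------------------------------
# Terms and function sets
# ---------------------------------------------------------------------------

_TERM_KINDS = ("linear", "power", "product", "truncated_power")


@dataclass(frozen=True)
class Term:
    """One column of a polynomial/interaction/truncated-power function set.

    kind:
        ``linear``          v
        ``power``           v ** exponent (exponent >= 2; exponent 1 collapses
                            to ``linear`` on construction)
        ``product``         v_a * v_b  (two distinct variables; order ignored)
        ``truncated_power`` max(v - knot, 0) ** degree
    Variables are referenced by integer position into the input vector of the
    owning :class:`FunctionSpec`.  No term can encode a constant, which keeps
    intercepts identified.
    """

    kind: str
    var: Union[int, tuple]
    exponent: int = 1
    knot: Optional[float] = None
    degree: Optional[int] = None

    def __post_init__(self):
        if self.kind not in _TERM_KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "product":
            a, b = self.var
            if a == b:
                raise ValueError("product term must reference two distinct variables")
            object.__setattr__(self, "var", (min(a, b), max(a, b)))
        else:
            object.__setattr__(self, "var", int(self.var))
        if self.kind == "power":
            if self.exponent < 1:
                raise ValueError("power exponent must be >= 1")
            if self.exponent == 1:
                object.__setattr__(self, "kind", "linear")
        if self.kind == "linear":
            object.__setattr__(self, "exponent", 1)
        if self.kind == "truncated_power":
            if self.degree is None or self.degree < 1:
                raise ValueError("truncated_power degree must be >= 1")
            if self.knot is None:
                raise ValueError("truncated_power term requires a knot")
            object.__setattr__(self, "knot", float(self.knot))

    @property
    def variables(self) -> tuple:
        return self.var if self.kind == "product" else (self.var,)


@dataclass(frozen=True)
class FunctionSpec:
    """Ordered set of :class:`Term` over a common input vector of length ``arity``."""

    terms: tuple
    arity: int

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        seen = set()
        for t in self.terms:
            if t in seen:
                raise ValueError(f"duplicate term {t}")
            seen.add(t)
            for v in t.variables:
                if not (0 <= v < self.arity):
                    raise ValueError(f"term {t} references variable {v} outside arity {self.arity}")

    @property
    def out_dim(self) -> int:
        return len(self.terms)

    @staticmethod
    def empty(arity: int = 0) -> "FunctionSpec":
        return FunctionSpec((), arity)

    def is_linear(self) -> bool:
        """True when every term is a plain first-order term."""
        return all(t.kind == "linear" for t in self.terms)


def check_disjoint_terms(a: FunctionSpec, b: FunctionSpec) -> bool:
    """True iff no term appears in both function sets.

    Sharing even one column between, say, g1 and G1 makes the corresponding
    covariate effect appear twice in one regression equation, which is not
    identified.  Term equality is structural (kind, variables, exponent, knot,
    degree); product terms compare unordered.
    """
    if a.arity != b.arity:
        raise ValueError(f"function sets have mismatched arity ({a.arity} vs {b.arity})")
    return not (set(a.terms) & set(b.terms))


# ---------------------------------------------------------------------------
# Indicator links
# ---------------------------------------------------------------------------

_LINKS = ("identity", "ordered", "poisson_log")


@dataclass
class IndicatorSpec:
    """Observation link of one indicator column.

    ``ordered`` uses the threshold rule: observed category s iff the underlying
    normal variable falls in (tau_s, tau_{s+1}); interior thresholds are stored
    (length n_categories - 1) and must be strictly increasing.  ``poisson_log``
    treats the linear predictor as log of the Poisson rate (simulation only).
    """

    link: str = "identity"
    n_categories: Optional[int] = None
    thresholds: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.link not in _LINKS:
            raise ValueError(f"unknown link {self.link!r}")
        if self.link == "ordered":
            if self.n_categories is None or self.n_categories < 2:
                raise ValueError("ordered link needs n_categories >= 2")
            self.thresholds = np.asarray(self.thresholds, dtype=float)
            if self.thresholds.shape != (self.n_categories - 1,):
                raise ValueError("ordered link needs n_categories - 1 interior thresholds")
            if not np.all(np.diff(self.thresholds) > 0):
                raise ValueError("thresholds must be strictly increasing")
        elif self.thresholds is not None:
            raise ValueError(f"{self.link} link takes no thresholds")


# ---------------------------------------------------------------------------
# Measurement / structural / mixture blocks
# ---------------------------------------------------------------------------


def _as_bool(mask, shape) -> np.ndarray:
    out = np.asarray(mask, dtype=bool)
    if out.shape != shape:
        raise ValueError(f"mask shape {out.shape} != {shape}")
    return out


@dataclass
class MeasurementSpec:
    """Indicators = nu + Lambda f(eta) + K g(x) + eps,  eps ~ N(0, Theta).

    ``*_free`` masks mark entries the estimator samples; fixed entries act as
    identification constraints (scaling loadings fixed to 1, anchor intercepts
    fixed to 0).
    """

    nu: np.ndarray
    Lambda: np.ndarray
    K: np.ndarray
    Theta: np.ndarray
    f: FunctionSpec
    g: FunctionSpec
    nu_free: np.ndarray = None
    Lambda_free: np.ndarray = None
    K_free: np.ndarray = None
    theta_diagonal: bool = True
    theta_free: bool = True

    def __post_init__(self):
        self.nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        J = self.nu.shape[0]
        self.Lambda = np.asarray(self.Lambda, dtype=float).reshape(J, self.f.out_dim)
        self.K = np.asarray(self.K, dtype=float).reshape(J, self.g.out_dim)
        self.Theta = np.asarray(self.Theta, dtype=float).reshape(J, J)
        if self.nu_free is None:
            self.nu_free = np.ones(J, dtype=bool)
        if self.Lambda_free is None:
            self.Lambda_free = self.Lambda != 0.0
        if self.K_free is None:
            self.K_free = self.K != 0.0
        self.nu_free = _as_bool(self.nu_free, (J,))
        self.Lambda_free = _as_bool(self.Lambda_free, self.Lambda.shape)
        self.K_free = _as_bool(self.K_free, self.K.shape)
        if not np.allclose(self.Theta, self.Theta.T):
            raise ValueError("Theta must be symmetric")
        if J and np.linalg.eigvalsh(self.Theta).min() <= 0:
            raise ValueError("Theta must be positive definite")
        if self.theta_diagonal and not np.allclose(self.Theta, np.diag(np.diag(self.Theta))):
            raise ValueError("theta_diagonal=True but Theta has off-diagonal entries")

    @property
    def n_indicators(self) -> int:
        return self.nu.shape[0]


@dataclass
class StructuralSpec:
    """Recursive structural system among the latents of one level.

    Latents are ordered exogenous-first; the first ``n_exog`` entries are drawn
    from a per-class Gaussian with means ``alpha[class, :n_exog]`` and
    covariance ``Psi_exog``; the remaining (endogenous) entries satisfy

        eta_r = alpha_r + B[r] . F(eta) + Gamma[r] . G(x) + zeta_r

    with independent disturbances ``zeta_r ~ N(0, psi_end[r])``.  Recursivity:
    a term may feed equation r only if all its latent arguments precede r.
    """

    latent_names: Sequence[str]
    n_exog: int
    alpha: np.ndarray            # (n_classes, m): exog cols = class means, endo cols = intercepts
    Psi_exog: np.ndarray         # (n_exog, n_exog) or (n_classes, n_exog, n_exog)
    psi_end: np.ndarray          # (m - n_exog,) disturbance variances
    B: np.ndarray                # (m, out_dim(F)); exog rows must be zero
    Gamma: np.ndarray            # (m, out_dim(G))
    F: FunctionSpec
    G: FunctionSpec
    alpha_free: np.ndarray = None
    B_free: np.ndarray = None
    Gamma_free: np.ndarray = None
    psi_free: bool = True
    psi_exog_class_varying: bool = False

    def __post_init__(self):
        self.latent_names = tuple(self.latent_names)
        m = len(self.latent_names)
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        n_classes = self.alpha.shape[0]
        if self.alpha.shape != (n_classes, m):
            raise ValueError("alpha must be (n_classes, m)")
        self.Psi_exog = np.asarray(self.Psi_exog, dtype=float)
        if self.psi_exog_class_varying:
            self.Psi_exog = self.Psi_exog.reshape(n_classes, self.n_exog, self.n_exog)
        else:
            self.Psi_exog = self.Psi_exog.reshape(self.n_exog, self.n_exog)
        self.psi_end = np.atleast_1d(np.asarray(self.psi_end, dtype=float))
        if self.psi_end.shape != (m - self.n_exog,):
            raise ValueError("psi_end must have one variance per endogenous latent")
        if np.any(self.psi_end <= 0):
            raise ValueError("disturbance variances must be positive")
        if self.n_exog:
            for sigma in self.Psi_exog.reshape(-1, self.n_exog, self.n_exog):
                if not np.allclose(sigma, sigma.T) or np.linalg.eigvalsh(sigma).min() <= 0:
                    raise ValueError("Psi_exog must be symmetric positive definite")
        self.B = np.asarray(self.B, dtype=float).reshape(m, self.F.out_dim)
        self.Gamma = np.asarray(self.Gamma, dtype=float).reshape(m, self.G.out_dim)
        if self.alpha_free is None:
            self.alpha_free = np.ones(m, dtype=bool)
        self.alpha_free = _as_bool(self.alpha_free, (m,))
        if self.B_free is None:
            self.B_free = self.B != 0.0
        if self.Gamma_free is None:
            self.Gamma_free = self.Gamma != 0.0
        self.B_free = _as_bool(self.B_free, self.B.shape)
        self.Gamma_free = _as_bool(self.Gamma_free, self.Gamma.shape)
        if np.any(self.B[: self.n_exog] != 0) or np.any(self.B_free[: self.n_exog]):
            raise ValueError("exogenous latents cannot have structural predictors")
        if np.any(self.Gamma[: self.n_exog] != 0) or np.any(self.Gamma_free[: self.n_exog]):
            raise ValueError("exogenous latents cannot have covariate predictors")
        self._check_recursive()

    def _check_recursive(self):
        """Each active term in row r may only involve latents with index < r."""
        for r in range(self.n_exog, len(self.latent_names)):
            for t_idx, term in enumerate(self.F.terms):
                if self.B[r, t_idx] != 0 or self.B_free[r, t_idx]:
                    if any(v >= r for v in term.variables):
                        raise ValueError(
                            f"non-recursive system: equation for "
                            f"{self.latent_names[r]!r} uses term over "
                            f"{[self.latent_names[v] for v in term.variables]}"
                        )

    @property
    def m(self) -> int:
        return len(self.latent_names)

    @property
    def n_endog(self) -> int:
        return self.m - self.n_exog

    @property
    def n_classes(self) -> int:
        return self.alpha.shape[0]

    def psi_exog_for(self, cls: int) -> np.ndarray:
        return self.Psi_exog[cls] if self.psi_exog_class_varying else self.Psi_exog


@dataclass
class MixtureSpec:
    """Multinomial-logit class membership: P(class=c | x) = softmax(a_c + b_c . h(x)).

    Class 0 is the reference (a_0 = 0, b_0 = 0), which with sum-to-one
    normalization identifies the logit scale.
    """

    n_classes: int
    a: np.ndarray = None
    b: np.ndarray = None
    h: FunctionSpec = None

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.h is None:
            self.h = FunctionSpec.empty(0)
        if self.a is None:
            self.a = np.zeros(self.n_classes)
        if self.b is None:
            self.b = np.zeros((self.n_classes, self.h.out_dim))
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float))
        self.b = np.asarray(self.b, dtype=float).reshape(self.n_classes, self.h.out_dim)
        if self.a.shape != (self.n_classes,):
            raise ValueError("logit intercepts must have one entry per class")
        if self.a[0] != 0 or np.any(self.b[0] != 0):
            raise ValueError("reference class must have a=0, b=0")


@dataclass(frozen=True)
class RandomCoefficient:
    """Maps one level-1 parameter to a coordinate of the level-2 latent vector.

    ``target_kind`` is ``intercept`` (the structural intercept of a level-1
    endogenous latent) or ``slope`` (one B entry, identified by the F1 term
    index).  The mapped parameter drops out of the fixed parameter vector and
    is replaced, per cluster, by the named level-2 latent.
    """

    target_kind: str
    latent: str
    eta2_var: str
    term_index: Optional[int] = None

    def __post_init__(self):
        if self.target_kind not in ("intercept", "slope"):
            raise ValueError("target_kind must be 'intercept' or 'slope'")
        if self.target_kind == "slope" and self.term_index is None:
            raise ValueError("slope target needs a term_index")


# ---------------------------------------------------------------------------
# ModelSpec
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """Complete two-level model; ``level2`` parts may be ``None`` for single-level use."""

    y_names: Sequence[str]
    x1_names: Sequence[str]
    measurement1: MeasurementSpec
    structural1: StructuralSpec
    mixture1: MixtureSpec
    z_names: Sequence[str] = ()
    x2_names: Sequence[str] = ()
    measurement2: Optional[MeasurementSpec] = None
    structural2: Optional[StructuralSpec] = None
    mixture2: Optional[MixtureSpec] = None
    random_map: Sequence[RandomCoefficient] = ()
    y_links: Sequence[IndicatorSpec] = None
    z_links: Sequence[IndicatorSpec] = None
    # rule-4 label-switching guard: ("level2", latent_name) or ("level1", latent_name);
    # None only valid when every mixture has a single class.
    ordered_block: Optional[tuple] = None

    def __post_init__(self):
        self.y_names = tuple(self.y_names)
        self.x1_names = tuple(self.x1_names)
        self.z_names = tuple(self.z_names)
        self.x2_names = tuple(self.x2_names)
        self.random_map = tuple(self.random_map)
        if self.mixture2 is None:
            self.mixture2 = MixtureSpec(1, h=FunctionSpec.empty(len(self.x2_names)))
        if self.y_links is None:
            self.y_links = tuple(IndicatorSpec() for _ in self.y_names)
        if self.z_links is None:
            self.z_links = tuple(IndicatorSpec() for _ in self.z_names)
        self.y_links = tuple(self.y_links)
        self.z_links = tuple(self.z_links)
        if len(self.y_links) != len(self.y_names):
            raise ValueError("one IndicatorSpec per y column required")
        if len(self.z_links) != len(self.z_names):
            raise ValueError("one IndicatorSpec per z column required")
        if self.measurement1.n_indicators != len(self.y_names):
            raise ValueError("measurement1 row count must match y_names")
        if self.structural2 is None and self.random_map:
            raise ValueError("random coefficients require a level-2 structural model")
        if self.structural2 is not None:
            names2 = self.structural2.latent_names
            for rc in self.random_map:
                if rc.eta2_var not in names2:
                    raise ValueError(f"random coefficient target {rc.eta2_var!r} not a level-2 latent")
                if rc.latent not in self.structural1.latent_names:
                    raise ValueError(f"random coefficient source {rc.latent!r} not a level-1 latent")
            used = [rc.eta2_var for rc in self.random_map]
            if len(used) != len(set(used)):
                raise ValueError("each level-2 latent may carry at most one random coefficient")
        if self.ordered_block is None and self.n_total_classes > 1:
            # default: order the class means of the first exogenous latent of the
            # level that actually mixes
            if self.mixture2.n_classes > 1 and self.structural2 is not None and self.structural2.n_exog:
                self.ordered_block = ("level2", self.structural2.latent_names[0])
            elif self.mixture1.n_classes > 1 and self.structural1.n_exog:
                self.ordered_block = ("level1", self.structural1.latent_names[0])

    @property
    def n_total_classes(self) -> int:
        return self.mixture1.n_classes * self.mixture2.n_classes

    @property
    def has_level2(self) -> bool:
        return self.structural2 is not None

    def random_targets(self):
        """(kind, level1 latent index, term_index, level2 latent index) tuples."""
        out = []
        if self.structural2 is None:
            return out
        for rc in self.random_map:
            r = self.structural1.latent_names.index(rc.latent)
            u = self.structural2.latent_names.index(rc.eta2_var)
            out.append((rc.target_kind, r, rc.term_index, u))
        return out


# ---------------------------------------------------------------------------
# Identification rules
# ---------------------------------------------------------------------------


@dataclass
class RuleResult:
    rule: int
    passed: bool
    detail: str


@dataclass
class ValidationReport:
    results: Sequence[RuleResult]

    @property
    def ok(self) -> bool:
        return all(r.passed for r in self.results)

    def failures(self):
        return [r for r in self.results if not r.passed]

    def __str__(self):
        lines = []
        for r in self.results:
            lines.append(f"rule {r.rule}: {'pass' if r.passed else 'FAIL'} — {r.detail}")
        return "\n".join(lines)


def _scaling_problems(meas: MeasurementSpec, struct: StructuralSpec, level: str,
                      skip: set) -> list:
    """Latents lacking a scaling constraint (fixed nonzero loading on a linear term)."""
    problems = []
    for idx, name in enumerate(struct.latent_names):
        if name in skip:
            continue
        cols = [t_idx for t_idx, t in enumerate(meas.f.terms)
                if t.kind == "linear" and t.var == idx]
        loads_anywhere = any(
            meas.Lambda[j, t_idx] != 0 or meas.Lambda_free[j, t_idx]
            for t_idx in cols for j in range(meas.n_indicators)
        )
        if not loads_anywhere:
            continue  # latent without own indicators (e.g. a pure random effect)
        anchored = any(
            not meas.Lambda_free[j, t_idx] and meas.Lambda[j, t_idx] != 0
            for t_idx in cols for j in range(meas.n_indicators)
        )
        if not anchored:
            problems.append(f"{level}:{name} has no fixed scaling loading")
        # intercept side: at least one anchoring indicator with fixed intercept,
        # or the latent's own mean/intercept fixed
        mean_free = struct.alpha_free[idx]
        nu_anchor = any(
            not meas.nu_free[j]
            for t_idx in cols for j in range(meas.n_indicators)
            if meas.Lambda[j, t_idx] != 0 or meas.Lambda_free[j, t_idx]
        )
        if mean_free and not nu_anchor:
            problems.append(f"{level}:{name} mean and all its indicator intercepts are free")
    return problems


def validate_identification(spec: ModelSpec) -> ValidationReport:
    """Run the four necessary identification checks; always returns a report.

    1. every measured latent carries a scaling constraint (a loading fixed to a
       nonzero value) and a resolved intercept constraint;
    2. the covariate sets g/G and the latent sets f/F are disjoint on each
       level, and contain no constant columns (structural impossibility of
       constants is re-asserted);
    3. every level-2 exogenous latent that is not itself a random-coefficient
       carrier has at least one indicator with a scaling constraint;
    4. reference-class logit coefficients are fixed at zero and, when any
       mixture has more than one class, an ordering constraint is declared on
       exactly one parameter block.
    """
    results = []

    # rule 1 — scaling constraints
    rc_targets = {rc.eta2_var for rc in spec.random_map}
    problems = _scaling_problems(spec.measurement1, spec.structural1, "level1", set())
    if spec.has_level2 and spec.measurement2 is not None:
        problems += _scaling_problems(spec.measurement2, spec.structural2, "level2", rc_targets)
    results.append(RuleResult(1, not problems,
                              "; ".join(problems) or "all latents scaled"))

    # rule 2 — no term may reach one indicator equation twice.  A term shared
    # between the measurement set (f or g) and the structural set (F or G) is
    # collinear exactly when an indicator carries it directly AND loads on an
    # endogenous latent whose equation also carries it: the direct and the
    # mediated coefficient then enter the same reduced-form column.
    problems = []
    levels = [("level1", spec.measurement1, spec.structural1,
               spec.y_names, spec.x1_names)]
    if spec.has_level2 and spec.measurement2 is not None:
        levels.append(("level2", spec.measurement2, spec.structural2,
                       spec.z_names, spec.x2_names))
    for label, meas, struct, ind_names, x_names in levels:
        for j in range(meas.n_indicators):
            f_terms_j = {meas.f.terms[t] for t in range(meas.f.out_dim)
                         if meas.Lambda[j, t] != 0 or meas.Lambda_free[j, t]}
            g_terms_j = {meas.g.terms[t] for t in range(meas.g.out_dim)
                         if meas.K[j, t] != 0 or meas.K_free[j, t]}
            loaded = {v for t in f_terms_j for v in t.variables}
            for r in range(struct.n_exog, struct.m):
                if r not in loaded:
                    continue
                F_terms_r = {struct.F.terms[t] for t in range(struct.F.out_dim)
                             if struct.B[r, t] != 0 or struct.B_free[r, t]}
                G_terms_r = {struct.G.terms[t] for t in range(struct.G.out_dim)
                             if struct.Gamma[r, t] != 0 or struct.Gamma_free[r, t]}
                for t in sorted(f_terms_j & F_terms_r, key=str):
                    problems.append(
                        f"{label}: {ind_names[j]} receives "
                        f"{_term_label(t, struct.latent_names)} directly and "
                        f"through {struct.latent_names[r]}")
                for t in sorted(g_terms_j & G_terms_r, key=str):
                    problems.append(
                        f"{label}: {ind_names[j]} receives "
                        f"{_term_label(t, x_names)} directly and "
                        f"through {struct.latent_names[r]}")
    results.append(RuleResult(2, not problems,
                              "; ".join(problems) or "function sets disjoint per equation, no constants"))

    # rule 3 — level-2 exogenous latents need measured anchors
    problems = []
    if spec.has_level2 and spec.measurement2 is not None:
        st2, me2 = spec.structural2, spec.measurement2
        for idx in range(st2.n_exog):
            name = st2.latent_names[idx]
            if name in rc_targets:
                continue  # identified through the level-1 equations it enters
            cols = [t_idx for t_idx, t in enumerate(me2.f.terms)
                    if t.kind == "linear" and t.var == idx]
            anchored = any(
                not me2.Lambda_free[j, t_idx] and me2.Lambda[j, t_idx] != 0
                for t_idx in cols for j in range(me2.n_indicators)
            )
            if not anchored:
                problems.append(f"level2 exogenous {name} lacks an anchored indicator")
    results.append(RuleResult(3, not problems,
                              "; ".join(problems) or "level-2 exogenous latents anchored"))

    # rule 4 — reference class + ordering constraint
    problems = []
    for label, mix in (("level1", spec.mixture1), ("level2", spec.mixture2)):
        if mix.a[0] != 0 or np.any(mix.b[0] != 0):
            problems.append(f"{label} reference class logit not fixed at zero")
    if spec.n_total_classes > 1 and spec.ordered_block is None:
        problems.append("mixture present but no ordering constraint declared")
    results.append(RuleResult(4, not problems,
                              "; ".join(problems) or "mixtures identified"))

    return ValidationReport(results)


# ---------------------------------------------------------------------------
# Parameter indexing (pack/unpack)
# ---------------------------------------------------------------------------


def _term_label(term: Term, names: Sequence[str]) -> str:
    from . import basis  # local import to avoid a cycle

    return basis.term_to_string(term, names)


def _block_entries(spec: ModelSpec):
    """Yield (name, getter, setter) triples for every free scalar parameter.

    The ordering is deterministic: level 1 measurement, structural, mixture;
    then level 2; then thresholds.  Random-coefficient targets are excluded
    (their cluster-level values live in eta2, their spread in Psi2).
    """
    entries = []

    def scalar(name, arr, idx):
        entries.append((name, (arr, idx)))

    def level_entries(tag, meas: MeasurementSpec, struct: StructuralSpec,
                      mix: MixtureSpec, ind_names, lat_names, x_names,
                      random_intercepts, random_slopes, links):
        J = meas.n_indicators
        for j in range(J):
            if meas.nu_free[j]:
                scalar(f"{tag}.nu.{ind_names[j]}", meas.nu, (j,))
        for j in range(J):
            for t in range(meas.f.out_dim):
                if meas.Lambda_free[j, t]:
                    scalar(f"{tag}.lam.{ind_names[j]}.{_term_label(meas.f.terms[t], lat_names)}",
                           meas.Lambda, (j, t))
        for j in range(J):
            for t in range(meas.g.out_dim):
                if meas.K_free[j, t]:
                    scalar(f"{tag}.K.{ind_names[j]}.{_term_label(meas.g.terms[t], x_names)}",
                           meas.K, (j, t))
        if meas.theta_free:
            for j in range(J):
                if links[j].link == "identity":
                    scalar(f"{tag}.theta.{ind_names[j]}", meas.Theta, (j, j))
        # structural
        n_classes = struct.n_classes
        for idx in range(struct.n_exog):
            if struct.alpha_free[idx]:
                for cls in range(n_classes):
                    suffix = f".c{cls + 1}" if n_classes > 1 else ""
                    scalar(f"{tag}.mean.{lat_names[idx]}{suffix}", struct.alpha, (cls, idx))
        for idx in range(struct.n_exog, struct.m):
            if struct.alpha_free[idx] and idx not in random_intercepts:
                scalar(f"{tag}.alpha.{lat_names[idx]}", struct.alpha, (0, idx))
        for r in range(struct.n_exog, struct.m):
            for t in range(struct.F.out_dim):
                if struct.B_free[r, t] and (r, t) not in random_slopes:
                    scalar(f"{tag}.B.{lat_names[r]}.{_term_label(struct.F.terms[t], lat_names)}",
                           struct.B, (r, t))
            for t in range(struct.G.out_dim):
                if struct.Gamma_free[r, t]:
                    scalar(f"{tag}.G.{lat_names[r]}.{_term_label(struct.G.terms[t], x_names)}",
                           struct.Gamma, (r, t))
        if struct.psi_free:
            n_psi_cls = n_classes if struct.psi_exog_class_varying else 1
            for cls in range(n_psi_cls):
                suffix = f".c{cls + 1}" if n_psi_cls > 1 else ""
                for i in range(struct.n_exog):
                    for jj in range(i + 1):
                        idx = (cls, i, jj) if struct.psi_exog_class_varying else (i, jj)
                        scalar(f"{tag}.psi.{lat_names[i]}.{lat_names[jj]}{suffix}",
                               struct.Psi_exog, idx)
            for r in range(struct.n_endog):
                scalar(f"{tag}.psi.{lat_names[struct.n_exog + r]}", struct.psi_end, (r,))
        for cls in range(1, mix.n_classes):
            scalar(f"{tag}.logit.a.c{cls + 1}", mix.a, (cls,))
            for t in range(mix.h.out_dim):
                scalar(f"{tag}.logit.b.c{cls + 1}.{_term_label(mix.h.terms[t], x_names)}",
                       mix.b, (cls, t))

    rints = {r for kind, r, t, u in spec.random_targets() if kind == "intercept"}
    rslopes = {(r, t) for kind, r, t, u in spec.random_targets() if kind == "slope"}
    level_entries("L1", spec.measurement1, spec.structural1, spec.mixture1,
                  spec.y_names, spec.structural1.latent_names, spec.x1_names,
                  rints, rslopes, spec.y_links)
    if spec.has_level2 and spec.measurement2 is not None:
        level_entries("L2", spec.measurement2, spec.structural2, spec.mixture2,
                      spec.z_names, spec.structural2.latent_names, spec.x2_names,
                      set(), set(), spec.z_links)
    for j, link in enumerate(spec.y_links):
        if link.link == "ordered":
            for s in range(1, link.n_categories - 1):  # first threshold fixed at 0
                entries.append((f"tau.{spec.y_names[j]}.{s + 1}", ("tau_y", (j, s))))
    for l, link in enumerate(spec.z_links):
        if link.link == "ordered":
            for s in range(1, link.n_categories - 1):
                entries.append((f"tau.{spec.z_names[l]}.{s + 1}", ("tau_z", (l, s))))
    return entries


def parameter_index(spec: ModelSpec) -> list:
    """Deterministic ordered names of all free scalar parameters."""
    names = [name for name, _ in _block_entries(spec)]
    if len(names) != len(set(names)):
        raise RuntimeError("parameter names are not unique")
    return names


def pack_parameters(spec: ModelSpec) -> np.ndarray:
    """Flatten the free parameters of ``spec`` into a vector (parameter_index order)."""
    out = []
    for _, (arr, idx) in _block_entries(spec):
        if isinstance(arr, str):  # thresholds
            links = spec.y_links if arr == "tau_y" else spec.z_links
            j, s = idx
            out.append(links[j].thresholds[s])
        else:
            out.append(arr[idx])
    return np.asarray(out, dtype=float)


def unpack_parameters(spec: ModelSpec, vector: np.ndarray) -> ModelSpec:
    """Write a flat vector back into (a copy of) the spec; inverse of pack."""
    import copy

    spec = copy.deepcopy(spec)
    entries = _block_entries(spec)
    if len(vector) != len(entries):
        raise ValueError(f"vector length {len(vector)} != {len(entries)} free parameters")
    for value, (_, (arr, idx)) in zip(vector, entries):
        if isinstance(arr, str):
            links = spec.y_links if arr == "tau_y" else spec.z_links
            j, s = idx
            links[j].thresholds[s] = value
        else:
            arr[idx] = value
    # re-symmetrize exogenous covariance blocks (only lower triangle is packed)
    for struct in (spec.structural1, spec.structural2):
        if struct is None or struct.n_exog == 0:
            continue
        mats = struct.Psi_exog.reshape(-1, struct.n_exog, struct.n_exog)
        for mat in mats:
            lower = np.tril(mat)
            mat[:] = lower + np.tril(lower, -1).T
    return spec


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------


def _fspec_to_strings(fs: FunctionSpec, names) -> list:
    from . import basis

    return [basis.term_to_string(t, names) for t in fs.terms]


def _fspec_from_strings(strings, names) -> FunctionSpec:
    from . import basis

    terms = []
    for s in strings:
        terms.extend(basis.parse_term_string(s, names))
    return FunctionSpec(tuple(terms), len(names))


def _meas_to_dict(meas: MeasurementSpec, ind_names, lat_names, x_names, links):
    d = {
        "f": _fspec_to_strings(meas.f, lat_names),
        "g": _fspec_to_strings(meas.g, x_names),
        "nu": meas.nu.tolist(),
        "nu_free": meas.nu_free.tolist(),
        "Lambda": meas.Lambda.tolist(),
        "Lambda_free": meas.Lambda_free.tolist(),
        "K": meas.K.tolist(),
        "K_free": meas.K_free.tolist(),
        "Theta": meas.Theta.tolist(),
        "theta_diagonal": meas.theta_diagonal,
        "theta_free": meas.theta_free,
        "links": [
            {"link": lk.link, "n_categories": lk.n_categories,
             "thresholds": None if lk.thresholds is None else np.asarray(lk.thresholds).tolist()}
            for lk in links
        ],
    }
    return d


def _meas_from_dict(d, lat_names, x_names):
    f = _fspec_from_strings(d["f"], lat_names)
    g = _fspec_from_strings(d["g"], x_names)
    meas = MeasurementSpec(
        nu=np.asarray(d["nu"]), Lambda=np.asarray(d["Lambda"]), K=np.asarray(d["K"]),
        Theta=np.asarray(d["Theta"]), f=f, g=g,
        nu_free=np.asarray(d["nu_free"]), Lambda_free=np.asarray(d["Lambda_free"]),
        K_free=np.asarray(d["K_free"]), theta_diagonal=d["theta_diagonal"],
        theta_free=d.get("theta_free", True),
    )
    links = tuple(
        IndicatorSpec(link=lk["link"], n_categories=lk["n_categories"],
                      thresholds=None if lk["thresholds"] is None else np.asarray(lk["thresholds"]))
        for lk in d["links"]
    )
    return meas, links


def _struct_to_dict(st: StructuralSpec, x_names):
    return {
        "latents": list(st.latent_names),
        "n_exog": st.n_exog,
        "alpha": st.alpha.tolist(),
        "alpha_free": st.alpha_free.tolist(),
        "Psi_exog": st.Psi_exog.tolist(),
        "psi_exog_class_varying": st.psi_exog_class_varying,
        "psi_end": st.psi_end.tolist(),
        "psi_free": st.psi_free,
        "B": st.B.tolist(),
        "B_free": st.B_free.tolist(),
        "Gamma": st.Gamma.tolist(),
        "Gamma_free": st.Gamma_free.tolist(),
        "F": _fspec_to_strings(st.F, st.latent_names),
        "G": _fspec_to_strings(st.G, x_names),
    }


def _struct_from_dict(d, x_names):
    names = d["latents"]
    return StructuralSpec(
        latent_names=names, n_exog=d["n_exog"], alpha=np.asarray(d["alpha"]),
        Psi_exog=np.asarray(d["Psi_exog"]), psi_end=np.asarray(d["psi_end"]),
        B=np.asarray(d["B"]), Gamma=np.asarray(d["Gamma"]),
        F=_fspec_from_strings(d["F"], names), G=_fspec_from_strings(d["G"], x_names),
        alpha_free=np.asarray(d["alpha_free"]), B_free=np.asarray(d["B_free"]),
        Gamma_free=np.asarray(d["Gamma_free"]), psi_free=d.get("psi_free", True),
        psi_exog_class_varying=d.get("psi_exog_class_varying", False),
    )


def _mix_to_dict(mix: MixtureSpec, x_names):
    if isinstance(mix.n_classes, (list, tuple)):
        raise ValueError("per-level-2-class within-class counts are not supported")
    return {
        "n_classes": int(mix.n_classes),
        "a": mix.a.tolist(),
        "b": mix.b.tolist(),
        "h": _fspec_to_strings(mix.h, x_names),
    }


def _mix_from_dict(d, x_names):
    if isinstance(d["n_classes"], (list, tuple)):
        raise ValueError("per-level-2-class within-class counts are not supported")
    h = _fspec_from_strings(d["h"], x_names)
    return MixtureSpec(n_classes=int(d["n_classes"]), a=np.asarray(d["a"]),
                       b=np.asarray(d["b"]), h=h)


def spec_to_yaml(spec: ModelSpec) -> str:
    """Serialize a ModelSpec (structure, constraints and values) to YAML text."""
    doc = {
        "level1": {
            "indicators": list(spec.y_names),
            "covariates": list(spec.x1_names),
            "measurement": _meas_to_dict(spec.measurement1, spec.y_names,
                                         spec.structural1.latent_names,
                                         spec.x1_names, spec.y_links),
            "structural": _struct_to_dict(spec.structural1, spec.x1_names),
        },
        "mixtures": {
            "level1": _mix_to_dict(spec.mixture1, spec.x1_names),
            "level2": _mix_to_dict(spec.mixture2, spec.x2_names),
        },
        "random": [
            {"target_kind": rc.target_kind, "latent": rc.latent,
             "eta2_var": rc.eta2_var, "term_index": rc.term_index}
            for rc in spec.random_map
        ],
        "ordered_block": list(spec.ordered_block) if spec.ordered_block else None,
    }
    if spec.has_level2:
        doc["level2"] = {
            "indicators": list(spec.z_names),
            "covariates": list(spec.x2_names),
            "measurement": _meas_to_dict(spec.measurement2, spec.z_names,
                                         spec.structural2.latent_names,
                                         spec.x2_names, spec.z_links),
            "structural": _struct_to_dict(spec.structural2, spec.x2_names),
        }
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_yaml(text: str) -> ModelSpec:
    """Parse a YAML model configuration produced by :func:`spec_to_yaml`."""
    doc = yaml.safe_load(io.StringIO(text))
    l1 = doc["level1"]
    st1 = _struct_from_dict(l1["structural"], l1["covariates"])
    me1, links1 = _meas_from_dict(l1["measurement"], st1.latent_names, l1["covariates"])
    mix1 = _mix_from_dict(doc["mixtures"]["level1"], l1["covariates"])
    kwargs = {}
    if "level2" in doc:
        l2 = doc["level2"]
        st2 = _struct_from_dict(l2["structural"], l2["covariates"])
        me2, links2 = _meas_from_dict(l2["measurement"], st2.latent_names, l2["covariates"])
        kwargs = {
            "z_names": l2["indicators"], "x2_names": l2["covariates"],
            "measurement2": me2, "structural2": st2, "z_links": links2,
        }
    mix2 = _mix_from_dict(doc["mixtures"]["level2"],
                          kwargs.get("x2_names", []))
    random_map = tuple(
        RandomCoefficient(target_kind=rc["target_kind"], latent=rc["latent"],
                          eta2_var=rc["eta2_var"], term_index=rc["term_index"])
        for rc in doc.get("random", [])
    )
    ordered = doc.get("ordered_block")
    return ModelSpec(
        y_names=l1["indicators"], x1_names=l1["covariates"],
        measurement1=me1, structural1=st1, mixture1=mix1,
        mixture2=mix2, random_map=random_map, y_links=links1,
        ordered_block=tuple(ordered) if ordered else None,
        **kwargs,
    )
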