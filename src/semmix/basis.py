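"""Evaluation of polynomial, interaction and truncated-power-spline function sets.

The truncated-power parameterization of a cubic spline with knots xi_1 < ... <
xi_q is the column set (v, v^2, v^3, (v-xi_1)_+^3, ..., (v-xi_q)_+^3).  It is
kept deliberately (instead of a B-spline basis) so that fitted coefficients map
one-to-one onto the usual reporting convention for latent spline models, at the
cost of poorer numerical conditioning.  Columns are not centred or
orthogonalized by default.
"""

from __future__ import annotations

import re
from typing import Sequence

import numpy as np

from .model_spec import FunctionSpec, Term

__all__ = [
    "eval_term",
    "eval_function",
    "eval_function_matrix",
    "spline_terms",
    "parse_term_string",
    "term_to_string",
    "parse_function",
]


def eval_term(term: Term, values: np.ndarray) -> float:
    """Evaluate a single term at one input vector.

    Non-finite inputs propagate (the result is then non-finite); callers that
    need a hard failure should check ``np.isfinite`` on the output.
    """
    v = np.asarray(values, dtype=float)
    if term.kind == "linear":
        return float(v[term.var])
    if term.kind == "power":
        return float(v[term.var] ** term.exponent)
    if term.kind == "product":
        a, b = term.var
        return float(v[a] * v[b])
    # truncated power
    return float(np.maximum(v[term.var] - term.knot, 0.0) ** term.degree)


def eval_function(fspec: FunctionSpec, values: np.ndarray) -> np.ndarray:
    """Evaluate all terms of a function set at one input vector (order preserved)."""
    v = np.asarray(values, dtype=float)
    if v.shape != (fspec.arity,):
        raise ValueError(f"expected input of length {fspec.arity}, got shape {v.shape}")
    return np.array([eval_term(t, v) for t in fspec.terms], dtype=float)


_COMPILED_CACHE: dict = {}


def _compile_terms(fspec: FunctionSpec):
    """Group term metadata by kind for fast column evaluation (cached)."""
    key = (id(fspec), fspec.terms)
    hit = _COMPILED_CACHE.get(key)
    if hit is not None:
        return hit
    lin_k, lin_v = [], []
    pow_k, pow_v, pow_e = [], [], []
    prd_k, prd_a, prd_b = [], [], []
    tp_k, tp_v, tp_knot, tp_d = [], [], [], []
    for k, t in enumerate(fspec.terms):
        if t.kind == "linear":
            lin_k.append(k)
            lin_v.append(t.var)
        elif t.kind == "power":
            pow_k.append(k)
            pow_v.append(t.var)
            pow_e.append(t.exponent)
        elif t.kind == "product":
            prd_k.append(k)
            prd_a.append(t.var[0])
            prd_b.append(t.var[1])
        else:
            tp_k.append(k)
            tp_v.append(t.var)
            tp_knot.append(t.knot)
            tp_d.append(t.degree)
    compiled = (
        (np.array(lin_k, dtype=int), np.array(lin_v, dtype=int)),
        (np.array(pow_k, dtype=int), np.array(pow_v, dtype=int),
         np.array(pow_e, dtype=float)),
        (np.array(prd_k, dtype=int), np.array(prd_a, dtype=int),
         np.array(prd_b, dtype=int)),
        (np.array(tp_k, dtype=int), np.array(tp_v, dtype=int),
         np.array(tp_knot, dtype=float), np.array(tp_d, dtype=float)),
    )
    if len(_COMPILED_CACHE) > 256:
        _COMPILED_CACHE.clear()
    _COMPILED_CACHE[key] = compiled
    return compiled


def eval_function_matrix(fspec: FunctionSpec, X: np.ndarray) -> np.ndarray:
    """Row-wise evaluation: X (n, arity) -> basis matrix (n, out_dim)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != fspec.arity:
        raise ValueError(f"expected (n, {fspec.arity}) input, got {X.shape}")
    n = X.shape[0]
    out = np.empty((n, fspec.out_dim))
    (lin_k, lin_v), (pow_k, pow_v, pow_e), (prd_k, prd_a, prd_b), \
        (tp_k, tp_v, tp_knot, tp_d) = _compile_terms(fspec)
    if lin_k.size:
        out[:, lin_k] = X[:, lin_v]
    if pow_k.size:
        out[:, pow_k] = X[:, pow_v] ** pow_e
    if prd_k.size:
        out[:, prd_k] = X[:, prd_a] * X[:, prd_b]
    if tp_k.size:
        out[:, tp_k] = np.maximum(X[:, tp_v] - tp_knot, 0.0) ** tp_d
    return out


def spline_terms(var: int, knots: Sequence[float], degree: int,
                 arity: int = None) -> FunctionSpec:
    """Truncated-power spline columns for one variable.

    Returns (v, v^2, ..., v^degree, (v-xi_1)_+^degree, ..., (v-xi_q)_+^degree)
    with no intercept column.  ``degree=1`` with no knots degenerates to the
    single linear term.
    """
    knots = [float(k) for k in knots]
    if any(b <= a for a, b in zip(knots, knots[1:])):
        raise ValueError("knots must be strictly increasing")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if arity is None:
        arity = var + 1
    terms = [Term("linear", var)]
    terms += [Term("power", var, exponent=p) for p in range(2, degree + 1)]
    terms += [Term("truncated_power", var, knot=k, degree=degree) for k in knots]
    return FunctionSpec(tuple(terms), arity)


# ---------------------------------------------------------------------------
# Term string syntax
# ---------------------------------------------------------------------------
#
#   "Att"                          linear
#   "Att^3"                        power
#   "Att*Strat"                    product
#   "tp(Att, knot=2, degree=3)"    single truncated-power column
#   "spline(Att, knots=[2,3], degree=3)"   expands to the full spline set

_SPLINE_RE = re.compile(
    r"^spline\(\s*(?P<var>\w+)\s*,\s*knots\s*=\s*\[(?P<knots>[^\]]*)\]\s*,"
    r"\s*degree\s*=\s*(?P<deg>\d+)\s*\)$"
)
_TP_RE = re.compile(
    r"^tp\(\s*(?P<var>\w+)\s*,\s*knot\s*=\s*(?P<knot>[-+0-9.eE]+)\s*,"
    r"\s*degree\s*=\s*(?P<deg>\d+)\s*\)$"
)
_POW_RE = re.compile(r"^(?P<var>\w+)\s*\^\s*(?P<exp>\d+)$")
_PROD_RE = re.compile(r"^(?P<a>\w+)\s*\*\s*(?P<b>\w+)$")


def _resolve(name: str, names: Sequence[str]) -> int:
    try:
        return list(names).index(name)
    except ValueError:
        raise ValueError(f"unknown variable {name!r}; known: {list(names)}") from None


def parse_term_string(s: str, names: Sequence[str]) -> list:
    """Parse one term string into a list of Terms (spline strings expand)."""
    s = s.strip()
    m = _SPLINE_RE.match(s)
    if m:
        knots = [float(x) for x in m.group("knots").split(",") if x.strip()]
        fs = spline_terms(_resolve(m.group("var"), names), knots,
                          int(m.group("deg")), arity=len(names))
        return list(fs.terms)
    m = _TP_RE.match(s)
    if m:
        return [Term("truncated_power", _resolve(m.group("var"), names),
                     knot=float(m.group("knot")), degree=int(m.group("deg")))]
    m = _POW_RE.match(s)
    if m:
        return [Term("power", _resolve(m.group("var"), names), exponent=int(m.group("exp")))]
    m = _PROD_RE.match(s)
    if m:
        return [Term("product", (_resolve(m.group("a"), names), _resolve(m.group("b"), names)))]
    if re.fullmatch(r"\w+", s):
        return [Term("linear", _resolve(s, names))]
    raise ValueError(f"cannot parse term {s!r}")


def term_to_string(term: Term, names: Sequence[str]) -> str:
    """Serialize one Term (inverse of parse_term_string for non-spline strings)."""
    if term.kind == "linear":
        return names[term.var]
    if term.kind == "power":
        return f"{names[term.var]}^{term.exponent}"
    if term.kind == "product":
        a, b = term.var
        return f"{names[a]}*{names[b]}"
    knot = term.knot
    knot_repr = int(knot) if float(knot).is_integer() else knot
    return f"tp({names[term.var]}, knot={knot_repr}, degree={term.degree})"


def parse_function(strings: Sequence[str], names: Sequence[str]) -> FunctionSpec:
    """Parse a list of term strings into one FunctionSpec over ``names``."""
    terms = []
    for s in strings:
        terms.extend(parse_term_string(s, names))
    return FunctionSpec(tuple(terms), len(names))
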