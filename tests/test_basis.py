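"""Polynomial / interaction / truncated-power basis evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semmix import basis
from semmix.model_spec import FunctionSpec, Term


@pytest.mark.parametrize(
    "term, values, expected",
    [
        (Term("truncated_power", 0, knot=2, degree=3), [4.0], 8.0),
        (Term("truncated_power", 0, knot=3, degree=3), [2.0], 0.0),
        (Term("product", (0, 1)), [2.0, 3.0], 6.0),
        (Term("linear", 1), [5.0, -1.5], -1.5),
        (Term("power", 0, exponent=4), [2.0], 16.0),
    ],
)
def test_eval_term_examples(term, values, expected):
    assert basis.eval_term(term, np.asarray(values)) == pytest.approx(expected)


def test_cubic_spline_basis_at_knot_and_beyond():
    """Truncated terms vanish at the first knot and activate beyond it."""
    fs = basis.spline_terms(0, [2.0, 3.0], 3)
    np.testing.assert_allclose(basis.eval_function(fs, np.array([2.0])),
                               [2.0, 4.0, 8.0, 0.0, 0.0])
    np.testing.assert_allclose(basis.eval_function(fs, np.array([4.0])),
                               [4.0, 16.0, 64.0, 8.0, 1.0])


def test_interaction_basis_all_ones_point():
    fs = FunctionSpec((Term("linear", 0), Term("linear", 1),
                       Term("product", (0, 1))), 2)
    np.testing.assert_allclose(basis.eval_function(fs, np.array([1.0, 1.0])),
                               [1.0, 1.0, 1.0])


def test_spline_terms_construction():
    fs = basis.spline_terms(0, [], 1)
    assert fs.out_dim == 1 and fs.terms[0].kind == "linear"
    fs = basis.spline_terms(0, [0.0], 2)
    kinds = [t.kind for t in fs.terms]
    assert kinds == ["linear", "power", "truncated_power"]
    with pytest.raises(ValueError):
        basis.spline_terms(0, [3.0, 2.0], 3)
    with pytest.raises(ValueError):
        basis.spline_terms(0, [1.0], 0)


def test_eval_function_arity_mismatch():
    fs = basis.spline_terms(0, [2.0], 3)
    with pytest.raises(ValueError):
        basis.eval_function(fs, np.zeros(3))


@settings(max_examples=40, deadline=None)
@given(coefs=st.lists(st.floats(-2, 2), min_size=5, max_size=5))
def test_spline_is_twice_continuously_differentiable(coefs):
    """Any coefficient combination gives a C2 function across both knots.

    The smooth polynomial part cancels in the jump: centred finite
    differences of s minus its left-piece polynomial extension isolate the
    discontinuity each truncated term could introduce, and all vanish at the
    O(eps) level for value, first and second differences.
    """
    fs = basis.spline_terms(0, [2.0, 3.0], 3)
    beta = np.asarray(coefs)
    scale = max(1.0, np.abs(beta).max())

    def s(v):
        return float(beta @ basis.eval_function(fs, np.array([v])))

    def left_extension(v, knot):
        # polynomial + already-active truncated terms, the knot's own term dropped
        val = beta[0] * v + beta[1] * v ** 2 + beta[2] * v ** 3
        if knot > 2.0:
            val += beta[3] * max(v - 2.0, 0.0) ** 3
        return val

    eps = 1e-6
    for knot in (2.0, 3.0):
        d = lambda v: s(v) - left_extension(v, knot)
        assert abs(d(knot + eps) - d(knot - eps)) < 1e-6 * scale
        assert abs(d(knot + eps) - d(knot - eps)) / (2 * eps) < 1e-6 * scale
        second = abs(d(knot + eps) - 2 * d(knot) + d(knot - eps)) / eps ** 2
        assert second <= (1 + 1e-9) * eps * scale


def test_spline_equals_plain_cubic_below_first_knot():
    fs = basis.spline_terms(0, [2.0, 3.0], 3)
    beta = np.array([0.3, -0.2, 0.05, 1.7, -2.4])
    for v in np.linspace(-3, 1.999, 25):
        spline_val = beta @ basis.eval_function(fs, np.array([v]))
        cubic_val = beta[0] * v + beta[1] * v ** 2 + beta[2] * v ** 3
        assert spline_val == pytest.approx(cubic_val, abs=1e-12)


def test_eval_function_matrix_matches_rowwise():
    fs = FunctionSpec((Term("linear", 0), Term("power", 1, exponent=2),
                       Term("product", (0, 1)),
                       Term("truncated_power", 0, knot=0.5, degree=2)), 2)
    X = np.random.default_rng(0).normal(size=(40, 2))
    M = basis.eval_function_matrix(fs, X)
    for i in range(40):
        np.testing.assert_allclose(M[i], basis.eval_function(fs, X[i]))


@pytest.mark.parametrize("s, n_terms", [
    ("Att", 1), ("Att^3", 1), ("Att*Strat", 1),
    ("tp(Att, knot=2, degree=3)", 1),
    ("spline(Att, knots=[2,3], degree=3)", 5),
])
def test_parse_term_strings(s, n_terms):
    names = ["Att", "Strat"]
    terms = basis.parse_term_string(s, names)
    assert len(terms) == n_terms
    # non-spline strings round-trip exactly
    if n_terms == 1:
        assert basis.term_to_string(terms[0], names) == s


def test_parse_unknown_variable_raises():
    with pytest.raises(ValueError, match="unknown variable"):
        basis.parse_term_string("Foo^2", ["Att"])
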