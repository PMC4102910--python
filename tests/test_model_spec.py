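"""Model declaration, identification rules, parameter indexing, config I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semmix import examples
from semmix.model_spec import (
    FunctionSpec,
    IndicatorSpec,
    MeasurementSpec,
    MixtureSpec,
    ModelSpec,
    StructuralSpec,
    Term,
    check_disjoint_terms,
    pack_parameters,
    parameter_index,
    spec_from_yaml,
    spec_to_yaml,
    unpack_parameters,
    validate_identification,
)


# ---------------------------------------------------------------------------
# Terms and function sets
# ---------------------------------------------------------------------------


def test_term_invariants():
    with pytest.raises(ValueError):
        Term("product", (1, 1))
    with pytest.raises(ValueError):
        Term("power", 0, exponent=0)
    with pytest.raises(ValueError):
        Term("truncated_power", 0, knot=1.0, degree=0)
    # exponent-1 power collapses to linear; product variable order canonical
    assert Term("power", 0, exponent=1) == Term("linear", 0)
    assert Term("product", (2, 0)) == Term("product", (0, 2))


def test_function_spec_rejects_duplicates_and_out_of_range():
    with pytest.raises(ValueError, match="duplicate"):
        FunctionSpec((Term("linear", 0), Term("linear", 0)), 1)
    with pytest.raises(ValueError, match="outside arity"):
        FunctionSpec((Term("linear", 3),), 2)


def test_check_disjoint_terms():
    a = FunctionSpec((Term("linear", 0), Term("power", 0, exponent=2)), 1)
    b_same = FunctionSpec((Term("linear", 0), Term("power", 0, exponent=2)), 1)
    b_power = FunctionSpec((Term("power", 0, exponent=2),), 1)
    assert not check_disjoint_terms(a, b_same)
    assert check_disjoint_terms(FunctionSpec((Term("linear", 0),), 1),
                                FunctionSpec((Term("power", 0, exponent=2),), 1))
    assert check_disjoint_terms(FunctionSpec.empty(1), b_power)
    # symmetry
    assert check_disjoint_terms(a, b_power) == check_disjoint_terms(b_power, a)
    with pytest.raises(ValueError, match="arity"):
        check_disjoint_terms(FunctionSpec.empty(1), FunctionSpec.empty(2))


def test_indicator_spec_threshold_invariants():
    with pytest.raises(ValueError):
        IndicatorSpec(link="ordered", n_categories=3, thresholds=[1.0, 0.5])
    with pytest.raises(ValueError):
        IndicatorSpec(link="identity", thresholds=[0.0])
    lk = IndicatorSpec(link="ordered", n_categories=3, thresholds=[0.0, 1.0])
    assert lk.thresholds.shape == (2,)


def test_structural_spec_rejects_cycles():
    # Y's equation referencing Y itself (through a term) is non-recursive
    F = FunctionSpec((Term("linear", 1),), 2)
    with pytest.raises(ValueError, match="non-recursive"):
        StructuralSpec(
            latent_names=("X", "Y"), n_exog=1, alpha=np.zeros((1, 2)),
            Psi_exog=np.eye(1), psi_end=np.array([0.5]),
            B=np.array([[0.0], [0.7]]), Gamma=np.zeros((2, 0)),
            F=F, G=FunctionSpec.empty(0),
        )


# ---------------------------------------------------------------------------
# Identification rules
# ---------------------------------------------------------------------------


def test_school_model_passes_all_rules(school_spec):
    report = validate_identification(school_spec)
    assert report.ok, str(report)
    assert [r.rule for r in report.results] == [1, 2, 3, 4]


def _covariate_collinear_model():
    """g1 = G1 = (x11) with an indicator loading on the endogenous latent."""
    f = FunctionSpec((Term("linear", 0),), 1)
    g = FunctionSpec((Term("linear", 0),), 1)
    meas = MeasurementSpec(
        nu=np.zeros(1), Lambda=np.ones((1, 1)), K=np.ones((1, 1)),
        Theta=np.eye(1) * 0.3, f=f, g=g,
        nu_free=np.zeros(1, bool), Lambda_free=np.zeros((1, 1), bool))
    st = StructuralSpec(
        latent_names=("Eta",), n_exog=0, alpha=np.zeros((1, 1)),
        Psi_exog=np.zeros((0, 0)), psi_end=np.array([0.5]),
        B=np.zeros((1, 0)), Gamma=np.ones((1, 1)),
        F=FunctionSpec.empty(1), G=g)
    return ModelSpec(y_names=("y1",), x1_names=("x11",), measurement1=meas,
                     structural1=st, mixture1=MixtureSpec(1, h=FunctionSpec.empty(1)))


def test_shared_covariate_term_fails_rule2_naming_the_culprit():
    report = validate_identification(_covariate_collinear_model())
    rule2 = report.results[1]
    assert not rule2.passed
    assert "x11" in rule2.detail


def test_single_class_model_needs_no_ordering_constraint():
    spec = examples.quadratic_factor_model()
    report = validate_identification(spec)
    assert report.results[3].passed  # rule 4


def test_missing_scaling_loading_fails_rule1():
    spec = examples.quadratic_factor_model()
    spec.measurement1.Lambda_free[:, 0] = True  # free every Xi loading
    report = validate_identification(spec)
    assert not report.results[0].passed
    assert "Xi" in report.results[0].detail


def test_mixture_without_ordering_fails_rule4():
    spec = examples.random_intercept_mixture_model(n_classes=2)
    spec.ordered_block = None
    report = validate_identification(spec)
    assert not report.results[3].passed


def test_validation_is_pure(school_spec):
    r1 = validate_identification(school_spec)
    r2 = validate_identification(school_spec)
    assert str(r1) == str(r2)


# ---------------------------------------------------------------------------
# Parameter index / pack / unpack
# ---------------------------------------------------------------------------


def test_parameter_index_contents(school_spec):
    names = parameter_index(school_spec)
    assert len(names) == len(set(names))
    # ten level-1 spline coefficients (five per latent predictor)
    spline_coefs = [n for n in names if n.startswith("L1.B.Math.")]
    assert len(spline_coefs) == 10
    # three level-2 structural coefficients including the interaction
    assert "L2.B.alpha3.Prob*Soc" in names
    # class-indexed level-2 means, both classes
    for latent in ("Prob", "Soc"):
        for cls in ("c1", "c2"):
            assert f"L2.mean.{latent}.{cls}" in names
    # fixed scaling loadings are absent
    assert "L1.lam.y1.Att" not in names
    # single level-1 class: no level-1 logit parameters
    assert not any(n.startswith("L1.logit") for n in names)


def test_single_class_model_lists_no_logits():
    names = parameter_index(examples.quadratic_factor_model())
    assert not any("logit" in n for n in names)
    assert names == ["L1.B.Y.Xi", "L1.B.Y.Xi^2"]


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 2 ** 31 - 1))
def test_pack_unpack_roundtrip_is_identity(school_spec, seed):
    names = parameter_index(school_spec)
    rng = np.random.default_rng(seed)
    vec = rng.normal(size=len(names))
    # keep covariance diagonals positive so spec invariants hold
    base = pack_parameters(school_spec)
    vec = base + 0.01 * vec
    spec2 = unpack_parameters(school_spec, vec)
    np.testing.assert_allclose(pack_parameters(spec2), vec)


def test_yaml_roundtrip_preserves_everything(school_spec):
    text = spec_to_yaml(school_spec)
    spec2 = spec_from_yaml(text)
    assert parameter_index(spec2) == parameter_index(school_spec)
    np.testing.assert_allclose(pack_parameters(spec2), pack_parameters(school_spec))
    assert spec2.ordered_block == school_spec.ordered_block
    assert validate_identification(spec2).ok
    # serialization is stable
    assert spec_to_yaml(spec2) == text


def test_yaml_roundtrip_single_level():
    spec = examples.quadratic_measurement_model()
    spec2 = spec_from_yaml(spec_to_yaml(spec))
    assert not spec2.has_level2
    np.testing.assert_allclose(pack_parameters(spec2), pack_parameters(spec))
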