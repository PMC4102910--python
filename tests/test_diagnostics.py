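"""EPSR, posterior summaries, DIC, relabeling, quadrature oracle."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from semmix import diagnostics, estimator, examples, simulator
from semmix.diagnostics import epsr, marginal_loglik_small, relabel, summarize
from semmix.estimator import PosteriorDraws, SamplerSettings
from semmix.simulator import ClusterSizePlan, simulate_dataset


def _fake_draws(arr, names=None):
    arr = np.asarray(arr, dtype=float)
    names = names or [f"p{i}" for i in range(arr.shape[2])]
    return PosteriorDraws(
        names=names, draws=arr, loglik=np.zeros(arr.shape[:2]),
        eta1_mean=np.zeros((0, 0)), eta2_mean=None, acceptance={},
        settings=None, spec_hash="")


# ---------------------------------------------------------------------------
# EPSR
# ---------------------------------------------------------------------------


def test_epsr_identical_chains_is_exactly_one():
    chain = np.random.default_rng(0).normal(size=(1, 500, 2))
    draws = _fake_draws(np.repeat(chain, 3, axis=0))
    assert (epsr(draws) == 1.0).all()


def test_epsr_offset_chains_flags_nonconvergence():
    rng = np.random.default_rng(1)
    base = rng.normal(size=(2, 400, 1))
    base[1] += 5.0 * base[0].std()  # second chain displaced by 5 within-chain SDs
    e = float(epsr(_fake_draws(base)).iloc[0])
    # direct formula evaluation
    W = base.var(axis=1, ddof=1).mean()
    B = 400 * base.mean(axis=1).var(ddof=1)
    expected = np.sqrt((399 / 400 * W + B / 400) / W)
    assert e == pytest.approx(expected)
    assert e > 1.2


def test_epsr_of_iid_chains_is_near_one():
    rng = np.random.default_rng(2)
    draws = _fake_draws(rng.normal(size=(3, 10_000, 4)))
    e = epsr(draws)
    assert ((e >= 0.999) & (e < 1.05)).all()


def test_epsr_requires_multiple_chains():
    with pytest.raises(ValueError, match="chains"):
        epsr(_fake_draws(np.zeros((1, 100, 1))))
    with pytest.raises(ValueError, match="iterations"):
        epsr(_fake_draws(np.zeros((2, 5, 1))))


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def test_summarize_constant_draws():
    table = summarize(_fake_draws(np.full((2, 50, 1), 0.5)))
    row = table.iloc[0]
    assert row["mean"] == 0.5 and row["se"] == 0.0
    assert np.isinf(row["t"]) and row["t"] > 0
    assert row["p2.5"] == row["p50"] == row["p97.5"] == 0.5


def test_summarize_standard_normal_percentiles():
    rng = np.random.default_rng(3)
    table = summarize(_fake_draws(rng.standard_normal((1, 100_000, 1))))
    row = table.iloc[0]
    assert abs(row["p2.5"] - (-1.96)) < 0.02
    assert abs(row["p50"]) < 0.02
    assert abs(row["p97.5"] - 1.96) < 0.02


def test_t_value_is_mean_over_sd():
    rng = np.random.default_rng(4)
    draws = _fake_draws(0.558 + 0.101 * rng.standard_normal((1, 200_000, 1)))
    t = summarize(draws)["t"].iloc[0]
    assert t == pytest.approx(0.558 / 0.101, rel=0.02)


def test_summarize_invariant_to_chain_order():
    rng = np.random.default_rng(5)
    arr = rng.normal(size=(3, 200, 2))
    t1 = summarize(_fake_draws(arr))
    t2 = summarize(_fake_draws(arr[::-1].copy()))
    assert np.allclose(t1["mean"], t2["mean"])
    assert np.allclose(t1["p50"], t2["p50"])


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------


def test_dic_positive_complexity_on_fit():
    spec = examples.random_intercept_mixture_model(n_classes=1)
    data = simulate_dataset(spec, 40, ClusterSizePlan(n=5), seed=61)
    draws = estimator.run_gibbs(spec, data, settings=SamplerSettings(
        chains=2, iterations=800, burn_in=400, seed=62))
    d, p_d = diagnostics.dic(draws, spec, data)
    assert np.isfinite(d)
    assert p_d > 0


def test_conditional_dic_requires_recorded_loglik():
    spec = examples.random_intercept_mixture_model(n_classes=1)
    data = simulate_dataset(spec, 20, ClusterSizePlan(n=4), seed=63)
    draws = estimator.run_gibbs(spec, data, settings=SamplerSettings(
        chains=2, iterations=200, burn_in=100, seed=64, record_loglik=False))
    with pytest.raises(ValueError, match="log-likelihood"):
        diagnostics.dic(draws, spec, data, variant="conditional")


def test_marginal_dic_matches_quadrature_oracle():
    """The linear-scope marginal deviance agrees with the generic adaptive
    Gauss-Hermite oracle on a two-class random-intercept model."""
    from semmix.diagnostics import _linear_marginal_loglik

    spec = examples.random_intercept_mixture_model(n_classes=2, gap=0.4)
    data = simulate_dataset(spec, 20, ClusterSizePlan(n=3), seed=66)
    a = _linear_marginal_loglik(spec, data)
    b = marginal_loglik_small(spec, data, n_nodes=30)
    assert abs(a - b) < 1e-6


# ---------------------------------------------------------------------------
# Quadrature oracle
# ---------------------------------------------------------------------------


def test_oracle_matches_closed_form_linear_factor_model():
    spec = examples.quadratic_measurement_model(beta_lin=0.5, beta_quad=0.0)
    data = simulate_dataset(spec, 30, ClusterSizePlan(n=1), seed=9)
    got = marginal_loglik_small(spec, data, n_nodes=40)
    lam = np.array([[1.0], [0.8], [0.5]])
    cov = lam @ lam.T + np.diag([0.25, 0.25, 0.3])
    want = multivariate_normal(mean=np.zeros(3), cov=cov).logpdf(
        data.y.to_numpy()).sum()
    assert abs(got - want) < 1e-6


def test_oracle_two_level_matches_closed_form():
    spec = examples.hierarchical_normal_model()
    data = simulate_dataset(spec, 15, ClusterSizePlan(n=4), seed=5)
    got = marginal_loglik_small(spec, data, n_nodes=30)
    y = data.y["y1"].to_numpy()
    want = 0.0
    for k in range(15):
        yy = y[data.cluster_of == k]
        n = len(yy)
        cov = 0.3 * np.ones((n, n)) + (0.2 + 0.4) * np.eye(n)
        want += multivariate_normal(mean=0.5 * np.ones(n), cov=cov).logpdf(yy)
    assert abs(got - want) < 1e-6


def test_oracle_stable_under_node_doubling():
    spec = examples.quadratic_measurement_model()
    data = simulate_dataset(spec, 50, ClusterSizePlan(n=1), seed=10)
    l1 = marginal_loglik_small(spec, data, n_nodes=20)
    l2 = marginal_loglik_small(spec, data, n_nodes=40)
    assert abs(l1 - l2) < 1e-4


def test_oracle_refuses_out_of_scope_models(school_spec, school_data):
    with pytest.raises(ValueError, match="dimension"):
        marginal_loglik_small(school_spec, school_data)


# ---------------------------------------------------------------------------
# Relabeling
# ---------------------------------------------------------------------------


def test_relabel_restores_monotone_class_means():
    rng = np.random.default_rng(6)
    kept = 400
    c1 = 1.0 + 0.05 * rng.standard_normal((1, kept))
    c2 = 2.0 + 0.05 * rng.standard_normal((1, kept))
    other = rng.normal(size=(1, kept))
    arr = np.stack([c1[0], c2[0], other[0]], axis=1)[None, :, :]
    # permute labels on half of the iterations
    flip = rng.random(kept) < 0.5
    arr[0, flip, 0], arr[0, flip, 1] = arr[0, flip, 1].copy(), arr[0, flip, 0].copy()
    draws = _fake_draws(arr, names=["L2.mean.u.c1", "L2.mean.u.c2", "L2.psi.u.u"])
    fixed = relabel(draws, level=2)
    assert np.all(fixed.param("L2.mean.u.c1") < fixed.param("L2.mean.u.c2"))
    # untouched parameters stay in place
    np.testing.assert_array_equal(fixed.param("L2.psi.u.u"), other)


def test_relabel_is_identity_when_already_ordered():
    rng = np.random.default_rng(7)
    kept = 200
    arr = np.stack([1 + 0.01 * rng.standard_normal(kept),
                    2 + 0.01 * rng.standard_normal(kept)], axis=1)[None]
    draws = _fake_draws(arr, names=["L2.mean.u.c1", "L2.mean.u.c2"])
    fixed = relabel(draws, level=2)
    np.testing.assert_array_equal(fixed.draws, draws.draws)


def test_relabel_single_class_is_noop():
    draws = _fake_draws(np.zeros((1, 50, 1)), names=["L2.mean.u"])
    assert relabel(draws, level=2) is draws


def test_epsr_trace_plot_written(tmp_path):
    rng = np.random.default_rng(8)
    draws = _fake_draws(rng.normal(size=(2, 300, 3)))
    out = tmp_path / "trace.png"
    diagnostics.plot_epsr_trace(draws, str(out))
    assert out.exists() and out.stat().st_size > 0
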