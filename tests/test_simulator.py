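"""Generative sampling: class draws, noise-free limits, moment recovery, MAR."""

import numpy as np
import pytest

from semmix import examples, simulator
from semmix.model_spec import FunctionSpec, MixtureSpec, Term
from semmix.simulator import (
    ClusterSizePlan,
    apply_mar_mask,
    class_probabilities,
    draw_class,
    draw_level1,
    draw_level2,
    marginal_exog_mean,
    model_implied_moments,
    simulate_dataset,
)


# ---------------------------------------------------------------------------
# Class draws
# ---------------------------------------------------------------------------


def test_symmetric_logit_gives_uniform_probabilities():
    mix = MixtureSpec(2, h=FunctionSpec.empty(0))
    np.testing.assert_allclose(class_probabilities(mix, np.zeros(0)), [0.5, 0.5])


def test_softmax_arithmetic():
    mix = MixtureSpec(2, a=[0.0, -np.log(3.0)], h=FunctionSpec.empty(0))
    np.testing.assert_allclose(class_probabilities(mix, np.zeros(0)),
                               [0.75, 0.25])


def test_class_frequencies_match_probabilities(rng):
    # the school mixture proportions: P(class 1) = 0.532
    mix = MixtureSpec(2, a=[0.0, float(np.log(0.468 / 0.532))],
                      h=FunctionSpec.empty(0))
    draws = np.array([draw_class(mix, np.zeros(0), rng) for _ in range(10 ** 5)])
    assert abs((draws == 0).mean() - 0.532) < 0.005


def test_covariate_dependent_class_probability():
    h = FunctionSpec((Term("linear", 0),), 1)
    mix = MixtureSpec(2, a=[0.0, 0.0], b=[[0.0], [2.0]], h=h)
    p_low = class_probabilities(mix, np.array([-2.0]))
    p_high = class_probabilities(mix, np.array([2.0]))
    assert p_high[1] > 0.9 > 0.5 > p_low[1]


# ---------------------------------------------------------------------------
# Deterministic limits and closed forms
# ---------------------------------------------------------------------------


def test_noise_free_limit_returns_mean_path(school_spec, rng):
    import copy

    spec = copy.deepcopy(school_spec)
    tiny = 1e-12
    spec.structural2.Psi_exog[:] = np.eye(2) * tiny
    spec.structural2.psi_end[:] = tiny
    spec.measurement2.Theta[:] = np.eye(6) * tiny
    mu = spec.structural2.alpha[0]
    eta2, z, _ = draw_level2(spec, 0, np.zeros(0), rng)
    # exogenous latents collapse to their class means
    np.testing.assert_allclose(eta2[:2], mu[:2], atol=1e-5)
    # alpha3 equals the deterministic interaction path
    b3, b4, b5 = 0.558, 0.442, -0.289
    expected = -0.365 + b3 * mu[0] + b4 * mu[1] + b5 * mu[0] * mu[1]
    assert eta2[2] == pytest.approx(expected, abs=1e-5)
    # z equals nu + Lambda f2(eta2)
    me2 = spec.measurement2
    np.testing.assert_allclose(
        z, me2.nu + me2.Lambda @ eta2[:2], atol=1e-5)


def test_interaction_mean_matches_quadratic_closed_form(school_spec):
    """With Prob = Soc = c fixed, E[alpha3] = mu3 + (b3+b4) c + b5 c^2."""
    import copy

    spec = copy.deepcopy(school_spec)
    c = 2.4
    spec.structural2.alpha[:, :2] = c
    spec.structural2.Psi_exog[:] = np.eye(2) * 1e-12
    rng = np.random.default_rng(7)
    draws = np.array([draw_level2(spec, 0, np.zeros(0), rng)[0][2]
                      for _ in range(4000)])
    expected = -0.365 + (0.558 + 0.442) * c - 0.289 * c ** 2
    se = draws.std() / np.sqrt(len(draws))
    assert abs(draws.mean() - expected) < 3 * se + 1e-9


def test_level2_class_mean_recovery(school_spec, rng):
    draws = np.array([draw_level2(school_spec, 0, np.zeros(0), rng)[0][0]
                      for _ in range(10 ** 4)])
    se = np.sqrt(0.291 / len(draws))
    assert abs(draws.mean() - 1.921) < 3 * se


def test_ordered_link_threshold_rule(rng):
    import copy

    from semmix.model_spec import IndicatorSpec

    spec = copy.deepcopy(examples.quadratic_factor_model())
    spec.y_links = tuple(
        [IndicatorSpec(link="ordered", n_categories=2, thresholds=[0.0])]
        + list(spec.y_links[1:]))
    spec.measurement1.Theta[0, 0] = 1.0
    found = set()
    for _ in range(200):
        eta1, y, ystar = draw_level1(spec, 0, 0, None, np.zeros(0), rng)
        assert y[0] == (1.0 if ystar[0] < 0 else 2.0)
        found.add(y[0])
    assert found == {1.0, 2.0}


# ---------------------------------------------------------------------------
# Full-dataset properties
# ---------------------------------------------------------------------------


def test_simulate_is_deterministic(school_spec):
    plan = ClusterSizePlan(n=5)
    d1 = simulate_dataset(school_spec, 20, plan, seed=9)
    d2 = simulate_dataset(school_spec, 20, plan, seed=9)
    assert d1.equals(d2)
    np.testing.assert_array_equal(d1.truth["eta2"], d2.truth["eta2"])


def test_growing_cluster_count_preserves_existing_clusters(school_spec):
    plan20 = ClusterSizePlan(n=4)
    d_small = simulate_dataset(school_spec, 20, plan20, seed=3)
    d_large = simulate_dataset(school_spec, 30, ClusterSizePlan(n=4), seed=3)
    np.testing.assert_allclose(d_small.z.to_numpy(), d_large.z.to_numpy()[:20])
    n_small = d_small.n_individuals
    np.testing.assert_allclose(d_small.y.to_numpy(),
                               d_large.y.to_numpy()[:n_small])


def test_study_design_dimensions(school_spec):
    plan = ClusterSizePlan.from_total(226, 1474)
    data = simulate_dataset(school_spec, 226, plan, seed=1)
    assert data.n_clusters == 226
    assert data.n_individuals == 1474
    assert data.y.shape == (1474, 9)
    assert data.z.shape == (226, 6)


def test_linear_single_class_moment_recovery():
    """Sample moments of a linear two-level model match the Lambda-based
    model-implied moments (elementwise within 3 MC standard errors)."""
    spec = examples.school_model(n_level2_classes=1)
    # drop the non-linear terms so the closed-form oracle applies
    spec.structural1.B[:] = 0.0
    spec.structural1.B[2, 0] = 0.3   # linear Att -> Math
    spec.structural1.B[2, 5] = 0.2   # linear Strat -> Math
    spec.structural1.B_free = spec.structural1.B != 0
    spec.structural2.B[2] = [0.558, 0.442, 0.0]
    spec.structural2.B_free = spec.structural2.B != 0
    oracle = model_implied_moments(spec)
    n = 20_000
    data = simulate_dataset(spec, 2000, ClusterSizePlan(n=10), seed=77)
    y = data.y.to_numpy()[:n]
    emp_mean = y.mean(axis=0)
    emp_cov = np.cov(y.T)
    se_mean = np.sqrt(np.diag(oracle["cov_y"]) / n)
    assert np.all(np.abs(emp_mean - oracle["mean_y"]) < 3.2 * se_mean)
    S = oracle["cov_y"]
    se_cov = np.sqrt((np.outer(np.diag(S), np.diag(S)) + S ** 2) / n)
    # clustered draws are dependent; inflate the independent-sample SE by the
    # design effect of cluster size 10 as a conservative bound
    assert np.all(np.abs(emp_cov - S) < 3.2 * se_cov * np.sqrt(10))


def test_mixture_marginal_mean(school_spec):
    data = simulate_dataset(school_spec, 3000, ClusterSizePlan(n=1), seed=13)
    target = marginal_exog_mean(school_spec, level=2)
    emp = data.truth["eta2"][:, :2].mean(axis=0)
    se = np.sqrt(np.array([0.291, 0.239]) / 3000) + \
        0.1 / np.sqrt(3000)  # between-class spread
    assert np.all(np.abs(emp - target) < 4 * se)


# ---------------------------------------------------------------------------
# MAR masking
# ---------------------------------------------------------------------------


def test_mar_rate_zero_is_identity(school_data):
    out = apply_mar_mask(school_data, 0.0, "y1", seed=5)
    assert out is school_data


def test_mar_rate_calibration(school_spec):
    data = simulate_dataset(school_spec, 250, ClusterSizePlan(n=6), seed=21)
    masked = apply_mar_mask(data, 0.10, "y1", seed=22)
    frac = masked.y_mask[:, 1:].mean()  # predictor column never masked
    assert abs(frac - 0.10) < 0.01
    assert not masked.y_mask[:, 0].any()
    # masked cells are NaN, not zero-filled
    assert masked.y.to_numpy()[masked.y_mask].size == np.isnan(
        masked.y.to_numpy()[masked.y_mask]).sum()


def test_mar_is_idempotent_on_masked_cells(school_data):
    m1 = apply_mar_mask(school_data, 0.1, "y1", seed=5)
    m2 = apply_mar_mask(m1, 0.1, "y1", seed=6)
    assert (m2.y_mask & m1.y_mask).sum() == m1.y_mask.sum()


def test_mar_depends_on_predictor(school_spec):
    data = simulate_dataset(school_spec, 400, ClusterSizePlan(n=5), seed=31)
    masked = apply_mar_mask(data, 0.2, "y1", seed=32)
    p = data.y["y1"].to_numpy()
    miss_rate_high = masked.y_mask[p > np.median(p), 1:].mean()
    miss_rate_low = masked.y_mask[p <= np.median(p), 1:].mean()
    assert miss_rate_high > miss_rate_low + 0.05


def test_cluster_size_plans():
    plan = ClusterSizePlan.from_total(226, 1474)
    sizes = plan.resolve(226)
    assert sizes.sum() == 1474 and set(sizes) == {6, 7}
    with pytest.raises(ValueError):
        ClusterSizePlan(n=3, sizes=[1, 2]).resolve(2)
    with pytest.raises(ValueError):
        ClusterSizePlan(n=0).resolve(5)
    with pytest.raises(ValueError):
        simulate_dataset(examples.quadratic_factor_model(), 0,
                         ClusterSizePlan(n=1), seed=1)
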