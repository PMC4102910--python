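"""Sampler correctness: analytic posteriors, oracles, determinism, augmentation."""

import copy

import numpy as np
import pytest
from scipy import stats

from semmix import diagnostics, estimator, examples, simulator
from semmix.estimator import GibbsSampler, PriorSpec, SamplerSettings, run_gibbs
from semmix.simulator import ClusterSizePlan, apply_mar_mask, simulate_dataset


def _mcse_pooled(x):
    """MCSE of the pooled posterior mean from per-chain batch means."""
    per = np.array([diagnostics.mcse(x[c]) for c in range(x.shape[0])])
    return float(np.sqrt(np.mean(per ** 2) / x.shape[0]))


# ---------------------------------------------------------------------------
# Conjugate / analytic correctness
# ---------------------------------------------------------------------------


def test_normal_normal_posterior_matches_closed_form():
    """Hierarchical normal-normal submodel: the sampler's posterior for the
    grand mean agrees with the exact conjugate posterior."""
    mu, su2, sz2, th = 0.5, 0.3, 0.2, 0.4
    spec = examples.hierarchical_normal_model(mu, su2, sz2, th)
    data = simulate_dataset(spec, 40, ClusterSizePlan(n=8), seed=7)
    draws = run_gibbs(spec, data, settings=SamplerSettings(
        chains=2, iterations=1500, burn_in=500, seed=3, record_loglik=False))
    got = draws.param("L2.mean.u")

    y = data.y["y1"].to_numpy()
    nk = np.bincount(data.cluster_of)
    ybar = np.bincount(data.cluster_of, weights=y) / nk
    se2 = sz2 + th
    prior_var = su2 * PriorSpec().h0
    prec = (1.0 / (su2 + se2 / nk)).sum() + 1.0 / prior_var
    mean = (ybar / (su2 + se2 / nk)).sum() / prec

    assert abs(got.mean() - mean) < 3 * _mcse_pooled(got)
    assert abs(got.reshape(-1).var() - 1.0 / prec) < 0.05 / prec


def test_same_seed_gives_identical_draws():
    spec = examples.hierarchical_normal_model()
    data = simulate_dataset(spec, 20, ClusterSizePlan(n=5), seed=1)
    s = SamplerSettings(chains=2, iterations=300, burn_in=100, seed=11,
                        record_loglik=False)
    d1 = run_gibbs(spec, data, settings=s)
    d2 = run_gibbs(spec, data, settings=s)
    np.testing.assert_array_equal(d1.draws, d2.draws)


def test_identification_failure_refused():
    spec = examples.quadratic_factor_model()
    spec.measurement1.Lambda_free[:, 0] = True
    data = simulate_dataset(examples.quadratic_factor_model(), 10,
                            ClusterSizePlan(n=1), seed=1)
    with pytest.raises(ValueError, match="not identified"):
        run_gibbs(spec, data, settings=SamplerSettings(
            chains=1, iterations=20, burn_in=10))


def test_poisson_link_estimation_refused():
    from semmix.model_spec import IndicatorSpec

    spec = copy.deepcopy(examples.quadratic_factor_model())
    spec.y_links = tuple([IndicatorSpec(link="poisson_log")] + list(spec.y_links[1:]))
    data = simulate_dataset(spec, 10, ClusterSizePlan(n=1), seed=1)
    with pytest.raises(ValueError, match="simulation-only"):
        run_gibbs(spec, data, settings=SamplerSettings(
            chains=1, iterations=20, burn_in=10))


def test_flat_prior_linear_coefficient_matches_least_squares():
    """Near-noiseless measurement turns the latent regression into an
    observable one; with a flat-ish prior the posterior mean of the slope
    matches ordinary least squares."""
    from semmix.model_spec import (FunctionSpec, MeasurementSpec, MixtureSpec,
                                   ModelSpec, StructuralSpec, Term)

    f = FunctionSpec((Term("linear", 0), Term("linear", 1)), 2)
    meas = MeasurementSpec(
        nu=np.zeros(2), Lambda=np.eye(2), K=np.zeros((2, 0)),
        Theta=np.eye(2) * 1e-4, f=f, g=FunctionSpec.empty(0),
        nu_free=np.zeros(2, bool), Lambda_free=np.zeros((2, 2), bool),
        theta_free=False)
    struct = StructuralSpec(
        latent_names=("X", "Y"), n_exog=1, alpha=np.zeros((1, 2)),
        Psi_exog=np.eye(1), psi_end=np.array([0.4]),
        B=np.array([[0.0], [0.6]]), Gamma=np.zeros((2, 0)),
        F=FunctionSpec((Term("linear", 0),), 2), G=FunctionSpec.empty(0),
        B_free=np.array([[False], [True]]), alpha_free=np.array([False, False]),
        psi_free=True)
    spec = ModelSpec(y_names=("yx", "yy"), x1_names=(), measurement1=meas,
                     structural1=struct, mixture1=MixtureSpec(1))
    data = simulate_dataset(spec, 300, ClusterSizePlan(n=1), seed=5)
    draws = run_gibbs(spec, data, priors=PriorSpec(h0=1e4),
                      settings=SamplerSettings(chains=2, iterations=1200,
                                               burn_in=400, seed=9,
                                               record_loglik=False))
    b = draws.param("L1.B.Y.X")
    yx = data.y["yx"].to_numpy()
    yy = data.y["yy"].to_numpy()
    ols = float(yx @ yy / (yx @ yx))
    assert abs(b.mean() - ols) < 3 * _mcse_pooled(b) + 2e-3


def test_exact_linear_latent_draw_matches_factor_score_posterior():
    """With all parameters fixed, exact latent draws for a linear factor model
    reproduce the closed-form Bayesian factor-score posterior (KS test)."""
    spec = examples.quadratic_measurement_model(beta_lin=0.0, beta_quad=0.0)
    # freeze the outcome loadings too: nothing is free, latents only
    spec.measurement1.Lambda_free[:] = False
    spec.measurement1.Lambda[2] = [0.0, 0.0]
    # drop the quadratic column entirely so the exact linear path is used
    from semmix.model_spec import FunctionSpec, Term

    spec.measurement1.f = FunctionSpec((Term("linear", 0),), 1)
    spec.measurement1.Lambda = np.array([[1.0], [0.8], [0.0]])
    spec.measurement1.Lambda_free = np.zeros((3, 1), bool)
    data = simulate_dataset(spec, 30, ClusterSizePlan(n=1), seed=2)
    sampler = GibbsSampler(spec, data, PriorSpec(),
                           SamplerSettings(chains=1, iterations=10, burn_in=5))
    rng = np.random.default_rng(4)
    st = sampler.init_state(rng)
    n_draws = 4000
    collected = np.empty(n_draws)
    for i in range(n_draws):
        sampler.update_latents(st, rng, adapt=False)
        collected[i] = st.eta1[0, 0]
    # closed form for individual 0
    lam = np.array([1.0, 0.8, 0.0])
    th = np.diag(spec.measurement1.Theta)
    prec = 1.0 + (lam ** 2 / th).sum()
    mean = (lam / th) @ data.y.to_numpy()[0] / prec
    ks = stats.kstest(collected, "norm", args=(mean, 1.0 / np.sqrt(prec)))
    assert ks.pvalue > 0.01


def test_well_separated_classes_classified_correctly():
    """Two level-2 classes five marginal SDs apart: posterior class
    assignment matches the Bayes-rule oracle and the generating truth."""
    spec = examples.random_intercept_mixture_model(
        n_classes=2, mu=0.0, gap=2.7, sigma_u2=0.25, sigma_z2=0.1, theta=0.25)
    data = simulate_dataset(spec, 150, ClusterSizePlan(n=8), seed=17)
    draws = run_gibbs(spec, data, settings=SamplerSettings(
        chains=2, iterations=1200, burn_in=600, seed=18, record_loglik=False))
    assigned = (draws.d_freq[:, 1] > 0.5).astype(int)
    truth = data.truth["D"]
    # Bayes oracle on cluster means under the generating parameters
    nk = np.bincount(data.cluster_of)
    ybar = np.bincount(data.cluster_of, weights=data.y["y1"].to_numpy()) / nk
    se2 = 0.1 + 0.25
    var_k = 0.25 + se2 / nk
    ll0 = -0.5 * (ybar - 0.0) ** 2 / var_k
    ll1 = -0.5 * (ybar - 2.7) ** 2 / var_k
    oracle = (ll1 > ll0).astype(int)
    oracle_acc = (oracle == truth).mean()
    sampler_acc = (assigned == truth).mean()
    assert oracle_acc > 0.97
    assert sampler_acc >= oracle_acc - 0.02


def test_mh_acceptance_in_target_band_after_adaptation(school_spec):
    data = simulate_dataset(school_spec, 40, ClusterSizePlan(n=7), seed=23)
    draws = run_gibbs(school_spec, data, settings=SamplerSettings(
        chains=1, iterations=800, burn_in=400, seed=24, record_loglik=False))
    lo, hi = 0.2, 0.5
    assert lo < draws.acceptance["eta1"] < hi
    assert lo < draws.acceptance["eta2"] < hi


def test_ordered_probit_recovery():
    """Ordered indicators via truncated-normal augmentation: loadings and
    interior thresholds recovered from categorical data."""
    from semmix.model_spec import (FunctionSpec, IndicatorSpec, MeasurementSpec,
                                   MixtureSpec, ModelSpec, StructuralSpec, Term)

    f = FunctionSpec((Term("linear", 0),), 1)
    lam = np.array([[1.0], [0.9], [0.8]])
    lam_free = np.array([[False], [True], [True]])
    links = tuple(IndicatorSpec(link="ordered", n_categories=4,
                                thresholds=[0.0, 0.8, 1.6]) for _ in range(3))
    meas = MeasurementSpec(
        nu=np.full(3, 0.8), Lambda=lam, K=np.zeros((3, 0)),
        Theta=np.eye(3), f=f, g=FunctionSpec.empty(0),
        nu_free=np.ones(3, bool), Lambda_free=lam_free, theta_free=False)
    struct = StructuralSpec(
        latent_names=("Xi",), n_exog=1, alpha=np.zeros((1, 1)),
        Psi_exog=np.eye(1), psi_end=np.zeros(0),
        B=np.zeros((1, 0)), Gamma=np.zeros((1, 0)),
        F=FunctionSpec.empty(1), G=FunctionSpec.empty(0),
        alpha_free=np.array([False]), psi_free=False)
    spec = ModelSpec(y_names=("o1", "o2", "o3"), x1_names=(),
                     measurement1=meas, structural1=struct,
                     mixture1=MixtureSpec(1), y_links=links)
    data = simulate_dataset(spec, 500, ClusterSizePlan(n=1), seed=31)
    assert set(np.unique(data.y.to_numpy())) <= {1.0, 2.0, 3.0, 4.0}
    draws = run_gibbs(spec, data, settings=SamplerSettings(
        chains=2, iterations=1500, burn_in=700, seed=32, record_loglik=False))
    assert abs(draws.pooled("L1.lam.o2.Xi").mean() - 0.9) < 0.25
    assert abs(draws.pooled("tau.o1.2").mean() - 0.8) < 0.25
    # thresholds stay strictly ordered in every draw
    assert np.all(draws.pooled("tau.o1.3") > draws.pooled("tau.o1.2"))


def test_mar_missingness_imputed_within_sampler():
    spec = examples.quadratic_measurement_model()
    data = simulate_dataset(spec, 400, ClusterSizePlan(n=1), seed=41)
    masked = apply_mar_mask(data, 0.15, "x1", seed=42, columns=["x2", "w"])
    draws = run_gibbs(spec, masked, priors=PriorSpec(loading_mean=0.0),
                      settings=SamplerSettings(chains=2, iterations=1500,
                                               burn_in=700, seed=43,
                                               record_loglik=False))
    b1 = draws.pooled("L1.lam.w.Xi")
    b2 = draws.pooled("L1.lam.w.Xi^2")
    assert abs(b1.mean() - 0.4) < 3 * b1.std()
    assert abs(b2.mean() - (-0.3)) < 3 * b2.std()


def test_cluster_permutation_leaves_posterior_unchanged():
    import pandas as pd

    spec = examples.hierarchical_normal_model()
    data = simulate_dataset(spec, 30, ClusterSizePlan(n=6), seed=51)
    perm = np.random.default_rng(0).permutation(30)
    inv = np.argsort(perm)
    order = np.argsort(inv[data.cluster_of], kind="stable")
    data_p = simulator.Dataset(
        y=data.y.iloc[order].reset_index(drop=True),
        z=data.z.iloc[perm].reset_index(drop=True),
        x1=data.x1.iloc[order].reset_index(drop=True),
        x2=data.x2.iloc[perm].reset_index(drop=True),
        cluster_ids=data.cluster_ids[perm],
        cluster_of=inv[data.cluster_of][order],
    )
    s = SamplerSettings(chains=2, iterations=1200, burn_in=400, seed=52,
                        record_loglik=False)
    d1 = run_gibbs(spec, data, settings=s)
    d2 = run_gibbs(spec, data_p, settings=s)
    m1, m2 = d1.param("L2.mean.u"), d2.param("L2.mean.u")
    tol = 3 * np.hypot(_mcse_pooled(m1), _mcse_pooled(m2))
    assert abs(m1.mean() - m2.mean()) < tol
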