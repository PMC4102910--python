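"""Reproducible validation experiments.

Each function runs one self-contained experiment on simulated data --
spline-basis fidelity, mixture-logit normalization, simulator moment recovery,
sampler-versus-oracle agreement, parameter recovery on the bundled school
model, the label-switching guard, EPSR behaviour, DIC parsimony and MAR
robustness -- and returns a dictionary of computed quantities.  The test suite
asserts on these quantities; ``scripts/acceptance.py`` reports them.

Problem sizes are chosen so the full battery runs on a single CPU in well
under an hour; the replication counts and sampler lengths of each experiment
are parameters with those defaults.
"""

from __future__ import annotations

import copy

import numpy as np

from . import basis, diagnostics, estimator, examples, simulator
from .estimator import PriorSpec, SamplerSettings, run_gibbs
from .model_spec import pack_parameters, parameter_index
from .simulator import ClusterSizePlan, apply_mar_mask, simulate_dataset

__all__ = [
    "spline_fidelity",
    "logit_normalization",
    "simulator_moments",
    "oracle_equivalence",
    "recovery_experiment",
    "dic_parsimony",
]

# the structural quantities whose recovery the school-model experiment tracks
_STRUCTURAL_PREFIXES = (".B.", ".mean.", ".alpha.")


def _mcse_pooled(x: np.ndarray) -> float:
    per = np.array([diagnostics.mcse(x[c]) for c in range(x.shape[0])])
    return float(np.sqrt(np.mean(per ** 2) / x.shape[0]))


# ---------------------------------------------------------------------------
# 1. Spline fidelity
# ---------------------------------------------------------------------------


def spline_fidelity(eps: float = 1e-6) -> dict:
    """Continuity of the assembled cubic spline across its knots.

    Uses the school model's generating coefficients on the knots-(2,3) basis.
    The smooth polynomial part cancels in the jump, so centred finite
    differences of the spline minus its left-piece polynomial extension
    measure the value / first / second discontinuities directly.  Also checks
    exact agreement with the plain cubic below the first knot.
    """
    fs = basis.spline_terms(0, [2.0, 3.0], 3)
    beta = np.array([0.005, 0.009, -0.005, 0.046, -0.164])

    def s(v):
        return float(beta @ basis.eval_function(fs, np.array([v])))

    def left_ext(v, knot):
        val = beta[0] * v + beta[1] * v ** 2 + beta[2] * v ** 3
        if knot > 2.0:
            val += beta[3] * max(v - 2.0, 0.0) ** 3
        return val

    jump0 = jump1 = jump2 = 0.0
    for knot in (2.0, 3.0):
        d = lambda v: s(v) - left_ext(v, knot)
        jump0 = max(jump0, abs(d(knot + eps) - d(knot - eps)))
        jump1 = max(jump1, abs(d(knot + eps) - d(knot - eps)) / (2 * eps))
        jump2 = max(jump2, abs(d(knot + eps) - 2 * d(knot) + d(knot - eps)) / eps ** 2)
    below = max(
        abs(s(v) - (beta[0] * v + beta[1] * v ** 2 + beta[2] * v ** 3))
        for v in np.linspace(-2.0, 1.999, 50))
    return {"value_jump": jump0, "first_diff_jump": jump1,
            "second_diff_jump": jump2, "below_first_knot_error": below}


# ---------------------------------------------------------------------------
# 2. Mixture-logit normalization
# ---------------------------------------------------------------------------


def logit_normalization(n: int = 1000, seed: int = 0) -> dict:
    """Class probabilities sum to one and are shift-invariant in the
    intercepts, over random (a, b, x) draws."""
    from .model_spec import FunctionSpec, MixtureSpec, Term

    rng = np.random.default_rng(seed)
    h = FunctionSpec((Term("linear", 0), Term("linear", 1)), 2)
    worst_sum = 0.0
    worst_shift = 0.0
    for _ in range(n):
        n_classes = int(rng.integers(2, 5))
        a = np.concatenate(([0.0], rng.normal(0, 2, n_classes - 1)))
        b = np.vstack([np.zeros(2), rng.normal(0, 2, (n_classes - 1, 2))])
        mix = MixtureSpec(n_classes, a=a, b=b, h=h)
        x = rng.normal(0, 2, 2)
        p = simulator.class_probabilities(mix, x)
        worst_sum = max(worst_sum, abs(p.sum() - 1.0))
        shifted = MixtureSpec(n_classes, a=a, b=b, h=h)
        c = rng.normal(0, 5)
        logits = (a + c) + b @ basis.eval_function(h, x)
        p2 = np.exp(logits - logits.max())
        p2 /= p2.sum()
        worst_shift = max(worst_shift, np.abs(p - p2).max())
    return {"max_sum_deviation": worst_sum, "max_shift_deviation": worst_shift}


# ---------------------------------------------------------------------------
# 3. Simulator moment recovery
# ---------------------------------------------------------------------------


def simulator_moments(seed: int = 0, n: int = 50_000) -> dict:
    """Single-class linear two-level model: empirical y moments versus the
    closed-form model-implied moments; plus the mixture marginal mean of the
    two-class variant against sum_d pi_d mu_d."""
    spec = examples.school_model(n_level2_classes=1)
    spec.structural1.B[:] = 0.0
    spec.structural1.B[2, 0] = 0.3
    spec.structural1.B[2, 5] = 0.2
    spec.structural1.B_free = spec.structural1.B != 0
    spec.structural2.B[2] = [0.558, 0.442, 0.0]
    spec.structural2.B_free = spec.structural2.B != 0
    oracle = simulator.model_implied_moments(spec)
    n_per = 10
    K = int(np.ceil(n / n_per))
    data = simulate_dataset(spec, K, ClusterSizePlan(n=n_per), seed=seed)
    y = data.y.to_numpy()[:n]
    emp_mean = y.mean(axis=0)
    emp_cov = np.cov(y.T)
    S = oracle["cov_y"]
    se_mean = np.sqrt(np.diag(S) / n)
    se_cov = np.sqrt((np.outer(np.diag(S), np.diag(S)) + S ** 2) / n)
    deff = np.sqrt(n_per)  # clustered draws: conservative design-effect bound
    z_mean = np.abs(emp_mean - oracle["mean_y"]) / (se_mean * deff)
    z_cov = np.abs(emp_cov - S) / (se_cov * deff)

    spec2 = examples.school_model(n_level2_classes=2)
    K2 = 4000
    data2 = simulate_dataset(spec2, K2, ClusterSizePlan(n=1), seed=seed + 1)
    target = simulator.marginal_exog_mean(spec2, level=2)
    emp = data2.truth["eta2"][:, :2].mean(axis=0)
    within_sd = np.sqrt(np.array([0.291, 0.239]))
    between_sd = 0.5 * 0.19  # class-mean gap contribution
    se_mix = np.sqrt(within_sd ** 2 + between_sd ** 2) / np.sqrt(K2)
    z_mix = np.abs(emp - target) / se_mix
    return {"max_z_mean": float(z_mean.max()), "max_z_cov": float(z_cov.max()),
            "max_z_mixture_mean": float(z_mix.max()), "n_used": n}


# ---------------------------------------------------------------------------
# 4. Conjugate / quadrature oracle equivalence
# ---------------------------------------------------------------------------


def oracle_equivalence(seed: int = 0, grid_size: int = 41,
                       n_nodes: int = 24) -> dict:
    """Tiny models where independent posteriors exist.

    (a) hierarchical normal-normal: sampler versus exact conjugate posterior
    of the grand mean (z-score of the mean, ratio of variances);
    (b) one-latent quadratic model: sampler versus a dense-grid posterior over
    the two regression coefficients with Gauss-Hermite likelihoods.
    """
    # (a) analytic conjugate posterior
    mu, su2, sz2, th = 0.5, 0.3, 0.2, 0.4
    spec = examples.hierarchical_normal_model(mu, su2, sz2, th)
    data = simulate_dataset(spec, 40, ClusterSizePlan(n=8), seed=seed + 7)
    draws = run_gibbs(spec, data, settings=SamplerSettings(
        chains=2, iterations=1500, burn_in=500, seed=seed + 3,
        record_loglik=False))
    got = draws.param("L2.mean.u")
    y = data.y["y1"].to_numpy()
    nk = np.bincount(data.cluster_of)
    ybar = np.bincount(data.cluster_of, weights=y) / nk
    se2 = sz2 + th
    prior_var = su2 * PriorSpec().h0
    prec = (1.0 / (su2 + se2 / nk)).sum() + 1.0 / prior_var
    mean = (ybar / (su2 + se2 / nk)).sum() / prec
    z_mean = abs(got.mean() - mean) / _mcse_pooled(got)
    var_ratio = float(got.reshape(-1).var() * prec)

    # (b) grid posterior for the quadratic measurement model
    spec_q = examples.quadratic_measurement_model()
    data_q = simulate_dataset(spec_q, 50, ClusterSizePlan(n=1), seed=seed + 10)
    pri = PriorSpec(loading_mean=0.0)
    theta_w, h0 = 0.3, pri.h0

    def grid_pass(lo1, hi1, lo2, hi2, npts, nodes):
        g1 = np.linspace(lo1, hi1, npts)
        g2 = np.linspace(lo2, hi2, npts)
        sp = copy.deepcopy(spec_q)
        lp = np.empty((npts, npts))
        for i, b1 in enumerate(g1):
            for j, b2 in enumerate(g2):
                sp.measurement1.Lambda[2, 0] = b1
                sp.measurement1.Lambda[2, 1] = b2
                lp[i, j] = diagnostics.marginal_loglik_small(sp, data_q,
                                                             n_nodes=nodes) \
                    - 0.5 * (b1 ** 2 + b2 ** 2) / (theta_w * h0)
        w = np.exp(lp - lp.max())
        w /= w.sum()
        m1 = float((w.sum(axis=1) * g1).sum())
        m2 = float((w.sum(axis=0) * g2).sum())
        s1 = float(np.sqrt((w.sum(axis=1) * (g1 - m1) ** 2).sum()))
        s2 = float(np.sqrt((w.sum(axis=0) * (g2 - m2) ** 2).sum()))
        return m1, m2, s1, s2

    m1, m2, s1, s2 = grid_pass(-1.5, 1.5, -1.5, 1.5, 25, max(12, n_nodes // 2))
    m1, m2, s1, s2 = grid_pass(m1 - 6 * s1, m1 + 6 * s1,
                               m2 - 6 * s2, m2 + 6 * s2, grid_size, n_nodes)
    draws_q = run_gibbs(spec_q, data_q, priors=pri,
                        settings=SamplerSettings(chains=3, iterations=4000,
                                                 burn_in=1500, seed=seed + 21,
                                                 record_loglik=False))
    g1 = draws_q.param("L1.lam.w.Xi")
    g2 = draws_q.param("L1.lam.w.Xi^2")
    z_lin = abs(g1.mean() - m1) / _mcse_pooled(g1)
    z_quad = abs(g2.mean() - m2) / _mcse_pooled(g2)
    return {"normal_normal_z": float(z_mean),
            "normal_normal_var_ratio": var_ratio,
            "grid_gibbs_z_linear": float(z_lin),
            "grid_gibbs_z_quadratic": float(z_quad),
            "grid_mean_linear": m1, "grid_mean_quadratic": m2}


# ---------------------------------------------------------------------------
# 5 / 6 / 9. Parameter recovery on the school model
# ---------------------------------------------------------------------------


def recovery_experiment(n_reps: int = 5, seed: int = 0, mar_rate: float = 0.0,
                        K: int = 100, total: int = 700, chains: int = 3,
                        iterations: int = 5000, burn_in: int = 2500,
                        keep_last_draws: bool = False) -> dict:
    """Generate-and-refit battery on the two-level spline/interaction/mixture
    school model with its bundled generating values as truth.

    Per replication: simulate K clusters (about total/K pupils each),
    optionally mask ``mar_rate`` of the indicator cells missing-at-random,
    fit with ``chains`` x ``iterations`` Gibbs chains, and record the maximum
    EPSR, 95%-interval coverage of the structural parameters, the sign of the
    recovered interaction, ordering violations of the class means, and the
    mean posterior interval width of the interaction coefficient.
    """
    spec = examples.school_model()
    names = parameter_index(spec)
    truth = pack_parameters(spec)
    keys = [i for i, nme in enumerate(names)
            if any(p in nme for p in _STRUCTURAL_PREFIXES)]
    i_b5 = names.index("L2.B.alpha3.Prob*Soc")
    i_c1 = names.index("L2.mean.Prob.c1")
    i_c2 = names.index("L2.mean.Prob.c2")

    meas_keys = [i for i, nme in enumerate(names)
                 if nme.startswith(("L1.lam.", "L1.theta."))]
    per_rep = []
    cover_cells = []
    last = None
    for rep in range(n_reps):
        data = simulate_dataset(spec, K, ClusterSizePlan.from_total(K, total),
                                seed=seed + 1000 + rep)
        if mar_rate > 0:
            data = apply_mar_mask(data, mar_rate, "y1", seed=seed + 3000 + rep)
        draws = run_gibbs(spec, data, settings=SamplerSettings(
            chains=chains, iterations=iterations, burn_in=burn_in,
            seed=seed + 2000 + rep, record_loglik=False))
        flat = draws.draws.reshape(-1, len(names))
        e = diagnostics.epsr(draws)
        cov = []
        for i in keys:
            lo, hi = np.percentile(flat[:, i], [2.5, 97.5])
            cov.append(bool(lo <= truth[i] <= hi))
        cover_cells.extend(cov)
        lo5, hi5 = np.percentile(flat[:, i_b5], [2.5, 97.5])
        violations = int(np.sum(flat[:, i_c2] <= flat[:, i_c1]))
        q_meas = np.percentile(flat[:, meas_keys], [2.5, 97.5], axis=0)
        per_rep.append({
            "max_epsr": float(e.max()),
            "coverage": float(np.mean(cov)),
            "b5_negative": bool(flat[:, i_b5].mean() < 0),
            "b5_interval_width": float(hi5 - lo5),
            "meas_interval_width": float(np.mean(q_meas[1] - q_meas[0])),
            "ordering_violations": violations,
        })
        last = draws
    out = {
        "n_reps": n_reps,
        "coverage_rate": float(np.mean(cover_cells)),
        "n_cells": len(cover_cells),
        "sign_recovered": int(sum(r["b5_negative"] for r in per_rep)),
        "worst_epsr": float(max(r["max_epsr"] for r in per_rep)),
        "all_epsr_below_1p2": bool(all(r["max_epsr"] < 1.2 for r in per_rep)),
        "total_ordering_violations": int(sum(r["ordering_violations"]
                                             for r in per_rep)),
        "mean_b5_interval_width": float(np.mean([r["b5_interval_width"]
                                                 for r in per_rep])),
        "mean_meas_interval_width": float(np.mean([r["meas_interval_width"]
                                                   for r in per_rep])),
        "per_rep": per_rep,
    }
    if keep_last_draws:
        out["last_draws"] = last
    return out


# ---------------------------------------------------------------------------
# 8. DIC parsimony
# ---------------------------------------------------------------------------


def dic_parsimony(n_reps: int = 10, seed: int = 0, K: int = 100,
                  n_per: int = 4, iterations: int = 1500,
                  burn_in: int = 750) -> dict:
    """Data simulated WITHOUT a level-2 mixture: fit one- and two-class
    random-intercept models and compare them by the observed-data (marginal)
    DIC.  A spurious second class should not be rewarded, so the one-class
    DIC is expected to win in most replications; note however that the
    constrained two-class model is nearly indistinguishable from the
    one-class model on such data, which makes the DIC difference per
    replication small (see the methods note)."""
    gen = examples.random_intercept_mixture_model(n_classes=1)
    wins = 0
    dic_pairs = []
    for rep in range(n_reps):
        data = simulate_dataset(gen, K, ClusterSizePlan(n=n_per),
                                seed=seed + 100 + rep)
        dics = {}
        for n_classes in (1, 2):
            spec = examples.random_intercept_mixture_model(n_classes=n_classes)
            draws = run_gibbs(spec, data, settings=SamplerSettings(
                chains=2, iterations=iterations, burn_in=burn_in,
                seed=seed + 200 + 10 * rep + n_classes,
                record_loglik=False))
            d, p_d = diagnostics.dic(draws, spec, data)
            dics[n_classes] = d
        dic_pairs.append((dics[1], dics[2]))
        if dics[1] <= dics[2]:
            wins += 1
    return {"n_reps": n_reps, "one_class_wins": wins,
            "mean_dic_1class": float(np.mean([a for a, _ in dic_pairs])),
            "mean_dic_2class": float(np.mean([b for _, b in dic_pairs]))}
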