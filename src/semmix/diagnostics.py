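"""Convergence assessment, posterior summaries, DIC, relabeling, and a
small-model quadrature oracle for the marginal likelihood.

EPSR is the classic (non-split) multi-chain potential-scale-reduction factor:
with within-chain variance W, between-chain variance B and n retained
iterations, EPSR = sqrt(((n-1)/n W + B/n) / W); convergence is declared when
every parameter is below 1.2, the threshold conventional in the Bayesian SEM
literature.

DIC is reported conditional on the continuous latent variables but marginal
over the discrete class labels: the deviance is -2 times the joint log-density
of the observed indicators and the latent vectors with classes summed out,
which keeps mixture and non-mixture fits comparable.  pD = mean deviance minus
the deviance at the posterior means of parameters and latents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import basis
from .estimator import PosteriorDraws, _Compiled, complete_data_loglik
from .model_spec import ModelSpec, unpack_parameters
from .simulator import Dataset

__all__ = [
    "epsr",
    "summarize",
    "DiagnosticsReport",
    "diagnostics_report",
    "dic",
    "marginal_loglik_small",
    "relabel",
    "mcse",
    "plot_epsr_trace",
]

EPSR_THRESHOLD = 1.2


# ---------------------------------------------------------------------------
# EPSR
# ---------------------------------------------------------------------------


def epsr(draws: PosteriorDraws) -> pd.Series:
    """Per-parameter potential scale reduction across chains.

    Requires at least two chains and ten retained iterations; byte-identical
    chains return exactly 1 (the B = 0 edge case is explicit).
    """
    arr = draws.draws
    chains, n, P = arr.shape
    if chains < 2:
        raise ValueError("EPSR needs >= 2 chains; rerun with more chains")
    if n < 10:
        raise ValueError("EPSR needs >= 10 retained iterations")
    W = arr.var(axis=1, ddof=1).mean(axis=0)          # (P,)
    B = n * arr.mean(axis=1).var(axis=0, ddof=1)      # (P,)
    out = np.ones(P)
    pos = (W > 0) & (B > 1e-300)
    out[pos] = np.sqrt(((n - 1) / n * W[pos] + B[pos] / n) / W[pos])
    out[(W <= 0) & (B > 1e-300)] = np.inf
    # B == 0 (byte-identical chains) is exactly 1 by convention
    return pd.Series(out, index=list(draws.names))


def mcse(values: np.ndarray, n_batches: int = 30) -> float:
    """Batch-means Monte-Carlo standard error of the mean of one chain of draws."""
    values = np.asarray(values).reshape(-1)
    n = len(values)
    b = max(n // n_batches, 2)
    nb = n // b
    means = values[: nb * b].reshape(nb, b).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(nb))


# ---------------------------------------------------------------------------
# Posterior summary (Table-style)
# ---------------------------------------------------------------------------


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Pooled posterior mean, SE (posterior SD), t = mean/SD, percentiles.

    Zero-variance parameters get t = +/- inf with the sign of the mean.
    """
    flat = draws.draws.reshape(-1, draws.draws.shape[2])
    if flat.size == 0:
        raise ValueError("no retained draws to summarize")
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / sd, np.sign(mean) * np.inf)
    q = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {"mean": mean, "se": sd, "t": t,
         "p2.5": q[0], "p50": q[1], "p97.5": q[2]},
        index=list(draws.names),
    )


@dataclass
class DiagnosticsReport:
    epsr: pd.Series
    max_epsr: float
    converged: bool
    acceptance: dict
    dic: Optional[float] = None
    p_d: Optional[float] = None
    dic_variant: str = ("plug-in posterior-mean latents, "
                        "marginal over classes")

    def __str__(self):
        lines = [f"max EPSR: {self.max_epsr:.4f} "
                 f"(threshold {EPSR_THRESHOLD}); converged: {self.converged}"]
        if self.dic is not None:
            lines.append(f"DIC: {self.dic:.1f} (pD = {self.p_d:.1f}; {self.dic_variant})")
        for k, v in self.acceptance.items():
            lines.append(f"MH acceptance [{k}]: {v:.3f}")
        return "\n".join(lines)


def diagnostics_report(draws: PosteriorDraws, spec: ModelSpec = None,
                       data: Dataset = None,
                       threshold: float = EPSR_THRESHOLD) -> DiagnosticsReport:
    e = epsr(draws)
    report = DiagnosticsReport(
        epsr=e, max_epsr=float(e.max()), converged=bool((e < threshold).all()),
        acceptance=dict(draws.acceptance),
    )
    if spec is not None and data is not None:
        report.dic, report.p_d = dic(draws, spec, data)
    return report


# ---------------------------------------------------------------------------
# DIC
# ---------------------------------------------------------------------------


def dic(draws: PosteriorDraws, spec: ModelSpec, data: Dataset,
        variant: str = "auto", max_eval: int = 400) -> tuple:
    """(DIC, pD): DIC = Dbar + pD, pD = Dbar - D(theta_bar).

    Mixture DICs are not unique; three deviance variants are provided, all
    marginal over the discrete classes:

    ``marginal``: observed-data deviance -2 log p(y, z | theta) with the
    continuous latents integrated out analytically.  Available only for
    linear-Gaussian models (all active function-set columns linear, identity
    links, no covariates, random intercepts only, single within-level class);
    there the cluster-level marginal is an exact mixture of multivariate
    normals.  This is the best-behaved variant for model comparison: pD
    counts parameters, not latent variables.

    ``conditional``: per-iteration complete-data deviance D(theta_t; eta_t)
    recorded during sampling (requires ``record_loglik=True``); pD is of the
    order of the number of latent variables and the Monte-Carlo noise is
    large.

    ``auto`` (default): ``marginal`` when the model is in linear scope,
    otherwise ``conditional``.  The variant actually used is the third
    element of ``DiagnosticsReport.dic_variant`` when reported there.
    """
    flat = draws.draws.reshape(-1, draws.draws.shape[2])
    theta_bar = flat.mean(axis=0)
    if variant == "auto":
        variant = "marginal" if _linear_marginal_scope(spec) else "conditional"
    if variant == "marginal":
        step = max(1, len(flat) // max_eval)
        vals = [_linear_marginal_loglik(unpack_parameters(spec, flat[t]), data)
                for t in range(0, len(flat), step)]
        d_bar = float(-2.0 * np.mean(vals))
        d_hat = -2.0 * _linear_marginal_loglik(
            unpack_parameters(spec, theta_bar), data)
    elif variant == "conditional":
        if not np.any(draws.loglik):
            raise ValueError("draws carry no recorded log-likelihood; "
                             "rerun with SamplerSettings(record_loglik=True)")
        d_bar = float(-2.0 * draws.loglik.mean())
        spec_bar = unpack_parameters(spec, theta_bar)
        comp = _Compiled(spec_bar, data)
        d_hat = -2.0 * complete_data_loglik(spec_bar, comp, draws.eta1_mean,
                                            draws.eta2_mean)
    else:
        raise ValueError(f"unknown DIC variant {variant!r}")
    p_d = d_bar - d_hat
    return d_bar + p_d, p_d


def _linear_marginal_scope(spec: ModelSpec) -> bool:
    """True when the observed-data likelihood is an exact MVN mixture."""
    def lin_ok(f, coef):
        return all(t.kind == "linear" or not np.any(coef[:, i] != 0)
                   for i, t in enumerate(f.terms))

    me1, st1 = spec.measurement1, spec.structural1
    ok = lin_ok(me1.f, me1.Lambda) and lin_ok(st1.F, st1.B)
    ok = ok and not spec.x1_names and not spec.x2_names
    ok = ok and spec.mixture1.n_classes == 1
    ok = ok and all(lk.link == "identity" for lk in spec.y_links)
    ok = ok and all(lk.link == "identity" for lk in spec.z_links)
    ok = ok and all(kind == "intercept" for kind, *_ in spec.random_targets())
    if spec.has_level2:
        me2, st2 = spec.measurement2, spec.structural2
        if me2 is not None and me2.n_indicators:
            ok = ok and lin_ok(me2.f, me2.Lambda)
        ok = ok and lin_ok(st2.F, st2.B)
        ok = ok and not st1.psi_exog_class_varying
    return bool(ok)


def _lin_sel_active(f, m, coef):
    S = np.zeros((f.out_dim, m))
    for i, t in enumerate(f.terms):
        if t.kind == "linear":
            S[i, t.var] = 1.0
    return S


def _linear_marginal_loglik(spec: ModelSpec, data: Dataset) -> float:
    """Exact observed-data log-likelihood of a linear-Gaussian mixture model.

    Per cluster and level-2 class d, y stacked over the cluster is
    N(1 x mu_d, I x W + 11' x B_d); the class sum is exact.
    """
    st1, me1 = spec.structural1, spec.measurement1
    m = st1.m
    A1 = np.linalg.inv(np.eye(m) - st1.B @ _lin_sel_active(st1.F, m, st1.B))
    Lam1 = me1.Lambda @ _lin_sel_active(me1.f, m, me1.Lambda)
    L1A = Lam1 @ A1
    psi1 = np.zeros((m, m))
    if st1.n_exog:
        psi1[: st1.n_exog, : st1.n_exog] = st1.psi_exog_for(0)
    for r in range(st1.n_endog):
        psi1[st1.n_exog + r, st1.n_exog + r] = st1.psi_end[r]
    W = L1A @ psi1 @ L1A.T + me1.Theta
    a_base = st1.alpha[0].copy()
    y = data.y.to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("marginal DIC variant requires complete data")

    if not spec.has_level2:
        mean = me1.nu + L1A @ a_base
        from scipy.stats import multivariate_normal

        return float(multivariate_normal(mean=mean, cov=W).logpdf(y).sum())

    st2 = spec.structural2
    U = st2.m
    A2 = np.linalg.inv(np.eye(U) - st2.B @ _lin_sel_active(st2.F, U, st2.B))
    R = np.zeros((m, U))
    for kind, r, t, u in spec.random_targets():
        R[r, u] = 1.0
        a_base[r] = 0.0
    M = L1A @ R                       # (J, U) cluster-effect loading on y
    base_mean = me1.nu + L1A @ a_base
    from .simulator import class_probabilities

    pi = class_probabilities(spec.mixture2, np.zeros(0))
    D = st2.n_classes if hasattr(st2, "n_classes") else spec.mixture2.n_classes
    means2, covs2 = [], []
    for d in range(spec.mixture2.n_classes):
        psi2 = np.zeros((U, U))
        if st2.n_exog:
            psi2[: st2.n_exog, : st2.n_exog] = st2.psi_exog_for(d)
        for r in range(st2.n_endog):
            psi2[st2.n_exog + r, st2.n_exog + r] = st2.psi_end[r]
        means2.append(A2 @ st2.alpha[d])
        covs2.append(A2 @ psi2 @ A2.T)

    # z contribution (indicators of eta2) handled jointly with y per cluster
    me2 = spec.measurement2
    if me2 is not None and me2.n_indicators:
        Lam2 = me2.Lambda @ _lin_sel_active(me2.f, U, me2.Lambda)
        z = data.z.to_numpy(dtype=float)
        if np.isnan(z).any():
            raise ValueError("marginal DIC variant requires complete data")
    else:
        Lam2 = np.zeros((0, U))
        z = np.zeros((data.n_clusters, 0))

    J = me1.n_indicators
    L = Lam2.shape[0]
    sizes = np.bincount(data.cluster_of, minlength=data.n_clusters)
    total = 0.0
    # batch clusters of equal size: shared covariance Cholesky per (size, d)
    order = np.argsort(data.cluster_of, kind="stable")
    y_sorted = y[order]
    starts = np.concatenate(([0], np.cumsum(sizes)))
    for size in np.unique(sizes):
        ks = np.flatnonzero(sizes == size)
        obs = np.empty((len(ks), size * J + L))
        for i, k in enumerate(ks):
            obs[i, : size * J] = y_sorted[starts[k]: starts[k] + size].ravel()
            obs[i, size * J:] = z[k]
        comps = np.empty((len(ks), spec.mixture2.n_classes))
        for d in range(spec.mixture2.n_classes):
            dim = size * J + L
            mean = np.empty(dim)
            mean[: size * J] = np.tile(base_mean + M @ means2[d], size)
            mean[size * J:] = me2.nu + Lam2 @ means2[d] if L else []
            cov = np.zeros((dim, dim))
            B_y = M @ covs2[d] @ M.T
            for a in range(size):
                for b in range(size):
                    blk = B_y + (W if a == b else 0.0)
                    cov[a * J:(a + 1) * J, b * J:(b + 1) * J] = blk
            if L:
                C_yz = M @ covs2[d] @ Lam2.T
                for a in range(size):
                    cov[a * J:(a + 1) * J, size * J:] = C_yz
                    cov[size * J:, a * J:(a + 1) * J] = C_yz.T
                cov[size * J:, size * J:] = Lam2 @ covs2[d] @ Lam2.T + me2.Theta
            Lc = np.linalg.cholesky(cov)
            diff = obs - mean
            sol = np.linalg.solve(Lc, diff.T)
            comps[:, d] = np.log(pi[d]) - 0.5 * (
                np.sum(sol ** 2, axis=0) + 2 * np.log(np.diag(Lc)).sum()
                + dim * np.log(2 * np.pi))
        total += float(_lse(comps, axis=1).sum()) if comps.shape[1] > 1 \
            else float(comps[:, 0].sum())
    return total


# ---------------------------------------------------------------------------
# Quadrature oracle for the marginal likelihood of tiny models
# ---------------------------------------------------------------------------


def _gh_nodes(n: int):
    """Probabilists' Gauss-Hermite nodes/weights for integrals against N(0,1)."""
    x, w = np.polynomial.hermite_e.hermegauss(n)
    return x, w / np.sqrt(2.0 * np.pi)


def _latent_grid(struct, cls: int, n_nodes: int, proposal=None):
    """Grid over the latent vector of one level, for one mixture class.

    Exogenous block: joint Cholesky-transformed Gauss-Hermite grid, either on
    the class prior or on an adaptive Gaussian ``proposal`` (mean, chol-cov)
    with exact importance reweighting against the prior.  Endogenous dims:
    node offsets around the (grid-dependent) structural mean, applied
    recursively.  Returns (points (G, m), log-weights (G,)) with all latent
    Gaussian densities absorbed into the weights.
    """
    x, w = _gh_nodes(n_nodes)
    m, n_ex = struct.m, struct.n_exog
    pts = np.zeros((1, 0))
    logw = np.zeros(1)
    if n_ex:
        psi = struct.psi_exog_for(cls)
        Lp = np.linalg.cholesky(psi)
        mesh = np.meshgrid(*([x] * n_ex), indexing="ij")
        xi = np.stack([g.ravel() for g in mesh], axis=1)        # (nodes^n_ex, n_ex)
        wmesh = np.meshgrid(*([np.log(w)] * n_ex), indexing="ij")
        logw = sum(g.ravel() for g in wmesh)
        if proposal is None:
            pts = struct.alpha[cls, :n_ex] + xi @ Lp.T
        else:
            mean_q, Lq = proposal
            pts = mean_q + xi @ Lq.T
            # reweight: + log prior(pts) - log proposal(pts)
            diff_p = pts - struct.alpha[cls, :n_ex]
            sol_p = np.linalg.solve(Lp, diff_p.T)
            log_prior = -0.5 * (np.sum(sol_p ** 2, axis=0)
                                + 2 * np.log(np.diag(Lp)).sum()
                                + n_ex * np.log(2 * np.pi))
            log_q = -0.5 * (np.sum(xi ** 2, axis=1)
                            + 2 * np.log(np.diag(Lq)).sum()
                            + n_ex * np.log(2 * np.pi))
            logw = logw + log_prior - log_q
    for ridx in range(struct.n_endog):
        r = n_ex + ridx
        G = pts.shape[0]
        full = np.zeros((G, m))
        full[:, : pts.shape[1]] = pts
        Fb = basis.eval_function_matrix(struct.F, full)
        mean_r = struct.alpha[cls, r] + Fb @ struct.B[r]
        sd_r = np.sqrt(struct.psi_end[ridx])
        pts = np.concatenate(
            [np.repeat(pts, n_nodes, axis=0),
             (mean_r[:, None] + sd_r * x[None, :]).reshape(-1, 1)], axis=1)
        logw = (logw[:, None] + np.log(w)[None, :]).reshape(-1)
    return pts, logw


def _exog_proposals(meas, links, struct, cls, rows):
    """Per-row adaptive Gaussian proposals for the exogenous block.

    Laplace-style: linearize the measurement model in the exogenous latents
    (linear f-columns, identity links, observed cells only) and combine with
    the class prior.  Endogenous latents are plugged in at their intercepts
    for the residualization; the proposal only steers node placement, the
    importance weights keep the integral exact.
    """
    n_ex = struct.n_exog
    R = rows.shape[0]
    psi = struct.psi_exog_for(cls)
    psi_inv = np.linalg.inv(psi)
    if meas is None or meas.n_indicators == 0:
        L = np.linalg.cholesky(psi)
        return [(struct.alpha[cls, :n_ex].copy(), L) for _ in range(R)]
    J = meas.n_indicators
    lam_ex = np.zeros((J, n_ex))
    lam_end = np.zeros((J, struct.n_endog))
    for t, term in enumerate(meas.f.terms):
        if term.kind == "linear":
            if term.var < n_ex:
                lam_ex[:, term.var] += meas.Lambda[:, t]
            else:
                lam_end[:, term.var - n_ex] += meas.Lambda[:, t]
    th = np.diag(meas.Theta)
    endo0 = struct.alpha[cls, n_ex:]
    base = meas.nu + lam_end @ endo0
    out = []
    ident = np.array([lk.link == "identity" for lk in links])
    for i in range(R):
        obs = ident & ~np.isnan(rows[i])
        Q = psi_inv + (lam_ex[obs].T / th[obs]) @ lam_ex[obs]
        rhs = psi_inv @ struct.alpha[cls, :n_ex] \
            + (lam_ex[obs].T / th[obs]) @ (rows[i, obs] - base[obs])
        cov = np.linalg.inv(Q)
        out.append((cov @ rhs, np.linalg.cholesky(cov)))
    return out


def _meas_loglik_grid(meas, links, pts, rows):
    """log p(observed rows | latent grid): (R, G); NaN cells contribute 0."""
    rows = np.atleast_2d(rows)
    R, G = rows.shape[0], len(pts)
    out = np.zeros((R, G))
    if meas is None or meas.n_indicators == 0 or R == 0:
        return out
    fb = basis.eval_function_matrix(meas.f, pts)
    mean = meas.nu + fb @ meas.Lambda.T           # (G, J)
    th = np.diag(meas.Theta)
    for j in range(meas.n_indicators):
        obs = ~np.isnan(rows[:, j])
        if not obs.any():
            continue
        if links[j].link == "identity":
            diff = rows[obs, j][:, None] - mean[None, :, j]
            out[obs] += -0.5 * (diff ** 2 / th[j] + np.log(2 * np.pi * th[j]))
        elif links[j].link == "ordered":
            from scipy.special import ndtr

            bounds = np.concatenate(([-np.inf], links[j].thresholds, [np.inf]))
            s = rows[obs, j].astype(int)
            p = ndtr(bounds[s][:, None] - mean[None, :, j]) \
                - ndtr(bounds[s - 1][:, None] - mean[None, :, j])
            out[obs] += np.log(np.clip(p, 1e-300, None))
        else:
            raise ValueError("quadrature oracle supports identity/ordered links")
    return out



def _paired_grid(struct, cls: int, n_nodes: int, means, chols):
    """Per-unit adaptive grids sharing node offsets: returns pts (R, G, m),
    logw (R, G) with prior/proposal reweighting and endogenous recursion."""
    x, w = _gh_nodes(n_nodes)
    m, n_ex = struct.m, struct.n_exog
    R = means.shape[0]
    if n_ex:
        psi = struct.psi_exog_for(cls)
        Lp = np.linalg.cholesky(psi)
        Lp_inv = np.linalg.inv(Lp)
        mesh = np.meshgrid(*([x] * n_ex), indexing="ij")
        xi = np.stack([g.ravel() for g in mesh], axis=1)          # (G0, n_ex)
        wmesh = np.meshgrid(*([np.log(w)] * n_ex), indexing="ij")
        logw0 = sum(g.ravel() for g in wmesh)                     # (G0,)
        pts = means[:, None, :] + np.einsum("gj,rkj->rgk", xi, chols)
        diff_p = (pts - struct.alpha[cls, :n_ex]) @ Lp_inv.T
        log_prior = -0.5 * (np.einsum("rgk,rgk->rg", diff_p, diff_p)
                            + 2 * np.log(np.diag(Lp)).sum()
                            + n_ex * np.log(2 * np.pi))
        logdet_q = np.log(np.einsum("rkk->rk", chols)).sum(axis=1)  # (R,)
        log_q = -0.5 * ((xi ** 2).sum(axis=1)[None, :]
                        + 2 * logdet_q[:, None] + n_ex * np.log(2 * np.pi))
        logw = logw0[None, :] + log_prior - log_q                 # (R, G0)
    else:
        pts = np.zeros((R, 1, 0))
        logw = np.zeros((R, 1))
    for ridx in range(struct.n_endog):
        r = n_ex + ridx
        R_, G = pts.shape[0], pts.shape[1]
        full = np.zeros((R_ * G, m))
        full[:, : pts.shape[2]] = pts.reshape(R_ * G, -1)
        Fb = basis.eval_function_matrix(struct.F, full)
        mean_r = (struct.alpha[cls, r] + Fb @ struct.B[r]).reshape(R_, G)
        sd_r = np.sqrt(struct.psi_end[ridx])
        new_col = mean_r[:, :, None] + sd_r * x[None, None, :]    # (R, G, nodes)
        pts = np.concatenate(
            [np.repeat(pts, n_nodes, axis=1),
             new_col.reshape(R_, G * n_nodes, 1)], axis=2)
        logw = (logw[:, :, None] + np.log(w)[None, None, :]).reshape(R_, G * n_nodes)
    return pts, logw


def _paired_meas_ll(meas, links, pts, rows):
    """(R, G) log p(row_i | pts_i); each unit evaluated on its own grid."""
    R, G, m = pts.shape
    out = np.zeros((R, G))
    if meas is None or meas.n_indicators == 0:
        return out
    fb = basis.eval_function_matrix(meas.f, pts.reshape(R * G, m))
    mean = (meas.nu + fb @ meas.Lambda.T).reshape(R, G, meas.n_indicators)
    th = np.diag(meas.Theta)
    for j in range(meas.n_indicators):
        obs = ~np.isnan(rows[:, j])
        if not obs.any():
            continue
        if links[j].link == "identity":
            diff = rows[obs, j][:, None] - mean[obs, :, j]
            out[obs] += -0.5 * (diff ** 2 / th[j] + np.log(2 * np.pi * th[j]))
        elif links[j].link == "ordered":
            from scipy.special import ndtr

            bounds = np.concatenate(([-np.inf], links[j].thresholds, [np.inf]))
            s = rows[obs, j].astype(int)
            p = ndtr(bounds[s][:, None] - mean[obs, :, j]) \
                - ndtr(bounds[s - 1][:, None] - mean[obs, :, j])
            out[obs] += np.log(np.clip(p, 1e-300, None))
        else:
            raise ValueError("quadrature oracle supports identity/ordered links")
    return out


def _lse(a, axis=None):
    if axis is None:
        m = float(np.max(a))
        return m + float(np.log(np.sum(np.exp(a - m))))
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))).squeeze(axis)


def marginal_loglik_small(spec: ModelSpec, data: Dataset,
                          n_nodes: int = 24) -> float:
    """Observed-data log-likelihood by nested adaptive Gauss-Hermite quadrature.

    Oracle scope: total latent dimension (both levels) <= 3, <= 2 classes per
    mixture, <= 50 clusters, random intercepts only.  Classes are summed
    exactly; exogenous latents are integrated on per-unit adaptive grids with
    importance reweighting, endogenous latents on recursively mean-shifted
    grids.  Intended as an independent cross-check of the sampler on tiny
    models, not as an estimation route.
    """
    st1, st2 = spec.structural1, spec.structural2
    total_dim = st1.m + (st2.m if spec.has_level2 else 0)
    if total_dim > 3:
        raise ValueError("quadrature oracle limited to total latent dimension <= 3")
    if spec.mixture1.n_classes > 2 or spec.mixture2.n_classes > 2:
        raise ValueError("quadrature oracle limited to <= 2 classes per mixture")
    if data.n_clusters > 50:
        raise ValueError("quadrature oracle limited to K <= 50 clusters")
    if spec.x1_names or spec.x2_names:
        raise ValueError("quadrature oracle supports covariate-free models only")

    from .simulator import class_probabilities

    y = data.y.to_numpy(dtype=float)
    z = data.z.to_numpy(dtype=float)
    pi1 = class_probabilities(spec.mixture1, np.zeros(0))

    def rows_loglik_level1(rows, intercept_shift):
        """(R,) log sum_c pi_c int p(y_row | eta1) p(eta1 | c) deta1."""
        R = rows.shape[0]
        per_class = np.empty((R, spec.mixture1.n_classes))
        alpha_saved = st1.alpha.copy()
        try:
            for r, val in intercept_shift.items():
                st1.alpha[:, r] = val
            for c in range(spec.mixture1.n_classes):
                if st1.n_exog:
                    props = _exog_proposals(spec.measurement1, spec.y_links,
                                            st1, c, rows)
                    means = np.stack([p[0] for p in props])
                    chols = np.stack([p[1] for p in props])
                else:
                    means = np.zeros((R, 0))
                    chols = np.zeros((R, 0, 0))
                pts, logw = _paired_grid(st1, c, n_nodes, means, chols)
                ll = _paired_meas_ll(spec.measurement1, spec.y_links, pts, rows)
                per_class[:, c] = np.log(pi1[c]) + _lse(logw + ll, axis=1)
        finally:
            st1.alpha[:] = alpha_saved
        return _lse(per_class, axis=1) if per_class.shape[1] > 1 else per_class[:, 0]

    if not spec.has_level2:
        return float(np.sum(rows_loglik_level1(y, {})))

    pi2 = class_probabilities(spec.mixture2, np.zeros(0))
    rand = spec.random_targets()
    for kind, *_ in rand:
        if kind != "intercept":
            raise ValueError("oracle supports random intercepts only")
    total = 0.0
    for k in range(data.n_clusters):
        rows = y[data.cluster_of == k]
        vals = []
        for d in range(spec.mixture2.n_classes):
            pts2, logw2 = _latent_grid(st2, d, n_nodes)
            ll_z = _meas_loglik_grid(spec.measurement2, spec.z_links, pts2,
                                     z[k] if z.size else np.zeros((1, 0)))[0]
            inner = np.empty(len(pts2))
            for gidx in range(len(pts2)):
                shift = {r: pts2[gidx, u] for kind, r, t, u in rand}
                inner[gidx] = float(np.sum(rows_loglik_level1(rows, shift)))
            vals.append(np.log(pi2[d]) + _lse(logw2 + ll_z + inner))
        total += _lse(np.asarray(vals))
    return float(total)


# ---------------------------------------------------------------------------
# Relabeling
# ---------------------------------------------------------------------------


def relabel(draws: PosteriorDraws, level: int = 2, rule: str = "mean",
            block: str = None) -> PosteriorDraws:
    """Post-hoc relabeling of mixture classes by an ordering rule.

    ``rule='mean'`` orders classes by the class-specific means of ``block``
    (default: the first class-indexed mean parameter found); ``rule='logit'``
    orders by the class logit intercepts (proportions).  When the
    ordered-increment prior was active the draws are already monotone and the
    operation is the identity.  Ties break deterministically by class index
    (numpy stable argsort).
    """
    import copy as _copy

    prefix = f"L{level}."
    names = list(draws.names)
    # class-suffixed parameter groups on this level: base name -> [idx per class]
    groups = {}
    for i, n in enumerate(names):
        if not n.startswith(prefix):
            continue
        parts = n.rsplit(".", 1)
        if len(parts) == 2 and parts[1].startswith("c") and parts[1][1:].isdigit():
            groups.setdefault(parts[0], []).append((int(parts[1][1:]), i))
    groups = {k: [i for _, i in sorted(v)] for k, v in groups.items()
              if len(v) > 1}
    if not groups:
        return draws

    if rule == "mean":
        candidates = [k for k in groups if ".mean." in k]
        if block is not None:
            candidates = [k for k in candidates if k == f"{prefix}mean.{block}"]
        if not candidates:
            raise ValueError("no class-indexed mean block found for relabeling")
        key_idx = groups[sorted(candidates)[0]]
    elif rule == "logit":
        raise ValueError("logit-proportion relabeling requires class-indexed "
                         "logit parameters including the reference; use rule='mean'")
    else:
        raise ValueError(f"unknown relabeling rule {rule!r}")

    out = _copy.deepcopy(draws)
    arr = out.draws
    keys = arr[:, :, key_idx]                       # (chains, kept, C)
    order = np.argsort(keys, axis=2, kind="stable")  # permutation per draw
    for idx_list in groups.values():
        block_vals = arr[:, :, idx_list]
        arr[:, :, idx_list] = np.take_along_axis(block_vals, order, axis=2)
    return out


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------


def plot_epsr_trace(draws: PosteriorDraws, path: str, every: int = 25,
                    params: Sequence[str] = None):
    """Running-EPSR trace (recomputed on growing prefixes) written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(params or draws.names)
    idx = [draws.index(n) for n in names]
    arr = draws.draws[:, :, idx]
    chains, n, P = arr.shape
    steps = list(range(10, n + 1, every)) or [n]
    curves = np.empty((len(steps), P))
    for si, s in enumerate(steps):
        sub = arr[:, :s]
        W = sub.var(axis=1, ddof=1).mean(axis=0)
        B = s * sub.mean(axis=1).var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            curves[si] = np.where(W > 0, np.sqrt(((s - 1) / s * W + B / s) / W), 1.0)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(steps, curves, lw=0.7, alpha=0.6)
    ax.axhline(EPSR_THRESHOLD, color="red", ls="--", lw=1)
    ax.set_xlabel("retained iterations")
    ax.set_ylabel("EPSR")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
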