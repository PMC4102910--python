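"""Metropolis-within-Gibbs posterior sampling for two-level SEM mixture models.

The update cycle exploits that, given the basis rows of the current latent
configuration, every measurement and structural equation is linear in its
coefficients: coefficient blocks and precision blocks are drawn from exact
conjugate conditionals (normal, inverse-gamma, Wishart), class indicators from
their multinomial conditionals, and ordered-probit utilities and MAR-missing
cells from truncated/conditional normals.  Only the latent vectors (when a
function set is genuinely non-linear) and the multinomial-logit coefficients
need random-walk Metropolis steps; step sizes adapt by Robbins–Monro during
burn-in only, which preserves detailed balance in the retained draws.

Label switching is prevented at its source: the class-varying means of the
designated ordered block are parameterized as a base value plus strictly
positive increments with half-normal priors, so class ordering holds in every
single draw.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from . import basis
from .model_spec import (
    MeasurementSpec,
    ModelSpec,
    StructuralSpec,
    _block_entries,
    parameter_index,
    validate_identification,
)
from .simulator import Dataset

__all__ = [
    "PriorSpec",
    "SamplerSettings",
    "PosteriorDraws",
    "GibbsSampler",
    "run_gibbs",
    "complete_data_loglik",
]

_LOG2PI = float(np.log(2.0 * np.pi))


def _lse_rows(a: np.ndarray) -> np.ndarray:
    """Stable row-wise log-sum-exp for a 2-D array."""
    m = np.max(a, axis=1)
    return m + np.log(np.sum(np.exp(a - m[:, None]), axis=1))


def _softmax_rows(a: np.ndarray) -> np.ndarray:
    m = np.max(a, axis=1, keepdims=True)
    e = np.exp(a - m)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Configuration containers
# ---------------------------------------------------------------------------


@dataclass
class PriorSpec:
    """Weakly informative conjugate prior system.

    Coefficient blocks get normal priors whose variance is the residual
    variance of their equation times ``h0`` (larger ``h0`` = flatter prior).
    Precision blocks get Wishart priors (full exogenous covariance blocks,
    degrees of freedom ``wishart_df`` >= dimension, scale centred at the
    identity) or inverse-gamma priors (diagonal residual variances).  Ordered
    class-mean increments get half-normal priors on (0, inf).
    """

    h0: float = 4.0
    loading_mean: float = 1.0
    coef_mean: float = 0.0
    latent_mean_prior: float = 0.0
    wishart_df: Optional[int] = None       # default: dim + 2
    wishart_scale: Optional[np.ndarray] = None  # default: identity
    ig_shape: float = 2.0
    ig_scale: float = 0.5
    logit_sd: float = 1.5
    delta_h0: float = 1.0  # half-normal scale of ordered increments, x block variance

    def wishart_params(self, dim: int):
        df = self.wishart_df if self.wishart_df is not None else dim + 2
        if df < dim:
            raise ValueError("Wishart degrees of freedom must be >= dimension")
        scale = self.wishart_scale if self.wishart_scale is not None else np.eye(dim)
        return df, np.asarray(scale, dtype=float).reshape(dim, dim)


@dataclass
class SamplerSettings:
    chains: int = 3
    iterations: int = 2000
    burn_in: int = 1000
    thinning: int = 1
    seed: int = 0
    target_accept: float = 0.35
    accept_band: tuple = (0.2, 0.5)
    adapt_interval: int = 50
    record_loglik: bool = True
    mixture_subsweeps: int = 3   # extra scans of the (cheap) mixture block per sweep
    eta1_subsweeps: int = 2      # MH scans of the level-1 latents per sweep
    eta2_subsweeps: int = 3      # MH scans of the level-2 latents per sweep

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class PosteriorDraws:
    """Retained draws: chains x iterations x named parameters, plus metadata."""

    names: Sequence[str]
    draws: np.ndarray            # (chains, kept, P)
    loglik: np.ndarray           # (chains, kept) complete-data log-likelihood
    eta1_mean: np.ndarray        # posterior mean of level-1 latents (N, m)
    eta2_mean: Optional[np.ndarray]
    acceptance: dict
    settings: SamplerSettings
    spec_hash: str
    c_freq: Optional[np.ndarray] = None   # (N, C*) posterior class frequencies
    d_freq: Optional[np.ndarray] = None   # (K, D*) posterior class frequencies

    def index(self, name: str) -> int:
        return list(self.names).index(name)

    def param(self, name: str) -> np.ndarray:
        """(chains, kept) draws of one named parameter."""
        return self.draws[:, :, self.index(name)]

    def pooled(self, name: str) -> np.ndarray:
        return self.param(name).reshape(-1)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def to_frame(self):
        import pandas as pd

        chains, kept, P = self.draws.shape
        recs = {
            "chain": np.repeat(np.arange(chains), kept * P),
            "iteration": np.tile(np.repeat(np.arange(kept), P), chains),
            "parameter": np.tile(np.asarray(self.names, dtype=object), chains * kept),
            "value": self.draws.reshape(-1),
        }
        return pd.DataFrame(recs)

    @staticmethod
    def from_frame(frame, settings=None, spec_hash=""):
        import pandas as pd  # noqa: F401

        names = list(dict.fromkeys(frame["parameter"]))
        chains = int(frame["chain"].max()) + 1
        kept = int(frame["iteration"].max()) + 1
        draws = np.full((chains, kept, len(names)), np.nan)
        pos = {n: i for i, n in enumerate(names)}
        draws[frame["chain"].to_numpy(),
              frame["iteration"].to_numpy(),
              frame["parameter"].map(pos).to_numpy()] = frame["value"].to_numpy()
        return PosteriorDraws(names=names, draws=draws,
                              loglik=np.zeros((chains, kept)),
                              eta1_mean=np.zeros((0, 0)), eta2_mean=None,
                              acceptance={}, settings=settings, spec_hash=spec_hash)


# ---------------------------------------------------------------------------
# Compiled problem
# ---------------------------------------------------------------------------


def _link_codes(links):
    return np.array([{"identity": 0, "ordered": 1, "poisson_log": 2}[lk.link]
                     for lk in links], dtype=int)


class _Compiled:
    """Precomputed index structures shared by all update steps."""

    def __init__(self, spec: ModelSpec, data: Dataset):
        self.spec = spec
        self.N = data.n_individuals
        self.K = data.n_clusters
        self.cluster_of = data.cluster_of
        self.y = data.y.to_numpy(dtype=float)
        self.z = data.z.to_numpy(dtype=float)
        self.y_missing = data.y_mask.copy()
        self.z_missing = data.z_mask.copy()
        x1 = data.x1.to_numpy(dtype=float).reshape(self.N, -1)
        x2 = data.x2.to_numpy(dtype=float).reshape(self.K, -1)
        self.g1x = basis.eval_function_matrix(spec.measurement1.g, x1)
        self.G1x = basis.eval_function_matrix(spec.structural1.G, x1)
        self.h1x = basis.eval_function_matrix(spec.mixture1.h, x1)
        st2, me2 = spec.structural2, spec.measurement2
        if spec.has_level2:
            self.g2x = basis.eval_function_matrix(me2.g, x2)
            self.G2x = basis.eval_function_matrix(st2.G, x2)
        self.h2x = basis.eval_function_matrix(spec.mixture2.h, x2)
        self.y_link = _link_codes(spec.y_links)
        self.z_link = _link_codes(spec.z_links)
        if np.any(self.y_link == 2) or np.any(self.z_link == 2):
            raise ValueError("Poisson-link indicators are simulation-only; "
                             "estimation supports identity and ordered links")
        if not spec.measurement1.theta_diagonal or \
                (me2 is not None and me2.n_indicators and not me2.theta_diagonal):
            raise ValueError("estimation requires diagonal residual covariances Theta")
        # ordered categories as ints (NaN-safe)
        self.y_cat = np.where(self.y_missing, 1, np.nan_to_num(self.y, nan=1.0)).astype(int)
        self.z_cat = np.where(self.z_missing, 1, np.nan_to_num(self.z, nan=1.0)).astype(int)
        self.random = spec.random_targets()
        self.random_eqs = sorted({r for _, r, _, _ in self.random})
        self.l1_exact = spec.measurement1.f.is_linear() and spec.structural1.F.is_linear()
        # coordinates of eta1 that appear only through linear terms everywhere:
        # their full conditionals are Gaussian and can be drawn exactly after
        # the MH step on the genuinely non-linear coordinates
        st1 = spec.structural1
        self.lin_coords1 = []
        if not self.l1_exact:
            for v in range(st1.m):
                ok = all(term.kind == "linear" or v not in term.variables
                         for term in spec.measurement1.f.terms)
                ok = ok and all(term.kind == "linear" or v not in term.variables
                                for term in st1.F.terms)
                if ok:
                    self.lin_coords1.append(v)
        self.l2_exact = spec.has_level2 and (me2 is None or me2.f.is_linear()) \
            and st2.F.is_linear()
        self.ordered_block = None
        if spec.ordered_block is not None:
            level, name = spec.ordered_block
            st = spec.structural1 if level == "level1" else spec.structural2
            self.ordered_block = (level, st.latent_names.index(name))
        # anchors for latent initialization: latent index -> (indicator, loading, level)
        self.anchor1 = self._anchors(spec.measurement1, spec.structural1)
        self.anchor2 = self._anchors(me2, st2) if spec.has_level2 and me2 else {}
        # free/fixed column index lists, computed once
        self.meas_cols1 = _meas_cols(spec.measurement1)
        self.meas_cols2 = _meas_cols(me2) if (spec.has_level2 and me2 is not None) else None
        # level-2 endogenous latents that carry a level-1 random intercept and
        # are otherwise unmeasured: their coefficient blocks can be drawn with
        # the random intercept integrated out (partially collapsed Gibbs)
        self.collapsible = {}
        if spec.has_level2:
            for kind, r1, t, u in self.random:
                if kind != "intercept" or u < st2.n_exog:
                    continue
                touched = False
                if me2 is not None:
                    for tt, term in enumerate(me2.f.terms):
                        if u in term.variables and (
                                np.any(me2.Lambda[:, tt] != 0)
                                or np.any(me2.Lambda_free[:, tt])):
                            touched = True
                for tt, term in enumerate(st2.F.terms):
                    if u in term.variables and (
                            np.any(st2.B[:, tt] != 0) or np.any(st2.B_free[:, tt])):
                        touched = True
                if not touched:
                    self.collapsible[u] = r1
        slope_eqs = {r for kind, r, t, u in self.random if kind == "slope"}
        # joint collapse: the level-1 coefficients of the carrying equation are
        # drawn jointly with the level-2 coefficients, random intercept
        # integrated out; requires an exchangeable within-cluster covariance,
        # i.e. no random slopes on that equation
        self.joint_collapse = {u: r1 for u, r1 in self.collapsible.items()
                               if r1 not in slope_eqs}

    @staticmethod
    def _anchors(meas, struct):
        anchors = {}
        if meas is None:
            return anchors
        for idx in range(struct.m):
            for t, term in enumerate(meas.f.terms):
                if term.kind != "linear" or term.var != idx:
                    continue
                for j in range(meas.n_indicators):
                    if meas.Lambda[j, t] != 0 and not meas.Lambda_free[j, t]:
                        anchors[idx] = (j, meas.Lambda[j, t])
                        break
                if idx in anchors:
                    break
        return anchors


def _meas_cols(meas: MeasurementSpec):
    """Per-indicator free/fixed column indices of the measurement equation."""
    cols = []
    for j in range(meas.n_indicators):
        cols.append({
            "lam_free": np.flatnonzero(meas.Lambda_free[j]),
            "lam_fixed": np.flatnonzero(~meas.Lambda_free[j] & (meas.Lambda[j] != 0)),
            "k_free": np.flatnonzero(meas.K_free[j]),
            "k_fixed": np.flatnonzero(~meas.K_free[j] & (meas.K[j] != 0)),
        })
    return cols


def _theta_vec(meas: MeasurementSpec, link_codes: np.ndarray) -> np.ndarray:
    th = np.diag(meas.Theta).copy()
    th[link_codes == 1] = 1.0  # ordered probit: residual variance fixed at 1
    return th


def _meas_mean(meas: MeasurementSpec, eta: np.ndarray, gx: np.ndarray) -> np.ndarray:
    mean = meas.nu + basis.eval_function_matrix(meas.f, eta) @ meas.Lambda.T
    if meas.g.out_dim:
        mean = mean + gx @ meas.K.T
    return mean


def _chol_logdet(L: np.ndarray) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(L))))


# ---------------------------------------------------------------------------
# Sampler state
# ---------------------------------------------------------------------------


class _State:
    __slots__ = ("spec", "eta1", "eta2", "C", "D", "ystar", "zstar",
                 "f1b", "F1b", "f2b", "F2b", "cache",
                 "step_eta1", "step_eta2", "step_logit1", "step_logit2",
                 "acc", "tries")

    def __init__(self):
        self.acc = {}
        self.tries = {}
        self.cache = {}


# ---------------------------------------------------------------------------
# Main sampler
# ---------------------------------------------------------------------------


class GibbsSampler:
    """One-chain sampler; ``run_gibbs`` orchestrates multiple chains."""

    def __init__(self, spec: ModelSpec, data: Dataset, priors: PriorSpec,
                 settings: SamplerSettings):
        report = validate_identification(spec)
        if not report.ok:
            raise ValueError("model not identified:\n" + str(report))
        self.spec = spec
        self.comp = _Compiled(spec, data)
        self.priors = priors
        self.settings = settings
        self.entries = None  # filled per state (bound to its spec copy)

    # -- initialization ----------------------------------------------------

    def init_state(self, rng: np.random.Generator) -> _State:
        comp, spec = self.comp, self.spec
        st = _State()
        st.spec = copy.deepcopy(spec)
        self.entries = _block_entries(st.spec)

        # augmented indicators: observed values; ordered mapped to centred scores;
        # missing cells to column means
        ystar = comp.y.copy()
        for j in range(len(spec.y_names)):
            if comp.y_link[j] == 1:
                ncat = spec.y_links[j].n_categories
                ystar[:, j] = comp.y_cat[:, j] - (ncat + 1) / 2.0
        col_mean = np.nanmean(np.where(comp.y_missing, np.nan, ystar), axis=0)
        col_mean = np.nan_to_num(col_mean)
        ystar = np.where(comp.y_missing | ~np.isfinite(ystar), col_mean, ystar)
        st.ystar = ystar
        zstar = comp.z.copy() if comp.z.size else comp.z.reshape(comp.K, -1)
        if zstar.size:
            for l in range(len(spec.z_names)):
                if comp.z_link[l] == 1:
                    ncat = spec.z_links[l].n_categories
                    zstar[:, l] = comp.z_cat[:, l] - (ncat + 1) / 2.0
            zmean = np.nan_to_num(np.nanmean(np.where(comp.z_missing, np.nan, zstar), axis=0))
            zstar = np.where(comp.z_missing | ~np.isfinite(zstar), zmean, zstar)
        st.zstar = zstar

        # latents from anchored indicators (+ per-chain jitter for overdispersion)
        m1 = spec.structural1.m
        eta1 = np.zeros((comp.N, m1))
        for idx in range(m1):
            if idx in comp.anchor1:
                j, lam = comp.anchor1[idx]
                eta1[:, idx] = (st.ystar[:, j] - st.spec.measurement1.nu[j]) / lam
        eta1 += 0.2 * rng.standard_normal(eta1.shape)
        st.eta1 = eta1
        if spec.has_level2:
            U = spec.structural2.m
            eta2 = np.zeros((comp.K, U))
            for idx in range(U):
                if idx in comp.anchor2:
                    j, lam = comp.anchor2[idx]
                    eta2[:, idx] = (st.zstar[:, j] - st.spec.measurement2.nu[j]) / lam
            for kind, r, t, u in comp.random:
                if kind == "intercept":
                    sums = np.bincount(comp.cluster_of, weights=eta1[:, r], minlength=comp.K)
                    eta2[:, u] = sums / np.maximum(np.bincount(comp.cluster_of, minlength=comp.K), 1)
            eta2 += 0.2 * rng.standard_normal(eta2.shape)
            st.eta2 = eta2
        else:
            st.eta2 = None

        st.C = rng.integers(0, spec.mixture1.n_classes, comp.N)
        st.D = rng.integers(0, spec.mixture2.n_classes, comp.K)

        self._neutral_params(st, rng)
        self.refresh_basis(st, 1)
        self.refresh_basis(st, 2)
        st.step_eta1 = 0.5
        st.step_eta2 = 0.5
        st.step_logit1 = 0.5
        st.step_logit2 = 0.5
        for key in ("eta1", "eta2", "logit1", "logit2"):
            st.acc[key] = 0
            st.tries[key] = 0
        return st

    def _neutral_params(self, st: _State, rng: np.random.Generator):
        """Data-scale neutral starting values for all free parameters."""
        spec_c = st.spec
        jitter = lambda s: rng.normal(0.0, s)

        def init_level(meas, struct, eta, star, link):
            if meas is not None:
                J = meas.n_indicators
                for j in range(J):
                    if meas.nu_free[j]:
                        meas.nu[j] = star[:, j].mean() + jitter(0.1)
                meas.Lambda[meas.Lambda_free] = 1.0 + 0.1 * rng.standard_normal(
                    int(meas.Lambda_free.sum()))
                meas.K[meas.K_free] = 0.0
                if meas.theta_free:
                    for j in range(J):
                        if link[j] == 0:
                            v = star[:, j].var()
                            meas.Theta[j, j] = max(0.5 * v, 0.05)
            n_ex = struct.n_exog
            if n_ex:
                emp_mean = eta[:, :n_ex].mean(axis=0)
                emp_cov = np.cov(eta[:, :n_ex].T).reshape(n_ex, n_ex)
                emp_cov += 0.05 * np.eye(n_ex)
                for cls in range(struct.n_classes):
                    for p in range(n_ex):
                        if struct.alpha_free[p]:
                            struct.alpha[cls, p] = emp_mean[p] + 0.2 * cls + jitter(0.1)
                if struct.psi_free:
                    mats = struct.Psi_exog.reshape(-1, n_ex, n_ex)
                    for mat in mats:
                        mat[:] = emp_cov
            for r in range(n_ex, struct.m):
                if struct.alpha_free[r]:
                    struct.alpha[:, r] = eta[:, r].mean() + jitter(0.1)
                idx = r - n_ex
                if struct.psi_free:
                    struct.psi_end[idx] = max(0.5 * eta[:, r].var(), 0.05)
            struct.B[struct.B_free] = 0.0 + 0.05 * rng.standard_normal(
                int(struct.B_free.sum()))
            struct.Gamma[struct.Gamma_free] = 0.0

        init_level(spec_c.measurement1, spec_c.structural1, st.eta1, st.ystar, self.comp.y_link)
        if spec_c.has_level2:
            init_level(spec_c.measurement2, spec_c.structural2, st.eta2, st.zstar, self.comp.z_link)
        for mix in (spec_c.mixture1, spec_c.mixture2):
            mix.a[1:] = 0.0
            mix.b[1:] = 0.0
        for links, codes in ((spec_c.y_links, self.comp.y_link),
                             (spec_c.z_links, self.comp.z_link)):
            for j, lk in enumerate(links):
                if codes[j] == 1:
                    lk.thresholds[:] = np.arange(lk.n_categories - 1, dtype=float)

    # -- building blocks ---------------------------------------------------

    def refresh_basis(self, st: _State, level: int):
        """Recompute cached basis matrices after a latent-vector change."""
        spec_c = st.spec
        if level == 1:
            st.f1b = basis.eval_function_matrix(spec_c.measurement1.f, st.eta1)
            st.F1b = basis.eval_function_matrix(spec_c.structural1.F, st.eta1)
        elif spec_c.has_level2:
            me2 = spec_c.measurement2
            st.f2b = basis.eval_function_matrix(me2.f, st.eta2) \
                if me2 is not None else None
            st.F2b = basis.eval_function_matrix(spec_c.structural2.F, st.eta2)

    def _endo_means(self, st: _State, level: int, eta=None, Fb=None) -> np.ndarray:
        """Per-unit structural means of the endogenous latents (n, n_endog)."""
        comp, spec_c = self.comp, st.spec
        if level == 1:
            struct, Gx, n = spec_c.structural1, comp.G1x, comp.N
            if eta is None:
                eta, Fb = st.eta1, (st.F1b if Fb is None else Fb)
        else:
            struct, Gx, n = spec_c.structural2, comp.G2x, comp.K
            if eta is None:
                eta, Fb = st.eta2, (st.F2b if Fb is None else Fb)
        if Fb is None:
            Fb = basis.eval_function_matrix(struct.F, eta)
        out = np.empty((n, struct.n_endog))
        rints = {r: u for kind, r, t, u in comp.random if kind == "intercept"}
        rslopes = {(r, t): u for kind, r, t, u in comp.random if kind == "slope"}
        for r in range(struct.n_exog, struct.m):
            if level == 1 and r in rints:
                mean = st.eta2[comp.cluster_of, rints[r]] + Fb @ struct.B[r]
            elif level == 1 and any(rr == r for rr, _ in rslopes):
                Brow = struct.B[r].copy()
                extra = 0.0
                for (rr, t), u in rslopes.items():
                    if rr == r:
                        Brow[t] = 0.0
                        extra = extra + st.eta2[comp.cluster_of, u] * Fb[:, t]
                mean = struct.alpha[0, r] + Fb @ Brow + extra
            else:
                mean = struct.alpha[0, r] + Fb @ struct.B[r]
            if struct.G.out_dim:
                mean = mean + Gx @ struct.Gamma[r]
            out[:, r - struct.n_exog] = mean
        return out

    def _exog_loglik(self, struct: StructuralSpec, eta_ex, classes,
                     cache=None) -> np.ndarray:
        """(n,) class-conditional Gaussian log-density of the exogenous block."""
        n = len(classes)
        if struct.n_exog == 0:
            return np.zeros(n)
        out = np.empty(n)
        single = struct.n_classes == 1
        for cls in range(struct.n_classes):
            mask = None if single else classes == cls
            if mask is not None and not mask.any():
                continue
            key = (id(struct), cls)
            hit = None if cache is None else cache.get(key)
            if hit is None:
                psi = struct.psi_exog_for(cls)
                L = np.linalg.cholesky(psi)
                Linv = np.linalg.inv(L)
                if cache is not None:
                    cache[key] = (L, Linv)
            else:
                L, Linv = hit
            diff = (eta_ex if single else eta_ex[mask]) \
                - struct.alpha[cls, : struct.n_exog]
            sol = diff @ Linv.T
            val = -0.5 * (np.einsum("ij,ij->i", sol, sol)
                          + _chol_logdet(L) + struct.n_exog * _LOG2PI)
            if single:
                out = val
            else:
                out[mask] = val
        return out

    def _meas_loglik_rows(self, st: _State, level: int, eta=None, fb=None) -> np.ndarray:
        comp, spec_c = self.comp, st.spec
        if level == 1:
            meas, gx, star, link = spec_c.measurement1, comp.g1x, st.ystar, comp.y_link
            if eta is None:
                eta, fb = st.eta1, (st.f1b if fb is None else fb)
        else:
            meas, gx, star, link = spec_c.measurement2, comp.g2x, st.zstar, comp.z_link
            if eta is None:
                eta, fb = st.eta2, (st.f2b if fb is None else fb)
        if meas is None or meas.n_indicators == 0:
            return np.zeros(len(eta))
        if fb is None:
            fb = basis.eval_function_matrix(meas.f, eta)
        th = _theta_vec(meas, link)
        mean = meas.nu + fb @ meas.Lambda.T
        if meas.g.out_dim:
            mean = mean + gx @ meas.K.T
        const = float(np.log(th).sum()) + meas.n_indicators * _LOG2PI
        return -0.5 * (((star - mean) ** 2) @ (1.0 / th) + const)

    def _endo_loglik_rows(self, st: _State, level: int, eta=None, Fb=None) -> np.ndarray:
        spec_c = st.spec
        struct = spec_c.structural1 if level == 1 else spec_c.structural2
        if struct.n_endog == 0:
            n = self.comp.N if level == 1 else self.comp.K
            return np.zeros(n)
        if eta is None:
            eta_use = st.eta1 if level == 1 else st.eta2
            means = self._endo_means(st, level)
        else:
            eta_use = eta
            means = self._endo_means(st, level, eta_use, Fb=Fb)
        resid = eta_use[:, struct.n_exog:] - means
        const = float(np.log(struct.psi_end).sum()) + struct.n_endog * _LOG2PI
        return -0.5 * ((resid ** 2) @ (1.0 / struct.psi_end) + const)

    # -- update steps ------------------------------------------------------

    def update_augmented(self, st: _State, rng: np.random.Generator):
        """Ordered-probit utilities, their thresholds, and MAR-missing cells."""
        comp, spec_c = self.comp, st.spec
        for level in (1, 2):
            if level == 1:
                meas, gx, star, link = spec_c.measurement1, comp.g1x, st.ystar, comp.y_link
                eta, missing, cat = st.eta1, comp.y_missing, comp.y_cat
                links = spec_c.y_links
            else:
                if not spec_c.has_level2 or spec_c.measurement2 is None \
                        or spec_c.measurement2.n_indicators == 0:
                    continue
                meas, gx, star, link = spec_c.measurement2, comp.g2x, st.zstar, comp.z_link
                eta, missing, cat = st.eta2, comp.z_missing, comp.z_cat
                links = spec_c.z_links
            if meas.n_indicators == 0:
                continue
            need = missing.any() or (link == 1).any()
            if not need:
                continue
            fb = st.f1b if level == 1 else st.f2b
            mean = meas.nu + fb @ meas.Lambda.T
            if meas.g.out_dim:
                mean = mean + gx @ meas.K.T
            th = _theta_vec(meas, link)
            for j in range(meas.n_indicators):
                col_missing = missing[:, j]
                if link[j] == 1:
                    lk = links[j]
                    bounds = np.concatenate(([-np.inf], lk.thresholds, [np.inf]))
                    obs = ~col_missing
                    lo = bounds[cat[obs, j] - 1]
                    hi = bounds[cat[obs, j]]
                    mu = mean[obs, j]
                    a, b = ndtr(lo - mu), ndtr(hi - mu)
                    u = rng.uniform(np.minimum(a, b - 1e-12), b)
                    star[obs, j] = mu + ndtri(np.clip(u, 1e-12, 1 - 1e-12))
                    if col_missing.any():
                        star[col_missing, j] = mean[col_missing, j] + \
                            rng.standard_normal(int(col_missing.sum()))
                    # thresholds: uniform conditionals respecting monotonicity
                    ncat = lk.n_categories
                    for s in range(1, ncat - 1):  # first interior threshold fixed at 0
                        below = star[obs, j][cat[obs, j] == s + 1]
                        above = star[obs, j][cat[obs, j] == s + 2]
                        lo_b = below.max() if below.size else (lk.thresholds[s - 1])
                        hi_b = above.min() if above.size else lo_b + 1.0
                        lo_b = max(lo_b, lk.thresholds[s - 1])
                        if s + 1 < ncat - 1:
                            hi_b = min(hi_b, lk.thresholds[s + 1])
                        if hi_b > lo_b:
                            lk.thresholds[s] = rng.uniform(lo_b, hi_b)
                elif col_missing.any():
                    star[col_missing, j] = mean[col_missing, j] + \
                        np.sqrt(th[j]) * rng.standard_normal(int(col_missing.sum()))

    def update_classes(self, st: _State, rng: np.random.Generator):
        """Multinomial conditionals for D (clusters) then C (individuals)."""
        comp, spec_c = self.comp, st.spec
        mix2 = spec_c.mixture2
        if spec_c.has_level2 and mix2.n_classes > 1:
            st2 = spec_c.structural2
            logp = comp.h2x @ mix2.b.T + mix2.a  # (K, D*)
            for d in range(mix2.n_classes):
                cls = np.full(comp.K, d)
                logp[:, d] += self._exog_loglik(st2, st.eta2[:, : st2.n_exog], cls, st.cache)
            st.D = _categorical_rows(_softmax_rows(logp), rng)
        mix1 = spec_c.mixture1
        if mix1.n_classes > 1:
            st1 = spec_c.structural1
            logp = comp.h1x @ mix1.b.T + mix1.a
            for c in range(mix1.n_classes):
                cls = np.full(comp.N, c)
                logp[:, c] += self._exog_loglik(st1, st.eta1[:, : st1.n_exog], cls, st.cache)
            st.C = _categorical_rows(_softmax_rows(logp), rng)

    # latent vectors -------------------------------------------------------

    def _eta1_logtarget(self, st: _State, eta=None, fb=None, Fb=None) -> np.ndarray:
        spec_c = st.spec
        st1 = spec_c.structural1
        eta_ex = (st.eta1 if eta is None else eta)[:, : st1.n_exog]
        ll = self._meas_loglik_rows(st, 1, eta, fb)
        ll += self._exog_loglik(st1, eta_ex, st.C, st.cache)
        ll += self._endo_loglik_rows(st, 1, eta, Fb)
        return ll

    def _eta2_logtarget(self, st: _State, eta2=None, fb=None, Fb2=None) -> np.ndarray:
        comp, spec_c = self.comp, st.spec
        st2 = spec_c.structural2
        ll = self._meas_loglik_rows(st, 2, eta2, fb)
        eta2_use = st.eta2 if eta2 is None else eta2
        ll += self._exog_loglik(st2, eta2_use[:, : st2.n_exog], st.D, st.cache)
        ll += self._endo_loglik_rows(st, 2, eta2, Fb2)
        eta2 = eta2_use
        # level-1 coupling through random coefficients
        if comp.random:
            st1 = spec_c.structural1
            Fb = st.F1b
            rints = {r: u for kind, r, t, u in comp.random if kind == "intercept"}
            rslopes = {}
            for kind, r, t, u in comp.random:
                if kind == "slope":
                    rslopes.setdefault(r, []).append((t, u))
            for r in comp.random_eqs:
                idx = r - st1.n_exog
                mean = np.full(comp.N, st1.alpha[0, r])
                if r in rints:
                    mean = eta2[comp.cluster_of, rints[r]]
                Brow = st1.B[r].copy()
                for t, u in rslopes.get(r, []):
                    Brow[t] = 0.0
                contrib = Fb @ Brow
                for t, u in rslopes.get(r, []):
                    contrib = contrib + eta2[comp.cluster_of, u] * Fb[:, t]
                if st1.G.out_dim:
                    contrib = contrib + comp.G1x @ st1.Gamma[r]
                resid = st.eta1[:, r] - mean - contrib
                ll += np.bincount(comp.cluster_of,
                                  weights=-0.5 * resid ** 2 / st1.psi_end[idx],
                                  minlength=comp.K)
        return ll

    def _exact_eta1(self, st: _State, rng: np.random.Generator):
        """Exact Gaussian conditional draw when f1 and F1 are linear."""
        comp, spec_c = self.comp, st.spec
        me, st1 = spec_c.measurement1, spec_c.structural1
        m = st1.m
        Lam = me.Lambda @ _lin_sel(me.f, m)
        th = _theta_vec(me, comp.y_link)
        meas_prec = (Lam.T / th) @ Lam
        resid_star = st.ystar - me.nu - (comp.g1x @ me.K.T if me.g.out_dim else 0.0)
        meas_lin = (resid_star / th) @ Lam  # (N, m)
        Bt = st1.B @ _lin_sel(st1.F, m)
        rints = {r: u for kind, r, t, u in comp.random if kind == "intercept"}
        A = np.eye(m) - Bt
        # intercept vector per individual (class means for exog, intercepts/random for endo)
        a_vec = st1.alpha[st.C].copy()
        for r in range(st1.n_exog, m):
            a_vec[:, r] = st1.alpha[0, r]
            if r in rints:
                a_vec[:, r] = st.eta2[comp.cluster_of, rints[r]]
        if st1.G.out_dim:
            a_vec[:, st1.n_exog:] += comp.G1x @ st1.Gamma[st1.n_exog:].T
        for cls in range(st1.n_classes):
            mask = st.C == cls
            if not mask.any():
                continue
            psi_full = np.zeros((m, m))
            if st1.n_exog:
                psi_full[: st1.n_exog, : st1.n_exog] = st1.psi_exog_for(cls)
            for rr in range(st1.n_endog):
                psi_full[st1.n_exog + rr, st1.n_exog + rr] = st1.psi_end[rr]
            Ainv = np.linalg.inv(A)
            prior_cov = Ainv @ psi_full @ Ainv.T
            prior_prec = np.linalg.inv(prior_cov)
            P = prior_prec + meas_prec
            mean_prior = a_vec[mask] @ Ainv.T
            bvec = mean_prior @ prior_prec.T + meas_lin[mask]
            L = np.linalg.cholesky(P)
            mu = np.linalg.solve(L.T, np.linalg.solve(L, bvec.T)).T
            noise = np.linalg.solve(L.T, rng.standard_normal((m, int(mask.sum())))).T
            st.eta1[mask] = mu + noise

    def _exact_eta2(self, st: _State, rng: np.random.Generator):
        """Exact Gaussian conditional draw for eta2 when f2 and F2 are linear."""
        comp, spec_c = self.comp, st.spec
        me, st2 = spec_c.measurement2, spec_c.structural2
        U = st2.m
        if me is not None and me.n_indicators:
            Lam = me.Lambda @ _lin_sel(me.f, U)
            th = _theta_vec(me, comp.z_link)
            meas_prec = (Lam.T / th) @ Lam
            resid_star = st.zstar - me.nu - (comp.g2x @ me.K.T if me.g.out_dim else 0.0)
            meas_lin = (resid_star / th) @ Lam
        else:
            meas_prec = np.zeros((U, U))
            meas_lin = np.zeros((comp.K, U))
        Bt = st2.B @ _lin_sel(st2.F, U)
        A = np.eye(U) - Bt
        Ainv = np.linalg.inv(A)
        a_vec = st2.alpha[st.D].copy()
        for r in range(st2.n_exog, U):
            a_vec[:, r] = st2.alpha[0, r]
        if st2.G.out_dim:
            a_vec[:, st2.n_exog:] += comp.G2x @ st2.Gamma[st2.n_exog:].T
        # level-1 coupling (always linear in eta2 given eta1)
        st1 = spec_c.structural1
        couple_prec = np.zeros((comp.K, U, U))
        couple_lin = np.zeros((comp.K, U))
        if comp.random:
            Fb = basis.eval_function_matrix(st1.F, st.eta1)
            rints = {r: u for kind, r, t, u in comp.random if kind == "intercept"}
            rslopes = {}
            for kind, r, t, u in comp.random:
                if kind == "slope":
                    rslopes.setdefault(r, []).append((t, u))
            for r in comp.random_eqs:
                idx = r - st1.n_exog
                psi_r = st1.psi_end[idx]
                W = np.zeros((comp.N, U))
                base = st.eta1[:, r].copy()
                if r in rints:
                    W[:, rints[r]] = 1.0
                else:
                    base -= st1.alpha[0, r]
                Brow = st1.B[r].copy()
                for t, u in rslopes.get(r, []):
                    Brow[t] = 0.0
                    W[:, u] = Fb[:, t]
                base -= Fb @ Brow
                if st1.G.out_dim:
                    base -= comp.G1x @ st1.Gamma[r]
                for u in range(U):
                    wu = W[:, u]
                    if not np.any(wu):
                        continue
                    couple_lin[:, u] += np.bincount(
                        comp.cluster_of, weights=wu * base / psi_r, minlength=comp.K)
                    for v in range(U):
                        wv = W[:, v]
                        if np.any(wv):
                            couple_prec[:, u, v] += np.bincount(
                                comp.cluster_of, weights=wu * wv / psi_r, minlength=comp.K)
        for d in range(st2.n_classes):
            mask = st.D == d
            if not mask.any():
                continue
            psi_full = np.zeros((U, U))
            if st2.n_exog:
                psi_full[: st2.n_exog, : st2.n_exog] = st2.psi_exog_for(d)
            for rr in range(st2.n_endog):
                psi_full[st2.n_exog + rr, st2.n_exog + rr] = st2.psi_end[rr]
            prior_cov = Ainv @ psi_full @ Ainv.T
            prior_prec = np.linalg.inv(prior_cov)
            P = prior_prec + meas_prec + couple_prec[mask]
            mean_prior = a_vec[mask] @ Ainv.T
            bvec = mean_prior @ prior_prec.T + meas_lin[mask] + couple_lin[mask]
            L = np.linalg.cholesky(P)
            mu = np.squeeze(np.linalg.solve(
                np.transpose(L, (0, 2, 1)),
                np.linalg.solve(L, bvec[:, :, None])), axis=-1)
            noise = np.squeeze(np.linalg.solve(
                np.transpose(L, (0, 2, 1)),
                rng.standard_normal((int(mask.sum()), U, 1))), axis=-1)
            st.eta2[mask] = mu + noise

    def _exact_coord_l1(self, st: _State, v: int, rng: np.random.Generator):
        """Exact Gaussian draw of one conditionally-linear eta1 coordinate.

        Valid whenever every basis term involving the coordinate is linear:
        the measurement rows, its own structural equation (or exogenous
        conditional prior) and every downstream equation it predicts are then
        all Gaussian in it.
        """
        comp, spec_c = self.comp, st.spec
        me, st1 = spec_c.measurement1, spec_c.structural1
        N = comp.N
        th = _theta_vec(me, comp.y_link)
        lam_v = np.zeros(me.n_indicators)
        lin_cols = []
        for t, term in enumerate(me.f.terms):
            if term.kind == "linear" and term.var == v:
                lam_v += me.Lambda[:, t]
                lin_cols.append(t)
        eta_v = st.eta1[:, v]
        prec = np.full(N, (lam_v ** 2 / th).sum())
        mean_meas = me.nu + st.f1b @ me.Lambda.T
        if me.g.out_dim:
            mean_meas = mean_meas + comp.g1x @ me.K.T
        resid0 = st.ystar - mean_meas + np.outer(eta_v, lam_v)
        lin = resid0 @ (lam_v / th)
        # own equation / exogenous conditional prior
        endo_means = self._endo_means(st, 1) if st1.n_endog else None
        if v < st1.n_exog:
            for cls in range(st1.n_classes):
                mask = slice(None) if st1.n_classes == 1 else st.C == cls
                Q = np.linalg.inv(st1.psi_exog_for(cls))
                resid = st.eta1[mask, : st1.n_exog] - st1.alpha[cls, : st1.n_exog]
                cond = st1.alpha[cls, v] - (resid @ Q[v] - Q[v, v] * resid[:, v]) / Q[v, v]
                prec_add = Q[v, v]
                if st1.n_classes == 1:
                    prec += prec_add
                    lin += prec_add * cond
                else:
                    prec[mask] += prec_add
                    lin[mask] += prec_add * cond
        else:
            idx = v - st1.n_exog
            prec += 1.0 / st1.psi_end[idx]
            lin += endo_means[:, idx] / st1.psi_end[idx]
        # downstream equations with active linear terms of v
        rslopes = {(r, t): u for kind, r, t, u in comp.random if kind == "slope"}
        for t, term in enumerate(st1.F.terms):
            if term.kind != "linear" or term.var != v:
                continue
            for r in range(max(st1.n_exog, v + 1), st1.m):
                coef = None
                if (r, t) in rslopes:
                    coef = st.eta2[comp.cluster_of, rslopes[(r, t)]]
                elif st1.B[r, t] != 0 or st1.B_free[r, t]:
                    coef = st1.B[r, t]
                if coef is None:
                    continue
                ridx = r - st1.n_exog
                resid_r = st.eta1[:, r] - endo_means[:, ridx] + coef * eta_v
                prec += np.square(coef) / st1.psi_end[ridx]
                lin += coef * resid_r / st1.psi_end[ridx]
        new = lin / prec + rng.standard_normal(N) / np.sqrt(prec)
        st.eta1[:, v] = new
        for t in lin_cols:
            st.f1b[:, t] = new
        for t, term in enumerate(st1.F.terms):
            if term.kind == "linear" and term.var == v:
                st.F1b[:, t] = new

    def _eta2_mh_scan(self, st: _State, rng: np.random.Generator, adapt: bool):
        comp = self.comp
        spec_c = st.spec
        me2 = spec_c.measurement2
        scale = self._latent_scale(spec_c.structural2).copy()
        scale[list(comp.collapsible)] = 0.0  # exact conditional draws cover these
        prop = st.eta2 + st.step_eta2 * scale * rng.standard_normal(st.eta2.shape)
        prop_fb = None if me2 is None else basis.eval_function_matrix(me2.f, prop)
        prop_Fb = basis.eval_function_matrix(spec_c.structural2.F, prop)
        cur = self._eta2_logtarget(st)
        new = self._eta2_logtarget(st, prop, prop_fb, prop_Fb)
        accept = np.log(rng.random(comp.K)) < new - cur
        st.eta2[accept] = prop[accept]
        if st.f2b is not None and prop_fb is not None:
            st.f2b[accept] = prop_fb[accept]
        st.F2b[accept] = prop_Fb[accept]
        st.acc["eta2"] += int(accept.sum())
        st.tries["eta2"] += comp.K
        if adapt:
            st.step_eta2 = _rm_adapt(st.step_eta2, accept.mean(),
                                     self.settings.target_accept)

    def update_latents(self, st: _State, rng: np.random.Generator, adapt: bool):
        comp = self.comp
        has_rslope = any(kind == "slope" for kind, *_ in comp.random)
        if comp.l1_exact and not has_rslope:
            self._exact_eta1(st, rng)
            self.refresh_basis(st, 1)
        else:
            spec_c = st.spec
            scale = self._latent_scale(spec_c.structural1).copy()
            scale[comp.lin_coords1] = 0.0  # exact conditional draws cover these
            for _ in range(max(1, self.settings.eta1_subsweeps)):
                prop = st.eta1 + st.step_eta1 * scale * rng.standard_normal(st.eta1.shape)
                prop_fb = basis.eval_function_matrix(spec_c.measurement1.f, prop)
                prop_Fb = basis.eval_function_matrix(spec_c.structural1.F, prop)
                cur = self._eta1_logtarget(st)
                new = self._eta1_logtarget(st, prop, prop_fb, prop_Fb)
                accept = np.log(rng.random(comp.N)) < new - cur
                st.eta1[accept] = prop[accept]
                st.f1b[accept] = prop_fb[accept]
                st.F1b[accept] = prop_Fb[accept]
                st.acc["eta1"] += int(accept.sum())
                st.tries["eta1"] += comp.N
                if adapt:
                    st.step_eta1 = _rm_adapt(st.step_eta1, accept.mean(),
                                             self.settings.target_accept)
            for v in comp.lin_coords1:
                self._exact_coord_l1(st, v, rng)
        if st.spec.has_level2:
            if comp.l2_exact:
                self._exact_eta2(st, rng)
                self.refresh_basis(st, 2)
            else:
                spec_c = st.spec
                me2 = spec_c.measurement2
                scale = self._latent_scale(spec_c.structural2)
                prop = st.eta2 + st.step_eta2 * scale * rng.standard_normal(st.eta2.shape)
                prop_fb = None if me2 is None else                     basis.eval_function_matrix(me2.f, prop)
                prop_Fb = basis.eval_function_matrix(spec_c.structural2.F, prop)
                cur = self._eta2_logtarget(st)
                new = self._eta2_logtarget(st, prop, prop_fb, prop_Fb)
                accept = np.log(rng.random(comp.K)) < new - cur
                st.eta2[accept] = prop[accept]
                if st.f2b is not None and prop_fb is not None:
                    st.f2b[accept] = prop_fb[accept]
                st.F2b[accept] = prop_Fb[accept]
                st.acc["eta2"] += int(accept.sum())
                st.tries["eta2"] += comp.K
                if adapt:
                    st.step_eta2 = _rm_adapt(st.step_eta2, accept.mean(),
                                             self.settings.target_accept)

    @staticmethod
    def _latent_scale(struct: StructuralSpec) -> np.ndarray:
        scale = np.ones(struct.m)
        if struct.n_exog:
            psi = struct.psi_exog_for(0)
            scale[: struct.n_exog] = np.sqrt(np.diag(psi))
        scale[struct.n_exog:] = np.sqrt(struct.psi_end)
        return scale

    # coefficients ---------------------------------------------------------

    def _draw_regression(self, w, X, sigma2, prior_mean, h0, rng):
        """Conjugate normal draw for a linear block with N(m0, sigma2*h0) prior."""
        p = X.shape[1]
        XtX = X.T @ X + np.eye(p) / h0
        rhs = X.T @ w + prior_mean / h0
        try:
            L = np.linalg.cholesky(XtX)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(XtX + 1e-8 * np.eye(p))
        half = np.linalg.solve(L, rhs)
        return np.linalg.solve(
            L.T, half + np.sqrt(sigma2) * rng.standard_normal(p))

    def update_coefficients(self, st: _State, rng: np.random.Generator):
        """Conjugate draws for measurement and structural coefficient blocks."""
        comp, spec_c = self.comp, st.spec
        pri = self.priors
        # measurement blocks
        for level in (1, 2):
            if level == 1:
                meas, gx, star, link, eta = (spec_c.measurement1, comp.g1x,
                                             st.ystar, comp.y_link, st.eta1)
                Fb, cols_info = st.f1b, comp.meas_cols1
            else:
                if not spec_c.has_level2 or spec_c.measurement2 is None:
                    continue
                meas, gx, star, link, eta = (spec_c.measurement2, comp.g2x,
                                             st.zstar, comp.z_link, st.eta2)
                Fb, cols_info = st.f2b, comp.meas_cols2
            if meas.n_indicators == 0:
                continue
            th = _theta_vec(meas, link)
            ones = np.ones(len(eta))
            for j in range(meas.n_indicators):
                ci = cols_info[j]
                lam_idx, k_idx = ci["lam_free"], ci["k_free"]
                n_cols = int(meas.nu_free[j]) + lam_idx.size + k_idx.size
                if n_cols == 0:
                    continue
                parts, m0 = [], []
                if meas.nu_free[j]:
                    parts.append(ones[:, None])
                    m0.append(pri.coef_mean)
                if lam_idx.size:
                    parts.append(Fb[:, lam_idx])
                    m0.extend([pri.loading_mean] * lam_idx.size)
                if k_idx.size:
                    parts.append(gx[:, k_idx])
                    m0.extend([pri.coef_mean] * k_idx.size)
                offset = 0.0 if meas.nu_free[j] else meas.nu[j]
                if ci["lam_fixed"].size:
                    offset = offset + Fb[:, ci["lam_fixed"]] @ meas.Lambda[j, ci["lam_fixed"]]
                if ci["k_fixed"].size:
                    offset = offset + gx[:, ci["k_fixed"]] @ meas.K[j, ci["k_fixed"]]
                X = parts[0] if len(parts) == 1 else np.hstack(parts)
                beta = self._draw_regression(star[:, j] - offset, X, th[j],
                                             np.asarray(m0), pri.h0, rng)
                pos = 0
                if meas.nu_free[j]:
                    meas.nu[j] = beta[pos]
                    pos += 1
                if lam_idx.size:
                    meas.Lambda[j, lam_idx] = beta[pos: pos + lam_idx.size]
                    pos += lam_idx.size
                if k_idx.size:
                    meas.K[j, k_idx] = beta[pos:]
        # structural endogenous equations
        rints = {r: u for kind, r, t, u in comp.random if kind == "intercept"}
        rslopes = {}
        for kind, r, t, u in comp.random:
            if kind == "slope":
                rslopes.setdefault(r, []).append(t)
        for level in (1, 2):
            if level == 1:
                struct, Gx, eta, n = spec_c.structural1, comp.G1x, st.eta1, comp.N
                my_rints, my_rslopes = rints, rslopes
                Fb = st.F1b
            else:
                if not spec_c.has_level2:
                    continue
                struct, Gx, eta, n = spec_c.structural2, comp.G2x, st.eta2, comp.K
                my_rints, my_rslopes = {}, {}
                Fb = st.F2b
            if struct.n_endog == 0:
                continue
            for r in range(struct.n_exog, struct.m):
                if level == 1 and r in comp.joint_collapse.values():
                    continue  # drawn jointly with its level-2 equation below
                if level == 2 and r in comp.collapsible:
                    self._collapsed_endo2_update(st, r, rng)
                    continue
                idx = r - struct.n_exog
                cols, m0 = [], []
                if struct.alpha_free[r] and r not in my_rints:
                    cols.append(np.ones(n))
                    m0.append(pri.coef_mean)
                b_idx = [t for t in np.flatnonzero(struct.B_free[r])
                         if t not in my_rslopes.get(r, [])]
                for t in b_idx:
                    cols.append(Fb[:, t])
                    m0.append(pri.coef_mean)
                g_idx = np.flatnonzero(struct.Gamma_free[r])
                for t in g_idx:
                    cols.append(Gx[:, t])
                    m0.append(pri.coef_mean)
                offset = np.zeros(n)
                if r in my_rints:
                    offset += st.eta2[comp.cluster_of, my_rints[r]]
                elif not struct.alpha_free[r]:
                    offset += struct.alpha[0, r]
                for t in my_rslopes.get(r, []):
                    u = next(u for kind, rr, tt, u in comp.random
                             if kind == "slope" and rr == r and tt == t)
                    offset += st.eta2[comp.cluster_of, u] * Fb[:, t]
                fixed_b = np.flatnonzero(~struct.B_free[r] & (struct.B[r] != 0))
                for t in fixed_b:
                    offset += struct.B[r, t] * Fb[:, t]
                fixed_g = np.flatnonzero(~struct.Gamma_free[r] & (struct.Gamma[r] != 0))
                for t in fixed_g:
                    offset += struct.Gamma[r, t] * Gx[:, t]
                if not cols:
                    continue
                X = np.column_stack(cols)
                beta = self._draw_regression(eta[:, r] - offset, X,
                                             struct.psi_end[idx],
                                             np.asarray(m0), pri.h0, rng)
                pos = 0
                if struct.alpha_free[r] and r not in my_rints:
                    struct.alpha[:, r] = beta[pos]
                    pos += 1
                for t in b_idx:
                    struct.B[r, t] = beta[pos]
                    pos += 1
                for t in g_idx:
                    struct.Gamma[r, t] = beta[pos]
                    pos += 1
        # exogenous class means (includes the ordered block)
        self.update_ordered_class_intercepts(st, rng)

    def _collapsed_endo2_update(self, st: _State, r: int,
                                rng: np.random.Generator):
        """Joint conjugate draw of the level-1 and level-2 coefficients of a
        random-intercept chain, with the intercepts integrated out, followed
        by an exact redraw of the intercepts.

        With the random intercepts alpha_k marginalized, the level-1 outcome
        obeys a linear model in BOTH the level-1 basis columns and the
        (cluster-broadcast) level-2 regression columns, with exchangeable
        within-cluster covariance psi1 I + psi2 11'.  Drawing all these
        coefficients in one GLS block removes the ridge between the
        between-level intercept/slopes and any near-constant direction of the
        within-level basis, which otherwise mixes very slowly.
        """
        comp, spec_c, pri = self.comp, st.spec, self.priors
        st1, st2 = spec_c.structural1, spec_c.structural2
        r1 = comp.collapsible[r]
        idx1, idx2 = r1 - st1.n_exog, r - st2.n_exog
        psi1, psi2 = st1.psi_end[idx1], st2.psi_end[idx2]
        nk = np.bincount(comp.cluster_of, minlength=comp.K).astype(float)
        Fb1, G1x = st.F1b, comp.G1x
        Fb2, G2x = st.F2b, comp.G2x
        joint = r in comp.joint_collapse

        # level-1 design/offset of the carrying equation (random slopes, if
        # any, stay conditioned and go into the offset)
        rslope_cols = {t: u for kind, rr, t, u in comp.random
                       if kind == "slope" and rr == r1}
        offset1 = np.zeros(comp.N)
        for t in np.flatnonzero(~st1.B_free[r1] & (st1.B[r1] != 0)):
            offset1 += st1.B[r1, t] * Fb1[:, t]
        for t, u in rslope_cols.items():
            offset1 += st.eta2[comp.cluster_of, u] * Fb1[:, t]
        for t in np.flatnonzero(~st1.Gamma_free[r1] & (st1.Gamma[r1] != 0)):
            offset1 += st1.Gamma[r1, t] * G1x[:, t]
        b1_idx = [t for t in np.flatnonzero(st1.B_free[r1])
                  if t not in rslope_cols]
        g1_idx = list(np.flatnonzero(st1.Gamma_free[r1]))

        # level-2 design/offset of the intercept equation
        offset2 = np.zeros(comp.K)
        if not st2.alpha_free[r]:
            offset2 += st2.alpha[0, r]
        for t in np.flatnonzero(~st2.B_free[r] & (st2.B[r] != 0)):
            offset2 += st2.B[r, t] * Fb2[:, t]
        for t in np.flatnonzero(~st2.Gamma_free[r] & (st2.Gamma[r] != 0)):
            offset2 += st2.Gamma[r, t] * G2x[:, t]
        b2_idx = list(np.flatnonzero(st2.B_free[r]))
        g2_idx = list(np.flatnonzero(st2.Gamma_free[r]))

        parts, prior_prec = [], []
        if joint:
            for t in b1_idx:
                parts.append(Fb1[:, t])
                prior_prec.append(1.0 / (pri.h0 * psi1))
            for t in g1_idx:
                parts.append(G1x[:, t])
                prior_prec.append(1.0 / (pri.h0 * psi1))
        if st2.alpha_free[r]:
            parts.append(np.ones(comp.K)[comp.cluster_of])
            prior_prec.append(1.0 / (pri.h0 * psi2))
        for t in b2_idx:
            parts.append(Fb2[comp.cluster_of, t])
            prior_prec.append(1.0 / (pri.h0 * psi2))
        for t in g2_idx:
            parts.append(G2x[comp.cluster_of, t])
            prior_prec.append(1.0 / (pri.h0 * psi2))

        if parts:
            if joint:
                w = st.eta1[:, r1] - offset1 - offset2[comp.cluster_of]
                X = np.stack(parts, axis=1)
                ck = psi2 / (psi1 * (psi1 + nk * psi2))
                S = np.zeros((comp.K, X.shape[1]))
                np.add.at(S, comp.cluster_of, X)
                tsum = np.bincount(comp.cluster_of, weights=w, minlength=comp.K)
                A = X.T @ X / psi1 - np.einsum("k,ki,kj->ij", ck, S, S) \
                    + np.diag(prior_prec)
                rhs = X.T @ w / psi1 - S.T @ (ck * tsum)
            else:
                # conditional on the level-1 coefficients: heteroscedastic
                # cluster-level regression of the residual cluster means
                mean1 = self._endo_means(st, 1)[:, idx1]
                base = st.eta1[:, r1] - mean1 + st.eta2[comp.cluster_of, r]
                mk = np.bincount(comp.cluster_of, weights=base,
                                 minlength=comp.K) / nk
                wk = 1.0 / (psi2 + psi1 / nk)
                parts_k, prior_prec = [], []
                if st2.alpha_free[r]:
                    parts_k.append(np.ones(comp.K))
                    prior_prec.append(1.0 / (pri.h0 * psi2))
                for t in b2_idx:
                    parts_k.append(Fb2[:, t])
                    prior_prec.append(1.0 / (pri.h0 * psi2))
                for t in g2_idx:
                    parts_k.append(G2x[:, t])
                    prior_prec.append(1.0 / (pri.h0 * psi2))
                Xk = np.stack(parts_k, axis=1)
                sw = np.sqrt(wk)
                Xw = Xk * sw[:, None]
                A = Xw.T @ Xw + np.diag(prior_prec)
                rhs = Xw.T @ ((mk - offset2) * sw)
            try:
                L = np.linalg.cholesky(A)
            except np.linalg.LinAlgError:
                L = np.linalg.cholesky(A + 1e-8 * np.eye(A.shape[0]))
            beta = np.linalg.solve(
                L.T, np.linalg.solve(L, rhs) + rng.standard_normal(len(rhs)))
            pos = 0
            if joint:
                for t in b1_idx:
                    st1.B[r1, t] = beta[pos]
                    pos += 1
                for t in g1_idx:
                    st1.Gamma[r1, t] = beta[pos]
                    pos += 1
            if st2.alpha_free[r]:
                st2.alpha[:, r] = beta[pos]
                pos += 1
            for t in b2_idx:
                st2.B[r, t] = beta[pos]
                pos += 1
            for t in g2_idx:
                st2.Gamma[r, t] = beta[pos]
                pos += 1

        # exact Gaussian redraw of the random intercepts under the new
        # coefficients, from level-2 prior x level-1 residual information
        resid1 = st.eta1[:, r1] - offset1
        for t in b1_idx:
            resid1 = resid1 - st1.B[r1, t] * Fb1[:, t]
        for t in g1_idx:
            resid1 = resid1 - st1.Gamma[r1, t] * G1x[:, t]
        mk = np.bincount(comp.cluster_of, weights=resid1, minlength=comp.K) / nk
        mean_struct = offset2.copy()
        if st2.alpha_free[r]:
            mean_struct = mean_struct + st2.alpha[0, r]
        for t in b2_idx:
            mean_struct = mean_struct + st2.B[r, t] * Fb2[:, t]
        for t in g2_idx:
            mean_struct = mean_struct + st2.Gamma[r, t] * G2x[:, t]
        prec = 1.0 / psi2 + nk / psi1
        mu = (mean_struct / psi2 + nk * mk / psi1) / prec
        st.eta2[:, r] = mu + rng.standard_normal(comp.K) / np.sqrt(prec)
        self.refresh_basis(st, 2)

    def update_ordered_class_intercepts(self, st: _State, rng: np.random.Generator,
                                        only_mixing: bool = False):
        """Class means of the exogenous blocks; the designated block uses the
        recursive base-plus-positive-increment parameterization so class order
        is strict in every draw."""
        comp, spec_c, pri = self.comp, st.spec, self.priors
        for level in (1, 2):
            if level == 1:
                struct, classes, eta = spec_c.structural1, st.C, st.eta1
            else:
                if not spec_c.has_level2:
                    continue
                struct, classes, eta = spec_c.structural2, st.D, st.eta2
            n_ex = struct.n_exog
            if n_ex == 0 or (only_mixing and struct.n_classes < 2):
                continue
            ordered_coord = None
            if comp.ordered_block is not None and \
                    comp.ordered_block[0] == ("level1" if level == 1 else "level2"):
                ordered_coord = comp.ordered_block[1]
            eta_ex = eta[:, :n_ex]
            for p in range(n_ex):
                if not struct.alpha_free[p]:
                    continue
                # scalar pseudo-observations for coordinate p given the others
                if struct.psi_exog_class_varying:
                    # conditional obs built class-wise
                    o = np.empty(len(classes))
                    v = np.empty(len(classes))
                    for cls in range(struct.n_classes):
                        mask = classes == cls
                        if not mask.any():
                            continue
                        Q = np.linalg.inv(struct.psi_exog_for(cls))
                        resid_others = (eta_ex[mask] - struct.alpha[cls, :n_ex]) @ Q[p]
                        o[mask] = eta_ex[mask, p] + (resid_others
                                                     - Q[p, p] * (eta_ex[mask, p]
                                                                  - struct.alpha[cls, p])) / Q[p, p]
                        v[mask] = 1.0 / Q[p, p]
                    prior_var = float(np.mean([struct.psi_exog_for(c)[p, p]
                                               for c in range(struct.n_classes)])) * pri.h0
                else:
                    Q = np.linalg.inv(struct.psi_exog_for(0))
                    resid = eta_ex - struct.alpha[classes][:, :n_ex]
                    o = eta_ex[:, p] + (resid @ Q[p]
                                        - Q[p, p] * resid[:, p]) / Q[p, p]
                    v = np.full(len(classes), 1.0 / Q[p, p])
                    prior_var = struct.psi_exog_for(0)[p, p] * pri.h0
                if struct.n_classes == 1 or p != ordered_coord:
                    for cls in range(struct.n_classes):
                        mask = classes == cls
                        prec = (mask / v).sum() + 1.0 / prior_var
                        lin = (np.where(mask, o, 0.0) / v).sum() \
                            + pri.latent_mean_prior / prior_var
                        struct.alpha[cls, p] = lin / prec \
                            + rng.standard_normal() / np.sqrt(prec)
                else:
                    self._ordered_mean_update(struct, classes, o, v, p,
                                              prior_var, prior_var / pri.h0, rng)

    def _ordered_mean_update(self, struct, classes, o, v, p, prior_var,
                             block_var, rng):
        """base + positive increments parameterization of the ordered coordinate."""
        pri = self.priors
        delta_var = block_var * pri.delta_h0
        C = struct.n_classes
        means = struct.alpha[:, p].copy()
        deltas = np.diff(means)
        base = means[0]
        # base | deltas
        offset = np.concatenate(([0.0], np.cumsum(deltas)))
        prec = (1.0 / v).sum() + 1.0 / prior_var
        lin = ((o - offset[classes]) / v).sum() + pri.latent_mean_prior / prior_var
        base = lin / prec + rng.standard_normal() / np.sqrt(prec)
        # each delta | rest: truncated normal on (0, inf), half-normal prior
        for cidx in range(C - 1):
            involved = classes > cidx
            offset = np.concatenate(([0.0], np.cumsum(deltas)))
            other = base + offset[classes] - np.where(involved, deltas[cidx], 0.0)
            prec = (involved / v).sum() + 1.0 / delta_var
            lin = (np.where(involved, o - other, 0.0) / v).sum()
            mu, sd = lin / prec, 1.0 / np.sqrt(prec)
            a = ndtr(-mu / sd)
            u = rng.uniform(a, 1.0)
            deltas[cidx] = mu + sd * ndtri(np.clip(u, a + 1e-14, 1 - 1e-14))
            deltas[cidx] = max(deltas[cidx], 1e-10)
        struct.alpha[:, p] = base + np.concatenate(([0.0], np.cumsum(deltas)))

    # precisions -----------------------------------------------------------

    def update_precisions(self, st: _State, rng: np.random.Generator):
        """Wishart draws for exogenous covariance blocks, inverse-gamma for
        diagonal residual/disturbance variances."""
        comp, spec_c, pri = self.comp, st.spec, self.priors
        st.cache.clear()
        # measurement residual variances
        for level in (1, 2):
            if level == 1:
                meas, gx, star, link, eta = (spec_c.measurement1, comp.g1x,
                                             st.ystar, comp.y_link, st.eta1)
                fb = st.f1b
            else:
                if not spec_c.has_level2 or spec_c.measurement2 is None:
                    continue
                meas, gx, star, link, eta = (spec_c.measurement2, comp.g2x,
                                             st.zstar, comp.z_link, st.eta2)
                fb = st.f2b
            if meas.n_indicators == 0 or not meas.theta_free:
                continue
            mean = meas.nu + fb @ meas.Lambda.T
            if meas.g.out_dim:
                mean = mean + gx @ meas.K.T
            resid = star - mean
            n = len(eta)
            for j in range(meas.n_indicators):
                if link[j] == 1:
                    continue  # ordered: residual variance fixed at 1
                # coefficient priors scale with Theta_j (normal-inverse-gamma),
                # so free coefficients contribute to the conditional of Theta_j
                nfree = int(meas.nu_free[j]) + int(meas.Lambda_free[j].sum()) \
                    + int(meas.K_free[j].sum())
                qf = 0.0
                if meas.nu_free[j]:
                    qf += (meas.nu[j] - pri.coef_mean) ** 2
                qf += float(np.sum((meas.Lambda[j, meas.Lambda_free[j]]
                                    - pri.loading_mean) ** 2))
                qf += float(np.sum((meas.K[j, meas.K_free[j]] - pri.coef_mean) ** 2))
                shape = pri.ig_shape + 0.5 * n + 0.5 * nfree
                rate = pri.ig_scale + 0.5 * float(resid[:, j] @ resid[:, j]) \
                    + 0.5 * qf / pri.h0
                meas.Theta[j, j] = max(rate / rng.gamma(shape), 1e-10)
        # structural blocks
        for level in (1, 2):
            if level == 1:
                struct, classes, eta = spec_c.structural1, st.C, st.eta1
            else:
                if not spec_c.has_level2:
                    continue
                struct, classes, eta = spec_c.structural2, st.D, st.eta2
            if not struct.psi_free:
                continue
            n_ex = struct.n_exog
            if n_ex:
                df0, S0 = pri.wishart_params(n_ex)
                if struct.psi_exog_class_varying:
                    groups = [(cls, classes == cls) for cls in range(struct.n_classes)]
                else:
                    groups = [(None, np.ones(len(classes), dtype=bool))]
                for cls, mask in groups:
                    resid = eta[mask, :n_ex] - struct.alpha[classes[mask], :n_ex]
                    S = S0 + resid.T @ resid
                    df = df0 + int(mask.sum())
                    prec = _draw_wishart(df, np.linalg.inv(S), rng)
                    cov = np.linalg.inv(prec)
                    cov = 0.5 * (cov + cov.T)
                    if cls is None:
                        struct.Psi_exog[:] = cov
                    else:
                        struct.Psi_exog[cls] = cov
            if struct.n_endog:
                means = self._endo_means(st, level)
                resid = eta[:, n_ex:] - means
                n = len(eta)
                rints_here = {r for kind, r, t, u in comp.random if kind == "intercept"}
                rslope_cols = {(r, t) for kind, r, t, u in comp.random if kind == "slope"}
                for idx in range(struct.n_endog):
                    r = n_ex + idx
                    free_int = struct.alpha_free[r] and not (level == 1 and r in rints_here)
                    b_cols = np.array([struct.B_free[r, t] and not
                                       (level == 1 and (r, t) in rslope_cols)
                                       for t in range(struct.F.out_dim)], dtype=bool)
                    nfree = int(free_int) + int(b_cols.sum()) \
                        + int(struct.Gamma_free[r].sum())
                    qf = (struct.alpha[0, r] - pri.coef_mean) ** 2 if free_int else 0.0
                    qf += float(np.sum((struct.B[r, b_cols] - pri.coef_mean) ** 2))
                    qf += float(np.sum((struct.Gamma[r, struct.Gamma_free[r]]
                                        - pri.coef_mean) ** 2))
                    shape = pri.ig_shape + 0.5 * n + 0.5 * nfree
                    rate = pri.ig_scale + 0.5 * float(resid[:, idx] @ resid[:, idx]) \
                        + 0.5 * qf / pri.h0
                    struct.psi_end[idx] = max(rate / rng.gamma(shape), 1e-10)

    # mixture logits ---------------------------------------------------------

    def update_logit_params(self, st: _State, rng: np.random.Generator, adapt: bool):
        comp, spec_c, pri = self.comp, st.spec, self.priors
        for level, key in ((1, "logit1"), (2, "logit2")):
            mix = spec_c.mixture1 if level == 1 else spec_c.mixture2
            if mix.n_classes < 2:
                continue
            classes = st.C if level == 1 else st.D
            hx = comp.h1x if level == 1 else comp.h2x
            step = st.step_logit1 if level == 1 else st.step_logit2

            def loglik(a, b):
                logits = hx @ b.T + a
                logits = logits - _lse_rows(logits)[:, None]
                ll = logits[np.arange(len(classes)), classes].sum()
                ll += -0.5 * (np.sum(a[1:] ** 2) + np.sum(b[1:] ** 2)) / pri.logit_sd ** 2
                return ll

            a_new = mix.a.copy()
            b_new = mix.b.copy()
            if mix.h.out_dim == 0:
                # intercept-only logits: independence proposal from the
                # count-based asymptotic normal of a_d = log(n_d / n_0)
                counts = np.bincount(classes, minlength=mix.n_classes) + 0.5
                centre = np.log(counts[1:] / counts[0])
                sd = np.sqrt(1.0 / counts[1:] + 1.0 / counts[0])
                a_new[1:] = centre + sd * rng.standard_normal(mix.n_classes - 1)
                logq_new = float(np.sum(-0.5 * ((a_new[1:] - centre) / sd) ** 2
                                        - np.log(sd)))
                logq_cur = float(np.sum(-0.5 * ((mix.a[1:] - centre) / sd) ** 2
                                        - np.log(sd)))
                cur = loglik(mix.a, mix.b) + logq_new
                new = loglik(a_new, b_new) + logq_cur
            else:
                a_new[1:] += step * rng.standard_normal(mix.n_classes - 1)
                b_new[1:] += step * rng.standard_normal((mix.n_classes - 1, mix.h.out_dim))
                cur = loglik(mix.a, mix.b)
                new = loglik(a_new, b_new)
            accepted = np.log(rng.random()) < new - cur
            if accepted:
                mix.a[:] = a_new
                mix.b[:] = b_new
            st.acc[key] += int(accepted)
            st.tries[key] += 1
            if adapt:
                new_step = _rm_adapt(step, float(accepted), self.settings.target_accept)
                if level == 1:
                    st.step_logit1 = new_step
                else:
                    st.step_logit2 = new_step

    # one full cycle ---------------------------------------------------------

    def sweep(self, st: _State, rng: np.random.Generator, adapt: bool):
        self.update_augmented(st, rng)
        self.update_classes(st, rng)
        self.update_latents(st, rng, adapt)
        self.update_logit_params(st, rng, adapt)
        self.update_coefficients(st, rng)
        self.update_precisions(st, rng)
        # extra scans of the weakly identified mixture block (classes, class
        # means, logits) to improve its mixing at negligible cost
        if st.spec.n_total_classes > 1:
            for _ in range(max(0, self.settings.mixture_subsweeps - 1)):
                self.update_classes(st, rng)
                self.update_ordered_class_intercepts(st, rng, only_mixing=True)
                self.update_logit_params(st, rng, adapt)


def _lin_sel(f, m: int) -> np.ndarray:
    S = np.zeros((f.out_dim, m))
    for k, t in enumerate(f.terms):
        S[k, t.var] = 1.0
    return S


def _rm_adapt(step: float, rate: float, target: float) -> float:
    step = step * float(np.exp(0.5 * (rate - target)))
    return float(np.clip(step, 1e-3, 10.0))


def _categorical_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized categorical draw, one row of probabilities per unit."""
    u = rng.random(probs.shape[0])
    return (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).clip(0, probs.shape[1] - 1)


def _draw_wishart(df: float, scale: np.ndarray, rng: np.random.Generator,
                  max_tries: int = 5) -> np.ndarray:
    """Bartlett-decomposition Wishart(df, scale) draw with PD retry."""
    scale = 0.5 * (scale + scale.T)
    p = scale.shape[0]
    for attempt in range(max_tries):
        try:
            L = np.linalg.cholesky(scale)
            A = np.zeros((p, p))
            idx = np.tril_indices(p, -1)
            A[idx] = rng.standard_normal(len(idx[0]))
            A[np.diag_indices(p)] = np.sqrt(
                rng.chisquare(df - np.arange(p)))
            LA = L @ A
            draw = LA @ LA.T
            np.linalg.cholesky(draw)
            return draw
        except np.linalg.LinAlgError:
            scale = scale + 10.0 ** (attempt - 10) * np.eye(p)
    raise RuntimeError("Wishart draw failed to produce a positive-definite matrix")


# ---------------------------------------------------------------------------
# Complete-data log-likelihood (DIC support)
# ---------------------------------------------------------------------------


def complete_data_loglik(spec: ModelSpec, comp: _Compiled, eta1: np.ndarray,
                         eta2: Optional[np.ndarray]) -> float:
    """log p(observed y, z, eta1, eta2 | theta), marginal over both class labels.

    Measurement terms use only observed cells (ordered cells via the probit
    category probability); the latent structural densities are marginalized
    over classes with log-sum-exp, which is what lets the deviance distinguish
    mixture from non-mixture specifications.
    """
    total = 0.0
    # level-1 measurement (observed cells)
    me1 = spec.measurement1
    mean1 = _meas_mean(me1, eta1, comp.g1x)
    th1 = _theta_vec(me1, comp.y_link)
    total += _obs_meas_ll(comp.y, comp.y_cat, comp.y_missing, comp.y_link,
                          mean1, th1, spec.y_links)
    # level-1 structural, classes marginalized
    st1 = spec.structural1
    total += _struct_marginal_ll(st1, spec.mixture1, comp.h1x, eta1,
                                 _endo_means_static(spec, comp, eta1, eta2, level=1))
    if spec.has_level2:
        st2 = spec.structural2
        me2 = spec.measurement2
        if me2 is not None and me2.n_indicators:
            mean2 = _meas_mean(me2, eta2, comp.g2x)
            th2 = _theta_vec(me2, comp.z_link)
            total += _obs_meas_ll(comp.z, comp.z_cat, comp.z_missing, comp.z_link,
                                  mean2, th2, spec.z_links)
        total += _struct_marginal_ll(st2, spec.mixture2, comp.h2x, eta2,
                                     _endo_means_static(spec, comp, eta1, eta2, level=2))
    return float(total)


def _obs_meas_ll(raw, cat, missing, link, mean, th, links) -> float:
    total = 0.0
    for j in range(mean.shape[1]):
        obs = ~missing[:, j]
        if not obs.any():
            continue
        if link[j] == 0:
            r = raw[obs, j] - mean[obs, j]
            total += -0.5 * np.sum(r ** 2 / th[j] + np.log(th[j]) + _LOG2PI)
        else:
            bounds = np.concatenate(([-np.inf], links[j].thresholds, [np.inf]))
            lo = bounds[cat[obs, j] - 1] - mean[obs, j]
            hi = bounds[cat[obs, j]] - mean[obs, j]
            p = np.clip(ndtr(hi) - ndtr(lo), 1e-300, None)
            total += float(np.log(p).sum())
    return total


def _endo_means_static(spec, comp, eta1, eta2, level: int) -> np.ndarray:
    struct = spec.structural1 if level == 1 else spec.structural2
    eta = eta1 if level == 1 else eta2
    Gx = comp.G1x if level == 1 else comp.G2x
    n = len(eta)
    Fb = basis.eval_function_matrix(struct.F, eta)
    out = np.empty((n, struct.n_endog))
    rints = {r: u for kind, r, t, u in comp.random if kind == "intercept"}
    rslopes = {}
    for kind, r, t, u in comp.random:
        if kind == "slope":
            rslopes.setdefault(r, []).append((t, u))
    for r in range(struct.n_exog, struct.m):
        mean = np.full(n, struct.alpha[0, r])
        if level == 1 and r in rints:
            mean = eta2[comp.cluster_of, rints[r]]
        Brow = struct.B[r].copy()
        extra = 0.0
        if level == 1:
            for t, u in rslopes.get(r, []):
                Brow[t] = 0.0
                extra = extra + eta2[comp.cluster_of, u] * Fb[:, t]
        mean = mean + Fb @ Brow + extra
        if struct.G.out_dim:
            mean = mean + Gx @ struct.Gamma[r]
        out[:, r - struct.n_exog] = mean
    return out


def _struct_marginal_ll(struct, mix, hx, eta, endo_means) -> float:
    n = len(eta)
    n_ex = struct.n_exog
    # endogenous part is class-invariant here
    total = 0.0
    if struct.n_endog:
        resid = eta[:, n_ex:] - endo_means
        total += float(-0.5 * np.sum(resid ** 2 / struct.psi_end
                                     + np.log(struct.psi_end) + _LOG2PI))
    if n_ex == 0:
        return total
    logits = hx @ mix.b.T + mix.a
    logpi = logits - _lse_rows(logits)[:, None]
    comps = np.empty((n, struct.n_classes))
    for cls in range(struct.n_classes):
        psi = struct.psi_exog_for(cls)
        L = np.linalg.cholesky(psi)
        diff = eta[:, :n_ex] - struct.alpha[cls, :n_ex]
        sol = np.linalg.solve(L, diff.T)
        comps[:, cls] = -0.5 * (np.sum(sol ** 2, axis=0)
                                + _chol_logdet(L) + n_ex * _LOG2PI)
    total += float(_lse_rows(logpi[:, : struct.n_classes] + comps).sum())
    return total


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def run_gibbs(spec: ModelSpec, data: Dataset, priors: PriorSpec = None,
              settings: SamplerSettings = None) -> PosteriorDraws:
    """Posterior sampling: ``settings.chains`` independent chains, identical
    update cycle, per-chain substreams of the master seed; fully reproducible.
    """
    priors = priors or PriorSpec()
    settings = settings or SamplerSettings()
    sampler = GibbsSampler(spec, data, priors, settings)
    comp = sampler.comp
    names = parameter_index(spec)
    kept_per_chain = (settings.iterations - settings.burn_in - 1) // settings.thinning + 1
    draws = np.empty((settings.chains, kept_per_chain, len(names)))
    loglik = np.zeros((settings.chains, kept_per_chain))
    eta1_sum = np.zeros((comp.N, spec.structural1.m))
    eta2_sum = np.zeros((comp.K, spec.structural2.m)) if spec.has_level2 else None
    c_freq = np.zeros((comp.N, spec.mixture1.n_classes))
    d_freq = np.zeros((comp.K, spec.mixture2.n_classes))
    acc_summary = {}

    chain_seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
    for chain in range(settings.chains):
        rng = np.random.default_rng(chain_seeds[chain])
        st = sampler.init_state(rng)
        entries = sampler.entries
        kept = 0
        for key in st.acc:
            st.acc[key] = 0
            st.tries[key] = 0
        for it in range(settings.iterations):
            adapt = it < settings.burn_in
            if it == settings.burn_in:  # acceptance reported on retained phase
                for key in st.acc:
                    st.acc[key] = 0
                    st.tries[key] = 0
            sampler.sweep(st, rng, adapt)
            if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning == 0:
                draws[chain, kept] = _pack_entries(entries, st.spec)
                if settings.record_loglik:
                    loglik[chain, kept] = complete_data_loglik(st.spec, comp,
                                                               st.eta1, st.eta2)
                eta1_sum += st.eta1
                if eta2_sum is not None:
                    eta2_sum += st.eta2
                c_freq[np.arange(comp.N), st.C] += 1
                d_freq[np.arange(comp.K), st.D] += 1
                kept += 1
        for key, n_try in st.tries.items():
            if n_try:
                acc_summary.setdefault(key, []).append(st.acc[key] / n_try)
    acc_summary = {k: float(np.mean(v)) for k, v in acc_summary.items()}

    denom = settings.chains * kept_per_chain
    spec_hash = hashlib.sha256(
        "|".join(names).encode() + str(len(names)).encode()).hexdigest()[:16]
    return PosteriorDraws(
        names=names, draws=draws, loglik=loglik,
        eta1_mean=eta1_sum / denom,
        eta2_mean=None if eta2_sum is None else eta2_sum / denom,
        acceptance=acc_summary, settings=settings, spec_hash=spec_hash,
        c_freq=c_freq / denom, d_freq=d_freq / denom,
    )


def _pack_entries(entries, spec_cur) -> np.ndarray:
    out = np.empty(len(entries))
    for i, (_, (arr, idx)) in enumerate(entries):
        if isinstance(arr, str):
            links = spec_cur.y_links if arr == "tau_y" else spec_cur.z_links
            j, s = idx
            out[i] = links[j].thresholds[s]
        else:
            out[i] = arr[idx]
    return out
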