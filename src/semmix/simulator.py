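"""Generative sampling of complete two-level datasets from a ModelSpec.

Generation follows the hierarchy: level-2 class -> level-2 latents -> cluster
indicators; then per individual: level-1 class -> level-1 latents (with random
coefficients substituted from the cluster's level-2 latent vector) -> indicator
vector -> observation link.  Exogenous latents are Gaussian within class;
endogenous latents are computed from their recursive structural equations plus
a Gaussian disturbance.

One master seed spawns an independent substream per cluster, so increasing the
number of clusters extends a dataset without reshuffling existing clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from . import basis
from .model_spec import MeasurementSpec, MixtureSpec, ModelSpec, StructuralSpec

__all__ = [
    "Dataset",
    "ClusterSizePlan",
    "class_probabilities",
    "draw_class",
    "draw_level2",
    "draw_level1",
    "simulate_dataset",
    "apply_mar_mask",
    "model_implied_moments",
    "marginal_exog_mean",
]


# ---------------------------------------------------------------------------
# Dataset container
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """Clustered observed data.

    ``y``/``x1`` are individual-level (N rows), ``z``/``x2`` cluster-level
    (K rows).  Missing cells are NaN in the frames and True in the masks; they
    are never zero-filled.  ``cluster_of`` codes each individual's cluster as
    an index into ``cluster_ids`` (order of first appearance).  ``truth``
    optionally records the latent quantities used during generation.
    """

    y: pd.DataFrame
    z: pd.DataFrame
    x1: pd.DataFrame
    x2: pd.DataFrame
    cluster_ids: np.ndarray
    cluster_of: np.ndarray
    y_mask: np.ndarray = None
    z_mask: np.ndarray = None
    truth: Optional[dict] = None

    def __post_init__(self):
        if self.y_mask is None:
            self.y_mask = np.asarray(self.y.isna().to_numpy())
        if self.z_mask is None:
            self.z_mask = np.asarray(self.z.isna().to_numpy())
        self.cluster_ids = np.asarray(self.cluster_ids)
        self.cluster_of = np.asarray(self.cluster_of, dtype=int)
        if self.cluster_of.min(initial=0) < 0 or \
                (len(self.cluster_of) and self.cluster_of.max() >= len(self.cluster_ids)):
            raise ValueError("cluster_of indexes outside the cluster table")

    @property
    def n_individuals(self) -> int:
        return len(self.y)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_of, minlength=self.n_clusters)

    def equals(self, other: "Dataset") -> bool:
        return (
            self.y.equals(other.y) and self.z.equals(other.z)
            and self.x1.equals(other.x1) and self.x2.equals(other.x2)
            and np.array_equal(self.cluster_ids.astype(str), other.cluster_ids.astype(str))
            and np.array_equal(self.cluster_of, other.cluster_of)
            and np.array_equal(self.y_mask, other.y_mask)
            and np.array_equal(self.z_mask, other.z_mask)
        )


@dataclass
class ClusterSizePlan:
    """Either a common size ``n`` for every cluster or an explicit size list."""

    n: Optional[int] = None
    sizes: Optional[Sequence[int]] = None

    def resolve(self, K: int) -> np.ndarray:
        if (self.n is None) == (self.sizes is None):
            raise ValueError("specify exactly one of n / sizes")
        if self.n is not None:
            if self.n < 1:
                raise ValueError("cluster sizes must be >= 1")
            return np.full(K, int(self.n))
        sizes = np.asarray(self.sizes, dtype=int)
        if len(sizes) != K or sizes.min() < 1:
            raise ValueError("need K sizes, all >= 1")
        return sizes

    @staticmethod
    def from_total(K: int, total: int) -> "ClusterSizePlan":
        """Near-balanced sizes summing exactly to ``total`` (larger clusters first)."""
        base, extra = divmod(total, K)
        if base < 1:
            raise ValueError("total must be >= K")
        sizes = np.full(K, base)
        sizes[:extra] += 1
        return ClusterSizePlan(sizes=sizes)


# ---------------------------------------------------------------------------
# Elementary draws
# ---------------------------------------------------------------------------


def class_probabilities(mix: MixtureSpec, x: np.ndarray) -> np.ndarray:
    """softmax(a_c + b_c . h(x)) across classes; numerically stabilized."""
    hx = basis.eval_function(mix.h, np.asarray(x, dtype=float))
    logits = mix.a + mix.b @ hx
    return np.exp(logits - logsumexp(logits))


def draw_class(mix: MixtureSpec, x: np.ndarray, rng: np.random.Generator) -> int:
    """Draw a class index (0-based) from the multinomial-logit model."""
    p = class_probabilities(mix, x)
    return int(rng.choice(mix.n_classes, p=p))


def _draw_links(ystar: np.ndarray, links, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(ystar)
    for j, link in enumerate(links):
        if link.link == "identity":
            out[j] = ystar[j]
        elif link.link == "ordered":
            # category s (1-based) iff tau_s < y* < tau_{s+1}, tau_1 = -inf
            out[j] = float(np.searchsorted(link.thresholds, ystar[j]) + 1)
        else:  # poisson_log
            out[j] = float(rng.poisson(np.exp(ystar[j])))
    return out


def _structural_draw(struct: StructuralSpec, cls: int, intercepts: np.ndarray,
                     B: np.ndarray, x: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Exogenous Gaussian draw + recursive endogenous computation."""
    eta = np.zeros(struct.m)
    if struct.n_exog:
        eta[: struct.n_exog] = rng.multivariate_normal(
            intercepts[: struct.n_exog], struct.psi_exog_for(cls),
            method="cholesky",
        )
    gx = basis.eval_function(struct.G, x)
    for r in range(struct.n_exog, struct.m):
        fe = basis.eval_function(struct.F, eta)  # recursive: row r uses only earlier entries
        mean = intercepts[r] + B[r] @ fe + struct.Gamma[r] @ gx
        eta[r] = mean + rng.normal(0.0, np.sqrt(struct.psi_end[r - struct.n_exog]))
    return eta


def _measurement_draw(meas: MeasurementSpec, eta: np.ndarray, x: np.ndarray,
                      links, rng: np.random.Generator):
    mean = meas.nu + meas.Lambda @ basis.eval_function(meas.f, eta) \
        + meas.K @ basis.eval_function(meas.g, x)
    if meas.n_indicators:
        noise = rng.multivariate_normal(np.zeros(meas.n_indicators), meas.Theta,
                                        method="cholesky")
    else:
        noise = np.zeros(0)
    # count links carry no Gaussian residual: the randomness is Poisson
    for j, link in enumerate(links):
        if link.link == "poisson_log":
            noise[j] = 0.0
    ystar = mean + noise
    return _draw_links(ystar, links, rng), ystar


def draw_level2(spec: ModelSpec, d: int, x2: np.ndarray, rng: np.random.Generator):
    """One cluster: eta2 realization and z row (link applied). Returns (eta2, z, zstar)."""
    st2 = spec.structural2
    eta2 = _structural_draw(st2, d, st2.alpha[d].copy(), st2.B, x2, rng)
    if spec.measurement2 is not None and spec.measurement2.n_indicators:
        z, zstar = _measurement_draw(spec.measurement2, eta2, x2, spec.z_links, rng)
    else:
        z = zstar = np.zeros(0)
    return eta2, z, zstar


def draw_level1(spec: ModelSpec, c: int, d: int, eta2: Optional[np.ndarray],
                x1: np.ndarray, rng: np.random.Generator):
    """One individual: eta1 realization and y row. Returns (eta1, y, ystar)."""
    st1 = spec.structural1
    intercepts = st1.alpha[c].copy()
    B = st1.B
    for kind, r, t_idx, u in spec.random_targets():
        if kind == "intercept":
            intercepts[r] = eta2[u]
        else:
            if B is st1.B:
                B = st1.B.copy()
            B[r, t_idx] = eta2[u]
    eta1 = _structural_draw(st1, c, intercepts, B, x1, rng)
    y, ystar = _measurement_draw(spec.measurement1, eta1, x1, spec.y_links, rng)
    return eta1, y, ystar


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------


def _default_x_sampler(rng: np.random.Generator, dim: int) -> np.ndarray:
    return rng.standard_normal(dim)


def simulate_dataset(spec: ModelSpec, K: int, plan: ClusterSizePlan, seed: int,
                     x1_sampler: Callable = None,
                     x2_sampler: Callable = None) -> Dataset:
    """Generate a complete dataset of K clusters from ``spec``.

    Covariates default to independent standard normals; pass samplers
    ``f(rng, dim) -> vector`` to change that (e.g. for binary dummies).
    The truth record retains classes and latent vectors for recovery tests.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    x1_sampler = x1_sampler or _default_x_sampler
    x2_sampler = x2_sampler or _default_x_sampler
    sizes = plan.resolve(K)
    streams = np.random.SeedSequence(seed).spawn(K)

    Q, V = len(spec.x1_names), len(spec.x2_names)
    has_l2 = spec.has_level2
    U = spec.structural2.m if has_l2 else 0
    rows_y, rows_x1, cluster_of = [], [], []
    rows_z, rows_x2 = [], []
    D = np.zeros(K, dtype=int)
    C_all, eta1_all = [], []
    eta2_all = np.zeros((K, U))

    for k in range(K):
        rng = np.random.default_rng(streams[k])
        x2 = x2_sampler(rng, V)
        if has_l2:
            D[k] = draw_class(spec.mixture2, x2, rng)
            eta2, z, _ = draw_level2(spec, D[k], x2, rng)
            eta2_all[k] = eta2
        else:
            eta2, z = None, np.zeros(0)
        rows_z.append(z)
        rows_x2.append(x2)
        for _ in range(sizes[k]):
            x1 = x1_sampler(rng, Q)
            c = draw_class(spec.mixture1, x1, rng)
            eta1, y, _ = draw_level1(spec, c, D[k] if has_l2 else 0, eta2, x1, rng)
            rows_y.append(y)
            rows_x1.append(x1)
            cluster_of.append(k)
            C_all.append(c)
            eta1_all.append(eta1)

    cluster_ids = np.array([f"cl{k + 1:04d}" for k in range(K)])
    data = Dataset(
        y=pd.DataFrame(np.asarray(rows_y), columns=list(spec.y_names)),
        z=pd.DataFrame(np.asarray(rows_z).reshape(K, -1), columns=list(spec.z_names)),
        x1=pd.DataFrame(np.asarray(rows_x1).reshape(len(rows_y), -1),
                        columns=list(spec.x1_names)),
        x2=pd.DataFrame(np.asarray(rows_x2).reshape(K, -1), columns=list(spec.x2_names)),
        cluster_ids=cluster_ids,
        cluster_of=np.asarray(cluster_of, dtype=int),
        truth={
            "C": np.asarray(C_all, dtype=int), "D": D,
            "eta1": np.asarray(eta1_all, dtype=float), "eta2": eta2_all,
            "seed": seed,
        },
    )
    return data


def apply_mar_mask(data: Dataset, rate: float, predictor: str, seed: int,
                   columns: Sequence[str] = None) -> Dataset:
    """Mask individual-level cells missing-at-random.

    The per-cell missingness probability is logistic in the (standardized)
    values of one fully observed ``predictor`` column (from y or x1), with the
    intercept calibrated so the expected missing fraction equals ``rate``.
    Because masking depends only on an observed column, the mechanism is MAR.
    The predictor column itself is never masked; already-masked cells stay
    masked (idempotent).
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return data
    if predictor in data.y.columns:
        pvals = data.y[predictor].to_numpy(dtype=float)
    elif predictor in data.x1.columns:
        pvals = data.x1[predictor].to_numpy(dtype=float)
    else:
        raise ValueError(f"predictor {predictor!r} not an individual-level column")
    if np.isnan(pvals).any():
        raise ValueError("MAR predictor must be fully observed")
    sd = pvals.std()
    p_std = (pvals - pvals.mean()) / (sd if sd > 0 else 1.0)

    def mean_rate(g0):
        return expit(g0 + p_std).mean() - rate

    g0 = brentq(mean_rate, -30.0, 30.0)
    probs = expit(g0 + p_std)

    columns = [c for c in (columns or data.y.columns) if c != predictor]
    rng = np.random.default_rng(seed)
    y = data.y.copy()
    mask = data.y_mask.copy()
    for col in columns:
        j = list(data.y.columns).index(col)
        hit = rng.random(len(y)) < probs
        mask[:, j] |= hit
        y.loc[hit, col] = np.nan
    return Dataset(y=y, z=data.z, x1=data.x1, x2=data.x2,
                   cluster_ids=data.cluster_ids, cluster_of=data.cluster_of,
                   y_mask=mask, z_mask=data.z_mask, truth=data.truth)


# ---------------------------------------------------------------------------
# Closed-form moment oracle (linear, single-class models)
# ---------------------------------------------------------------------------


def _linear_selection(f, m: int, coef: np.ndarray = None) -> np.ndarray:
    """S (out_dim, m) with f(eta) = S eta on the active columns.

    Non-linear terms are tolerated only when inactive (their coefficient
    column in ``coef`` is entirely zero); otherwise the linear oracle does not
    apply and an error is raised.
    """
    S = np.zeros((f.out_dim, m))
    for k, t in enumerate(f.terms):
        if t.kind == "linear":
            S[k, t.var] = 1.0
        elif coef is None or np.any(coef[:, k] != 0):
            raise ValueError("moment oracle requires linear (active) function sets")
    return S


def _linear_struct_moments(struct: StructuralSpec, extra_mean=None, extra_cov=None):
    """Mean and covariance of the latent vector of one level (single class).

    ``extra_mean``/``extra_cov`` inject the contribution of random intercepts
    (mean and covariance of the intercept vector beyond its fixed part).
    """
    m = struct.m
    SF = _linear_selection(struct.F, m, struct.B)
    Bt = struct.B @ SF  # (m, m) linear coefficient matrix
    A = np.linalg.inv(np.eye(m) - Bt)
    a = struct.alpha[0].copy()
    if extra_mean is not None:
        a = a + extra_mean
    psi_full = np.zeros((m, m))
    if struct.n_exog:
        psi_full[: struct.n_exog, : struct.n_exog] = struct.psi_exog_for(0)
    for r in range(struct.n_endog):
        psi_full[struct.n_exog + r, struct.n_exog + r] = struct.psi_end[r]
    if extra_cov is not None:
        psi_full = psi_full + extra_cov
    mean = A @ a
    cov = A @ psi_full @ A.T
    return mean, cov


def model_implied_moments(spec: ModelSpec) -> dict:
    """Population mean/covariance of y (and z) for linear single-class models.

    Serves as an independent oracle for the simulator: valid only when every
    function set is linear, both mixtures have a single class, covariate sets
    are empty, and random effects are intercepts.  y moments pool individuals
    across clusters (total = within + between covariance).
    """
    if spec.n_total_classes != 1:
        raise ValueError("moment oracle requires single-class models")
    if spec.x1_names or spec.x2_names:
        raise ValueError("moment oracle requires no covariates")
    for kind, *_ in spec.random_targets():
        if kind != "intercept":
            raise ValueError("moment oracle requires intercept-only random effects")

    out = {}
    if spec.has_level2:
        st2 = spec.structural2
        mean2, cov2 = _linear_struct_moments(st2)
        if spec.measurement2 is not None and spec.measurement2.n_indicators:
            me2 = spec.measurement2
            L2 = me2.Lambda @ _linear_selection(me2.f, st2.m, me2.Lambda)
            out["mean_z"] = me2.nu + L2 @ mean2
            out["cov_z"] = L2 @ cov2 @ L2.T + me2.Theta
        # propagate random intercepts into level 1
        m1 = spec.structural1.m
        R = np.zeros((m1, st2.m))
        for kind, r, _, u in spec.random_targets():
            R[r, u] = 1.0
        base = spec.structural1.alpha[0]
        extra_mean = R @ mean2 - np.where(R.any(axis=1), base, 0.0)
        extra_cov = R @ cov2 @ R.T
    else:
        extra_mean = extra_cov = None

    st1, me1 = spec.structural1, spec.measurement1
    mean1, cov1 = _linear_struct_moments(st1, extra_mean, extra_cov)
    L1 = me1.Lambda @ _linear_selection(me1.f, st1.m, me1.Lambda)
    out["mean_y"] = me1.nu + L1 @ mean1
    out["cov_y"] = L1 @ cov1 @ L1.T + me1.Theta
    out["mean_eta1"], out["cov_eta1"] = mean1, cov1
    return out


def marginal_exog_mean(spec: ModelSpec, level: int = 2,
                       x: np.ndarray = None) -> np.ndarray:
    """Mixture-marginal mean of the exogenous latents: sum_c pi_c(x) mu_c."""
    if level == 2:
        mix, struct = spec.mixture2, spec.structural2
    else:
        mix, struct = spec.mixture1, spec.structural1
    if x is None:
        x = np.zeros(mix.h.arity)
    pi = class_probabilities(mix, x)
    return pi @ struct.alpha[:, : struct.n_exog]
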