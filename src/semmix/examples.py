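"""Bundled example models.

``school_model()`` is the package's reference two-level model of pupils' math
achievement: at the pupil level, a latent math skill is predicted by latent
attitude-toward-reading and experienced-teaching-strategies through cubic
truncated-power splines (knots at 2 and 3); at the school level, the random
intercept of math skill is explained by two latent school characteristics
(structural problems, social environment), their interaction, and a two-class
mixture on the school-level predictors' means.  The numeric parameter values
are realistic posterior-scale magnitudes for standardized educational survey
parcels and serve as generating truth in simulation studies.

The tiny models at the bottom are deliberately small submodels used as
cross-checking oracles (analytic or quadrature-based posteriors).
"""

from __future__ import annotations

import numpy as np

from . import basis
from .model_spec import (
    FunctionSpec,
    MeasurementSpec,
    MixtureSpec,
    ModelSpec,
    RandomCoefficient,
    StructuralSpec,
    Term,
)

__all__ = [
    "school_model",
    "hierarchical_normal_model",
    "quadratic_factor_model",
    "random_intercept_mixture_model",
]


def school_model(n_level2_classes: int = 2) -> ModelSpec:
    """Two-level latent spline + interaction + mixture model (K schools, pupils nested).

    Level 1 (pupil): latents (Att, Strat, Math), three parcels each, first
    loading fixed to 1 and first intercept to 0 per latent;
    Math = alpha3_k + spline(Att) + spline(Strat) + zeta.
    Level 2 (school): latents (Prob, Soc, alpha3); alpha3 is the random
    intercept of Math, regressed on Prob, Soc and Prob*Soc; Prob/Soc means
    follow a ``n_level2_classes``-component mixture with an ordering constraint
    on the Prob means.
    """
    lat1 = ("Att", "Strat", "Math")
    y_names = tuple(f"y{j}" for j in range(1, 10))

    f1 = FunctionSpec(tuple(Term("linear", i) for i in range(3)), 3)
    lam1 = np.zeros((9, 3))
    lam1[0:3, 0] = [1.0, 1.141, 0.997]
    lam1[3:6, 1] = [1.0, 0.687, 1.213]
    lam1[6:9, 2] = [1.0, 0.754, 0.553]
    lam1_free = lam1 != 0.0
    lam1_free[0, 0] = lam1_free[3, 1] = lam1_free[6, 2] = False  # scaling anchors
    nu1 = np.array([0.0, -1.078, -0.409, 0.0, 0.411, -0.419, 0.0, 0.058, 0.340])
    nu1_free = np.ones(9, dtype=bool)
    nu1_free[[0, 3, 6]] = False
    theta1 = np.diag([0.147, 0.198, 0.212, 0.212, 0.323, 0.219, 0.066, 0.047, 0.049])
    meas1 = MeasurementSpec(nu=nu1, Lambda=lam1, K=np.zeros((9, 0)), Theta=theta1,
                            f=f1, g=FunctionSpec.empty(0),
                            nu_free=nu1_free, Lambda_free=lam1_free,
                            K_free=np.zeros((9, 0), dtype=bool))

    # Math on cubic splines of Att and Strat, knots (2, 3)
    spl_att = basis.spline_terms(0, [2.0, 3.0], 3, arity=3)
    spl_strat = basis.spline_terms(1, [2.0, 3.0], 3, arity=3)
    F1 = FunctionSpec(spl_att.terms + spl_strat.terms, 3)
    B1 = np.zeros((3, F1.out_dim))
    B1[2, :5] = [0.005, 0.009, -0.005, 0.046, -0.164]
    B1[2, 5:] = [-0.070, 0.079, -0.017, 0.007, 0.018]
    B1_free = np.zeros_like(B1, dtype=bool)
    B1_free[2, :] = True
    psi1_ex = np.array([[0.506, 0.072], [0.072, 0.250]])
    alpha1 = np.array([[2.856, 2.700, 0.0]])  # Math intercept is the random effect
    struct1 = StructuralSpec(
        latent_names=lat1, n_exog=2, alpha=alpha1, Psi_exog=psi1_ex,
        psi_end=np.array([0.041]), B=B1, Gamma=np.zeros((3, 0)),
        F=F1, G=FunctionSpec.empty(0), B_free=B1_free,
        alpha_free=np.array([True, True, True]),
    )

    # ---- level 2 ----
    lat2 = ("Prob", "Soc", "alpha3")
    z_names = tuple(f"z{l}" for l in range(1, 7))
    f2 = FunctionSpec((Term("linear", 0), Term("linear", 1)), 3)
    lam2 = np.zeros((6, 2))
    lam2[0:3, 0] = [1.0, 1.029, 0.700]
    lam2[3:6, 1] = [1.0, 1.002, 0.794]
    lam2_free = lam2 != 0.0
    lam2_free[0, 0] = lam2_free[3, 1] = False
    nu2 = np.array([0.0, 0.759, 0.603, 0.0, -0.024, 0.279])
    nu2_free = np.ones(6, dtype=bool)
    nu2_free[[0, 3]] = False
    theta2 = np.diag([0.415, 0.723, 0.366, 0.183, 0.130, 0.176])
    meas2 = MeasurementSpec(nu=nu2, Lambda=lam2, K=np.zeros((6, 0)), Theta=theta2,
                            f=f2, g=FunctionSpec.empty(0),
                            nu_free=nu2_free, Lambda_free=lam2_free,
                            K_free=np.zeros((6, 0), dtype=bool))

    F2 = FunctionSpec((Term("linear", 0), Term("linear", 1), Term("product", (0, 1))), 3)
    B2 = np.zeros((3, 3))
    B2[2] = [0.558, 0.442, -0.289]
    B2_free = np.zeros_like(B2, dtype=bool)
    B2_free[2] = True
    psi2_ex = np.array([[0.291, 0.007], [0.007, 0.239]])
    if n_level2_classes == 2:
        mu = np.array([[1.921, 1.938, -0.365], [2.107, 2.091, -0.365]])
        # P(D=1) = 0.532 via reference-class logit
        a2 = np.array([0.0, float(np.log(0.468 / 0.532))])
        mix2 = MixtureSpec(2, a=a2, h=FunctionSpec.empty(0))
    elif n_level2_classes == 1:
        mu = np.array([[2.008, 2.010, -0.365]])
        mix2 = MixtureSpec(1, h=FunctionSpec.empty(0))
    else:
        raise ValueError("school_model supports 1 or 2 level-2 classes")
    struct2 = StructuralSpec(
        latent_names=lat2, n_exog=2, alpha=mu, Psi_exog=psi2_ex,
        psi_end=np.array([0.051]), B=B2, Gamma=np.zeros((3, 0)),
        F=F2, G=FunctionSpec.empty(0), B_free=B2_free,
    )

    return ModelSpec(
        y_names=y_names, x1_names=(), measurement1=meas1, structural1=struct1,
        mixture1=MixtureSpec(1, h=FunctionSpec.empty(0)),
        z_names=z_names, x2_names=(), measurement2=meas2, structural2=struct2,
        mixture2=mix2,
        random_map=(RandomCoefficient("intercept", "Math", "alpha3"),),
        ordered_block=("level2", "Prob") if n_level2_classes > 1 else None,
    )


def hierarchical_normal_model(mu: float = 0.5, sigma_u2: float = 0.3,
                              sigma_z2: float = 0.2, theta: float = 0.4,
                              free_variances: bool = False) -> ModelSpec:
    """Normal–normal random-intercept submodel with a fully analytic posterior.

    y_ik = M_ik + eps, M_ik = u_k + zeta, u_k ~ N(mu, sigma_u2).  With the
    variances fixed, the only free parameter is mu, whose posterior under the
    conjugate normal prior is available in closed form.
    """
    meas1 = MeasurementSpec(
        nu=np.zeros(1), Lambda=np.ones((1, 1)), K=np.zeros((1, 0)),
        Theta=np.array([[theta]]), f=FunctionSpec((Term("linear", 0),), 1),
        g=FunctionSpec.empty(0), nu_free=np.zeros(1, dtype=bool),
        Lambda_free=np.zeros((1, 1), dtype=bool), theta_free=free_variances,
    )
    struct1 = StructuralSpec(
        latent_names=("M",), n_exog=0, alpha=np.zeros((1, 1)),
        Psi_exog=np.zeros((0, 0)), psi_end=np.array([sigma_z2]),
        B=np.zeros((1, 0)), Gamma=np.zeros((1, 0)),
        F=FunctionSpec.empty(1), G=FunctionSpec.empty(0),
        alpha_free=np.array([True]), psi_free=free_variances,
    )
    struct2 = StructuralSpec(
        latent_names=("u",), n_exog=1, alpha=np.array([[mu]]),
        Psi_exog=np.array([[sigma_u2]]), psi_end=np.zeros(0),
        B=np.zeros((1, 0)), Gamma=np.zeros((1, 0)),
        F=FunctionSpec.empty(1), G=FunctionSpec.empty(0),
        alpha_free=np.array([True]), psi_free=free_variances,
    )
    meas2 = MeasurementSpec(
        nu=np.zeros(0), Lambda=np.zeros((0, 0)), K=np.zeros((0, 0)),
        Theta=np.zeros((0, 0)), f=FunctionSpec.empty(1), g=FunctionSpec.empty(0),
        nu_free=np.zeros(0, dtype=bool), Lambda_free=np.zeros((0, 0), dtype=bool),
        theta_free=False,
    )
    return ModelSpec(
        y_names=("y1",), x1_names=(), measurement1=meas1, structural1=struct1,
        mixture1=MixtureSpec(1, h=FunctionSpec.empty(0)),
        z_names=(), x2_names=(), measurement2=meas2, structural2=struct2,
        mixture2=MixtureSpec(1, h=FunctionSpec.empty(0)),
        random_map=(RandomCoefficient("intercept", "M", "u"),),
    )


def quadratic_factor_model(beta_lin: float = 0.4, beta_quad: float = -0.3,
                           psi_xi: float = 1.0, psi_y: float = 0.3,
                           theta: float = 0.25) -> ModelSpec:
    """Single-level latent quadratic regression (2 latent dims) for oracle checks.

    Xi ~ N(0, psi_xi) measured by x1 (loading 1) and x2 (loading 0.8, both
    fixed); Y = beta_lin Xi + beta_quad Xi^2 + zeta measured by w1 (loading 1).
    Only the two structural coefficients are free, so a dense-grid posterior
    over (beta_lin, beta_quad) — with the likelihood from Gauss–Hermite
    quadrature — is a feasible independent oracle.
    """
    f1 = FunctionSpec((Term("linear", 0), Term("linear", 1)), 2)
    lam = np.array([[1.0, 0.0], [0.8, 0.0], [0.0, 1.0]])
    meas1 = MeasurementSpec(
        nu=np.zeros(3), Lambda=lam, K=np.zeros((3, 0)),
        Theta=np.diag([theta, theta, theta]), f=f1, g=FunctionSpec.empty(0),
        nu_free=np.zeros(3, dtype=bool), Lambda_free=np.zeros((3, 2), dtype=bool),
        theta_free=False,
    )
    F1 = FunctionSpec((Term("linear", 0), Term("power", 0, exponent=2)), 2)
    B = np.array([[0.0, 0.0], [beta_lin, beta_quad]])
    B_free = np.array([[False, False], [True, True]])
    struct1 = StructuralSpec(
        latent_names=("Xi", "Y"), n_exog=1, alpha=np.zeros((1, 2)),
        Psi_exog=np.array([[psi_xi]]), psi_end=np.array([psi_y]),
        B=B, Gamma=np.zeros((2, 0)), F=F1, G=FunctionSpec.empty(0),
        B_free=B_free, alpha_free=np.array([False, False]), psi_free=False,
    )
    return ModelSpec(
        y_names=("x1", "x2", "w1"), x1_names=(),
        measurement1=meas1, structural1=struct1,
        mixture1=MixtureSpec(1, h=FunctionSpec.empty(0)),
    )


def quadratic_measurement_model(beta_lin: float = 0.4, beta_quad: float = -0.3,
                                psi_xi: float = 1.0, theta: float = 0.25,
                                theta_w: float = 0.3) -> ModelSpec:
    """One latent dimension with a quadratic effect on an observed outcome.

    Xi ~ N(0, psi_xi) measured by x1 (loading 1, fixed) and x2 (0.8, fixed);
    the outcome w carries the latent quadratic regression directly in its
    measurement row: w = beta_lin Xi + beta_quad Xi^2 + e.  With everything
    else fixed, the two coefficients are the only free parameters, so a dense
    grid posterior with Gauss-Hermite likelihood evaluation is an exact
    independent oracle for the Metropolis-within-Gibbs sampler.
    """
    f1 = FunctionSpec((Term("linear", 0), Term("power", 0, exponent=2)), 1)
    lam = np.array([[1.0, 0.0], [0.8, 0.0], [beta_lin, beta_quad]])
    lam_free = np.zeros((3, 2), dtype=bool)
    lam_free[2] = True
    meas1 = MeasurementSpec(
        nu=np.zeros(3), Lambda=lam, K=np.zeros((3, 0)),
        Theta=np.diag([theta, theta, theta_w]), f=f1, g=FunctionSpec.empty(0),
        nu_free=np.zeros(3, dtype=bool), Lambda_free=lam_free,
        theta_free=False,
    )
    struct1 = StructuralSpec(
        latent_names=("Xi",), n_exog=1, alpha=np.zeros((1, 1)),
        Psi_exog=np.array([[psi_xi]]), psi_end=np.zeros(0),
        B=np.zeros((1, 0)), Gamma=np.zeros((1, 0)),
        F=FunctionSpec.empty(1), G=FunctionSpec.empty(0),
        alpha_free=np.array([False]), psi_free=False,
    )
    return ModelSpec(
        y_names=("x1", "x2", "w"), x1_names=(),
        measurement1=meas1, structural1=struct1,
        mixture1=MixtureSpec(1, h=FunctionSpec.empty(0)),
    )


def random_intercept_mixture_model(n_classes: int = 2, mu: float = 0.8,
                                   gap: float = 0.0, sigma_u2: float = 0.25,
                                   sigma_z2: float = 0.15, theta: float = 0.3,
                                   class_varying_variance: bool = False
                                   ) -> ModelSpec:
    """Random-intercept model whose level-2 mean carries an optional mixture.

    Used for the parsimony study: data generated from the single-class variant
    are fit with both 1- and 2-class specifications and compared by DIC.
    """
    meas1 = MeasurementSpec(
        nu=np.zeros(1), Lambda=np.ones((1, 1)), K=np.zeros((1, 0)),
        Theta=np.array([[theta]]), f=FunctionSpec((Term("linear", 0),), 1),
        g=FunctionSpec.empty(0), nu_free=np.zeros(1, dtype=bool),
        Lambda_free=np.zeros((1, 1), dtype=bool),
    )
    struct1 = StructuralSpec(
        latent_names=("M",), n_exog=0, alpha=np.zeros((1, 1)),
        Psi_exog=np.zeros((0, 0)), psi_end=np.array([sigma_z2]),
        B=np.zeros((1, 0)), Gamma=np.zeros((1, 0)),
        F=FunctionSpec.empty(1), G=FunctionSpec.empty(0),
        alpha_free=np.array([True]),
    )
    means = np.array([[mu + gap * c] for c in range(n_classes)])
    # components differ in their means by default; optionally also in their
    # variances (fully class-conditional Gaussians)
    varying = class_varying_variance and n_classes > 1
    psi2 = np.array([[[sigma_u2]]] * n_classes) if varying \
        else np.array([[sigma_u2]])
    struct2 = StructuralSpec(
        latent_names=("u",), n_exog=1, alpha=means,
        Psi_exog=psi2, psi_end=np.zeros(0),
        B=np.zeros((1, 0)), Gamma=np.zeros((1, 0)),
        F=FunctionSpec.empty(1), G=FunctionSpec.empty(0),
        alpha_free=np.array([True]),
        psi_exog_class_varying=varying,
    )
    meas2 = MeasurementSpec(
        nu=np.zeros(0), Lambda=np.zeros((0, 0)), K=np.zeros((0, 0)),
        Theta=np.zeros((0, 0)), f=FunctionSpec.empty(1), g=FunctionSpec.empty(0),
        nu_free=np.zeros(0, dtype=bool), Lambda_free=np.zeros((0, 0), dtype=bool),
        theta_free=False,
    )
    return ModelSpec(
        y_names=("y1",), x1_names=(), measurement1=meas1, structural1=struct1,
        mixture1=MixtureSpec(1, h=FunctionSpec.empty(0)),
        z_names=(), x2_names=(), measurement2=meas2, structural2=struct2,
        mixture2=MixtureSpec(n_classes, h=FunctionSpec.empty(0)),
        random_map=(RandomCoefficient("intercept", "M", "u"),),
        ordered_block=("level2", "u") if n_classes > 1 else None,
    )
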