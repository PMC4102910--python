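# Methods

This note records the modelling assumptions, algorithmic choices and known
limitations of `semmix`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Model class

A model has two levels.  Level 1 (within): a `J`-vector of indicators per
individual, generated from an `m`-vector of latent variables through a linear
measurement map applied to a *function set* `f1` (ordered collection of
linear / power / product / truncated-power terms) plus covariate terms
`g1(x1)`; the latents obey a recursive structural system whose right-hand
sides are function sets `F1, G1`.  Level 2 (between): the same structure over
clusters (`z`, `eta2`, `f2, F2, g2, G2`).  Finite mixtures act through
multinomial-logit class models on each level; class-varying parameters are
the exogenous latent means (see restrictions below).  A random-coefficient
map ties level-1 structural intercepts or slopes to coordinates of `eta2`.

Distributional assumptions: within each class, exogenous latents are
Gaussian; endogenous latents equal their structural mean plus an independent
Gaussian disturbance; measurement residuals are Gaussian (identity links),
underlie a thresholded normal (ordered links), or are absent (Poisson
log-link, where the randomness is the count distribution itself).

**Recursivity.** The structural system must be recursive: a term may feed
equation *r* only if all its latent arguments precede *r* in the declared
order (exogenous first).  Simultaneity is rejected at spec construction.
This is a deliberate restriction: allowing an endogenous variable to predict
itself would make the generative direction ambiguous, and no worked example
in the literature this package follows exercises it.

## Identification rules

`validate_identification` runs four necessary checks and returns a report:

1. every measured latent carries a scaling constraint (one loading fixed to
   a nonzero value; fixing the first loading to 1 is the default convention
   because it preserves conjugacy of the remaining loadings) and a resolved
   intercept constraint (anchor indicator intercept fixed, or latent mean
   fixed);
2. no term may reach one indicator equation twice.  A term shared between a
   measurement set (`f`/`g`) and a structural set (`F`/`G`) is collinear
   exactly when some indicator receives it directly *and* loads on an
   endogenous latent whose equation also carries it — then the direct and the
   mediated coefficient occupy the same reduced-form column.  The check is
   therefore per indicator equation, which correctly admits models where the
   same linear term measures one latent and predicts a different one.
   Constant columns cannot be expressed at all (terms have no intercepts);
3. level-2 exogenous latents need an anchored indicator, except those that
   are themselves random-coefficient carriers (they are identified through
   the level-1 equations they enter);
4. reference-class logit coefficients are fixed at zero, and any model with
   more than one class must declare an ordering constraint on exactly one
   parameter block (default: the class means of the first exogenous latent of
   the mixing level).

These are necessary, not sufficient, conditions; a pathological model can
pass them and still be empirically under-identified.

## Sampler

One sweep updates, in order: augmented data (ordered-probit utilities,
thresholds, MAR-missing cells), class labels (`D` then `C`, exact multinomial
conditionals with latent-prior terms), latent vectors, logit coefficients,
measurement and structural coefficient blocks, class means, and precision
blocks.

- **Latent vectors.** When the relevant function sets are all-linear the full
  conditional is Gaussian and is drawn exactly (batched Cholesky across
  units).  Otherwise a per-unit random-walk Metropolis step is used, with a
  single step-size per level scaled by the prior SDs per coordinate and
  adapted by Robbins–Monro towards 0.35 acceptance during burn-in only, so
  detailed balance holds for all retained draws.  Two refinements: level-1
  coordinates that appear only through linear terms everywhere (e.g. a latent
  outcome predicted by splines of the other latents) still have Gaussian full
  conditionals and are redrawn exactly after the MH step; and the cheap
  level-2 MH scan is repeated ``eta2_subsweeps`` times per sweep (default 3),
  since the cluster-level latents gate the mixing of the between-level
  structural coefficients.
- **Coefficients.** Conditional on basis rows, every block is a Bayesian
  linear regression with prior `N(m0, sigma^2 h0)` (the equation's residual
  variance scales the prior), drawn exactly.  Free loadings default to prior
  mean 1, all other coefficients to 0; `h0 = 4`.
- **Collapsed random-intercept block.** For a level-2 endogenous latent that
  carries a level-1 random intercept and is otherwise unmeasured, the
  coefficients of the *whole chain* — the within-level coefficients of the
  carrying equation and the between-level intercept and slopes of the
  random-intercept equation — are drawn jointly with the intercepts
  integrated out: marginally the level-1 outcome is linear in both column
  sets with exchangeable within-cluster covariance `psi1 I + psi2 11'`, a
  single conjugate GLS block; the intercepts are then redrawn from their
  exact Gaussian conditionals.  This partially collapsed step is essential
  at moderate cluster counts: a truncated-power spline basis over a narrow
  predictor range contains a near-constant direction that is additively
  confounded with the between-level intercept, and alternating conditional
  updates walk that ridge extremely slowly (EPSR far above 1.2 at routine
  chain lengths), whereas the joint marginal draw removes the ridge
  entirely.  (When the carrying equation also has a random slope the
  within-cluster covariance is no longer exchangeable and the update falls
  back to conditioning on the level-1 coefficients.)
- **Precisions.** Exogenous covariance blocks get Wishart conditionals
  (Bartlett sampling; prior df `dim + 2`, identity scale); diagonal residual
  and disturbance variances get inverse-gamma conditionals (shape 2, scale
  0.5) that include the coefficient-prior quadratic forms, since those priors
  scale with the variance.
- **Mixture block.** Class means are conjugate per coordinate via scalar
  pseudo-observations (conditioning on the other coordinates through the
  precision matrix).  The designated ordered block is parameterized as a base
  mean plus strictly positive increments with half-normal priors (scale =
  block variance x `delta_h0`, default 1), so class order is strict in every
  draw and label switching cannot occur by construction; post-hoc `relabel`
  is consequently the identity on constrained draws.  Intercept-only logits
  use an independence Metropolis proposal built from the class counts (near
  iid mixing); covariate logits use an adapted random walk.  Logit
  coefficients carry a moderately informative N(0, 1.5^2) prior: for weakly
  separated mixtures a diffuse logit prior leaves a near-degenerate
  one-class posterior mode that routine-length chains visit unevenly; the
  1.5-SD prior keeps the mixing proportion in a plausible range (roughly
  0.05-0.95 at two prior SDs) and is the package default, adjustable via
  ``PriorSpec.logit_sd``.  Because the mixture block (labels, class means, logits) is cheap
  but slow-mixing when classes overlap, each sweep rescans it
  `mixture_subsweeps` times (default 3).
- **Ordered probit.** Per ordered indicator the first interior threshold is
  fixed at 0 and the residual variance at 1; utilities are truncated-normal
  draws, thresholds uniform conditionals respecting monotonicity.
- **Missing data.** MAR cells are imputed from their conditional normals
  each sweep, which is exact under the stated model.

Chains are seeded from independent substreams of the master seed; runs are
bit-reproducible for fixed inputs and seed.  Starting values are data-scale
neutral (anchored-indicator latent scores, loadings 1, coefficients 0,
moment-based variances) with per-chain jitter for overdispersion.

**Estimation scope.** Poisson/logistic links are simulation-only; estimation
supports identity and ordered links.  Measurement residual covariances must
be diagonal in estimation (the Wishart machinery covers the latent blocks);
random factor loadings and random logit coefficients are out of scope;
within-level class counts do not vary across level-2 classes; class-varying
parameters are the exogenous latent means (optionally exogenous covariances
in the simulator).

## Diagnostics

- **EPSR** is the classic non-split multi-chain potential scale reduction
  `sqrt((((n-1)/n) W + B/n) / W)`; the byte-identical-chains edge (B = 0)
  returns exactly 1.  Convergence is declared below 1.2, the threshold
  conventional in the Bayesian SEM literature.  The non-split form is kept
  deliberately for comparability with that literature.
- **DIC** comes in two variants because mixture DICs are not unique.  For
  linear-Gaussian models (all active basis columns linear, identity links,
  random intercepts only) the default is the observed-data variant: the
  deviance `-2 log p(y_obs, z_obs | theta)` with the continuous latents
  integrated out *exactly* (per cluster, the marginal is a mixture of
  multivariate normals) and classes summed out; `pD = Dbar - D(theta_bar)`
  then counts parameters.  This evaluator is cross-checked against the
  generic quadrature oracle to ~1e-9.  Outside linear scope the conditional
  variant is used: the per-iteration complete-data deviance with classes
  marginalized but latents at their sampled values; its `pD` is of the order
  of the number of latent variables and its Monte-Carlo noise is large, which
  limits its resolution.  A caution established by the package's own
  simulations: when a constrained (ordered-increment) extra mixture component
  is fitted to data that have no mixture, the two models are so close that
  *every* DIC variant yields a difference near zero plus dataset noise — the
  spurious component's parameters are prior-dominated and contribute almost
  nothing to `pD`.  A DIC comparison between k- and (k+1)-class fits of
  weakly separated data should therefore be read as "no evidence the extra
  class is needed", not as a reliable sign test; this mirrors the known
  difficulties of DIC for mixtures.
- **`marginal_loglik_small`** evaluates the observed-data log-likelihood of
  tiny models (total latent dimension <= 3, <= 2 classes, K <= 50, random
  intercepts only) by nested Gauss–Hermite quadrature with exact class sums.
  Exogenous blocks use per-unit adaptive proposals (a Laplace approximation
  from the linearized measurement model) with exact importance reweighting;
  endogenous dimensions use recursively mean-shifted nodes.  Adaptivity
  matters: prior-centred grids lose several digits when the per-unit
  posterior is much narrower than the prior.  The function is an independent
  oracle for the sampler, not an estimation route.
- **`t`-values** in summaries are posterior mean / posterior SD, matching the
  mean/SE/t reporting convention of the applied literature this package
  follows.

## The simulator and what passing tests show

`simulate_dataset` draws exactly from the generative model in the order
class -> latents -> structural recursion -> measurement -> link, with one RNG
substream per cluster (extending K leaves existing clusters unchanged).  The
bundled school model is a realistic two-level educational design: ~700 pupils
in 100 schools (the configuration used in the recovery experiments; the CLI
default emits 1474 pupils in 226 schools), nine pupil-level parcels measuring
three latents, a latent cubic spline with knots at 2 and 3 inside the
predictor range, six school-level parcels measuring two latent school
characteristics whose interaction explains the random intercept of math
skill, and a weakly separated two-class mixture (class-mean gap ~0.19 versus
within-class SD ~0.5) on the school-level means.

The simulator emulates clustered, continuous (or ordered-categorical),
conditionally Gaussian data with MAR missingness driven by an observed
column.  It does not emulate item-level responses (indicators are parcels),
sampling weights, MNAR mechanisms, or longitudinal structure — recovery
results here say nothing about those features of real survey data.

## Problem sizes of the validation experiments

The recovery battery fits 3 chains x 5000 iterations (burn-in 2500) to
datasets of 100 clusters / ~700 individuals, with 5 (complete-data) and 4
(10% MAR) replications in the test suite and 3/3 in the acceptance script;
the DIC comparison uses 10 replications of a small random-intercept design
(K=100, n=4) with 2 chains x 1500 iterations; the oracle comparisons use
the tiny models described above.  These sizes are the
package's own choice of a battery that a user can re-run routinely; the
weakly separated mixture keeps its generating values, which makes the
mixture parameters the binding constraint on convergence (their posteriors
are intrinsically ridge-like — visible in the wide class-probability
posteriors such designs produce).

## Known limitations

- Necessary-only identification checking (see above).
- The truncated-power spline basis is kept for coefficient interpretability
  but is ill-conditioned for many or extreme knots; no orthogonalization is
  applied by default.  Knots are user-fixed, never data-adaptive.
- DIC is a relative index only; no absolute fit measure exists for these
  models.
- The quadrature oracle scope is intentionally tiny; it exists to check the
  sampler, not to estimate real models.
- Spline predictors are not centred before basis expansion; users whose
  predictors live far from zero may prefer to centre them for conditioning.
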