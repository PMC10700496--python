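# Methods

## Models

All models share the 2PL Bernoulli likelihood
`P(y_ij = 1) = logistic(alpha_i (theta_j - beta_i))` with
`theta_j ~ N(0, 1)` fixing the latent scale; no further identification
constraints are imposed.  Missing responses contribute nothing to the
likelihood (missing-at-random).

**Hierarchical (non-centered) 2PL.**  The item vector
`xi_i = (log alpha_i, beta_i)` has grand means `mu = (mu_alpha, mu_beta)`
with priors `mu_alpha ~ N(0, 1)` and `mu_beta ~ N(0, sd 2)`, scales
`(tau_alpha, tau_beta)` and correlation Cholesky factor `L_Omega ~ LKJ(2)`
(unnormalized density `prod_k L_kk^(K-k+2*eta-2)`).  Only z-scores
`xi_tilde ~ N(0, 1)` are sampled; items are rebuilt as
`xi_i = diag(tau) L_Omega xi_tilde_i`,
`alpha_i = exp(mu_alpha + xi_alpha,i)`, `beta_i = mu_beta + xi_beta,i`.
The scales come from bounded uniform auxiliaries — `tau = s tan(u)`,
`u ~ U(0, pi/2)` (half-Cauchy(0, s)) or `tau = -s log(u)`, `u ~ U(0, 1)`
(Exponential, mean s) — or are sampled directly with an inverse-Gamma(a, b)
prior.  The twelve named hyperprior specifications are, per family
(WI1 / WI2 / NI1 / NI2): half-Cauchy scale 1 / 2.5 / 5 / 25; Exponential
rate 1 / 0.4 / 0.2 / 0.04; inverse-Gamma (3,2) / (1,0.5) / (1,2) /
(0.001,0.001).

Two readings are ambiguous in the literature and are explicit switches
here: normal priors written "N(0, 2)" are read with 2 as the *standard
deviation* (the Stan convention; `scale_is_variance=True` selects the
variance reading), and the inverse-Gamma prior is placed on tau itself
(`ig_on_variance=True` moves it to tau², with the change-of-variables
Jacobian included).

**Comparators.**  The centered hierarchical 2PL samples `xi_i ~
MVN(mu, Sigma)` with `Sigma ~ inverse-Wishart(3, I)`; the nonhierarchical
2PL uses independent `alpha_i ~ logN(0, 1)`, `beta_i ~ N(0, sd 2)`.
Marginal maximum likelihood integrates theta out by Bock–Aitkin EM
(below).

## Posterior computation

Sampling uses an adaptive Hamiltonian Monte Carlo engine written for this
package: all parameters are mapped to an unconstrained space (sigmoid for
bounded auxiliaries, exp for scales, tanh for the correlation coordinate,
log-diagonal Cholesky for covariance matrices) with the appropriate
Jacobian terms, and the log posterior plus its *analytic* gradient is
evaluated in one O(N·I) pass (the test suite verifies every gradient
against central finite differences).  Leapfrog trajectories have a
uniformly jittered number of steps (1..`max_leapfrog`, default 24); the
step size is tuned by Nesterov dual averaging toward 0.8 acceptance during
burn-in; a diagonal mass matrix is estimated from the first half of the
burn-in window and then frozen.  Non-finite proposals count as divergences
and are rejected.  Each chain starts from dispersed uniform(-1, 1) values
on the unconstrained scale (re-drawn up to three times if the density is
not finite there); chains are seeded from independent child streams of the
chain-spec seed, making runs bit-reproducible.

The default protocol is three chains of 4000 iterations with 1000 burn-in
each.  Summaries are computed on the classical scale (each kept draw is
transformed to alpha, beta, theta, tau, rho before averaging): posterior
mean (median optional), SD, 95% highest-density interval (sample-based
shortest window; width ties broken toward the smaller lower bound), the
classic Gelman–Rubin between/within R-hat (no rank normalization; a
split-chain variant is available; constant chains return exactly 1), and
an effective sample size from FFT autocorrelations truncated by Geyer's
initial positive-sequence rule.  A fit is "converged" when every monitored
parameter (all alpha, beta, mu, tau — not individual theta, since item
calibration is the target) has R-hat < 1.05, strictly.  Poor mixing flags
the result; it never raises.

## Marginal maximum likelihood

The E-step evaluates each person's posterior over an equally spaced
41-point grid on [-6, 6] with normal-density weights (Gauss–Hermite
optional) and accumulates expected correct/attempt counts per item; the
M-step solves a weighted logistic regression per item in slope/intercept
form `logistic(a*theta + c)` by damped Newton steps.  The marginal
log-likelihood is monotone non-decreasing; iteration stops when it changes
by less than 1e-6 (default).  Estimates map to the classical form via
`alpha = a`, `beta = -c/a`.  A fit is *inadmissible* when the EM did not
converge, any `a <= 0`, or any estimate exceeds the caps `alpha > 10`,
`|beta| > 10` (caps configurable; these operationalize "impossible or
extreme estimates" — boundary response patterns routinely produce
discriminations in the tens).  An optional per-item lognormal penalty on
the slope is available as a rescue prior for boundary patterns.  EAP
ability scores are posterior means on the same grid under the N(0, 1)
population prior.

## Synthetic data generator

The generator emulates operational calibration data: item parameters with
controlled spread and discrimination–difficulty correlation, standard
normal abilities, Bernoulli responses.  Per item set:

1. draw (alpha, beta) pairs from a bivariate normal with mean (1, 0)
   truncated to [0.65, 4.0] x [-4.5, 4.5] (rejection sampling; an
   acceptance rate below 1e-4 raises);
2. enforce the *exact* target sample covariance
   `Sigma = diag(tau) Omega diag(tau)` by centering, whitening with the
   inverse Cholesky factor of the sample covariance (n-1 denominator) and
   coloring with the Cholesky factor of Sigma — sample SDs and correlation
   hit the design values to ~1e-10 for every seed, so each replication
   sits exactly at its design condition rather than merely in expectation;
3. shift each column to the true marginal means of the truncated
   bivariate normal, computed by 1-D adaptive quadrature over the
   closed-form conditional-normal inner integral (absolute tolerance
   1e-8, cached per box/covariance).

Design choices made where the procedure was genuinely open: generation
happens on the natural (alpha, beta) scale, as implied by the truncation
limits (0.65–4.0 is a discrimination range and the grand mean 1 matches
alpha, not log alpha), even though the *model* correlates (log alpha,
beta); a log-scale generator sits behind a flag.  At the small and typical
scale pairs the natural/log distinction is second-order (delta method:
SD(log alpha) differs from SD(alpha)/mean(alpha) by O(tau²)).  The
operational ranges 0.5 < alpha < 3.5 and |beta| < 4 are enforced by
redrawing the whole item set (up to 100 times).  Under the extreme scale
pair (0.75, 1.50) a normal spread that wide cannot keep 25–50
discriminations above 0.5 simultaneously, so whole-set enforcement is
infeasible there; the study runner therefore disables range enforcement
for extreme cells and keeps it for small/typical cells.  The initial
covariance fed to the truncated draw equals the target Sigma; the exact
rescaling step makes this choice immaterial to the final moments.  At
least 3 items are required (the sample covariance of two points is
singular).

What passing recovery tests do *not* show about real data: the generator
produces responses that follow the 2PL exactly — no guessing, no local
dependence, no multidimensionality, no differential item functioning, and
complete data.  Recovery results transfer to real calibrations only to the
extent those assumptions hold.

## Recovery-study harness

The full design crosses sample size {50, 75, 100, 150, 200, 500}, test
length {25, 50}, scale pair {(0.10,0.40), (0.25,0.90), (0.75,1.50)},
correlation {0, .3} and twelve hyperprior cells — 864 conditions, default
100 replications.  Evaluation: bias = estimate − truth, averaged across
items within a replication and then across replications; RMSE per item
across replications, then averaged across items; scale components
evaluated directly across replications; person parameters mirror the item
rule (chosen here; only the item rule is standard).  Bayesian fits with
any monitored R-hat ≥ 1.05 and inadmissible ML fits are discarded before
evaluation and reported as per-cell rates.  Robustness across the four
specifications of a family is assessed against their conditional mean
(per-specification deviations sum to zero by construction).  Seeds derive
from a master seed per (cell, replication) via seed-sequence spawning, so
cells are independently reproducible, replications are embarrassingly
parallel, and results merge deterministically; each record is checkpointed
as one JSON line for resumable runs.

## Problem sizes in the shipped checks

The full 864 x 100 study is a cluster-scale computation.  The shipped test
suite runs the same machinery at reduced scale, chosen as the smallest
runs that still measure each claim: 10 replications per condition at
N=100, k=25 (bias bounds) and N=50, k=25 (hierarchical-versus-
nonhierarchical RMSE comparison), with three chains of 900 iterations (400
burn-in), and 10 replications at N=500, k=50 with three chains of 500
iterations for the large-sample bias check.  Structural and deterministic
properties (design enumeration, generator exactness, transform
distributions, evaluation algebra, diagnostics) are checked exactly or
against closed forms.

## Known limitations

* Unidimensional, dichotomous 2PL only — no 3PL guessing parameter,
  polytomous or multidimensional extensions.
* The HMC engine is plain adaptive HMC, not NUTS; very stiff posteriors
  (e.g. the noninformative half-Cauchy specification on tiny datasets) mix
  more slowly and are flagged by the convergence check rather than
  repaired.
* Marginal-ML standard errors are not computed; the inadmissibility caps
  are an operationalization, not a community standard.
* The effective-sample-size estimator (pooled FFT autocorrelation with
  Geyer truncation) is one of several in use; reported ESS values are
  comparable within, not necessarily across, packages.
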