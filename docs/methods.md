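# Methods

This note documents the statistical model, the numerical choices, and the
limitations of `robmeta`, in the spirit of a package methods appendix.

## Analysis scale

All likelihoods operate on Fisher z effects with standard errors
`se = 1/sqrt(n - 3)`.  The z scale is unbounded, approximately normal, and
its standard error is orthogonal to the effect — a prerequisite for
meta-regressions on the standard error (PET/PEESE), where a mechanical
effect–precision dependence on the r scale would masquerade as small-study
bias.  Estimates are reported back on the correlation scale.

Priors stated on the Cohen's d scale are moved to z by the exact change of
variables `d = 2 sinh z` (equivalently `d = 2r/sqrt(1 - r^2)`, `r = tanh z`);
`prior_rescale: linear` switches to the small-effect linearization
`d = 2z`, under which every family stays closed (location and scale are
halved).  The two agree within 1% for |z| < 0.2.  A prior on the
heterogeneity scale tau has no exact pushforward under a nonlinear mean
map, so inverse-gamma priors always use `tau_z = tau_d / 2`.  The PET
slope is dimensionless and transfers unchanged; the PEESE slope carries
units of 1/se, so its half-Cauchy scale doubles (5 on d becomes 10 on z).

## The ensemble

36 members: {effect absent, present} x {heterogeneity absent, present} x
{no bias, 6 selection models, PET, PEESE}.  Defaults:

| ingredient | prior (d scale) | default |
|---|---|---|
| effect, present | Normal(0, 1) | alternative: Student-t+(0.35, 0.10, 3) |
| heterogeneity, present | Inverse-Gamma(shape 1, scale 0.15) | |
| selection weights | cumulative unit Dirichlet on omega | non-increasing in p, omega_1 = 1 |
| PET slope | Cauchy+(0, 1) | |
| PEESE slope | Cauchy+(0, 5) | |

The six weight functions are two-sided {.05} and {.05, .10}, and one-sided
{.05}, {.025, .05}, {.05, .5}, {.025, .05, .5}.  The set is configurable;
p-values are recomputed from (z, se), and a p exactly on a cut-off belongs
to the more significant interval.  Prior model probability is 1/2 per
hypothesis, with bias-present mass split equally between the selection
family and PET–PEESE and then equally within family: per effect x
heterogeneity cell, 1/8 no-bias, 1/96 per selection model, 1/32 each for
PET and PEESE.  The literature states this inverse-gamma with the
parameters printed in (scale, shape) order; we follow the reference
software convention shape = 1, scale = 0.15.

Selection likelihood (per study): `ln omega(p_i) + ln phi(z_i; mu, s_i)
− ln A_i`, with `s_i^2 = tau^2 + se_i^2` and
`A_i = sum_j omega_j P(p in interval j | mu, s_i)`, interval probabilities
from normal CDF differences at the z-space images of the p cut-offs.
One-sided p-values take the positive direction as favoured; every
meta-analysis is oriented before fitting (see below).

## Marginal likelihoods

Every member has 0–5 free parameters (mu, tau, and either J−1 Dirichlet
sticks or one regression slope).  The integrator maps each parameter to an
unbounded working coordinate — mu directly, tau through log, and bounded
or heavy-tailed parameters (sticks, slopes, truncated effect priors)
through the probability integral transform of their prior followed by a
logit — finds the joint mode by damped Newton ascent with a
finite-difference Hessian, and applies a tensor Gauss–Hermite rule centred
at the mode with covariance `1.5^2 * (-H)^-1` (eigenvalue-clipped to stay
positive definite).  Node counts per dimension default to
(25, 15, 11, 9, 7) for 1–5 total dimensions; the `small` preset uses
(15, 9, 7, 5, 5).

The PIT+logit map is what makes selection models tractable: when the data
are incompatible with publishing non-significant studies, the likelihood
concentrates in a boundary layer of the weight simplex (omega -> 0) whose
width can be ~10^-3; in logit coordinates that layer becomes a smooth
interior bump the centred rule resolves.  The error estimate is the
disagreement between the two finest rules; when it exceeds
`rel_tol * max(1, |ln ML|)` the integrator escalates once or twice (more
nodes, inflation 2.0) and otherwise flags the member — flagged members are
reported, never silently used.  Validation: point-mass models match the
closed form to machine precision; conjugate normal models match the exact
marginal to < 1e-3; all 36 members agree with 200k–400k-draw prior Monte
Carlo within ~0.2 ln units in unbiased, selected, and null scenarios.
Prior-draw Monte Carlo (`integration.method: mc`) remains available as an
independent cross-check, with a delta-method ln-scale standard error.

Conditional effect posteriors come from the same weighted nodes (mean,
`E[tanh mu]`, and a histogram density on a fixed z grid); model-averaged
summaries mix them by posterior model probability, point-null members
contributing an atom at zero.  The averaged r-scale estimate is the
posterior mean of `tanh(mu)` under the mixture, not the tanh of the mean
(both are reported); the 95% interval is the central weighted quantile of
the pooled mixture.  Posterior model probabilities use log-sum-exp with
the maximum subtracted; probabilities below 1e-300 are reported as zero.

## The corpus pipeline

Orientation: if a meta-analysis's reMA estimate is negative, all signs are
flipped before fitting (PET/PEESE and the one-sided weight functions
assume selection favours positive effects).  The flag is stored; record
fields are on the oriented scale, so the original-direction estimate is
`-1 * value` where flipped.  Adjustments (RoBMA − reMA, RoBMA − BMA) are
therefore magnitude reductions when negative.  An oriented RoBMA estimate
that crosses zero is flagged as a sign reversal — such metas can show
*more* evidence after adjustment, in the opposite direction.

reMA is REML by default (1-D bounded optimization of the restricted
likelihood over tau^2, exact snap to zero when the profile is flat there);
DerSimonian–Laird is a config switch.  Its tau-hat is the heterogeneity
covariate downstream.  Single-study metas fall back to a fixed-effect fit
with a warning; metas with k < 3 are fitted but flagged.

The heterogeneity regression predicts the z-scale RoBMA−BMA adjustment
from raw tau-hat and the mean-centred unadjusted (BMA) estimate, using a
unit-information (g = n) conjugate normal linear model: marginal
likelihoods are closed-form, per-coefficient Bayes factors compare the
full model to the model without that column, and 95% intervals come from
the multivariate-t posterior.  Raw tau keeps the intercept interpretable
as the adjustment expected for a homogeneous meta-analysis; a standardized
slope is also reported.  The closed form replaces numerical integration
here because the conjugate answer is exact.

The three-level model treats each meta-analysis's two adjustments (vs
reMA, vs BMA; r scale) as observations with a method fixed effect, an
article random intercept, a meta random intercept, and residual noise.
The intercepts are marginalized analytically — after a within-pair
rotation the covariance is block compound-symmetric with closed-form
determinant and inverse — leaving a 5-parameter posterior (two fixed
effects, three scales) sampled with emcee (differential-evolution moves,
24 walkers, 6000 kept steps), with Normal(0, 1) priors on the fixed
effects and half-t(3, 0, 0.5) on the scales, sampled on the natural scale
so near-zero variance components mix well.  Convergence requires
split-R-hat < 1.01 on every parameter, with one automatic chain-doubling
retry before erroring.

## Synthetic corpora

The generator mimics the structure of large published corpora of
psychology meta-analyses: by default 90 articles with 4–5 meta-analyses
each (~400 total), 5–40 studies per meta-analysis, true effects
`mu_z ~ Normal(0.15, 0.15)`, heterogeneity `tau_z ~ half-Normal(0.10)`,
and sample sizes log-normal with median 60 (floor 10) — magnitudes chosen
to be typical for the field.  Selection draws a study, computes its
p-value, and publishes with the probability attached to its p interval
(default: significant always, non-significant with probability 0.3);
generation repeats until the target number of published studies is
reached, with an attempt cap that aborts pathological settings.  The
generator matches the fitted selection-model family exactly, so it
emulates pure significance-based selection — not p-hacking, not correlated
estimates within a meta-analysis, not non-normal primary outcomes.
Passing recovery tests therefore demonstrates correct inference under the
assumed data-generating process, not robustness to mechanisms outside the
model family (the ensemble contains no p-hacking member by construction).

## Validation scale and known behaviour

Benchmark corpora use 100 meta-analyses of K = 30 studies at
`mu_z = 0.2`, `tau_z = 0.1` with the reduced integration preset — sizes
chosen so a full two-corpus run completes in a couple of minutes while
keeping 100 replicates for corpus-level proportions.  Under harsh
selection the model-averaged estimate beats the naive random-effects
estimate in RMSE and sits below it in essentially every meta-analysis,
and posterior effect probabilities deflate as designed.

Under *no* selection with heterogeneous sample sizes, the ensemble shows a
mild conservative pull (~0.03–0.05 on z at these settings): the truncated
non-negative PET/PEESE slope priors can only shift estimates down, chance
positive effect–se correlations are absorbed by PET while chance negative
ones produce no opposite correction, and the bias family holds half the
prior mass.  This asymmetry is inherent to the model family, not an
integration artifact (member-level marginals and conditional means match
dense-grid brute force).  It vanishes when per-study standard errors are
(near-)equal — the regressor then has no leverage — which is typical of
multi-lab replication designs but not of observed meta-analyses.  Users
comparing adjusted and unadjusted estimates on corpora they believe
bias-free should expect small downward adjustments of this order.

## Degenerate inputs and edge rules

Empty study lists error; k = 1 fits with a fixed-effect fallback and a
warning; |r| >= 1, n < 4, and non-positive standard errors are rejected at
construction.  Weight-function omegas must be strictly positive for direct
likelihood evaluation (the Dirichlet prior handles zeros in the ensemble
by integration).  Records whose ensemble fit fails outright are excluded
from summaries and counted, never silently dropped.  Reports are
deterministic given inputs (figure hash salts and metadata dates pinned);
corpus runs derive one integration seed per meta-analysis from the base
seed, so results do not depend on processing order.
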