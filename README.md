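# robmeta

Robust Bayesian model-averaged meta-analysis with publication-bias
adjustment, and a corpus-level pipeline that quantifies how much
publication bias inflates meta-analytic evidence and effect sizes.

## Who this is for

Meta-analysts and methods researchers who want publication-bias-adjusted
estimates of correlation effect sizes without committing to a single
adjustment method, and who want to run that analysis over many
meta-analyses at once (a meta-meta-analysis) with proper uncertainty
quantification.

## The model

Primary studies enter as correlations `r` with sample sizes `n` (or
directly as Fisher `z = atanh(r)` with standard errors
`se = 1/sqrt(n - 3)`); all fitting happens on the Fisher z scale.  The
core is a 36-member model ensemble crossing three binary/multi-way
hypotheses:

* **Effect**: point mass at `mu = 0` vs `mu != 0` with a standard normal
  prior on Cohen's d (`d = 2 sinh z` maps it to the analysis scale); an
  elicited alternative prior, Student-t+(0.35, 0.10, 3), is a config
  switch.
* **Heterogeneity**: `tau = 0` vs `tau ~ Inverse-Gamma(1, 0.15)` (d scale).
* **Publication bias**: none, vs six Vevea–Hedges selection models (step
  weight functions `omega(p)` over one- and two-sided p-value intervals
  with cumulative unit-Dirichlet priors), vs PET and PEESE meta-regressions
  (`E[z_i] = mu + b * se_i` or `mu + b * se_i^2`, `b >= 0`, half-Cauchy
  priors).

Each hypothesis has prior probability 1/2; bias-present mass is split
equally between the selection family and PET–PEESE, then equally within
each family.  Members are combined by their marginal likelihoods
(deterministic mode-centred Gauss–Hermite quadrature in transformed
coordinates; prior-draw Monte Carlo is available as a cross-check), giving
posterior model probabilities, inclusion Bayes factors for
effect/heterogeneity/bias, and a model-averaged posterior for the effect.
Dropping the bias members and renormalizing yields the unadjusted Bayesian
model-averaged meta-analysis (BMA); comparing the two isolates the
publication-bias correction.

The corpus pipeline fits reMA (REML random-effects), BMA, and the full
ensemble (RoBMA) for every meta-analysis, summarizes evidence changes and
effect-size adjustments across the corpus, regresses the adjustment on
heterogeneity, and fits a three-level hierarchical model of the
adjustments (effect sizes nested in meta-analyses nested in articles,
random intercepts marginalized analytically, MCMC via emcee with
split-R-hat checks).  A seeded synthetic-corpus generator with
significance-based selection provides ground truth for validation.

## Worked example

Simulate one meta-analysis of 25 published studies with a small true
effect (`mu_z = 0.1`, `tau_z = 0.1`) under harsh one-sided selection
(non-significant studies published with probability 0.1), then analyze it:

```python
import numpy as np
from robmeta import AnalysisConfig, analyze_one
from robmeta.synthetic_data import DistSpec, SelectionSpec, simulate_meta_analysis

rng = np.random.default_rng(7)
n_sizes = DistSpec("lognormal", {"mean_log": np.log(60.0), "sd_log": 0.6, "minimum": 10})
selection = SelectionSpec("one_sided", cutpoints=(0.05,), publish_probs=(1.0, 0.1))
studies, truth = simulate_meta_analysis(
    true_mu_z=0.1, true_tau_z=0.1, K_target=25,
    n_dist=n_sizes, selection=selection, rng=rng,
)
record = analyze_one(studies, AnalysisConfig.small(seed=1))
print(f"reMA estimate  r = {record.rema_est_r:.3f}  (tau_z = {record.rema_tau_z:.3f})")
print(f"BMA  estimate  r = {record.bma_est_r:.3f}   P(effect) = {record.bma_p_effect:.3f}")
print(f"RoBMA estimate r = {record.robma_est_r:.3f}   P(effect) = {record.robma_p_effect:.3f}")
print(f"adjustment vs BMA: {record.adj_vs_bma_r:+.3f} (r)")
print(f"evidence: {record.evidence_category_before} -> {record.evidence_category_after}")
```

prints

```
reMA estimate  r = 0.202  (tau_z = 0.113)
BMA  estimate  r = 0.199   P(effect) = 1.000
RoBMA estimate r = 0.019   P(effect) = 0.257
adjustment vs BMA: -0.181 (r)
evidence: strong_alt -> undecided
```

Selection inflated the naive estimate from a true `r ≈ 0.10` to 0.20 and
manufactured seemingly certain evidence; model averaging over the
bias-adjusting members pulls the estimate back toward zero and the
posterior probability of an effect down to 0.26 — the evidence category
drops from strong support to undecided.

The same analysis scales to corpora from the shell:

```bash
robmeta simulate --seed 1 --out corpus.csv --truth truth.csv
robmeta analyze --corpus corpus.csv --small --seed 1 --outdir report/
```

`report/summary.md` then holds the corpus-level medians, evidence-category
percentages before/after adjustment, the heterogeneity regression, and the
three-level adjustment model.

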