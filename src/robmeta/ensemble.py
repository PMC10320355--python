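"""The model-averaged ensemble: construction, fitting, and inference.

The full publication-bias-robust ensemble (RoBMA-PSMA) crosses

* effect: absent (point mass at 0) vs present (prior on the z scale,
  default a standard normal on Cohen's d rescaled to z),
* heterogeneity: absent (tau = 0) vs present (inverse-gamma on tau),
* publication bias: absent vs six selection-model weight functions vs PET
  vs PEESE,

for 2 x 2 x 9 = 36 members.  Each of the three hypotheses carries prior
probability 1/2; within bias-present cells the mass is split equally
between the selection family and the PET-PEESE family, then equally within
each family.  Dropping the bias-adjusting members and renormalizing yields
the 4-model Bayesian model-averaged meta-analysis (BMA) used as the
publication-bias-unadjusted reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .effect_scale import Study, rescale_prior_d_to_z
from .model_core import (
    BiasComponent,
    FittedModel,
    IntegrationSettings,
    ModelSpec,
    PriorSpec,
    WeightFunctionSpec,
    fit_model,
)

__all__ = [
    "DEFAULT_WEIGHT_FUNCTIONS",
    "EnsembleResult",
    "build_ensemble",
    "restrict_to_bma",
    "fit_ensemble",
    "categorize_evidence",
    "default_effect_prior_d",
    "default_heterogeneity_prior_d",
]

logger = logging.getLogger("robmeta")

#: The six step weight functions of the published ensemble: cut-offs on
#: significant and marginally significant p-values, one- and two-sided.
DEFAULT_WEIGHT_FUNCTIONS = (
    WeightFunctionSpec("two_sided", (0.05,)),
    WeightFunctionSpec("two_sided", (0.05, 0.10)),
    WeightFunctionSpec("one_sided", (0.05,)),
    WeightFunctionSpec("one_sided", (0.025, 0.05)),
    WeightFunctionSpec("one_sided", (0.05, 0.50)),
    WeightFunctionSpec("one_sided", (0.025, 0.05, 0.50)),
)


def default_effect_prior_d(kind: str = "normal") -> PriorSpec:
    """Effect prior on the Cohen's d scale.

    ``normal`` is the standard normal describing a plausible range of
    effect sizes; ``oosterwijk`` is the elicited Student-t_+(0.35, 0.10, 3)
    prior centred at small positive effects.
    """
    if kind == "normal":
        return PriorSpec("normal", {"loc": 0.0, "scale": 1.0})
    if kind == "oosterwijk":
        return PriorSpec(
            "student_t_plus", {"loc": 0.35, "scale": 0.10, "df": 3.0}
        )
    raise ValueError(f"unknown effect prior kind {kind!r}")


def default_heterogeneity_prior_d() -> PriorSpec:
    """Inverse-gamma(shape=1, scale=0.15) on tau, Cohen's d scale."""
    return PriorSpec("inverse_gamma", {"shape": 1.0, "scale": 0.15})


def _pet_peese_priors_z(prior_rescale: str):
    """PET/PEESE coefficient priors moved from the d scale to the z scale.

    The PET slope is dimensionless (effect per standard error) and is
    unchanged under the linear map d = 2z (both effect and its standard
    error scale by 2); the PEESE slope carries units of 1/se so its scale
    doubles: Cauchy_+(0, 1) and Cauchy_+(0, 5) on d become Cauchy_+(0, 1)
    and Cauchy_+(0, 10) on z.
    """
    del prior_rescale  # coefficient priors always use the linear scaling
    pet = PriorSpec("cauchy_plus", {"loc": 0.0, "scale": 1.0})
    peese = PriorSpec("cauchy_plus", {"loc": 0.0, "scale": 10.0})
    return pet, peese


def build_ensemble(
    effect_prior_alt: Optional[PriorSpec] = None,
    config=None,
) -> list[ModelSpec]:
    """Build the 36-member ensemble with its prior model probabilities.

    ``effect_prior_alt`` is the d-scale prior under the effect-present
    hypothesis (default standard normal); ``config`` (an
    :class:`robmeta.config.AnalysisConfig`) can override the prior-rescale
    mode and the weight-function list.
    """
    prior_rescale = getattr(config, "prior_rescale", "exact")
    weight_functions = getattr(config, "weight_functions", None) or DEFAULT_WEIGHT_FUNCTIONS
    if effect_prior_alt is None:
        kind = getattr(config, "effect_prior", "normal")
        effect_prior_alt = default_effect_prior_d(kind)

    mu_alt = rescale_prior_d_to_z(effect_prior_alt, prior_rescale)
    mu_null = PriorSpec("point", {"loc": 0.0})
    tau_alt = rescale_prior_d_to_z(default_heterogeneity_prior_d(), prior_rescale)
    tau_null = PriorSpec("point", {"loc": 0.0})
    pet_prior, peese_prior = _pet_peese_priors_z(prior_rescale)

    n_wf = len(weight_functions)
    bias_components = [("none", BiasComponent("none"), 1.0 / 2.0)]
    for wf in weight_functions:
        bias_components.append(
            (
                f"sel:{wf.label}",
                BiasComponent("selection", weight_function=wf),
                1.0 / 2.0 / 2.0 / n_wf,
            )
        )
    bias_components.append(
        ("pet", BiasComponent("pet", coefficient_prior=pet_prior), 1.0 / 2.0 / 2.0 / 2.0)
    )
    bias_components.append(
        ("peese", BiasComponent("peese", coefficient_prior=peese_prior), 1.0 / 2.0 / 2.0 / 2.0)
    )

    specs = []
    for mu_name, mu_prior, p_mu in (("null", mu_null, 0.5), ("alt", mu_alt, 0.5)):
        for tau_name, tau_prior, p_tau in (("fixed", tau_null, 0.5), ("random", tau_alt, 0.5)):
            for bias_name, bias, p_bias in bias_components:
                specs.append(
                    ModelSpec(
                        effect_prior=mu_prior,
                        heterogeneity_prior=tau_prior,
                        bias=bias,
                        prior_prob=p_mu * p_tau * p_bias,
                        label=f"mu={mu_name}|tau={tau_name}|bias={bias_name}",
                    )
                )
    total = sum(s.prior_prob for s in specs)
    if abs(total - 1.0) > 1e-12:
        raise AssertionError(f"prior model probabilities sum to {total}")
    return specs


def restrict_to_bma(ensemble: Sequence[ModelSpec]) -> list[ModelSpec]:
    """The bias-unadjusted reduction: keep the 4 bias-absent members.

    Prior probabilities are renormalized, keeping the prior probability of
    the effect at 1/2.
    """
    kept = [s for s in ensemble if not s.has_bias]
    if not kept:
        raise ValueError("ensemble has no bias-absent members")
    total = sum(s.prior_prob for s in kept)
    return [replace(s, prior_prob=s.prior_prob / total) for s in kept]


def categorize_evidence(bf10: float) -> str:
    """Rule-of-thumb evidence category for a Bayes factor BF10.

    BF > 10 strong and BF > 3 moderate evidence for the alternative; the
    mirror thresholds 1/10 and 1/3 for the null; in between, undecided.
    """
    if not bf10 > 0:
        raise ValueError("bf10 must be > 0")
    if bf10 > 10.0:
        return "strong_alt"
    if bf10 > 3.0:
        return "moderate_alt"
    if bf10 >= 1.0 / 3.0:
        return "undecided"
    if bf10 >= 1.0 / 10.0:
        return "moderate_null"
    return "strong_null"


EVIDENCE_CATEGORIES = (
    "strong_null", "moderate_null", "undecided", "moderate_alt", "strong_alt"
)


@dataclass
class EnsembleResult:
    """Posterior summary of a fitted model-averaged ensemble."""

    fitted: list[FittedModel]
    posterior_model_probs: np.ndarray
    p_effect: float
    p_heterogeneity: float
    p_bias: float
    bf_effect: float
    bf_heterogeneity: float
    bf_bias: float
    averaged_effect_mean_z: float
    averaged_effect_mean_r: float  # posterior mean of tanh(mu) under the mixture
    averaged_effect_r_of_mean: float  # tanh of the z-scale mixture mean, for comparison
    averaged_ci_z: tuple
    averaged_ci_r: tuple
    warnings: list = field(default_factory=list)

    @property
    def bf10(self) -> float:
        return self.bf_effect

    def mixture_density(self, grid: Optional[np.ndarray] = None):
        """Model-averaged posterior density of mu on the tabulation grid.

        Point-mass members contribute an atom at their location, returned
        separately as (grid, density, point_mass_weight).
        """
        dens = None
        atom = 0.0
        for fm, p in zip(self.fitted, self.posterior_model_probs):
            if fm.point_mass_at is not None:
                atom += p
                continue
            g, d = fm.effect_posterior_density
            if grid is None:
                grid = g
            if dens is None:
                dens = np.zeros_like(g, dtype=float)
            dens += p * d
        if dens is None:
            dens = np.zeros_like(grid, dtype=float) if grid is not None else None
        return grid, dens, atom

    def to_dict(self) -> dict:
        """JSON-serializable summary (schema version 1)."""
        return {
            "schema_version": 1,
            "models": [
                {
                    "label": fm.spec.label,
                    "prior_prob": fm.spec.prior_prob,
                    "ln_marg_lik": fm.ln_marg_lik,
                    "posterior_prob": float(p),
                    "method": fm.method,
                    "error_estimate": fm.error_estimate,
                    "flagged": fm.flagged,
                }
                for fm, p in zip(self.fitted, self.posterior_model_probs)
            ],
            "p_effect": self.p_effect,
            "p_heterogeneity": self.p_heterogeneity,
            "p_bias": self.p_bias,
            "bf_effect": self.bf_effect,
            "bf_heterogeneity": self.bf_heterogeneity,
            "bf_bias": self.bf_bias,
            "averaged_effect_mean_z": self.averaged_effect_mean_z,
            "averaged_effect_mean_r": self.averaged_effect_mean_r,
            "averaged_effect_r_of_mean": self.averaged_effect_r_of_mean,
            "averaged_ci_z": list(self.averaged_ci_z),
            "averaged_ci_r": list(self.averaged_ci_r),
            "warnings": list(self.warnings),
        }


def _inclusion_bf(p_post: float, p_prior: float) -> float:
    if p_post >= 1.0:
        return math.inf
    if p_post <= 0.0:
        return 0.0
    post_odds = p_post / (1.0 - p_post)
    prior_odds = p_prior / (1.0 - p_prior)
    return post_odds / prior_odds


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return np.interp(qs, cw, v)


def fit_ensemble(
    ensemble: Sequence[ModelSpec],
    studies: Sequence[Study],
    settings: Optional[IntegrationSettings] = None,
) -> EnsembleResult:
    """Fit every member and model-average.

    Posterior model probabilities are proportional to prior probability
    times marginal likelihood (computed via log-sum-exp); inclusion Bayes
    factors are posterior-to-prior odds for each component.  The averaged
    effect posterior is the probability-weighted mixture of the members'
    conditional posteriors, with point-effect members contributing mass at
    their point value.
    """
    settings = settings or IntegrationSettings()
    if len(studies) == 0:
        raise ValueError("at least one study is required")
    warnings_list = []
    if len(studies) < 3:
        warnings_list.append(f"only {len(studies)} studies (k < 3)")

    fitted = []
    for i, spec in enumerate(ensemble):
        rng = np.random.default_rng(np.random.SeedSequence([settings.seed, i]))
        fm = fit_model(spec, studies, settings, rng)
        if fm.flagged:
            warnings_list.append(
                f"model {spec.label!r}: integration error {fm.error_estimate:.3g}"
            )
        fitted.append(fm)
    if all(fm.flagged for fm in fitted):
        raise RuntimeError("all ensemble members failed to integrate reliably")

    ln_prior = np.log([s.prior_prob for s in ensemble])
    ln_ml = np.array([fm.ln_marg_lik for fm in fitted])
    ln_post = ln_prior + ln_ml
    ln_post -= logsumexp(ln_post)
    post = np.exp(ln_post)
    post[post < 1e-300] = 0.0
    post /= post.sum()

    eff = np.array([s.has_effect for s in ensemble])
    het = np.array([s.has_heterogeneity for s in ensemble])
    bias = np.array([s.has_bias for s in ensemble])
    prior = np.exp(ln_prior)

    p_eff = float(post[eff].sum())
    p_het = float(post[het].sum())
    p_bias = float(post[bias].sum())

    # model-averaged effect posterior: pooled weighted samples + atoms
    vals = []
    wts = []
    mean_z = 0.0
    tanh_mean = 0.0
    for fm, p in zip(fitted, post):
        mean_z += p * fm.effect_posterior_mean
        tanh_mean += p * fm.effect_mean_r
        if fm.point_mass_at is not None:
            vals.append(np.array([fm.point_mass_at]))
            wts.append(np.array([p]))
        else:
            vals.append(fm.mu_samples)
            wts.append(p * fm.mu_weights)
    vals = np.concatenate(vals)
    wts = np.concatenate(wts)
    ci_z = tuple(_weighted_quantile(vals, wts, [0.025, 0.975]))
    ci_r = (math.tanh(ci_z[0]), math.tanh(ci_z[1]))

    return EnsembleResult(
        fitted=fitted,
        posterior_model_probs=post,
        p_effect=p_eff,
        p_heterogeneity=p_het,
        p_bias=p_bias,
        bf_effect=_inclusion_bf(p_eff, float(prior[eff].sum())),
        bf_heterogeneity=_inclusion_bf(p_het, float(prior[het].sum())),
        bf_bias=_inclusion_bf(p_bias, float(prior[bias].sum())) if bias.any() else math.nan,
        averaged_effect_mean_z=mean_z,
        averaged_effect_mean_r=tanh_mean,
        averaged_effect_r_of_mean=math.tanh(mean_z),
        averaged_ci_z=ci_z,
        averaged_ci_r=ci_r,
        warnings=warnings_list,
    )
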