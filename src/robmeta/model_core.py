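"""Likelihoods, priors, and marginal likelihoods for publication-bias models.

This module implements every member family of the model-averaged ensemble:

* the random-effects normal likelihood (no bias adjustment),
* Vevea-Hedges style selection-model likelihoods, where each study's
  contribution is re-weighted by a step function omega(p) of its p-value and
  renormalized by the per-study expected weight,
* PET / PEESE meta-regression likelihoods (effect regressed on the standard
  error or its square, with a non-negative slope),

together with the prior families used for effects, heterogeneity, weight
functions (cumulative Dirichlet), and regression coefficients, and a
marginal-likelihood integrator.

Integration contract: every model (up to five free dimensions) is handled
by deterministic mode-centred adaptive Gauss-Hermite quadrature in
unbounded working coordinates -- the effect mu directly, log tau for the
heterogeneity, and a probability-integral-transform + logit map for
bounded or heavy-tailed parameters (Dirichlet sticks of the weight
functions, PET/PEESE coefficients, truncated effect priors).  The latter
map turns the boundary-layer concentration that selection-model
likelihoods develop under strong selection into a smooth interior bump
that the centred rule resolves.  Prior-draw Monte Carlo with a reported
ln-scale standard error is available as an independent cross-check
(``method='mc'``).  Results whose error estimate exceeds the configured
tolerance are flagged, never silently accepted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy import stats
from scipy.special import logsumexp, ndtr, ndtri

from .effect_scale import Study

__all__ = [
    "IntegrationSettings",
    "PriorSpec",
    "WeightFunctionSpec",
    "BiasComponent",
    "ModelSpec",
    "FittedModel",
    "EffectPosterior",
    "p_value",
    "ln_lik_random_effects",
    "ln_lik_selection",
    "ln_lik_pet_peese",
    "prior_logpdf",
    "omega_from_eta",
    "ln_marginal_likelihood",
    "conditional_effect_posterior",
    "fit_model",
]

logger = logging.getLogger("robmeta")

_LN_2PI = math.log(2.0 * math.pi)


def _cauchy_cdf(x: float, loc: float, scale: float) -> float:
    return 0.5 + math.atan((x - loc) / scale) / math.pi


# --------------------------------------------------------------------------
# integration settings
# --------------------------------------------------------------------------


@dataclass
class IntegrationSettings:
    """Controls for the marginal-likelihood integrator.

    method : 'auto' (deterministic mode-centred quadrature throughout) or
        'mc' (prior-draw Monte Carlo, mainly for cross-checks).
    quad_nodes : Gauss-Hermite nodes per dimension, indexed by the total
        number of free dimensions (entry 0 is used for 1-D models, ...).
    mc_draws : prior draws for the Monte Carlo path.
    rel_tol : quadrature error threshold on the ln scale, relative to
        max(1, |ln ML|); exceeding it flags the fit.
    mc_se_tol : Monte Carlo ln-scale standard-error threshold for flagging.
    grid : (lo, hi, npoints) tabulation grid for effect posteriors (z scale).
    """

    method: str = "auto"
    quad_nodes: tuple = (25, 15, 11, 9, 7)
    mc_draws: int = 20000
    seed: int = 0
    rel_tol: float = 0.01
    mc_se_tol: float = 0.05
    grid: tuple = (-2.5, 2.5, 501)

    @classmethod
    def small(cls, seed: int = 0) -> "IntegrationSettings":
        """Reduced-resolution preset for large corpus runs."""
        return cls(quad_nodes=(15, 9, 7, 5, 5), mc_draws=4000, seed=seed)

    def nodes_for(self, ndim: int) -> int:
        return int(self.quad_nodes[min(ndim, len(self.quad_nodes)) - 1])

    def grid_points(self) -> np.ndarray:
        lo, hi, n = self.grid
        return np.linspace(lo, hi, int(n))


# --------------------------------------------------------------------------
# prior families
# --------------------------------------------------------------------------

_FAMILIES = (
    "point",
    "normal",
    "inverse_gamma",
    "cauchy_plus",
    "student_t_plus",
    "cumulative_dirichlet",
    "transformed_d_to_z",
)


@dataclass(frozen=True)
class PriorSpec:
    """A prior distribution for one model ingredient.

    Families and parameters:

    - ``point``: {loc}
    - ``normal``: {loc, scale}
    - ``inverse_gamma``: {shape, scale}  (used for the heterogeneity tau)
    - ``cauchy_plus``: {loc, scale[, lower=0]} half-Cauchy on [lower, inf)
    - ``student_t_plus``: {loc, scale, df[, lower=0]} truncated Student-t
    - ``cumulative_dirichlet``: {alpha} prior on weight-function sticks
    - ``transformed_d_to_z``: {base} exact pushforward of a d-scale prior
      to the Fisher z scale under d = 2 sinh(z)
    """

    family: str
    params: dict

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}")
        p = self.params
        if self.family == "normal" and not p["scale"] > 0:
            raise ValueError("normal prior needs scale > 0")
        if self.family == "inverse_gamma" and not (
            p["shape"] > 0 and p["scale"] > 0
        ):
            raise ValueError("inverse_gamma prior needs shape, scale > 0")
        if self.family in ("cauchy_plus", "student_t_plus") and not p["scale"] > 0:
            raise ValueError("truncated prior needs scale > 0")
        if self.family == "student_t_plus" and not p["df"] > 0:
            raise ValueError("student_t_plus prior needs df > 0")
        if self.family == "cumulative_dirichlet":
            alpha = np.asarray(p["alpha"], dtype=float)
            if alpha.ndim != 1 or np.any(alpha <= 0):
                raise ValueError("cumulative_dirichlet needs positive alpha vector")

    # -- basic structure -------------------------------------------------

    @property
    def is_point(self) -> bool:
        return self.family == "point"

    @property
    def location(self) -> float:
        if self.family == "point":
            return float(self.params["loc"])
        raise ValueError("location is defined for point priors only")

    @property
    def lower(self) -> float:
        return float(self.params.get("lower", 0.0))

    def support_bounded_below(self) -> bool:
        if self.family in ("cauchy_plus", "student_t_plus", "inverse_gamma"):
            return True
        if self.family == "transformed_d_to_z":
            return self.params["base"].support_bounded_below()
        return False

    def scale_hint(self) -> float:
        """Rough prior scale, used as a numerical fallback only."""
        if self.family == "point":
            return 0.0
        if self.family == "transformed_d_to_z":
            return 0.5 * self.params["base"].scale_hint()
        return float(self.params["scale"])

    # -- density / quantiles / sampling ----------------------------------
    # closed forms throughout: these sit in the innermost integration loop

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        p = self.params
        if self.family == "point":
            raise ValueError("point priors have no density")
        if self.family == "normal":
            t = (x - p["loc"]) / p["scale"]
            return -0.5 * t * t - math.log(p["scale"]) - 0.5 * _LN_2PI
        if self.family == "inverse_gamma":
            a, s = p["shape"], p["scale"]
            with np.errstate(divide="ignore", invalid="ignore"):
                out = np.where(
                    x > 0,
                    a * math.log(s)
                    - math.lgamma(a)
                    - (a + 1.0) * np.log(np.where(x > 0, x, 1.0))
                    - s / np.where(x > 0, x, 1.0),
                    -np.inf,
                )
            return out
        if self.family == "cauchy_plus":
            loc, sc, lo = p["loc"], p["scale"], self.lower
            lnz = math.log1p(-_cauchy_cdf(lo, loc, sc))
            t = (x - loc) / sc
            base = -math.log(math.pi * sc) - np.log1p(t * t)
            return np.where(x >= lo, base - lnz, -np.inf)
        if self.family == "student_t_plus":
            loc, sc, df, lo = p["loc"], p["scale"], p["df"], self.lower
            lnz = math.log1p(-stats.t.cdf(lo, df, loc=loc, scale=sc))
            base = stats.t.logpdf(x, df, loc=loc, scale=sc)
            return np.where(x >= lo, base - lnz, -np.inf)
        if self.family == "transformed_d_to_z":
            base = self.params["base"]
            d = 2.0 * np.sinh(x)
            return base.logpdf(d) + np.log(2.0 * np.cosh(x))
        if self.family == "cumulative_dirichlet":
            alpha = np.asarray(self.params["alpha"], dtype=float)
            return stats.dirichlet(alpha).logpdf(np.asarray(x, dtype=float))
        raise ValueError(self.family)

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        p = self.params
        if self.family == "point":
            return np.full_like(u, p["loc"])
        if self.family == "normal":
            return p["loc"] + p["scale"] * ndtri(u)
        if self.family == "inverse_gamma":
            return stats.invgamma.ppf(u, p["shape"], scale=p["scale"])
        if self.family == "cauchy_plus":
            loc, sc = p["loc"], p["scale"]
            c0 = _cauchy_cdf(self.lower, loc, sc)
            q = c0 + u * (1.0 - c0)
            return loc + sc * np.tan(math.pi * (q - 0.5))
        if self.family == "student_t_plus":
            loc, sc, df = p["loc"], p["scale"], p["df"]
            c0 = stats.t.cdf(self.lower, df, loc=loc, scale=sc)
            return stats.t.ppf(c0 + u * (1.0 - c0), df, loc=loc, scale=sc)
        if self.family == "transformed_d_to_z":
            return np.arcsinh(self.params["base"].ppf(u) / 2.0)
        raise ValueError(f"no quantile function for family {self.family!r}")

    def rvs(self, rng: np.random.Generator, size: int):
        if self.family == "cumulative_dirichlet":
            return rng.dirichlet(np.asarray(self.params["alpha"], float), size)
        return self.ppf(rng.uniform(1e-12, 1.0 - 1e-12, size))


def prior_logpdf(prior: PriorSpec, value):
    """Log density of ``prior`` at ``value`` (-inf outside the support)."""
    out = prior.logpdf(value)
    arr = np.asarray(out)
    return float(arr) if arr.ndim == 0 else arr


# --------------------------------------------------------------------------
# weight functions and bias components
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class WeightFunctionSpec:
    """A step weight function over p-value intervals.

    ``cutpoints`` are strictly increasing p cut-offs in (0, 1); the weight
    function has ``J = len(cutpoints) + 1`` steps, non-increasing with p and
    with weight 1 on the most significant interval.  ``omega`` carries fixed
    weights for direct likelihood evaluation; in the ensemble the weights are
    a free parameter under a cumulative unit-Dirichlet prior and ``omega``
    stays None.  A p-value exactly at a cutpoint belongs to the more
    significant interval.
    """

    sidedness: str
    cutpoints: tuple
    omega: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.sidedness not in ("one_sided", "two_sided"):
            raise ValueError(f"invalid sidedness {self.sidedness!r}")
        c = np.asarray(self.cutpoints, dtype=float)
        if c.ndim != 1 or len(c) < 1:
            raise ValueError("cutpoints must be a non-empty 1-D sequence")
        if np.any(c <= 0) or np.any(c >= 1) or np.any(np.diff(c) <= 0):
            raise ValueError("cutpoints must be strictly increasing in (0, 1)")
        if self.omega is not None:
            w = np.asarray(self.omega, dtype=float)
            if len(w) != self.J:
                raise ValueError("omega must have len(cutpoints) + 1 entries")
            if np.any(w <= 0):
                raise ValueError("omega entries must be > 0")

    @property
    def J(self) -> int:
        return len(self.cutpoints) + 1

    @property
    def label(self) -> str:
        cuts = ",".join(f"{c:g}" for c in self.cutpoints)
        return f"{self.sidedness}[{cuts}]"

    def interval_index(self, p) -> np.ndarray:
        """Interval of each p-value (0-based; boundary p goes left)."""
        return np.searchsorted(np.asarray(self.cutpoints), np.asarray(p), "left")


@dataclass(frozen=True)
class BiasComponent:
    """The publication-bias ingredient of one ensemble member."""

    kind: str  # none | selection | pet | peese
    weight_function: Optional[WeightFunctionSpec] = None
    coefficient_prior: Optional[PriorSpec] = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "selection", "pet", "peese"):
            raise ValueError(f"invalid bias kind {self.kind!r}")
        if self.kind == "selection":
            if self.weight_function is None or self.coefficient_prior is not None:
                raise ValueError("selection bias needs exactly a weight_function")
        elif self.kind in ("pet", "peese"):
            if self.coefficient_prior is None or self.weight_function is not None:
                raise ValueError(f"{self.kind} bias needs exactly a coefficient_prior")
        elif self.weight_function is not None or self.coefficient_prior is not None:
            raise ValueError("bias kind 'none' takes no further fields")

    @property
    def order(self) -> int:
        if self.kind == "pet":
            return 1
        if self.kind == "peese":
            return 2
        raise ValueError("order is defined for pet/peese only")


@dataclass(frozen=True)
class ModelSpec:
    """One ensemble member: effect prior x heterogeneity prior x bias."""

    effect_prior: PriorSpec
    heterogeneity_prior: PriorSpec
    bias: BiasComponent
    prior_prob: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.prior_prob < 1.0:
            raise ValueError("prior_prob must be in (0, 1)")

    @property
    def has_effect(self) -> bool:
        return not self.effect_prior.is_point

    @property
    def has_heterogeneity(self) -> bool:
        return not self.heterogeneity_prior.is_point

    @property
    def has_bias(self) -> bool:
        return self.bias.kind != "none"


# --------------------------------------------------------------------------
# p-values and weight-function algebra
# --------------------------------------------------------------------------


def p_value(study: Study, sidedness: str) -> float:
    """P-value of a study's z statistic against a zero effect.

    One-sided p favours positive effects: p = 1 - Phi(z / se); two-sided
    p = 2 (1 - Phi(|z| / se)).
    """
    if not study.se_z > 0:
        raise ValueError("se_z must be > 0")
    stat = study.effect_z / study.se_z
    if sidedness == "one_sided":
        return float(ndtr(-stat))
    if sidedness == "two_sided":
        return float(2.0 * ndtr(-abs(stat)))
    raise ValueError(f"invalid sidedness {sidedness!r}")


def omega_from_eta(eta) -> np.ndarray:
    """Map Dirichlet increments eta to cumulative weights omega.

    ``omega_j = sum_{k >= j} eta_k``, so the most significant interval has
    weight 1 and omega is non-increasing; a unit Dirichlet on eta induces
    the cumulative unit-Dirichlet prior on omega.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.ndim != 1 or np.any(eta < 0) or abs(eta.sum() - 1.0) > 1e-8:
        raise ValueError("eta must be a simplex vector")
    return np.cumsum(eta[::-1])[::-1]


def _sticks_to_eta(u: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Stick-breaking map from unit-cube coordinates to Dirichlet(alpha).

    ``u`` has shape (N, J-1); the k-th stick is the Beta(alpha_k,
    sum(alpha[k+1:])) quantile of u[:, k].
    """
    n, jm1 = u.shape
    J = jm1 + 1
    eta = np.empty((n, J))
    rem = np.ones(n)
    tails = np.cumsum(alpha[::-1])[::-1]
    for k in range(jm1):
        if alpha[k] == 1.0:  # Beta(1, b) quantile in closed form
            v = 1.0 - (1.0 - u[:, k]) ** (1.0 / tails[k + 1])
        else:
            v = stats.beta.ppf(u[:, k], alpha[k], tails[k + 1])
        eta[:, k] = rem * v
        rem = rem * (1.0 - v)
    eta[:, J - 1] = rem
    return eta


def _omega_matrix(eta: np.ndarray) -> np.ndarray:
    return np.cumsum(eta[:, ::-1], axis=1)[:, ::-1]


def _z_thresholds(wf: WeightFunctionSpec, se: np.ndarray) -> np.ndarray:
    """Map p cut-offs to per-study z thresholds; shape (K, J-1)."""
    c = np.asarray(wf.cutpoints, dtype=float)
    if wf.sidedness == "one_sided":
        q = ndtri(1.0 - c)
    else:
        q = ndtri(1.0 - c / 2.0)
    return se[:, None] * q[None, :]


def _interval_probs(
    mu: np.ndarray, s: np.ndarray, thr: np.ndarray, sidedness: str
) -> np.ndarray:
    """P(p in interval j | mu, s) per study; shapes (N,K),(N,K) -> (N,K,J)."""
    t = thr[None, :, :]  # (1, K, J-1)
    m = mu[:, :, None]
    sd = s[:, :, None]
    if sidedness == "one_sided":
        # G_j = P(z > t_j) = Phi((mu - t_j)/s); t_j decreasing in j
        G = ndtr((m - t) / sd)
    else:
        # G_j = P(|z| > t_j)
        G = ndtr((-t - m) / sd) + ndtr((m - t) / sd)
    n, k, jm1 = G.shape
    probs = np.empty((n, k, jm1 + 1))
    probs[:, :, 0] = G[:, :, 0]
    if jm1 > 1:
        probs[:, :, 1:-1] = G[:, :, 1:] - G[:, :, :-1]
    probs[:, :, -1] = 1.0 - G[:, :, -1]
    return np.clip(probs, 1e-300, None)


# --------------------------------------------------------------------------
# likelihoods (vectorized internals + public scalar operations)
# --------------------------------------------------------------------------


def _study_arrays(studies: Sequence[Study]):
    if len(studies) == 0:
        raise ValueError("at least one study is required")
    z = np.array([s.effect_z for s in studies], dtype=float)
    se = np.array([s.se_z for s in studies], dtype=float)
    return z, se


def _ln_lik_plain(z, se, mu, tau, coef=None, order=0):
    """Vectorized ln likelihood; mu, tau, coef are (N,) arrays."""
    s2 = tau[:, None] ** 2 + se[None, :] ** 2
    mean = mu[:, None]
    if coef is not None:
        mean = mean + coef[:, None] * se[None, :] ** order
    return np.sum(-0.5 * (np.log(s2) + _LN_2PI) - 0.5 * (z[None, :] - mean) ** 2 / s2,
                  axis=1)


def _ln_lik_selection_vec(z, se, mu, tau, omega, wf, idx, thr):
    """Selection-model ln likelihood; omega is (N, J)."""
    s = np.sqrt(tau[:, None] ** 2 + se[None, :] ** 2)
    mu2 = np.broadcast_to(mu[:, None], s.shape)
    lnphi = np.sum(
        -0.5 * (2.0 * np.log(s) + _LN_2PI) - 0.5 * ((z[None, :] - mu2) / s) ** 2,
        axis=1,
    )
    probs = _interval_probs(mu2, s, thr, wf.sidedness)
    A = np.einsum("nkj,nj->nk", probs, omega)
    ln_w = np.log(omega[:, idx])
    return lnphi + ln_w.sum(axis=1) - np.log(A).sum(axis=1)


def ln_lik_random_effects(studies: Sequence[Study], mu: float, tau: float) -> float:
    """Random-effects normal log likelihood at (mu, tau) on the z scale."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    z, se = _study_arrays(studies)
    return float(_ln_lik_plain(z, se, np.array([mu]), np.array([tau]))[0])


def ln_lik_selection(
    studies: Sequence[Study], mu: float, tau: float, wf: WeightFunctionSpec
) -> float:
    """Weighted (selection) log likelihood with the step weights ``wf.omega``."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if wf.omega is None:
        raise ValueError("ln_lik_selection needs a weight function with fixed omega")
    z, se = _study_arrays(studies)
    omega = np.asarray(wf.omega, dtype=float)[None, :]
    p = np.array([p_value(s, wf.sidedness) for s in studies])
    idx = wf.interval_index(p)
    thr = _z_thresholds(wf, se)
    return float(
        _ln_lik_selection_vec(
            z, se, np.array([mu]), np.array([tau]), omega, wf, idx, thr
        )[0]
    )


def ln_lik_pet_peese(
    studies: Sequence[Study], mu: float, tau: float, coef: float, order: int
) -> float:
    """PET (order 1) / PEESE (order 2) meta-regression log likelihood."""
    if order not in (1, 2):
        raise ValueError("order must be 1 (PET) or 2 (PEESE)")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if coef < 0:
        raise ValueError("coef must be >= 0 (prior support)")
    z, se = _study_arrays(studies)
    return float(
        _ln_lik_plain(
            z, se, np.array([mu]), np.array([tau]), np.array([coef]), order
        )[0]
    )


# --------------------------------------------------------------------------
# marginal likelihood engine
# --------------------------------------------------------------------------


@dataclass
class EffectPosterior:
    """Tabulated conditional posterior of the effect mu (z scale)."""

    grid: np.ndarray
    density: np.ndarray
    mean: float
    point_mass_at: Optional[float] = None


@dataclass
class FittedModel:
    """A ModelSpec with its log marginal likelihood and effect posterior."""

    spec: ModelSpec
    ln_marg_lik: float
    error_estimate: float
    method: str
    flagged: bool
    effect_posterior_mean: float
    effect_mean_r: float
    mu_samples: Optional[np.ndarray]
    mu_weights: Optional[np.ndarray]
    point_mass_at: Optional[float]
    effect_posterior_density: Optional[tuple]
    diagnostics: dict = field(default_factory=dict)


class _ModelEval:
    """Parameter layout and joint density for one model fit.

    Every free parameter is mapped to an unbounded working coordinate:
    the effect mu directly (its default priors are unbounded), the
    heterogeneity tau through log, and bounded or heavy-tailed parameters
    (Dirichlet sticks of the weight function, PET/PEESE coefficients,
    truncated effect priors) through the probability integral transform of
    their prior followed by a logit.  In these coordinates the integrand is
    a smooth interior bump -- including the boundary layers that selection
    models develop when the data are incompatible with large weights -- so
    a single mode-centred Gauss-Hermite rule integrates every member.
    """

    def __init__(self, spec: ModelSpec, studies: Sequence[Study]):
        self.spec = spec
        self.z, self.se = _study_arrays(studies)
        ep, hp = spec.effect_prior, spec.heterogeneity_prior

        self.mu_fixed = ep.location if ep.is_point else None
        self.tau_fixed = hp.location if hp.is_point else None

        self.dims: list[str] = []
        self.mu_dim = None
        if not ep.is_point:
            self.mu_dim = len(self.dims)
            self.dims.append("mu_pit" if ep.support_bounded_below() else "mu_id")
        self.tau_dim = None
        if not hp.is_point:
            self.tau_dim = len(self.dims)
            self.dims.append("tau_log")

        bias = spec.bias
        self.wf = None
        self.idx = None
        self.thr = None
        self.alpha = None
        self.stick_dims: list[int] = []
        self.coef_dim = None
        if bias.kind == "selection":
            self.wf = bias.weight_function
            if self.wf.sidedness == "one_sided":
                p = ndtr(-self.z / self.se)
            else:
                p = 2.0 * ndtr(-np.abs(self.z) / self.se)
            self.idx = self.wf.interval_index(p)
            self.thr = _z_thresholds(self.wf, self.se)
            self.alpha = np.ones(self.wf.J)
            for _ in range(self.wf.J - 1):
                self.stick_dims.append(len(self.dims))
                self.dims.append("stick")
        elif bias.kind in ("pet", "peese"):
            self.coef_dim = len(self.dims)
            self.dims.append("coef_pit")
        self.ndim = len(self.dims)

    # -- working coordinates -> parameters -------------------------------

    def mu_values(self, x: np.ndarray):
        if self.mu_dim is None:
            return None
        col = x[:, self.mu_dim]
        if self.dims[self.mu_dim] == "mu_id":
            return col
        return self.spec.effect_prior.ppf(_expit_clipped(col))

    def log_joint(self, x: np.ndarray, reps: int = 1) -> np.ndarray:
        """ln [likelihood x density in working coordinates], rows of x."""
        del reps  # rows are self-contained; kept for the batched-call API
        n = len(x)
        extra = np.zeros(n)

        if self.mu_dim is None:
            mu = np.full(n, self.mu_fixed)
        else:
            col = x[:, self.mu_dim]
            if self.dims[self.mu_dim] == "mu_id":
                mu = col
                extra += self.spec.effect_prior.logpdf(mu)
            else:
                mu = self.spec.effect_prior.ppf(_expit_clipped(col))
                extra += _ln_sigmoid_deriv(col)

        if self.tau_dim is None:
            tau = np.full(n, self.tau_fixed)
        else:
            ltau = x[:, self.tau_dim]
            tau = np.exp(ltau)
            extra += self.spec.heterogeneity_prior.logpdf(tau) + ltau

        bias = self.spec.bias
        if bias.kind == "selection":
            xs = x[:, self.stick_dims]
            u = _expit_clipped(xs)
            eta = _sticks_to_eta(u, self.alpha)
            omega = _omega_matrix(eta)
            extra += _ln_sigmoid_deriv(xs).sum(axis=1)
            ll = _ln_lik_selection_vec(
                self.z, self.se, mu, tau, omega, self.wf, self.idx, self.thr
            )
        elif bias.kind in ("pet", "peese"):
            xc = x[:, self.coef_dim]
            coef = bias.coefficient_prior.ppf(_expit_clipped(xc))
            extra += _ln_sigmoid_deriv(xc)
            ll = _ln_lik_plain(self.z, self.se, mu, tau, coef, bias.order)
        else:
            ll = _ln_lik_plain(self.z, self.se, mu, tau)
        return ll + extra


def _expit_clipped(x: np.ndarray) -> np.ndarray:
    u = 1.0 / (1.0 + np.exp(-x))
    return np.clip(u, 1e-15, 1.0 - 1e-15)


def _ln_sigmoid_deriv(x: np.ndarray) -> np.ndarray:
    # d/dx sigmoid = sigmoid(x) sigmoid(-x); stable in both tails
    return -(np.logaddexp(0.0, x) + np.logaddexp(0.0, -x))


@lru_cache(maxsize=16)
def _stencil(d: int) -> np.ndarray:
    """Central-difference stencil: centre, +/- per axis, 4 points per pair."""
    rows = [np.zeros(d)]
    for i in range(d):
        e = np.zeros(d); e[i] = 1.0
        rows.append(e.copy()); rows.append(-e)
    for i in range(d):
        for j in range(i + 1, d):
            for si, sj in ((1, 1), (-1, -1), (1, -1), (-1, 1)):
                e = np.zeros(d); e[i] = si; e[j] = sj
                rows.append(e)
    return np.array(rows)


def _fd_grad_hess(f_batch, x, h=1e-3):
    """Finite-difference gradient and Hessian, vectorized over rows of x."""
    n, d = x.shape
    sten = _stencil(d)
    reps = len(sten)
    pts = (x[:, None, :] + h * sten[None, :, :]).reshape(-1, d)
    vals = f_batch(pts, reps).reshape(n, reps)
    f0 = vals[:, 0]
    g = np.empty((n, d))
    H = np.empty((n, d, d))
    for i in range(d):
        fp, fm = vals[:, 1 + 2 * i], vals[:, 2 + 2 * i]
        g[:, i] = (fp - fm) / (2 * h)
        H[:, i, i] = (fp - 2 * f0 + fm) / h**2
    k = 1 + 2 * d
    for i in range(d):
        for j in range(i + 1, d):
            vpp, vmm, vpm, vmp = (vals[:, k], vals[:, k + 1],
                                  vals[:, k + 2], vals[:, k + 3])
            H[:, i, j] = H[:, j, i] = (vpp + vmm - vpm - vmp) / (4 * h**2)
            k += 4
    return f0, g, H


def _newton_step(g: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Regularized ascent direction -H^-1 g, batched over rows."""
    n, d = g.shape
    lam_max = np.linalg.eigvalsh(H)[:, -1]
    shift = np.where(lam_max > -1e-8, lam_max + 0.1, 0.0)
    H_reg = H - shift[:, None, None] * np.eye(d)[None, :, :]
    return -np.linalg.solve(H_reg, g[..., None])[..., 0]


def _newton_mode(f_batch, x0, iters=50, tol=1e-8):
    """Vectorized damped-Newton ascent to the per-row mode of f.

    Backtracking halving rejects any step that would decrease the
    objective (undamped Newton can limit-cycle on skewed integrands).
    """
    x = x0.copy()
    n, d = x.shape
    for _ in range(iters):
        f0, g, H = _fd_grad_hess(f_batch, x)
        step = np.clip(_newton_step(g, H), -2.0, 2.0)
        scale = np.ones(n)
        accepted = np.zeros(n, dtype=bool)
        x_new = x.copy()
        for _bt in range(5):
            trial = ~accepted
            if not trial.any():
                break
            cand = x + step * scale[:, None]
            fc = f_batch(cand, 1)
            better = fc >= f0 - 1e-10
            take = trial & better
            x_new[take] = cand[take]
            accepted |= take
            scale[trial & ~better] *= 0.25
        if not accepted.all():
            # regularized Newton direction can point downhill on strongly
            # non-concave ridges; fall back to a damped gradient step
            gstep = np.clip(g / (np.abs(g).max(axis=1, keepdims=True) + 1e-12),
                            -1.0, 1.0)
            scale = np.full(n, 0.5)
            for _bt in range(6):
                trial = ~accepted
                if not trial.any():
                    break
                cand = x + gstep * scale[:, None]
                fc = f_batch(cand, 1)
                better = fc > f0 + 1e-12
                take = trial & better
                x_new[take] = cand[take]
                accepted |= take
                scale[trial & ~better] *= 0.25
        moved = np.abs(x_new - x).max()
        x = x_new
        if moved < tol:
            break
    f0, g, H = _fd_grad_hess(f_batch, x)
    return x, H


def _safe_cov(H, fallback_sd, infl=1.5):
    """Inflated inverse negative Hessian, kept positive definite.

    Eigenvalues of the inverse are clipped to [1e-8, 25] (sd between 1e-4
    and 5 on the working scale) so that a flat or indefinite Hessian falls
    back to a prior-scale spread instead of breaking the Cholesky.
    """
    fb = max(fallback_sd, 1e-3) ** 2
    w, v = np.linalg.eigh(-H)  # batched
    lam = np.where(w > 1e-8, 1.0 / np.maximum(w, 1e-8), fb)
    lam = np.clip(lam * infl**2, 1e-8, 25.0)
    return np.einsum("nij,nj,nkj->nik", v, lam, v)


@lru_cache(maxsize=64)
def _gh_tensor(n_nodes: int, d: int):
    x, w = hermgauss(n_nodes)
    grids = np.meshgrid(*([x] * d), indexing="ij")
    nodes = np.column_stack([g.ravel() for g in grids])
    lnw = np.zeros(len(nodes))
    for g in np.meshgrid(*([np.log(w)] * d), indexing="ij"):
        lnw += g.ravel()
    lnw += (nodes**2).sum(axis=1)
    return nodes, lnw


def _gh_sum(ev, x_mode, L, n_nodes):
    """ln integral by Gauss-Hermite centred at (x_mode, sqrt(2) L)."""
    d = ev.ndim
    nodes, lnw = _gh_tensor(n_nodes, d)
    theta = x_mode[0][None, :] + math.sqrt(2.0) * nodes @ L[0].T
    vals = ev.log_joint(theta)
    ln_detL = float(np.log(np.diag(L[0])).sum())
    ln_ml = float(logsumexp(vals + lnw) + 0.5 * d * math.log(2.0) + ln_detL)
    return ln_ml, theta, vals + lnw


def _quadrature(ev: _ModelEval, settings: IntegrationSettings):
    d = ev.ndim
    x0 = np.zeros((1, d))
    if ev.mu_dim is not None and ev.dims[ev.mu_dim] == "mu_id":
        prec = 1.0 / ev.se**2
        x0[0, ev.mu_dim] = float(
            np.clip(np.sum(ev.z * prec) / np.sum(prec), -3.0, 3.0)
        )
    if ev.tau_dim is not None:
        x0[0, ev.tau_dim] = math.log(0.1)

    x_mode, H = _newton_mode(ev.log_joint, x0)
    fallback = max(ev.spec.effect_prior.scale_hint(), 1.0)

    n_fine = settings.nodes_for(d)
    cap = {1: 61, 2: 41, 3: 21, 4: 15, 5: 11}[d]

    def level(n_nodes, infl):
        cov = _safe_cov(H, fallback, infl=infl)
        L = np.linalg.cholesky(cov)
        return _gh_sum(ev, x_mode, L, n_nodes)

    ln_ml, theta, lnw = level(n_fine, 1.5)
    n_coarse = max(5, (2 * n_fine) // 3)
    ln_ml_prev, _, _ = level(n_coarse, 1.5)
    err = abs(ln_ml - ln_ml_prev)
    n_used = n_fine
    # escalate node count and spread while the two finest rules disagree:
    # hard members (curved ridges between log tau and the weight sticks
    # under strong selection) are rare but need the wider rule
    for n_try, infl in ((min(n_fine + 4, cap), 2.0), (min(n_fine + 8, cap), 2.0)):
        if err <= settings.rel_tol * max(1.0, abs(ln_ml)) or n_try <= n_used:
            break
        ln_ml_new, theta, lnw = level(n_try, infl)
        err = abs(ln_ml_new - ln_ml)
        ln_ml = ln_ml_new
        n_used = n_try
    mu = ev.mu_values(theta)
    return ln_ml, err, mu, lnw, {"ndim": d, "gh_nodes": n_used}


def _mc_pass(ev: _ModelEval, settings: IntegrationSettings,
             rng: np.random.Generator):
    m = settings.mc_draws
    spec = ev.spec
    if ev.mu_dim is not None:
        mu = spec.effect_prior.rvs(rng, m)
    else:
        mu = np.full(m, ev.mu_fixed)
    if ev.tau_dim is not None:
        tau = spec.heterogeneity_prior.rvs(rng, m)
    else:
        tau = np.full(m, ev.tau_fixed)
    if spec.bias.kind == "selection":
        eta = rng.dirichlet(ev.alpha, m)
        omega = _omega_matrix(eta)
        lnw = _ln_lik_selection_vec(
            ev.z, ev.se, mu, tau, omega, ev.wf, ev.idx, ev.thr
        )
    elif spec.bias.kind in ("pet", "peese"):
        coef = spec.bias.coefficient_prior.rvs(rng, m)
        lnw = _ln_lik_plain(ev.z, ev.se, mu, tau, coef, spec.bias.order)
    else:
        lnw = _ln_lik_plain(ev.z, ev.se, mu, tau)

    ln_ml = float(logsumexp(lnw) - math.log(m))
    shift = lnw.max()
    w = np.exp(lnw - shift)
    mean_w = w.mean()
    se_ln = float(w.std(ddof=1) / (mean_w * math.sqrt(m))) if mean_w > 0 else np.inf
    has_mu = ev.mu_dim is not None
    return ln_ml, se_ln, (mu if has_mu else None), (lnw if has_mu else None)


def _density_from_samples(mu, lnw, grid):
    """Weighted histogram density on the tabulation grid (integrates to 1)."""
    widths = np.diff(grid)
    edges = np.concatenate(
        [[grid[0] - widths[0] / 2], grid[:-1] + widths / 2, [grid[-1] + widths[-1] / 2]]
    )
    w = np.exp(lnw - logsumexp(lnw))
    hist, _ = np.histogram(mu, bins=edges, weights=w)
    cell = np.diff(edges)
    inside = hist.sum()
    if inside <= 0:
        return np.zeros_like(grid)
    return hist / inside / cell


def fit_model(
    spec: ModelSpec,
    studies: Sequence[Study],
    settings: Optional[IntegrationSettings] = None,
    rng: Optional[np.random.Generator] = None,
) -> FittedModel:
    """Fit one ensemble member: marginal likelihood + effect posterior."""
    settings = settings or IntegrationSettings()
    ev = _ModelEval(spec, studies)
    grid = settings.grid_points()

    if ev.ndim == 0:
        if spec.bias.kind != "none":
            raise ValueError("zero-dimensional bias models are not expected")
        ln_ml = float(
            _ln_lik_plain(
                ev.z, ev.se, np.array([ev.mu_fixed]), np.array([ev.tau_fixed])
            )[0]
        )
        return FittedModel(
            spec, ln_ml, 0.0, "closed_form", False,
            ev.mu_fixed, math.tanh(ev.mu_fixed), None, None, ev.mu_fixed, None,
            {"ndim": 0},
        )

    method = settings.method
    if method == "auto":
        method = "quadrature"

    if method == "quadrature":
        ln_ml, err, mu_samples, lnw, diag = _quadrature(ev, settings)
        flagged = err > settings.rel_tol * max(1.0, abs(ln_ml))
    elif method == "mc":
        rng = rng or np.random.default_rng(settings.seed)
        ln_ml, err, mu_samples, lnw = _mc_pass(ev, settings, rng)
        flagged = err > settings.mc_se_tol
        diag = {"ndim": ev.ndim, "mc_draws": settings.mc_draws}
    else:
        raise ValueError(f"unknown integration method {method!r}")

    if flagged:
        logger.warning(
            "integration flagged for model %s: error %.4g (method %s)",
            spec.label or spec.bias.kind, err, method,
        )

    if mu_samples is None:
        mean_z = ev.mu_fixed
        mean_r = math.tanh(ev.mu_fixed)
        weights = None
        density = None
        point_mass = ev.mu_fixed
    else:
        w = np.exp(lnw - logsumexp(lnw))
        mean_z = float(np.sum(w * mu_samples))
        mean_r = float(np.sum(w * np.tanh(mu_samples)))
        weights = w
        density = (grid, _density_from_samples(mu_samples, lnw, grid))
        point_mass = None

    return FittedModel(
        spec, ln_ml, float(err), method, bool(flagged),
        mean_z, mean_r, mu_samples, weights, point_mass, density, diag,
    )


def ln_marginal_likelihood(
    spec: ModelSpec,
    studies: Sequence[Study],
    settings: Optional[IntegrationSettings] = None,
    rng: Optional[np.random.Generator] = None,
):
    """Log marginal likelihood of one model and its error estimate."""
    fitted = fit_model(spec, studies, settings, rng)
    return fitted.ln_marg_lik, fitted.error_estimate


def conditional_effect_posterior(
    spec: ModelSpec,
    studies: Sequence[Study],
    settings: Optional[IntegrationSettings] = None,
    rng: Optional[np.random.Generator] = None,
) -> EffectPosterior:
    """Tabulated posterior density and mean of mu given data and model."""
    settings = settings or IntegrationSettings()
    fitted = fit_model(spec, studies, settings, rng)
    grid = settings.grid_points()
    if fitted.point_mass_at is not None:
        return EffectPosterior(
            grid, np.zeros_like(grid), fitted.effect_posterior_mean,
            fitted.point_mass_at,
        )
    g, dens = fitted.effect_posterior_density
    return EffectPosterior(g, dens, fitted.effect_posterior_mean, None)
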