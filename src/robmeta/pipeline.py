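"""Corpus-level analysis: evidence inflation and effect-size overestimation.

For every meta-analysis in a corpus this pipeline fits three estimators on
the Fisher z scale:

* reMA -- a conventional random-effects meta-analysis (REML by default),
* BMA  -- the 4-member Bayesian model-averaged ensemble without
  publication-bias adjustment,
* RoBMA -- the full 36-member ensemble including selection models and
  PET/PEESE,

and compares them: the drop in the posterior probability of a non-zero
effect (BMA vs RoBMA) measures evidence inflation attributable to
publication bias, and the difference in posterior mean estimates measures
effect-size overestimation.  Corpus-level summaries, an exploratory
heterogeneity regression, and a three-level hierarchical model of the
adjustments (effect sizes nested in meta-analyses nested in articles)
aggregate the per-meta records.

Each meta-analysis is oriented so its reMA estimate is non-negative before
fitting (the PET/PEESE and one-sided selection components assume selection
favours positive effects); the orientation flag is recorded and reported
estimates can be sign-restored by multiplying with the flag.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import AnalysisConfig
from .effect_scale import Study, inverse_fisher
from .ensemble import (
    EVIDENCE_CATEGORIES,
    build_ensemble,
    categorize_evidence,
    fit_ensemble,
    restrict_to_bma,
)

__all__ = [
    "MetaRecord",
    "CorpusSummary",
    "RegressionResult",
    "ThreeLevelResult",
    "orient_meta",
    "fit_re_ma",
    "analyze_one",
    "analyze_corpus",
    "summarize_corpus",
    "heterogeneity_regression",
    "three_level_adjustment_model",
    "report",
    "records_to_frame",
    "records_from_frame",
]

logger = logging.getLogger("robmeta")


# --------------------------------------------------------------------------
# orientation and random-effects meta-analysis
# --------------------------------------------------------------------------


def orient_meta(studies: Sequence[Study]):
    """Flip all signs if the reMA estimate is negative.

    Returns (studies, flipped); idempotent, and the flip is an exact sign
    symmetry of every downstream estimator.
    """
    est, _, _ = fit_re_ma(studies)
    if est < 0:
        flipped = [Study(effect_z=-s.effect_z, se_z=s.se_z) for s in studies]
        return flipped, True
    return list(studies), False


def _reml_nll(tau2: float, z: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = np.sum(w * z) / np.sum(w)
    return 0.5 * (
        np.sum(np.log(v + tau2)) + math.log(np.sum(w)) + np.sum(w * (z - mu) ** 2)
    )


def fit_re_ma(studies: Sequence[Study], method: str = "reml"):
    """Random-effects meta-analysis on the z scale.

    Returns (estimate_z, tau_z, se_estimate).  ``method='reml'`` maximizes
    the restricted likelihood over tau^2 (1-D bounded optimization);
    ``'dl'`` is the DerSimonian-Laird moment estimator.  A single study
    falls back to a fixed-effect fit with tau = 0.
    """
    z = np.array([s.effect_z for s in studies], dtype=float)
    v = np.array([s.se_z**2 for s in studies], dtype=float)
    k = len(z)
    if k == 0:
        raise ValueError("at least one study is required")
    if k == 1:
        logger.warning("single-study meta-analysis: fixed-effect fallback")
        return float(z[0]), 0.0, float(math.sqrt(v[0]))

    if method == "dl":
        w = 1.0 / v
        mu_fe = np.sum(w * z) / np.sum(w)
        Q = np.sum(w * (z - mu_fe) ** 2)
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / c)
    elif method == "reml":
        spread = float(np.var(z)) + float(np.max(v))
        upper = max(4.0 * spread, 0.1)
        res = optimize.minimize_scalar(
            _reml_nll, bounds=(0.0, upper), args=(z, v), method="bounded",
            options={"xatol": 1e-10},
        )
        tau2 = float(res.x)
        # the bounded optimizer never lands exactly on 0; snap if flat there
        if _reml_nll(0.0, z, v) <= res.fun + 1e-10:
            tau2 = 0.0
    else:
        raise ValueError(f"unknown reMA method {method!r}")

    w = 1.0 / (v + tau2)
    est = float(np.sum(w * z) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return est, float(math.sqrt(tau2)), se


# --------------------------------------------------------------------------
# per-meta analysis
# --------------------------------------------------------------------------


@dataclass
class MetaRecord:
    """Per-meta-analysis comparison of reMA, BMA, and RoBMA.

    Estimates are stored on the oriented scale (reMA estimate made
    non-negative); multiply by -1 where ``orientation_flipped`` to recover
    the original direction.  Adjustments are RoBMA minus the unadjusted
    estimator on the oriented scale, so negative values mean the
    bias-adjusted estimate is smaller in magnitude.
    """

    meta_id: int
    article_id: int
    k: int
    orientation_flipped: bool
    rema_est_z: float = math.nan
    rema_est_r: float = math.nan
    rema_tau_z: float = math.nan
    bma_est_z: float = math.nan
    bma_est_r: float = math.nan
    bma_p_effect: float = math.nan
    bma_bf10: float = math.nan
    robma_est_z: float = math.nan
    robma_est_r: float = math.nan
    robma_p_effect: float = math.nan
    robma_bf10: float = math.nan
    adj_vs_rema_r: float = math.nan
    adj_vs_bma_r: float = math.nan
    adj_vs_rema_z: float = math.nan
    adj_vs_bma_z: float = math.nan
    delta_p_effect: float = math.nan
    evidence_category_before: str = ""
    evidence_category_after: str = ""
    sign_reversal: bool = False
    flagged: bool = False
    warnings: list = field(default_factory=list)


def analyze_one(
    studies: Sequence[Study],
    config: Optional[AnalysisConfig] = None,
    meta_id: int = 1,
    article_id: int = 1,
) -> MetaRecord:
    """Orient, fit reMA + BMA + RoBMA, and fill a MetaRecord."""
    config = config or AnalysisConfig()
    oriented, flipped = orient_meta(studies)
    rec = MetaRecord(meta_id, article_id, len(studies), flipped)
    est_z, tau_z, _ = fit_re_ma(oriented, config.rema_method)
    rec.rema_est_z = est_z
    rec.rema_est_r = inverse_fisher(est_z)
    rec.rema_tau_z = tau_z

    specs = build_ensemble(config=config)
    bma_specs = restrict_to_bma(specs)
    try:
        robma = fit_ensemble(specs, oriented, config.integration)
        bma = fit_ensemble(bma_specs, oriented, config.integration)
    except RuntimeError as exc:
        rec.flagged = True
        rec.warnings.append(str(exc))
        logger.error("meta %s excluded: %s", meta_id, exc)
        return rec

    rec.warnings.extend(robma.warnings)
    rec.bma_est_z = bma.averaged_effect_mean_z
    rec.bma_est_r = bma.averaged_effect_mean_r
    rec.bma_p_effect = bma.p_effect
    rec.bma_bf10 = bma.bf_effect
    rec.robma_est_z = robma.averaged_effect_mean_z
    rec.robma_est_r = robma.averaged_effect_mean_r
    rec.robma_p_effect = robma.p_effect
    rec.robma_bf10 = robma.bf_effect
    rec.adj_vs_rema_r = rec.robma_est_r - rec.rema_est_r
    rec.adj_vs_bma_r = rec.robma_est_r - rec.bma_est_r
    rec.adj_vs_rema_z = rec.robma_est_z - rec.rema_est_z
    rec.adj_vs_bma_z = rec.robma_est_z - rec.bma_est_z
    rec.delta_p_effect = rec.robma_p_effect - rec.bma_p_effect
    rec.evidence_category_before = categorize_evidence(rec.bma_bf10)
    rec.evidence_category_after = categorize_evidence(rec.robma_bf10)
    # adjustment past zero: the corrected estimate points the other way,
    # which can *increase* the evidence for an (opposite-sign) effect
    rec.sign_reversal = rec.robma_est_r < 0.0
    return rec


def analyze_corpus(
    corpus: pd.DataFrame,
    config: Optional[AnalysisConfig] = None,
    json_dir: Optional[Path] = None,
    progress: bool = False,
) -> list[MetaRecord]:
    """Run :func:`analyze_one` for every meta-analysis in a corpus table.

    Integration seeds are derived per meta from the configured base seed,
    so results are independent of processing order.  ``json_dir`` writes a
    per-meta ensemble-result JSON (the fit output schema).
    """
    config = config or AnalysisConfig()
    base_seed = config.integration.seed
    records = []
    groups = list(corpus.groupby("meta_id", sort=True))
    for i, (meta_id, df) in enumerate(groups):
        studies = [
            Study(effect_z=float(r.z), se_z=float(r.se_z))
            for r in df.itertuples(index=False)
        ]
        cfg = replace(
            config,
            integration=replace(config.integration, seed=base_seed + int(meta_id)),
        )
        article_id = int(df["article_id"].iloc[0])
        rec = analyze_one(studies, cfg, int(meta_id), article_id)
        records.append(rec)
        if json_dir is not None:
            _write_meta_json(json_dir, rec)
        if progress and (i + 1) % 25 == 0:
            logger.info("analyzed %d / %d meta-analyses", i + 1, len(groups))
    return records


def _write_meta_json(json_dir: Path, rec: MetaRecord) -> None:
    json_dir = Path(json_dir)
    json_dir.mkdir(parents=True, exist_ok=True)
    payload = {k: v for k, v in rec.__dict__.items()}
    with open(json_dir / f"meta_{rec.meta_id:04d}.json", "w") as fh:
        json.dump(payload, fh, indent=1, default=float)


def records_to_frame(records: Sequence[MetaRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dict(r.__dict__)
        d["warnings"] = "; ".join(d["warnings"])
        rows.append(d)
    return pd.DataFrame(rows)


def records_from_frame(df: pd.DataFrame) -> list[MetaRecord]:
    records = []
    for row in df.to_dict("records"):
        w = row.get("warnings", "")
        row["warnings"] = [x for x in str(w).split("; ") if x and x != "nan"]
        records.append(MetaRecord(**row))
    return records


# --------------------------------------------------------------------------
# corpus summaries
# --------------------------------------------------------------------------


def _median_iqr(x: np.ndarray) -> tuple:
    return (
        float(np.median(x)),
        float(np.percentile(x, 25)),
        float(np.percentile(x, 75)),
    )


@dataclass
class CorpusSummary:
    """Corpus-level evidence and effect-size summaries."""

    n: int
    n_excluded: int
    p_before: tuple  # (median, q25, q75) of the BMA posterior P(effect)
    p_after: tuple  # same for RoBMA
    cat_before_pct: dict
    cat_after_pct: dict
    prop_p_change_small: float  # share with |delta p| <= threshold
    est_rema: tuple
    est_bma: tuple
    est_robma: tuple
    adj_vs_rema: tuple
    adj_vs_bma: tuple
    prop_adj_bma_small: float  # share with |RoBMA - BMA| < threshold (r)
    prob_change_threshold: float
    r_adjust_threshold: float


def summarize_corpus(
    records: Sequence[MetaRecord],
    prob_change_threshold: float = 0.05,
    r_adjust_threshold: float = 0.03,
) -> CorpusSummary:
    """Medians, IQRs, category percentages, and robustness proportions."""
    good = [r for r in records if not r.flagged]
    if not good:
        raise ValueError("no unflagged records to summarize")
    n_exc = len(records) - len(good)
    if n_exc:
        logger.warning("excluding %d flagged records from summaries", n_exc)

    p_b = np.array([r.bma_p_effect for r in good])
    p_a = np.array([r.robma_p_effect for r in good])
    cat_b = [r.evidence_category_before for r in good]
    cat_a = [r.evidence_category_after for r in good]
    pct = lambda cats: {
        c: 100.0 * sum(x == c for x in cats) / len(cats) for c in EVIDENCE_CATEGORIES
    }
    return CorpusSummary(
        n=len(good),
        n_excluded=n_exc,
        p_before=_median_iqr(p_b),
        p_after=_median_iqr(p_a),
        cat_before_pct=pct(cat_b),
        cat_after_pct=pct(cat_a),
        prop_p_change_small=float(
            np.mean(np.abs(p_a - p_b) <= prob_change_threshold)
        ),
        est_rema=_median_iqr(np.array([r.rema_est_r for r in good])),
        est_bma=_median_iqr(np.array([r.bma_est_r for r in good])),
        est_robma=_median_iqr(np.array([r.robma_est_r for r in good])),
        adj_vs_rema=_median_iqr(np.array([r.adj_vs_rema_r for r in good])),
        adj_vs_bma=_median_iqr(np.array([r.adj_vs_bma_r for r in good])),
        prop_adj_bma_small=float(
            np.mean(np.abs([r.adj_vs_bma_r for r in good]) < r_adjust_threshold)
        ),
        prob_change_threshold=prob_change_threshold,
        r_adjust_threshold=r_adjust_threshold,
    )


# --------------------------------------------------------------------------
# heterogeneity regression (conjugate Bayesian linear model)
# --------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Bayesian regression of the bias adjustment on heterogeneity.

    The response is the z-scale adjustment RoBMA - BMA; predictors are the
    raw reMA heterogeneity estimate tau (so the intercept is the expected
    adjustment of a homogeneous meta-analysis at an average unadjusted
    effect size) and the mean-centred unadjusted (BMA) estimate.
    """

    slope_b: float  # adjustment per unit tau (raw)
    slope_b_std: float  # per SD of tau
    intercept_z: float
    coef: dict
    ci_95: dict
    bf10: dict
    n: int
    collinear: bool = False


def _g_prior_ln_ml(y: np.ndarray, X: np.ndarray, g: float) -> float:
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fit = float(beta @ (X.T @ X) @ beta)
    S = float(y @ y) - g / (1.0 + g) * fit
    return -0.5 * p * math.log(1.0 + g) - 0.5 * n * math.log(max(S, 1e-300))


def heterogeneity_regression(records: Sequence[MetaRecord]) -> RegressionResult:
    """Unit-information (g = n) conjugate regression with per-coefficient BFs.

    Bayes factors compare the full model against the model dropping each
    column; 95% credible intervals come from the multivariate-t posterior.
    """
    good = [r for r in records if not r.flagged]
    n = len(good)
    if n < 3:
        raise ValueError("need at least 3 records for the regression")
    if n < 10:
        logger.warning("heterogeneity regression on only %d records", n)

    y = np.array([r.adj_vs_bma_z for r in good])
    tau = np.array([r.rema_tau_z for r in good])
    est = np.array([r.bma_est_z for r in good])
    est_c = est - est.mean()
    X = np.column_stack([np.ones(n), tau, est_c])
    names = ["intercept", "tau", "unadjusted_est"]

    cond = np.linalg.cond(X.T @ X)
    collinear = bool(cond > 1e10)
    if collinear:
        logger.warning("collinear predictors (cond=%.3g)", cond)

    g = float(n)
    ln_full = _g_prior_ln_ml(y, X, g)
    beta_hat, *_ = np.linalg.lstsq(X, y, rcond=None)
    shrink = g / (1.0 + g)
    beta_post = shrink * beta_hat
    S = float(y @ y) - shrink * float(beta_hat @ (X.T @ X) @ beta_hat)
    XtX_inv = np.linalg.pinv(X.T @ X)
    scale = np.sqrt(np.diag(shrink * XtX_inv) * S / n)
    tq = stats.t.ppf(0.975, n)
    ci = {nm: (float(b - tq * s), float(b + tq * s))
          for nm, b, s in zip(names, beta_post, scale)}
    bf = {}
    for j, nm in enumerate(names):
        Xr = np.delete(X, j, axis=1)
        ln_red = _g_prior_ln_ml(y, Xr, g)
        bf[nm] = float(np.exp(np.clip(ln_full - ln_red, -700, 700)))

    tau_sd = float(tau.std(ddof=1)) if n > 1 else 0.0
    return RegressionResult(
        slope_b=float(beta_post[1]),
        slope_b_std=float(beta_post[1] * tau_sd),
        intercept_z=float(beta_post[0]),
        coef={nm: float(b) for nm, b in zip(names, beta_post)},
        ci_95=ci,
        bf10=bf,
        n=n,
        collinear=collinear,
    )


# --------------------------------------------------------------------------
# three-level hierarchical adjustment model
# --------------------------------------------------------------------------


@dataclass
class ThreeLevelResult:
    """Posterior summary of the nested adjustment model.

    adjustment ~ method fixed effect + article intercept + meta intercept
    + residual, with adjustments (r scale) nested two-per-meta (vs reMA and
    vs BMA), metas nested in articles.
    """

    beta: dict  # method -> (posterior mean, 2.5%, 97.5%)
    sd_article: float
    sd_meta: float
    sd_resid: float
    rhat_max: float
    n_samples: int
    converged: bool


def _half_t_logpdf(x: np.ndarray, df: float = 3.0, scale: float = 0.5) -> np.ndarray:
    """Half-Student-t log density on [0, inf), vectorized."""
    c = (
        math.lgamma((df + 1) / 2)
        - math.lgamma(df / 2)
        - 0.5 * math.log(df * math.pi * scale**2)
        + math.log(2.0)
    )
    return c - 0.5 * (df + 1) * np.log1p(x**2 / (df * scale**2))


class _ThreeLevelPosterior:
    """Vectorized log posterior with random intercepts marginalized out.

    Observations come in per-meta pairs (one adjustment per method); the
    within-pair contrast d has variance sigma_e^2, and the pair means s
    form, per article, a compound-symmetric Gaussian with diagonal
    a = sigma_e^2 + 2 sigma_m^2 and common covariance b = 2 sigma_a^2.
    Everything reduces to per-article sufficient statistics, so the
    posterior evaluates for a whole walker ensemble in a few array ops.
    """

    def __init__(self, y1, y2, art_idx, n_art):
        self.m = len(y1)
        self.n_art = n_art
        d = (y1 - y2) / math.sqrt(2.0)
        s = (y1 + y2) / math.sqrt(2.0)
        self.d_sum = float(d.sum())
        self.d_sq = float(d @ d)
        self.s_sq = float(s @ s)
        self.cnt = np.bincount(art_idx, minlength=n_art).astype(float)
        self.s_sum = np.bincount(art_idx, weights=s, minlength=n_art)
        self.d = d
        self.s = s

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        b1, b2, sa, sm, s_e = theta.T
        ok = (s_e > 1e-12) & (sa >= 0) & (sm >= 0) & \
            (np.maximum(np.maximum(sa, sm), s_e) < 1e3)
        sa = np.where(ok, sa, 1.0)
        sm = np.where(ok, sm, 1.0)
        s_e = np.where(ok, s_e, 1.0)
        sa2, sm2, se2 = sa**2, sm**2, s_e**2

        lp = -0.5 * (b1**2 + b2**2)  # Normal(0, 1) on the fixed effects
        lp += _half_t_logpdf(sa) + _half_t_logpdf(sm) + _half_t_logpdf(s_e)

        m, n_art = self.m, self.n_art
        cd = (b1 - b2) / math.sqrt(2.0)
        cs = (b1 + b2) / math.sqrt(2.0)
        qd = self.d_sq - 2.0 * self.d_sum * cd + m * cd**2
        lp += -0.5 * m * np.log(2 * math.pi * se2) - 0.5 * qd / se2

        a = se2 + 2.0 * sm2
        b = 2.0 * sa2
        qs = self.s_sq - 2.0 * cs * self.s_sum.sum() + m * cs**2
        rs_sum = self.s_sum[None, :] - self.cnt[None, :] * cs[:, None]
        denom = a[:, None] + self.cnt[None, :] * b[:, None]
        lp += -0.5 * (
            m * math.log(2 * math.pi)
            + (m - n_art) * np.log(a)
            + np.log(denom).sum(axis=1)
            + qs / a
            - (b / a) * (rs_sum**2 / denom).sum(axis=1)
        )
        out = np.where(ok, lp, -np.inf)
        return out if len(out) > 1 else float(out[0])


def _split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat over (n_chains, n_draws) for one parameter."""
    n = chains.shape[1] // 2
    halves = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W)) if W > 0 else 1.0


def three_level_adjustment_model(
    records: Sequence[MetaRecord],
    seed: int = 0,
    n_steps: int = 6000,
    n_burn: int = 1500,
    n_walkers: int = 24,
) -> ThreeLevelResult:
    """Fit the nested adjustment model by MCMC (affine-invariant ensemble).

    The article and meta random intercepts are marginalized analytically
    (the marginal covariance is block compound-symmetric), leaving a
    5-parameter posterior: two method fixed effects and three variance
    scales.  Convergence requires split-Rhat < 1.01 on every parameter;
    one automatic retry doubles the chain length.
    """
    import emcee

    good = [r for r in records if not r.flagged]
    arts = sorted({r.article_id for r in good})
    art_map = {a: i for i, a in enumerate(arts)}
    by_art_metas = {}
    for r in good:
        by_art_metas.setdefault(r.article_id, []).append(r)
    if len(arts) < 2 or not any(len(v) >= 2 for v in by_art_metas.values()):
        raise ValueError("need >= 2 articles and >= 2 metas within an article")

    y1 = np.array([r.adj_vs_rema_r for r in good])
    y2 = np.array([r.adj_vs_bma_r for r in good])
    art_idx = np.array([art_map[r.article_id] for r in good])
    n_art = len(arts)
    logpost = _ThreeLevelPosterior(y1, y2, art_idx, n_art)

    rng = np.random.default_rng(seed)
    ndim = 5
    # data-driven start: contrast spread fixes sigma_e; the pair-mean
    # spread bounds the article and meta scales
    s_e0 = max(float(np.std(logpost.d)), 1e-7)
    s_lvl = max(float(np.std(logpost.s)) / 2.0, 1e-7)
    center = np.array([y1.mean(), y2.mean(), s_lvl, s_lvl, s_e0])

    def run(steps):
        moves = [
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ]
        sampler = emcee.EnsembleSampler(
            n_walkers, ndim, logpost, vectorize=True, moves=moves
        )
        sampler._random = np.random.RandomState(seed)
        jit = rng.standard_normal((n_walkers, ndim))
        p0 = np.empty((n_walkers, ndim))
        p0[:, :2] = center[None, :2] + 0.5 * (s_e0 + s_lvl) * jit[:, :2]
        p0[:, 2:] = np.abs(center[None, 2:] * (1.0 + 0.3 * jit[:, 2:])) + 1e-9
        sampler.run_mcmc(p0, steps + n_burn, progress=False)
        chain = sampler.get_chain()[n_burn:]  # (steps, walkers, dim)
        return np.moveaxis(chain, 0, 1)  # (walkers, steps, dim)

    chains = run(n_steps)
    rhat = max(_split_rhat(chains[:, :, j]) for j in range(ndim))
    if rhat >= 1.01:
        chains = run(2 * n_steps)
        rhat = max(_split_rhat(chains[:, :, j]) for j in range(ndim))
    converged = rhat < 1.01
    if not converged:
        raise RuntimeError(
            f"three-level model failed to converge (split-Rhat = {rhat:.4f})"
        )

    flat = chains.reshape(-1, ndim)
    def summ(x):
        return (float(x.mean()), float(np.percentile(x, 2.5)),
                float(np.percentile(x, 97.5)))
    return ThreeLevelResult(
        beta={"vs_rema": summ(flat[:, 0]), "vs_bma": summ(flat[:, 1])},
        sd_article=float(flat[:, 2].mean()),
        sd_meta=float(flat[:, 3].mean()),
        sd_resid=float(flat[:, 4].mean()),
        rhat_max=rhat,
        n_samples=flat.shape[0],
        converged=converged,
    )


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------


def _fmt_mi(t: tuple) -> str:
    return f"{t[0]:.3f} (IQR {t[1]:.3f}, {t[2]:.3f})"


def summary_to_frame(summary: CorpusSummary) -> pd.DataFrame:
    rows = [
        ("n_meta_analyses", summary.n),
        ("n_excluded", summary.n_excluded),
        ("p_effect_median_before", summary.p_before[0]),
        ("p_effect_median_after", summary.p_after[0]),
        ("prop_p_change_small", summary.prop_p_change_small),
        ("est_rema_median_r", summary.est_rema[0]),
        ("est_bma_median_r", summary.est_bma[0]),
        ("est_robma_median_r", summary.est_robma[0]),
        ("adj_vs_rema_median_r", summary.adj_vs_rema[0]),
        ("adj_vs_bma_median_r", summary.adj_vs_bma[0]),
        ("prop_adj_bma_small", summary.prop_adj_bma_small),
    ]
    for c in EVIDENCE_CATEGORIES:
        rows.append((f"pct_before_{c}", summary.cat_before_pct[c]))
        rows.append((f"pct_after_{c}", summary.cat_after_pct[c]))
    return pd.DataFrame(rows, columns=["quantity", "value"])


def report(
    records: Sequence[MetaRecord],
    summary: CorpusSummary,
    regression: Optional[RegressionResult] = None,
    three_level: Optional[ThreeLevelResult] = None,
    outdir: Path = Path("robmeta_report"),
    figures: bool = True,
) -> dict:
    """Write the corpus report: records CSV, summary CSV + markdown, figures.

    Deterministic given identical inputs (figure hash salts and metadata
    dates are pinned).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    df = records_to_frame(records)
    paths["records"] = outdir / "records.csv"
    df.to_csv(paths["records"], index=False)

    sdf = summary_to_frame(summary)
    paths["summary_csv"] = outdir / "summary.csv"
    sdf.to_csv(paths["summary_csv"], index=False)

    lines = [
        "# Corpus summary",
        "",
        f"Meta-analyses: {summary.n} (excluded: {summary.n_excluded})",
        "",
        "## Evidence for the presence of the effect",
        "",
        f"- median posterior P(effect), unadjusted (BMA): {_fmt_mi(summary.p_before)}",
        f"- median posterior P(effect), adjusted (RoBMA): {_fmt_mi(summary.p_after)}",
        f"- share with |change in P(effect)| <= {summary.prob_change_threshold:g}: "
        f"{100 * summary.prop_p_change_small:.1f}%",
        "",
        "| category | before (BMA) % | after (RoBMA) % |",
        "|---|---|---|",
    ]
    for c in EVIDENCE_CATEGORIES:
        lines.append(
            f"| {c} | {summary.cat_before_pct[c]:.1f} | {summary.cat_after_pct[c]:.1f} |"
        )
    lines += [
        "",
        "## Effect size estimates (r scale, oriented)",
        "",
        f"- reMA:  {_fmt_mi(summary.est_rema)}",
        f"- BMA:   {_fmt_mi(summary.est_bma)}",
        f"- RoBMA: {_fmt_mi(summary.est_robma)}",
        f"- adjustment RoBMA - reMA: {_fmt_mi(summary.adj_vs_rema)}",
        f"- adjustment RoBMA - BMA:  {_fmt_mi(summary.adj_vs_bma)}",
        f"- share adjusted by less than r = {summary.r_adjust_threshold:g} "
        f"(vs BMA): {100 * summary.prop_adj_bma_small:.1f}%",
    ]
    if regression is not None:
        lines += [
            "",
            "## Heterogeneity regression (z scale)",
            "",
            f"- slope on tau: b = {regression.slope_b:.3f}, "
            f"95% CI [{regression.ci_95['tau'][0]:.3f}, {regression.ci_95['tau'][1]:.3f}], "
            f"BF10 = {regression.bf10['tau']:.3g}",
            f"- intercept (homogeneous metas): {regression.intercept_z:.3f}, "
            f"95% CI [{regression.ci_95['intercept'][0]:.3f}, "
            f"{regression.ci_95['intercept'][1]:.3f}], "
            f"BF10 = {regression.bf10['intercept']:.3g}",
        ]
    if three_level is not None:
        lines += ["", "## Three-level adjustment model (r scale)", ""]
        for name, (m, lo, hi) in three_level.beta.items():
            lines.append(f"- beta[{name}] = {m:.3f}, 95% CI [{lo:.3f}, {hi:.3f}]")
        lines.append(
            f"- sd(article) = {three_level.sd_article:.4f}, "
            f"sd(meta) = {three_level.sd_meta:.4f}, "
            f"sd(resid) = {three_level.sd_resid:.4f} "
            f"(split-Rhat max {three_level.rhat_max:.3f})"
        )
    paths["summary_md"] = outdir / "summary.md"
    paths["summary_md"].write_text("\n".join(lines) + "\n")

    if figures:
        paths.update(_figures(records, outdir))
    return paths


def _figures(records: Sequence[MetaRecord], outdir: Path) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "robmeta"
    meta = {"Date": None}
    good = [r for r in records if not r.flagged]
    p_b = np.array([r.bma_p_effect for r in good])
    p_a = np.array([r.robma_p_effect for r in good])
    paths = {}

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot([0, 1], [0, 1], ":", color="grey", lw=1)
    ax.scatter(p_b, p_a, s=12, alpha=0.6, edgecolors="none")
    ax.set_xlabel("P(effect), unadjusted (BMA)")
    ax.set_ylabel("P(effect), bias-adjusted (RoBMA)")
    fig.tight_layout()
    paths["fig_probabilities"] = outdir / "fig_probabilities.svg"
    fig.savefig(paths["fig_probabilities"], metadata=meta)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4.5), sharey=True)
    for ax, x, lab in (
        (axes[0], [r.rema_est_r for r in good], "reMA estimate (r)"),
        (axes[1], [r.bma_est_r for r in good], "BMA estimate (r)"),
    ):
        x = np.asarray(x)
        lim = [min(-0.1, x.min()), max(0.6, x.max())]
        ax.plot(lim, lim, ":", color="grey", lw=1)
        ax.scatter(x, [r.robma_est_r for r in good], s=12, alpha=0.6,
                   edgecolors="none")
        ax.set_xlabel(lab)
    axes[0].set_ylabel("RoBMA estimate (r)")
    fig.tight_layout()
    paths["fig_estimates"] = outdir / "fig_estimates.svg"
    fig.savefig(paths["fig_estimates"], metadata=meta)
    plt.close(fig)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    for est, lab in (
        ([r.rema_est_r for r in good], "reMA"),
        ([r.bma_est_r for r in good], "BMA"),
        ([r.robma_est_r for r in good], "RoBMA"),
    ):
        axes[0].hist(est, bins=30, histtype="step", density=True, label=lab)
    axes[0].set_xlabel("estimate (r)")
    axes[0].legend(frameon=False)
    for adj, lab in (
        ([r.adj_vs_rema_r for r in good], "RoBMA - reMA"),
        ([r.adj_vs_bma_r for r in good], "RoBMA - BMA"),
    ):
        axes[1].hist(adj, bins=30, histtype="step", density=True, label=lab)
    axes[1].set_xlabel("adjustment (r)")
    axes[1].legend(frameon=False)
    fig.tight_layout()
    paths["fig_adjustments"] = outdir / "fig_adjustments.svg"
    fig.savefig(paths["fig_adjustments"], metadata=meta)
    plt.close(fig)
    return paths
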