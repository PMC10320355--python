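"""Synthetic corpora of meta-analyses with known truth.

Generates nested article -> meta-analysis -> study data emulating the
structure of large published meta-analysis corpora in psychology (tens of
articles, each contributing several meta-analyses of correlation effect
sizes).  Each meta-analysis has a true mean effect mu (Fisher z scale), a
true between-study heterogeneity tau, per-study sample sizes, and optional
significance-based publication selection: a study is drawn, its p-value
computed, and it is published with the probability attached to its p-value
interval.  Selection mirrors the step weight-function form of the fitted
selection models, so the generator and the model family are matched.

Study generation repeats until the target number of published studies is
reached (meta-analyses are observed at their published size), with a cap
on attempts to abort pathological configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .effect_scale import Study
from .model_core import WeightFunctionSpec

__all__ = [
    "DistSpec",
    "SelectionSpec",
    "SimulationConfig",
    "TruthRecord",
    "simulate_meta_analysis",
    "simulate_corpus",
    "small_preset",
    "corpus_preset",
]


@dataclass(frozen=True)
class DistSpec:
    """A small distribution spec for generator inputs.

    kinds: ``point`` {value}; ``normal`` {loc, scale}; ``halfnormal``
    {scale}; ``uniform`` {low, high}; ``lognormal`` {mean_log, sd_log,
    minimum} (values are shifted up to ``minimum`` if given).
    """

    kind: str
    params: dict

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.kind == "point":
            return np.full(size, float(p["value"]))
        if self.kind == "normal":
            return rng.normal(p["loc"], p["scale"], size)
        if self.kind == "halfnormal":
            return np.abs(rng.normal(0.0, p["scale"], size))
        if self.kind == "uniform":
            return rng.uniform(p["low"], p["high"], size)
        if self.kind == "lognormal":
            x = rng.lognormal(p["mean_log"], p["sd_log"], size)
            lo = p.get("minimum")
            return np.maximum(x, lo) if lo is not None else x
        raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass(frozen=True)
class SelectionSpec:
    """Significance-based publication selection.

    ``publish_probs`` gives, per p-value interval (most significant
    first), the probability that a finished study is published; intervals
    are defined by ``cutpoints`` under ``sidedness`` exactly as in the
    selection-model weight functions.
    """

    sidedness: str = "one_sided"
    cutpoints: tuple = (0.05,)
    publish_probs: tuple = (1.0,)

    def __post_init__(self) -> None:
        wf = WeightFunctionSpec(self.sidedness, self.cutpoints)  # validates
        probs = np.asarray(self.publish_probs, dtype=float)
        if len(probs) != wf.J:
            raise ValueError("publish_probs must have len(cutpoints) + 1 entries")
        if np.any(probs <= 0) or np.any(probs > 1):
            raise ValueError("publish_probs must be in (0, 1]")

    @property
    def none(self) -> bool:
        return all(p == 1.0 for p in self.publish_probs)

    def weight_function(self) -> WeightFunctionSpec:
        return WeightFunctionSpec(self.sidedness, self.cutpoints)


NO_SELECTION = SelectionSpec("one_sided", (0.05,), (1.0, 1.0))


@dataclass
class TruthRecord:
    """Per-meta-analysis generating truth, for parameter recovery."""

    meta_id: int
    true_mu_z: float
    true_tau_z: float
    n_generated: int
    n_published: int

    def __post_init__(self) -> None:
        if self.n_published > self.n_generated:
            raise ValueError("n_published cannot exceed n_generated")


@dataclass
class SimulationConfig:
    """Layout and generating process of a synthetic corpus.

    Defaults mimic the scale of the published corpus this package is built
    to analyse: 90 articles with 4-5 meta-analyses each (about 400
    meta-analyses), 5-40 studies per meta-analysis, true effects centred
    on small positive correlations, modest heterogeneity, and sample sizes
    with median about 60.
    """

    seed: int
    n_articles: int = 90
    metas_per_article: tuple = (4, 5)
    K: tuple = (5, 40)
    mu_z_dist: DistSpec = field(
        default_factory=lambda: DistSpec("normal", {"loc": 0.15, "scale": 0.15})
    )
    tau_z_dist: DistSpec = field(
        default_factory=lambda: DistSpec("halfnormal", {"scale": 0.10})
    )
    n_dist: DistSpec = field(
        default_factory=lambda: DistSpec(
            "lognormal", {"mean_log": math.log(60.0), "sd_log": 0.6, "minimum": 10}
        )
    )
    selection: SelectionSpec = field(
        default_factory=lambda: SelectionSpec("one_sided", (0.05,), (1.0, 0.3))
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory (no silent nondeterminism)")
        for name in ("metas_per_article", "K"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"invalid range for {name}: {(lo, hi)}")


def small_preset(seed: int) -> SimulationConfig:
    """Tiny corpus (about 20 metas, K <= 20) for fast checks."""
    return SimulationConfig(
        seed=seed, n_articles=7, metas_per_article=(2, 4), K=(4, 20)
    )


def corpus_preset(seed: int) -> SimulationConfig:
    """Full-scale corpus preset (~90 articles, ~400 meta-analyses)."""
    return SimulationConfig(seed=seed)


class SimulationError(RuntimeError):
    pass


def simulate_meta_analysis(
    true_mu_z: float,
    true_tau_z: float,
    K_target: int,
    n_dist: DistSpec,
    selection: SelectionSpec,
    rng: np.random.Generator,
    meta_id: int = 0,
    max_attempts_factor: int = 100,
):
    """Draw studies until ``K_target`` are published.

    Each attempt draws a true study effect theta ~ N(mu, tau), a sample
    size n, an observed z ~ N(theta, 1/sqrt(n-3)), computes the p-value
    under the selection spec's sidedness, and publishes with the
    probability of the p-value's interval.
    """
    if true_tau_z < 0:
        raise ValueError("true_tau_z must be >= 0")
    if K_target < 1:
        raise ValueError("K_target must be >= 1")
    wf = selection.weight_function()
    probs = np.asarray(selection.publish_probs, dtype=float)
    cap = max_attempts_factor * K_target
    studies: list[Study] = []
    n_generated = 0
    while len(studies) < K_target:
        if n_generated >= cap:
            worst = int(np.argmin(probs))
            raise SimulationError(
                f"meta {meta_id}: exceeded {cap} attempts; publish probability "
                f"{probs[worst]:g} in p-interval {worst} is likely too small"
            )
        batch = min(max(4 * (K_target - len(studies)), 16), cap - n_generated)
        theta = rng.normal(true_mu_z, true_tau_z, batch)
        n = np.floor(n_dist.draw(rng, batch)).astype(int)
        n = np.maximum(n, 4)
        se = 1.0 / np.sqrt(n - 3.0)
        z = rng.normal(theta, se)
        stat = z / se
        if wf.sidedness == "one_sided":
            p = 1.0 - _ndtr(stat)
        else:
            p = 2.0 * (1.0 - _ndtr(np.abs(stat)))
        keep = rng.uniform(size=batch) < probs[wf.interval_index(p)]
        n_generated += batch
        for zi, ni in zip(z[keep], n[keep]):
            if len(studies) < K_target:
                studies.append(Study(effect_z=float(zi), n=int(ni)))
            else:
                n_generated -= 1  # overdrawn in the final batch; not consumed
    truth = TruthRecord(meta_id, true_mu_z, true_tau_z, n_generated, len(studies))
    return studies, truth


def _ndtr(x):
    from scipy.special import ndtr

    return ndtr(x)


def simulate_corpus(config: SimulationConfig):
    """Generate a corpus; returns (study-level DataFrame, truth DataFrame).

    Ids are 1-based and nested (article -> meta -> study); the study table
    follows the study-level CSV schema.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    truths = []
    meta_id = 0
    for article in range(1, config.n_articles + 1):
        m_lo, m_hi = config.metas_per_article
        n_metas = int(rng.integers(m_lo, m_hi + 1))
        for _ in range(n_metas):
            meta_id += 1
            k_lo, k_hi = config.K
            K = int(rng.integers(k_lo, k_hi + 1))
            mu = float(config.mu_z_dist.draw(rng, 1)[0])
            tau = float(np.abs(config.tau_z_dist.draw(rng, 1)[0]))
            try:
                studies, truth = simulate_meta_analysis(
                    mu, tau, K, config.n_dist, config.selection, rng, meta_id
                )
            except SimulationError as exc:
                raise SimulationError(f"while simulating meta {meta_id}: {exc}")
            truths.append(truth)
            for j, s in enumerate(studies, start=1):
                rows.append(
                    (article, meta_id, j, s.effect_r, s.n, s.effect_z, s.se_z)
                )
    corpus = pd.DataFrame(
        rows, columns=["article_id", "meta_id", "study_id", "r", "n", "z", "se_z"]
    )
    truth_df = pd.DataFrame(
        [
            (t.meta_id, t.true_mu_z, t.true_tau_z, t.n_generated, t.n_published)
            for t in truths
        ],
        columns=["meta_id", "true_mu_z", "true_tau_z", "n_generated", "n_published"],
    )
    return corpus, truth_df
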