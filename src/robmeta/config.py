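"""Analysis configuration: priors, integration, thresholds, YAML I/O."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Optional

import yaml

from .model_core import IntegrationSettings, WeightFunctionSpec

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """End-to-end analysis options.

    effect_prior : 'normal' (standard normal on Cohen's d) or 'oosterwijk'
        (elicited Student-t_+(0.35, 0.10, 3)); the sensitivity analysis
        switches only this.
    prior_rescale : 'exact' (d = 2 sinh z change of variables) or 'linear'
        (d = 2z) for moving d-scale priors to the analysis scale.
    rema_method : 'reml' (default) or 'dl' for the random-effects
        meta-analysis heterogeneity estimator.
    prob_change_threshold : |delta posterior probability| below which a
        meta-analysis counts as evidence-robust (default 0.05).
    r_adjust_threshold : |r adjustment| below which an estimate counts as
        essentially unadjusted (default 0.03).
    """

    effect_prior: str = "normal"
    prior_rescale: str = "exact"
    rema_method: str = "reml"
    prob_change_threshold: float = 0.05
    r_adjust_threshold: float = 0.03
    integration: IntegrationSettings = field(default_factory=IntegrationSettings)
    weight_functions: Optional[tuple] = None  # None -> the default six

    def __post_init__(self) -> None:
        if self.effect_prior not in ("normal", "oosterwijk"):
            raise ValueError(f"unknown effect_prior {self.effect_prior!r}")
        if self.prior_rescale not in ("exact", "linear"):
            raise ValueError(f"unknown prior_rescale {self.prior_rescale!r}")
        if self.rema_method not in ("reml", "dl"):
            raise ValueError(f"unknown rema_method {self.rema_method!r}")

    @classmethod
    def small(cls, seed: int = 0, **kw) -> "AnalysisConfig":
        """Preset with the reduced-resolution integration settings."""
        return cls(integration=IntegrationSettings.small(seed=seed), **kw)

    def with_seed(self, seed: int) -> "AnalysisConfig":
        return replace(self, integration=replace(self.integration, seed=seed))

    # -- YAML round trip --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["integration"] = asdict(self.integration)
        if self.weight_functions is not None:
            d["weight_functions"] = [
                {"sidedness": wf.sidedness, "cutpoints": list(wf.cutpoints)}
                for wf in self.weight_functions
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        integ = d.pop("integration", None)
        wfs = d.pop("weight_functions", None)
        cfg = cls(**d)
        if integ is not None:
            cfg.integration = IntegrationSettings(**integ)
        if wfs is not None:
            cfg.weight_functions = tuple(
                WeightFunctionSpec(w["sidedness"], tuple(w["cutpoints"]))
                for w in wfs
            )
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
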