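"""Effect-size scale conversions: correlation r, Fisher z, and Cohen's d.

Meta-analytic fitting happens on the Fisher z scale, whose sampling
distribution is approximately normal with variance 1/(n - 3) and whose
standard error is orthogonal to the effect itself (a requirement of
small-study meta-regressions such as PET/PEESE).  Priors elicited on the
Cohen's d scale are moved to the z scale either by the exact change of
variables d = 2 sinh(z) (equivalently d = 2r / sqrt(1 - r^2) with
r = tanh z) or by its small-effect linearization d = 2z.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Study",
    "fisher_transform",
    "inverse_fisher",
    "fisher_se",
    "rescale_prior_d_to_z",
    "studies_from_frame",
    "studies_to_frame",
    "CSV_COLUMNS",
]

logger = logging.getLogger("robmeta")

#: Study-level CSV schema (either (r, n) or (z, se_z) must be present).
CSV_COLUMNS = ("article_id", "meta_id", "study_id", "r", "n", "z", "se_z")


def fisher_transform(r):
    """Fisher z transform, z = atanh(r).

    Parameters
    ----------
    r : float or array-like
        Correlation(s) strictly inside (-1, 1).
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_transform requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher(z):
    """Back-transform Fisher z to the correlation scale, r = tanh(z)."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("inverse_fisher requires finite z")
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


def fisher_se(n):
    """Standard error of Fisher z for a correlation from n pairs: 1/sqrt(n-3)."""
    n_arr = np.asarray(n)
    if np.any(n_arr < 4):
        raise ValueError("fisher_se requires n >= 4")
    out = 1.0 / np.sqrt(n_arr - 3.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class Study:
    """One primary-study effect with its precision, on the Fisher z scale.

    Either ``(effect_r, n)`` or ``(effect_z, se_z)`` suffices; missing
    members are filled from the invariants ``effect_z = atanh(effect_r)``
    and ``se_z = 1/sqrt(n - 3)``.  An explicitly supplied ``se_z`` wins
    over the one implied by ``n`` (a warning is logged).
    """

    effect_z: float = math.nan
    se_z: float = math.nan
    effect_r: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        has_z = math.isfinite(self.effect_z)
        if self.effect_r is not None:
            if not -1.0 < self.effect_r < 1.0:
                raise ValueError(f"effect_r must be in (-1, 1), got {self.effect_r}")
            z_from_r = math.atanh(self.effect_r)
            if has_z:
                if abs(z_from_r - self.effect_z) > 1e-8:
                    raise ValueError("effect_z inconsistent with atanh(effect_r)")
            else:
                self.effect_z = z_from_r
        elif has_z:
            self.effect_r = math.tanh(self.effect_z)
        else:
            raise ValueError("Study needs effect_r or effect_z")

        has_se = math.isfinite(self.se_z)
        if self.n is not None:
            if self.n < 4:
                raise ValueError(f"sample size must be >= 4, got {self.n}")
            se_from_n = 1.0 / math.sqrt(self.n - 3.0)
            if has_se:
                if abs(se_from_n - self.se_z) > 1e-12:
                    logger.warning(
                        "Study has both n=%s and se_z=%.4g; using the supplied se_z",
                        self.n,
                        self.se_z,
                    )
            else:
                self.se_z = se_from_n
        elif not has_se:
            raise ValueError("Study needs n or se_z")
        if not self.se_z > 0:
            raise ValueError("se_z must be > 0")


def rescale_prior_d_to_z(prior, mode: str = "exact"):
    """Re-express a prior given on the Cohen's d scale on the Fisher z scale.

    ``mode='exact'`` applies the change of variables under d = 2 sinh(z)
    (point masses map their location; continuous location families become a
    transformed density with Jacobian 2 cosh z).  ``mode='linear'`` uses the
    small-effect linearization d = 2z, which keeps each family closed under
    the rescaling (location and scale are halved).  A scale parameter such
    as the heterogeneity tau has no exact pushforward under the nonlinear
    mean map, so inverse-gamma priors always use the linearization
    tau_z = tau_d / 2.
    """
    from .model_core import PriorSpec  # deferred: model_core imports Study

    if not isinstance(prior, PriorSpec):
        raise TypeError("rescale_prior_d_to_z expects a PriorSpec")
    if mode not in ("exact", "linear"):
        raise ValueError(f"unknown prior_rescale mode {mode!r}")

    fam = prior.family
    p = prior.params
    if fam == "point":
        loc = p["loc"]
        new_loc = math.asinh(loc / 2.0) if mode == "exact" else loc / 2.0
        return PriorSpec("point", {"loc": new_loc})
    if fam == "inverse_gamma":
        return PriorSpec(
            "inverse_gamma", {"shape": p["shape"], "scale": p["scale"] / 2.0}
        )
    if fam in ("normal", "student_t_plus", "cauchy_plus"):
        if mode == "linear":
            q = dict(p)
            q["loc"] = p["loc"] / 2.0
            q["scale"] = p["scale"] / 2.0
            return PriorSpec(fam, q)
        return PriorSpec("transformed_d_to_z", {"base": prior})
    raise ValueError(f"cannot rescale prior family {fam!r} from d to z")


def studies_from_frame(df: pd.DataFrame) -> list[Study]:
    """Build Study objects from rows of the study-level CSV schema."""
    studies = []
    for row in df.itertuples(index=False):
        r = getattr(row, "r", None)
        n = getattr(row, "n", None)
        z = getattr(row, "z", None)
        se = getattr(row, "se_z", None)
        kwargs = {}
        if r is not None and pd.notna(r):
            kwargs["effect_r"] = float(r)
        if n is not None and pd.notna(n):
            kwargs["n"] = int(n)
        if z is not None and pd.notna(z):
            kwargs["effect_z"] = float(z)
        if se is not None and pd.notna(se):
            kwargs["se_z"] = float(se)
        studies.append(Study(**kwargs))
    return studies


def studies_to_frame(
    studies: Sequence[Study], article_id: int = 1, meta_id: int = 1
) -> pd.DataFrame:
    """Serialize studies to the study-level CSV schema (1-based ids)."""
    return pd.DataFrame(
        {
            "article_id": article_id,
            "meta_id": meta_id,
            "study_id": np.arange(1, len(studies) + 1),
            "r": [s.effect_r for s in studies],
            "n": [s.n if s.n is not None else np.nan for s in studies],
            "z": [s.effect_z for s in studies],
            "se_z": [s.se_z for s in studies],
        }
    )
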