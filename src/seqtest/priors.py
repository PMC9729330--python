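"""Effect-size priors for sequential t-test models.

A prior describes the distribution placed on the standardized mean
difference (Cohen's delta) under a hypothesis.  A point prior encodes a
fixed effect size (the SPRT case); continuous families (normal, Cauchy,
scaled t) encode parameter uncertainty (the Bayesian case).  One-sided
models truncate the prior to a half-line and renormalize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

__all__ = ["PriorSpec", "point", "normal", "cauchy", "student_t", "DEFAULT_CAUCHY_SCALE"]

#: Scale of the conventional zero-centered Cauchy default prior, sqrt(2)/2.
DEFAULT_CAUCHY_SCALE = math.sqrt(2.0) / 2.0

_FAMILIES = ("point", "normal", "cauchy", "t")
_TRUNCATIONS = ("none", "positive", "negative")


@dataclass(frozen=True)
class PriorSpec:
    """A (possibly truncated) prior on Cohen's delta.

    Parameters
    ----------
    family
        One of ``point``, ``normal``, ``cauchy``, ``t``.
    location
        Center of the distribution (the fixed value for ``point``).
    scale
        Standard deviation for ``normal``; scale parameter for ``cauchy``
        and ``t``.  Must be 0 for ``point`` and positive otherwise.
    df
        Degrees of freedom, ``t`` family only.
    truncation
        ``none``, ``positive`` (support delta > 0) or ``negative``
        (support delta < 0).  Continuous families are renormalized over
        the truncated support.
    """

    family: str
    location: float = 0.0
    scale: float = 0.0
    df: Optional[float] = None
    truncation: str = "none"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown prior family {self.family!r}; expected one of {_FAMILIES}")
        if self.truncation not in _TRUNCATIONS:
            raise ValueError(f"unknown truncation {self.truncation!r}; expected one of {_TRUNCATIONS}")
        if not np.isfinite(self.location):
            raise ValueError("prior location must be finite")
        if self.family == "point":
            if self.scale != 0.0:
                raise ValueError("point prior requires scale = 0")
            if self.truncation == "positive" and self.location <= 0:
                raise ValueError("point prior has zero mass on the positive half-line")
            if self.truncation == "negative" and self.location >= 0:
                raise ValueError("point prior has zero mass on the negative half-line")
        else:
            if not (self.scale > 0 and np.isfinite(self.scale)):
                raise ValueError(f"{self.family} prior requires a positive finite scale")
        if self.family == "t":
            if self.df is None or not (self.df > 0):
                raise ValueError("t prior requires positive df")
        elif self.df is not None:
            raise ValueError("df is only meaningful for the t family")

    # ------------------------------------------------------------------
    @property
    def is_point(self) -> bool:
        return self.family == "point"

    @property
    def support(self) -> tuple[float, float]:
        """Support interval (lo, hi) after truncation."""
        if self.truncation == "positive":
            return (0.0, math.inf)
        if self.truncation == "negative":
            return (-math.inf, 0.0)
        return (-math.inf, math.inf)

    def _frozen(self):
        if self.family == "normal":
            return stats.norm(self.location, self.scale)
        if self.family == "cauchy":
            return stats.cauchy(self.location, self.scale)
        if self.family == "t":
            return stats.t(self.df, loc=self.location, scale=self.scale)
        raise ValueError("point prior has no density")

    def _log_trunc_mass(self) -> float:
        """Log prior mass of the untruncated family on the truncated support."""
        if self.truncation == "none":
            return 0.0
        dist = self._frozen()
        if self.truncation == "positive":
            mass = dist.sf(0.0)
        else:
            mass = dist.cdf(0.0)
        if mass <= 0.0:
            raise ValueError("prior places zero mass on its truncation region")
        return math.log(mass)

    def logpdf(self, delta) -> np.ndarray:
        """Log density at ``delta``, renormalized over the truncated support."""
        if self.is_point:
            raise ValueError("point prior has no density; handle as a point mass")
        delta = np.asarray(delta, dtype=float)
        out = self._frozen().logpdf(delta) - self._log_trunc_mass()
        lo, hi = self.support
        out = np.where((delta >= lo) & (delta <= hi), out, -np.inf)
        return out

    def mass(self, lo: float, hi: float) -> float:
        """Probability of ``delta in [lo, hi]`` under the truncated prior."""
        if not lo < hi:
            raise ValueError("require lo < hi")
        if self.is_point:
            return float(lo <= self.location <= hi)
        slo, shi = self.support
        lo, hi = max(lo, slo), min(hi, shi)
        if lo >= hi:
            return 0.0
        dist = self._frozen()
        num = dist.cdf(hi) - dist.cdf(lo)
        return float(num / math.exp(self._log_trunc_mass()))

    def ppf(self, q) -> np.ndarray:
        """Quantile function of the truncated prior."""
        if self.is_point:
            return np.full_like(np.asarray(q, dtype=float), self.location)
        dist = self._frozen()
        q = np.asarray(q, dtype=float)
        if self.truncation == "none":
            return dist.ppf(q)
        if self.truncation == "positive":
            c0 = dist.cdf(0.0)
            return dist.ppf(c0 + q * (1.0 - c0))
        c0 = dist.cdf(0.0)
        return dist.ppf(q * c0)


def point(delta: float, truncation: str = "none") -> PriorSpec:
    return PriorSpec("point", location=delta, truncation=truncation)


def normal(location: float, scale: float, truncation: str = "none") -> PriorSpec:
    return PriorSpec("normal", location=location, scale=scale, truncation=truncation)


def cauchy(location: float = 0.0, scale: float = DEFAULT_CAUCHY_SCALE,
           truncation: str = "none") -> PriorSpec:
    return PriorSpec("cauchy", location=location, scale=scale, truncation=truncation)


def student_t(location: float, scale: float, df: float, truncation: str = "none") -> PriorSpec:
    return PriorSpec("t", location=location, scale=scale, df=df, truncation=truncation)
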