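"""Stopping thresholds, the three-way decision rule, and live sequential tests.

A sequential design monitors log evidence against a lower boundary log B
(decide for the null) and an upper boundary log A (decide for the
alternative).  Wald's closed-form thresholds A = (1-beta)/alpha and
B = beta/(1-alpha) bound the effective error rates by roughly 1/A and B
when one of the two models generated the data; arbitrary (possibly
asymmetric) thresholds are permitted, e.g. ones found by simulation-based
optimization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .evidence import TTestSummary, log_bf, log_lr_one_sided, log_lr_two_sided
from .priors import PriorSpec, point

__all__ = [
    "ThresholdPair",
    "HypothesisSpec",
    "DesignSpec",
    "Decision",
    "wald_thresholds",
    "stopping_decision",
    "run_sequential",
]


@dataclass(frozen=True)
class ThresholdPair:
    """Decision boundaries on the natural-log evidence scale."""

    log_lower: float
    log_upper: float

    def __post_init__(self) -> None:
        if not self.log_lower < self.log_upper:
            raise ValueError("require log_lower < log_upper")

    @property
    def lower(self) -> float:
        return math.exp(self.log_lower)

    @property
    def upper(self) -> float:
        return math.exp(self.log_upper)


@dataclass(frozen=True)
class HypothesisSpec:
    """A hypothesis about Cohen's delta, encoded as a prior.

    A point prior encodes the SPRT's fixed effect size; a continuous
    prior encodes the Bayesian alternative.  The conventional sharp null
    is a point prior at delta = 0.
    """

    prior: PriorSpec

    @property
    def is_point(self) -> bool:
        return self.prior.is_point


@dataclass(frozen=True)
class DesignSpec:
    """A full sequential two-sample t-test design.

    Sampling proceeds in balanced fashion: ``n_step`` observations are
    added to each group per step, starting once both groups hold
    ``n_start`` observations, up to ``n_max`` per group.
    """

    test_type: str  # "sprt" | "sbft"
    sided: int  # 1 | 2
    alt: HypothesisSpec
    thresholds: ThresholdPair
    null: HypothesisSpec = field(default_factory=lambda: HypothesisSpec(point(0.0)))
    n_start: int = 2
    n_step: int = 1
    n_max: int = 10_000

    def __post_init__(self) -> None:
        if self.test_type not in ("sprt", "sbft"):
            raise ValueError("test_type must be 'sprt' or 'sbft'")
        if self.sided not in (1, 2):
            raise ValueError("sided must be 1 or 2")
        if self.n_start < 2:
            raise ValueError("n_start must be at least 2 (pooled-variance t)")
        if self.n_step < 1:
            raise ValueError("n_step must be at least 1")
        if self.n_max < self.n_start:
            raise ValueError("n_max must be at least n_start")
        if self.test_type == "sprt":
            if not (self.alt.is_point and self.null.is_point):
                raise ValueError("the SPRT requires point priors on both hypotheses")
        if self.test_type == "sbft" and self.sided == 2 and self.alt.prior.truncation != "none":
            raise ValueError("two-sided SBFT requires an untruncated alternative prior")

    # ------------------------------------------------------------------
    @property
    def n_grid(self) -> np.ndarray:
        """Per-group sample sizes at which evidence is evaluated."""
        return np.arange(self.n_start, self.n_max + 1, self.n_step)

    def log_evidence(self, summary: TTestSummary) -> float:
        """Monitored log evidence (log LR10 or log BF10) for one summary."""
        if self.test_type == "sprt":
            d1 = self.alt.prior.location
            d0 = self.null.prior.location
            if self.sided == 1:
                return log_lr_one_sided(summary, d1, d0)
            return log_lr_two_sided(summary, d1, d0)
        return log_bf(summary, self.alt.prior, self.null.prior, sided=self.sided)


@dataclass(frozen=True)
class Decision:
    """Outcome of one sequential run."""

    outcome: str  # "accept_null" | "accept_alt" | "undecided"
    n_per_group: int
    final_log_evidence: float


def wald_thresholds(alpha: float, beta: float) -> ThresholdPair:
    """Wald's boundaries A = (1-beta)/alpha, B = beta/(1-alpha) in log space.

    ``alpha`` and ``beta`` are the maximum tolerated rates of
    false-positive and false-negative decisions.
    """
    if not (0.0 < alpha < 1.0 and 0.0 < beta < 1.0):
        raise ValueError("alpha and beta must lie strictly between 0 and 1")
    if alpha + beta >= 1.0:
        raise ValueError("require alpha + beta < 1 for ordered thresholds")
    return ThresholdPair(
        log_lower=math.log(beta / (1.0 - alpha)),
        log_upper=math.log((1.0 - beta) / alpha),
    )


def stopping_decision(log_evidence: float, thresholds: ThresholdPair) -> str:
    """Three-way stopping rule with inclusive boundaries.

    Returns ``accept_alt`` if the evidence is at or above the upper
    boundary, ``accept_null`` at or below the lower boundary, and
    ``continue`` in between.
    """
    if log_evidence >= thresholds.log_upper:
        return "accept_alt"
    if log_evidence <= thresholds.log_lower:
        return "accept_null"
    return "continue"


def _pairs(stream) -> Iterator[tuple[float, float]]:
    """Normalize a stream into an iterator of (group1, group2) pairs."""
    if isinstance(stream, tuple) and len(stream) == 2 and not np.isscalar(stream[0]):
        x1, x2 = np.asarray(stream[0], float), np.asarray(stream[1], float)
        return iter(zip(x1, x2))
    return iter((float(a), float(b)) for a, b in stream)


def run_sequential(stream, design: DesignSpec) -> Decision:
    """Run a live sequential test over a balanced two-group stream.

    ``stream`` is either an iterable of ``(group1_value, group2_value)``
    pairs or a tuple of two equal-length arrays.  Groups are filled in
    balanced alternation; the evidence is evaluated each time both groups
    have grown by ``n_step`` beyond ``n_start`` observations, and the
    first inclusive boundary hit terminates the run.  Reaching ``n_max``
    per group without a hit yields an ``undecided`` outcome whose final
    evidence is still interpretable as strength of evidence.
    """
    it = _pairs(stream)
    s1 = s2 = ss1 = ss2 = 0.0
    n = 0
    log_ev = math.nan
    checkpoints = set(design.n_grid.tolist())
    while n < design.n_max:
        try:
            a, b = next(it)
        except StopIteration:
            if n < design.n_start:
                raise ValueError(
                    f"stream exhausted at n={n} per group before n_start={design.n_start}"
                ) from None
            return Decision("undecided", n, log_ev)
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ValueError("non-numeric or non-finite observation in stream")
        n += 1
        s1 += a
        ss1 += a * a
        s2 += b
        ss2 += b * b
        if n not in checkpoints:
            continue
        m1, m2 = s1 / n, s2 / n
        pooled = (ss1 - n * m1 * m1 + ss2 - n * m2 * m2) / (2 * n - 2)
        if pooled <= 0.0:
            raise ValueError(f"zero pooled variance at n={n} per group; t undefined")
        t = (m1 - m2) / math.sqrt(pooled * 2.0 / n)
        log_ev = design.log_evidence(TTestSummary(t, n, n))
        verdict = stopping_decision(log_ev, design.thresholds)
        if verdict != "continue":
            return Decision(verdict, n, log_ev)
    return Decision("undecided", design.n_max, log_ev)
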