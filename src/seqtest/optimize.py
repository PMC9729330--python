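"""Simulation-based stopping-threshold optimization.

Wald's closed-form thresholds bound but generally overcontrol the error
rates of a sequential test (boundary overshoot).  Exact control is
obtained by searching the two-dimensional log-threshold space for the
pair that minimizes expected sample size subject to the target rates.
Because the data-generating models do not depend on the thresholds, the
Monte-Carlo trajectories are drawn once per hypothesis and every
candidate threshold pair merely cuts the cached paths, which makes each
objective evaluation a handful of array comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import differential_evolution

from .simulate import OperatingCharacteristics, TrajectoryBank, _first_crossing, \
    build_bank, operating_characteristics
from .stopping import DesignSpec, ThresholdPair

__all__ = [
    "ErrorTargets",
    "OptimizationResult",
    "DEFAULT_BOUNDS",
    "objective",
    "optimize_thresholds",
    "matched_design_comparison",
]

#: Default search box on (log B, log A); brackets Wald's thresholds for
#: all plausible nominal rates.
DEFAULT_BOUNDS = ((math.log(1e-4), -1e-9), (1e-9, math.log(1e4)))

_INFEASIBLE = 1e12


@dataclass(frozen=True)
class ErrorTargets:
    """Target decision-error rates for threshold optimization.

    ``at_most`` mode penalizes only rates exceeding the targets (exact
    control at minimum sample size); ``match`` mode penalizes deviation
    from the targets in either direction beyond ``tolerance`` (to equate
    two designs on effective error rates).
    """

    alpha_target: float
    beta_target: float
    mode: str = "at_most"
    tolerance: float = 0.002

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_target < 1.0 and 0.0 < self.beta_target < 1.0):
            raise ValueError("targets must lie strictly between 0 and 1")
        if self.mode not in ("at_most", "match"):
            raise ValueError("mode must be 'at_most' or 'match'")
        if self.mode == "match" and not self.tolerance > 0.0:
            raise ValueError("match mode requires a positive tolerance")


@dataclass(frozen=True)
class OptimizationResult:
    thresholds: ThresholdPair
    achieved_null: OperatingCharacteristics
    achieved_alt: OperatingCharacteristics
    objective_value: float
    n_evaluations: int
    converged: bool


def _rates_and_mean_n(bank: TrajectoryBank, thresholds: ThresholdPair):
    outcome, idx = _first_crossing(bank.log_evidence_paths, thresholds)
    stop_n = bank.n_grid[idx]
    return outcome, float(np.mean(stop_n))


def _penalty(alpha_hat: float, beta_hat: float, targets: ErrorTargets) -> float:
    if targets.mode == "at_most":
        return max(0.0, alpha_hat - targets.alpha_target) + max(0.0, beta_hat - targets.beta_target)
    return (max(0.0, abs(alpha_hat - targets.alpha_target) - targets.tolerance)
            + max(0.0, abs(beta_hat - targets.beta_target) - targets.tolerance))


def objective(thresholds: ThresholdPair | tuple[float, float], bank_null: TrajectoryBank,
              bank_alt: TrajectoryBank, targets: ErrorTargets,
              penalty_weight: float | None = None, null_weight: float = 0.5) -> float:
    """Penalized expected-sample-size objective on cached trajectories.

    ``null_weight * mean_n(null) + (1 - null_weight) * mean_n(alt)`` plus
    ``penalty_weight`` times the error-rate penalty.  The false-positive
    rate is the upper-boundary crossing rate under the null bank, the
    false-negative rate the lower-boundary crossing rate under the
    alternative bank.  An unordered threshold pair returns a large finite
    value so that stochastic optimizers can recover.
    """
    if isinstance(thresholds, ThresholdPair):
        log_b, log_a = thresholds.log_lower, thresholds.log_upper
    else:
        log_b, log_a = thresholds
    if not log_b < log_a:
        return _INFEASIBLE
    pair = ThresholdPair(log_b, log_a)
    if penalty_weight is None:
        penalty_weight = 1e6 * max(bank_null.n_grid[-1], bank_alt.n_grid[-1])
    out0, mean_n0 = _rates_and_mean_n(bank_null, pair)
    out1, mean_n1 = _rates_and_mean_n(bank_alt, pair)
    alpha_hat = float(np.mean(out0 == 1))
    beta_hat = float(np.mean(out1 == 0))
    size_term = null_weight * mean_n0 + (1.0 - null_weight) * mean_n1
    return size_term + penalty_weight * _penalty(alpha_hat, beta_hat, targets)


def optimize_thresholds(bank_null: TrajectoryBank, bank_alt: TrajectoryBank,
                        targets: ErrorTargets, seed: int = 0,
                        bounds=DEFAULT_BOUNDS, penalty_weight: float | None = None,
                        null_weight: float = 0.5, popsize: int = 20,
                        maxiter: int = 120, tol: float = 1e-4) -> OptimizationResult:
    """Differential-evolution search for minimal-sample-size thresholds.

    Any derivative-free global optimizer over the (log B, log A) box would
    do; differential evolution is robust to the objective's piecewise
    constancy (rates only change when a threshold passes a path value).
    Reproducible for a fixed ``seed``.
    """
    n_eval = 0

    def fun(x):
        nonlocal n_eval
        n_eval += 1
        return objective((x[0], x[1]), bank_null, bank_alt, targets,
                         penalty_weight=penalty_weight, null_weight=null_weight)

    res = differential_evolution(fun, bounds=bounds, seed=seed, popsize=popsize,
                                 maxiter=maxiter, tol=tol, polish=False, init="sobol")
    pair = ThresholdPair(float(res.x[0]), float(res.x[1]))
    oc_null = operating_characteristics(bank_null, pair)
    oc_alt = operating_characteristics(bank_alt, pair)
    feasible = _penalty(oc_null.rate_accept_alt, oc_alt.rate_accept_null, targets) == 0.0
    return OptimizationResult(
        thresholds=pair,
        achieved_null=oc_null,
        achieved_alt=oc_alt,
        objective_value=float(res.fun),
        n_evaluations=n_eval,
        converged=bool(feasible),
    )


def matched_design_comparison(design_a: DesignSpec, design_b: DesignSpec,
                              delta_true_alt: float, n_replicates: int, seed: int,
                              tolerance: float = 0.002, quad_order: int = 16,
                              **opt_kwargs):
    """Compare two designs after equating their effective error rates.

    Design A keeps its own thresholds; its Monte-Carlo error rates under
    the null (delta_true = 0) and the alternative (``delta_true_alt``)
    become the match targets for design B, whose thresholds are then
    optimized.  Returns a dict with both designs' operating
    characteristics, design B's optimized thresholds, and the
    optimization result.
    """
    ss = np.random.SeedSequence(seed)
    s_a0, s_a1, s_b0, s_b1, s_opt = ss.spawn(5)
    bank_a0 = build_bank(design_a, 0.0, n_replicates, s_a0, quad_order=quad_order)
    bank_a1 = build_bank(design_a, delta_true_alt, n_replicates, s_a1, quad_order=quad_order)
    oc_a0 = operating_characteristics(bank_a0, design_a.thresholds)
    oc_a1 = operating_characteristics(bank_a1, design_a.thresholds)

    targets = ErrorTargets(
        alpha_target=max(oc_a0.rate_accept_alt, 1e-6),
        beta_target=max(oc_a1.rate_accept_null, 1e-6),
        mode="match",
        tolerance=tolerance,
    )
    bank_b0 = build_bank(design_b, 0.0, n_replicates, s_b0, quad_order=quad_order)
    bank_b1 = build_bank(design_b, delta_true_alt, n_replicates, s_b1, quad_order=quad_order)
    opt = optimize_thresholds(bank_b0, bank_b1, targets,
                              seed=int(s_opt.generate_state(1)[0] % (2**31)), **opt_kwargs)
    return {
        "design_a": {"null": oc_a0, "alt": oc_a1, "thresholds": design_a.thresholds},
        "design_b": {"null": opt.achieved_null, "alt": opt.achieved_alt,
                     "thresholds": opt.thresholds},
        "targets": targets,
        "optimization": opt,
    }
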