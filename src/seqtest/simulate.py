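"""Monte-Carlo operating characteristics of sequential t-test designs.

Replicate two-group normal data streams are generated under a stated true
effect size; the cumulative log-evidence path of each replicate is either
stored in full (a :class:`TrajectoryBank`, reusable across any stopping
thresholds, which is what makes threshold optimization cheap) or followed
only until it first leaves the continuation region (the early-stopping
fast path of :func:`simulate_design`).  Both routes evaluate the exact
same per-step evidence values and therefore agree bit-for-bit for equal
seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evidence import _log_kernel, _log_marginal_grid
from .stopping import DesignSpec, ThresholdPair

__all__ = [
    "TrajectoryBank",
    "OperatingCharacteristics",
    "generate_stream",
    "build_bank",
    "operating_characteristics",
    "simulate_design",
    "misspecification_profile",
]

_QUANTILES = (0.25, 0.5, 0.75, 0.9)


def _seedseq(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


@dataclass(frozen=True)
class TrajectoryBank:
    """Cached cumulative log-evidence paths under one data-generating delta.

    Row r of ``log_evidence_paths`` is the log evidence of replicate r
    evaluated at every per-group size in ``n_grid``.  Banks are immutable
    once built and independent of any stopping thresholds.
    """

    delta_true: float
    n_grid: np.ndarray
    log_evidence_paths: np.ndarray
    seed: int
    n_replicates: int
    n_regenerated: int = 0

    def __post_init__(self) -> None:
        self.n_grid.setflags(write=False)
        self.log_evidence_paths.setflags(write=False)
        if not np.all(np.isfinite(self.log_evidence_paths)):
            raise ValueError("bank paths must be finite at every stored n")


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Decision rates and sample-size summary of a design under one truth.

    Rates sum to one; undecided-at-cap runs are reported separately and
    never folded into the accept/reject rates.  ``mc_se_rates`` is the
    largest binomial Monte-Carlo standard error among the three rates.
    """

    rate_accept_alt: float
    rate_accept_null: float
    rate_undecided: float
    mean_n: float
    se_mean_n: float
    median_n: float
    n_quantiles: dict
    n_replicates: int
    mc_se_rates: float

    def rate_se(self, rate: float) -> float:
        """Binomial MC standard error sqrt(p(1-p)/R) of a decision rate."""
        return math.sqrt(rate * (1.0 - rate) / self.n_replicates)


# ----------------------------------------------------------------------
# data generation
# ----------------------------------------------------------------------

def generate_stream(delta_true: float, n_max: int, rng_state) -> tuple[np.ndarray, np.ndarray]:
    """One replicate stream: group 1 ~ N(delta_true, 1), group 2 ~ N(0, 1).

    ``rng_state`` may be an integer seed, a ``SeedSequence`` or a
    ``Generator``; equal states yield identical streams.
    """
    if n_max < 2:
        raise ValueError("n_max must be at least 2")
    rng = rng_state if isinstance(rng_state, np.random.Generator) else np.random.default_rng(rng_state)
    x1 = rng.normal(delta_true, 1.0, n_max)
    x2 = rng.normal(0.0, 1.0, n_max)
    return x1, x2


def _t_statistics(x1: np.ndarray, x2: np.ndarray, n_grid: np.ndarray) -> np.ndarray:
    """Pooled-variance t at every n in ``n_grid``, vectorized over replicates.

    ``x1``/``x2`` have shape (R, n_max); raises on zero pooled variance.
    """
    ns = n_grid.astype(float)
    c1 = np.cumsum(x1, axis=1)[:, n_grid - 1]
    c2 = np.cumsum(x2, axis=1)[:, n_grid - 1]
    q1 = np.cumsum(x1 * x1, axis=1)[:, n_grid - 1]
    q2 = np.cumsum(x2 * x2, axis=1)[:, n_grid - 1]
    m1, m2 = c1 / ns, c2 / ns
    pooled = (q1 - ns * m1 * m1 + q2 - ns * m2 * m2) / (2.0 * ns - 2.0)
    if np.any(pooled <= 0.0):
        raise FloatingPointError("zero pooled variance")
    return (m1 - m2) / np.sqrt(pooled * 2.0 / ns)


def _draw_t_chunk(delta_true: float, n_grid: np.ndarray, n_max: int,
                  children: list) -> tuple[np.ndarray, int]:
    """t-statistic matrix for one chunk of replicates; regenerates the rare
    degenerate (zero pooled variance) replicate from fresh child entropy."""
    R = len(children)
    x1 = np.empty((R, n_max))
    x2 = np.empty((R, n_max))
    for i, child in enumerate(children):
        x1[i], x2[i] = generate_stream(delta_true, n_max, child)
    regenerated = 0
    while True:
        try:
            return _t_statistics(x1, x2, n_grid), regenerated
        except FloatingPointError:
            # find offending rows and redraw them
            ns = n_grid.astype(float)
            for i in range(R):
                q = (np.cumsum(x1[i] * x1[i])[n_grid - 1]
                     - ns * (np.cumsum(x1[i])[n_grid - 1] / ns) ** 2
                     + np.cumsum(x2[i] * x2[i])[n_grid - 1]
                     - ns * (np.cumsum(x2[i])[n_grid - 1] / ns) ** 2)
                if np.any(q <= 0.0):
                    children[i] = children[i].spawn(1)[0] if hasattr(children[i], "spawn") \
                        else np.random.SeedSequence().spawn(1)[0]
                    x1[i], x2[i] = generate_stream(delta_true, n_max, children[i])
                    regenerated += 1


# ----------------------------------------------------------------------
# evidence paths
# ----------------------------------------------------------------------

def _evidence_columns(design: DesignSpec, t_cols: np.ndarray, n_values: np.ndarray,
                      quad_order: int) -> np.ndarray:
    """Log evidence for a block of t-statistic columns.

    ``t_cols`` has shape (R, B) with per-group sizes ``n_values`` (B,).
    """
    nu = 2.0 * n_values - 2.0
    c = np.sqrt(n_values / 2.0)
    if design.test_type == "sprt":
        d1 = design.alt.prior.location
        d0 = design.null.prior.location
        num = _log_kernel(t_cols, nu[None, :], c[None, :] * d1, design.sided)
        den = _log_kernel(t_cols, nu[None, :], c[None, :] * d0, design.sided)
        return num - den
    out = np.empty_like(t_cols)
    for j in range(t_cols.shape[1]):
        num = _log_marginal_grid(t_cols[:, j], nu[j], c[j], design.alt.prior,
                                 design.sided, order=quad_order)
        den = _log_marginal_grid(t_cols[:, j], nu[j], c[j], design.null.prior,
                                 design.sided, order=quad_order)
        out[:, j] = num - den
    return out


def build_bank(design: DesignSpec, delta_true: float, n_replicates: int, seed: int,
               chunk_size: int = 512, quad_order: int = 16) -> TrajectoryBank:
    """Full log-evidence paths for ``n_replicates`` independent streams.

    The design's thresholds are ignored: a bank caches paths over the
    whole ``n_grid`` so that any thresholds can later be applied by
    simply cutting the trajectories.  One master seed spawns independent
    per-replicate substreams, so equal seeds give identical banks.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    n_grid = design.n_grid
    children = _seedseq(seed).spawn(n_replicates)
    paths = np.empty((n_replicates, n_grid.size))
    regenerated = 0
    for lo in range(0, n_replicates, chunk_size):
        hi = min(lo + chunk_size, n_replicates)
        t_mat, reg = _draw_t_chunk(delta_true, n_grid, design.n_max, children[lo:hi])
        regenerated += reg
        paths[lo:hi] = _evidence_columns(design, t_mat, n_grid, quad_order)
    return TrajectoryBank(
        delta_true=delta_true,
        n_grid=n_grid,
        log_evidence_paths=paths,
        seed=seed,
        n_replicates=n_replicates,
        n_regenerated=regenerated,
    )


# ----------------------------------------------------------------------
# operating characteristics
# ----------------------------------------------------------------------

def _first_crossing(paths: np.ndarray, thresholds: ThresholdPair) -> tuple[np.ndarray, np.ndarray]:
    """Outcome code (0 null, 1 alt, 2 undecided) and grid index at stopping."""
    up = paths >= thresholds.log_upper
    dn = paths <= thresholds.log_lower
    crossed = up | dn
    any_cross = crossed.any(axis=1)
    first = np.argmax(crossed, axis=1)
    outcome = np.where(any_cross, np.where(up[np.arange(paths.shape[0]), first], 1, 0), 2)
    idx = np.where(any_cross, first, paths.shape[1] - 1)
    return outcome, idx


def _summarize(outcome: np.ndarray, stop_n: np.ndarray) -> OperatingCharacteristics:
    R = outcome.size
    p_alt = float(np.mean(outcome == 1))
    p_null = float(np.mean(outcome == 0))
    p_und = float(np.mean(outcome == 2))
    ses = [math.sqrt(p * (1 - p) / R) for p in (p_alt, p_null, p_und)]
    return OperatingCharacteristics(
        rate_accept_alt=p_alt,
        rate_accept_null=p_null,
        rate_undecided=p_und,
        mean_n=float(np.mean(stop_n)),
        se_mean_n=float(np.std(stop_n, ddof=1) / math.sqrt(R)) if R > 1 else float("nan"),
        median_n=float(np.median(stop_n)),
        n_quantiles={q: float(np.quantile(stop_n, q)) for q in _QUANTILES},
        n_replicates=R,
        mc_se_rates=max(ses),
    )


def operating_characteristics(bank: TrajectoryBank,
                              thresholds: ThresholdPair) -> OperatingCharacteristics:
    """Cut a bank's cached trajectories at the given thresholds.

    Each path stops at its first inclusive boundary exit; paths that
    never leave the continuation region count as undecided at the cap.
    """
    outcome, idx = _first_crossing(bank.log_evidence_paths, thresholds)
    return _summarize(outcome, bank.n_grid[idx])


def simulate_design(design: DesignSpec, delta_true: float, n_replicates: int, seed: int,
                    chunk_size: int = 2048, quad_order: int = 16,
                    block: int = 32) -> OperatingCharacteristics:
    """Operating characteristics by direct simulation with early stopping.

    Equivalent to ``operating_characteristics(build_bank(...), design.thresholds)``
    for the same seed, but stops evaluating a replicate's evidence once it
    has crossed a boundary, which is much cheaper when stopping times are
    far below ``n_max``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be positive")
    n_grid = design.n_grid
    children = _seedseq(seed).spawn(n_replicates)
    outcome = np.empty(n_replicates, dtype=int)
    stop_n = np.empty(n_replicates, dtype=int)
    for lo in range(0, n_replicates, chunk_size):
        hi = min(lo + chunk_size, n_replicates)
        t_mat, _ = _draw_t_chunk(delta_true, n_grid, design.n_max, children[lo:hi])
        out = np.full(hi - lo, 2, dtype=int)
        sn = np.full(hi - lo, n_grid[-1], dtype=int)
        active = np.arange(hi - lo)
        for j0 in range(0, n_grid.size, block):
            j1 = min(j0 + block, n_grid.size)
            ev = _evidence_columns(design, t_mat[active][:, j0:j1], n_grid[j0:j1], quad_order)
            oc, idx = _first_crossing(ev, design.thresholds)
            hit = oc != 2
            rows = active[hit]
            out[rows] = oc[hit]
            sn[rows] = n_grid[j0:j1][idx[hit]]
            active = active[~hit]
            if active.size == 0:
                break
        outcome[lo:hi] = out
        stop_n[lo:hi] = sn
    return _summarize(outcome, stop_n)


def misspecification_profile(design: DesignSpec, delta_true_grid, n_replicates: int,
                             seed: int, **kwargs) -> pd.DataFrame:
    """Operating characteristics of one fixed design over a grid of truths.

    One row per data-generating effect size; the design (models and
    thresholds) is held constant, so rows with ``delta_true`` away from
    the hypothesized values show the design's misspecification behavior.
    """
    delta_true_grid = list(delta_true_grid)
    if not delta_true_grid:
        raise ValueError("delta_true_grid must be nonempty")
    children = _seedseq(seed).spawn(len(delta_true_grid))
    rows = []
    for d, child in zip(delta_true_grid, children):
        oc = simulate_design(design, d, n_replicates, child, **kwargs)
        rows.append({
            "delta_true": d,
            "rate_accept_alt": oc.rate_accept_alt,
            "rate_accept_null": oc.rate_accept_null,
            "rate_undecided": oc.rate_undecided,
            "mean_n": oc.mean_n,
            "se_mean_n": oc.se_mean_n,
            "median_n": oc.median_n,
            "n_replicates": oc.n_replicates,
            "mc_se_rates": oc.mc_se_rates,
        })
    return pd.DataFrame(rows)
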