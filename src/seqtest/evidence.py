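"""Log evidence for sequential two-sample t-tests.

The monitored quantity of a sequential t-test is either a likelihood
ratio between two point-hypothesis models (the SPRT case) or a Bayes
factor in which the alternative carries a prior on Cohen's delta (the
sequential-Bayes-factor case).  Both are functions of the pooled-variance
t-statistic alone: the likelihood of ``t`` under effect size ``delta`` is
a noncentral t-density with ``nu = n1 + n2 - 2`` degrees of freedom and
noncentrality ``Delta = delta * sqrt(n1*n2/(n1+n2))``.  Two-sided models
work on the squared statistic, i.e. on the noncentral-F density of
``t**2``, which equals the sign-symmetrized noncentral-t density up to a
Jacobian that cancels in every ratio.

Everything is computed and returned in natural-log space so that the
extreme evidence values reached at large n never underflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .priors import PriorSpec

__all__ = [
    "TTestSummary",
    "QuadratureError",
    "noncentrality",
    "log_lr_one_sided",
    "log_lr_two_sided",
    "log_bf",
    "prior_mass",
]


class QuadratureError(RuntimeError):
    """Raised when the marginal-likelihood quadrature fails to converge."""


@dataclass(frozen=True)
class TTestSummary:
    """A two-sample pooled-variance t-statistic with its group sizes."""

    t: float
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if not (self.n1 >= 2 and self.n2 >= 2):
            raise ValueError("need n1 >= 2 and n2 >= 2 for a pooled-variance t")
        if not np.isfinite(self.t):
            raise ValueError("t-statistic must be finite")

    @property
    def nu(self) -> int:
        """Degrees of freedom, n1 + n2 - 2."""
        return self.n1 + self.n2 - 2

    @property
    def ncp_scale(self) -> float:
        """Effect-size-to-noncentrality factor sqrt(n1*n2/(n1+n2))."""
        return math.sqrt(self.n1 * self.n2 / (self.n1 + self.n2))


def noncentrality(delta: float, n1: int, n2: int) -> float:
    """Noncentrality parameter Delta = delta * sqrt(n1*n2/(n1+n2))."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    return delta * math.sqrt(n1 * n2 / (n1 + n2))


# ----------------------------------------------------------------------
# log noncentral-t kernels
# ----------------------------------------------------------------------

_NCT_NODES = 32


def _nct_gl_nodes():
    # cached Gauss-Legendre rule for the scale-mixture integral
    global _NCT_XW
    try:
        return _NCT_XW
    except NameError:
        _NCT_XW = np.polynomial.legendre.leggauss(_NCT_NODES)
        return _NCT_XW


def _log_nct(t, nu, ncp):
    """Vectorized log noncentral-t density, stable for any noncentrality.

    Writes the density as the scale mixture
    ``f(t) = C(nu) * int_0^inf u**nu * phi(t*u - ncp) * exp(-nu*u**2/2) du``
    (with ``u = sqrt(V/nu)``, ``V ~ chi2(nu)``) and integrates the smooth,
    unimodal log-concave integrand by Gauss-Legendre centered on its
    analytic mode.  Evaluated entirely in log space, so it neither
    underflows nor overflows for the extreme noncentralities reached by
    quadrature nodes far from the likelihood peak, where library
    implementations of the closed form break down.
    """
    t = np.asarray(t, dtype=float)
    ncp = np.asarray(ncp, dtype=float)
    if ncp.ndim == 0 and float(ncp) == 0.0:
        return stats.t.logpdf(t, nu)
    t_b, ncp_b, nu_b = np.broadcast_arrays(t, ncp, np.asarray(nu, dtype=float))
    shape = t_b.shape
    tf = t_b.reshape(-1)
    df = ncp_b.reshape(-1)
    nf = nu_b.reshape(-1)
    out = np.empty(tf.size)
    step = 1 << 18  # bound the (chunk x nodes) temporaries
    for lo_i in range(0, tf.size, step):
        sl = slice(lo_i, min(lo_i + step, tf.size))
        out[sl] = _log_nct_flat(tf[sl], nf[sl], df[sl])
    return out.reshape(shape) if shape else float(out[0])


def _log_nct_flat(t: np.ndarray, nu: np.ndarray, ncp: np.ndarray) -> np.ndarray:
    # mode of the log-integrand solves (t^2+nu) u^2 - t*ncp*u - nu = 0
    a = t * t + nu
    u_hat = (t * ncp + np.sqrt(t * t * ncp * ncp + 4.0 * nu * a)) / (2.0 * a)
    s = 1.0 / np.sqrt(nu / (u_hat * u_hat) + a)
    lo = np.maximum(u_hat - 9.0 * s, 0.0)
    half = 0.5 * (u_hat + 9.0 * s - lo)
    x, w = _nct_gl_nodes()
    u = (lo + half)[:, None] + half[:, None] * x  # (R, K)
    with np.errstate(divide="ignore"):
        z = t[:, None] * u
        z -= ncp[:, None]
        li = np.log(u)
        li *= nu[:, None]
        li -= 0.5 * z * z
        li -= (0.5 * nu)[:, None] * (u * u)
        peak = li.max(axis=1)  # exact integrand max lies inside the panel
        li -= peak[:, None]
    np.exp(li, out=li)
    core = peak + np.log(li @ w) + np.log(half)
    log_c = (math.log(2.0) + 0.5 * nu * np.log(nu) - 0.5 * nu * math.log(2.0)
             - gammaln(0.5 * nu) - 0.5 * math.log(2.0 * math.pi))
    return log_c + core


def _log_kernel(t, nu, ncp, sided: int):
    """Log likelihood of the observed statistic at noncentrality ``ncp``.

    ``sided=1`` uses the signed t-statistic; ``sided=2`` uses the
    sign-symmetrized density, equivalent to the noncentral-F density of
    ``t**2`` up to a Jacobian that is constant across models.
    """
    if sided == 1:
        return _log_nct(t, nu, ncp)
    if sided == 2:
        a = _log_nct(t, nu, ncp)
        b = _log_nct(np.negative(t), nu, ncp)
        return np.logaddexp(a, b) - math.log(2.0)
    raise ValueError("sided must be 1 or 2")


# ----------------------------------------------------------------------
# likelihood ratios (point hypotheses)
# ----------------------------------------------------------------------

def log_lr_one_sided(summary: TTestSummary, delta1: float, delta0: float = 0.0) -> float:
    """Log likelihood ratio of the one-sided SPRT t-test.

    Ratio of noncentral-t densities at the observed ``t`` with
    noncentralities mapped from ``delta1`` (numerator) and ``delta0``
    (denominator).
    """
    nu = summary.nu
    c = summary.ncp_scale
    if delta1 == delta0:
        return 0.0
    num = _log_nct(summary.t, nu, c * delta1)
    den = _log_nct(summary.t, nu, c * delta0)
    return float(num - den)


def log_lr_two_sided(summary: TTestSummary, delta1: float, delta0: float = 0.0) -> float:
    """Log likelihood ratio of the two-sided SPRT t-test.

    Equals ``log f(t**2 | 1, nu, Delta1**2) - log f(t**2 | 1, nu, Delta0**2)``
    for the (non)central-F densities; evaluated through the symmetrized
    noncentral-t form, which shares that value exactly and stays finite
    at ``t = 0`` where both F log-densities diverge.
    """
    nu = summary.nu
    c = summary.ncp_scale
    if abs(delta1) == abs(delta0):
        return 0.0
    num = _log_kernel(summary.t, nu, c * delta1, sided=2)
    den = _log_kernel(summary.t, nu, c * delta0, sided=2)
    out = float(num - den)
    if np.isnan(out):
        raise FloatingPointError("two-sided log likelihood ratio is indeterminate")
    return out


# ----------------------------------------------------------------------
# marginal likelihoods (Bayes factors)
# ----------------------------------------------------------------------

_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _gl_nodes(order: int) -> tuple[np.ndarray, np.ndarray]:
    if order not in _GL_CACHE:
        _GL_CACHE[order] = np.polynomial.legendre.leggauss(order)
    return _GL_CACHE[order]


def _prior_breakpoints(prior: PriorSpec) -> np.ndarray:
    """Panel boundaries resolving the prior's own mass."""
    if prior.family == "normal":
        mult = np.array([-12.0, -4.0, -1.0, 0.0, 1.0, 4.0, 12.0])
    else:  # cauchy / t: heavy tails need a wider hull
        mult = np.array([-48.0, -12.0, -4.0, -1.0, 0.0, 1.0, 4.0, 12.0, 48.0])
    return prior.location + mult * prior.scale


def _likelihood_breakpoints(t: np.ndarray, nu: float, c: float, sided: int) -> np.ndarray:
    """Panel boundaries resolving the likelihood peak(s), shape (R, K)."""
    delta_hat = t / c
    # spread of the noncentral-t density in Delta units, mapped to delta
    width = np.sqrt(1.0 + t * t / (2.0 * nu)) / c
    offs = np.array([-12.0, -4.0, 0.0, 4.0, 12.0])
    bps = delta_hat[:, None] + width[:, None] * offs[None, :]
    if sided == 2:
        bps = np.concatenate([bps, -bps], axis=1)
    return bps


def _log_marginal_grid(t, nu: float, c: float, prior: PriorSpec, sided: int,
                       order: int = 16) -> np.ndarray:
    """Log marginal likelihood of the statistic(s) ``t`` under ``prior``.

    Composite Gauss-Legendre quadrature over panels that jointly resolve
    the prior mass and the likelihood peak(s); vectorized over ``t`` at a
    common (nu, c).  Point priors reduce to a single kernel evaluation.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if prior.is_point:
        return _log_kernel(t, nu, c * prior.location, sided)

    lo, hi = prior.support
    bp_prior = np.broadcast_to(_prior_breakpoints(prior), (t.size, _prior_breakpoints(prior).size))
    bp_lik = _likelihood_breakpoints(t, nu, c, sided)
    bps = np.sort(np.clip(np.concatenate([bp_prior, bp_lik], axis=1), lo, hi), axis=1)

    x, w = _gl_nodes(order)
    a = bps[:, :-1]
    half = 0.5 * (bps[:, 1:] - a)  # (R, P)
    mid = a + half
    nodes = mid[:, :, None] + half[:, :, None] * x[None, None, :]  # (R, P, m)
    with np.errstate(divide="ignore"):
        logw = np.where(half > 0, np.log(np.maximum(half, 1e-300)), -np.inf)
    logw = logw[:, :, None] + np.log(w)[None, None, :]

    shape = nodes.shape
    flat = nodes.reshape(t.size, -1)
    logf = _log_kernel(t[:, None], nu, c * flat, sided) + prior.logpdf(flat)
    logf = logf.reshape(shape)
    return logsumexp(np.where(np.isfinite(logw), logf + logw, -np.inf), axis=(1, 2))


def log_marginal(t: float, nu: float, c: float, prior: PriorSpec, sided: int,
                 tol: float = 1e-6, max_order: int = 256) -> float:
    """Adaptive-order log marginal likelihood for a single statistic.

    Doubles the per-panel quadrature order until two successive
    refinements agree to ``tol`` on the log scale.
    """
    if prior.is_point:
        return float(_log_kernel(np.asarray([t]), nu, c * prior.location, sided)[0])
    prev = None
    order = 16
    while order <= max_order:
        cur = float(_log_marginal_grid(np.asarray([t]), nu, c, prior, sided, order=order)[0])
        if prev is not None and abs(cur - prev) < tol:
            return cur
        prev = cur
        order *= 2
    raise QuadratureError(
        f"marginal-likelihood quadrature did not reach log-tolerance {tol:g} "
        f"by order {max_order}"
    )


def log_bf(summary: TTestSummary, alt_prior: PriorSpec,
           null_prior: PriorSpec | None = None, sided: int = 1,
           tol: float = 1e-6) -> float:
    """Log Bayes factor BF10 for the sequential t-test.

    The numerator is the marginal likelihood of the observed statistic
    under ``alt_prior``; the denominator under ``null_prior`` (default: a
    point mass at delta = 0, the conventional sharp null).  ``sided=1``
    evaluates the signed-t likelihood (use a positively truncated
    alternative prior for a directional test); ``sided=2`` evaluates the
    squared-statistic likelihood and requires an untruncated alternative
    prior.
    """
    from .priors import point as _point

    if null_prior is None:
        null_prior = _point(0.0)
    if sided == 2 and alt_prior.truncation != "none":
        raise ValueError("two-sided Bayes factor requires an untruncated alternative prior")
    nu = summary.nu
    c = summary.ncp_scale
    num = log_marginal(summary.t, nu, c, alt_prior, sided, tol=tol)
    den = log_marginal(summary.t, nu, c, null_prior, sided, tol=tol)
    return float(num - den)


def prior_mass(prior: PriorSpec, lo: float, hi: float) -> float:
    """Probability that delta lies in [lo, hi] under the truncated prior."""
    return prior.mass(lo, hi)
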