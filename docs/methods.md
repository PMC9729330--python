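# Methods

This note records the statistical and numerical choices behind `seqtest`,
in enough detail to re-derive every quantity the package computes.

## Setting

Two-group comparison with balanced sampling: observations arrive in pairs
(one per group), each group i.i.d. Normal(μ_g, σ²) with common unknown
variance.  The effect size is Cohen's δ = (μ₁ − μ₂)/σ.  After n
observations per group the pooled-variance two-sample t-statistic `t_n` is
sufficient for δ, with ν = 2n − 2 degrees of freedom and noncentrality
Δ = δ·√(n²/2n) = δ·√(n/2) (general form Δ = δ·√(n₁n₂/(n₁+n₂))).

Both sequential tests monitor a ratio of marginal likelihoods of the
observed t-statistic and stop the first time the monitored evidence
leaves the interval (B, A), deciding for the alternative at or above A
and for the null at or below B (inclusive boundaries).  Reaching the
sample-size cap `n_max` without a boundary hit is reported as a third
outcome, `undecided`, never folded into the decision rates.

## Evidence

**SPRT.** Two point hypotheses δ₀, δ₁.  The monitored quantity is the
likelihood ratio of noncentral-t densities,

    LR_n = f(t_n; ν, Δ₁) / f(t_n; ν, Δ₀),

computed in log space.  The two-sided SPRT replaces the signed statistic
by its square, i.e. uses noncentral-F densities of t² with 1 and ν
degrees of freedom.  The implementation evaluates the mathematically
identical sign-symmetrized noncentral-t form
½[f(t; ν, Δ) + f(−t; ν, Δ)] — the Jacobian of t ↦ t² cancels in the
ratio — which stays finite at t = 0 where both F log-densities diverge.

**SBFT.** The alternative hypothesis carries a prior π(δ) (default:
zero-centered Cauchy with scale √2/2); the monitored quantity is the
Bayes factor

    BF_n = ∫ f(t_n; ν, δ·c_n) π(δ) dδ / f(t_n; ν, 0),

against the sharp null (an arbitrary point or continuous null prior is
allowed).  One-sided (directional) alternatives use a half-line-truncated,
renormalized prior with the signed-t kernel; two-sided alternatives use an
untruncated prior with the symmetrized (squared-statistic) kernel.

As the alternative prior's scale shrinks to zero around δ₁ the Bayes
factor converges to the SPRT likelihood ratio; the package treats the two
tests as one family distinguished only by the prior.

## Numerics

**Log noncentral-t density.** Library closed-form implementations of the
noncentral-t density overflow or silently underflow at the extreme
noncentralities reached by quadrature nodes far from the likelihood peak
(e.g. ν in the thousands, |Δ| in the hundreds).  The package therefore
evaluates the scale-mixture representation

    f(t; ν, Δ) = C(ν) ∫₀^∞ u^ν φ(tu − Δ) exp(−νu²/2) du,
    C(ν) = 2 (ν/2)^{ν/2} / (Γ(ν/2) √(2π)),

whose integrand is smooth, unimodal and log-concave in u.  Its mode û
solves a quadratic, (t²+ν)u² − tΔu − ν = 0, and a Laplace scale s at û
bounds the mass; 32-node Gauss–Legendre quadrature on [max(û−9s, 0),
û+9s], evaluated in log space with max-subtraction, reproduces reference
values to ~1e-7 across the usable range and stays finite everywhere.
Against the library implementation, agreement is ≤1e-6 wherever the
library returns a representable value.

**Marginal likelihoods.** ∫ f(t; ν, δ·c) π(δ) dδ is computed by composite
Gauss–Legendre quadrature over panels whose boundaries jointly resolve
the prior (location ± {1, 4, 12}·scale, plus ±48·scale for heavy-tailed
families) and the likelihood peak δ̂ = t/c ± {4, 12}·w with width
w = √(1 + t²/2ν)/c (mirrored for two-sided kernels), clipped to the
truncated support.  Order 16 per panel agrees with an adaptive
order-doubling reference (tolerance 1e-9) to better than 5e-8 across
priors, sample sizes 2–5000 and |t| ≤ 12; the adaptive version backs the
scalar public API and raises if 1e-6 log-tolerance is not reached by
order 256.

**Simulation.** Replicate streams draw all `n_max` observations per group
from per-replicate `SeedSequence` substreams spawned from one master
seed; t-statistics at every monitored n come from cumulative sums.  A
`TrajectoryBank` stores the full log-evidence path of every replicate so
that any threshold pair can later be applied by cutting cached paths —
this makes threshold optimization cheap and exactly consistent with
direct simulation (same seeds ⇒ bit-identical evidence).  The
early-stopping path (`simulate_design`) evaluates evidence in blocks of
sample sizes and drops replicates once they cross a boundary.  The rare
degenerate replicate (zero pooled variance at some monitored n, possible
only for pathological draws) is redrawn from fresh spawned entropy and
counted in `n_regenerated`.

Monte-Carlo standard errors: binomial √(p̂(1−p̂)/R) for decision rates;
sample-SD/√R for mean stopping n.

## Error control

Wald's thresholds A = (1−β)/α, B = β/(1−α) guarantee α′ ≤ 1/A and
β′ ≤ B for the simple-vs-simple SPRT; discrete monitoring overshoots the
boundaries, so realized rates fall below nominal ones and increasingly so
for large effects (more evidence accrues between checks).  Exact control
is obtained by simulation-based threshold search: minimize
w·E[n | null] + (1−w)·E[n | alt] (w = ½ by default) plus a penalty
λ·(rate excesses) with λ = 10⁶·n_max, over the box
log B ∈ [log 10⁻⁴, 0), log A ∈ (0, log 10⁴], using differential
evolution on cached banks.  `at_most` mode penalizes only exceedances
(exact control); `match` mode penalizes deviations beyond a tolerance
(default 0.002) from target rates, e.g. to equate two designs' effective
error rates before comparing their sample sizes.

## Known behaviors worth noting

* Effective error rates of Wald-threshold designs depend visibly on the
  first monitored sample size (`n_start`): the later monitoring starts,
  the more evidence the first check already carries and the larger the
  overshoot-driven overcontrol.  The package default is `n_start = 2`
  (the earliest n at which a pooled-variance t exists).
* Evidence streams for the same seed but different `n_max` differ: the
  second group's draws follow the first group's `n_max` draws in the
  replicate's random stream.  Fix `n_max` when comparing runs.
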