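# seqtest

Design planning for **sequential two-sample t-tests**.

Instead of fixing the sample size in advance, a sequential design adds
observations in balanced pairs and monitors the evidence after every
step, stopping as soon as a decision boundary is crossed.  `seqtest`
implements the two standard monitoring statistics in one framework:

* **SPRT** — the Sequential Probability Ratio Test, monitoring the
  likelihood ratio between two point hypotheses on Cohen's δ;
* **SBFT** — the Sequential Bayes Factor Test, monitoring a Bayes factor
  whose alternative hypothesis carries a prior on δ (default: a
  zero-centered Cauchy with scale √2/2).

The two are one family: as the alternative prior collapses onto a point,
the Bayes factor converges to the likelihood ratio.

On top of the evidence computations the package provides

* **Monte-Carlo operating characteristics** — decision-error rates and
  stopping-sample-size distributions of any design, under hypothesized or
  misspecified true effects;
* **threshold optimization** — simulation-based search for the narrowest
  stopping thresholds that still meet target error rates exactly
  (Wald's closed-form thresholds only bound them, conservatively), or
  that match another design's effective rates;
* **reproducible study grids** — YAML-configured design × true-effect
  grids producing tidy, seed-stamped, resumable CSVs;
* a **CLI** (`seqtest`) exposing all of the above.

## Worked example

Plan a one-sided study expecting δ = 0.5, stopping at Wald thresholds for
nominal α = 0.05, β = 0.10:

```python
import numpy as np
from seqtest import (DesignSpec, HypothesisSpec, point, wald_thresholds,
                     run_sequential, simulate_design)

thresholds = wald_thresholds(0.05, 0.1)   # A = 18, B = 0.105
design = DesignSpec(test_type="sprt", sided=1,
                    alt=HypothesisSpec(point(0.5)),
                    thresholds=thresholds, n_max=5000)

# how will this design behave?  (10,000-replicate planning simulation)
oc_null = simulate_design(design, delta_true=0.0, n_replicates=10_000, seed=0)
oc_alt  = simulate_design(design, delta_true=0.5, n_replicates=10_000, seed=1)
print(f"false-positive rate {oc_null.rate_accept_alt:.3f}, "
      f"false-negative rate {oc_alt.rate_accept_null:.3f}")
print(f"mean n per group: {oc_null.mean_n:.0f} (null), {oc_alt.mean_n:.0f} (alt)")

# run it on (simulated) incoming data
rng = np.random.default_rng(7)
decision = run_sequential((rng.normal(0.5, 1, 500), rng.normal(0, 1, 500)), design)
print(decision.outcome, "at n =", decision.n_per_group, "per group")
```

Output (seeds as shown):

```
false-positive rate 0.045, false-negative rate 0.080
mean n per group: 36 (null), 44 (alt)
accept_alt at n = 42 per group
```

Note the realized error rates sit *below* the nominal 0.05/0.10 — Wald's
thresholds bound the rates but overshoot makes them conservative.  To
convert that slack into smaller samples, optimize the thresholds:

```python
from seqtest import ErrorTargets, build_bank, optimize_thresholds

bank0 = build_bank(design, 0.0, 2000, seed=101)   # cached evidence paths
bank1 = build_bank(design, 0.5, 2000, seed=102)
res = optimize_thresholds(bank0, bank1, ErrorTargets(0.05, 0.10))
print(res.thresholds, res.achieved_null.rate_accept_alt,
      res.achieved_alt.rate_accept_null)
```

The banks are built once; every candidate threshold pair merely cuts the
cached trajectories, so the global search costs seconds.

The same design in one shell line:

```
seqtest oc --test sprt --delta1 0.5 --delta-true 0 --delta-true 0.5 \
        --replicates 10000 --seed 0
```

More narrative walkthroughs live in `examples/`:

1. `01_monitor_a_study.py` — live monitoring, SPRT and SBFT side by side
2. `02_operating_characteristics.py` — error rates, stopping-n
   distributions, misspecification profiles
3. `03_optimize_thresholds.py` — exact error control via trajectory banks
4. `04_study_grid.py` — YAML study configs and reproducible grids

## Choosing between SPRT and SBFT

* If the truth matches a point alternative exactly, the SPRT is the most
  efficient design; SBFT efficiency approaches it as the prior
  concentrates near the true effect.
* Under misspecification (true effect smaller than hypothesized), the
  SPRT's false-negative rate deteriorates sharply, while a spread-out
  SBFT prior hedges: it rarely accepts the null when some effect exists,
  at the price of larger samples.
* `misspecification_profile` and `matched_design_comparison` quantify
  this trade-off for your design; see `docs/methods.md` for the
  statistical details and numerical methods.

## Reproducibility

All simulations are driven by `numpy.random.SeedSequence` spawning: one
master seed yields independent per-replicate substreams, grid cells use
position-based spawn keys (safe to resume or reorder), and every results
row records the seed, replicate count and package version that produced
it.

## Repository layout

```
src/seqtest/        the library (evidence, priors, stopping, simulate,
                    optimize, reporting, cli)
tests/              pytest suite; tests/test_acceptance.py holds the
                    top-level acceptance criteria
scripts/acceptance.py   recomputes the Monte-Carlo acceptance targets
examples/           narrative walkthroughs (start here)
docs/methods.md     statistical and numerical methods
```
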