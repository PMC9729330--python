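"""Monitor a single sequential study as data arrive.

A research team plans a two-sample experiment and, instead of fixing the
sample size in advance, monitors the evidence after every added pair of
observations.  This script shows both monitoring styles on the same
simulated data stream:

* an SPRT comparing the point hypotheses delta = 0.5 vs delta = 0, and
* an SBFT with the default positively truncated Cauchy(0, sqrt(2)/2)
  alternative prior against the sharp null.

Run:  python examples/01_monitor_a_study.py
"""

import numpy as np

from seqtest import (
    DesignSpec,
    HypothesisSpec,
    TTestSummary,
    cauchy,
    point,
    run_sequential,
    stopping_decision,
    wald_thresholds,
)

# ----------------------------------------------------------------------
# the design: stop when the evidence leaves (B, A), Wald thresholds for
# nominal alpha = 0.05, beta = 0.1 -> A = 18, B = 0.105
thresholds = wald_thresholds(0.05, 0.1)
print(f"thresholds: A = {thresholds.upper:.3f}, B = {thresholds.lower:.3f}")

sprt = DesignSpec(test_type="sprt", sided=1, alt=HypothesisSpec(point(0.5)),
                  thresholds=thresholds, n_max=500)
sbft = DesignSpec(test_type="sbft", sided=1,
                  alt=HypothesisSpec(cauchy(truncation="positive")),
                  thresholds=thresholds, n_max=500)

# ----------------------------------------------------------------------
# simulated data: the true effect is delta = 0.5
rng = np.random.default_rng(2024)
group1 = rng.normal(0.5, 1.0, 500)
group2 = rng.normal(0.0, 1.0, 500)

for name, design in [("SPRT", sprt), ("SBFT", sbft)]:
    decision = run_sequential((group1, group2), design)
    print(f"{name}: {decision.outcome} at n = {decision.n_per_group} per group "
          f"(log evidence {decision.final_log_evidence:+.3f})")

# ----------------------------------------------------------------------
# the same run, step by step, for the SPRT (first few checkpoints)
print("\nfirst SPRT checkpoints:")
s1 = s2 = q1 = q2 = 0.0
for n in range(1, 16):
    a, b = group1[n - 1], group2[n - 1]
    s1 += a; q1 += a * a; s2 += b; q2 += b * b
    if n < 2:
        continue
    pooled = (q1 - s1 * s1 / n + q2 - s2 * s2 / n) / (2 * n - 2)
    t = (s1 / n - s2 / n) / np.sqrt(pooled * 2.0 / n)
    log_lr = sprt.log_evidence(TTestSummary(float(t), n, n))
    print(f"  n = {n:2d}: t = {t:+.3f}, log LR = {log_lr:+.3f} "
          f"-> {stopping_decision(log_lr, thresholds)}")
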