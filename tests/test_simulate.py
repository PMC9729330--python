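"""Monte-Carlo banks and operating characteristics."""

from __future__ import annotations

import math

import numpy as np
import pytest

from seqtest import (
    DesignSpec,
    HypothesisSpec,
    ThresholdPair,
    TrajectoryBank,
    build_bank,
    cauchy,
    generate_stream,
    misspecification_profile,
    operating_characteristics,
    point,
    run_sequential,
    simulate_design,
    wald_thresholds,
)

WALD = wald_thresholds(0.05, 0.1)


def sprt(delta1=0.5, n_max=200, **kw):
    return DesignSpec(test_type="sprt", sided=1, alt=HypothesisSpec(point(delta1)),
                      thresholds=WALD, n_max=n_max, **kw)


def sbft(n_max=80, sided=1, **kw):
    trunc = "positive" if sided == 1 else "none"
    return DesignSpec(test_type="sbft", sided=sided,
                      alt=HypothesisSpec(cauchy(truncation=trunc)),
                      thresholds=WALD, n_max=n_max, **kw)


def test_generate_stream_calibration():
    x1, x2 = generate_stream(0.5, 200_000, 123)
    assert np.mean(x1) == pytest.approx(0.5, abs=0.01)
    assert np.mean(x2) == pytest.approx(0.0, abs=0.01)
    assert np.std(x1) == pytest.approx(1.0, abs=0.01)
    assert np.std(x2) == pytest.approx(1.0, abs=0.01)


def test_generate_stream_deterministic_and_validated():
    a = generate_stream(0.3, 50, 99)
    b = generate_stream(0.3, 50, 99)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
    with pytest.raises(ValueError):
        generate_stream(0.3, 1, 99)


def test_bank_is_reproducible_and_readonly():
    d = sprt(n_max=50)
    b1 = build_bank(d, 0.5, 64, seed=5)
    b2 = build_bank(d, 0.5, 64, seed=5)
    assert np.array_equal(b1.log_evidence_paths, b2.log_evidence_paths)
    assert np.all(np.isfinite(b1.log_evidence_paths))
    with pytest.raises(ValueError):
        b1.log_evidence_paths[0, 0] = 0.0


def test_bank_rejects_nonfinite_paths():
    with pytest.raises(ValueError):
        TrajectoryBank(delta_true=0.0, n_grid=np.array([2, 3]),
                       log_evidence_paths=np.array([[0.0, math.inf]]),
                       seed=0, n_replicates=1)


@pytest.mark.parametrize("design,delta_true", [
    (sprt(n_max=120), 0.5),
    (sprt(n_max=120), 0.0),
    (sbft(n_max=60), 0.6),
])
def test_bank_route_equals_early_stopping_route(design, delta_true):
    # the early-stopping fast path evaluates the identical per-step
    # evidence, so both routes must agree exactly for equal seeds
    r = 150 if design.test_type == "sprt" else 40
    bank = build_bank(design, delta_true, r, seed=21)
    via_bank = operating_characteristics(bank, design.thresholds)
    direct = simulate_design(design, delta_true, r, seed=21)
    assert via_bank == direct


def test_bank_route_matches_run_sequential():
    # per-replicate cross-check against the live sequential runner
    d = sprt(n_max=150)
    seed = np.random.SeedSequence(77)
    bank = build_bank(d, 0.4, 50, seed=77)
    outcomes = []
    for child in seed.spawn(50):
        x1, x2 = generate_stream(0.4, 150, child)
        outcomes.append(run_sequential((x1, x2), d))
    oc = operating_characteristics(bank, d.thresholds)
    assert oc.rate_accept_alt == pytest.approx(
        np.mean([o.outcome == "accept_alt" for o in outcomes]), abs=1e-12)
    assert oc.mean_n == pytest.approx(
        np.mean([o.n_per_group for o in outcomes]), abs=1e-9)


def test_equal_hypotheses_never_stop():
    # delta1 == delta0 gives identically zero evidence: all undecided
    d = sprt(0.0, n_max=30)
    oc = simulate_design(d, 0.0, 25, seed=3)
    assert oc.rate_undecided == 1.0
    assert oc.mean_n == 30.0


def test_unreachable_thresholds_all_undecided():
    d = sprt(0.5, n_max=40)
    wide = DesignSpec(test_type="sprt", sided=1, alt=d.alt,
                      thresholds=ThresholdPair(-1e9, 1e9), n_max=40)
    oc = simulate_design(wide, 0.5, 30, seed=4)
    assert oc.rate_undecided == 1.0
    assert oc.median_n == 40.0


def test_rates_sum_to_one_and_se_fields():
    oc = simulate_design(sprt(n_max=150), 0.5, 200, seed=6)
    assert oc.rate_accept_alt + oc.rate_accept_null + oc.rate_undecided \
        == pytest.approx(1.0, abs=1e-12)
    assert oc.mc_se_rates == pytest.approx(
        max(oc.rate_se(r) for r in
            (oc.rate_accept_alt, oc.rate_accept_null, oc.rate_undecided)), abs=1e-15)
    assert 0.0 < oc.se_mean_n < oc.mean_n
    qs = oc.n_quantiles
    assert qs[0.25] <= oc.median_n <= qs[0.75] <= qs[0.9]


def test_seed_changes_results():
    a = simulate_design(sprt(n_max=150), 0.5, 100, seed=1)
    b = simulate_design(sprt(n_max=150), 0.5, 100, seed=2)
    assert a != b


def test_misspecification_profile_shape_and_monotone_power():
    d = sprt(0.5, n_max=400)
    table = misspecification_profile(d, [0.0, 0.4, 0.8], 150, seed=9)
    assert list(table["delta_true"]) == [0.0, 0.4, 0.8]
    assert len(table) == 3
    power = table["rate_accept_alt"].to_numpy()
    assert power[0] < power[1] < power[2]
    with pytest.raises(ValueError):
        misspecification_profile(d, [], 10, seed=0)


def test_replicate_count_validation():
    with pytest.raises(ValueError):
        simulate_design(sprt(), 0.5, 0, seed=0)
    with pytest.raises(ValueError):
        build_bank(sprt(), 0.5, 0, seed=0)


def test_wald_bound_small_scale():
    # alpha' <= 1/A and beta' <= B up to MC error, modest replicates
    d = sprt(0.5, n_max=2000)
    null = simulate_design(d, 0.0, 400, seed=14)
    alt = simulate_design(d, 0.5, 400, seed=15)
    assert null.rate_accept_alt <= 1 / 18 + 3 * null.rate_se(1 / 18)
    assert alt.rate_accept_null <= 0.1 / 0.95 + 3 * alt.rate_se(0.1 / 0.95)
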