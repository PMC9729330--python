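"""Evidence module: frozen independent-oracle values and invariants.

The frozen constants below were computed with independent oracles
(high-precision adaptive quadrature of the noncentral-t scale-mixture
integral and of the prior-marginalized likelihood) and must never be
regenerated from the code under test.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import stats

from seqtest import (
    TTestSummary,
    cauchy,
    log_bf,
    log_lr_one_sided,
    log_lr_two_sided,
    noncentrality,
    normal,
    point,
    prior_mass,
)
from seqtest.evidence import _log_kernel, _log_nct

S_REF = TTestSummary(2.5, 50, 50)

# frozen oracle values at t=2.5, n1=n2=50 (delta1=0.5, delta0=0)
ORACLE_LOG_LR1 = 3.0446326119131
ORACLE_LOG_LR2 = 2.3514907070858
ORACLE_LOG_BF2_CAUCHY = 1.1735389191737  # Cauchy(0, sqrt(2)/2), two-sided
ORACLE_LOG_BF1_CAUCHY_POS = 1.8566674901337  # positive-truncated, one-sided

TOL = 1e-8


def test_summary_validation():
    with pytest.raises(ValueError):
        TTestSummary(1.0, 1, 50)
    with pytest.raises(ValueError):
        TTestSummary(math.inf, 50, 50)
    s = TTestSummary(2.5, 40, 60)
    assert s.nu == 98
    assert s.ncp_scale == pytest.approx(math.sqrt(40 * 60 / 100))


def test_noncentrality():
    assert noncentrality(0.5, 50, 50) == pytest.approx(2.5)
    with pytest.raises(ValueError):
        noncentrality(0.5, 0, 50)


def test_log_lr_one_sided_oracle():
    assert log_lr_one_sided(S_REF, 0.5, 0.0) == pytest.approx(ORACLE_LOG_LR1, abs=TOL)


def test_log_lr_one_sided_at_zero_t_is_minus_half_ncp_sq():
    # at t = 0 the likelihood ratio reduces to phi(Delta)/phi(0) exactly
    s = TTestSummary(0.0, 50, 50)
    delta = noncentrality(0.5, 50, 50)
    assert log_lr_one_sided(s, 0.5, 0.0) == pytest.approx(-0.5 * delta**2, abs=TOL)


def test_log_lr_two_sided_oracle():
    assert log_lr_two_sided(S_REF, 0.5, 0.0) == pytest.approx(ORACLE_LOG_LR2, abs=TOL)


def test_log_lr_two_sided_matches_noncentral_f_ratio():
    # independent oracle: ratio of noncentral-F densities of t**2 (df1=1)
    for t in (0.5, 1.0, 2.0, 3.5):
        for n in (5, 50, 400):
            for d1 in (0.2, 0.5, 0.8):
                s = TTestSummary(t, n, n)
                delta1 = noncentrality(d1, n, n)
                ref = (stats.ncf.logpdf(t * t, 1, s.nu, delta1**2)
                       - stats.f.logpdf(t * t, 1, s.nu))
                assert log_lr_two_sided(s, d1, 0.0) == pytest.approx(ref, abs=1e-8), \
                    (t, n, d1)


def test_log_lr_two_sided_even_in_t():
    for t in (0.3, 1.7, 4.2):
        a = log_lr_two_sided(TTestSummary(t, 30, 30), 0.5)
        b = log_lr_two_sided(TTestSummary(-t, 30, 30), 0.5)
        assert a == pytest.approx(b, abs=1e-12)


def test_log_lr_one_sided_monotone_in_t():
    ts = np.linspace(-4, 6, 41)
    vals = [log_lr_one_sided(TTestSummary(float(t), 25, 25), 0.5) for t in ts]
    assert np.all(np.diff(vals) > 0)


def test_equal_hypotheses_give_zero_evidence():
    assert log_lr_one_sided(S_REF, 0.3, 0.3) == 0.0
    assert log_lr_two_sided(S_REF, 0.3, -0.3) == 0.0


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_log_nct_matches_scipy_where_scipy_works():
    # the library closed form over/underflows in parts of this grid (which
    # is why the package carries its own kernel); compare wherever the
    # library returns a finite, representable value
    compared = 0
    for t in np.linspace(-6.0, 6.0, 13):
        for nu in (3, 8, 98, 998):
            for nc in (-4.0, 0.0, 1.5, 5.0):
                try:
                    ref = (stats.nct.logpdf(t, nu, nc) if nc != 0.0
                           else stats.t.logpdf(t, nu))
                except OverflowError:
                    continue
                if not np.isfinite(ref) or ref < -300.0:
                    continue
                ours = float(_log_nct(np.array([t]), float(nu), np.array([nc]))[0])
                assert ours == pytest.approx(ref, abs=1e-6), (t, nu, nc)
                compared += 1
    assert compared > 150


def test_log_nct_finite_at_extreme_noncentrality():
    # regions where closed-form library implementations over/underflow
    ts = np.array([1000.0, 40.0, -50.0, 0.0])
    nus = np.array([2.0, 8000.0, 10.0, 50.0])
    ncs = np.array([1000.0, 80.0, 200.0, -300.0])
    vals = _log_nct(ts, nus, ncs)
    assert np.all(np.isfinite(vals))
    # peak case: density at its mode cannot be astronomically small
    assert vals[0] > -20.0


def test_log_bf_cauchy_oracles():
    assert log_bf(S_REF, cauchy(), sided=2) == pytest.approx(
        ORACLE_LOG_BF2_CAUCHY, abs=TOL)
    assert log_bf(S_REF, cauchy(truncation="positive"), sided=1) == pytest.approx(
        ORACLE_LOG_BF1_CAUCHY_POS, abs=TOL)


def test_bf_converges_to_lr_as_prior_narrows():
    # Bayes factor -> likelihood ratio as the alternative prior collapses
    target = log_lr_two_sided(S_REF, 0.5, 0.0)
    gaps = []
    for var in (0.3, 0.1, 0.001, 1e-6):
        bf = log_bf(S_REF, normal(0.5, math.sqrt(var)), sided=2)
        gaps.append(abs(bf - target))
    assert all(a > b for a, b in zip(gaps, gaps[1:]))
    assert gaps[-1] < 1e-2


def test_point_alt_prior_reduces_to_likelihood_ratio():
    assert log_bf(S_REF, point(0.5), sided=1) == pytest.approx(
        log_lr_one_sided(S_REF, 0.5, 0.0), abs=1e-12)
    assert log_bf(S_REF, point(0.5), sided=2) == pytest.approx(
        log_lr_two_sided(S_REF, 0.5, 0.0), abs=1e-12)


def test_two_sided_bf_rejects_truncated_prior():
    with pytest.raises(ValueError):
        log_bf(S_REF, cauchy(truncation="positive"), sided=2)


def test_one_sided_bf_favors_sign_consistent_data():
    pos = cauchy(truncation="positive")
    neg = cauchy(truncation="negative")
    s = TTestSummary(2.0, 30, 30)
    assert log_bf(s, pos, sided=1) > log_bf(s, neg, sided=1)


def test_prior_mass_default_cauchy_interquartile():
    assert prior_mass(cauchy(), -math.sqrt(2) / 2, math.sqrt(2) / 2) == pytest.approx(
        0.5, abs=5e-4)


def test_kernel_rejects_bad_sided():
    with pytest.raises(ValueError):
        _log_kernel(np.array([1.0]), 10.0, np.array([0.5]), sided=3)
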