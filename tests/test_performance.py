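import itertools

import numpy as np
import pandas as pd
import pytest

from ehrprep.performance import (
    bootstrap_ci,
    c_index,
    calibration_curve,
    calibration_in_the_large,
    calibration_slope,
    evaluate,
    km_observed_risk,
)


def _logit(p):
    return np.log(p / (1 - p))


# ---- concordance ------------------------------------------------------------

def test_c_perfect_ordering():
    time = np.array([1.0, 2.0, 3.0, 4.0])
    lp = np.array([4.0, 3.0, 2.0, 1.0])  # higher lp, earlier event
    assert c_index(lp, time, np.ones(4)) == 1.0


def test_c_five_subject_hand_enumeration():
    # exhaustive pair enumeration done by hand:
    # subjects (lp, time, event): A(2.0, 1, 1) B(1.5, 2, 1) C(1.0, 3, 0)
    #                             D(0.5, 4, 1) E(2.0, 5, 1)
    # usable pairs (earlier member an event):
    #  A-B concordant, A-C concordant, A-D concordant, A-E tie in lp (1/2)
    #  B-C concordant, B-D concordant, B-E discordant
    #  D-E discordant          (C censored at 3 < 4: C-D, C-E unusable)
    # C = (5 + 0.5) / 8
    lp = np.array([2.0, 1.5, 1.0, 0.5, 2.0])
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    event = np.array([1, 1, 0, 1, 1])
    assert c_index(lp, time, event) == pytest.approx(5.5 / 8)


def test_c_exhaustive_enumeration_oracle(rng):
    # independent brute-force enumeration over all pairs on random data
    n = 60
    lp = rng.normal(size=n).round(1)  # rounding forces lp ties
    time = rng.uniform(1, 30, n)  # continuous: no time ties
    event = rng.integers(0, 2, n)
    num = den = 0.0
    for i, j in itertools.combinations(range(n), 2):
        a, b = (i, j) if time[i] < time[j] else (j, i)
        if not event[a]:
            continue
        den += 1
        if lp[a] > lp[b]:
            num += 1
        elif lp[a] == lp[b]:
            num += 0.5
    assert c_index(lp, time, event) == pytest.approx(num / den)


def test_c_null_random_lp():
    rng = np.random.default_rng(5)
    n = 10_000
    lp = rng.permutation(n).astype(float)
    time = rng.exponential(10, n)
    event = (rng.random(n) < 0.7).astype(int)
    se = 1.0 / np.sqrt(event.sum())  # conservative scale
    assert abs(c_index(lp, time, event) - 0.5) < 3 * se


def test_c_invariant_to_monotone_transform(rng):
    n = 200
    lp = rng.normal(size=n)
    time = rng.exponential(5, n)
    event = rng.integers(0, 2, n)
    a = c_index(lp, time, event)
    b = c_index(np.exp(2 * lp) + 7, time, event)
    assert a == pytest.approx(b)


def test_c_undefined_without_events():
    with pytest.raises(ValueError):
        c_index(np.array([1.0, 2.0]), np.array([1.0, 2.0]), np.array([0, 0]))


# ---- calibration in the large ----------------------------------------------

def test_intercept_closed_form_underestimation():
    # observed 7.5% vs mean predicted 3.4% -> logit difference 0.835
    time = np.array([5.0] * 925 + [1.0] * 75)
    event = np.array([0] * 925 + [1] * 75)
    predicted = np.full(1000, 0.034)
    alpha = calibration_in_the_large(predicted, time, event, tau=2.0)
    expected = _logit(0.075) - _logit(0.034)
    assert alpha == pytest.approx(expected, abs=1e-9)
    assert alpha == pytest.approx(0.835, abs=1e-3)


def test_intercept_closed_form_overestimation():
    time = np.array([5.0] * 925 + [1.0] * 75)
    event = np.array([0] * 925 + [1] * 75)
    predicted = np.full(1000, 0.114)
    alpha = calibration_in_the_large(predicted, time, event, tau=2.0)
    assert alpha == pytest.approx(_logit(0.075) - _logit(0.114), abs=1e-9)
    assert alpha == pytest.approx(-0.462, abs=5e-4)


def test_intercept_antisymmetry():
    # swapping observed and predicted proportions flips the sign
    time = np.array([5.0] * 966 + [1.0] * 34)
    event = np.array([0] * 966 + [1] * 34)
    a1 = calibration_in_the_large(np.full(1000, 0.075), time, event, tau=2.0)
    time2 = np.array([5.0] * 925 + [1.0] * 75)
    event2 = np.array([0] * 925 + [1] * 75)
    a2 = calibration_in_the_large(np.full(1000, 0.034), time2, event2, tau=2.0)
    assert a1 == pytest.approx(-a2, abs=1e-9)


def test_intercept_perfect_calibration_near_zero(rng):
    n = 50_000
    p = rng.uniform(0.02, 0.2, n)
    event = (rng.random(n) < p).astype(int)
    time = np.where(event, 0.5, 1.0)
    alpha = calibration_in_the_large(p, time, event, tau=0.75)
    assert abs(alpha) < 0.05


def test_intercept_requires_valid_risks():
    with pytest.raises(ValueError):
        calibration_in_the_large(
            np.array([0.0, 0.5]), np.array([1.0, 2.0]), np.array([1, 0]), tau=1.5
        )


def test_km_undefined_beyond_last_time():
    with pytest.raises(ValueError, match="beyond"):
        km_observed_risk(np.array([1.0, 2.0]), np.array([1, 0]), tau=5.0)


def test_km_handles_censoring():
    # half censored early: KM corrects the naive event fraction upward
    time = np.array([1.0] * 50 + [10.0] * 40 + [4.0] * 10)
    event = np.array([0] * 50 + [0] * 40 + [1] * 10)
    km = km_observed_risk(time, event, tau=9.0)
    assert km > (event.sum() / len(event))


# ---- calibration slope ------------------------------------------------------

def _slope_data(seed=0, n=4000, scale=1.0):
    rng = np.random.default_rng(seed)
    lp = rng.normal(0, 0.7, n)
    t_event = rng.exponential(1 / (0.05 * np.exp(lp)))
    t_cens = np.minimum(rng.exponential(25, n), 30.0)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return lp * scale, time, event


def test_slope_self_consistency_near_one():
    lp, time, event = _slope_data(seed=1)
    b = calibration_slope(lp, time, event)
    se = 1 / (np.std(lp) * np.sqrt(event.sum()))
    assert b == pytest.approx(1.0, abs=3 * se)


def test_slope_halved_lp_doubles():
    lp, time, event = _slope_data(seed=2)
    b_full = calibration_slope(lp, time, event)
    b_half = calibration_slope(lp / 2.0, time, event)
    assert b_half == pytest.approx(2 * b_full, rel=1e-6)


def test_slope_degenerate_lp_errors():
    with pytest.raises(ValueError):
        calibration_slope(np.ones(100), np.arange(1, 101.0), np.ones(100, dtype=int))


def test_thinning_shifts_intercept_not_slope():
    # non-differential thinning of derivation events: slope stays ~1 while the
    # intercept becomes positive (shift without rotation)
    rng = np.random.default_rng(3)
    n = 30_000
    lp = rng.normal(0, 0.7, n)
    t_event = rng.exponential(1 / (0.008 * np.exp(lp)))
    t_cens = np.full(n, 15.0)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # model trained on thinned outcomes predicts half the true risk
    h0 = -np.log(1 - 0.5 * km_observed_risk(time, event, 10.0))
    predicted = 1 - np.exp(-h0 * np.exp(lp))
    alpha = calibration_in_the_large(predicted, time, event, tau=10.0)
    b = calibration_slope(lp, time, event)
    assert alpha > 0.4
    assert b == pytest.approx(1.0, abs=0.05)


# ---- calibration curve ------------------------------------------------------

def test_curve_monotone_predicted_and_diagonal(rng):
    n = 20_000
    p = rng.uniform(0.05, 0.5, n)
    event = (rng.random(n) < p).astype(int)
    time = np.where(event, 0.5, 1.0)
    curve = calibration_curve(p, time, event, tau=0.75)
    assert len(curve) == 10
    assert (np.diff(curve["mean_predicted"]) >= 0).all()
    # perfectly calibrated: points near the diagonal
    assert np.max(np.abs(curve["mean_predicted"] - curve["observed"])) < 0.05


def test_curve_underprediction_above_diagonal(rng):
    n = 20_000
    p = rng.uniform(0.05, 0.4, n)
    event = (rng.random(n) < p).astype(int)
    time = np.where(event, 0.5, 1.0)
    curve = calibration_curve(p / 2, time, event, tau=0.75)
    assert (curve["observed"] > curve["mean_predicted"]).all()


def test_curve_sparse_bin_flagged():
    p = np.linspace(0.01, 0.2, 100)
    event = np.zeros(100, dtype=int)
    event[-10:] = 1
    time = np.ones(100)
    curve = calibration_curve(p, time, event, tau=0.5, n_bins=10)
    assert curve.loc[0, "sparse"]
    assert curve.loc[0, "observed"] == 0.0


def test_curve_requires_enough_subjects():
    with pytest.raises(ValueError):
        calibration_curve(np.array([0.1]), np.array([1.0]), np.array([1]), tau=0.5)


# ---- bootstrap CI -----------------------------------------------------------

def test_bootstrap_ci_constant_zero_width():
    lo, hi = bootstrap_ci([0.7] * 10)
    assert lo == hi == 0.7


def test_bootstrap_ci_within_min_max(rng):
    vals = rng.normal(size=50)
    lo, hi = bootstrap_ci(vals)
    assert vals.min() <= lo <= hi <= vals.max()


def test_bootstrap_ci_coverage(rng):
    # percentile interval over repeat-level means covers the truth ~95%
    cover = 0
    meta = 200
    for _ in range(meta):
        reps = rng.normal(0.0, 1.0, 1000)
        lo, hi = bootstrap_ci(reps)
        cover += lo <= 0.0 <= hi
    assert cover / meta > 0.9


def test_bootstrap_ci_needs_two():
    with pytest.raises(ValueError):
        bootstrap_ci([1.0])


# ---- aggregate --------------------------------------------------------------

def test_evaluate_bundle(rng):
    lp, time, event = _slope_data(seed=9, n=2000)
    risk = 1 - np.exp(-0.3 * np.exp(lp))
    res = evaluate(lp, risk, time, event, tau=10.0)
    assert 0.5 < res.c_index < 1.0
    assert res.n == 2000
    assert res.median_followup_days == pytest.approx(np.median(time))
    assert len(res.curve) == 10
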