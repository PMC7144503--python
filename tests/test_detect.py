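import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suddengains.cohort import CohortConfig, generate_cohort
from suddengains.detect import (GainCriteriaConfig, classify_reversals,
                                cohort_gain_summary, compute_rci_cutoff,
                                evaluate_criteria,
                                extract_values_around_gain,
                                identify_sudden_gains,
                                identify_sudden_losses, report_percentage)
from conftest import make_record

CFG = GainCriteriaConfig()


# ---------------------------------------------------------------- oracle
def brute_force_gains(series, cfg=CFG):
    """Independent re-derivation of the criteria, interval by interval."""
    s = list(map(float, series))
    found = []
    lo, hi = cfg.candidate_pregain_sessions
    for n in range(lo, min(hi, len(s) - 2) + 1):
        if math.isnan(s[n]) or math.isnan(s[n + 1]):
            continue
        pre = [s[i] for i in (n - 2, n - 1, n)
               if i >= 0 and not math.isnan(s[i])]
        post = [s[i] for i in (n + 1, n + 2, n + 3)
                if i < len(s) and not math.isnan(s[i])]
        if len(pre) < cfg.min_present or len(post) < cfg.min_present:
            continue
        drop = s[n] - s[n + 1]
        if drop < cfg.cutoff or drop < cfg.relative_fraction * s[n]:
            continue
        sd_pre = statistics.stdev(pre)
        sd_post = statistics.stdev(post)
        pooled = math.sqrt((sd_pre ** 2 + sd_post ** 2) / 2)
        gap = statistics.mean(pre) - statistics.mean(post)
        crit = {4: 2.776, 3: 3.182, 2: 4.303}[len(pre) + len(post) - 2]
        ok = gap > 0 if pooled == 0 else gap > crit * pooled
        if ok:
            found.append((n, drop))
    return found


def test_detector_matches_brute_force_oracle():
    cfg = CohortConfig(n_patients=200, gain_fraction=0.4,
                       gain_magnitude_mean=10, gain_magnitude_sd=3,
                       noise_sd=2.5, missing_rate=0.1, seed=17)
    for rec in generate_cohort(cfg):
        got = [(g.pregain_session, g.magnitude)
               for g in identify_sudden_gains(rec, CFG)]
        assert got == brute_force_gains(rec.symptom_series)


# ------------------------------------------------------------ RCI cutoff
@pytest.mark.parametrize("sd,r,expected", [
    (10.0, 0.5, 10.0),
    (4.2, 1.0, 0.0),
    (8.7, 0.75, 6.152),
])
def test_rci_cutoff_formula(sd, r, expected):
    assert compute_rci_cutoff(sd, r) == pytest.approx(expected, abs=5e-4)


def test_rci_cutoff_rejects_bad_reliability():
    with pytest.raises(ValueError):
        compute_rci_cutoff(10.0, 1.2)


def test_default_cutoff_constant():
    assert GainCriteriaConfig().cutoff == 6.15


# --------------------------------------------------------------- criteria
def test_criteria_all_met_on_clean_step():
    # pre [30,29,28], post [14,13,12]: drop 14, both window SDs 1.0
    series = np.array([30, 29, 28, 14, 13, 12, 11], float)
    res = evaluate_criteria(series, 2, CFG)
    assert res.eligible and res.c1 and res.c2 and res.c3
    assert res.df_used == 4
    assert res.pooled_sd == pytest.approx(1.0)
    assert res.mean_pre - res.mean_post == pytest.approx(16.0)


def test_criteria_all_fail_on_small_noisy_drop():
    # pre [30,20,28], post [22,21,20]: drop 6 < 6.15 and < 25% of 28;
    # pooled sd sqrt((28+1)/2) makes the stability gap (5) too small
    series = np.array([30, 20, 28, 22, 21, 20], float)
    res = evaluate_criteria(series, 2, CFG)
    assert res.eligible
    assert not (res.c1 or res.c2 or res.c3)
    assert res.pooled_sd == pytest.approx(math.sqrt(29 / 2))


def test_missing_flank_lowers_df_and_critical_value():
    series = np.array([30, np.nan, 28, 14, 13, 12, 11], float)
    res = evaluate_criteria(series, 2, CFG)
    assert res.eligible and res.df_used == 3
    # passes against t(3) = 3.182
    assert res.c3


def test_missing_endpoint_is_ineligible():
    series = np.array([30, 29, 28, np.nan, 13, 12, 11], float)
    res = evaluate_criteria(series, 2, CFG)
    assert not res.eligible and not res.all_met


def test_pregain_session_outside_candidate_range_raises():
    with pytest.raises(ValueError):
        evaluate_criteria(np.arange(13, dtype=float), 1, CFG)


# -------------------------------------------------------------- detection
def test_single_step_detected_once(step_record):
    gains = identify_sudden_gains(step_record, CFG)
    assert len(gains) == 1
    assert gains[0].pregain_session == 5
    assert gains[0].magnitude == 12.0
    assert gains[0].is_primary


def test_constant_series_has_no_gains():
    rec = make_record([30.0] * 13)
    assert identify_sudden_gains(rec, CFG) == []


def test_two_steps_earliest_is_primary():
    series = np.array([36.0] * 4 + [26.0] * 5 + [16.0] * 4)
    gains = identify_sudden_gains(make_record(series), CFG)
    assert [g.pregain_session for g in gains] == [3, 8]
    assert gains[0].is_primary and not gains[1].is_primary


def test_monotonicity_in_cutoff_and_fraction():
    cfg = CohortConfig(n_patients=60, gain_fraction=0.4, noise_sd=3.0,
                       seed=23)
    cohort = generate_cohort(cfg)
    for strict in (GainCriteriaConfig(cutoff=9.0),
                   GainCriteriaConfig(relative_fraction=0.4)):
        for rec in cohort:
            loose = identify_sudden_gains(rec, CFG)
            tight = identify_sudden_gains(rec, strict)
            assert len(tight) <= len(loose)


# ----------------------------------------------------------------- losses
def test_step_increase_is_a_sudden_loss():
    series = np.array([18.0] * 6 + [30.0] * 7)
    losses = identify_sudden_losses(make_record(series), CFG)
    assert len(losses) == 1
    assert losses[0].pregain_session == 5
    assert losses[0].magnitude == 12.0


def test_constant_series_has_no_losses():
    assert identify_sudden_losses(make_record([30.0] * 13), CFG) == []


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=51),
                min_size=13, max_size=13))
def test_losses_equal_gains_on_reflected_series(scores):
    series = np.array(scores, float)
    losses = [(l.pregain_session, l.magnitude)
              for l in identify_sudden_losses(make_record(series), CFG)]
    reflected = [(g.pregain_session, g.magnitude)
                 for g in identify_sudden_gains(
                     make_record(51.0 - series), CFG)]
    assert losses == reflected


# -------------------------------------------------------------- reversals
def _gain_then_tail(tail):
    series = np.array([30, 29, 28, 14, 13, 12] + list(tail), float)
    rec = make_record(series)
    gains = identify_sudden_gains(rec, CFG)
    assert gains and gains[0].pregain_session == 2
    return gains[0]


def test_no_reversal_below_half_threshold():
    # gain 28 -> 14, threshold 21: later scores never reach it
    g = _gain_then_tail([20, 19, 18, 17, 16, 15, 14])
    assert not g.reversed and not g.stable_reversal


def test_transient_reversal_regained_by_end():
    g = _gain_then_tail([22, 13, 12, 11, 10, 9, 8])
    assert g.reversed and g.regained_by_end and not g.stable_reversal


def test_sustained_rise_is_stable_reversal():
    g = _gain_then_tail([26, 26, 26, 26, 26, 26, 26])
    assert g.reversed and g.stable_reversal and not g.regained_by_end


# ------------------------------------------------------------ around-gain
def test_extract_values_alignment():
    series = np.array([33, 31, 30, 29, 15, 14, 13, 12, 11, 10, 9, 8, 7],
                      float)
    rec = make_record(series)
    assert np.allclose(extract_values_around_gain(rec, 3, "pds"),
                       [31, 30, 29, 15, 14])
    at2 = extract_values_around_gain(rec, 2, "pds")
    assert at2[0] == 33  # position N-2 is the baseline
    assert np.isfinite(at2).all()


# ---------------------------------------------------------------- summary
def test_report_percentage_half_up():
    assert report_percentage(76, 248) == 30.65
    assert report_percentage(1, 800) == 0.13  # 0.125 rounds up


def test_summary_counts_on_constructed_cohort():
    gainer = make_record(np.array([30.0] * 6 + [18.0] * 7), "g1")
    flat1 = make_record([25.0] * 13, "f1")
    flat2 = make_record([25.0] * 13, "f2")
    summary = cohort_gain_summary([gainer, flat1, flat2], CFG)
    assert summary["n_gainers"] == 1
    assert summary["pct_gainers"] == 33.33
    assert summary["total_gains"] == 1
    assert summary["mean_gain_magnitude"] == 12.0
    assert summary["pregain_session_counts"] == {5: 1}


def test_summary_zero_gainers():
    summary = cohort_gain_summary([make_record([25.0] * 13)], CFG)
    assert summary["pct_gainers"] == 0.0
    assert summary["mean_gain_magnitude"] is None


def test_summary_empty_cohort_raises():
    with pytest.raises(ValueError):
        cohort_gain_summary([], CFG)
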