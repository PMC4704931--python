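"""Unit tests for the visual and quantitative ovulation classifiers."""

import numpy as np
import pytest

from bbtagree import (
    CycleParams,
    adjudicate_majority,
    classify_mtm,
    classify_visual,
    detect_biphasic_shift,
    detect_nadir,
    expected_ovulation_day,
    generate_cycle,
)
from bbtagree.ovulation_calls import OvulationCall, check_thermal_shift_adequacy
from conftest import make_series


def _call(category):
    return OvulationCall("P1", "visual", category)


def _biphasic_series(shift=0.4, length=28, shift_day=15, base=36.3):
    """Hand-built step series without nadir or noise."""
    t = np.full(length, base)
    t[shift_day - 1 :] = base + shift
    return make_series(np.round(t, 2))


class TestExpectedOvulationDay:
    @pytest.mark.parametrize("length,day", [(28, 15), (21, 8), (35, 22)])
    def test_two_weeks_before_next_menses(self, length, day):
        assert expected_ovulation_day(make_series([36.3] * length)) == day

    def test_unknown_cycle_end_gives_no_anchor(self):
        s = make_series([36.3] * 28, next_menses_known=False)
        assert expected_ovulation_day(s) is None


class TestBiphasicShift:
    def test_generated_ovulatory_cycle_detected_on_true_day(self, clean_ovulatory):
        series, truth = clean_ovulatory
        res = detect_biphasic_shift(series, expected_ovulation_day(series))
        assert res.shift_day == truth.shift_day == 15

    def test_flat_series_has_no_shift(self, clean_flat):
        series, _ = clean_flat
        res = detect_biphasic_shift(series, expected_ovulation_day(series))
        assert res.shift_day is None and not res.undetermined

    def test_exact_threshold_shift_is_absent(self):
        # the criterion is strictly greater than 0.2 degC
        res = detect_biphasic_shift(_biphasic_series(shift=0.2), 15)
        assert res.shift_day is None
        res = detect_biphasic_shift(_biphasic_series(shift=0.21), 15)
        assert res.shift_day == 15

    def test_compared_against_maximum_of_six(self):
        t = np.full(28, 36.3)
        t[10] = 36.5  # one warm follicular day raises the reference
        t[14:] = 36.66  # > 0.2 above 36.3 but not above 36.5
        res = detect_biphasic_shift(make_series(t), 15)
        assert res.shift_day is None

    def test_too_few_preceding_days_is_undetermined(self):
        # six usable days before the shift: detectable despite early gaps
        t = np.full(28, np.nan)
        t[8:] = 36.3
        t[13] = 36.1
        t[14:] = 36.8
        res = detect_biphasic_shift(make_series(t), 15)
        assert res.shift_day == 15 and not res.undetermined
        # fewer than six usable preceding days for every candidate: undetermined
        t[:13] = np.nan
        res = detect_biphasic_shift(make_series(t), 15)
        assert res.shift_day is None and res.undetermined

    def test_fever_days_excluded_from_reference(self):
        series, _ = generate_cycle(
            CycleParams(
                daily_noise_sd=0.0,
                missing_prob=0.0,
                shift_magnitude=0.4,
                fever_days=frozenset({12}),
                fever_delta=0.8,
            ),
            seed=0,
        )
        # the fever spike on day 12 must not become the reference maximum
        res = detect_biphasic_shift(series, expected_ovulation_day(series))
        assert res.shift_day == 15


class TestThermalShiftAdequacy:
    def test_clean_ovulatory_cycle_passes(self, clean_ovulatory):
        series, _ = clean_ovulatory
        res = check_thermal_shift_adequacy(series, 15)
        assert res.outcome.passed is True
        assert res.luteal_length_days == 14
        assert res.rise_days == 1

    def test_short_luteal_phase_fails(self):
        series, _ = generate_cycle(
            CycleParams(luteal_length=8, daily_noise_sd=0.0, missing_prob=0.0), seed=0
        )
        res = check_thermal_shift_adequacy(series, 21)
        assert res.outcome.passed is False
        assert "sustained" in res.outcome.detail

    def test_deep_fall_in_luteal_phase_fails(self, clean_ovulatory):
        series, _ = clean_ovulatory
        t = series.temps.copy()
        t[21] = 36.3  # one luteal day back at the follicular level
        res = check_thermal_shift_adequacy(make_series(t), 15)
        assert res.outcome.passed is False
        assert "deep fall" in res.outcome.detail

    def test_slow_rise_fails(self, clean_ovulatory):
        series, _ = clean_ovulatory
        t = series.temps.copy()
        t[13] = np.nan  # nadir day missing: last pre-shift day is day 13
        res = check_thermal_shift_adequacy(make_series(t), 15)
        assert res.outcome.passed is False
        assert "rise" in res.outcome.detail

    def test_many_missing_luteal_days_undetermined(self, clean_ovulatory):
        series, _ = clean_ovulatory
        t = series.temps.copy()
        t[[16, 18, 20]] = np.nan
        res = check_thermal_shift_adequacy(make_series(t), 15)
        assert res.outcome.passed is None


class TestNadir:
    def test_generated_nadir_found_on_ovulation_day(self, clean_ovulatory):
        series, truth = clean_ovulatory
        assert detect_nadir(series, 15) == truth.ovulation_day == 14

    def test_no_dip_no_nadir(self):
        series = _biphasic_series()
        assert detect_nadir(series, 15) is None

    def test_monotone_rising_series_has_no_nadir(self):
        t = np.round(np.linspace(36.0, 36.9, 28), 2)
        assert detect_nadir(make_series(t), 15) is None


class TestClassifyVisual:
    def test_clean_ovulatory_cycle(self, clean_ovulatory):
        series, truth = clean_ovulatory
        call = classify_visual(series)
        assert call.category == "ovulatory"
        assert call.shift_day == truth.shift_day
        assert call.nadir_day == truth.ovulation_day
        assert call.luteal_length_days == 14

    def test_clean_flat_cycle(self, clean_flat):
        series, _ = clean_flat
        assert classify_visual(series).category == "anovulatory"

    def test_four_day_series_inconclusive(self):
        call = classify_visual(make_series([36.3, 36.4, 36.3, 36.4]))
        assert call.category == "inconclusive"

    def test_heavy_missingness_inconclusive(self, clean_ovulatory):
        series, _ = clean_ovulatory
        t = series.temps.copy()
        t[:7] = np.nan  # 25% of days missing, though 21 >= 17 recorded
        assert classify_visual(make_series(t)).category == "inconclusive"

    def test_unanchored_window_inconclusive(self, clean_ovulatory):
        series, _ = clean_ovulatory
        series.next_menses_known = False
        assert classify_visual(series).category == "inconclusive"

    def test_nadir_failure_alone_cannot_force_anovulatory(self):
        # biphasic + adequate shift but no nadir: still ovulatory
        call = classify_visual(_biphasic_series(shift=0.4))
        assert call.category == "ovulatory"
        assert call.nadir_day is None

    def test_invariant_to_off_window_missing_days(self, clean_ovulatory):
        series, _ = clean_ovulatory
        t = series.temps.copy()
        t[[1, 3]] = np.nan  # early-follicular days, far from the search window
        before = classify_visual(series)
        after = classify_visual(make_series(t))
        assert (before.category, before.shift_day) == (after.category, after.shift_day)

    def test_increasing_shift_never_flips_ovulatory_to_anovulatory(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            noise = rng.normal(0, 0.05, 28)
            was_ovulatory = False
            for shift in (0.15, 0.25, 0.35, 0.45):
                t = np.full(28, 36.3)
                t[14:] += shift
                t[13] -= 0.2
                series = make_series(np.round(t + noise, 2))
                cat = classify_visual(series).category
                if was_ovulatory:
                    assert cat == "ovulatory"
                was_ovulatory = cat == "ovulatory"


class TestClassifyMtm:
    def test_clean_ovulatory_cycle(self, clean_ovulatory):
        series, truth = clean_ovulatory
        call = classify_mtm(series)
        assert call.category == "ovulatory"
        assert call.shift_day == truth.shift_day

    def test_clean_flat_cycle_no_day_exceeds_mean(self, clean_flat):
        series, _ = clean_flat
        assert classify_mtm(series).category == "anovulatory"

    def test_agrees_with_visual_on_archetypes(self, clean_ovulatory, clean_flat):
        for fixture in (clean_ovulatory, clean_flat):
            series, _ = fixture
            assert classify_mtm(series).category == classify_visual(series).category

    def test_short_run_above_mean_not_ovulatory(self):
        # 10-day elevation cannot satisfy the 11-day run requirement
        t = np.full(28, 36.3)
        t[18:] = 36.7
        assert classify_mtm(make_series(t)).category == "anovulatory"

    def test_incomplete_data_inconclusive(self):
        assert classify_mtm(make_series([36.3] * 10)).category == "inconclusive"


class TestAdjudication:
    def test_two_concordant_calls_decide(self):
        res = adjudicate_majority([_call("ovulatory"), _call("ovulatory")])
        assert res.category == "ovulatory" and not res.needs_third_rater

    def test_two_discordant_calls_escalate(self):
        res = adjudicate_majority([_call("ovulatory"), _call("anovulatory")])
        assert res.category is None and res.needs_third_rater

    def test_three_calls_majority(self):
        res = adjudicate_majority(
            [_call("ovulatory"), _call("anovulatory"), _call("ovulatory")]
        )
        assert res.category == "ovulatory"

    def test_three_way_tie_inconclusive(self):
        res = adjudicate_majority(
            [_call("ovulatory"), _call("anovulatory"), _call("inconclusive")]
        )
        assert res.category == "inconclusive" and not res.needs_third_rater

    @pytest.mark.parametrize("n", [0, 1, 4])
    def test_wrong_rater_count_rejected(self, n):
        with pytest.raises(ValueError):
            adjudicate_majority([_call("ovulatory")] * n)


def brute_force_biphasic(series, center, halfwidth=4):
    """Independent exhaustive scan over all (candidate day, 6-back window)
    pairs, in plain Python."""
    temps = series.temps
    L = len(temps)
    usable = [
        d
        for d in range(1, L + 1)
        if np.isfinite(temps[d - 1]) and not series.illness[d - 1]
    ]
    uset = set(usable)
    for d in range(max(1, center - halfwidth), min(L - 2, center + halfwidth) + 1):
        prev = [u for u in usable if u < d]
        if len(prev) < 6:
            continue
        prev = prev[-6:]
        if not all(x in uset for x in (d, d + 1, d + 2)):
            continue
        ref = max(temps[u - 1] for u in prev)
        if all(temps[x - 1] - ref > 0.2 + 1e-9 for x in (d, d + 1, d + 2)):
            return d
    return None


def test_biphasic_matches_brute_force_on_random_cycles():
    rng = np.random.default_rng(2015)
    for _ in range(60):
        params = CycleParams(
            cycle_length=int(rng.integers(24, 34)),
            ovulatory=bool(rng.random() < 0.6),
            luteal_length=int(rng.integers(9, 16)),
            shift_magnitude=float(rng.uniform(0.05, 0.5)),
            nadir_depth=float(rng.uniform(0, 0.3)),
            daily_noise_sd=float(rng.uniform(0, 0.3)),
            missing_prob=float(rng.uniform(0, 0.2)),
        )
        series, _ = generate_cycle(params, rng)
        center = expected_ovulation_day(series)
        assert detect_biphasic_shift(series, center).shift_day == brute_force_biphasic(
            series, center
        )
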