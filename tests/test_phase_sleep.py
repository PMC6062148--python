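import numpy as np
import pytest

from flyrhythm import (
    FlyParams, average_day_profile, dd_phase, detect_anticipation,
    evening_onset, morning_index, simulate_cohort, simulate_fly, sleep_summary,
)
from flyrhythm.phase_sleep import DayProfile


def profile_from(values):
    return DayProfile(values=np.asarray(values, dtype=float), n_days_averaged=1)


class TestAverageDayProfile:
    def test_constant_series(self, make_series, schedule):
        s = make_series([5] * 48 * 3)
        prof = average_day_profile(s, [0, 1, 2], schedule)
        assert np.allclose(prof.values, 5.0)

    def test_two_days_average(self, make_series, schedule):
        s = make_series([2] * 48 + [4] * 48)
        prof = average_day_profile(s, [0, 1], schedule)
        assert np.allclose(prof.values, 3.0)

    def test_single_day_identity(self, make_series, schedule):
        counts = np.arange(48)
        prof = average_day_profile(make_series(counts), [0], schedule)
        assert np.allclose(prof.values, counts)

    def test_day_outside_recording_rejected(self, make_series, schedule):
        with pytest.raises(ValueError, match="outside"):
            average_day_profile(make_series([1] * 48), [1], schedule)


class TestMorningIndex:
    def test_block_contrast_arithmetic(self):
        v = np.zeros(48)
        v[36:42] = 10  # ZT18-21
        v[42:48] = 20  # ZT21-24
        assert morning_index(profile_from(v)) == pytest.approx(1 / 3)

    def test_flat_profile_zero(self):
        assert morning_index(profile_from(np.full(48, 7.0))) == 0.0

    def test_boundary_all_late(self):
        v = np.zeros(48)
        v[42:48] = 5
        assert morning_index(profile_from(v)) == 1.0

    def test_antisymmetric_under_block_swap(self):
        rng = np.random.default_rng(5)
        v = rng.random(48) * 10
        swapped = v.copy()
        swapped[36:42], swapped[42:48] = v[42:48].copy(), v[36:42].copy()
        assert morning_index(profile_from(swapped)) == pytest.approx(
            -morning_index(profile_from(v)))


class TestAnticipation:
    @pytest.mark.parametrize(
        "thirds, expected",
        [((2, 5, 9), True), ((5, 5, 5), False), ((9, 5, 2), False),
         ((0, 0, 0), False), ((2, 2, 9), True)],
    )
    def test_three_third_rule_before_lights_on(self, thirds, expected):
        v = np.zeros(48)
        for j, val in enumerate(thirds):
            v[42 + 2 * j: 44 + 2 * j] = val
        assert detect_anticipation(profile_from(v), "lights_on") is expected

    def test_simulated_ramp_cohort_recall_and_specificity(self, schedule):
        ramp, _ = simulate_cohort(20, FlyParams(anticipation_ramp_hours=3.0),
                                  0.0, schedule, seed=60)
        none, _ = simulate_cohort(20, FlyParams(anticipation_ramp_hours=0.0),
                                  0.0, schedule, seed=61)

        def ma(s):
            prof = average_day_profile(s, range(3), schedule)
            return detect_anticipation(prof, "lights_on")

        recall = np.mean([ma(s) for s in ramp])
        specificity = 1 - np.mean([ma(s) for s in none])
        assert recall >= 0.9
        # the three-thirds rule fires on pure noise with chance rate 1/6
        # (any of the 6 orderings of iid thirds), so specificity is bounded
        # near 5/6 by construction
        assert specificity >= 0.75


class TestEveningOnset:
    def test_hand_trace_rest_then_rising_bout(self):
        # rest (0,0) at ZT5-6; small sub-threshold bins at ZT6.5/7.0 end the
        # walk; bout 1,3,6,10 rises to the evening peak 12 at ZT9.5
        v = np.zeros(48)
        v[12] = 1.0   # ZT6
        v[13] = 1.0   # ZT6.5
        v[14] = 2.0   # ZT7 (> bout start, stops the walk; below rest threshold)
        v[15], v[16], v[17], v[18], v[19] = 1, 3, 6, 10, 12
        assert evening_onset(profile_from(v)) == pytest.approx(7.5)

    def test_flat_profile_has_no_onset(self):
        assert evening_onset(profile_from(np.full(48, 4.0))) is None

    def test_single_interior_zero_bin_tolerated(self):
        v = np.zeros(48)
        v[15] = 2.0   # ZT7.5: below threshold, ends the walk, part of the rest
        v[17], v[18], v[19], v[20] = 1, 0, 4, 9  # bout from ZT8.5 with one zero
        assert evening_onset(profile_from(v)) == pytest.approx(8.5)

    def test_bout_without_preceding_rest_rejected(self):
        v = np.full(48, 8.0)  # high activity all day: no siesta anywhere
        v[16], v[17], v[18], v[19] = 9, 10, 11, 12
        assert evening_onset(profile_from(v)) is None

    def test_cohorts_offset_by_90_minutes_recover_separation(self, schedule):
        a, _ = simulate_cohort(30, FlyParams(phase_offset_hours=0.0),
                               0.0, schedule, seed=70)
        b, _ = simulate_cohort(30, FlyParams(phase_offset_hours=-1.5),
                               0.0, schedule, seed=71)

        def mean_onset(cohort):
            vals = [evening_onset(average_day_profile(s, range(3), schedule))
                    for s in cohort]
            vals = [x for x in vals if x is not None]
            return np.mean(vals)

        assert mean_onset(a) - mean_onset(b) == pytest.approx(1.5, abs=0.5)


class TestDdPhase:
    def test_burst_centred_at_ct15(self, make_series, schedule):
        counts = np.zeros(48 * 10, dtype=int)
        day4 = 48 * (3 + 3)  # fourth DD day starts after 3 LD + 3 DD days
        counts[day4 + 29: day4 + 32] = (5, 9, 5)  # CT14.5, 15.0, 15.5
        assert dd_phase(make_series(counts), schedule) == pytest.approx(15.0)

    def test_all_zero_day_absent(self, make_series, schedule):
        counts = np.ones(48 * 10, dtype=int)
        day4 = 48 * 6
        counts[day4: day4 + 48] = 0
        assert dd_phase(make_series(counts), schedule) is None

    def test_width_one_smoothing_is_raw_argmax(self, make_series, schedule):
        rng = np.random.default_rng(9)
        counts = rng.poisson(4, 48 * 10)
        s = make_series(counts)
        day4 = 48 * 6
        raw = np.argmax(counts[day4: day4 + 48])
        assert dd_phase(s, schedule, smooth_bins=1) == pytest.approx(raw * 0.5)


class TestSleep:
    def test_all_zero_day_sleeps_full_day(self, make_series, schedule):
        s = make_series([0] * 288 * 3, bin_minutes=5)
        assert sleep_summary(s, schedule, 0) == (1440.0, 720.0, 720.0)

    def test_alternating_bins_sleep_half_day(self, make_series, schedule):
        s = make_series([1, 0] * 144, bin_minutes=5)
        total, _, _ = sleep_summary(s, schedule, 0)
        assert total == 720.0

    def test_single_thirty_minute_nap(self, make_series, schedule):
        counts = np.ones(288, dtype=int)
        counts[100:106] = 0
        total, _, _ = sleep_summary(make_series(counts, bin_minutes=5), schedule, 0)
        assert total == 30.0

    def test_rejects_coarse_bins(self, make_series, schedule):
        with pytest.raises(ValueError, match="5-min"):
            sleep_summary(make_series([0] * 48), schedule, 0)

    def test_sleep_and_activity_partition_the_day(self, schedule):
        series, _ = simulate_cohort(5, FlyParams(), 0.2, schedule, seed=33)
        for s in series:
            day = s.counts[:288]
            total, d, n = sleep_summary(s, schedule, 0)
            assert d + n == total
            assert total + 5 * int((day > 0).sum()) == 1440
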