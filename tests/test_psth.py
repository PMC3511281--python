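import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spikelight import (
    Alignment,
    DetectionConfig,
    ResponseCategory,
    build_psth,
    detect_response,
    latency_to_peak,
    normalize_population,
    post_train_suppression,
    response_magnitude,
    simulate_session,
)
from spikelight.psth import InsufficientDataError
from spikelight.simulate import RESPONSE_FIXTURES, CellKind, CellProfile, SimConfig

from conftest import make_psth, make_train
from oracles import oracle_detect

ALTERNATING_BASELINE = [8, 12] * 20  # mu = 10, sample SD ~ 2.03


class TestBuildPsth:
    def test_direct_bin_placement(self):
        t = make_train([10.004], end=20.0)  # 4 ms after the event
        psth = build_psth(t, [10.0], bin_width=8.125, n_pre=40, n_post=40)
        assert psth.counts[40] == 1
        assert psth.counts.sum() == 1

    def test_empty_train_gives_all_zero_counts(self):
        t = make_train([], end=20.0)
        psth = build_psth(t, [10.0], bin_width=8.125, n_pre=40, n_post=40)
        assert psth.counts.sum() == 0

    def test_left_closed_right_open_bins(self):
        # spike exactly at the event goes to the first post bin; a spike at
        # the right window edge is excluded
        t = make_train([10.0, 10.325], end=20.0)
        psth = build_psth(t, [10.0], bin_width=8.125, n_pre=40, n_post=40)
        assert psth.counts[40] == 1
        assert psth.counts.sum() == 1

    def test_events_outside_recording_dropped_with_warning(self):
        t = make_train([5.0], end=20.0)
        with pytest.warns(UserWarning, match="dropping"):
            psth = build_psth(t, [0.1, 10.0], bin_width=8.125, n_pre=40, n_post=40)
        assert psth.n_trials == 1

    def test_no_usable_events_raises(self):
        t = make_train([5.0], end=20.0)
        with pytest.raises(InsufficientDataError):
            build_psth(t, [0.1], bin_width=8.125, n_pre=40, n_post=40)

    def test_poisson_rate_recovered_in_bins(self):
        """A 100 spikes/s unit yields ~40.6 expected counts per bin over 50 trials."""
        profile = CellProfile(CellKind.FSN, baseline_rate=100.0, target_cv=1.0)
        from spikelight import simulate_baseline_train

        ts = simulate_baseline_train(profile, 52.0, seed=42)
        t = make_train(ts, end=52.0)
        psth = build_psth(t, np.arange(1.0, 51.0), bin_width=8.125,
                          n_pre=40, n_post=40)
        expected = 100 * 0.008125 * 50  # 40.625
        assert abs(psth.counts.mean() - expected) / expected < 0.1


class TestDetectResponse:
    def test_flat_psth_is_none(self):
        psth = make_psth([10] * 80, n_pre=40)
        res = detect_response(psth)
        assert res.category is ResponseCategory.NONE
        assert "sigma_zero" in res.flags

    def test_constructed_increase_run(self):
        post = [10] * 40
        post[5:8] = [30, 31, 29]
        psth = make_psth(ALTERNATING_BASELINE + post, n_pre=40)
        res = detect_response(psth)
        assert res.category is ResponseCategory.INCREASE
        assert (5, 1) in res.significant_bins

    def test_increase_then_decrease_is_combination(self):
        post = [10] * 40
        post[2:4] = [30, 31]
        post[20:22] = [0, 0]
        psth = make_psth(ALTERNATING_BASELINE + post, n_pre=40)
        res = detect_response(psth)
        assert res.category is ResponseCategory.COMBINATION

    def test_single_exceeding_bin_is_not_a_run(self):
        post = [10] * 40
        post[5] = 100
        psth = make_psth(ALTERNATING_BASELINE + post, n_pre=40)
        assert detect_response(psth).category is ResponseCategory.NONE

    def test_few_trials_flagged_provisional(self):
        psth = make_psth([10] * 80, n_pre=40, n_trials=20)
        assert "provisional" in detect_response(psth).flags

    @settings(max_examples=200, deadline=None)
    @given(
        counts=st.lists(st.integers(0, 6), min_size=12, max_size=12),
    )
    def test_matches_bruteforce_run_scanner(self, counts):
        psth = make_psth(counts, n_pre=6)
        got = detect_response(psth).category.value
        assert got == oracle_detect(counts, n_pre=6)

    @settings(max_examples=100, deadline=None)
    @given(
        data=st.data(),
        counts=st.lists(st.integers(0, 8), min_size=16, max_size=16),
    )
    def test_adding_stimulation_spikes_never_cancels_increase(self, data, counts):
        """Extra spikes inside the stimulation window cannot turn INCREASE off."""
        psth = make_psth(counts, n_pre=8)
        if detect_response(psth).category is not ResponseCategory.INCREASE:
            return
        extra = data.draw(st.lists(st.integers(0, 5), min_size=8, max_size=8))
        boosted = list(counts)
        for i, e in enumerate(extra):
            boosted[8 + i] += e
        assert (
            detect_response(make_psth(boosted, n_pre=8)).category
            is ResponseCategory.INCREASE
        )

    def test_null_false_positive_rate_stable_across_rates(self):
        """Detector FPR is rate-independent for tonic baselines (5-60 Hz)."""
        from spikelight import Chr2Kinetics

        kin = Chr2Kinetics()
        fprs = []
        for rate in (5.0, 20.0, 60.0):
            profile = CellProfile(CellKind.TAN, rate, 1.0)
            fp = 0
            n = 400
            for i in range(n):
                unit, proto, _ = simulate_session(
                    profile, kin, SimConfig(seed=50_000 + i, n_trains=50)
                )
                psth = build_psth(unit, proto.train_onsets(), 8.125, 40, 40)
                fp += detect_response(psth).category is not ResponseCategory.NONE
            fprs.append(fp / n)
        assert max(fprs) - min(fprs) <= 0.06


class TestResponseMagnitude:
    @pytest.mark.parametrize(
        "pre_total, post_total, expected",
        [(100, 100, 1.0), (10, 450, 45.0), (0, 50, 50.0)],
    )
    def test_fold_change_with_baseline_floor(self, pre_total, post_total, expected):
        pre = [pre_total // 20] * 20
        pre[0] += pre_total - sum(pre)
        post = [post_total // 20] * 20
        post[0] += post_total - sum(post)
        psth = make_psth(pre + post, n_pre=20)
        assert response_magnitude(psth) == pytest.approx(expected)

    def test_zero_baseline_flagged_by_detector(self):
        counts = [0] * 40 + [0] * 10 + [20, 21] + [0] * 28
        res = detect_response(make_psth(counts, n_pre=40))
        assert res.category is ResponseCategory.INCREASE
        assert "zero_baseline" in res.flags
        assert res.magnitude == pytest.approx(41.0)

    def test_magnitude_invariant_to_trial_order(self, rng):
        trials = rng.poisson(2.0, size=(30, 40))
        counts = trials.sum(axis=0)
        shuffled = trials[rng.permutation(30)].sum(axis=0)
        a = response_magnitude(make_psth(counts, n_pre=20, n_trials=30))
        b = response_magnitude(make_psth(shuffled, n_pre=20, n_trials=30))
        assert a == b


class TestLatencyToPeak:
    def test_spike_at_5_1_ms_lands_in_bin_center_5_125(self):
        events = np.arange(1.0, 51.0)
        t = make_train(events + 0.0051, end=60.0)
        psth = build_psth(t, events, bin_width=0.25, n_pre=40, n_post=80,
                          alignment=Alignment.PULSE_ONSET)
        assert latency_to_peak(psth) == pytest.approx(5.125)

    def test_flat_response_ties_to_earliest_bin(self):
        psth = make_psth([0] * 10 + [3] * 10, n_pre=10, bin_width=0.25)
        assert latency_to_peak(psth) == pytest.approx(0.125)

    def test_silent_post_window_is_undefined(self):
        psth = make_psth([1] * 10 + [0] * 10, n_pre=10, bin_width=0.25)
        with pytest.warns(UserWarning):
            assert latency_to_peak(psth) is None

    def test_transient_profile_peaks_within_5_ms(self):
        """Rapid thalamic-type responders peak in the first 5 ms of the pulse."""
        from spikelight import Chr2Kinetics

        profile = RESPONSE_FIXTURES["vl_transient"]
        hits = 0
        n = 100
        for i in range(n):
            unit, proto, _ = simulate_session(
                profile, Chr2Kinetics(), SimConfig(seed=60_000 + i, n_trains=50)
            )
            psth = build_psth(unit, proto.train_onsets(), 0.25, 100, 100,
                              alignment=Alignment.PULSE_ONSET)
            lat = latency_to_peak(psth)
            hits += lat is not None and lat < 5.0
        assert hits >= 0.9 * n


class TestNormalizePopulation:
    def test_single_unit_normalizes_to_unit_max(self):
        psth = make_psth([1, 2, 8, 4], n_pre=2)
        trace = normalize_population([psth])
        assert trace.max() == pytest.approx(1.0)
        assert trace[2] == pytest.approx(1.0)

    def test_two_identical_units_average_to_same_trace(self):
        p = make_psth([1, 2, 8, 4], n_pre=2)
        assert np.allclose(normalize_population([p, p]), normalize_population([p]))

    def test_distinct_peaks_both_visible(self):
        early = make_psth([0] * 4 + [10, 1, 1, 1, 1, 1, 1, 1], n_pre=4,
                          bin_width=1.0)
        late = make_psth([0] * 4 + [1, 1, 1, 1, 1, 1, 1, 10], n_pre=4,
                         bin_width=1.0)
        trace = normalize_population([early, late])
        assert trace[4] > trace[6] and trace[11] > trace[6]

    def test_all_zero_unit_excluded_with_warning(self):
        good = make_psth([1, 2, 8, 4], n_pre=2)
        silent = make_psth([0, 0, 0, 0], n_pre=2)
        with pytest.warns(UserWarning, match="all-zero"):
            trace = normalize_population([good, silent])
        assert trace.max() == pytest.approx(1.0)


class TestPostTrainSuppression:
    def _psth(self, post):
        return make_psth(ALTERNATING_BASELINE + post, n_pre=40)

    def test_no_subthreshold_run_returns_none(self):
        psth = self._psth([10] * 96)
        assert post_train_suppression(psth, train_duration_ms=320.0) is None

    def test_five_bin_run_is_40_625_ms(self):
        post = [10] * 96
        post[40:45] = [0] * 5  # first bins fully after the 320 ms train
        psth = self._psth(post)
        assert post_train_suppression(psth, 320.0) == pytest.approx(40.625)

    def test_window_too_short_raises(self):
        psth = make_psth(ALTERNATING_BASELINE + [10] * 40, n_pre=40)
        with pytest.raises(ValueError, match="400 ms"):
            post_train_suppression(psth, 320.0)

    def test_simulated_suppression_duration_recovered(self):
        """Deep 150 ms post-train suppression is recovered within 50 ms."""
        from spikelight import Chr2Kinetics

        profile = RESPONSE_FIXTURES["vl_combination"]
        hits = 0
        n = 100
        for i in range(n):
            unit, proto, _ = simulate_session(
                profile, Chr2Kinetics(), SimConfig(seed=70_000 + i, n_trains=50)
            )
            psth = build_psth(unit, proto.train_onsets(), 8.125, 40, 96)
            dur = post_train_suppression(psth, proto.trains[0].span_s * 1000)
            hits += dur is not None and abs(dur - 150.0) <= 50.0
        assert hits >= 0.8 * n
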