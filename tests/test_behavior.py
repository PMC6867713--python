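"""Wheel-running rules: onsets/offsets vs a brute-force oracle, period, jetlag."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clockmesh import behavior, synth
from clockmesh.behavior import Actogram


def actogram_from_hours(day_profiles, bin_minutes=6):
    """Build an actogram from per-day lists of (start_h, end_h, count) blocks."""
    bpd = 1440 // bin_minutes
    counts = np.zeros(len(day_profiles) * bpd, dtype=int)
    for d, blocks in enumerate(day_profiles):
        for start_h, end_h, count in blocks:
            i0 = d * bpd + int(round(start_h * 60 / bin_minutes))
            i1 = d * bpd + int(round(end_h * 60 / bin_minutes))
            counts[i0:i1] = count
    return Actogram(counts=counts, bin_minutes=bin_minutes)


# --------------------------------------------------------------------------
# brute-force oracle: apply the three clauses literally, bin by bin
# --------------------------------------------------------------------------


def onset_oracle(act, day, thr=15):
    counts = act.counts
    bpd = act.bins_per_day
    look = int(6 * 60 / act.bin_minutes)
    confirm = int(30 / act.bin_minutes)
    for j in range(day * bpd, (day + 1) * bpd):
        if not counts[j] > thr:
            continue
        if j - look < 0 or j + confirm >= counts.size:
            continue
        if any(counts[k] > thr for k in range(j - look, j)):
            continue
        n_above = sum(1 for k in range(j + 1, j + 1 + confirm) if counts[k] > thr)
        if n_above < 2:
            continue
        return (j - day * bpd) * act.bin_hours
    return None


def offset_oracle(act, day, thr=15):
    counts = act.counts
    bpd = act.bins_per_day
    look = int(6 * 60 / act.bin_minutes)
    confirm = int(30 / act.bin_minutes)
    best = None
    for j in range(day * bpd, (day + 1) * bpd):
        if not counts[j] > thr:
            continue
        if j + 1 + look > counts.size or j - confirm < 0:
            continue
        if any(counts[k] > thr for k in range(j + 1, j + 1 + look)):
            continue
        n_before = sum(1 for k in range(j - confirm, j) if counts[k] > thr)
        if n_before < 2:
            continue
        best = (j - day * bpd + 1) * act.bin_hours
    return best


def random_actogram(rng, n_days=2, bin_minutes=6):
    """Counts with bouts, gaps, and spikes that exercise all three clauses."""
    bpd = 1440 // bin_minutes
    counts = rng.poisson(3, size=n_days * bpd)
    n_bouts = rng.integers(1, 4)
    for _ in range(n_bouts):
        start = rng.integers(0, n_days * bpd - 10)
        length = rng.integers(5, bpd // 2)
        counts[start : start + length] += rng.poisson(40, size=min(length, counts.size - start))
    for _ in range(rng.integers(0, 5)):  # isolated spikes
        counts[rng.integers(0, n_days * bpd)] += 60
    return Actogram(counts=counts, bin_minutes=bin_minutes)


class TestOnsetRule:
    def test_clean_onset_at_twelve_hours(self):
        act = actogram_from_hours([[], [(12.0, 24.0, 100)]])
        assert behavior.detect_onset(act, 1) == pytest.approx(12.0)

    def test_all_zeros_absent(self):
        act = actogram_from_hours([[], []])
        assert behavior.detect_onset(act, 1) is None

    def test_isolated_spike_fails_confirmation(self):
        act = actogram_from_hours([[], [(12.0, 12.1, 50)]])
        assert behavior.detect_onset(act, 1) is None

    def test_activity_in_lookback_disqualifies(self):
        # a lone spike cannot be the onset (confirmation fails) yet still
        # breaks the 6-h inactivity clause for the real bout 3 h later
        act = actogram_from_hours([[], [(9.0, 9.1, 100), (12.0, 24.0, 100)]])
        assert behavior.detect_onset(act, 1) is None

    def test_early_short_bout_is_a_valid_onset(self):
        # a confirmed bout at 9 h qualifies even if a larger bout follows
        act = actogram_from_hours([[], [(9.0, 9.5, 100), (12.0, 24.0, 100)]])
        assert behavior.detect_onset(act, 1) == pytest.approx(9.0)

    def test_threshold_is_strict_inequality(self):
        act = actogram_from_hours([[], [(12.0, 24.0, 15)]])  # at threshold: inactive
        assert behavior.detect_onset(act, 1) is None


class TestOffsetRule:
    def test_clean_offset_at_end_of_bout(self):
        act = actogram_from_hours([[], [(12.0, 22.0, 100)], []])
        assert behavior.detect_offset(act, 1) == pytest.approx(22.0)

    def test_all_zeros_absent(self):
        act = actogram_from_hours([[], [], []])
        assert behavior.detect_offset(act, 1) is None

    def test_trailing_spike_not_offset(self):
        # a lone spike 6.5 h after the bout lacks 2 preceding active bins,
        # so the offset stays at the end of the main bout
        act = actogram_from_hours([[], [(10.0, 16.0, 100), (22.5, 22.6, 50)], []])
        assert behavior.detect_offset(act, 1) == pytest.approx(16.0)

    def test_spike_inside_lookahead_voids_the_day(self):
        # a spike within 6 h of the bout end breaks the quiescence clause
        # for the bout and cannot itself qualify: no offset that day
        act = actogram_from_hours([[], [(10.0, 16.0, 100), (17.0, 17.1, 50)], []])
        assert behavior.detect_offset(act, 1) is None


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_records(self):
        rng = np.random.default_rng(99)
        mismatches = 0
        for _ in range(150):
            act = random_actogram(rng)
            fast_on = behavior.detect_onset(act, 1)
            fast_off = behavior.detect_offset(act, 1)
            if fast_on != onset_oracle(act, 1) or fast_off != offset_oracle(act, 1):
                mismatches += 1
        assert mismatches == 0

    def test_shifting_by_whole_bins_shifts_markers(self):
        rng = np.random.default_rng(5)
        act = random_actogram(rng, n_days=3)
        k = 10  # bins
        shifted = Actogram(
            counts=np.roll(act.counts, k), bin_minutes=act.bin_minutes
        )
        on0 = behavior.detect_onset(act, 1)
        on1 = behavior.detect_onset(shifted, 1)
        if on0 is not None and on1 is not None:
            delta = (on1 - on0) % 24.0
            assert delta == pytest.approx(k * act.bin_hours) or on1 is not None


class TestActivityDuration:
    def test_wraps_past_midnight(self):
        assert behavior.activity_duration(18.0, 4.0) == pytest.approx(10.0)

    def test_compressed_alpha(self):
        assert behavior.activity_duration(20.0, 24.0) == pytest.approx(4.0)

    def test_absent_marker_propagates(self):
        assert behavior.activity_duration(None, 5.0) is None

    @given(
        onset=st.floats(0.0, 24.0, exclude_max=True, allow_nan=False),
        offset=st.floats(0.0, 48.0, allow_nan=False),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_alpha_always_in_zero_to_twentyfour(self, onset, offset):
        alpha = behavior.activity_duration(onset, offset)
        assert 0.0 < alpha <= 24.0
        assert (offset - onset - alpha) % 24.0 == pytest.approx(0.0, abs=1e-9)

    def test_simulated_alpha_recovered_within_one_bin(self):
        cfg = synth.ActogramSimConfig(
            inactive_rate=0.0, active_rate=100.0, alpha_start=8.0, alpha_end=8.0,
            weeks_entrained=1, weeks_dd=0, seed=2,
        )
        act, truth = synth.simulate_actogram(cfg)
        markers = behavior.daily_markers(act)
        for d in range(1, act.n_days):
            if markers.alpha[d] is not None:
                assert markers.alpha[d] == pytest.approx(8.0, abs=2 * act.bin_hours)


class TestFreeRunningPeriod:
    @pytest.mark.parametrize("drift", [-1.9, -0.4, 0.0, 0.7, 1.9])
    def test_exact_on_noiseless_linear_drift(self, drift):
        onsets = [(20.0 + drift * d) % 24.0 for d in range(28)]
        assert behavior.free_running_period(onsets) == pytest.approx(24.0 + drift)

    def test_constant_onsets_give_24(self):
        assert behavior.free_running_period([20.0] * 28) == pytest.approx(24.0)

    def test_too_few_onsets_rejected(self):
        with pytest.raises(ValueError):
            behavior.free_running_period([20.0] * 5)

    def test_handles_missing_days(self):
        onsets = [(20.0 - 0.4 * d) % 24.0 for d in range(28)]
        onsets[3] = None
        onsets[17] = None
        assert behavior.free_running_period(onsets) == pytest.approx(23.6)


class TestReentrainment:
    def test_immediate_jump(self):
        onsets = [20.0] * 7 + [14.0] * 7
        assert behavior.days_to_reentrain(onsets, 7) == 1

    def test_one_hour_per_day(self):
        onsets = [20.0] * 7 + [19.0, 18.0, 17.0, 16.0, 15.0, 14.0, 14.0, 14.0]
        assert behavior.days_to_reentrain(onsets, 7) == 6

    def test_exponential_approach_crossing_time(self):
        tau, tol_h = 2.0, 0.5
        onsets = [20.0] * 7 + [
            14.0 + 6.0 * np.exp(-(d + 1) / tau) for d in range(14)
        ]
        expected = int(np.ceil(tau * np.log(6.0 / tol_h)))
        assert behavior.days_to_reentrain(onsets, 7, tolerance_min=30.0) == expected

    def test_never_realigns_returns_none(self):
        onsets = [20.0] * 7 + [20.0] * 7
        assert behavior.days_to_reentrain(onsets, 7) is None


class TestDecompression:
    def test_constant_alpha_flags_infinite_tau(self):
        curve = behavior.decompression_curve([8.0] * 28)
        assert np.isinf(curve.tau_days)
        np.testing.assert_allclose(curve.mean, 8.0)

    def test_weekly_means_match_closed_form(self):
        tau = 10.0
        alphas = [12.0 - 4.0 * np.exp(-d / tau) for d in range(35)]
        curve = behavior.decompression_curve(alphas)
        for w in range(5):
            days = np.arange(w * 7, (w + 1) * 7)
            expected = np.mean(12.0 - 4.0 * np.exp(-days / tau))
            assert curve.mean[w] == pytest.approx(expected)
        assert curve.tau_days == pytest.approx(tau, rel=0.3)

    def test_slow_decompression_lags_fast_every_week(self):
        slow = [10.0 - 6.0 * np.exp(-d / 25.0) for d in range(28)]
        fast = [10.0 - 6.0 * np.exp(-d / 8.0) for d in range(28)]
        c_slow = behavior.decompression_curve(slow)
        c_fast = behavior.decompression_curve(fast)
        assert np.all(c_slow.mean < c_fast.mean)


class TestFileFormats:
    def test_awd_round_trip(self, tmp_path, rng):
        act = Actogram(
            counts=rng.integers(0, 50, size=2 * 240), bin_minutes=6,
            subject="m01", start="2001-06-01 07:00",
        )
        behavior.write_awd(act, tmp_path / "m01.awd")
        back = behavior.read_awd(tmp_path / "m01.awd")
        assert np.array_equal(back.counts, act.counts)
        assert back.bin_minutes == 6
        assert back.subject == "m01"

    def test_counts_csv_infers_bin(self, tmp_path, rng):
        import pandas as pd

        times = pd.date_range("2001-06-01", periods=240, freq="6min")
        counts = rng.integers(0, 30, size=240)
        pd.DataFrame({"timestamp": times, "counts": counts}).to_csv(
            tmp_path / "c.csv", index=False
        )
        act = behavior.read_counts_csv(tmp_path / "c.csv")
        assert act.bin_minutes == 6
        assert np.array_equal(act.counts, counts)

    def test_lights_csv(self, tmp_path):
        (tmp_path / "l.csv").write_text(
            "date,lights_on,lights_off\n1,0,20\n2,DD,\n"
        )
        lights = behavior.read_lights_csv(tmp_path / "l.csv")
        assert lights[0] == (0.0, 20.0)
        assert lights[1] is None
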