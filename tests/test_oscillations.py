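import numpy as np
import pytest

import ripplecoord as rc
from ripplecoord.data_model import StateIntervals
from ripplecoord.oscillations import (
    DEFAULT_BANDS,
    UpDownIntervals,
    bandpass_zero_phase,
    classify_ripple_size,
    detect_updown,
    peri_event_spectrogram,
    pre_post_power_ratio,
    ripple_envelope,
    ripple_onset_trough_lags,
    updown_probability_around,
)

FS = 2000.0


def _sws(dur):
    return StateIntervals([(0.0, dur, "SWS")])


class TestBandpass:
    def test_passband_tone_preserved_and_unshifted(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 180.0 * t)
        y = bandpass_zero_phase(x, FS, 150, 250)
        mid = slice(int(FS), int(3 * FS))
        assert np.max(np.abs(y[mid])) == pytest.approx(1.0, rel=0.05)
        # zero phase: peak positions displaced < 1 sample
        xp = np.flatnonzero((x[mid][1:-1] > x[mid][:-2]) & (x[mid][1:-1] > x[mid][2:]))
        yp = np.flatnonzero((y[mid][1:-1] > y[mid][:-2]) & (y[mid][1:-1] > y[mid][2:]))
        assert np.max(np.abs(xp - yp)) <= 1

    def test_stopband_tone_attenuated_20db(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 50.0 * t)
        y = bandpass_zero_phase(x, FS, 150, 250)
        mid = slice(int(FS), int(3 * FS))
        assert 20 * np.log10(np.max(np.abs(y[mid]))) < -20

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass_zero_phase(np.zeros(4000), FS, 150, 250), 0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_zero_phase(np.zeros(4000), FS, 250, 150)


class TestEnvelope:
    def test_constant_tone_envelope_near_amplitude(self):
        t = np.arange(int(4 * FS)) / FS
        env = ripple_envelope(3.0 * np.sin(2 * np.pi * 180.0 * t), FS)
        mid = slice(int(FS), int(3 * FS))
        assert np.allclose(env[mid], 3.0, rtol=0.02)

    def test_modulated_burst_peak_within_4ms_of_center(self):
        t = np.arange(int(2 * FS)) / FS
        center = 1.0
        mod = np.exp(-0.5 * ((t - center) / 0.02) ** 2)
        env = ripple_envelope(mod * np.sin(2 * np.pi * 180.0 * t), FS)
        assert abs(t[np.argmax(env)] - center) <= 0.004

    def test_zero_signal_zero_envelope(self):
        assert np.allclose(ripple_envelope(np.zeros(2000), FS), 0)


class TestRippleSize:
    @pytest.mark.parametrize(
        "depth,expected",
        [(9.0, "LARGE"), (8.5, "LARGE"), (7.0, "MEDIUM"), (6.5, "MEDIUM"),
         (5.0, "SMALL"), (4.5, "SMALL"), (4.0, None), (2.0, None)],
    )
    def test_thresholds(self, depth, expected):
        assert classify_ripple_size(depth) == expected


def _noise_with_burst(rng, dur=60.0, burst_t=30.0, amp_sd=7.0, burst_dur=0.05):
    """Pink-ish noise plus a Hann-windowed 180 Hz burst of known SD amplitude."""
    n = int(dur * FS)
    x = rng.normal(0, 20.0, n)
    bp = bandpass_zero_phase(x, FS, 150, 250)
    sd = bp.std()
    nb = int(burst_dur * FS) | 1
    tb = (np.arange(nb) - nb // 2) / FS
    burst = -np.hanning(nb) * np.cos(2 * np.pi * 180.0 * tb)
    i = int(burst_t * FS)
    x[i - nb // 2 : i + nb // 2 + 1] += amp_sd * sd * burst
    return x


class TestDetectRipples:
    def test_injected_burst_detected_once_with_accurate_onset(self, rng):
        x = _noise_with_burst(rng)
        events = rc.detect_ripples(x, FS, _sws(60.0))
        assert len(events) == 1
        ev = events[0]
        # envelope crosses threshold within a few ms of the burst edge
        assert ev.onset == pytest.approx(30.0 - 0.025, abs=0.012)
        assert ev.trough_time == pytest.approx(30.0, abs=0.003)
        assert ev.trough_depth_sd == pytest.approx(7.0, rel=0.25)

    def test_10ms_burst_too_short(self, rng):
        x = _noise_with_burst(rng, burst_dur=0.010)
        assert rc.detect_ripples(x, FS, _sws(60.0)) == []

    def test_flat_noise_no_events(self, rng):
        x = rng.normal(0, 20.0, int(60 * FS))
        assert rc.detect_ripples(x, FS, _sws(60.0)) == []

    def test_scale_invariance(self, rng):
        x = _noise_with_burst(rng)
        a = rc.detect_ripples(x, FS, _sws(60.0))
        b = rc.detect_ripples(x * 37.2, FS, _sws(60.0))
        assert [e.trough_time for e in a] == [e.trough_time for e in b]
        assert [e.size for e in a] == [e.size for e in b]

    def test_short_eligible_time_rejected(self, rng):
        x = rng.normal(0, 20.0, int(60 * FS))
        with pytest.raises(ValueError):
            rc.detect_ripples(x, FS, StateIntervals([(0.0, 5.0, "SWS")]))

    def test_size_classes_partition_events(self, detected_ripples):
        counts = {s: sum(e.size == s for e in detected_ripples)
                  for s in ("LARGE", "MEDIUM", "SMALL")}
        assert sum(counts.values()) == len(detected_ripples)

    def test_events_sorted_and_well_formed(self, detected_ripples):
        onsets = [e.onset for e in detected_ripples]
        assert onsets == sorted(onsets)
        for e in detected_ripples:
            e.validate()

    def test_time_reversal_leaves_trough_times_fixed(self, rng):
        """Zero-phase filtering: detection commutes with time reversal."""
        x = _noise_with_burst(rng, dur=40.0, burst_t=17.0)
        fwd = rc.detect_ripples(x, FS, _sws(40.0))
        rev = rc.detect_ripples(x[::-1], FS, _sws(40.0))
        assert len(fwd) == len(rev) == 1
        reflected = (x.size - 1) / FS - rev[0].trough_time
        assert abs(reflected - fwd[0].trough_time) <= 1.0 / FS


class TestUpDown:
    def test_slow_sinusoid_alternating_quarter_cycles(self):
        t = np.arange(int(60 * FS)) / FS
        x = 100.0 * np.sin(2 * np.pi * 1.0 * t)
        ud = detect_updown(x, FS, _sws(60.0))
        ups, downs = ud.pairs("UP"), ud.pairs("DOWN")
        assert len(ups) >= 50 and len(downs) >= 50
        # threshold at 1 SD = A/sqrt(2): each excursion lasts a quarter cycle
        for s, e in ups[1:-1]:
            assert e - s == pytest.approx(0.25, abs=0.02)
        starts = sorted([(s, "UP") for s, _ in ups] + [(s, "DOWN") for s, _ in downs])
        assert all(a[1] != b[1] for a, b in zip(starts, starts[1:]))

    def test_flat_signal_no_intervals(self):
        assert len(detect_updown(np.zeros(int(30 * FS)), FS, _sws(30.0))) == 0

    def test_matches_brute_force_threshold_scan(self):
        """Detection equals a brute-force scan of the filtered trace, and
        above-threshold excursions <= 50 ms are rejected."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1.0, int(120 * FS))
        ud = detect_updown(x, FS, _sws(120.0))
        bp = bandpass_zero_phase(x, FS, 1, 4)
        mu, sd = bp.mean(), bp.std()
        for lab, sign in (("UP", 1), ("DOWN", -1)):
            above = sign * (bp - mu) > sd
            runs, start = [], None
            for i, a in enumerate(np.append(above, False)):
                if a and start is None:
                    start = i
                elif not a and start is not None:
                    runs.append((start / FS, i / FS))
                    start = None
            brief = [r for r in runs if r[1] - r[0] <= 0.050 + 1e-9]
            kept = [r for r in runs if r[1] - r[0] > 0.050 + 1e-9]
            assert brief, "noise should produce some sub-50 ms excursions"
            got = ud.pairs(lab)
            assert len(got) == len(kept)
            for (s1, e1), (s2, e2) in zip(got, kept):
                assert s1 == pytest.approx(s2, abs=1.0 / FS)
                assert e1 == pytest.approx(e2, abs=1.0 / FS)


class TestUpDownProbability:
    def test_up_everywhere_probability_one(self):
        ud = UpDownIntervals(intervals=[(0.0, 100.0, "UP")], extremum_times=[50.0])
        centers, p_up, p_down = updown_probability_around([50.0, 60.0], ud)
        assert np.allclose(p_up, 1.0)
        assert np.allclose(p_down, 0.0)

    def test_ripples_at_up_to_down_transitions(self, default_recording,
                                               scored_states, trough_times):
        rec, _ = default_recording
        ud = detect_updown(rec.lfp_rsc, rec.fs_rsc, scored_states)
        centers, p_up, p_down = updown_probability_around(trough_times, ud)
        assert p_up[centers < -0.05].mean() > p_up[centers > 0.05].mean()
        assert p_down[centers > 0.05].mean() > p_down[centers < -0.05].mean()

    def test_no_events_is_an_error(self):
        ud = UpDownIntervals(intervals=[(0.0, 1.0, "UP")], extremum_times=[0.5])
        with pytest.raises(ValueError):
            updown_probability_around([], ud)


@pytest.fixture(scope="module")
def stationary():
    rng = np.random.default_rng(5)
    x = rng.normal(size=int(240 * FS))
    events = np.sort(rng.uniform(3.0, 237.0, 60))
    return x, events


class TestPeriEventSpectrogram:
    def test_baseline_columns_near_zero_mean(self, stationary):
        x, events = stationary
        spec = peri_event_spectrogram(x, FS, events)
        bl = (spec.times >= -1.0) & (spec.times < -0.5)
        assert np.abs(spec.z[:, bl].mean(axis=1)).max() < 0.5

    def test_column_mode_baseline_unit_sd_by_construction(self, stationary):
        x, events = stationary
        spec = peri_event_spectrogram(x, FS, events, baseline_stat="columns")
        bl = (spec.times >= -1.0) & (spec.times < -0.5)
        np.testing.assert_allclose(spec.z[:, bl].mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(spec.z[:, bl].std(axis=1), 1.0, rtol=1e-9)

    def test_injected_high_band_power_positive_z(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=int(240 * FS))
        events = np.sort(rng.uniform(3.0, 230.0, 40))
        t = np.arange(x.size) / FS
        for ev in events:  # 200 Hz tone for 300 ms after each event
            sel = (t >= ev) & (t < ev + 0.3)
            x[sel] += 2.0 * np.sin(2 * np.pi * 200.0 * t[sel])
        spec = peri_event_spectrogram(x, FS, events)
        rows = (spec.freqs >= 150) & (spec.freqs <= 300)
        post = (spec.times > 0.05) & (spec.times < 0.25)
        pre = spec.times < -0.3
        assert spec.z[np.ix_(rows, post)].mean() > 3
        assert abs(spec.z[np.ix_(rows, pre)].mean()) < 2

    def test_edge_events_dropped_with_count(self, stationary):
        x, events = stationary
        spec = peri_event_spectrogram(x, FS, np.concatenate([[0.2], events]))
        assert spec.n_dropped == 1
        assert spec.n_events == len(events)

    def test_too_few_events_rejected(self, stationary):
        x, _ = stationary
        with pytest.raises(ValueError):
            peri_event_spectrogram(x, FS, [10.0, 20.0])


class TestPrePostRatio:
    def test_post_high_band_boost_lowers_high_band_ratio(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=int(240 * FS))
        events = np.sort(rng.uniform(3.0, 230.0, 50))
        t = np.arange(x.size) / FS
        for ev in events:
            sel = (t >= ev) & (t < ev + 0.2)
            x[sel] += 2.0 * np.sin(2 * np.pi * 200.0 * t[sel])
        spec = peri_event_spectrogram(x, FS, events)
        ratios = pre_post_power_ratio(spec)
        assert len(ratios) == len(DEFAULT_BANDS)
        assert ratios[(150.0, 300.0)] < 0.5
        assert abs(ratios[(1.0, 4.0)] - 1.0) < 0.25

    def test_band_outside_axis_rejected(self, default_recording):
        rng = np.random.default_rng(9)
        x = rng.normal(size=int(120 * FS))
        events = np.sort(rng.uniform(3.0, 117.0, 20))
        spec = peri_event_spectrogram(x, FS, events)
        with pytest.raises(ValueError):
            pre_post_power_ratio(spec, bands=[(400.0, 500.0)])


class TestOnsetTroughLags:
    def test_constant_lag_fraction_one(self):
        events = [rc.RippleEvent(t, t + 0.04, t + 0.010, 7.0, "MEDIUM")
                  for t in (1.0, 2.0, 3.0)]
        *_, frac = ripple_onset_trough_lags(events)
        assert frac == 1.0

    def test_synthetic_recording_median_lag_in_band(self, detected_ripples):
        lags, _, _, frac = ripple_onset_trough_lags(detected_ripples)
        assert 5.0 <= np.median(lags) <= 30.0
        assert frac > 0.5

    def test_single_event_fraction_binary(self):
        ev = [rc.RippleEvent(1.0, 1.04, 1.035, 7.0, "MEDIUM")]
        *_, frac = ripple_onset_trough_lags(ev)
        assert frac in (0.0, 1.0)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            ripple_onset_trough_lags([])
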