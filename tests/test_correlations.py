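import numpy as np
import pytest
from scipy import stats

from ripplecoord.correlations import (
    Correlogram,
    classify_opto_response,
    classify_ripple_response,
    pairwise_ccg,
    peth,
    phase_locking_delay,
    size_stratified_rates,
    zscore_correlogram,
)
from ripplecoord.data_model import RippleEvent


class TestPeth:
    def test_poisson_train_flat_at_rate(self, rng):
        dur, rate = 2000.0, 8.0
        spikes = np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
        refs = np.sort(rng.uniform(5, dur - 5, 400))
        corr = peth(spikes, refs, bin_s=0.05, window=(-1.0, 1.0))
        # each bin is Poisson(rate * bin * n_ref) / (bin * n_ref)
        sem = np.sqrt(rate / (0.05 * refs.size))
        assert np.all(np.abs(corr.rate - rate) < 5 * sem)
        assert corr.rate.mean() == pytest.approx(rate, rel=0.05)

    def test_fixed_latency_spikes_fill_single_bin(self):
        refs = np.arange(1.0, 50.0, 1.0)
        spikes = np.sort(refs + 0.005)
        corr = peth(spikes, refs, bin_s=0.002, window=(-0.02, 0.02))
        nz = np.flatnonzero(corr.counts)
        expected = np.flatnonzero((corr.centers > 0.004) & (corr.centers < 0.006))
        assert nz.tolist() == expected.tolist()
        assert corr.counts[nz[0]] == refs.size

    def test_no_spikes_zero_histogram(self):
        corr = peth(np.empty(0), [1.0, 2.0], bin_s=0.01, window=(-0.1, 0.1))
        assert np.all(corr.rate == 0)

    def test_no_references_rejected(self):
        with pytest.raises(ValueError):
            peth([1.0], [], 0.01, (-0.1, 0.1))

    def test_uneven_bin_rejected(self):
        with pytest.raises(ValueError):
            peth([1.0], [2.0], 0.03, (-0.1, 0.1))


class TestZScore:
    def _corr(self, rate):
        rate = np.asarray(rate, dtype=float)
        edges = -1.0 + np.arange(rate.size + 1) * 0.01
        return Correlogram(edges=edges, rate=rate, counts=rate.copy(),
                           n_ref=100, bin_s=0.01)

    def test_formula_identity(self, rng):
        base = rng.normal(10.0, 2.0, 200)
        corr = self._corr(base)
        bl = (corr.centers >= -1.0) & (corr.centers < -0.5)
        mu, sd = base[bl].mean(), base[bl].std()
        corr.rate[120] = mu + 3.3 * sd
        zscore_correlogram(corr, (-1.0, -0.5))
        assert corr.z[120] == pytest.approx(3.3)

    def test_flat_histogram_zero_z(self):
        corr = self._corr(np.full(200, 7.0) + np.r_[np.tile([0.5, -0.5], 100)])
        zscore_correlogram(corr, (-1.0, -0.5))
        assert np.allclose(np.abs(corr.z), 1.0)
        assert corr.z[:50].mean() == pytest.approx(0.0, abs=1e-9)

    def test_affine_invariance_additive_rate(self, rng):
        base = rng.normal(10.0, 2.0, 200)
        a = zscore_correlogram(self._corr(base), (-1.0, -0.5))
        b = zscore_correlogram(self._corr(base + 5.0), (-1.0, -0.5))
        np.testing.assert_allclose(a.z, b.z)

    def test_zero_baseline_sd_names_unit(self):
        corr = self._corr(np.full(200, 3.0))
        with pytest.raises(ValueError, match="u77"):
            zscore_correlogram(corr, (-1.0, -0.5), unit_id="u77")

    def test_too_few_baseline_bins_rejected(self, rng):
        corr = self._corr(rng.normal(10, 2, 200))
        with pytest.raises(ValueError):
            zscore_correlogram(corr, (-1.0, -0.95))


class TestRippleResponse:
    def test_synthetic_inhibitory_units_activated(self, default_recording,
                                                  trough_times):
        rec, truth = default_recording
        inh = [u for u in rec.units
               if truth.true_unit_labels.get(u.unit_id) == "INH"]
        calls = [classify_ripple_response(u.spike_times, trough_times,
                                          unit_id=u.unit_id) for u in inh]
        assert all(c.call == "ACTIVATED" for c in calls)
        assert all(c.peak_or_mean_z > 3.3 for c in calls)

    def test_onset_reference_reaches_same_calls(self, default_recording,
                                                detected_ripples, trough_times):
        """Onset- and trough-referenced calls agree when lags < bin size."""
        rec, truth = default_recording
        onsets = np.array([e.onset for e in detected_ripples])
        inh = [u for u in rec.units
               if truth.true_unit_labels.get(u.unit_id) == "INH"]
        for u in inh:
            a = classify_ripple_response(u.spike_times, trough_times)
            b = classify_ripple_response(u.spike_times, onsets)
            assert a.call == b.call == "ACTIVATED"

    def test_independent_poisson_unit_none(self, rng, trough_times):
        spikes = np.sort(rng.uniform(0, 540.0, 8000))
        assert classify_ripple_response(spikes, trough_times).call == "NONE"


def _pulse_trains(n_trains, iti=12.0, start=5.0):
    out = []
    t = start
    for _ in range(n_trains):
        out += [t, t + 0.04, t + 0.08]
        t += iti
    return np.array(out)


class TestOptoResponse:
    def test_fixed_latency_unit_activated_with_latency(self, rng):
        pulses = _pulse_trains(250)
        dur = pulses[-1] + 10
        base = np.sort(rng.uniform(0, dur, int(10 * dur)))
        resp = np.sort(np.concatenate(
            [base, pulses + 0.004 + rng.normal(0, 0.0005, pulses.size)]
        ))
        call = classify_opto_response(resp, pulses)
        assert call.call == "ACTIVATED"
        assert call.latency_ms == pytest.approx(4.0, abs=1.0)

    def test_silenced_unit_inhibited(self, rng):
        pulses = _pulse_trains(700, iti=10.0)
        dur = pulses[-1] + 10
        base = np.sort(rng.uniform(0, dur, int(50 * dur)))
        i0 = np.searchsorted(base, pulses)
        i1 = np.searchsorted(base, pulses + 0.020)
        mask = np.ones(base.size, bool)
        for a, b in zip(i0, i1):
            mask[a:b] = False
        call = classify_opto_response(base[mask], pulses)
        assert call.call == "INHIBITED"
        assert call.peak_or_mean_z < -3.3

    def test_independent_unit_none(self, rng):
        pulses = _pulse_trains(200)
        dur = pulses[-1] + 10
        spikes = np.sort(rng.uniform(0, dur, int(15 * dur)))
        assert classify_opto_response(spikes, pulses).call == "NONE"

    def test_single_train_rejected(self):
        with pytest.raises(ValueError):
            classify_opto_response([1.0, 2.0], [5.0, 5.04, 5.08])


class TestPhaseLocking:
    def test_injected_delay_recovered(self, default_recording, trough_times):
        rec, truth = default_recording
        for uid, delay in truth.injected_delay_ms.items():
            u = next(u for u in rec.units if u.unit_id == uid)
            locked, est, details = phase_locking_delay(u.spike_times, trough_times)
            assert abs(est - delay) <= 0.5
            assert 150 <= details["peak_freq_hz"] <= 250

    def test_poisson_unit_not_locked(self, rng, trough_times):
        spikes = np.sort(rng.uniform(0, 540.0, 9000))
        locked, _, _ = phase_locking_delay(spikes, trough_times)
        assert not locked

    def test_too_few_ripples_rejected(self, rng):
        with pytest.raises(ValueError):
            phase_locking_delay(np.sort(rng.uniform(0, 10, 100)), np.arange(50))


class TestSizeStratified:
    def test_injected_monotone_post_rate(self, default_recording, detected_ripples):
        rec, truth = default_recording
        inh = [u for u in rec.units
               if truth.true_unit_labels.get(u.unit_id) == "INH"]
        post = {"LARGE": [], "MEDIUM": [], "SMALL": []}
        for u in inh:
            for size, (_pre, p) in size_stratified_rates(
                u.spike_times, detected_ripples
            ).items():
                post[size].append(p)
        means = {s: np.mean(v) for s, v in post.items() if v}
        assert means["LARGE"] > means["MEDIUM"] > means["SMALL"]

    def test_poisson_unit_flat_across_sizes(self, rng):
        events = []
        t = 10.0
        for i in range(900):
            size = ("LARGE", "MEDIUM", "SMALL")[i % 3]
            events.append(RippleEvent(t, t + 0.04, t + 0.02, 9.0, size))
            t += 2.0
        rate = 20.0
        spikes = np.sort(rng.uniform(0, t + 10, rng.poisson(rate * (t + 10))))
        out = size_stratified_rates(spikes, events)
        pres = [v[0] for v in out.values()]
        assert np.ptp(pres) < 0.35 * rate
        for pre, _post in out.values():
            assert pre == pytest.approx(rate, rel=0.3)

    def test_empty_class_absent_not_zero(self, rng):
        events = [RippleEvent(1.0, 1.04, 1.02, 7.0, "MEDIUM"),
                  RippleEvent(3.0, 3.04, 3.02, 5.0, "SMALL")]
        out = size_stratified_rates(np.sort(rng.uniform(0, 5, 50)), events)
        assert "LARGE" not in out
        assert set(out) == {"MEDIUM", "SMALL"}


class TestPairwiseCCG:
    def test_injected_excitation_called_at_positive_lag(self, rng):
        dur = 600.0
        a = np.sort(rng.uniform(0, dur, 6000))
        b = np.sort(rng.uniform(0, dur, 5000))
        extra = a[rng.random(a.size) < 0.3] + 0.0015
        corr, call = pairwise_ccg(a, np.sort(np.concatenate([b, extra])))
        assert call.call_ab == "ACTIVATED"
        assert call.call_ba == "NONE"
        assert not call.synchrony

    def test_injected_suppression_called_inhibition(self, rng):
        dur = 3600.0
        a = np.sort(rng.uniform(0, dur, 40000))
        b = np.sort(rng.uniform(0, dur, int(50 * dur)))
        # remove b spikes 0-2 ms after each a spike
        keep = np.ones(b.size, bool)
        i0, i1 = np.searchsorted(b, a + 0.0002), np.searchsorted(b, a + 0.002)
        for x, y in zip(i0, i1):
            keep[x:y] = False
        corr, call = pairwise_ccg(a, b[keep])
        assert call.call_ab == "INHIBITED"

    def test_common_input_flags_synchrony_without_direction(self, rng):
        drive = np.sort(rng.uniform(0, 600.0, 4000))
        x = np.sort(drive + rng.normal(0, 0.0003, drive.size))
        y = np.sort(drive + rng.normal(0, 0.0003, drive.size))
        corr, call = pairwise_ccg(x, y)
        assert call.synchrony
        assert call.call_ab == "NONE" and call.call_ba == "NONE"

    def test_insufficient_spikes_flagged(self, rng):
        corr, call = pairwise_ccg(np.sort(rng.uniform(0, 10, 50)),
                                  np.sort(rng.uniform(0, 10, 500)))
        assert call.insufficient

    def test_independent_pair_call_rate_matches_multibin_null(self):
        """Across many independent pairs, directional calls appear at roughly
        the multiple-bin false-positive rate of the z > 3.3 rule."""
        rng = np.random.default_rng(99)
        dur = 300.0
        n_calls = 0
        n_pairs = 60
        n_bins = 8  # 4 bins per direction within (0, 2] ms at 0.5 ms
        for _ in range(n_pairs):
            a = np.sort(rng.uniform(0, dur, 3000))
            b = np.sort(rng.uniform(0, dur, 3000))
            _, call = pairwise_ccg(a, b)
            n_calls += (call.call_ab != "NONE") + (call.call_ba != "NONE")
        p_bin = 2 * (1 - stats.norm.cdf(3.3))
        p_dir = 1 - (1 - p_bin) ** 4
        upper = stats.binom.ppf(0.999, 2 * n_pairs, 5 * p_dir)
        assert n_calls <= max(upper, 3)
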