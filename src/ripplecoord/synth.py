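"""Synthetic dual-site recordings with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: slow-wave-sleep (SWS) epochs carrying a ~1 Hz slow oscillation with
nested 150-250 Hz CA1 ripples, theta-dominated REM epochs, RSC slow waves
whose Up states host ripple-like fast bursts and precede ripples,
excitatory/inhibitory spike trains with distinct waveform families and
firing-rate ranges, inhibitory units phase-locked to ripple-cycle troughs at
a configurable monosynaptic delay, and a common population ON/OFF envelope
gating all RSC spiking during SWS.

Amplitude convention: injected ripple amplitudes are expressed in SD units
of the ripple-band-filtered background noise, so "an n-SD ripple" is
well-defined independently of the voltage scale. Ripple times are a
homogeneous Poisson process within eligible states with a 200 ms minimum
separation; a configurable fraction is placed just before ON-cluster
offsets so that RSC clusters and ripples co-terminate. Spike trains are
inhomogeneous Poisson (Bernoulli on a 1 ms grid) given their rate
envelopes; phase-locked spikes are injected per ripple cycle with
probability p_lock weighted by the burst envelope. One global seed feeds a
named sub-stream per component, so components can be regenerated
independently; the same seed yields byte-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .data_model import (
    GroundTruth,
    Recording,
    SpikeUnit,
    StateIntervals,
    SWS,
    REM,
    AWAKE_IMMOBILE,
)
from .oscillations import RIPPLE_BAND, bandpass_zero_phase
from .units import EXC, INH, OTHER

_STREAMS = (
    "noise_ca1",
    "noise_rsc",
    "states",
    "envelope",
    "ripples",
    "waveforms",
    "rates",
    "spikes",
    "opto",
)


@dataclass
class SynthConfig:
    duration_s: float = 600.0
    seed: int = 0
    n_exc_units: int = 16
    n_inh_units: int = 4
    n_other_units: int = 2
    n_ca1_units: int = 6
    n_onset_pref_units: int = 8        # excitatory units biased to fire first at cluster onsets
    ripple_rate_hz: float = 0.3        # within eligible (SWS) time
    ripple_freq_hz: float = 180.0
    ripple_dur_ms: float = 50.0
    ripple_amp_sd: float = 7.0         # mean trough depth, SD units of ripple-band background
    ripple_amp_jitter_sd: float = 1.2
    ripple_min_amp_sd: float = 4.5
    ripple_min_sep_s: float = 0.2
    ripple_offset_coupling: float = 0.6  # fraction of ripples placed at ON-cluster ends
    slow_osc_freq_hz: float = 1.0
    theta_freq_hz: float = 8.0
    inh_delay_ms: float = 4.6          # monosynaptic delay after ripple(-cycle) troughs
    inh_delay_jitter_ms: float = 0.9
    p_lock: float = 0.6
    exc_rate_hz: tuple = (3.0, 12.0)
    inh_rate_hz: tuple = (15.0, 30.0)
    ca1_rate_hz: tuple = (1.0, 3.0)
    off_period_range_ms: tuple = (100.0, 600.0)
    on_period_range_ms: tuple = (350.0, 900.0)
    state_schedule: list = field(default_factory=lambda: [(SWS, 180.0), (REM, 60.0)])
    fs_lfp: float = 2000.0
    fs_waveform: float = 30000.0
    noise_sd_uv: float = 30.0
    slow_osc_amp_uv: float = 60.0
    theta_amp_uv: float = 60.0
    n_opto_trains: int = 0
    opto_pulses_per_train: int = 3
    opto_pulse_rate_hz: float = 25.0

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_exc_units + self.n_inh_units + self.n_ca1_units <= 0:
            raise ValueError("config must request at least one unit")
        if not (0.0 < self.inh_delay_ms < 10.0):
            raise ValueError("inh_delay_ms must lie in (0, 10) ms")
        if not (150.0 <= self.ripple_freq_hz <= 250.0):
            raise ValueError("ripple_freq_hz must lie in [150, 250] Hz")
        for name in ("ripple_rate_hz", "slow_osc_freq_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("exc_rate_hz", "inh_rate_hz", "ca1_rate_hz"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive (lo, hi) range")


def _streams(seed: int) -> dict:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _pink_noise(rng, n: int, fs: float, sd: float) -> np.ndarray:
    """1/f-amplitude noise with a 1 Hz corner, scaled to the given SD."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    x = np.fft.irfft(spec * shaping, n=n)
    return x / x.std() * sd


def _schedule_states(config: SynthConfig) -> StateIntervals:
    out = []
    t = 0.0
    i = 0
    sched = config.state_schedule
    while t < config.duration_s - 1e-9:
        lab, dur = sched[i % len(sched)]
        end = min(t + dur, config.duration_s)
        out.append((t, end, lab))
        t = end
        i += 1
    return StateIntervals(out)


def _on_off_envelope(config: SynthConfig, states: StateIntervals, rng):
    """Alternating ON/OFF intervals inside each SWS epoch (starts ON)."""
    on_lo, on_hi = (v / 1e3 for v in config.on_period_range_ms)
    off_lo, off_hi = (v / 1e3 for v in config.off_period_range_ms)
    on_ivs, off_ivs = [], []
    for s, e, lab in states:
        if lab != SWS:
            continue
        t = s
        is_on = True
        while t < e - 1e-9:
            dur = rng.uniform(on_lo, on_hi) if is_on else rng.uniform(off_lo, off_hi)
            end = min(t + dur, e)
            # truncated terminal intervals are kept only if they retain structure
            if is_on:
                on_ivs.append((t, end))
            elif end - t >= off_lo:
                off_ivs.append((t, end))
            t = end
            is_on = not is_on
    return on_ivs, off_ivs


def _draw_ripple_times(config: SynthConfig, states: StateIntervals, on_ivs, rng):
    """Trough times and amplitudes; a coupled fraction sits at ON-cluster ends."""
    eligible = states.select((SWS, AWAKE_IMMOBILE)).pairs()
    elig_dur = sum(e - s for s, e in eligible)
    n_target = rng.poisson(config.ripple_rate_hz * elig_dur)
    margin = 1.2  # keep events clear of recording edges (spectrogram windows)
    usable_on = [
        (s, e)
        for s, e in on_ivs
        if e - s >= 0.15 and s > margin and e < config.duration_s - margin
    ]
    times = []

    def _far_enough(t):
        return all(abs(t - u) >= config.ripple_min_sep_s for u in times)

    n_coupled = int(round(config.ripple_offset_coupling * n_target))
    if usable_on:
        chosen = rng.choice(
            len(usable_on), size=min(n_coupled, len(usable_on)), replace=False
        )
        for k in chosen:
            t = usable_on[k][1] - 0.020
            if _far_enough(t):
                times.append(t)
    n_left = n_target - len(times)
    attempts = 0
    while n_left > 0 and attempts < 50 * n_target + 100 and usable_on:
        k = rng.integers(len(usable_on))
        s, e = usable_on[k]
        t = rng.uniform(s + 0.04, e - 0.04)
        if _far_enough(t):
            times.append(t)
            n_left -= 1
        attempts += 1
    times = np.sort(np.array(times))
    amps = rng.normal(config.ripple_amp_sd, config.ripple_amp_jitter_sd, times.size)
    amps = np.maximum(amps, config.ripple_min_amp_sd)
    return times, amps


def _hann_burst(fs: float, freq: float, dur_s: float):
    """Hann-windowed cosine burst with its deepest trough at the center."""
    n = int(round(dur_s * fs))
    n += (n + 1) % 2  # odd length, exact center sample
    t = (np.arange(n) - n // 2) / fs
    return -np.hanning(n) * np.cos(2 * np.pi * freq * t), n // 2


def _add_bursts(lfp, fs, times, amps_uv, freq, dur_s):
    burst, half = _hann_burst(fs, freq, dur_s)
    for t, a in zip(times, amps_uv):
        i = int(round(t * fs))
        lo, hi = i - half, i + half + 1
        if lo < 0 or hi > lfp.size:
            continue
        lfp[lo:hi] += a * burst


def generate_waveforms(n_exc: int, n_inh: int, seed=0, n_other: int = 0,
                       fs: float = 30000.0):
    """Mean-waveform families with per-unit noise and arbitrary amplitude.

    Wide (putative excitatory) templates have trough-to-peak widths of
    ~0.5-0.8 ms, narrow (putative inhibitory) ~0.15-0.3 ms with a fast
    after-hyperpolarization, and intermediate ("other") ~0.35-0.45 ms with an
    initial positive deflection. Widths are unimodal (clipped normal) within
    each family, emulating the compact per-class clusters real populations
    show in principal-component space. Returns ``(waveforms, labels)``.
    """
    if n_exc + n_inh + n_other < 2:
        raise ValueError("need at least two units")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_samp = int(round(1.6e-3 * fs))
    t = np.arange(n_samp) / fs * 1e3  # ms
    t_tr = 0.35

    def g(mu, s):
        return np.exp(-0.5 * ((t - mu) / s) ** 2)

    waves, labels = [], []
    specs = [(EXC, n_exc), (INH, n_inh), (OTHER, n_other)]
    for label, count in specs:
        for _ in range(count):
            if label == EXC:
                delta = float(np.clip(rng.normal(0.63, 0.055), 0.5, 0.8))
                w = -g(t_tr, 0.10 + 0.05 * rng.random()) + 0.5 * g(
                    t_tr + delta, 0.28 + 0.08 * rng.random()
                )
            elif label == INH:
                delta = float(np.clip(rng.normal(0.22, 0.035), 0.15, 0.3))
                w = (
                    -g(t_tr, 0.045 + 0.015 * rng.random())
                    + 0.65 * g(t_tr + delta, 0.08 + 0.03 * rng.random())
                    - 0.22 * g(t_tr + delta + 0.35, 0.15)
                )
            else:
                delta = float(np.clip(rng.normal(0.40, 0.025), 0.35, 0.45))
                w = (
                    0.35 * g(t_tr - 0.18, 0.06)
                    - g(t_tr, 0.08)
                    + 0.45 * g(t_tr + delta, 0.18 + 0.04 * rng.random())
                )
            w = w + gaussian_filter1d(rng.normal(0.0, 0.02, n_samp), 2)
            w *= rng.uniform(50.0, 400.0)  # uV; classification is scale-invariant
            waves.append(w)
            labels.append(label)
    return waves, labels


def generate_locked_spikes(rng, trough_times, amps_sd, delay_ms, jitter_ms,
                           p_lock, cycle_s, nominal_amp_sd=7.0,
                           cycle_weights=(0.25, 0.6, 1.0, 0.6, 0.25)):
    """Spikes phase-locked to ripple-cycle troughs at a fixed delay.

    For each ripple, candidate spikes sit at trough + k*cycle + delay for
    cycle offsets k centered on the deepest trough, emitted with probability
    p_lock scaled by the burst-envelope weight of that cycle and by ripple
    amplitude (relative to ``nominal_amp_sd``), with Gaussian timing jitter.
    """
    half = len(cycle_weights) // 2
    out = []
    for t0, amp in zip(np.atleast_1d(trough_times), np.atleast_1d(amps_sd)):
        gain = min(amp / nominal_amp_sd, 1.5)
        for k, wk in zip(range(-half, half + 1), cycle_weights):
            if rng.random() < p_lock * wk * gain:
                out.append(
                    t0 + k * cycle_s + delay_ms * 1e-3
                    + rng.normal(0.0, jitter_ms * 1e-3)
                )
    return np.array(sorted(out))


def _bernoulli_spikes(rng, rate, dt):
    """Inhomogeneous Poisson via Bernoulli thinning on a fixed grid."""
    p = np.clip(np.asarray(rate) * dt, 0.0, 0.95)
    hits = np.flatnonzero(rng.random(p.size) < p)
    return (hits + rng.random(hits.size)) * dt


def _clean_train(times, duration, forbidden=None):
    """Sort, clip to the session, drop duplicates and forbidden intervals."""
    times = np.asarray(times, dtype=float)
    times = times[(times >= 0) & (times < duration)]
    if forbidden:
        from . import _intervals

        times = times[~_intervals.contains(forbidden, times)]
    times = np.unique(times)
    return times


def generate_recording(config: SynthConfig):
    """Generate a dual-site recording and its ground truth.

    Returns ``(Recording, GroundTruth)``; identical configs (including seed)
    produce identical output.
    """
    config.validate()
    rngs = _streams(config.seed)
    fs = config.fs_lfp
    n = int(round(config.duration_s * fs))
    dt_grid = 1e-3
    n_grid = int(round(config.duration_s / dt_grid))
    grid_t = np.arange(n_grid) * dt_grid

    states = _schedule_states(config)
    on_ivs, off_ivs = _on_off_envelope(config, states, rngs["envelope"])
    ripple_times, ripple_amps = _draw_ripple_times(
        config, states, on_ivs, rngs["ripples"]
    )

    from . import _intervals

    sws_pairs = states.select(SWS).pairs()
    rem_pairs = states.select(REM).pairs()

    # ---- CA1 LFP -----------------------------------------------------------
    lfp_ca1 = _pink_noise(rngs["noise_ca1"], n, fs, config.noise_sd_uv)
    bp_noise = bandpass_zero_phase(lfp_ca1, fs, *RIPPLE_BAND)
    mask_sws = _intervals.sample_mask(sws_pairs, fs, n)
    sd_unit = bp_noise[mask_sws].std() if mask_sws.any() else bp_noise.std()
    t_lfp = np.arange(n) / fs
    if sws_pairs:
        slow = config.slow_osc_amp_uv * np.sin(
            2 * np.pi * config.slow_osc_freq_hz * t_lfp
        )
        lfp_ca1[mask_sws] += slow[mask_sws]
    mask_rem = _intervals.sample_mask(rem_pairs, fs, n)
    if mask_rem.any():
        theta = config.theta_amp_uv * np.sin(2 * np.pi * config.theta_freq_hz * t_lfp)
        lfp_ca1[mask_rem] += theta[mask_rem]
    _add_bursts(
        lfp_ca1, fs, ripple_times, ripple_amps * sd_unit,
        config.ripple_freq_hz, config.ripple_dur_ms / 1e3,
    )

    # ---- RSC LFP -----------------------------------------------------------
    lfp_rsc = _pink_noise(rngs["noise_rsc"], n, fs, config.noise_sd_uv)
    env_sig = np.zeros(n)
    for s, e in on_ivs:
        i0, i1 = int(round(s * fs)), min(n, int(round(e * fs)))
        env_sig[i0:i1] = 1.0
    for s, e in off_ivs:
        i0, i1 = int(round(s * fs)), min(n, int(round(e * fs)))
        env_sig[i0:i1] = -1.4
    env_sig = gaussian_filter1d(env_sig, sigma=0.040 * fs)
    lfp_rsc += 55.0 * env_sig
    # ripple-like fast bursts inside Up states, shortly before coupled ripples
    rsc_bp_sd = bandpass_zero_phase(lfp_rsc, fs, *RIPPLE_BAND)[mask_sws].std() if mask_sws.any() else 1.0
    _add_bursts(
        lfp_rsc, fs, ripple_times - 0.030,
        np.full(ripple_times.size, 3.0 * rsc_bp_sd),
        config.ripple_freq_hz, 0.030,
    )

    # ---- waveforms and unit labels ----------------------------------------
    waves, wave_labels = generate_waveforms(
        config.n_exc_units, config.n_inh_units, rngs["waveforms"],
        n_other=config.n_other_units, fs=config.fs_waveform,
    )
    ca1_waves, _ = generate_waveforms(
        max(config.n_ca1_units, 2), 0, rngs["waveforms"], fs=config.fs_waveform
    )

    # ---- spike trains ------------------------------------------------------
    rate_rng = rngs["rates"]
    spike_rng = rngs["spikes"]
    cycle_s = 1.0 / config.ripple_freq_hz

    sws_grid = _intervals.sample_mask(sws_pairs, 1.0 / dt_grid, n_grid)
    on_grid = np.zeros(n_grid, dtype=bool)
    for s, e in on_ivs:
        i0, i1 = int(round(s / dt_grid)), min(n_grid, int(round(e / dt_grid)))
        on_grid[i0:i1] = True
    gate = np.where(sws_grid, on_grid.astype(float), 1.0)
    gate_delayed = gate.copy()
    for s, _e in on_ivs:  # non-preferring units join clusters ~10 ms late
        i0 = int(round(s / dt_grid))
        gate_delayed[i0 : i0 + 10] = 0.0

    def ripple_modulation(base, pre_gain_per_sd, dip=True):
        """Rate envelope edits around each ripple trough."""
        r = base.copy()
        for t0, amp in zip(ripple_times, ripple_amps):
            i = int(round(t0 / dt_grid))
            r[max(0, i - 100) : i] *= 1.0 + pre_gain_per_sd * amp
            if dip:
                r[i + 20 : i + 80] *= 0.25   # ~50 ms post-ripple suppression
                r[i + 80 : i + 150] *= 1.8   # ~100 ms rebound
        return r

    units = []
    true_labels = {}
    injected_delay = {}
    onset_pref_ids = []
    off_forbidden = off_ivs

    exc_ids = [f"rsc_e{i:02d}" for i in range(config.n_exc_units)]
    inh_ids = [f"rsc_i{i:02d}" for i in range(config.n_inh_units)]
    other_ids = [f"rsc_o{i:02d}" for i in range(config.n_other_units)]
    wf_iter = iter(waves)
    lab_iter = iter(wave_labels)

    n_pref = min(config.n_onset_pref_units, config.n_exc_units)
    for j, uid in enumerate(exc_ids):
        base_rate = rate_rng.uniform(*config.exc_rate_hz)
        pref = j < n_pref
        g = gate if pref else gate_delayed
        rate = ripple_modulation(base_rate * g, pre_gain_per_sd=0.05, dip=True)
        spikes = _bernoulli_spikes(spike_rng, rate, dt_grid)
        if pref:
            onset_pref_ids.append(uid)
            for s, _e in on_ivs:
                if spike_rng.random() < 0.8:
                    spikes = np.append(spikes, s + spike_rng.uniform(0.0, 0.002))
        spikes = _clean_train(spikes, config.duration_s, off_forbidden)
        units.append(
            SpikeUnit(uid, spikes, next(wf_iter), config.fs_waveform, region="RSC")
        )
        true_labels[uid] = next(lab_iter)

    for uid in inh_ids:
        base_rate = rate_rng.uniform(*config.inh_rate_hz)
        rate = ripple_modulation(base_rate * gate, pre_gain_per_sd=0.05, dip=False)
        spikes = _bernoulli_spikes(spike_rng, rate, dt_grid)
        locked = generate_locked_spikes(
            spike_rng, ripple_times, ripple_amps,
            config.inh_delay_ms, config.inh_delay_jitter_ms,
            config.p_lock, cycle_s, nominal_amp_sd=config.ripple_amp_sd,
        )
        spikes = _clean_train(
            np.concatenate([spikes, locked]), config.duration_s, off_forbidden
        )
        units.append(
            SpikeUnit(uid, spikes, next(wf_iter), config.fs_waveform, region="RSC")
        )
        true_labels[uid] = next(lab_iter)
        injected_delay[uid] = config.inh_delay_ms

    for uid in other_ids:
        base_rate = rate_rng.uniform(2.0, 8.0)
        spikes = _bernoulli_spikes(spike_rng, base_rate * gate, dt_grid)
        spikes = _clean_train(spikes, config.duration_s, off_forbidden)
        units.append(
            SpikeUnit(uid, spikes, next(wf_iter), config.fs_waveform, region="RSC")
        )
        true_labels[uid] = next(lab_iter)

    for j in range(config.n_ca1_units):
        uid = f"ca1_p{j:02d}"
        base_rate = rate_rng.uniform(*config.ca1_rate_hz)
        spikes = _bernoulli_spikes(spike_rng, np.full(n_grid, base_rate), dt_grid)
        locked = generate_locked_spikes(
            spike_rng, ripple_times, ripple_amps, 0.2, 0.4, 0.5, cycle_s,
            nominal_amp_sd=config.ripple_amp_sd,
        )
        spikes = _clean_train(np.concatenate([spikes, locked]), config.duration_s)
        units.append(
            SpikeUnit(uid, spikes, ca1_waves[j % len(ca1_waves)],
                      config.fs_waveform, region="CA1")
        )

    # ---- optostimulation ---------------------------------------------------
    opto_rng = rngs["opto"]
    pulses = []
    if config.n_opto_trains > 0:
        t = 20.0
        ipi = 1.0 / config.opto_pulse_rate_hz
        for _ in range(config.n_opto_trains):
            if t > config.duration_s - 5.0:
                break
            for k in range(config.opto_pulses_per_train):
                pulses.append(t + k * ipi)
            t += opto_rng.uniform(10.0, 15.0)
        pulses = np.array(pulses)
        for u in units:
            if u.region != "RSC":
                continue
            if true_labels.get(u.unit_id) == INH:
                extra = [
                    p + 0.004 + opto_rng.normal(0.0, 0.0005)
                    for p in pulses
                    if opto_rng.random() < 0.7
                ]
                u.spike_times = _clean_train(
                    np.concatenate([u.spike_times, extra]), config.duration_s
                )
            else:  # excitatory units are suppressed 0-20 ms after pulses
                keep = np.ones(u.spike_times.size, dtype=bool)
                for p in pulses:
                    sel = (u.spike_times > p) & (u.spike_times < p + 0.020)
                    keep &= ~sel | (opto_rng.random(u.spike_times.size) < 0.1)
                u.spike_times = u.spike_times[keep]
    pulses = np.asarray(pulses, dtype=float)

    recording = Recording(
        lfp_ca1=lfp_ca1.astype(np.float32),
        fs_ca1=fs,
        lfp_rsc=lfp_rsc.astype(np.float32),
        fs_rsc=fs,
        units=units,
        opto_pulses=pulses,
        immobility=[(0.0, config.duration_s)],
        duration=config.duration_s,
    )
    recording.validate()
    truth = GroundTruth(
        true_ripple_times=ripple_times,
        true_ripple_amp_sd=ripple_amps,
        true_state_intervals=states,
        true_unit_labels=true_labels,
        injected_delay_ms=injected_delay,
        true_off_periods=list(off_ivs),
        true_on_periods=list(on_ivs),
        onset_pref_unit_ids=onset_pref_ids,
    )
    return recording, truth


def config_from_dict(d: dict) -> SynthConfig:
    cfg = SynthConfig(**d)
    for name in ("exc_rate_hz", "inh_rate_hz", "ca1_rate_hz",
                 "off_period_range_ms", "on_period_range_ms"):
        setattr(cfg, name, tuple(getattr(cfg, name)))
    cfg.state_schedule = [(str(lab), float(dur)) for lab, dur in cfg.state_schedule]
    return cfg


def config_to_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    d["state_schedule"] = [[lab, dur] for lab, dur in cfg.state_schedule]
    return d
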