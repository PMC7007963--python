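"""Band-pass filtering, ripple detection and sizing, cortical up/down states,
peri-ripple spectrograms and the pre/post power-ratio statistic.

Detection conventions
---------------------
Ripples: the CA1 LFP is band-passed 150-250 Hz with a zero-phase order-5
Butterworth; the envelope is the Hilbert magnitude smoothed by a 4 ms-SD
Gaussian. Events are maximal runs where the envelope exceeds mean + 3 SD
(statistics over eligible state time only), kept if they last >= 15 ms;
events closer than 30 ms are merged. The trough is the minimum of the
band-passed trace within the event and its depth is expressed in SD units of
that trace, which sets the amplitude class (> 8 SD large, > 6 medium,
> 4 small; shallower excursions are not events). All thresholds are in SD
units, so detection is invariant to rescaling the raw voltage.

Up/Down states: the RSC LFP is band-passed 1-4 Hz; excursions > 1 SD above
(below) the mean lasting > 50 ms are Up (Down) states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from . import _intervals
from .data_model import (
    AWAKE_IMMOBILE,
    LARGE,
    MEDIUM,
    SMALL,
    SWS,
    RippleEvent,
    StateIntervals,
)

RIPPLE_BAND = (150.0, 250.0)
SLOW_BAND = (1.0, 4.0)
ENVELOPE_SMOOTH_SD_S = 0.004
ONSET_THRESHOLD_SD = 3.0
MIN_RIPPLE_DUR_S = 0.015
MERGE_GAP_S = 0.030
MIN_ELIGIBLE_S = 10.0
UPDOWN_THRESHOLD_SD = 1.0
MIN_UPDOWN_DUR_S = 0.050

DEFAULT_BANDS = (
    (1.0, 4.0),
    (4.0, 10.0),
    (10.0, 30.0),
    (30.0, 80.0),
    (80.0, 150.0),
    (150.0, 300.0),
)


def bandpass_zero_phase(x, fs: float, lo_hz: float, hi_hz: float, order: int = 5):
    """Forward-backward (zero-phase) Butterworth band-pass."""
    if not (0 < lo_hz < hi_hz < fs / 2):
        raise ValueError(f"invalid band ({lo_hz}, {hi_hz}) for fs={fs}")
    sos = signal.butter(order, [lo_hz, hi_hz], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def ripple_envelope(filtered, fs: float):
    """Hilbert magnitude of a ripple-band trace, Gaussian-smoothed (4 ms SD)."""
    env = np.abs(signal.hilbert(np.asarray(filtered, dtype=float)))
    return gaussian_filter1d(env, sigma=ENVELOPE_SMOOTH_SD_S * fs)


def classify_ripple_size(trough_depth_sd: float):
    """Amplitude class from trough depth in SD units; None below 4 SD."""
    if trough_depth_sd > 8.0:
        return LARGE
    if trough_depth_sd > 6.0:
        return MEDIUM
    if trough_depth_sd > 4.0:
        return SMALL
    return None


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs, stop exclusive."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def detect_ripples(lfp_ca1, fs: float, eligible: StateIntervals) -> list:
    """Detect sharp-wave ripples during eligible (SWS / awake-immobile) time."""
    elig = eligible.select((SWS, AWAKE_IMMOBILE))
    elig_pairs = elig.pairs()
    if _intervals.total_duration(elig_pairs) < MIN_ELIGIBLE_S:
        raise ValueError(
            "eligible time < 10 s: envelope mean/SD estimate would be unstable"
        )
    lfp_ca1 = np.asarray(lfp_ca1, dtype=float)
    bp = bandpass_zero_phase(lfp_ca1, fs, *RIPPLE_BAND)
    env = ripple_envelope(bp, fs)
    mask = _intervals.sample_mask(elig_pairs, fs, lfp_ca1.size)
    mu, sd_env = env[mask].mean(), env[mask].std()
    sd_bp = bp[mask].std()
    if sd_bp == 0 or sd_env == 0:
        return []
    above = env > mu + ONSET_THRESHOLD_SD * sd_env
    runs = _runs(above)
    # merge runs separated by < 30 ms
    merged = []
    gap = int(round(MERGE_GAP_S * fs))
    for a, b in runs:
        if merged and a - merged[-1][1] < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    events = []
    min_len = int(round(MIN_RIPPLE_DUR_S * fs))
    for a, b in merged:
        if b - a < min_len:
            continue
        i_tr = a + int(np.argmin(bp[a:b]))
        t_tr = i_tr / fs
        if not _intervals.contains(elig_pairs, [t_tr])[0]:
            continue
        depth = abs(bp[i_tr]) / sd_bp
        size = classify_ripple_size(depth)
        if size is None:
            continue
        onset, offset = a / fs, b / fs
        if not (onset < t_tr < offset):            # trough at a run edge
            t_tr = min(max(t_tr, onset + 0.5 / fs), offset - 0.5 / fs)
        events.append(
            RippleEvent(
                onset=onset,
                offset=offset,
                trough_time=t_tr,
                trough_depth_sd=depth,
                size=size,
            )
        )
    events.sort(key=lambda e: e.onset)
    return events


@dataclass
class UpDownIntervals:
    """Sorted (start, end, 'UP'|'DOWN') triples plus per-interval extremum time."""

    intervals: list = field(default_factory=list)
    extremum_times: list = field(default_factory=list)

    def pairs(self, label):
        return [(s, e) for s, e, lab in self.intervals if lab == label]

    def __len__(self):
        return len(self.intervals)


def detect_updown(lfp_rsc, fs: float, eligible: StateIntervals) -> UpDownIntervals:
    """Up/Down states from the 1-4 Hz filtered RSC trace during SWS."""
    elig_pairs = eligible.select(SWS).pairs()
    lfp_rsc = np.asarray(lfp_rsc, dtype=float)
    bp = bandpass_zero_phase(lfp_rsc, fs, *SLOW_BAND)
    mask = _intervals.sample_mask(elig_pairs, fs, lfp_rsc.size)
    if not mask.any():
        return UpDownIntervals()
    mu, sd = bp[mask].mean(), bp[mask].std()
    if sd == 0:
        return UpDownIntervals()
    min_len = int(round(MIN_UPDOWN_DUR_S * fs))
    out = UpDownIntervals()
    for lab, m in (("UP", bp > mu + UPDOWN_THRESHOLD_SD * sd),
                   ("DOWN", bp < mu - UPDOWN_THRESHOLD_SD * sd)):
        for a, b in _runs(m & mask):
            if b - a <= min_len:               # strictly "> 50 ms"
                continue
            seg = bp[a:b]
            i_ext = a + int(np.argmax(seg) if lab == "UP" else np.argmin(seg))
            out.intervals.append((a / fs, b / fs, lab))
            out.extremum_times.append(i_ext / fs)
    order = np.argsort([iv[0] for iv in out.intervals]) if out.intervals else []
    out.intervals = [out.intervals[i] for i in order]
    out.extremum_times = [out.extremum_times[i] for i in order]
    return out


def updown_probability_around(
    event_times,
    updown: UpDownIntervals,
    window_s: float = 0.5,
    bin_s: float = 0.010,
):
    """Per-bin probability that time relative to each event lies in an UP
    (resp. DOWN) state.

    Returns ``(bin_centers, p_up, p_down)``.
    """
    event_times = np.asarray(event_times, dtype=float)
    if event_times.size == 0:
        raise ValueError("at least one event required")
    edges = np.arange(-window_s, window_s + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    query = event_times[:, None] + centers[None, :]
    p = {}
    for lab in ("UP", "DOWN"):
        inside = _intervals.contains(updown.pairs(lab), query.ravel())
        p[lab] = inside.reshape(query.shape).mean(axis=0)
    return centers, p["UP"], p["DOWN"]


@dataclass
class PeriEventSpectrogram:
    """Event-averaged short-time power with per-frequency z-scoring.

    ``power`` is the raw event-averaged power (rows = ``freqs``, columns =
    ``times`` relative to the event); ``z`` is per-row z-scored against the
    baseline-window columns. ``baseline_stat`` records how the baseline SD was
    estimated: ``"events"`` pools per-event baseline samples and scales by
    1/sqrt(n_events) (SEM of the average; calibrated for a single session);
    ``"columns"`` uses the SD across baseline columns of the averaged matrix
    (the convention for grand averages).
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray
    z: np.ndarray
    baseline_window: tuple
    baseline_stat: str
    n_events: int
    n_dropped: int


def peri_event_spectrogram(
    lfp,
    fs: float,
    event_times,
    window_s: float = 1.0,
    baseline_window=(-1.0, -0.5),
    freq_range=(1.0, 300.0),
    stft_window_s: float = 0.100,
    step_s: float = 0.010,
    baseline_stat: str = "events",
    min_events: int = 10,
) -> PeriEventSpectrogram:
    """Event-averaged spectrogram (Hann short-time FFT), z-scored per band.

    Events whose +-window (plus half an STFT window) falls outside the
    recording are dropped; their count is reported in ``n_dropped``.
    """
    lfp = np.asarray(lfp, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    nperseg = int(round(stft_window_s * fs))
    hop = int(round(step_s * fs))
    n_half = int(round(window_s / step_s))           # columns each side of t=0
    seg_half = n_half * hop + nperseg // 2
    nfft = int(round(fs))                            # 1 Hz rows
    rel_times = np.arange(-n_half, n_half + 1) * step_s

    idx = np.round(event_times * fs).astype(int)
    ok = (idx - seg_half >= 0) & (idx + seg_half + nperseg - nperseg // 2 <= lfp.size)
    n_dropped = int((~ok).sum())
    idx = idx[ok]
    if idx.size < min_events:
        raise ValueError(f"need >= {min_events} usable events, got {idx.size}")

    win = signal.get_window("hann", nperseg)
    scale = 1.0 / (fs * (win**2).sum())              # PSD scaling
    freqs_full = np.fft.rfftfreq(nfft, d=1.0 / fs)
    fsel = (freqs_full >= freq_range[0]) & (freqs_full <= freq_range[1])
    freqs = freqs_full[fsel]

    bl = (rel_times >= baseline_window[0]) & (rel_times < baseline_window[1])
    if bl.sum() < 2:
        raise ValueError("baseline window too short for the chosen step")

    acc = np.zeros((freqs.size, rel_times.size))
    bl_sumsq = np.zeros(freqs.size)
    bl_sum = np.zeros(freqs.size)
    n_bl = 0
    for i0 in idx:
        # column k covers samples centered on i0 + (k - n_half) * hop
        starts = i0 + (np.arange(rel_times.size) - n_half) * hop - nperseg // 2
        segs = lfp[starts[:, None] + np.arange(nperseg)[None, :]] * win
        spec = np.abs(np.fft.rfft(segs, n=nfft, axis=1)) ** 2 * scale
        spec = spec[:, fsel].T                        # rows=freq, cols=time
        acc += spec
        bl_vals = spec[:, bl]
        bl_sum += bl_vals.sum(axis=1)
        bl_sumsq += (bl_vals**2).sum(axis=1)
        n_bl += int(bl.sum())
    power = acc / idx.size

    mu = power[:, bl].mean(axis=1)
    if baseline_stat == "events":
        var = bl_sumsq / n_bl - (bl_sum / n_bl) ** 2
        sd = np.sqrt(np.maximum(var, 0)) / np.sqrt(idx.size)
    elif baseline_stat == "columns":
        sd = power[:, bl].std(axis=1)
    else:
        raise ValueError("baseline_stat must be 'events' or 'columns'")
    sd = np.where(sd > 0, sd, np.inf)
    z = (power - mu[:, None]) / sd[:, None]
    return PeriEventSpectrogram(
        times=rel_times,
        freqs=freqs,
        power=power,
        z=z,
        baseline_window=tuple(baseline_window),
        baseline_stat=baseline_stat,
        n_events=int(idx.size),
        n_dropped=n_dropped,
    )


def pre_post_power_ratio(
    spec: PeriEventSpectrogram,
    bands=DEFAULT_BANDS,
    pre_window=(-0.2, 0.0),
    post_window=(0.0, 0.2),
):
    """Per-band ratio of mean raw pre-event power to mean raw post-event power."""
    ratios = {}
    pre = (spec.times >= pre_window[0]) & (spec.times < pre_window[1])
    post = (spec.times >= post_window[0]) & (spec.times < post_window[1])
    for lo, hi in bands:
        rows = (spec.freqs >= lo) & (spec.freqs <= hi)
        if not rows.any():
            raise ValueError(f"band ({lo}, {hi}) outside spectrogram frequency axis")
        p_pre = spec.power[np.ix_(rows, pre)].mean()
        p_post = spec.power[np.ix_(rows, post)].mean()
        if p_post == 0:
            raise ValueError(f"zero post-event power in band ({lo}, {hi})")
        ratios[(lo, hi)] = float(p_pre / p_post)
    return ratios


def ripple_onset_trough_lags(events, lag_band_ms=(5.0, 30.0), bin_ms: float = 2.5):
    """Onset-to-trough lag distribution and the fraction inside ``lag_band_ms``.

    Returns ``(lags_ms, hist_counts, hist_edges_ms, fraction_in_band)``.
    """
    if not events:
        raise ValueError("at least one event required")
    lags = np.array([(e.trough_time - e.onset) * 1e3 for e in events])
    edges = np.arange(0.0, max(lags.max() + bin_ms, lag_band_ms[1] + bin_ms), bin_ms)
    hist, edges = np.histogram(lags, bins=edges)
    frac = float(np.mean((lags >= lag_band_ms[0]) & (lags <= lag_band_ms[1])))
    return lags, hist, edges, frac
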