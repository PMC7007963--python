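"""Sleep-state scoring from the CA1 LFP theta/delta power ratio.

Within caller-supplied immobile "bed" periods, non-overlapping windows are
scored by the ratio of band power in theta (6-10 Hz) to delta (1-4 Hz)
from a Welch periodogram: ratio >= 2 -> REM, ratio <= 1 -> SWS, the gap band
in between -> OTHER (excluded from downstream slow-wave-sleep analyses).
Awake immobility (e.g. food consumption) is behavioral context this module
cannot infer; such intervals are passed in separately and labeled
AWAKE_IMMOBILE verbatim.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from . import _intervals
from .data_model import AWAKE_IMMOBILE, OTHER, REM, SWS, StateIntervals

THETA_BAND = (6.0, 10.0)
DELTA_BAND = (1.0, 4.0)
REM_THRESHOLD = 2.0
SWS_THRESHOLD = 1.0
DEFAULT_WINDOW_S = 5.0


def _band_power(freqs: np.ndarray, psd: np.ndarray, band) -> float:
    """Integrated band power (so equal-power tones in either band give ratio 1)."""
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.trapezoid(psd[sel], freqs[sel]))


def theta_delta_ratio(lfp, fs: float, window_s: float = DEFAULT_WINDOW_S):
    """Per-window theta/delta power ratio.

    Returns ``(centers, ratios)``: window-center times (s) and the ratio of
    integrated Welch band power in 6-10 Hz over 1-4 Hz for consecutive
    non-overlapping windows. ``window_s`` must be >= 2 s (two delta cycles at 1 Hz).
    """
    lfp = np.asarray(lfp, dtype=float)
    if window_s < 2.0:
        raise ValueError("window_s must be >= 2 s for delta-band resolution")
    n_win = int(round(window_s * fs))
    if n_win > lfp.size:
        raise ValueError("window longer than recording")
    nperseg = min(n_win, int(round(2.0 * fs)))
    centers, ratios = [], []
    for i0 in range(0, lfp.size - n_win + 1, n_win):
        seg = lfp[i0 : i0 + n_win]
        freqs, psd = signal.welch(seg, fs=fs, nperseg=nperseg)
        theta = _band_power(freqs, psd, THETA_BAND)
        delta = _band_power(freqs, psd, DELTA_BAND)
        centers.append((i0 + n_win / 2.0) / fs)
        ratios.append(theta / delta if delta > 0 else np.inf)
    return np.array(centers), np.array(ratios)


def score_sleep_states(
    lfp_ca1,
    fs: float,
    immobility,
    awake_immobile=None,
    window_s: float = DEFAULT_WINDOW_S,
) -> StateIntervals:
    """Score SWS / REM / OTHER within immobile bed periods.

    ``immobility``: list of (start, end) bed intervals to score by the
    theta/delta rule. ``awake_immobile``: optional list of (start, end)
    intervals labeled AWAKE_IMMOBILE as supplied. Adjacent same-label windows
    are merged; windows are clipped to their immobility interval.
    """
    lfp_ca1 = np.asarray(lfp_ca1, dtype=float)
    duration = lfp_ca1.size / fs
    labeled = []
    for s, e in immobility:
        s, e = max(0.0, s), min(duration, e)
        t0 = s
        while t0 + window_s <= e + 1e-9:
            t1 = min(t0 + window_s, e)
            i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
            seg = lfp_ca1[i0:i1]
            nperseg = min(seg.size, int(round(2.0 * fs)))
            freqs, psd = signal.welch(seg, fs=fs, nperseg=nperseg)
            theta = _band_power(freqs, psd, THETA_BAND)
            delta = _band_power(freqs, psd, DELTA_BAND)
            ratio = theta / delta if delta > 0 else np.inf
            if ratio >= REM_THRESHOLD:
                lab = REM
            elif ratio <= SWS_THRESHOLD:
                lab = SWS
            else:
                lab = OTHER
            labeled.append((t0, t1, lab))
            t0 = t1
    if awake_immobile:
        for s, e in awake_immobile:
            labeled.append((max(0.0, s), min(duration, e), AWAKE_IMMOBILE))
    labeled.sort(key=lambda iv: iv[0])
    merged = _intervals.merge_adjacent(labeled)
    out = StateIntervals(merged)
    out.validate()
    return out


def state_agreement(scored: StateIntervals, truth: StateIntervals) -> float:
    """Time-weighted fraction of truth time carrying the matching label."""
    agree = 0.0
    total = 0.0
    for s, e, lab in truth:
        total += e - s
        same = scored.select(lab).pairs()
        agree += _intervals.total_duration(_intervals.intersect([(s, e)], same))
    return agree / total if total > 0 else 1.0
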