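"""Population OFF periods, ON-cluster boundaries, boundary firing
probability against a shuffled chance level, and co-termination of clusters
with hippocampal ripples.

An OFF period is a gap of at least 100 ms in the merged spike train of the
simultaneously recorded RSC population, lying wholly inside slow-wave sleep;
the spikes bounding the gap define its edges. The complementary maximal
spike runs are ON clusters whose onset/offset are the first/last spikes.
Chance firing probability at cluster boundaries is estimated from seeded
circular shifts of the unit's whole spike train (which preserve its
inter-spike-interval structure); a unit is "high probability" when its
observed boundary firing is at least 5-fold above that chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _intervals
from .data_model import SWS, StateIntervals

MIN_OFF_GAP_S = 0.1
MIN_POPULATION_UNITS = 8
HIGH_PROBABILITY_FOLD = 5.0


@dataclass
class OffPeriod:
    start: float          # last population spike before the silence
    end: float            # first population spike after
    duration: float


@dataclass
class ClusterBoundary:
    onset: float          # first spike of the cluster
    offset: float         # last spike of the cluster


def merge_population_spikes(units) -> np.ndarray:
    """Sorted merge of all units' spike times."""
    trains = [np.asarray(u.spike_times, dtype=float) for u in units]
    if not trains:
        return np.empty(0)
    return np.sort(np.concatenate(trains))


def detect_off_periods(
    units,
    states: StateIntervals,
    min_gap_s: float = MIN_OFF_GAP_S,
    min_units: int = MIN_POPULATION_UNITS,
) -> list:
    """Population OFF periods: merged-train gaps >= min_gap_s wholly in SWS."""
    if len(units) < min_units:
        raise ValueError(
            f"only {len(units)} simultaneously recorded units; "
            f"population OFF analysis requires >= {min_units} "
            "(pass min_units to override)"
        )
    merged = merge_population_spikes(units)
    sws = states.select(SWS).pairs()
    out = []
    if merged.size < 2:
        return out
    gaps = np.diff(merged)
    for i in np.flatnonzero(gaps >= min_gap_s):
        s, e = merged[i], merged[i + 1]
        # wholly inside one SWS interval (gaps straddling state edges discarded)
        if any(s >= a and e <= b for a, b in sws):
            out.append(OffPeriod(start=float(s), end=float(e), duration=float(e - s)))
    return out


def cluster_boundaries(off_periods, merged_spikes) -> list:
    """ON clusters between consecutive OFF periods.

    Clusters truncated at session or state edges carry no defined
    onset/offset and are excluded: only spans between two OFF periods with at
    least one spike strictly inside are returned. The onset is the first
    spike after the earlier OFF period, the offset the last spike before the
    later one (a single-spike cluster has onset == offset).
    """
    if not off_periods:
        raise ValueError("at least one OFF period required")
    merged_spikes = np.asarray(merged_spikes, dtype=float)
    offs = sorted(off_periods, key=lambda o: o.start)
    out = []
    for prev, nxt in zip(offs[:-1], offs[1:]):
        i0 = np.searchsorted(merged_spikes, prev.end, side="left")
        i1 = np.searchsorted(merged_spikes, nxt.start, side="right")
        if i1 > i0:
            out.append(
                ClusterBoundary(onset=float(merged_spikes[i0]), offset=float(merged_spikes[i1 - 1]))
            )
    return out


def boundary_firing_probability(
    spike_times,
    boundaries,
    which: str = "onset",
    window=None,
    n_shuffles: int = 1000,
    seed: int = 0,
    duration: float | None = None,
    min_boundaries: int = 50,
):
    """Per-unit firing probability at cluster boundaries vs shuffled chance.

    ``window`` defaults to (0, 5 ms) after onsets and (-5 ms, 0) before
    offsets. ``prob`` is the fraction of boundaries with at least one spike
    of this unit in the window; ``chance`` is the mean of the same statistic
    over ``n_shuffles`` circular shifts of the whole train by a uniform
    offset in [10 s, duration - 10 s] modulo the session duration. Returns
    ``(prob, chance, ratio)`` with ratio = inf when chance is 0 but prob > 0.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    b_times = np.asarray(
        [getattr(b, which) for b in boundaries], dtype=float
    )
    if b_times.size < min_boundaries:
        raise ValueError(f"need >= {min_boundaries} boundaries, got {b_times.size}")
    if window is None:
        window = (0.0, 0.005) if which == "onset" else (-0.005, 0.0)
    if duration is None:
        duration = float(max(spike_times.max(), b_times.max()) + 1.0)

    def _prob(train_sorted):
        hit = (
            np.searchsorted(train_sorted, b_times + window[1], side="right")
            - np.searchsorted(train_sorted, b_times + window[0], side="left")
        ) > 0
        return hit.mean()

    prob = float(_prob(spike_times))
    rng = np.random.default_rng(seed)
    lo, hi = 10.0, max(duration - 10.0, 10.0 + 1e-6)
    shifts = rng.uniform(lo, hi, size=n_shuffles)
    chance = float(
        np.mean([_prob(np.sort((spike_times + s) % duration)) for s in shifts])
    )
    if chance == 0.0:
        ratio = np.inf if prob > 0 else 1.0
    else:
        ratio = prob / chance
    return prob, chance, float(ratio)


def classify_high_probability(ratio: float) -> bool:
    """5-fold or higher above chance (inclusive; infinity counts)."""
    return bool(ratio >= HIGH_PROBABILITY_FOLD)


def boundary_ripple_cotermination(
    boundaries,
    ripple_trough_times,
    window_s: float = 0.5,
    bin_s: float = 0.010,
):
    """Probability of cluster onsets/offsets per bin around ripple troughs.

    Returns ``(bin_centers, p_onset, p_offset)`` where each value is the mean
    number of boundaries per ripple falling in that bin.
    """
    troughs = np.asarray(ripple_trough_times, dtype=float)
    if troughs.size < 10 or len(boundaries) < 10:
        raise ValueError("need >= 10 ripples and >= 10 boundaries")
    edges = np.arange(-window_s, window_s + bin_s / 2, bin_s)
    centers = (edges[:-1] + edges[1:]) / 2
    out = {}
    for which in ("onset", "offset"):
        times = np.sort([getattr(b, which) for b in boundaries])
        rel = np.concatenate([times - t for t in troughs])
        counts, _ = np.histogram(rel, bins=edges)
        out[which] = counts / troughs.size
    return centers, out["onset"], out["offset"]


def ripple_cluster_intervals(events, max_gap_s: float = 0.2) -> list:
    """Group ripples whose inter-trough gaps are <= max_gap_s into clusters.

    Returns (onset, offset) pairs: the first and last trough of each cluster.
    Requires >= 2 events (a single ripple cannot define a cluster structure).
    """
    troughs = np.sort([e.trough_time if hasattr(e, "trough_time") else float(e) for e in events])
    if troughs.size < 2:
        raise ValueError("need >= 2 ripple events")
    out = []
    start = prev = troughs[0]
    for t in troughs[1:]:
        if t - prev <= max_gap_s:
            prev = t
        else:
            out.append((float(start), float(prev)))
            start = prev = t
    out.append((float(start), float(prev)))
    return out
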