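"""Half-open interval utilities shared across modules.

All intervals are [start, end) in seconds, t = 0 at recording start.
"""

from __future__ import annotations

import numpy as np


def validate_intervals(intervals, name="intervals"):
    """Check (start, end) pairs are well-formed, sorted and non-overlapping."""
    prev_end = -np.inf
    for iv in intervals:
        s, e = float(iv[0]), float(iv[1])
        if not e > s:
            raise ValueError(f"{name}: interval ({s}, {e}) has non-positive length")
        if s < prev_end:
            raise ValueError(f"{name}: intervals overlap or are unsorted at ({s}, {e})")
        prev_end = e


def total_duration(intervals) -> float:
    return float(sum(e - s for s, e, *_ in intervals))


def sample_mask(intervals, fs: float, n_samples: int) -> np.ndarray:
    """Boolean per-sample membership mask for a list of (start, end) pairs."""
    mask = np.zeros(n_samples, dtype=bool)
    for s, e, *_ in intervals:
        i0 = max(0, int(np.ceil(s * fs)))
        i1 = min(n_samples, int(np.ceil(e * fs)))
        if i1 > i0:
            mask[i0:i1] = True
    return mask


def contains(intervals, times) -> np.ndarray:
    """Vectorized membership test of times against sorted half-open intervals."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if len(intervals) == 0:
        return np.zeros(times.shape, dtype=bool)
    starts = np.array([iv[0] for iv in intervals], dtype=float)
    ends = np.array([iv[1] for iv in intervals], dtype=float)
    idx = np.searchsorted(starts, times, side="right") - 1
    ok = idx >= 0
    inside = np.zeros(times.shape, dtype=bool)
    inside[ok] = times[ok] < ends[idx[ok]]
    return inside


def restrict_times(intervals, times: np.ndarray) -> np.ndarray:
    """Subset of times falling inside any interval."""
    times = np.asarray(times, dtype=float)
    return times[contains(intervals, times)]


def intersect(a, b):
    """Intersection of two sorted non-overlapping interval lists."""
    out = []
    i = j = 0
    a = [(iv[0], iv[1]) for iv in a]
    b = [(iv[0], iv[1]) for iv in b]
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def jaccard(a, b, resolution_s: float = 1e-3) -> float:
    """Jaccard overlap of two interval sets (|A∩B| / |A∪B|) by duration."""
    inter = total_duration(intersect(a, b))
    union = total_duration(a) + total_duration(b) - inter
    if union <= 0:
        return 1.0 if inter == 0 else 0.0
    return inter / union


def merge_adjacent(labeled_intervals, tol: float = 1e-9):
    """Merge consecutive (start, end, label) triples that touch and share a label."""
    merged = []
    for s, e, lab in labeled_intervals:
        if merged and merged[-1][2] == lab and s - merged[-1][1] <= tol:
            merged[-1] = (merged[-1][0], e, lab)
        else:
            merged.append((s, e, lab))
    return merged
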