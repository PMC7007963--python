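"""Waveform-based classification of units into putative excitatory /
inhibitory / other classes, plus the low-rate inclusion screen.

Mean waveforms are trough-aligned, cropped to the 1 ms following the trough
and peak-normalized (classification is therefore amplitude-invariant). The
first three principal components of the normalized shapes are clustered
hierarchically (Euclidean distance, Ward linkage by default) and the tree is
cut to exactly three clusters. Identity is assigned post hoc by mean
trough-to-peak width: the narrowest cluster is putative inhibitory, the
widest putative excitatory, the remainder "other" — the standard
extracellular criterion for cortical cell types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

EXC = "EXC"
INH = "INH"
OTHER = "OTHER"

RATE_EXCLUSION_HZ = 0.5
N_NORM_SAMPLES = 33           # common 0-1 ms grid for PCA


@dataclass
class UnitLabel:
    unit_id: str
    label: str                       # EXC | INH | OTHER
    trough_to_peak_ms: float
    pc_scores: np.ndarray            # 3 values
    mean_rate_hz: float | None = None


def normalize_waveform(waveform, waveform_fs: float) -> np.ndarray:
    """Trough-aligned 0-1 ms segment scaled to unit peak magnitude.

    Output sample 0 is the global trough; the vector spans exactly 1 ms and
    its maximum absolute value is 1 (the trough itself, value -1, for any
    physiological spike shape).
    """
    w = np.asarray(waveform, dtype=float)
    if w.size == 0 or np.all(w == 0):
        raise ValueError("all-zero waveform cannot be normalized")
    i_tr = int(np.argmin(w))
    n_ms = int(round(waveform_fs * 1e-3))
    if i_tr + n_ms + 1 > w.size:
        raise ValueError("waveform must span >= 1 ms after its trough")
    seg = w[i_tr : i_tr + n_ms + 1]
    return seg / np.max(np.abs(seg))


def spike_width(waveform, fs: float) -> float:
    """Trough-to-peak width in ms: global trough to the subsequent maximum."""
    w = np.asarray(waveform, dtype=float)
    d = np.diff(w)
    if np.all(d >= 0) or np.all(d <= 0):
        raise ValueError("monotone waveform has no trough-to-peak width")
    i_tr = int(np.argmin(w))
    tail = w[i_tr + 1 :]
    if tail.size == 0:
        raise ValueError("waveform trough at final sample; no subsequent peak")
    i_pk = i_tr + 1 + int(np.argmax(tail))
    return (i_pk - i_tr) / fs * 1e3


def _resample(vec: np.ndarray, n_out: int) -> np.ndarray:
    x_in = np.linspace(0.0, 1.0, vec.size)
    x_out = np.linspace(0.0, 1.0, n_out)
    return np.interp(x_out, x_in, vec)


def classify_units(
    waveforms,
    waveform_fs,
    unit_ids=None,
    linkage_method: str = "ward",
) -> list:
    """PCA + hierarchical clustering of normalized waveforms into 3 classes.

    ``waveforms``: list of mean waveforms; ``waveform_fs``: scalar or
    per-unit sample rates. Returns one :class:`UnitLabel` per input, in input
    order. Requires >= 3 units. If the tree degenerates to fewer than three
    distinct clusters (e.g. identical waveforms) a warning is issued and
    labels fall back to the width-ordering rule on the clusters found.
    """
    waveforms = list(waveforms)
    n = len(waveforms)
    if n < 3:
        raise ValueError("need at least 3 units to classify")
    if np.isscalar(waveform_fs):
        waveform_fs = [float(waveform_fs)] * n
    if unit_ids is None:
        unit_ids = [str(i) for i in range(n)]

    norm = [normalize_waveform(w, fs) for w, fs in zip(waveforms, waveform_fs)]
    # width measured on the normalized 1 ms segment in its native sampling
    widths = np.array(
        [spike_width(v, fs) for v, fs in zip(norm, waveform_fs)]
    )
    mat = np.vstack([_resample(v, N_NORM_SAMPLES) for v in norm])

    n_pc = min(3, n - 1, mat.shape[1])
    pca = PCA(n_components=n_pc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate inputs may trip PCA internals
        scores = pca.fit_transform(mat)
    if n_pc < 3:
        scores = np.pad(scores, ((0, 0), (0, 3 - n_pc)))

    Z = linkage(scores, method=linkage_method, metric="euclidean")
    if Z[:, 2].max() < 1e-6:  # effectively identical waveforms: one cluster
        assignments = np.ones(n, dtype=int)
    else:
        assignments = fcluster(Z, t=3, criterion="maxclust")
    clusters = np.unique(assignments)
    if clusters.size < 3:
        warnings.warn(
            f"degenerate waveforms: only {clusters.size} cluster(s) found; "
            "labels assigned by width ordering on the clusters present"
        )
    # rank clusters by mean trough-to-peak width
    mean_w = {c: widths[assignments == c].mean() for c in clusters}
    order = sorted(clusters, key=lambda c: mean_w[c])
    label_of = {}
    if len(order) == 1:
        label_of[order[0]] = EXC
    elif len(order) == 2:
        label_of[order[0]], label_of[order[1]] = INH, EXC
    else:
        label_of[order[0]] = INH
        label_of[order[-1]] = EXC
        for c in order[1:-1]:
            label_of[c] = OTHER
    return [
        UnitLabel(
            unit_id=unit_ids[i],
            label=label_of[assignments[i]],
            trough_to_peak_ms=float(widths[i]),
            pc_scores=scores[i, :3].copy(),
        )
        for i in range(n)
    ]


def rate_screen(units, duration: float) -> dict:
    """Inclusion flags: units with overall mean rate < 0.5 Hz are excluded.

    The boundary is read literally: exactly 0.5 Hz is kept. Returns
    ``{unit_id: included}``.
    """
    out = {}
    for u in units:
        rate = u.n_spikes / duration if duration > 0 else 0.0
        out[u.unit_id] = rate >= RATE_EXCLUSION_HZ
    return out
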