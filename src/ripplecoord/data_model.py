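"""Domain types and the on-disk container for dual-site recordings.

A :class:`Recording` bundles two LFP channels (hippocampal CA1 and
retrosplenial cortex, RSC), sorted single units with mean spike waveforms,
optional optostimulation pulse times, and an immobility mask. Times are
seconds (float64) with t = 0 at recording start; all intervals are half-open
[start, end). Voltages are stored float32 (acquisition precision), times
float64 (timestamp precision).

HDF5 layout::

    /meta                  attrs: duration_s, format_version
    /lfp/ca1, /lfp/rsc     float32 voltage (uV), attr: fs
    /units/<id>/times      float64 spike times (s)
    /units/<id>/waveform   float32 mean waveform (uV), attrs: fs, region
    /events/opto_pulses    float64 (optional)
    /events/immobility     float64 (n, 2) start/end pairs (optional)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from . import _intervals

FORMAT_VERSION = 1

# state labels
SWS = "SWS"
REM = "REM"
AWAKE_IMMOBILE = "AWAKE_IMMOBILE"
OTHER = "OTHER"
STATE_LABELS = (SWS, REM, AWAKE_IMMOBILE, OTHER)

# ripple size classes
LARGE = "LARGE"
MEDIUM = "MEDIUM"
SMALL = "SMALL"
SIZE_CLASSES = (LARGE, MEDIUM, SMALL)

CA1 = "CA1"
RSC = "RSC"


class ValidationError(ValueError):
    """A Recording (or component) violates a structural invariant.

    ``field`` names the offending field.
    """

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


class ContainerFormatError(IOError):
    """The on-disk container does not conform to the documented layout."""


@dataclass
class SpikeUnit:
    unit_id: str
    spike_times: np.ndarray          # sorted, seconds
    waveform: np.ndarray             # mean spike shape, uV
    waveform_fs: float               # Hz
    region: str = RSC                # CA1 | RSC

    def validate(self, duration: float | None = None) -> None:
        st = np.asarray(self.spike_times, dtype=float)
        if st.ndim != 1:
            raise ValidationError("spike_times", f"unit {self.unit_id}: must be 1-D")
        if st.size > 1 and not np.all(np.diff(st) > 0):
            raise ValidationError(
                "spike_times", f"unit {self.unit_id}: must be strictly increasing"
            )
        if duration is not None and st.size and (st[0] < 0 or st[-1] > duration):
            raise ValidationError(
                "spike_times", f"unit {self.unit_id}: times outside [0, duration]"
            )
        wf = np.asarray(self.waveform, dtype=float)
        if wf.size and wf.size / float(self.waveform_fs) < 1e-3 - 1e-12:
            raise ValidationError(
                "waveform", f"unit {self.unit_id}: waveform must span >= 1 ms"
            )
        if self.region not in (CA1, RSC):
            raise ValidationError("region", f"unit {self.unit_id}: {self.region!r}")

    @property
    def n_spikes(self) -> int:
        return int(np.asarray(self.spike_times).size)


@dataclass
class StateIntervals:
    """Labeled, sorted, non-overlapping time intervals.

    Each element is ``(start_s, end_s, label)`` with label from
    ``STATE_LABELS``.
    """

    intervals: list = field(default_factory=list)

    def validate(self) -> None:
        _intervals.validate_intervals(self.intervals, "state intervals")
        for s, e, lab in self.intervals:
            if lab not in STATE_LABELS:
                raise ValidationError("label", f"unknown state label {lab!r}")

    def select(self, labels) -> "StateIntervals":
        if isinstance(labels, str):
            labels = (labels,)
        return StateIntervals(
            [(s, e, lab) for s, e, lab in self.intervals if lab in labels]
        )

    def pairs(self):
        return [(s, e) for s, e, _ in self.intervals]

    def total_duration(self, labels=None) -> float:
        ivs = self.intervals if labels is None else self.select(labels).intervals
        return _intervals.total_duration(ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass
class RippleEvent:
    """One detected sharp-wave ripple.

    ``trough_depth_sd`` is the magnitude of the band-passed trace's minimum in
    SD units of that trace over eligible time; ``size`` is the amplitude class
    (LARGE > 8 SD, MEDIUM 6-8 SD, SMALL 4-6 SD).
    """

    onset: float
    offset: float
    trough_time: float
    trough_depth_sd: float
    size: str

    def validate(self) -> None:
        if not (self.onset < self.trough_time < self.offset):
            raise ValidationError(
                "trough_time", "must satisfy onset < trough_time < offset"
            )
        if self.offset - self.onset < 0.015 - 1e-9:
            raise ValidationError("offset", "event shorter than 15 ms")
        if self.size not in SIZE_CLASSES:
            raise ValidationError("size", f"unknown size class {self.size!r}")


@dataclass
class GroundTruth:
    """Synthetic-only record of what the generator injected."""

    true_ripple_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_ripple_amp_sd: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_state_intervals: StateIntervals = field(default_factory=StateIntervals)
    true_unit_labels: dict = field(default_factory=dict)       # unit_id -> EXC|INH|OTHER
    injected_delay_ms: dict = field(default_factory=dict)      # inh unit_id -> delay
    true_off_periods: list = field(default_factory=list)       # (start, end)
    true_on_periods: list = field(default_factory=list)        # (start, end)
    onset_pref_unit_ids: list = field(default_factory=list)


@dataclass
class Recording:
    lfp_ca1: np.ndarray
    fs_ca1: float
    lfp_rsc: np.ndarray
    fs_rsc: float
    units: list = field(default_factory=list)
    opto_pulses: np.ndarray = field(default_factory=lambda: np.empty(0))
    immobility: list = field(default_factory=list)             # (start, end) pairs
    duration: float = 0.0

    def validate(self) -> None:
        n1 = np.asarray(self.lfp_ca1).size
        n2 = np.asarray(self.lfp_rsc).size
        d1, d2 = n1 / float(self.fs_ca1), n2 / float(self.fs_rsc)
        if abs(d1 - d2) > 1.0 / min(self.fs_ca1, self.fs_rsc) + 1e-9:
            raise ValidationError(
                "lfp_rsc", f"LFP durations differ by more than one sample ({d1} vs {d2})"
            )
        for name, fs in (("fs_ca1", self.fs_ca1), ("fs_rsc", self.fs_rsc)):
            if fs < 600.0:
                raise ValidationError(
                    name, f"sample rate {fs} Hz below the 600 Hz analysis floor"
                )
        if self.duration <= 0:
            raise ValidationError("duration", "must be positive")
        for u in self.units:
            u.validate(self.duration)
        op = np.asarray(self.opto_pulses, dtype=float)
        if op.size and (op.min() < 0 or op.max() > self.duration):
            raise ValidationError("opto_pulses", "event times outside [0, duration]")
        _intervals.validate_intervals(self.immobility, "immobility")
        for s, e in self.immobility:
            if s < -1e-9 or e > self.duration + 1e-9:
                raise ValidationError("immobility", "interval outside [0, duration]")

    def units_in(self, region: str):
        return [u for u in self.units if u.region == region]


# ---------------------------------------------------------------------------
# container I/O


def write_recording(recording: Recording, path) -> str:
    """Validate and write a Recording to the documented HDF5 layout."""
    recording.validate()
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["duration_s"] = float(recording.duration)
        meta.attrs["format_version"] = FORMAT_VERSION
        lfp = f.create_group("lfp")
        for name, sig, fs in (
            ("ca1", recording.lfp_ca1, recording.fs_ca1),
            ("rsc", recording.lfp_rsc, recording.fs_rsc),
        ):
            ds = lfp.create_dataset(name, data=np.asarray(sig, dtype=np.float32))
            ds.attrs["fs"] = float(fs)
        units = f.create_group("units")
        for u in recording.units:
            g = units.create_group(str(u.unit_id))
            g.create_dataset("times", data=np.asarray(u.spike_times, dtype=np.float64))
            wf = g.create_dataset("waveform", data=np.asarray(u.waveform, dtype=np.float32))
            wf.attrs["fs"] = float(u.waveform_fs)
            wf.attrs["region"] = u.region
        ev = f.create_group("events")
        if np.asarray(recording.opto_pulses).size:
            ev.create_dataset(
                "opto_pulses", data=np.asarray(recording.opto_pulses, dtype=np.float64)
            )
        if recording.immobility:
            ev.create_dataset(
                "immobility", data=np.asarray(recording.immobility, dtype=np.float64)
            )
    return str(path)


def read_recording(path) -> Recording:
    """Read a Recording; missing optional groups yield empty fields."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise ContainerFormatError(f"cannot open container {path}: {exc}") from exc
    with f:
        for group in ("meta", "lfp"):
            if group not in f:
                raise ContainerFormatError(f"missing required group /{group}")
        for ch in ("ca1", "rsc"):
            if ch not in f["lfp"]:
                raise ContainerFormatError(f"missing required dataset /lfp/{ch}")
        duration = float(f["meta"].attrs["duration_s"])
        lfp_ca1 = f["lfp/ca1"][...]
        fs_ca1 = float(f["lfp/ca1"].attrs["fs"])
        lfp_rsc = f["lfp/rsc"][...]
        fs_rsc = float(f["lfp/rsc"].attrs["fs"])
        units = []
        if "units" in f:
            for uid in sorted(f["units"].keys()):
                g = f["units"][uid]
                if "times" not in g or "waveform" not in g:
                    raise ContainerFormatError(f"malformed unit group /units/{uid}")
                units.append(
                    SpikeUnit(
                        unit_id=uid,
                        spike_times=g["times"][...],
                        waveform=g["waveform"][...],
                        waveform_fs=float(g["waveform"].attrs["fs"]),
                        region=str(g["waveform"].attrs["region"]),
                    )
                )
        opto = np.empty(0)
        immobility = []
        if "events" in f:
            if "opto_pulses" in f["events"]:
                opto = f["events/opto_pulses"][...]
            if "immobility" in f["events"]:
                immobility = [tuple(row) for row in f["events/immobility"][...]]
    return Recording(
        lfp_ca1=lfp_ca1,
        fs_ca1=fs_ca1,
        lfp_rsc=lfp_rsc,
        fs_rsc=fs_rsc,
        units=units,
        opto_pulses=opto,
        immobility=immobility,
        duration=duration,
    )


def export_events_table(events, path) -> str:
    """Write ripples or state intervals to CSV (times in s, 6 decimals)."""
    if isinstance(events, StateIntervals):
        df = pd.DataFrame(events.intervals, columns=["start", "end", "label"])
    else:
        events = list(events)
        if events and isinstance(events[0], RippleEvent):
            df = pd.DataFrame(
                [
                    {
                        "onset": e.onset,
                        "offset": e.offset,
                        "trough_time": e.trough_time,
                        "trough_depth_sd": e.trough_depth_sd,
                        "size": e.size,
                    }
                    for e in events
                ]
            )
        else:
            df = pd.DataFrame(
                [], columns=["onset", "offset", "trough_time", "trough_depth_sd", "size"]
            )
    df.to_csv(path, index=False, float_format="%.6f")
    return str(path)


def read_ripples_table(path) -> list:
    df = pd.read_csv(path)
    return [
        RippleEvent(
            onset=row.onset,
            offset=row.offset,
            trough_time=row.trough_time,
            trough_depth_sd=row.trough_depth_sd,
            size=row.size,
        )
        for row in df.itertuples()
    ]


def read_states_table(path) -> StateIntervals:
    df = pd.read_csv(path)
    return StateIntervals([(r.start, r.end, r.label) for r in df.itertuples()])
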