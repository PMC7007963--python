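"""One-command orchestration of the full analysis chain.

Given a recording container (or a synthetic config), runs: sleep-state
scoring, ripple detection, up/down states, waveform classification and rate
screening, peri-ripple response calls and phase-locking latency,
size-stratified firing, population OFF periods and cluster-boundary
statistics. Results land in an output directory as CSV tables plus a JSON
summary whose headline fields mirror the quantities this kind of study
reports (fractions of activated units, phase-locking delays, onset-trough
lags). Every stage parameter is echoed into the summary for provenance, and
runs are deterministic given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlations, oscillations, population, states as states_mod, units as units_mod
from .data_model import (
    RSC,
    SWS,
    Recording,
    StateIntervals,
    export_events_table,
    read_recording,
)
from .synth import SynthConfig, generate_recording

log = logging.getLogger("ripplecoord")


@dataclass
class PipelineConfig:
    recording_path: str | None = None      # read container; else synthesize
    synth: SynthConfig = field(default_factory=SynthConfig)
    out_dir: str = "ripplecoord_out"
    seed: int = 0
    state_window_s: float = 5.0
    peth_bin_s: float = 0.010
    peth_window: tuple = (-1.0, 1.0)
    peth_baseline: tuple = (-1.0, -0.5)
    fine_bin_s: float = 0.0005
    boundary_shuffles: int = 300
    min_population_units: int = 8
    make_figures: bool = False
    log_level: str = "INFO"

    def params_dict(self) -> dict:
        from .synth import config_to_dict

        d = {
            "recording_path": self.recording_path,
            "seed": self.seed,
            "state_window_s": self.state_window_s,
            "peth_bin_s": self.peth_bin_s,
            "peth_window": list(self.peth_window),
            "peth_baseline": list(self.peth_baseline),
            "fine_bin_s": self.fine_bin_s,
            "boundary_shuffles": self.boundary_shuffles,
            "min_population_units": self.min_population_units,
        }
        if self.recording_path is None:
            d["synth"] = config_to_dict(self.synth)
        return d


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict (also written to JSON)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"parameters": config.params_dict()}

    def stage(name, fn):
        log.info("stage: %s", name)
        try:
            return fn()
        except Exception as exc:  # partial outputs stay on disk
            (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
            raise StageError(name, exc) from exc

    # ---- input -------------------------------------------------------------
    if config.recording_path is not None:
        rec: Recording = stage("read", lambda: read_recording(config.recording_path))
        truth = None
    else:
        config.synth.seed = config.seed
        rec, truth = stage("synth", lambda: generate_recording(config.synth))

    # ---- states ------------------------------------------------------------
    scored: StateIntervals = stage(
        "states",
        lambda: states_mod.score_sleep_states(
            rec.lfp_ca1, rec.fs_ca1, rec.immobility, window_s=config.state_window_s
        ),
    )
    export_events_table(scored, out / "states.csv")
    summary["states"] = {
        "sws_s": scored.total_duration(SWS),
        "rem_s": scored.total_duration("REM"),
        "n_intervals": len(scored),
    }

    # ---- ripples -----------------------------------------------------------
    ripples = stage(
        "ripples", lambda: oscillations.detect_ripples(rec.lfp_ca1, rec.fs_ca1, scored)
    )
    export_events_table(ripples, out / "ripples.csv")
    troughs = np.array([e.trough_time for e in ripples])
    *_, lag_frac = (
        oscillations.ripple_onset_trough_lags(ripples) if ripples else (None, None, None, np.nan)
    )
    summary["ripples"] = {
        "n": len(ripples),
        "by_size": {s: sum(e.size == s for e in ripples) for s in ("LARGE", "MEDIUM", "SMALL")},
        "pct_onset_trough_lag_5_30ms": float(lag_frac * 100) if ripples else None,
    }

    # ---- up/down -----------------------------------------------------------
    updown = stage(
        "updown", lambda: oscillations.detect_updown(rec.lfp_rsc, rec.fs_rsc, scored)
    )
    pd.DataFrame(updown.intervals, columns=["start", "end", "label"]).to_csv(
        out / "updown.csv", index=False, float_format="%.6f"
    )
    summary["updown"] = {
        "n_up": len(updown.pairs("UP")),
        "n_down": len(updown.pairs("DOWN")),
    }

    # ---- units -------------------------------------------------------------
    rsc_units = rec.units_in(RSC)
    labels = stage(
        "classify_units",
        lambda: units_mod.classify_units(
            [u.waveform for u in rsc_units],
            [u.waveform_fs for u in rsc_units],
            unit_ids=[u.unit_id for u in rsc_units],
        ),
    )
    included = units_mod.rate_screen(rsc_units, rec.duration)
    rows = []
    for u, lab in zip(rsc_units, labels):
        lab.mean_rate_hz = u.n_spikes / rec.duration
        rows.append(
            {
                "unit_id": u.unit_id,
                "label": lab.label,
                "width_ms": lab.trough_to_peak_ms,
                "rate_hz": lab.mean_rate_hz,
                "included": included[u.unit_id],
                "pc1": lab.pc_scores[0],
                "pc2": lab.pc_scores[1],
                "pc3": lab.pc_scores[2],
            }
        )
    pd.DataFrame(rows).to_csv(out / "units.csv", index=False, float_format="%.6f")
    by_label = {
        lab: [u for u, L in zip(rsc_units, labels) if L.label == lab and included[u.unit_id]]
        for lab in ("EXC", "INH", "OTHER")
    }
    summary["units"] = {lab: len(v) for lab, v in by_label.items()}

    # ---- ripple responses --------------------------------------------------
    def responses():
        calls = {}
        delays = {}
        for lab in ("EXC", "INH"):
            for u in by_label[lab]:
                call = correlations.classify_ripple_response(
                    u.spike_times, troughs, unit_id=u.unit_id,
                    bin_s=config.peth_bin_s, window=config.peth_window,
                    baseline_window=config.peth_baseline,
                )
                calls[u.unit_id] = call
                if lab == "INH" and troughs.size >= 100:
                    locked, delay_ms, _ = correlations.phase_locking_delay(
                        u.spike_times, troughs, bin_s=config.fine_bin_s
                    )
                    if locked:
                        delays[u.unit_id] = delay_ms
        return calls, delays

    calls, delays = stage("responses", responses)
    pd.DataFrame(
        [
            {"unit_id": uid, "call": c.call, "z": c.peak_or_mean_z,
             "phase_lock_delay_ms": delays.get(uid)}
            for uid, c in calls.items()
        ]
    ).to_csv(out / "responses.csv", index=False, float_format="%.6f")

    def _frac_activated(lab):
        us = by_label[lab]
        if not us:
            return None
        k = sum(calls[u.unit_id].call == "ACTIVATED" for u in us)
        return {"n_activated": k, "n": len(us), "pct": 100.0 * k / len(us)}

    summary["ripple_responses"] = {
        "inhibitory": _frac_activated("INH"),
        "excitatory": _frac_activated("EXC"),
        "phase_locked_inh": {
            "n": len(delays),
            "mean_delay_ms": float(np.mean(list(delays.values()))) if delays else None,
        },
    }

    # ---- size-stratified rates --------------------------------------------
    def sizes():
        rows = []
        for lab in ("EXC", "INH"):
            for u in by_label[lab]:
                for size, (pre, post) in correlations.size_stratified_rates(
                    u.spike_times, ripples
                ).items():
                    rows.append(
                        {"unit_id": u.unit_id, "label": lab, "size": size,
                         "pre_rate_hz": pre, "post_rate_hz": post}
                    )
        return pd.DataFrame(rows)

    size_df = stage("size_stratified", sizes)
    size_df.to_csv(out / "size_stratified.csv", index=False, float_format="%.6f")

    # ---- opto --------------------------------------------------------------
    if np.asarray(rec.opto_pulses).size >= 2:
        def opto():
            return {
                u.unit_id: correlations.classify_opto_response(
                    u.spike_times, rec.opto_pulses, unit_id=u.unit_id
                )
                for lab in ("EXC", "INH")
                for u in by_label[lab]
            }

        opto_calls = stage("opto", opto)
        summary["opto_responses"] = {
            lab: {
                "n_activated": sum(
                    opto_calls[u.unit_id].call == "ACTIVATED" for u in by_label[lab]
                ),
                "n_inhibited": sum(
                    opto_calls[u.unit_id].call == "INHIBITED" for u in by_label[lab]
                ),
                "n": len(by_label[lab]),
            }
            for lab in ("EXC", "INH")
        }

    # ---- population --------------------------------------------------------
    def pop():
        if len(rsc_units) < config.min_population_units:
            return None
        offs = population.detect_off_periods(
            rsc_units, scored, min_units=config.min_population_units
        )
        merged = population.merge_population_spikes(rsc_units)
        bounds = population.cluster_boundaries(offs, merged) if offs else []
        rows = []
        if len(bounds) >= 50:
            for which in ("onset", "offset"):
                for lab in ("EXC", "INH"):
                    for u in by_label[lab]:
                        p, ch, ratio = population.boundary_firing_probability(
                            u.spike_times, bounds, which=which,
                            n_shuffles=config.boundary_shuffles,
                            seed=config.seed, duration=rec.duration,
                        )
                        rows.append(
                            {"unit_id": u.unit_id, "label": lab, "which": which,
                             "prob": p, "chance": ch, "ratio": ratio,
                             "high_probability": population.classify_high_probability(ratio)}
                        )
        return offs, bounds, pd.DataFrame(rows)

    pop_result = stage("population", pop)
    if pop_result is not None:
        offs, bounds, prob_df = pop_result
        pd.DataFrame(
            [{"start": o.start, "end": o.end, "duration": o.duration} for o in offs]
        ).to_csv(out / "off_periods.csv", index=False, float_format="%.6f")
        pd.DataFrame(
            [{"onset": b.onset, "offset": b.offset} for b in bounds]
        ).to_csv(out / "cluster_boundaries.csv", index=False, float_format="%.6f")
        prob_df.to_csv(out / "boundary_probability.csv", index=False, float_format="%.6f")
        onset_high = (
            prob_df.query("which == 'onset'")["high_probability"].sum()
            if len(prob_df)
            else 0
        )
        summary["population"] = {
            "n_off_periods": len(offs),
            "n_clusters": len(bounds),
            "n_high_probability_onset_units": int(onset_high),
        }

    # ---- ground-truth recovery (synthetic inputs only) ---------------------
    if truth is not None:
        from . import _intervals

        tol = 0.025
        true_t = np.asarray(truth.true_ripple_times)
        matched_true = (
            np.abs(true_t[:, None] - troughs[None, :]).min(axis=1) <= tol
            if troughs.size and true_t.size
            else np.zeros(true_t.size, dtype=bool)
        )
        matched_det = (
            np.abs(troughs[:, None] - true_t[None, :]).min(axis=1) <= tol
            if troughs.size and true_t.size
            else np.zeros(troughs.size, dtype=bool)
        )
        summary["ground_truth_recovery"] = {
            "ripple_sensitivity": float(matched_true.mean()) if true_t.size else None,
            "ripple_precision": float(matched_det.mean()) if troughs.size else None,
            "state_agreement": states_mod.state_agreement(
                scored, truth.true_state_intervals
            ),
        }
        if pop_result is not None:
            detected_off = [(o.start, o.end) for o in pop_result[0]]
            summary["ground_truth_recovery"]["off_period_jaccard"] = _intervals.jaccard(
                detected_off, truth.true_off_periods
            )

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    if config.make_figures:
        _make_figures(rec, scored, ripples, out)
    return summary


def _make_figures(rec, scored, ripples, out: Path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(2, 1, figsize=(10, 5), sharex=True)
    t = np.arange(min(rec.lfp_ca1.size, int(20 * rec.fs_ca1))) / rec.fs_ca1
    ax[0].plot(t, rec.lfp_ca1[: t.size], lw=0.3)
    ax[0].set_ylabel("CA1 (uV)")
    ax[1].plot(t, rec.lfp_rsc[: t.size], lw=0.3, color="tab:blue")
    ax[1].set_ylabel("RSC (uV)")
    for e in ripples:
        if e.trough_time < t[-1]:
            ax[0].axvline(e.trough_time, color="r", alpha=0.4, lw=0.5)
    ax[1].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(out / "overview.png", dpi=120)
    plt.close(fig)
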