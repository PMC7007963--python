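# ripplecoord

Analysis toolkit for dual-site sleep electrophysiology: hippocampal CA1 and
retrosplenial cortex (RSC) recorded simultaneously in freely behaving
rodents. It is written for systems neuroscientists who have LFP channels,
sorted single units with mean spike waveforms, and (optionally)
optostimulation pulse times, and who want to quantify how hippocampal
sharp-wave ripples coordinate cortical activity during slow-wave sleep
(SWS).

The package implements, as tested and reusable library code:

- **Sleep-state scoring** from the CA1 theta (6–10 Hz) / delta (1–4 Hz)
  band-power ratio within immobile periods (ratio ≥ 2 → REM, ≤ 1 → SWS).
- **Sharp-wave ripple detection**: zero-phase Butterworth band-pass
  150–250 Hz, Hilbert envelope smoothed with a 4 ms Gaussian, events where
  the envelope exceeds mean + 3 SD for ≥ 15 ms; amplitude classes from the
  trough depth of the band-passed trace (> 8 / 6–8 / 4–6 SD).
- **Cortical Up/Down states** (1–4 Hz, ±1 SD excursions > 50 ms) and
  peri-ripple Up/Down occupancy.
- **Peri-ripple spectrograms** (1–300 Hz) z-scored per band against a
  −1.0…−0.5 s baseline, and pre/post (±0.2 s) band power ratios.
- **Waveform-based unit classification**: normalized 0–1 ms spike shapes →
  3 principal components → hierarchical clustering (Ward, Euclidean) cut to
  three clusters → putative excitatory / inhibitory / other by
  trough-to-peak width; < 0.5 Hz units excluded from spike analyses.
- **Z-scored correlograms and response calls** using
  Zᵢ = (Xᵢ − x̄)/σ with per-analysis baselines: ripple activation (0–10 ms
  bin z > 3.3), optostimulation activation/inhibition (0.5 ms bins,
  pre-train baseline), pairwise E–I cross-correlograms with monosynaptic
  (≤ 2 ms) calls, ripple phase-locking tests and delay estimation, and
  size-stratified pre/post firing.
- **Population ON/OFF analysis**: OFF periods (no RSC spike for ≥ 100 ms,
  ≥ 8 units, SWS only), cluster onsets/offsets, per-unit boundary firing
  probability versus circularly shuffled chance with the 5-fold rule, and
  ripple co-termination profiles.
- **A ground-truthed synthetic-data generator** that emulates all of the
  above structure (nested ripples, state schedules, ON/OFF gating,
  phase-locked interneurons at a configurable monosynaptic delay, waveform
  families), used for recovery testing and as a stand-in for raw recordings
  that are not publicly deposited.

See `docs/methods.md` for the precise rules, parameter defaults, and the
generator's scope.

## Worked example

Run the whole chain on a synthetic 600 s session (states → ripples →
up/down → unit classes → responses → population statistics):

```python
from ripplecoord.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="out", seed=5)
cfg.synth.duration_s = 600.0
summary = run_pipeline(cfg)
```

or equivalently `ripplecoord run --out out --seed 5`. The summary (also in
`out/summary.json`, next to the CSV tables) prints:

```json
"ripples":   {"n": 129, "by_size": {"LARGE": 16, "MEDIUM": 68, "SMALL": 45},
              "pct_onset_trough_lag_5_30ms": 98.4},
"units":     {"EXC": 16, "INH": 4, "OTHER": 2},
"ripple_responses": {
  "inhibitory": {"n_activated": 4, "n": 4, "pct": 100.0},
  "excitatory": {"n_activated": 2, "n": 16, "pct": 12.5},
  "phase_locked_inh": {"n": 4, "mean_delay_ms": 4.51}},
"population": {"n_off_periods": 492, "n_clusters": 491,
               "n_high_probability_onset_units": 8},
"ground_truth_recovery": {"ripple_sensitivity": 0.985,
                          "ripple_precision": 1.0,
                          "state_agreement": 1.0,
                          "off_period_jaccard": 0.985}
```

Reading: 129 ripples were detected during scored SWS and classified by
trough depth; the waveform classifier recovered the generator's 16/4/2
excitatory/inhibitory/other split; all 4 putative inhibitory units show a
post-ripple (0–10 ms) z > 3.3 activation, phase-locked at a mean delay of
4.51 ms versus the injected 4.6 ms monosynaptic delay; 492 population OFF
periods segment RSC activity into clusters whose onsets are dominated by
the 8 planted onset-preferring units; and the bottom block scores the
pipeline against the generator's ground truth (fractions of injected
ripples / OFF intervals recovered).

Stage-level commands are available too:

```bash
ripplecoord synth --out rec.h5 --seed 1 --duration 600
ripplecoord score-states rec.h5 --out states.csv
ripplecoord detect-ripples rec.h5 --states states.csv --out ripples.csv
ripplecoord classify-units rec.h5 --out units.csv
ripplecoord peth rec.h5 --ref ripples.csv --out peth.csv
ripplecoord off-periods rec.h5 --states states.csv --out off.csv
```

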