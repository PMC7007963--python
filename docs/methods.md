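# Methods

`ripplecoord` analyzes dual-site extracellular recordings from hippocampal
CA1 and the granular retrosplenial cortex (RSC) during sleep: LFP channels at
2 kHz on both sites, sorted single units with mean spike waveforms (30 kHz),
optional optostimulation pulse times, and a behavioral immobility mask. This
note documents the models and rules each stage implements, the free
parameters and why their defaults are what they are, what the synthetic-data
generator does and does not emulate, and the numerical choices made where the
procedure left room.

All times are seconds from recording start; intervals are half-open
`[start, end)`. Voltages are float32, times float64.

## Sleep-state scoring

States are scored only within caller-supplied immobile "bed" intervals, in
non-overlapping windows (default 5 s), from the ratio of integrated Welch
band power in theta (6–10 Hz) to delta (1–4 Hz) of the CA1 LFP:
ratio ≥ 2 → REM, ratio ≤ 1 → SWS. The window length is a compromise between
delta-band resolution (≥ 2 s needed for two delta cycles) and latency at
state transitions; 5 s keeps transition mislabeling to one window per
boundary. Band power is integrated over the band (not averaged per bin) so
that two equal-power oscillations, one per band, give a ratio of exactly 1
regardless of the unequal bandwidths.

Windows whose ratio falls strictly between 1 and 2 match neither rule; they
are labeled OTHER and excluded from every SWS analysis rather than silently
absorbed into a sleep state. Awake immobility is behavioral context (e.g.
food consumption) that LFP alone cannot identify; such intervals are passed
in separately and labeled `AWAKE_IMMOBILE` verbatim.

## Ripple detection and sizing

The CA1 trace is band-passed 150–250 Hz with a zero-phase (forward–backward)
order-5 Butterworth filter; the envelope is the Hilbert magnitude smoothed by
a Gaussian kernel of 4 ms SD. Envelope mean and SD are estimated over
eligible state time only (SWS and awake immobility; configurable) — using
the whole session would dilute the statistics with movement artifact and
theta epochs. Events are maximal runs with envelope > mean + 3 SD lasting
≥ 15 ms; runs separated by < 30 ms are merged first (the merge gap is below
any inter-ripple spacing of interest and prevents double-counting envelope
dips within one event). Detection needs ≥ 10 s of eligible time for a stable
SD estimate and is invariant to rescaling the voltage, since every threshold
is in SD units.

The trough is the minimum of the band-passed trace within the event; its
depth in SD units of that trace sets the amplitude class: > 8 SD large,
6–8 SD medium, 4–6 SD small; shallower excursions are discarded. The 3-SD
rule applies to the smoothed envelope and the 4/6/8-SD rule to the signed
trace, which is the only object with a defined "amplitude below the mean".

## Up/Down states

The RSC LFP is band-passed 1–4 Hz (same zero-phase filter); Up (Down) states
are excursions > 1 SD above (below) the mean lasting > 50 ms, with mean/SD
over SWS time. Detection reduces to a threshold-run scan of the filtered
trace and is tested against an independent brute-force implementation.
`updown_probability_around` reports, per 10 ms bin in ±0.5 s around ripple
troughs, the fraction of ripples for which that bin lies inside an Up
(resp. Down) state.

## Peri-event spectrogram and band ratios

Event-triggered spectrograms use a 100 ms Hann window stepped by 10 ms
(both configurable), zero-padded to 1 Hz frequency spacing over 1–300 Hz,
averaged across events. Events whose window would cross a recording edge are
dropped and counted, never zero-padded.

Each frequency row is z-scored against the −1.0…−0.5 s baseline columns. The
baseline SD is estimated, by default, from the pooled per-event baseline
samples scaled by 1/√n_events — the standard error of the event average.
The alternative (`baseline_stat="columns"`), taking the SD across baseline
columns of the averaged matrix, is what one does when z-scoring a grand
average over many sessions; for a single session it is poorly conditioned:
with a 100 ms window and 10 ms hop, the 50 baseline columns contain only
~10 statistically independent values (the window autocorrelation sums to
~4.8 across lags), so the resulting z behaves like a t statistic with ~10
degrees of freedom and over-rejects under stationarity. The pooled estimator
has ~1000 effective degrees of freedom and calibrates correctly; both are
recorded in the result's metadata.

The pre/post power-ratio statistic divides mean raw (never z-scored) power
in −0.2–0 s by that in 0–0.2 s, per band; default bands 1–4, 4–10, 10–30,
30–80, 80–150 and 150–300 Hz. Note the time–bandwidth limit: a 0.2 s window
holds roughly one independent sample of 1–4 Hz power per event, so low-band
ratios have a sampling SD of ~1/√n_events even under perfect stationarity.

## Unit classification

Mean waveforms are trough-aligned, cropped to the 1 ms after the trough,
peak-normalized, and resampled to a common 33-sample grid. PCA (mean-centered,
no variance scaling — the samples share units after normalization) reduces
each to three scores; agglomerative clustering (Euclidean metric, Ward
linkage by default, configurable to single/average) is cut to exactly three
clusters. The tree is cut by cluster count rather than a distance criterion,
which makes the rule scale-free. Identities are assigned post hoc by mean
trough-to-peak width: narrowest cluster → putative inhibitory, widest →
putative excitatory, remainder → other. If the tree is degenerate
(effectively identical waveforms; total linkage height < 1e-6 in normalized
units) a warning is issued and the width rule is applied to the clusters
that exist.

Units with an overall mean rate below 0.5 Hz are excluded from spike-train
analyses (too few spikes for the z transforms); the boundary is read
exclusively, so exactly 0.5 Hz is kept.

## Correlograms, z transform and response calls

Peri-event histograms count spikes per bin across references and convert to
rate (count / (n_ref × bin)). The z transform is Zᵢ = (Xᵢ − x̄)/σ with x̄, σ
from declared baseline bins only (≥ 10 bins required; zero baseline SD is an
error naming the unit):

- Ripple responses: 10 ms bins, ±1 s window, baseline −1.0…−0.5 s. A unit is
  **activated** iff the z of the single 0–10 ms post-trough bin exceeds 3.3
  (per-test p < 0.001 two-sided under a normal null; no multiple-testing
  correction across units — the strict threshold is the control).
- Optostimulation: 0.5 ms bins referenced to **train onsets**, baseline
  −60…0 ms before the train. At 25 Hz a per-pulse baseline for pulses 2–3
  would contain the previous pulse's response — for a suppressed unit the
  baseline becomes bimodal and its SD explodes, making the inhibited call
  unreachable — so the stimulation-free pre-train stretch is the only
  coherent baseline. Per-pulse z segments (0–20 ms after each pulse) are then
  averaged across the train's pulses. Activated iff the averaged peak z in
  (0, 10] ms exceeds 3.3 (latency = time of the averaged peak rate);
  inhibited iff the averaged mean z over (0, 20] ms is below −3.3; activation
  takes precedence when both hold. The reachable |z| of a silenced unit is
  bounded by √(baseline counts per bin), so the inhibited call has power only
  with high firing rates and several hundred trains.
- Pairwise cross-correlograms: 0.5 ms bins, ±10 ms window, baseline
  −10…−5 ms. Excitation (inhibition) a→b is called when z > 3.3 (< −3.3) in
  some bin within (0, 2] ms — the monosynaptic latency bound — and b→a
  symmetrically at negative lags. When the global **positive** z peak sits
  within ±1 ms the pair is flagged as synchrony (common input) and no
  directional call is made; a trough within ±1 ms does not trigger the flag,
  since shared drive produces coincident excess, not coincident silence.
  Pairs with < 100 spikes in either train return an insufficient-data result.

### Phase locking and delay

Phase locking to the ripple rhythm is quantified from the fine PETH (0.5 ms
bins, ±20 ms around ripple troughs): the unit is locked iff the discrete
power spectrum of the mean-subtracted PETH peaks in 150–250 Hz and that peak
exceeds 10× the median spectral power. Two numerical points shaped this
statistic. First, the spectrum of a Poisson unit's PETH is approximately
i.i.d. exponential across bins, so its maximum is *expected* near 5.4× the
median — a smaller threshold is cleared by noise alone; at 10× the joint
null probability (in-band peak above threshold) is below 1%, while locked
units under study conditions score 40–70×. Second, the argmax competes only
among frequencies ≥ 100 Hz, because slow within-window rate modulation
(pre-ripple ramps, post-ripple suppression) is present in unlocked units too
and is not ripple-band periodicity. The threshold and the spectral details
are reported with every call.

The delay is the center of the maximal bin in (0, 10] ms, refined by a
baseline-subtracted center of mass over ±2 ms (the locking-jitter scale;
neighboring ripple-cycle peaks sit > 4 ms away and stay outside the
refinement window). The baseline is the mean rate earlier than −12 ms. The
refinement gives sub-bin placement; across seeded replicates the recovery
bias is well under a quarter bin.

Size-stratified firing reports mean rates in −100–0 ms (pre) and 0–10 ms
(post) per amplitude class per unit; classes with no events are absent from
the result rather than reported as zero rates.

## Population OFF periods and clusters

OFF periods are gaps ≥ 100 ms in the merged spike train of all RSC units,
lying wholly inside a single SWS interval (gaps straddling state edges are
discarded); their bounding spikes are the edges. The analysis refuses to run
with fewer than 8 simultaneously recorded units (overridable), since sparse
populations produce spurious silence. The implementation is a sorted-merge
gap scan and is tested for exact equivalence with a brute-force oracle.

ON clusters are the maximal spike runs between consecutive OFF periods;
onset/offset are the first/last spikes. Clusters truncated by session or
state edges have no defined boundary and are excluded from boundary
statistics.

Boundary firing probability for a unit is the fraction of cluster onsets
(offsets) with ≥ 1 spike of that unit within 0–5 ms after (−5–0 ms before)
the boundary. Chance is the mean of the same statistic over seeded circular
shifts of the unit's whole spike train modulo the session duration (default
1000 shuffles; uniform shift in [10 s, duration − 10 s]); circular shifting
preserves the inter-spike-interval structure, which jittering would destroy.
A unit is "high probability" at ratio ≥ 5 (inclusive); a zero chance with
nonzero observed probability reports an infinity flag, which counts as high.

Ripple clusters group troughs with inter-trough gaps ≤ 0.2 s (the procedure
gives no value; 0.2 s matches the minimum inter-ripple spacing the generator
enforces and the scale of ripple bursts). Co-termination profiles report
boundaries per ripple per 10 ms bin in ±0.5 s around troughs.

## Synthetic data generator

The generator produces recordings with the statistical structure the
analyses assume, plus a ground-truth record (injected ripple times and
amplitudes, state schedule, unit labels, per-unit delays, ON/OFF intervals).
One master seed feeds a named sub-stream per component, so identical
configurations reproduce byte-identical recordings.

- **LFP**: 1/f-amplitude ("pink") background noise (SD 30 µV); during SWS a
  1 Hz slow oscillation (60 µV) on CA1 and a smoothed ON/OFF envelope wave
  on RSC; during REM an 8 Hz theta component (60 µV) so theta/delta scoring
  recovers the schedule. CA1 ripples are Hann-windowed 180 Hz cosine bursts
  (50 ms) with the deepest trough at the center. Injected amplitudes are in
  SD units of the ripple-band-filtered background, which makes "an n-SD
  ripple" well defined; the default is 7 SD with 1.2 SD jitter, clipped at
  4.5 (below the small-ripple floor nothing should be considered an event).
- **Ripple times**: Poisson at 0.3 Hz within SWS with 200 ms minimum
  separation; 60% of them are placed 20 ms before the end of an ON cluster
  so that RSC clusters and ripples co-terminate, the rest uniformly inside
  ON periods. Events keep 1.2 s clear of recording edges.
- **ON/OFF envelope**: within each SWS epoch, alternating ON (350–900 ms)
  and OFF (100–600 ms) intervals; all RSC spiking is gated by it during SWS
  and ungated in REM, so OFF periods exist only in SWS.
- **Spike trains**: inhomogeneous Poisson via Bernoulli thinning on a 1 ms
  grid. Excitatory units: 3–12 Hz, a ~75% rate dip 20–80 ms post-ripple and
  a rebound 80–150 ms post-ripple, and a pre-ripple gain increasing with
  ripple amplitude. Inhibitory units: 15–30 Hz with extra spikes injected
  per ripple **cycle** (offsets −2…+2 cycles, Hann-like weights) at
  trough + delay (default 4.6 ms) with 0.9 ms Gaussian jitter and
  probability p_lock = 0.6 scaled by ripple amplitude — per-cycle injection
  is what makes the PETH periodic at the ripple frequency, as phase locking
  requires. CA1 pyramidal units fire at cycle troughs with ~0.4 ms jitter.
  Half of the excitatory units are "onset-preferring": they emit a spike
  within 2 ms of each cluster onset with probability 0.8, while the
  remaining units join clusters ~10 ms late, so cluster-onset probability
  analysis has a planted positive class.
- **Waveforms**: three template families parameterized by trough-to-peak
  width — wide/excitatory (0.5–0.8 ms, slow positive hump), narrow/
  inhibitory (0.15–0.3 ms, fast repolarization with an
  after-hyperpolarization dip), intermediate/other (0.35–0.45 ms, initial
  positive deflection) — with per-unit shape noise and arbitrary amplitude
  (50–400 µV). Widths are unimodal (clipped normal) within each family:
  real populations cluster compactly per class in principal-component
  space, and a uniform width spread would make within-class variance exceed
  the between-class gaps that a 3-cluster cut relies on.
- **Optostimulation** (off by default): trains of 3 pulses at 25 Hz every
  10–15 s; inhibitory units respond at 4 ms with probability 0.7, excitatory
  units are 90% suppressed for 20 ms per pulse.

What the generator does **not** emulate: spike-sorting noise and unit drift,
non-stationary state transitions (schedules are block-wise), sharp-wave
(stratum radiatum) components, realistic 1/f deviations, EMG/movement
artifact, and conductance-level biophysics. Passing recovery tests therefore
demonstrates that the pipeline implements its stated rules correctly and
recovers planted structure under in-model conditions — not that it is robust
to every artifact of real recordings.

## Problem sizes and determinism

Default test and acceptance runs use desk-scale sessions chosen to give each
statistic adequate counts: 600 s sessions (~140 ripples) for detector
recovery and response fractions, an 1100 s all-SWS session (~600 ripples)
for delay recovery, 170 waveforms (130/31/9) for classification, 200 Poisson
units for null calibration, and 900 s of stationary noise with 200 events
for spectrogram calibration. Every random step takes an explicit seed;
`scripts/acceptance.py` derives all of its sub-stream seeds from the single
`--seed` argument.

## Known limitations

- The phase-locking statistic is this package's explicit operationalization
  of "clear phase locking"; alternatives (circular statistics on spike
  phases) are out of scope and would need the instantaneous phase of the
  filtered trace.
- The opto inhibited call is count-limited (see above); with few trains or
  low rates it cannot fire, mirroring the limits of the underlying rule.
- The HDF5 container is this package's own layout; vendor formats and NWB
  are out of scope.
- State scoring assumes the caller's immobility mask is correct; no
  EMG/video inference is attempted.
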