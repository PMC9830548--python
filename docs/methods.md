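# Methods

This document describes the analysis methods implemented in `rodentpsg`, the
parameter defaults and their rationale, the synthetic ground-truth generator
used for validation, and the numerical choices that matter for
reproducibility.

## Signals and preprocessing

A recording consists of two epidural EEG channels (left and right) and one
nuchal EMG channel. Acquisition bands follow standard rodent practice
(EEG 0.1–100 Hz, EMG 0.1–400 Hz). All quantitative analysis runs at a common
200 Hz rate; higher-rate recordings are downsampled with polyphase
anti-aliased resampling (`scipy.signal.resample_poly`).

Band-pass filtering is a zero-phase (forward–backward) cascade of 4th-order
Butterworth high-pass and low-pass sections. A cascade is used instead of a
single band-pass design because a 0.1 Hz edge next to a 100 Hz edge makes the
normalized band-pass numerically fragile. The forward–backward pad length is
scaled to the low corner (`3 / low_hz` seconds, capped at the signal length):
a sub-hertz high-pass settles over tens of seconds and scipy's default
padding leaves edge transients that contaminate short segments.

Movement artifacts are flagged from EMG power because these recordings carry
no video channel: seconds where the 1-s EMG RMS exceeds
`median + 5 × 1.4826 × MAD` are masked. EMG tone is bimodal (wake tone versus
sleep atonia), so when a substantial high-tone mode exists the threshold is
anchored on that mode; otherwise half of a normal wake bout would be flagged.
Artifact intervals closer than 1 s are merged and the mask is idempotent.

## Vigilance-state staging

Staging uses 10-s epochs built from 1-s sub-epochs. Per-second features are
the EMG RMS, the EEG delta (0.5–4 Hz) and theta (6–10 Hz) band powers, total
0.5–30 Hz power, and the broadband envelope, averaged across the two EEG
channels.

Each second is labeled by rule:

- **wake** — EMG RMS above the tone threshold;
- **NREM** — delta fraction of total power > 0.5 and EEG envelope above the
  record median (high-amplitude slow activity with atonia);
- **REM** — theta/delta power ratio > 1.5 with low envelope and atonia.

Seconds matching no rule are assigned to the nearest state in feature space.
An epoch takes the state occupying more than 5 of its 10 seconds; a 5/5 tie
inherits the previous epoch's state. Epochs with more than 5 artifact-masked
seconds are labeled `artifact` and excluded from all downstream metrics.

Thresholds are calibrated per record (minimum 30 min): the EMG tone cut is
the midpoint of a 2-means split of the log EMG RMS distribution, and the
envelope reference is the record median. Per-record calibration absorbs
electrode impedance and gain differences between animals.

State metrics are per-state total duration, bout counts (a bout is a maximal
run of same-state epochs; artifact epochs break bouts), and transition
counts.

## Discharge detection (SWD and SSWD)

Spike-wave discharges (SWD, 6–12 Hz) and slow spike-wave discharges
(SSWD, 3–6 Hz) are detected per channel from the Hilbert envelope of the
band-passed signal and must exceed 1 s after refinement.

**State-dependent thresholds.** The local baseline is the median Hilbert
envelope over the preceding 10 s of same-state, artifact-free signal, looking
back at most 60 s. During wake and REM a candidate must reach 2× the
broadband (0.5–30 Hz) baseline; during NREM, where ongoing delta raises the
floor, it must reach 1.5× the delta-band (0.5–4 Hz) baseline. Detection runs
in two passes: events found in pass one are excluded from the baseline
windows of pass two, so dense discharge trains cannot inflate their own
baseline.

**Detection band padding.** The detection filter corners are widened by 15%
(e.g. 5.1–13.8 Hz for SWD). A 4th-order Butterworth is 3 dB down at its
corners, so a discharge at the band edge would present ~0.71× of its true
amplitude and be missed near threshold. To keep the padding from admitting
out-of-band activity, every accepted event must have its (unclipped) spectral
peak inside the *nominal* band.

**Segmentation.** Supra-threshold runs separated by < 0.3 s are merged;
onset and offset are then refined outward to the nearest broadband-baseline
crossing (at most 1 s each way), and refined spans must still exceed 1.0 s.
Overlapping SWD/SSWD candidates are resolved by the spectral peak of their
union over 3–12 Hz (≥ 6 Hz → SWD), first per channel and again across
channels after lateralization. Events on the two EEG channels whose
intersection covers at least 50% of the shorter span are merged as
`bilateral` (union extent); others are `left`/`right`.

For detection conditioning, the per-second state track is smoothed: runs
shorter than 6 s whose flanking states agree are absorbed, because 1-s
staging features are polluted at state boundaries and by the events
themselves, while genuine episodes last tens of seconds.

Events overlapping the artifact mask are discarded. Each event carries its
state at onset, band, spectral peak frequency, and laterality.

## Sleep-spindle detection

Spindles (10–15 Hz, 0.5–5 s) are detected only within NREM. The envelope is
smoothed with a 0.2-s moving average and compared to a dual threshold built
from the same two-pass baseline machinery: the core threshold is the baseline
envelope mean plus 1.5 × SD of the raw band-passed baseline signal, and the
extension floor is mean + 0.75 × SD. Cores must hold for ≥ 0.3 s; each core
is extended outward while the smoothed envelope stays above the floor (at
most 1 s each way, NREM and artifact-free only), near-adjacent spans are
merged, and the extended event must last 0.5–5 s. The dual threshold is
needed because a spindle envelope crosses the high threshold only near its
crest; a single threshold fragments events and truncates onsets. Spindles
overlapping a detected discharge are discarded. The spindle band is used
unpadded: corner padding raises the in-band noise SD and costs more recall
than edge attenuation does.

## Spectral analysis

Power spectral densities use unit-energy DPSS (Slepian) multitapers with
time–bandwidth `nw = 4` and 7 tapers, one-sided, on ≥ 1-s segments. The
estimator satisfies Parseval (`sum(psd) · df` equals the biased variance) and
scales exactly quadratically with amplitude. Band power is the mean PSD over
band bins.

NREM delta power is the mean delta-band ([0.1, 4] Hz) PSD across the first
`total_s / 10` artifact-free NREM 10-s windows, averaged over the two EEG
channels. Using a fixed number of windows rather than all NREM makes the
metric comparable between animals with different sleep amounts.

## Incidence metrics and group statistics

Per-state incidence pools SWD and SSWD: events per hour of state, discharge
seconds per hour of state, and percent of state time spent discharging — all
exact arithmetic on the detected event table and the hypnogram. Spindle
density is spindles per second of NREM.

Group comparisons use two-sided Student t-tests (paired or pooled unpaired;
Welch optional) and one-way ANOVA with Holm–Šidák-adjusted pairwise
follow-ups (via `statsmodels`). Degenerate inputs (identical groups) are
reported as statistic 0, p = 1 with a flag rather than raising. `cohort_report`
runs a declarative list of comparisons (split by genotype, sex, phase, or
state; optional row filters; paired designs matched by animal id) over
per-animal metrics.

## Synthetic ground-truth generator

Validation uses a generator whose every output is labeled exactly.

- **State sequence.** A semi-Markov chain at 1-s resolution with log-normal
  dwell times (wake 90 s, NREM 90 s, REM 75 s means; shape 0.6) and fixed
  transition probabilities (wake→NREM; NREM→wake 0.6/REM 0.4; REM→wake
  0.7/NREM 0.3).
- **Background signals.** 1/f noise plus state-gated delta (NREM, 0.15 mV
  RMS) and theta (REM, 0.06 mV RMS) band noise, blended across transitions
  with 0.5-s Hann crossfades; EMG RMS 0.10 / 0.02 / 0.008 mV in
  wake / NREM / REM. Each EEG channel receives 20% independent noise.
- **Events.** SWDs (6–12 Hz, 1.3–4 s, default 60/20/15 per hour of
  NREM/wake/REM), SSWDs (3–6 Hz, NREM only), and spindles (10–15 Hz,
  0.8–2.5 s, NREM only). Discharge waveforms are a fundamental plus a
  half-amplitude second harmonic under a Tukey(0.15) window, scaled to a
  multiple of the *local* median baseline envelope (delta-band in NREM,
  broadband elsewhere) so the injected contrast matches the detector's own
  definition of baseline. Spindle amplitude is set in SD units of the local
  band-passed signal under a Tukey(0.5) window. Events keep an 11-s margin
  from state boundaries and never overlap.
- **Artifacts.** Wake-only movement bursts (10× EMG, 6× EEG, 2 s, 2/hr).
- **Cohorts.** Each animal gets a log-normal random discharge-rate effect
  (σ = 0.25) shared across its phases; female animals get a `sex_effect`
  multiplier on NREM delta amplitude; `post` phases get `phase_effect`
  multipliers on discharge rates and NREM dwell. Per-animal seeds are drawn
  below 2³¹ from the cohort seed, so every record is individually
  reproducible.

Known limitations: waveforms are stylized (no spike asymmetry or chirp),
state dynamics ignore circadian structure, and artifacts are confined to
wake. The generator is a calibration target, not a biophysical model.

## Validation battery and problem sizes

`scripts/acceptance.py` (and `tests/test_acceptance.py`, one test per
criterion) checks:

1. incidence arithmetic is exact on a hand-computable example
   (12 events / 30 s / 0.1 h → 120 per hr, 300 s per hr, 8.33%);
2. the thresholded span primitive equals an explicit brute-force loop on 20
   random 60-s records, and t/F statistics match hand formulas to 1e-10;
3. staging a 6-h record: accuracy ≥ 95% and per-state bout counts within
   ±10% in < 5 min (measured: 99.2% accuracy, ≤ 1% bout error, ~75 s);
4. discharge precision and recall ≥ 0.9 at 2.5× baseline amplitude
   (0.5-s onset tolerance) in both threshold regimes, on two 30-min records;
5. Parseval within 10%, flat delta-density recovery within 15%, quadratic
   scaling to 1e-9;
6. end-to-end cohort recovery on 30-min records: NREM discharge preference
   (ANOVA over states, n = 8), paired pre/post rate increase at a 1.6×
   effect (n = 8), and female > male NREM delta power at a 2× amplitude
   effect (n = 13/13), all significant at α = 0.05 with the correct
   direction, in < 15 min;
7. the slow-wave-oscillation induction protocol (0.5 Hz; 1.8 s laser-on
   down-state, 0.2 s up-state with a 20-ms pulse) yields exactly 300 cycles
   and 300 pulses in 10 min;
8. the same seed reproduces signals, events, and analyses byte-for-byte.

## Numerical choices

- All envelopes are Hilbert magnitudes of zero-phase filtered signals.
- Multitaper windows are unit-energy; one-sided doubling halves the Nyquist
  bin for even lengths so Parseval holds exactly.
- EDF output quantizes to 16 bits over ±10 mV (step ≈ 0.3 µV); round-trip
  error is bounded by one quantization step.
- Event tables serialize floats with `np.format_float_positional` (unique
  round-trip representation, ≥ 3 decimals).
- All random draws flow from `numpy.random.default_rng` seeds; no global
  RNG state is used anywhere.
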