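# rodentpsg

Quantitative mouse polysomnography: vigilance-state staging, spike-wave
discharge and sleep-spindle detection, NREM delta power, and cohort
statistics for chronic EEG/EMG recordings in genetic epilepsy models — with
a ground-truthed synthetic generator for end-to-end validation.

## What it does

Given a recording with two EEG channels and one EMG channel, `rodentpsg`:

- **stages** wake / NREM / REM in 10-s epochs (a state must occupy > 5 s of
  an epoch; thresholds are calibrated per record from the EMG tone
  distribution and EEG envelope);
- **detects discharges** — SWDs (6–12 Hz) and slow SWDs (3–6 Hz), each
  > 1 s — against state-dependent local baselines: 2× the broadband envelope
  in wake/REM, 1.5× the delta-band envelope in NREM, with two-pass baseline
  estimation, onset/offset refinement, and left/right/bilateral labeling;
- **detects sleep spindles** (10–15 Hz, 0.5–5 s) within NREM, excluding
  spans claimed by discharges;
- **quantifies** per-state discharge incidence (events/hr, discharge-seconds/hr,
  % of state), spindle density, bout architecture, and multitaper NREM delta
  power ([0.1, 4] Hz);
- **compares groups** with paired/unpaired t-tests and one-way ANOVA with
  Holm–Šidák-corrected follow-ups, driven by a declarative cohort design;
- **simulates** fully labeled synthetic recordings (semi-Markov states,
  1/f + band-noise EEG, injected discharges/spindles/artifacts, cohort-level
  sex and treatment-phase effects) so every pipeline stage can be validated
  against exact ground truth.

See [docs/methods.md](docs/methods.md) for the full scientific description
and the validation battery.

## Quick start (CLI)

```bash
# simulate a 30-min ground-truthed recording
rodentpsg simulate --duration 1800 --seed 1 --out sim/

# stage it, detect events, and write tables
rodentpsg analyze sim/record.edf --out results/ --delta-power-s 300
```

`results/` then contains `events.csv` (one row per detected SWD/SSWD/spindle
with onset, duration, peak frequency, laterality, and state), `hypnogram.csv`
(10-s epochs), and `metrics.json`.

## Worked example (Python)

```python
from rodentpsg import GeneratorSpec, generate_record, analyze_record

record, truth = generate_record(GeneratorSpec(duration_s=1800.0, seed=1))
res = analyze_record(record, delta_power_total_s=300.0)

labels = res.hypnogram.labels
acc = sum(a == b for a, b in zip(labels, truth.epoch_labels())) / len(labels)
print(f"staging accuracy : {acc:.3f}")
print(f"detected events  : {len(res.events)} "
      f"(truth: {len(truth.events)})")
m = res.animal_metrics
print(f"NREM SWD rate    : {m.swd_per_hr['NREM']:.1f} /hr")
print(f"spindle density  : {m.spindle_density_hz * 60:.1f} /min of NREM")
print(f"NREM delta power : {m.nrem_delta_power_mv2_hz:.4f} mV^2/Hz")
```

Output:

```text
staging accuracy : 0.994
detected events  : 19 (truth: 19)
NREM SWD rate    : 32.0 /hr
spindle density  : 0.5 /min of NREM
NREM delta power : 0.0056 mV^2/Hz
```

## Validation

The acceptance battery generates everything it needs from one seed and
writes its headline numbers as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

It covers exact incidence arithmetic, brute-force detector oracles,
6-h staging accuracy (≥ 95%), discharge precision/recall (≥ 0.9 at 2.5×
baseline in both threshold regimes), multitaper calibration (Parseval,
known-density recovery, quadratic scaling), end-to-end recovery of cohort
effects (state preference, treatment phase, sex), the SWO induction
protocol timing, and byte-for-byte seed determinism. The same checks run as
`tests/test_acceptance.py`, one test per criterion:

```bash
pytest -q
```

## Layout

```
src/rodentpsg/
  core.py           records, hypnograms, event intervals, interval utilities
  io_signals.py     EDF read/write, event/hypnogram tables
  preprocess.py     filtering, resampling, EMG artifact masking
  staging.py        per-second features, calibration, epoch scoring
  events.py         SWD/SSWD and spindle detection
  spectral.py       multitaper PSD, spectrogram, NREM delta power
  stats_summary.py  incidence metrics, t-tests/ANOVA/Holm-Šidák, cohort report
  synthetic.py      ground-truthed generator, cohorts, SWO protocol
  pipeline.py       one-call record analysis
  cli.py            `rodentpsg simulate` / `rodentpsg analyze`
```
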