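# somnostim

Closed-loop auditory slow-wave stimulation, offline and testable.

During deep (N2/N3) sleep the EEG is dominated by ~0.5–2 Hz slow
oscillations. Brief sounds played at specific phases of these oscillations
can enhance or perturb slow-wave activity (SWA), and the enhancement is
echoed in cardiovascular dynamics (heart-rate slowing, increased
beat-to-beat variability). `somnostim` re-implements, as a plain Python
library, a windowed within-night stimulation protocol and its complete
analysis chain:

* **Stimulation engine** — causal sleep-state gating (low-delta 2–4 Hz /
  high-delta 3–5 Hz / high-beta 20–30 Hz power, EOG anti-correlation,
  movement holdoff, deep-sleep delta gate; 10 min of uninterrupted
  detected NREM before the first stimulation, 3 min after every
  interruption), a first-order phase-locked loop (PLL) that tracks the
  slow-oscillation phase and fires at a target phase (50° for up-phase,
  230° for down-phase, with the signal ∝ sin(phase)), a pseudorandomized
  permutation-block condition sequencer, and a scheduler that opens
  10 s ON + 10 s OFF stimulation windows. Conditions: UP, DOWN (one
  50 ms pink-noise burst per detected slow wave), ISI1 at 1 Hz with
  constant (45 / 42.5 dB) or ramped (40→45→42.5 dB) volume, 1 Hz
  amplitude-modulated pink noise (ENVELOPE), 400/401 Hz BINAURAL BEATS,
  and silent SHAM windows.
* **EEG metrics** — Welch spectra (4 s Hann, 50% overlap) with optional
  normalization to the cumulative power ≤ 30 Hz; SHAM-referenced %PSD
  change `100·(PSD_cond − PSD_sham)/PSD_sham`; slow-wave dynamics (the
  Hilbert amplitude of the 0.5–2 Hz band across the stimulation window,
  as % change vs the SHAM mean); SWA per 5 s sub-window; two-threshold
  envelope spindle detection in 10–16 Hz with a 2 s-bin start-probability
  distribution; baseline-SWA pairing; early/late night split.
* **ECG metrics** — R-peak detection, per-window RR extraction (both
  peaks inside the window), RMSSD / SDNN / extrema on ~20 s windows,
  continuous instantaneous heart rate (IHR = 60/RR) via shape-preserving
  makima interpolation with the last 2 s excluded, and %IHR change
  against the closest SHAM window within 5 min.
* **Statistics** — repeated-measures correlation (within-subject
  centering, df = N − k − 1), Benjamini–Hochberg and Hochberg
  adjustments, circular statistics, paired contrasts — implemented from
  their definitions and cross-checked against independent packages in the
  test suite.
* **Synthetic polysomnography** — a seeded generator of full nights
  (stage-dependent slow oscillations and delta activity, 1/f background,
  refractory Poisson spindles, REM eye movements, movement artifacts,
  ECG with respiratory sinus arrhythmia) with *known injected effects*: a
  decaying slow-wave amplitude response and a biphasic IHR kernel (brief
  acceleration, longer deceleration). Every analysis stage is validated
  by recovering what was injected.

The library is aimed at researchers prototyping or auditing closed-loop
auditory stimulation protocols who need a fully inspectable, deterministic
stand-in for the online system and its downstream analysis.

## Worked example

```python
from somnostim import clean_so_recording, run_closed_loop
from somnostim.engine import measure_delivery_phases
from somnostim.stats import circular_stats, circular_sd_deg
from somnostim.io import RunConfig
from somnostim.pipeline import run_pipeline

# 1) phase targeting on a clean 1 Hz slow-oscillation preset
rec, truth = clean_so_recording(duration_s=600, seed=1)
phases = measure_delivery_phases(rec, target=50.0)
mean, R = circular_stats(phases)
print(f"up-phase delivery: n={phases.size}, circular mean={mean:.1f} deg")

# 2) a full synthetic night through the whole chain
cfg = RunConfig(duration_h=1.0, n_subjects=1, seed=1)
bundle = run_pipeline(cfg, "out/")
print("counters:", bundle["manifest"]["counters"]["S01"])
```

prints

```
up-phase delivery: n=570, circular mean=48.3 deg
counters: {'scheduled': 17, 'valid': 17, 'sham': 3, 'baseline_pairs': 3,
           'spindles': 133, 'r_peaks': 3601}
```

570 stimuli were delivered over 10 minutes at a mean phase of 48.3°
(target 50°, circular SD 1.8°): the loop locks onto the slow oscillation
and fires on its late ascending phase. The pipeline run schedules 17
stimulation windows in a one-hour synthetic night, all in artifact-free
N2/N3; the tidy CSVs written to `out/` contain, per condition, the
slow-wave dynamics trace (which peaks early in the ON window at roughly
+100% vs SHAM, the injected response gain, and decays with the injected
time constant) and the per-window HRV features (mean RR lengthened,
RMSSD/SDNN raised in stimulated windows). With only a handful of SHAM
reference windows in so short a night the per-condition traces are noisy;
the test suite uses 100-window simulations for quantitative recovery.

A CLI wraps the same functions: `somnostim simulate`, `somnostim
stimulate <edf>`, `somnostim analyze <edf> <windows.csv>`, `somnostim
demo`.

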