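# Methods

## Conventions

All event times are seconds from recording start; intervals are half-open
`[start, end)`. EEG/EOG are microvolts, ECG millivolts, RR intervals
milliseconds. Instantaneous phase follows the *sine convention*: a
band-limited signal is written `x ∝ sin(θ)`, so θ = 0° is the
positive-going zero crossing, 90° the positive peak, 270° the trough. The
up-phase target 50° therefore sits on the late ascending limb of a slow
wave and the down-phase target 230° on the descending limb. Delivered
phases are always *measured* offline with a zero-phase FIR band-pass
(0.5–2 Hz) plus Hilbert transform, independent of the causal loop that
produced the triggers.

## Closed-loop engine

The engine is strictly causal: every detector and PLL output at time t is
a function of samples ≤ t, which the tests enforce by perturbing future
samples.

**Sleep-state detector.** Band power (low delta 2–4 Hz, high delta
3–5 Hz, high beta 20–30 Hz) is computed on 2 s Hann-tapered frames every
0.5 s and smoothed with a causal 5 s moving average (the 2 s estimates
alone are far too variable to support a "10 minutes uninterrupted" rule).
NREM is called when low-delta power exceeds 3× high-beta power with the
EOG and movement gates open. The first 10 min of uninterrupted detected
NREM calibrate a beta threshold (mean + 2 SD of the calibration segment —
a conventional outlier rule; the mechanism is fixed, the formula is an
implementation default) and the deep-sleep delta gate (25th percentile of
calibration low-delta power). Eligibility requires 10 min of
uninterrupted NREM for the first episode and 3 min afterwards, beta below
threshold, and delta above the gate; a beta excursion breaks the episode,
a delta shortfall merely defers eligibility (deep sleep waxes and wanes
within a stable episode). The EOG gate closes when the sliding 4 s
Pearson correlation of the two EOG derivations falls below −0.6
(zero-variance segments count as r = 0, gate open); the movement gate
closes for 10 s after any |EEG| excursion above 300 µV. The window
lengths, ratio cut, correlation cut and amplitude cut are configuration
defaults exposed in `DetectorConfig`; the bands, the 10/3 min rule and
the 10 s holdoff are part of the protocol itself.

**PLL.** The EEG is causally band-passed (2nd-order Butterworth,
0.5–2 Hz — phase response ≈ 0° at the 1 Hz band centre), decimated to
100 Hz, and amplitude-normalized by a 1 s envelope tracker. The phase
detector multiplies the normalized input with the quadrature reference
cos(θ̂) and low-passes the product at 0.4 Hz to strip the 2f term; the
loop advances θ̂ at the 1 Hz centre frequency plus 2 s⁻¹ × error
(first-order loop, lock within ~2 cycles). The loop counts as *locked* —
equivalently, a slow wave is *detected* — while the envelope exceeds
15 µV for 3 s. Triggers fire at each crossing of a target phase while
locked. On the clean sinusoidal preset the delivered phase lands within
2° of target with circular SD < 2°; at an off-centre input frequency
(0.8 Hz) a first-order loop necessarily carries a static phase offset but
keeps its jitter small. On broadband narrow-band-noise slow waves the
instantaneous phase is intrinsically ill-defined and delivered-phase
spread is large; tight phase control should only be claimed for
oscillations with a stable dominant frequency (see Limitations).

**Scheduling.** Conditions are drawn from a permutation-block sequencer
(shuffle, exhaust, reshuffle), so window counts per condition never
differ by more than one. A window opens at the first eligible trigger of
the opening phase (50° for every condition except DOWN, which opens at
230°); ON and OFF are 10 s each and no window opens before the previous
one ends or would overrun the recording. Tones: UP/DOWN place one 50 ms
pink-noise burst per own-target trigger inside ON; ISI1 variants place
bursts at exactly 1 s spacing from ON onset with their volume plans;
ENVELOPE and BINAURAL BEATS are single 10 s events; SHAM windows carry no
tones. A burst that would cross the ON boundary is dropped, not
truncated, keeping OFF windows stimulus-free. Audio rendering maps dB to
relative amplitude with 45 dB ≡ 1.0 and synthesizes pink noise by 1/f
spectral shaping.

## EEG analysis

Welch spectra use 4 s Hann windows with 50% overlap (0.25 Hz
resolution); sub-window SWA (the four 5 s quarters of a stimulation
window) drops to 2 s windows because a 4 s window cannot tile 5 s —
0.5 Hz resolution still resolves the 0.5–2 Hz band. Slow-wave dynamics
band-pass the whole recording (zero-phase windowed-sinc FIR, Hamming,
transition ≈ lower edge / 2) before slicing windows so edges carry no
transients; the per-timepoint condition mean is referenced to the
per-timepoint SHAM mean, matching the within-night design where SHAM
windows are interleaved with stimulation. The %change is computed on
condition means (not per window then averaged) — with the per-window SEM
reported alongside.

Spindle detection band-passes 10–16 Hz with a forward–backward Chebyshev
type-I filter (a type-II design with the same corner frequencies would
attenuate the upper half of the band, since its parameters set the
stopband, and was measurably biased against fast spindles). The analytic
envelope is smoothed over 0.3 s. The detection rule is the classic
two-times-mean threshold with an upper guard at five times the mean;
"mean of the filtered signal" is implemented as the mean *envelope*
(the raw mean of a zero-mean band-passed trace is ~0). Event boundaries
are delimited at the crossings of the mean envelope around each
above-2× excursion (two-threshold rule), excursions must hold the 2×
level for ≥ 0.25 s, events are merged across gaps < 0.25 s and kept if
≥ 0.5 s. Because the events themselves inflate the recording-mean
envelope, the baseline is re-estimated once with first-pass event samples
excluded. On synthetic nights at a 3:1 event-to-background envelope
ratio this detector holds ≥ 90% sensitivity and precision. Spindle
probability is the fraction of stimulation windows with ≥ 1 spindle
start per 2 s bin (a window contributes at most 1 per bin).

Baseline-SWA pairing computes the 5 s pre-ON low-SWA and the %change of
first-5 s SWA against the closest SHAM window within 5 min (ties to the
earlier window); unpaired windows are dropped. The night split assigns a
window exactly at first-ON + 4 h to the late set.

## ECG analysis

R peaks: 5–30 Hz band-pass, squared (polarity-robust), 120 ms smoothing,
adaptive threshold (30% of the 98th percentile), 250 ms refractory,
peak refinement on the band-passed trace. On rendered synthetic ECG the
detector recovers ≥ 99% of true R times within 10 ms. Only RR intervals
with both bounding peaks inside a window count; RMSSD is the RMS of
successive differences and SDNN the sample (n−1) SD — computed on ~20 s
windows, which is far below guideline durations and only meaningful as a
within-night contrast. IHR samples (60/RR in seconds) are anchored at the
closing R peak of each interval (midpoint anchoring is available),
resampled at 10 Hz with a modified-Akima interpolant and clipped to the
contributing samples' range (no-overshoot contract); the last 2 s of each
window are excluded, so traces cover ON plus 8 s of OFF. %IHR change
references the mean HR of the closest SHAM window within 5 min.

## Statistics

rmcorr centres x and y within each subject, pools, and correlates;
p comes from t = r·√(df/(1−r²)) with df = N − k − 1 (scipy's
t-distribution tail). Under the null its type-I error is calibrated
(0.05 ± 0.01 over 10,000 simulations in the test suite). BH-FDR and
Hochberg are step-up procedures with monotonicity enforcement. The
full-scale analyses this package mirrors use per-electrode linear
mixed-effects models; at desk scale the pipeline offers paired t
contrasts with Hochberg adjustment as a clearly-labelled analogue, and
mixed models are deliberately out of scope.

## Synthetic data: what it does and does not emulate

The generator aims at the *signal features the analysis keys on*, not at
full physiological realism. Slow oscillations are amplitude-modulated
narrow-band (0.5–2 Hz) noise scaled per stage (N3 45, N2 20 µV RMS by
default) plus a 2.25–4.5 Hz delta component (N3 22, N2 12 µV RMS) so
that the detector's 2–4 Hz gating band sees stage-dependent power;
background is 1/f noise (12 µV RMS). A clean-sinusoid preset provides
analytically known phase for PLL validation. Spindles are
Tukey-windowed sinusoids (uniform 0.5–1.5 s, refractory, Poisson at
3/min in N2+N3) whose peak envelope is calibrated to 3× the mean
background envelope in 10–16 Hz. The stimulus response multiplies the
0.5–2 Hz component inside non-SHAM windows by
`1 + g·exp(−(t−t₀)/τ)` (defaults g = 1.0, t₀ = 0.5 s, τ = 3 s; ramp
before t₀, applied across the full 20 s window for continuity) — the
true magnitude of the evoked response per tone in recorded sleep is not
established, so these are free parameters, documented as such and
recovered by the tests rather than assumed. The RR series is base 60 bpm + 30 ms RSA at
0.25 Hz + 20 ms slow drift + 4 ms white jitter + a biphasic kernel at
non-SHAM onsets (−20 ms over 2 s, then +30 ms over 6 s — chosen to
reproduce a ~20 ms prolongation of the longest RR interval with
significant RMSSD/SDNN shifts at 100 windows). ECG is a fixed QRS(T)
Gaussian template at the R times; no P-wave realism is claimed.

Not emulated: sleep micro-architecture (cyclic alternating patterns,
arousals, K-complex morphology), respiratory channels, electrode
topography (three EEG channels with a fixed frontal gradient), ectopy or
artifacts in the ECG. Passing tests therefore demonstrate that the
*chain recovers what the model injects* under realistic spectra and
noise — not that the detector thresholds are optimal for any particular
recording system.

## Problem sizes and numerical choices

The test suite uses 10 min phase-targeting runs, 20 min spindle nights,
100-window (≈ 85 min) recovery simulations and 10,000-draw statistical
calibrations; these sizes give Monte-Carlo error comfortably inside the
stated tolerances while keeping the whole suite under a minute of
compute. Degenerate inputs follow explicit rules: zero-variance EOG
counts as gate-open, a zero-resultant circular mean raises, HRV on < 2
intervals is flagged missing rather than fabricated, equidistant SHAM
ties go to the earlier window, and a tone crossing the ON boundary is
dropped. All randomness flows from one integer seed per night; identical
seeds give bit-identical recordings and byte-identical pipeline CSVs.

## Known limitations

* Delivered-phase precision on broadband slow-wave noise is poor
  (circular SD ≫ 20°); the accuracy contract holds on oscillations with
  a stable dominant frequency. A first-order loop also carries a static
  phase error proportional to the frequency offset.
* The %change traces from short nights with few SHAM windows are noisy;
  quantitative recovery needs on the order of 100 windows.
* HRV indices on 20 s windows must not be compared with guideline
  5 min/24 h HRV; no normal-beat (NN) artifact rejection is applied
  beyond the quality mask.
* The EDF writer emits uniform-rate 16-bit EDF with 1 s records;
  mixed-rate files are readable (via mne) but not written.
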