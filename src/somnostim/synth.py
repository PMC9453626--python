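"""Synthetic polysomnography with known ground truth.

Generates a full night of EEG / EOG / ECG plus hypnogram so that every
downstream stage (closed-loop engine, EEG metrics, ECG metrics, statistics)
can be exercised and validated without any recorded data.  The generator
emulates the signal features the analysis chain keys on:

* stage-dependent 0.5-2 Hz slow oscillations (largest in N3), generated as
  amplitude-modulated narrow-band noise for realistic spectra, with a
  dedicated clean-sinusoid preset for phase-lock validation;
* Poisson-placed 10-16 Hz sleep spindles (Gaussian-windowed sinusoids);
* 1/f background activity;
* anti-correlated EOG deflections confined to REM;
* high-amplitude movement artifacts;
* an RR-interval series with respiratory sinus arrhythmia, slow drift and
  a stimulus-locked biphasic kernel (brief RR shortening, i.e. heart-rate
  acceleration, then a longer RR lengthening / deceleration), rendered to
  an ECG trace through a QRS template.

Everything is driven by one seeded generator: identical parameters and
seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .ecg import RRSeries
from .signals import (
    EPOCH_S, Hypnogram, SignalRecording, analytic_amplitude, bandpass_fir,
)

SO_BAND = (0.5, 2.0)
DELTA_BAND = (2.25, 4.5)
SPINDLE_BAND = (10.0, 16.0)


@dataclass
class StimResponse:
    """Multiplicative slow-wave response to a stimulation window.

    The 0.5-2 Hz amplitude is scaled by ``1 + peak_gain * exp(-(t -
    peak_latency)/decay_tau)`` from ``peak_latency`` on (linear ramp from
    1 before), emulating a response that is strongest early in the ON
    window and decays across the window.
    """

    peak_gain: float = 1.0
    peak_latency: float = 0.5
    decay_tau: float = 3.0


@dataclass
class IHRKernel:
    """Biphasic stimulus-locked RR modulation (half-sine lobes, ms)."""

    accel_ms: float = 20.0   # RR shortening during the early lobe
    accel_dur_s: float = 2.0
    decel_ms: float = 30.0   # RR lengthening afterwards
    decel_dur_s: float = 6.0


@dataclass
class CardiacParams:
    base_hr: float = 60.0        # bpm
    rsa_amp: float = 30.0        # ms, respiratory sinus arrhythmia
    rsa_freq: float = 0.25       # Hz
    drift_amp: float = 20.0      # ms, slow baseline wander of RR
    drift_period: float = 600.0  # s
    jitter_ms: float = 4.0       # white beat-to-beat noise
    ecg_noise_mv: float = 0.02
    ihr_kernel: IHRKernel = field(default_factory=IHRKernel)


@dataclass
class SynthParams:
    """All knobs of the synthetic night.

    Amplitudes are RMS microvolts of the band-limited component.  The
    spindle amplitude is expressed as ``spindle_snr``, the ratio of a
    spindle's peak 10-16 Hz envelope to the mean 10-16 Hz background
    envelope, which is the quantity the detector thresholds on.
    """

    sampling_rate: float = 500.0
    so_freq: float = 1.0
    so_amp_by_stage: dict = field(default_factory=lambda: {
        "WAKE": 2.0, "N1": 6.0, "N2": 20.0, "N3": 45.0, "REM": 3.0,
    })
    delta_amp_by_stage: dict = field(default_factory=lambda: {
        "WAKE": 1.0, "N1": 4.0, "N2": 12.0, "N3": 22.0, "REM": 2.0,
    })
    spindle_rate: float = 3.0            # events/min in N2+N3
    spindle_freq_range: tuple = (10.0, 16.0)
    spindle_snr: float = 3.0
    noise_exponent: float = 1.0          # 1/f slope
    noise_rms: float = 12.0              # uV broadband background
    eog_deflection_rate: float = 4.0     # events/min in REM
    eog_deflection_amp: float = 120.0    # uV
    movement_rate_per_h: float = 5.0     # in WAKE/N1
    movement_amp: float = 400.0          # uV
    stim_response: StimResponse = field(default_factory=StimResponse)
    cardiac: CardiacParams = field(default_factory=CardiacParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.so_amp_by_stage.values()):
            raise ValueError("slow-oscillation amplitudes must be >= 0")
        if self.spindle_rate < 0 or self.noise_rms < 0:
            raise ValueError("rates and amplitudes must be >= 0")
        if self.sampling_rate <= 2 * max(self.spindle_freq_range):
            raise ValueError("sampling_rate must exceed twice the highest "
                             "generated frequency")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Injected-event bookkeeping for recovery tests."""

    so_events: list = field(default_factory=list)       # (time, phase_ref)
    spindle_events: list = field(default_factory=list)  # (start, dur, freq)
    eog_events: list = field(default_factory=list)      # times
    movement_events: list = field(default_factory=list)  # times
    injected_response_windows: list = field(default_factory=list)
    rr_truth: np.ndarray | None = None  # noise-free R times, s


def generate_hypnogram(duration_h: float, seed: int = 0) -> Hypnogram:
    """A plausible night in 20 s epochs.

    Built from ~90 min sleep cycles (N1 -> N2 -> N3 -> N2 -> REM) with
    deep sleep front-loaded and REM growing across the night; segment
    lengths are jittered by the seeded generator.  The first cycle always
    contains a continuous N2/N3 run of well over 10 min.
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_epochs = int(round(duration_h * 3600.0 / EPOCH_S))
    stages: list[str] = ["WAKE"] * int(rng.integers(6, 15))
    cycle = 0
    while len(stages) < n_epochs:
        jit = lambda n: max(1, int(round(n * rng.uniform(0.85, 1.15))))
        stages += ["N1"] * jit(3)
        stages += ["N2"] * jit(15)
        stages += ["N3"] * jit(max(6, 45 - 12 * cycle))
        stages += ["N2"] * jit(10)
        stages += ["REM"] * jit(5 + 8 * cycle)
        if rng.uniform() < 0.3:
            stages += ["WAKE"] * int(rng.integers(1, 4))
        cycle += 1
    return Hypnogram(stages[:n_epochs])


def _one_over_f_noise(n: int, fs: float, exponent: float, rms: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent spectrum, flattened below 0.5 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(f)
    ref = 0.5
    above = f >= ref
    shape[above] = (f[above] / ref) ** (-exponent / 2.0)
    spec *= shape
    x = np.fft.irfft(spec, n)
    sd = np.std(x)
    return x * (rms / sd) if sd > 0 else x


def _narrowband(n: int, fs: float, band: tuple,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS amplitude-modulated narrow-band noise."""
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = np.std(x)
    return x / sd if sd > 0 else x


def _smooth_stage_envelope(values: np.ndarray, fs: float,
                           smooth_s: float = 2.0) -> np.ndarray:
    win = int(smooth_s * fs) | 1
    kernel = np.hanning(win)
    kernel /= kernel.sum()
    return sps.fftconvolve(values, kernel, mode="same")


def generate_eeg(
    hyp: Hypnogram, params: SynthParams,
    eeg_channels: tuple = ("Fz", "Cz", "Pz"),
) -> tuple[SignalRecording, GroundTruth]:
    """Stage-dependent EEG plus an EOG pair, with event bookkeeping.

    Each EEG channel is 1/f background + stage-modulated narrow-band slow
    oscillations (frontal dominance: later channels scaled down) +
    Poisson-placed spindles.  The EOG pair carries anti-correlated
    deflections only in REM; movement artifacts land in WAKE/N1 on all
    channels.
    """
    if hyp.n_epochs == 0:
        raise ValueError("empty hypnogram")
    fs = params.sampling_rate
    n = int(round(hyp.duration * fs))
    rng = np.random.default_rng(params.seed)
    truth = GroundTruth()
    t = np.arange(n) / fs

    stage_labels = hyp.sample_stages(fs, n)
    so_amp = np.array(
        [params.so_amp_by_stage[s] for s in stage_labels], dtype=float
    )
    so_env = _smooth_stage_envelope(so_amp, fs)
    delta_amp = np.array(
        [params.delta_amp_by_stage[s] for s in stage_labels], dtype=float
    )
    delta_env = _smooth_stage_envelope(delta_amp, fs)

    # spindle placement (shared across channels: thalamocortical events)
    spindle_mask = hyp.mask(fs, n, ("N2", "N3"))
    eligible_min = spindle_mask.sum() / fs / 60.0
    n_spindles = rng.poisson(params.spindle_rate * eligible_min)
    eligible_idx = np.flatnonzero(spindle_mask)
    spindles = []
    if n_spindles > 0 and eligible_idx.size > 0:
        starts = np.sort(rng.choice(eligible_idx, size=n_spindles,
                                    replace=False)) / fs
        last_end = -np.inf
        for s0 in starts:
            dur = rng.uniform(0.5, 1.5)
            lo, hi = params.spindle_freq_range
            freq = rng.uniform(lo + 0.5, hi - 0.5)
            # spindles are refractory: no overlap on a channel
            if s0 < last_end + 0.5:
                continue
            if s0 + dur < hyp.duration:
                spindles.append((float(s0), float(dur), float(freq)))
                last_end = s0 + dur
    truth.spindle_events = spindles

    # calibrate spindle amplitude against the background envelope once
    probe = _one_over_f_noise(
        min(n, int(120 * fs)), fs, params.noise_exponent, params.noise_rms,
        np.random.default_rng(params.seed + 1),
    )
    bg_env = float(np.mean(analytic_amplitude(
        bandpass_fir(probe, fs, *SPINDLE_BAND))))
    spindle_peak_amp = params.spindle_snr * bg_env

    spindle_wave = np.zeros(n)
    for s0, dur, freq in spindles:
        i0, i1 = int(s0 * fs), int((s0 + dur) * fs)
        # waxing-waning envelope with a sustained core (Tukey window)
        taper = sps.windows.tukey(i1 - i0, alpha=0.5)
        tt = np.arange(i1 - i0) / fs
        phase = rng.uniform(0, 2 * np.pi)
        spindle_wave[i0:i1] += spindle_peak_amp * taper * np.sin(
            2 * np.pi * freq * tt + phase)

    # movement artifacts in WAKE/N1
    move_mask = hyp.mask(fs, n, ("WAKE", "N1"))
    move_idx = np.flatnonzero(move_mask)
    n_moves = rng.poisson(params.movement_rate_per_h * hyp.duration / 3600.0)
    movement = np.zeros(n)
    if n_moves > 0 and move_idx.size > 0:
        for i0 in np.sort(rng.choice(move_idx, size=n_moves, replace=False)):
            dur = int(rng.uniform(1.0, 3.0) * fs)
            i1 = min(i0 + dur, n)
            burst = rng.standard_normal(i1 - i0)
            burst *= np.hanning(i1 - i0)
            movement[i0:i1] += params.movement_amp * burst / max(
                np.max(np.abs(burst)), 1e-12)
            truth.movement_events.append(float(i0 / fs))

    gains = np.linspace(1.0, 0.8, len(eeg_channels))  # frontal dominance
    data = []
    for gain in gains:
        noise = _one_over_f_noise(n, fs, params.noise_exponent,
                                  params.noise_rms, rng)
        so = gain * so_env * _narrowband(n, fs, SO_BAND, rng)
        delta = gain * delta_env * _narrowband(n, fs, DELTA_BAND, rng)
        data.append(noise + so + delta + spindle_wave + movement)

    # EOG pair: background noise + anti-correlated REM deflections
    rem_mask = hyp.mask(fs, n, ("REM",))
    rem_idx = np.flatnonzero(rem_mask)
    n_defl = rng.poisson(
        params.eog_deflection_rate * rem_mask.sum() / fs / 60.0)
    defl = np.zeros(n)
    if n_defl > 0 and rem_idx.size > 0:
        width = 0.6
        for i0 in np.sort(rng.choice(rem_idx, size=n_defl, replace=False)):
            tt = np.arange(int(2 * width * fs)) / fs - width
            shape = -tt / width * np.exp(0.5 - 0.5 * (tt / (width / 2)) ** 2)
            i1 = min(i0 + tt.size, n)
            defl[i0:i1] += params.eog_deflection_amp * shape[: i1 - i0]
            truth.eog_events.append(float(i0 / fs))
    eog1 = _one_over_f_noise(n, fs, params.noise_exponent, 8.0, rng) + defl
    eog2 = _one_over_f_noise(n, fs, params.noise_exponent, 8.0, rng) - defl
    data += [eog1 + movement * 0.5, eog2 + movement * 0.5]

    names = list(eeg_channels) + ["EOG1", "EOG2"]
    roles = ["eeg"] * len(eeg_channels) + ["eog", "eog"]
    return SignalRecording(np.vstack(data), fs, names, roles), truth


def response_envelope(t_rel: np.ndarray, resp: StimResponse) -> np.ndarray:
    """Multiplier 1 + g*exp(-(t-latency)/tau), linear ramp before latency."""
    m = np.ones_like(t_rel)
    g, lat, tau = resp.peak_gain, resp.peak_latency, resp.decay_tau
    ramp = (t_rel >= 0) & (t_rel < lat)
    m[ramp] = 1.0 + g * t_rel[ramp] / lat if lat > 0 else 1.0 + g
    after = t_rel >= lat
    m[after] = 1.0 + g * np.exp(-(t_rel[after] - lat) / tau)
    return m


def inject_stim_response(
    rec: SignalRecording, windows, params: SynthParams,
) -> SignalRecording:
    """Scale the 0.5-2 Hz component of EEG channels inside stimulation windows.

    ``windows`` is an iterable of objects with ``condition`` and
    ``on_start`` attributes (see :class:`somnostim.engine.StimWindow`); the
    response envelope spans the full 20 s ON+OFF window so the modulation
    decays smoothly instead of jumping back to 1 at the ON/OFF border.
    SHAM windows are left bit-identical.  Only the band-limited component
    is scaled; background noise is untouched, which isolates the
    slow-wave effect for recovery tests.
    """
    out = rec.copy()
    fs = rec.fs
    wins = [w for w in windows if w.condition != "SHAM"]
    for w in windows:
        end = w.on_start + getattr(w, "on_duration", 10.0) + getattr(
            w, "off_duration", 10.0)
        if w.on_start < 0 or end > rec.duration + 1e-9:
            raise ValueError(f"window at {w.on_start:.1f}s outside recording")
    if params.stim_response.peak_gain == 0 or not wins:
        return out
    for name, role in zip(rec.channel_names, rec.channel_roles):
        if role != "eeg":
            continue
        i = rec.channel_names.index(name)
        x = rec.data[i]
        band = bandpass_fir(x, fs, *SO_BAND)
        # touch only stimulated spans so every other sample (and every
        # SHAM window) stays bit-identical to the input
        for w in wins:
            i0 = int(round(w.on_start * fs))
            i1 = int(round((w.on_start + 20.0) * fs))
            t_rel = np.arange(i1 - i0) / fs
            mult = response_envelope(t_rel, params.stim_response)
            out.data[i, i0:i1] = x[i0:i1] + band[i0:i1] * (mult - 1.0)
    return out


_QRS_POINTS = (  # (offset s, amplitude mV, width s): Q, R, S, T
    (-0.035, -0.15, 0.012), (0.0, 1.0, 0.012),
    (0.035, -0.20, 0.012), (0.22, 0.25, 0.05),
)


def generate_rr(
    duration_s: float, windows, params: SynthParams,
) -> tuple[RRSeries, SignalRecording]:
    """RR series with RSA, drift and the stimulus-locked kernel, plus ECG.

    The beat-to-beat interval is built iteratively: base RR (60000 /
    base_hr ms) + RSA sinusoid + slow drift + the biphasic kernel summed
    over non-SHAM window onsets + white jitter.  An ECG trace is rendered
    by placing a fixed QRS(T) template at each R time for peak-detection
    testing.
    """
    c = params.cardiac
    if not 30.0 <= c.base_hr <= 120.0:
        raise ValueError("base_hr must lie in 30-120 bpm")
    base_rr = 60000.0 / c.base_hr
    k = c.ihr_kernel
    if k.accel_ms >= base_rr - (c.rsa_amp + c.drift_amp):
        raise ValueError("kernel magnitude would drive RR <= 0")
    onsets = np.asarray(
        [w.on_start for w in windows if w.condition != "SHAM"], dtype=float)
    rng = np.random.default_rng(params.seed + 2)
    phi_rsa = rng.uniform(0, 2 * np.pi)
    phi_drift = rng.uniform(0, 2 * np.pi)

    def kernel(tt: float) -> float:
        if onsets.size == 0:
            return 0.0
        dt = tt - onsets
        val = 0.0
        for d in dt[(dt >= 0) & (dt < k.accel_dur_s + k.decel_dur_s)]:
            if d < k.accel_dur_s:
                val -= k.accel_ms * np.sin(np.pi * d / k.accel_dur_s)
            else:
                val += k.decel_ms * np.sin(
                    np.pi * (d - k.accel_dur_s) / k.decel_dur_s)
        return val

    times = [0.0]
    while times[-1] < duration_s:
        tt = times[-1]
        rr = (base_rr
              + c.rsa_amp * np.sin(2 * np.pi * c.rsa_freq * tt + phi_rsa)
              + c.drift_amp * np.sin(2 * np.pi * tt / c.drift_period
                                     + phi_drift)
              + kernel(tt)
              + (c.jitter_ms * rng.standard_normal() if c.jitter_ms else 0.0))
        if rr <= 0:
            raise ValueError("RR modulation drove an interval <= 0")
        times.append(tt + rr / 1000.0)
    r_times = np.asarray(times[:-1])

    fs = params.sampling_rate
    n = int(round(duration_s * fs))
    ecg = np.zeros(n)
    for off, amp, width in _QRS_POINTS:
        centers = r_times + off
        for tc in centers:
            i0 = max(int((tc - 4 * width) * fs), 0)
            i1 = min(int((tc + 4 * width) * fs) + 1, n)
            if i1 <= i0:
                continue
            tt = np.arange(i0, i1) / fs - tc
            ecg[i0:i1] += amp * np.exp(-0.5 * (tt / width) ** 2)
    if c.ecg_noise_mv:
        ecg += c.ecg_noise_mv * rng.standard_normal(n)
    rec = SignalRecording(ecg[None, :], fs, ["ECG"], ["ecg"], ["mV"])
    return RRSeries(r_times), rec


def clean_so_recording(
    duration_s: float = 600.0,
    fs: float = 500.0,
    so_freq: float = 1.0,
    amplitude: float = 75.0,
    noise_sd_frac: float = 0.1,
    seed: int = 0,
) -> tuple[SignalRecording, GroundTruth]:
    """Clean-sinusoid slow-oscillation preset for phase-lock validation.

    ``amplitude * sin(2 pi f t)`` plus Gaussian noise (SD a fraction of
    the amplitude) on a single frontal EEG channel.  Ground-truth
    ``so_events`` hold each cycle's positive-going zero crossing, i.e.
    sine phase 0 deg.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    x = amplitude * np.sin(2 * np.pi * so_freq * t)
    x = x + noise_sd_frac * amplitude * rng.standard_normal(n)
    truth = GroundTruth(
        so_events=[(float(k / so_freq), 0.0)
                   for k in range(int(duration_s * so_freq))]
    )
    rec = SignalRecording(x[None, :], fs, ["Fz"], ["eeg"])
    return rec, truth
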