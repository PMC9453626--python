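"""Offline re-implementation of the closed-loop stimulation algorithm.

The real-time system gates stimulation on detected stable NREM sleep
(spectral-power criteria plus EOG anti-correlation, movement and
slow-wave-sleep gates), tracks the slow-oscillation phase with a
first-order phase-locked loop (PLL), and schedules 10 s ON + 10 s OFF
stimulation windows whose conditions come from a permutation-block
("pseudorandomized") sequencer.  Everything here is causal: every output
at time t depends only on samples up to t, so the offline run reproduces
what the online system could have known.

Stimulation conditions
----------------------
UP / DOWN       one 50 ms pink-noise burst per detected slow wave, at the
                50 deg (ascending) / 230 deg (descending) sine phase
ISI1_*          bursts in a fixed 1 Hz rhythm from ON onset; the High /
                Low variants differ in constant volume (45 / 42.5 dB) and
                ISI1_Mod ramps 40 -> 45 -> 42.5 dB across its ten tones
ENVELOPE        10 s of 1 Hz amplitude-modulated pink noise
BINAURAL_BEATS  10 s dichotic pure tones, 400 and 401 Hz
SHAM            windows scheduled and logged, no sound
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy import signal as sps

from .signals import SignalRecording, bandpass_fir, sine_phase_deg

SO_BAND = (0.5, 2.0)
ON_S = 10.0
OFF_S = 10.0


@dataclass
class DetectorConfig:
    """Tunables of the sleep-state detector and PLL.

    The frequency bands, the 10 min / 3 min stable-NREM rule and the 10 s
    movement holdoff are fixed properties of the stimulation logic; the
    window lengths, thresholds and loop gain are implementation defaults
    (the logic is specified by mechanism, not by value) and are all
    exposed here.
    """

    # detection bands (Hz)
    low_delta: tuple = (2.0, 4.0)
    high_delta: tuple = (3.0, 5.0)
    high_beta: tuple = (20.0, 30.0)
    # stable-NREM rule (s)
    first_stable_nrem: float = 600.0
    later_stable_nrem: float = 180.0
    movement_holdoff: float = 10.0
    # online power estimation
    power_window: float = 2.0
    update_step: float = 0.5
    power_smooth_s: float = 5.0   # causal moving average of power streams
    # gates
    beta_k: float = 2.0               # threshold = mean + k*SD
    nrem_ratio_cut: float = 3.0       # low-delta / high-beta power ratio
    eog_anticorr_cut: float = -0.6
    eog_corr_window: float = 4.0
    movement_amp_cut: float = 300.0   # uV
    delta_gate_quantile: float = 0.25
    # PLL
    pll_rate: float = 100.0           # loop update rate after decimation
    pll_center_freq: float = 1.0
    pll_gain: float = 2.0             # 1/s, first-order loop
    pll_error_lp_hz: float = 0.4
    pll_lock_amp: float = 15.0        # uV envelope needed to call a slow wave
    pll_lock_settle: float = 3.0      # s above threshold before locked

    def __post_init__(self) -> None:
        for band in (self.low_delta, self.high_delta, self.high_beta):
            if band[0] >= band[1]:
                raise ValueError(f"band edges out of order: {band}")
        if self.first_stable_nrem <= self.later_stable_nrem:
            raise ValueError("first_stable_nrem must exceed later_stable_nrem")
        if not 0 < self.update_step <= self.power_window:
            raise ValueError("need 0 < update_step <= power_window")


@dataclass
class ConditionSpec:
    name: str
    tone_duration_ms: float = 50.0
    volume_plan: list | float = 45.0   # dB; list = per-tone plan
    phase_target: float | None = None  # degrees, None = rhythm/continuous
    carrier_hz: float | None = None
    beat_hz: float | None = None


def default_conditions() -> dict[str, ConditionSpec]:
    """The study-1/2/3 condition roster."""
    return {
        "UP": ConditionSpec("UP", phase_target=50.0),
        "DOWN": ConditionSpec("DOWN", phase_target=230.0),
        "ISI1_High": ConditionSpec("ISI1_High", volume_plan=45.0),
        "ISI1_Low": ConditionSpec("ISI1_Low", volume_plan=42.5),
        "ISI1_Mod": ConditionSpec(
            "ISI1_Mod",
            volume_plan=[40.0, 40.0, 42.5, 42.5, 45.0,
                         45.0, 45.0, 45.0, 42.5, 42.5],
        ),
        "ENVELOPE": ConditionSpec("ENVELOPE", tone_duration_ms=10000.0),
        "BINAURAL_BEATS": ConditionSpec(
            "BINAURAL_BEATS", tone_duration_ms=10000.0,
            carrier_hz=400.0, beat_hz=1.0,
        ),
        "SHAM": ConditionSpec("SHAM"),
    }


STUDY1_ROSTER = ("UP", "DOWN", "ISI1_High", "ENVELOPE", "BINAURAL_BEATS",
                 "SHAM")


@dataclass
class ToneEvent:
    onset: float          # s
    duration: float       # s
    volume_db: float
    payload: dict = field(default_factory=dict)


@dataclass
class StimWindow:
    condition: str
    on_start: float
    on_duration: float = ON_S
    off_duration: float = OFF_S
    tones: list = field(default_factory=list)
    valid: bool = True

    @property
    def on_end(self) -> float:
        return self.on_start + self.on_duration

    @property
    def end(self) -> float:
        return self.on_start + self.on_duration + self.off_duration


# ---------------------------------------------------------------------------
# causal power / gate streams
# ---------------------------------------------------------------------------

def _causal_frames(x: np.ndarray, fs: float,
                   cfg: DetectorConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sliding frames ending at each update step (causal).

    Returns (frame_end_times, frames); frame k covers the ``power_window``
    seconds ending at its timestamp.
    """
    win = int(round(cfg.power_window * fs))
    step = int(round(cfg.update_step * fs))
    if win > x.size:
        raise ValueError("signal shorter than the power window")
    view = np.lib.stride_tricks.sliding_window_view(x, win)[::step]
    times = (np.arange(view.shape[0]) * step + win) / fs
    return times, view


def band_power_stream(
    x: np.ndarray, fs: float, band: tuple[float, float], cfg: DetectorConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Causal sliding-window band power sampled every ``update_step``.

    Each frame is Hann-tapered and integrated over ``band`` from its
    periodogram (density scaling), using only samples up to the frame's
    timestamp.
    """
    if band[1] > fs / 2:
        raise ValueError(f"band {band} exceeds Nyquist ({fs / 2} Hz)")
    times, frames = _causal_frames(np.asarray(x, dtype=float), fs, cfg)
    win = frames.shape[1]
    taper = np.hanning(win)
    scale = 1.0 / (fs * np.sum(taper ** 2))
    spec = np.abs(np.fft.rfft(frames * taper, axis=1)) ** 2 * scale
    spec[:, 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    df = freqs[1] - freqs[0]
    return times, spec[:, sel].sum(axis=1) * df


def eog_anticorr_gate(
    eog1: np.ndarray, eog2: np.ndarray, fs: float, cfg: DetectorConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding EOG correlation; gate closes on strong anti-correlation.

    Pearson r over ``eog_corr_window`` s, stepped every ``update_step``;
    zero-variance segments are treated as r = 0 (gate open).  Returns
    (times, r, gate_open).
    """
    if eog1.shape != eog2.shape:
        raise ValueError("EOG pair must have equal length")
    win = int(round(cfg.eog_corr_window * fs))
    step = int(round(cfg.update_step * fs))
    v1 = np.lib.stride_tricks.sliding_window_view(eog1, win)[::step]
    v2 = np.lib.stride_tricks.sliding_window_view(eog2, win)[::step]
    times = (np.arange(v1.shape[0]) * step + win) / fs
    a = v1 - v1.mean(axis=1, keepdims=True)
    b = v2 - v2.mean(axis=1, keepdims=True)
    denom = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
    r = np.zeros(v1.shape[0])
    ok = denom > 0
    r[ok] = (a * b).sum(axis=1)[ok] / denom[ok]
    return times, r, r >= cfg.eog_anticorr_cut


def movement_gate(
    eeg: np.ndarray, fs: float, cfg: DetectorConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Gate closed for ``movement_holdoff`` s after any |EEG| threshold hit.

    Evaluated on ``update_step`` frames; a hit anywhere in a frame closes
    the gate for the holdoff counted from the *end* of that frame, and a
    later hit restarts the holdoff.  Returns (times, gate_open).
    """
    step = int(round(cfg.update_step * fs))
    n_frames = eeg.size // step
    x = np.abs(eeg[: n_frames * step]).reshape(n_frames, step)
    hit = (x > cfg.movement_amp_cut).any(axis=1)
    times = (np.arange(n_frames) + 1) * cfg.update_step
    open_gate = np.ones(n_frames, dtype=bool)
    hold = int(round(cfg.movement_holdoff / cfg.update_step))
    last_hit = -np.inf
    for k in range(n_frames):
        if hit[k]:
            last_hit = k
        open_gate[k] = not (k - last_hit < hold)
    return times, open_gate


def calibrate_beta_threshold(beta: np.ndarray, cfg: DetectorConfig) -> float:
    """Night-specific beta cutoff: mean + beta_k * SD of the calibration run."""
    beta = np.asarray(beta, dtype=float)
    if beta.size == 0:
        raise ValueError("no calibration samples")
    return float(beta.mean() + cfg.beta_k * beta.std())


@dataclass
class DetectorOutput:
    """Time-aligned detector streams (one sample per update step)."""

    times: np.ndarray
    nrem_detected: np.ndarray
    eligible: np.ndarray
    beta_threshold: float | None
    nrem_onset: float | None          # first detected-NREM step ever
    first_eligible: float | None
    low_delta: np.ndarray
    high_beta: np.ndarray
    first_episode_start: float | None = None  # onset of the uninterrupted
    # run that produced the first eligible step


def nrem_state_machine(
    rec: SignalRecording, cfg: DetectorConfig,
    eeg_channel: str | None = None,
) -> DetectorOutput:
    """Hypnogram-free stimulation-eligibility stream.

    NREM is called per update step when the low-delta / high-beta power
    ratio clears ``nrem_ratio_cut`` with the EOG and movement gates open.
    The first 10 min of uninterrupted detected NREM calibrate the beta
    threshold (and the delta SWS gate quantile); eligibility turns on only
    after 10 min of uninterrupted NREM for the first episode and 3 min for
    every later episode, with beta below threshold and delta above its
    gate.
    """
    eeg_names = rec.channels_by_role("eeg")
    if not eeg_names:
        raise ValueError("recording has no EEG channel")
    eeg = rec.channel(eeg_channel or eeg_names[0])
    fs = rec.fs

    def causal_smooth(p: np.ndarray) -> np.ndarray:
        k = max(int(round(cfg.power_smooth_s / cfg.update_step)), 1)
        c = np.cumsum(np.insert(p, 0, 0.0))
        lo = np.maximum(np.arange(p.size) - k + 1, 0)
        return (c[np.arange(p.size) + 1] - c[lo]) / (np.arange(p.size) + 1
                                                     - lo)

    times, p_delta = band_power_stream(eeg, fs, cfg.low_delta, cfg)
    _, p_beta = band_power_stream(eeg, fs, cfg.high_beta, cfg)
    p_delta = causal_smooth(p_delta)
    p_beta = causal_smooth(p_beta)
    _, mv_open = movement_gate(eeg, fs, cfg)
    eog_names = rec.channels_by_role("eog")
    if len(eog_names) >= 2:
        te, _, eog_open_raw = eog_anticorr_gate(
            rec.channel(eog_names[0]), rec.channel(eog_names[1]), fs, cfg)
        eog_open = np.interp(times, te, eog_open_raw.astype(float)) >= 0.5
    else:
        eog_open = np.ones(times.size, dtype=bool)
    m = min(times.size, mv_open.size, eog_open.size)
    times, p_delta, p_beta = times[:m], p_delta[:m], p_beta[:m]
    mv_open, eog_open = mv_open[:m], eog_open[:m]

    ratio_ok = p_delta > cfg.nrem_ratio_cut * p_beta
    nrem = ratio_ok & mv_open & eog_open

    step = cfg.update_step
    need_first = int(round(cfg.first_stable_nrem / step))
    need_later = int(round(cfg.later_stable_nrem / step))
    cal_len = int(round(cfg.first_stable_nrem / step))

    eligible = np.zeros(m, dtype=bool)
    beta_thr: float | None = None
    delta_gate: float | None = None
    run = 0
    had_first = False
    nrem_onset: float | None = None
    first_eligible: float | None = None
    first_episode: float | None = None
    run_start = 0
    for k in range(m):
        if not nrem[k]:
            run = 0
            continue
        if run == 0:
            run_start = k
        run += 1
        if nrem_onset is None:
            nrem_onset = float(times[k])
        need = need_later if had_first else need_first
        if run < need:
            continue
        if beta_thr is None:
            cal = p_beta[run_start: run_start + cal_len]
            beta_thr = calibrate_beta_threshold(cal, cfg)
            delta_gate = float(
                np.quantile(p_delta[run_start: run_start + cal_len],
                            cfg.delta_gate_quantile))
        if p_beta[k] > beta_thr:
            run = 0  # beta spike halts stimulation and breaks the episode
            continue
        if p_delta[k] < delta_gate:
            continue  # stable NREM but not deep enough: hold, don't reset
        eligible[k] = True
        had_first = True
        if first_eligible is None:
            first_eligible = float(times[k])
            first_episode = float(times[run_start])
    return DetectorOutput(times, nrem, eligible, beta_thr, nrem_onset,
                          first_eligible, p_delta, p_beta, first_episode)


# ---------------------------------------------------------------------------
# phase-locked loop
# ---------------------------------------------------------------------------

@dataclass
class PLLState:
    center_freq: float = 1.0
    loop_gain: float = 2.0
    phase_estimate: float = 0.0   # degrees in [0, 360)
    locked: bool = False
    target_phase: float = 50.0


@dataclass
class PLLRun:
    """Result of a PLL pass: per-step phase plus target-phase crossings."""

    times: np.ndarray
    phase_deg: np.ndarray
    locked: np.ndarray
    amplitude: np.ndarray
    triggers: dict              # target degrees -> crossing times (locked)


def run_pll(
    rec_or_signal, fs: float | None = None,
    cfg: DetectorConfig | None = None,
    targets: tuple = (50.0, 230.0),
) -> PLLRun:
    """Track the slow-oscillation phase causally and emit phase triggers.

    The EEG is causally band-passed to 0.5-2 Hz (2nd-order Butterworth,
    near-zero phase lag at the 1 Hz band centre), decimated to
    ``pll_rate`` and fed to a first-order PLL: the phase detector is the
    product of the amplitude-normalized input with the quadrature
    reference, one-pole low-passed to strip the double-frequency term;
    the loop advances the phase at ``pll_center_freq`` corrected by
    ``pll_gain`` times the phase error.  The loop is *locked* while the
    running slow-wave envelope stays above ``pll_lock_amp`` for
    ``pll_lock_settle`` s — this doubles as the slow-wave presence
    criterion for UP/DOWN stimulation.  A trigger is emitted each time
    the estimated phase crosses a target while locked.
    """
    cfg = cfg or DetectorConfig()
    if isinstance(rec_or_signal, SignalRecording):
        names = rec_or_signal.channels_by_role("eeg")
        x = rec_or_signal.channel(names[0])
        fs = rec_or_signal.fs
    else:
        x = np.asarray(rec_or_signal, dtype=float)
        if fs is None:
            raise ValueError("fs required for array input")

    sos = sps.butter(2, SO_BAND, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfilt(sos, x)  # causal
    dec = max(int(round(fs / cfg.pll_rate)), 1)
    y = filt[::dec]
    dt = dec / fs
    n = y.size
    w0 = 2 * np.pi * cfg.pll_center_freq

    # one-pole smoother coefficients
    a_err = np.exp(-2 * np.pi * cfg.pll_error_lp_hz * dt)
    a_amp = np.exp(-dt / 1.0)  # 1 s amplitude tracker
    settle = int(round(cfg.pll_lock_settle / dt))

    theta = 0.0
    err = 0.0
    amp = 0.0
    above = 0
    phase = np.empty(n)
    locked = np.zeros(n, dtype=bool)
    amps = np.empty(n)
    trig: dict[float, list] = {float(t): [] for t in targets}
    targ_rad = {float(t): np.deg2rad(t) for t in targets}
    for k in range(n):
        amp = a_amp * amp + (1 - a_amp) * abs(y[k]) * (np.pi / 2)
        norm = y[k] / amp if amp > 1e-9 else 0.0
        norm = max(min(norm, 3.0), -3.0)
        e = 2.0 * norm * np.cos(theta)
        err = a_err * err + (1 - a_err) * e
        new_theta = theta + (w0 + cfg.pll_gain * err) * dt
        above = above + 1 if amp >= cfg.pll_lock_amp else 0
        is_locked = above >= settle
        if is_locked:
            for tg, tr in targ_rad.items():
                # crossing of target (mod 2 pi) between theta and new_theta
                kcross = np.ceil((theta - tr) / (2 * np.pi))
                if tr + 2 * np.pi * kcross < new_theta:
                    trig[tg].append(k * dt)
        theta = new_theta
        phase[k] = theta
        locked[k] = is_locked
        amps[k] = amp
    times = np.arange(n) * dt
    return PLLRun(times, np.mod(np.degrees(phase), 360.0), locked, amps,
                  {t: np.asarray(v) for t, v in trig.items()})


# ---------------------------------------------------------------------------
# sequencing, scheduling, tone planning
# ---------------------------------------------------------------------------

def sequence_conditions(conditions: list[str], seed: int = 0) -> Iterator[str]:
    """Permutation-block iterator: shuffle, exhaust, reshuffle.

    Every consecutive block of ``len(conditions)`` draws contains each
    condition exactly once.
    """
    if not conditions:
        raise ValueError("need at least one condition")
    rng = np.random.default_rng(seed)
    conditions = list(conditions)
    while True:
        order = rng.permutation(len(conditions))
        for i in order:
            yield conditions[i]


def schedule_windows(
    det: DetectorOutput, pll: PLLRun, sequencer: Iterator[str],
    conditions: dict[str, ConditionSpec] | None = None,
    up_target: float = 50.0,
) -> list[StimWindow]:
    """Open 10 s ON + 10 s OFF windows on eligible phase triggers.

    A window opens at the first target-phase trigger (up-phase for every
    condition except DOWN, which waits for its own 230 deg trigger) that
    falls in an eligible step; no new window may open before the previous
    OFF window ends.  SHAM windows are scheduled identically but carry no
    tones.
    """
    conditions = conditions or default_conditions()
    windows: list[StimWindow] = []
    step = det.times[1] - det.times[0] if det.times.size > 1 else 0.5
    next_allowed = -np.inf
    pending = next(sequencer)
    spec = conditions[pending]
    open_target = (spec.phase_target
                   if spec.phase_target is not None else up_target)
    all_trigs = sorted(
        (tt, tg) for tg, v in pll.triggers.items() for tt in v
    )
    end_limit = float(pll.times[-1]) if pll.times.size else 0.0
    for tt, tg in all_trigs:
        if tg != open_target or tt < next_allowed:
            continue
        if tt + ON_S + OFF_S > end_limit:
            continue  # window would overrun the recording
        k = int(np.searchsorted(det.times, tt))
        if k >= det.eligible.size or not det.eligible[k]:
            continue
        windows.append(StimWindow(pending, on_start=tt))
        next_allowed = tt + ON_S + OFF_S
        pending = next(sequencer)
        spec = conditions[pending]
        open_target = (spec.phase_target
                       if spec.phase_target is not None else up_target)
    return windows


def plan_tones(
    window: StimWindow, spec: ConditionSpec, pll: PLLRun | None = None,
) -> list[ToneEvent]:
    """Tone plan of one ON window.

    ISI1 variants: tones every 1 s from ON onset, volumes from the plan
    (constant plans repeat).  UP/DOWN: one tone per own-target-phase
    trigger during ON.  ENVELOPE / BINAURAL_BEATS: a single 10 s event.
    SHAM: none.  A burst whose duration would cross the ON boundary is
    dropped, keeping the OFF window stimulus-free.
    """
    name = spec.name
    dur = spec.tone_duration_ms / 1000.0
    tones: list[ToneEvent] = []
    if name == "SHAM":
        return tones

    def vol(i: int) -> float:
        if isinstance(spec.volume_plan, (list, tuple)):
            return float(spec.volume_plan[min(i, len(spec.volume_plan) - 1)])
        return float(spec.volume_plan)

    if spec.phase_target is not None:  # UP / DOWN
        if pll is None:
            raise ValueError(f"{name} needs the PLL trigger stream")
        trig = pll.triggers.get(float(spec.phase_target), np.empty(0))
        sel = trig[(trig >= window.on_start) & (trig < window.on_end)]
        for i, tt in enumerate(sel):
            if tt + dur <= window.on_end:
                tones.append(ToneEvent(float(tt), dur, vol(i),
                                       {"kind": "pink_burst"}))
    elif name == "ENVELOPE":
        tones.append(ToneEvent(window.on_start, min(dur, ON_S), vol(0),
                               {"kind": "am_pink", "mod_hz": 1.0}))
    elif name == "BINAURAL_BEATS":
        tones.append(ToneEvent(
            window.on_start, min(dur, ON_S), vol(0),
            {"kind": "binaural", "carrier_hz": spec.carrier_hz,
             "beat_hz": spec.beat_hz}))
    else:  # ISI1 rhythm
        n_plan = (len(spec.volume_plan)
                  if isinstance(spec.volume_plan, (list, tuple)) else
                  int(ON_S))
        for i in range(n_plan):
            onset = window.on_start + float(i)
            if onset + dur <= window.on_end:
                tones.append(ToneEvent(onset, dur, vol(i),
                                       {"kind": "pink_burst"}))
    return tones


# ---------------------------------------------------------------------------
# audio rendering
# ---------------------------------------------------------------------------

REF_DB = 45.0  # dB value mapped to relative amplitude 1.0


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** -0.5
    x = np.fft.irfft(spec, n)
    return x / max(np.max(np.abs(x)), 1e-12)


def db_to_amp(db: float) -> float:
    return 10.0 ** ((db - REF_DB) / 20.0)


def render_audio(
    tones: list[ToneEvent], duration_s: float, audio_rate: float = 44100.0,
    t0: float = 0.0, seed: int = 0,
) -> np.ndarray:
    """Stereo waveform of a tone plan (2, n) in [-1, 1]-ish units.

    Pink noise via 1/f spectral shaping; volumes in dB map to relative
    amplitude with 45 dB as reference; binaural events are pure tones at
    the carrier (left) and carrier + beat (right).
    """
    if audio_rate < 8000:
        raise ValueError("audio_rate must be >= 8 kHz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * audio_rate))
    out = np.zeros((2, n))
    for tone in tones:
        i0 = int(round((tone.onset - t0) * audio_rate))
        ln = int(round(tone.duration * audio_rate))
        i1 = min(i0 + ln, n)
        if i1 <= i0 or i0 < 0:
            continue
        amp = db_to_amp(tone.volume_db)
        kind = tone.payload.get("kind", "pink_burst")
        tt = np.arange(i1 - i0) / audio_rate
        if kind == "binaural":
            fc = tone.payload["carrier_hz"]
            fb = tone.payload["beat_hz"]
            out[0, i0:i1] += amp * np.sin(2 * np.pi * fc * tt)
            out[1, i0:i1] += amp * np.sin(2 * np.pi * (fc + fb) * tt)
        elif kind == "am_pink":
            mod = 0.5 * (1 - np.cos(2 * np.pi * tone.payload["mod_hz"] * tt))
            burst = _pink_noise(i1 - i0, rng) * mod
            out[0, i0:i1] += amp * burst
            out[1, i0:i1] += amp * burst
        else:
            burst = _pink_noise(i1 - i0, rng)
            ramp_n = max(int(0.005 * audio_rate), 1)
            env = np.ones(i1 - i0)
            env[:ramp_n] = np.linspace(0, 1, ramp_n)
            env[-ramp_n:] = np.linspace(1, 0, ramp_n)
            out[0, i0:i1] += amp * burst * env
            out[1, i0:i1] += amp * burst * env
    return out


# ---------------------------------------------------------------------------
# end-to-end engine run
# ---------------------------------------------------------------------------

@dataclass
class EngineResult:
    windows: list[StimWindow]
    detector: DetectorOutput
    pll: PLLRun
    conditions: dict[str, ConditionSpec]


def run_closed_loop(
    rec: SignalRecording,
    cfg: DetectorConfig | None = None,
    roster: tuple = STUDY1_ROSTER,
    seed: int = 0,
) -> EngineResult:
    """Detector + PLL + scheduler + tone planner over a whole recording."""
    cfg = cfg or DetectorConfig()
    conditions = default_conditions()
    unknown = set(roster) - set(conditions)
    if unknown:
        raise ValueError(f"unknown conditions {sorted(unknown)}")
    det = nrem_state_machine(rec, cfg)
    pll = run_pll(rec, cfg=cfg)
    seq = sequence_conditions(list(roster), seed)
    windows = schedule_windows(det, pll, seq, conditions)
    for w in windows:
        w.tones = plan_tones(w, conditions[w.condition], pll)
    return EngineResult(windows, det, pll, conditions)


def measure_delivery_phases(
    rec: SignalRecording, target: float,
    cfg: DetectorConfig | None = None,
    skip_s: float = 30.0,
) -> np.ndarray:
    """Delivered-stimulus sine phases for one phase-targeted condition.

    Runs the causal loop on the recording, takes every locked
    target-phase trigger after an initial ``skip_s`` settling period as a
    stimulus delivery, and measures each delivery's phase offline
    (zero-phase filter + Hilbert).  Returns the phases in degrees.
    """
    pll = run_pll(rec, cfg=cfg, targets=(target,))
    trig = pll.triggers[float(target)]
    trig = trig[trig >= skip_s]
    return delivery_phases(rec, trig)


def delivery_phases(rec: SignalRecording, tone_times: np.ndarray,
                    eeg_channel: str | None = None) -> np.ndarray:
    """Offline sine phase (deg) of the 0.5-2 Hz EEG at delivery times.

    This is the evaluation convention: zero-phase band-pass then Hilbert,
    independent of the causal loop that produced the triggers.
    """
    names = rec.channels_by_role("eeg")
    x = rec.channel(eeg_channel or names[0])
    band = bandpass_fir(x, rec.fs, *SO_BAND)
    phase = sine_phase_deg(band)
    idx = np.clip((np.asarray(tone_times) * rec.fs).round().astype(int),
                  0, x.size - 1)
    return phase[idx]
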