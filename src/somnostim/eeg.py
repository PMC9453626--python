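"""EEG analysis chain for windowed auditory stimulation.

Welch spectra and SHAM-referenced percentage change, Hilbert slow-wave
dynamics (the envelope of the 0.5-2 Hz band across the stimulation
window), sub-window SWA, spindle detection with a 2 s-bin start
probability, baseline-SWA pairing and the early/late night split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.optimize import curve_fit

from .signals import analytic_amplitude, band_power, bandpass_fir

WINDOW_SPAN_S = 20.0


@dataclass(frozen=True)
class BandSet:
    """The analysis frequency bands (Hz)."""

    low_swa: tuple = (0.5, 2.0)
    high_swa: tuple = (2.25, 4.5)
    low_alpha: tuple = (8.0, 10.0)
    slow_spindle: tuple = (10.0, 12.0)
    fast_spindle: tuple = (13.0, 16.0)
    spindle_detect: tuple = (10.0, 16.0)


DEFAULT_BANDS = BandSet()


@dataclass
class PSDMatrix:
    frequencies: np.ndarray
    values: np.ndarray           # (..., n_freqs), >= 0
    normalization: str = "none"  # 'none' | 'cumulative_to_30Hz'

    def normalized(self, f_max: float = 30.0) -> "PSDMatrix":
        """Each spectrum divided by its cumulative power up to ``f_max``."""
        sel = self.frequencies <= f_max
        total = self.values[..., sel].sum(axis=-1, keepdims=True)
        if np.any(total <= 0):
            raise ValueError("spectrum with zero cumulative power")
        return PSDMatrix(self.frequencies, self.values / total,
                         "cumulative_to_30Hz")


def welch_psd(segment: np.ndarray, fs: float,
              window_s: float = 4.0) -> PSDMatrix:
    """Welch PSD with Hann windows of ``window_s`` s and 50% overlap.

    With the default 4 s window the frequency resolution is 0.25 Hz.
    Rejects segments shorter than one window.
    """
    segment = np.asarray(segment, dtype=float)
    nper = int(round(window_s * fs))
    if segment.shape[-1] < nper:
        raise ValueError(
            f"segment shorter than the {window_s} s Welch window")
    f, p = sps.welch(segment, fs=fs, window="hann", nperseg=nper,
                     noverlap=nper // 2, detrend="constant", axis=-1)
    return PSDMatrix(f, p)


def psd_percent_change(cond: PSDMatrix, sham: PSDMatrix) -> np.ndarray:
    """Per-bin 100 * (cond - sham) / sham; NaN where the SHAM bin is zero."""
    if (cond.frequencies.shape != sham.frequencies.shape
            or not np.allclose(cond.frequencies, sham.frequencies)):
        raise ValueError("frequency grids differ")
    if cond.normalization != sham.normalization:
        raise ValueError("normalizations differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * (cond.values - sham.values) / sham.values
    out[..., sham.values == 0] = np.nan
    return out


# ---------------------------------------------------------------------------
# Hilbert slow-wave dynamics
# ---------------------------------------------------------------------------

@dataclass
class DynamicsTrace:
    """Per-condition mean +/- SEM percentage change across a window."""

    times: np.ndarray            # s relative to ON onset, spans ON+OFF
    mean: np.ndarray             # % change vs SHAM (or raw amplitude)
    sem: np.ndarray
    n_windows: int
    condition: str = ""


def _window_slices(envelope: np.ndarray, fs: float, on_starts,
                   span_s: float) -> np.ndarray:
    n_t = int(round(span_s * fs))
    rows = []
    for on in on_starts:
        i0 = int(round(on * fs))
        if i0 < 0 or i0 + n_t > envelope.size:
            continue
        rows.append(envelope[i0: i0 + n_t])
    return np.vstack(rows) if rows else np.empty((0, n_t))


def hilbert_dynamics(
    eeg: np.ndarray, fs: float,
    cond_on_starts, sham_on_starts,
    band: tuple[float, float] = DEFAULT_BANDS.low_swa,
    span_s: float = WINDOW_SPAN_S,
    condition: str = "",
) -> DynamicsTrace:
    """Slow-wave dynamics: % change of the Hilbert amplitude vs SHAM.

    The channel is zero-phase FIR band-passed over the *whole* recording
    (so window edges carry no filter transients), the analytic amplitude
    is extracted, condition windows are averaged per timepoint, and the
    trace reports ``100 * (mean_cond(t) - mean_sham(t)) / mean_sham(t)``.
    The SEM is that of the per-window percentage change against the SHAM
    mean.  Only pass window onsets that survived the validity rules
    (artifact/arousal-free N2/N3).
    """
    env = analytic_amplitude(bandpass_fir(np.asarray(eeg, float), fs, *band))
    cond_m = _window_slices(env, fs, cond_on_starts, span_s)
    sham_m = _window_slices(env, fs, sham_on_starts, span_s)
    n_t = int(round(span_s * fs))
    times = np.arange(n_t) / fs
    if cond_m.shape[0] == 0 or sham_m.shape[0] == 0:
        nan = np.full(n_t, np.nan)
        return DynamicsTrace(times, nan, nan, 0, condition)
    sham_mean = sham_m.mean(axis=0)
    per_window = 100.0 * (cond_m - sham_mean) / sham_mean
    mean = per_window.mean(axis=0)
    sem = per_window.std(axis=0, ddof=1) / np.sqrt(per_window.shape[0]) \
        if per_window.shape[0] > 1 else np.zeros(n_t)
    return DynamicsTrace(times, mean, sem, cond_m.shape[0], condition)


def fit_response_decay(
    trace: DynamicsTrace, latency_s: float = 0.5,
    fit_until_s: float = 10.0,
) -> tuple[float, float]:
    """Fit ``100 * g * exp(-(t - latency)/tau)`` to a dynamics trace.

    Returns ``(gain, tau_s)`` of the decaying early response; used to
    recover the injected stimulus-response parameters.
    """
    sel = (trace.times >= latency_s) & (trace.times <= fit_until_s)
    t = trace.times[sel] - latency_s
    y = trace.mean[sel]

    def model(tt, g, tau):
        return 100.0 * g * np.exp(-tt / tau)

    g0 = max(y[0] / 100.0, 1e-3)
    popt, _ = curve_fit(model, t, y, p0=(g0, 3.0),
                        bounds=([0, 0.1], [20, 60]), maxfev=10000)
    return float(popt[0]), float(popt[1])


# ---------------------------------------------------------------------------
# sub-window SWA
# ---------------------------------------------------------------------------

def swa_subwindows(
    eeg: np.ndarray, fs: float, on_starts,
    band: tuple[float, float] = DEFAULT_BANDS.low_swa,
    sub_s: float = 5.0,
    welch_window_s: float = 2.0,
) -> np.ndarray:
    """Band power of each 5 s quarter of every stimulation window.

    Returns shape ``(n_windows, 4)``: ON[0-5), ON[5-10), OFF[0-5),
    OFF[5-10).  The Welch window is shortened to 2 s because a 4 s window
    cannot tile a 5 s segment; this trades frequency resolution (0.5 Hz)
    for an unbiased short-segment estimate.
    """
    eeg = np.asarray(eeg, dtype=float)
    n_sub = int(round(WINDOW_SPAN_S / sub_s))
    out = []
    for on in on_starts:
        vals = []
        for j in range(n_sub):
            i0 = int(round((on + j * sub_s) * fs))
            i1 = i0 + int(round(sub_s * fs))
            if i0 < 0 or i1 > eeg.size:
                vals = [np.nan] * n_sub
                break
            psd = welch_psd(eeg[i0:i1], fs, window_s=welch_window_s)
            vals.append(float(band_power(psd.frequencies, psd.values, *band)))
        out.append(vals)
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# spindles
# ---------------------------------------------------------------------------

@dataclass
class SpindleEvent:
    start: float      # s
    duration: float   # s
    frequency: float  # Hz, peak frequency of the event


def detect_spindles(
    eeg: np.ndarray, fs: float,
    band: tuple[float, float] = DEFAULT_BANDS.spindle_detect,
    low_k: float = 2.0, high_k: float = 5.0,
    min_duration: float = 0.5, merge_gap: float = 0.25,
    env_smooth_s: float = 0.3, min_core_s: float = 0.25,
) -> list[SpindleEvent]:
    """Envelope-threshold spindle detection.

    Forward-backward Chebyshev band-pass in 10-16 Hz (type I, so the
    passband covers the stated band without edge attenuation); the
    analytic envelope is smoothed over ``env_smooth_s``.  An event is
    seeded wherever the envelope spends at least ``min_core_s`` above
    ``low_k`` times the recording-mean envelope, its boundaries are the
    surrounding crossings of the mean envelope itself (the conventional
    two-threshold rule: detect high, delimit at baseline), events closer
    than ``merge_gap`` are merged, events shorter than ``min_duration``
    are dropped, and events whose peak envelope exceeds ``high_k`` times
    the mean are rejected (artifact guard).  The "mean of the filtered
    signal" is read as the mean *envelope* since a zero-mean band-passed
    trace has a vanishing raw mean.
    """
    eeg = np.asarray(eeg, dtype=float)
    sos = sps.cheby1(4, 0.5, band, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, eeg)
    env = analytic_amplitude(filt)
    k_sm = max(int(round(env_smooth_s * fs)), 1)
    env = np.convolve(env, np.ones(k_sm) / k_sm, mode="same")
    min_core_n = max(int(round(min_core_s * fs)), 1)

    def one_pass(mean_env: float) -> list[tuple[int, int]]:
        above_base = env > mean_env
        seed = env > low_k * mean_env
        if not seed.any():
            return []
        idx = np.flatnonzero(above_base)
        runs = []
        run_start = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if i != prev + 1:
                runs.append((run_start, prev))
                run_start = i
            prev = i
        runs.append((run_start, prev))
        runs = [(a, b) for a, b in runs
                if seed[a:b + 1].sum() >= min_core_n]
        if not runs:
            return []
        merged = [runs[0]]
        gap_n = merge_gap * fs
        for a, b in runs[1:]:
            if a - merged[-1][1] <= gap_n:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        return merged

    mean_env = float(env.mean())
    if mean_env <= 0:
        return []
    # two passes: the events themselves inflate the recording mean, so the
    # baseline is re-estimated with first-pass event samples excluded
    first = one_pass(mean_env)
    if first:
        keep = np.ones(env.size, dtype=bool)
        for a, b in first:
            keep[a:b + 1] = False
        if keep.any():
            mean_env = float(env[keep].mean())
    events = []
    for a, b in one_pass(mean_env):
        dur = (b - a + 1) / fs
        if dur < min_duration:
            continue
        if env[a:b + 1].max() > high_k * mean_env:
            continue
        seg = filt[a:b + 1] * np.hanning(b - a + 1)
        freqs = np.fft.rfftfreq(seg.size, 1.0 / fs)
        spec = np.abs(np.fft.rfft(seg))
        inband = (freqs >= band[0]) & (freqs <= band[1])
        fpk = float(freqs[inband][np.argmax(spec[inband])]) if inband.any() \
            else float("nan")
        events.append(SpindleEvent(a / fs, dur, fpk))
    return events


def spindle_probability(
    events: list[SpindleEvent], on_starts,
    bin_s: float = 2.0, span_s: float = WINDOW_SPAN_S,
) -> np.ndarray:
    """Fraction of windows with >= 1 spindle start per 2 s bin.

    Each window contributes 0 or 1 per bin regardless of how many
    spindles start there; the probability is the per-bin sum divided by
    the number of windows.
    """
    on_starts = np.asarray(list(on_starts), dtype=float)
    if on_starts.size == 0:
        raise ValueError("need at least one stimulation window")
    n_bins = int(round(span_s / bin_s))
    starts = np.asarray([e.start for e in events], dtype=float)
    counts = np.zeros(n_bins)
    for on in on_starts:
        rel = starts[(starts >= on) & (starts < on + span_s)] - on
        bins = np.unique((rel / bin_s).astype(int))
        counts[bins[bins < n_bins]] += 1.0
    return counts / on_starts.size


# ---------------------------------------------------------------------------
# baseline pairing and night split
# ---------------------------------------------------------------------------

def baseline_swa_pairs(
    eeg: np.ndarray, fs: float,
    isi1_on_starts, sham_on_starts,
    band: tuple[float, float] = DEFAULT_BANDS.low_swa,
    baseline_s: float = 5.0, first_s: float = 5.0,
    pair_radius_s: float = 300.0,
) -> np.ndarray:
    """Pairs of (pre-window baseline SWA, % first-5 s SWA change vs SHAM).

    For each rhythmic-stimulation window whose closest SHAM window lies
    within 5 min (ties to the earlier SHAM), the baseline is the low-SWA
    of the 5 s immediately before ON onset and the change is
    ``100 * (SWA_first5s_cond - SWA_first5s_sham) / SWA_first5s_sham``.
    Returns shape ``(n_pairs, 2)``; unpaired windows are dropped.
    """
    eeg = np.asarray(eeg, dtype=float)
    sham = np.asarray(list(sham_on_starts), dtype=float)

    def swa(t0: float, dur: float) -> float | None:
        i0, i1 = int(round(t0 * fs)), int(round((t0 + dur) * fs))
        if i0 < 0 or i1 > eeg.size:
            return None
        psd = welch_psd(eeg[i0:i1], fs, window_s=2.0)
        return float(band_power(psd.frequencies, psd.values, *band))

    pairs = []
    for on in isi1_on_starts:
        if sham.size == 0:
            break
        dist = np.abs(sham - on)
        order = np.lexsort((sham, dist))
        if dist[order[0]] > pair_radius_s:
            continue
        base = swa(on - baseline_s, baseline_s)
        first = swa(on, first_s)
        ref = swa(sham[order[0]], first_s)
        if base is None or first is None or ref is None or ref <= 0:
            continue
        pairs.append((base, 100.0 * (first - ref) / ref))
    return np.asarray(pairs, dtype=float).reshape(-1, 2)


def split_early_late(windows, first_on: float | None = None,
                     split_h: float = 4.0) -> tuple[list, list]:
    """Split windows into the first 4 h of stimulation and the remainder.

    The clock starts at the first stimulation ON window; a window exactly
    at the 4 h mark belongs to the late set (half-open convention).
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one window")
    if first_on is None:
        first_on = min(w.on_start for w in windows)
    cut = first_on + split_h * 3600.0
    early = [w for w in windows if w.on_start < cut]
    late = [w for w in windows if w.on_start >= cut]
    return early, late
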