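"""Cardiovascular analysis chain.

R-peak detection on the ECG, per-stimulation-window RR extraction,
short-window HRV indices (RMSSD, SDNN, extrema), continuous instantaneous
heart rate (IHR = 60 / RR in seconds), and SHAM-referenced percentage IHR
change.  HRV here is deliberately computed on ~20 s stimulation windows,
far below guideline durations; the indices are only meaningful as
within-night contrasts between conditions, never as clinical HRV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import Akima1DInterpolator

from .signals import SignalRecording

#: pairing radius for the closest-SHAM reference, seconds
SHAM_PAIR_RADIUS_S = 300.0
#: trailing part of each window excluded from IHR traces (interpolation of
#: the last beats is unreliable), seconds
IHR_TAIL_EXCLUDE_S = 2.0


@dataclass
class RRSeries:
    """Ordered R-peak times (s) with per-interval quality mask.

    Excluded segments are flagged through ``quality`` rather than deleted
    so that window bookkeeping stays aligned with the recording.
    """

    r_times: np.ndarray  # seconds, strictly increasing
    quality: np.ndarray | None = None  # per interval, True = usable

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.r_times.size > 1 and not np.all(np.diff(self.r_times) > 0):
            raise ValueError("r_times must be strictly increasing")
        n_int = max(self.r_times.size - 1, 0)
        if self.quality is None:
            self.quality = np.ones(n_int, dtype=bool)
        else:
            self.quality = np.asarray(self.quality, dtype=bool)
            if self.quality.size != n_int:
                raise ValueError("quality mask must have one entry per interval")

    @property
    def rr_ms(self) -> np.ndarray:
        return np.diff(self.r_times) * 1000.0

    def __len__(self) -> int:
        return self.r_times.size


@dataclass
class WindowHRV:
    """Per-window time-domain HRV summary (all in ms)."""

    mean_rr: float
    longest_rr: float
    shortest_rr: float
    rr_diff: float
    rmssd: float
    sdnn: float
    n_intervals: int
    valid: bool = True


def detect_r_peaks(
    ecg: np.ndarray,
    fs: float,
    refractory_s: float = 0.25,
    band: tuple[float, float] = (5.0, 30.0),
) -> RRSeries:
    """Detect R peaks with a band-pass + adaptive-threshold picker.

    The trace is band-passed to emphasise the QRS complex, squared (which
    also makes detection polarity-robust), smoothed over 120 ms, and peaks
    are picked above an adaptive threshold (30% of the 98th percentile of
    the smoothed energy) with a 250 ms refractory period.  Each pick is
    then refined to the extremum of the band-passed trace within 60 ms.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < fs:
        return RRSeries(np.empty(0))
    sos = sps.butter(3, band, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, ecg)
    energy = filt ** 2
    win = max(int(0.12 * fs), 1)
    smooth = np.convolve(energy, np.ones(win) / win, mode="same")
    thr = 0.3 * np.percentile(smooth, 98)
    if thr <= 0:
        return RRSeries(np.empty(0))
    locs, _ = sps.find_peaks(
        smooth, height=thr, distance=max(int(refractory_s * fs), 1)
    )
    if locs.size == 0:
        return RRSeries(np.empty(0))
    half = int(0.06 * fs)
    refined = np.empty(locs.size, dtype=int)
    for i, loc in enumerate(locs):
        a, b = max(loc - half, 0), min(loc + half + 1, filt.size)
        refined[i] = a + int(np.argmax(np.abs(filt[a:b])))
    refined = np.unique(refined)
    # enforce refractory after refinement
    keep = [0]
    for i in range(1, refined.size):
        if refined[i] - refined[keep[-1]] >= refractory_s * fs:
            keep.append(i)
    return RRSeries(refined[keep] / fs)


def detect_r_peaks_recording(rec: SignalRecording) -> RRSeries:
    names = rec.channels_by_role("ecg")
    if not names:
        raise ValueError(
            f"recording has no ECG channel; channels: {rec.channel_names}"
        )
    return detect_r_peaks(rec.channel(names[0]), rec.fs)


def window_rr(rr: RRSeries, on_start: float,
              span_s: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """RR intervals whose *both* bounding R peaks lie inside the window.

    Returns ``(interval_end_times_s, rr_ms)``; empty arrays when fewer
    than two usable peaks fall in ``[on_start, on_start + span_s)``.
    """
    t = rr.r_times
    inside = (t >= on_start) & (t < on_start + span_s)
    # interval i spans peaks i..i+1: need both inside and quality
    ok = inside[:-1] & inside[1:] & rr.quality
    return t[1:][ok], rr.rr_ms[ok]


def hrv_features(rr_ms: np.ndarray) -> WindowHRV:
    """Time-domain HRV indices of one window's RR intervals.

    RMSSD = sqrt(mean of squared successive differences); SDNN = sample
    (n-1) standard deviation of the intervals.
    """
    rr_ms = np.asarray(rr_ms, dtype=float)
    if rr_ms.size < 2:
        return WindowHRV(*(np.nan,) * 6, n_intervals=int(rr_ms.size),
                         valid=False)
    diffs = np.diff(rr_ms)
    return WindowHRV(
        mean_rr=float(np.mean(rr_ms)),
        longest_rr=float(np.max(rr_ms)),
        shortest_rr=float(np.min(rr_ms)),
        rr_diff=float(np.max(rr_ms) - np.min(rr_ms)),
        rmssd=float(np.sqrt(np.mean(diffs ** 2))),
        sdnn=float(np.std(rr_ms, ddof=1)),
        n_intervals=int(rr_ms.size),
    )


def ihr_continuous(
    rr: RRSeries,
    on_start: float,
    span_s: float = 20.0,
    grid_rate: float = 10.0,
    anchor: str = "end",
    max_gap_s: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Uniform IHR trace (bpm) over one stimulation window.

    IHR samples (60 / RR in seconds) are anchored at the closing R peak of
    each interval (``anchor='end'``) or the interval midpoint
    (``anchor='mid'``), resampled onto a ``grid_rate`` grid with a
    modified-Akima (makima) interpolant and clipped to the contributing
    samples' range so the trace never overshoots beyond neighbouring
    extrema.  The last 2 s of the window are dropped, so the trace covers
    the ON window plus the first 8 s of OFF.

    Returns ``(times_s, ihr_bpm, valid)``; ``valid`` is False when fewer
    than 3 intervals are available or an internal gap exceeds
    ``max_gap_s``.
    """
    end_t, rr_ms = window_rr(rr, on_start, span_s)
    t_grid = on_start + np.arange(
        0.0, span_s - IHR_TAIL_EXCLUDE_S, 1.0 / grid_rate
    )
    if rr_ms.size < 3:
        return t_grid, np.full(t_grid.size, np.nan), False
    anchors = end_t if anchor == "end" else end_t - rr_ms / 2000.0
    ihr = 60000.0 / rr_ms
    valid = bool(np.max(np.diff(anchors), initial=0.0) <= max_gap_s)
    interp = Akima1DInterpolator(anchors, ihr, method="makima",
                                 extrapolate=True)
    trace = np.clip(interp(t_grid), np.min(ihr), np.max(ihr))
    return t_grid, trace, valid


def sham_reference_hr(rr: RRSeries, sham_on_starts: np.ndarray,
                      cond_on_start: float,
                      span_s: float = 20.0) -> float | None:
    """Mean HR (bpm) of the closest SHAM window within the 5 min radius.

    Ties between two equidistant SHAM windows go to the earlier one.
    Returns None when no SHAM window qualifies or the SHAM window holds
    fewer than 2 usable intervals.
    """
    sham_on_starts = np.asarray(sham_on_starts, dtype=float)
    if sham_on_starts.size == 0:
        return None
    dist = np.abs(sham_on_starts - cond_on_start)
    order = np.lexsort((sham_on_starts, dist))  # distance, then earlier
    best = order[0]
    if dist[best] > SHAM_PAIR_RADIUS_S:
        return None
    _, rr_ms = window_rr(rr, sham_on_starts[best], span_s)
    if rr_ms.size < 2:
        return None
    return float(np.mean(60000.0 / rr_ms))


def relative_ihr(
    rr: RRSeries,
    cond_on_starts: np.ndarray,
    sham_on_starts: np.ndarray,
    span_s: float = 20.0,
    grid_rate: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentage IHR change traces referenced to the closest SHAM window.

    For each condition window with a SHAM window within 5 min, the trace
    is ``100 * (IHR(t) - meanHR_sham) / meanHR_sham`` on the common
    window-relative grid (ON + first 8 s of OFF).  Windows without a
    qualifying SHAM partner or with an invalid IHR trace are dropped.

    Returns ``(rel_times_s, traces)`` with ``traces`` of shape
    ``(n_kept_windows, n_times)``.
    """
    rel_t = np.arange(0.0, span_s - IHR_TAIL_EXCLUDE_S, 1.0 / grid_rate)
    kept = []
    for on in np.asarray(cond_on_starts, dtype=float):
        ref = sham_reference_hr(rr, sham_on_starts, on, span_s)
        if ref is None or ref <= 0:
            continue
        _, trace, ok = ihr_continuous(rr, on, span_s, grid_rate)
        if not ok:
            continue
        kept.append(100.0 * (trace - ref) / ref)
    if not kept:
        return rel_t, np.empty((0, rel_t.size))
    return rel_t, np.vstack(kept)
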