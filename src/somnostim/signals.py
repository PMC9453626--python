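"""Core containers and band-limited signal helpers.

Conventions used throughout the package:

* all event times are seconds from recording start, intervals half-open
  ``[start, end)``;
* EEG/EOG amplitudes are microvolts, ECG is millivolts, RR intervals are
  milliseconds;
* the instantaneous phase of a band-limited signal is the *sine phase*:
  the signal is proportional to ``sin(phase)``, so 0 deg is the
  positive-going zero crossing, 90 deg the positive peak and 270 deg the
  trough.  50 deg therefore lies on the late ascending (up) phase of a
  slow wave and 230 deg on the descending (down) phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

STAGES = ("WAKE", "N1", "N2", "N3", "REM")
NREM_STAGES = ("N2", "N3")
EPOCH_S = 20.0


@dataclass
class SignalRecording:
    """Uniformly sampled multichannel time series with channel roles."""

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_names: list[str]
    channel_roles: list[str]  # per channel: 'eeg' | 'eog' | 'ecg'
    units: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length does not match data rows")
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError("channel_roles length does not match data rows")
        if not self.units:
            self.units = [
                "mV" if r == "ecg" else "uV" for r in self.channel_roles
            ]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"no channel {name!r}; have {self.channel_names}"
            ) from None
        return self.data[i]

    def channels_by_role(self, role: str) -> list[str]:
        return [
            n for n, r in zip(self.channel_names, self.channel_roles)
            if r == role
        ]

    def copy(self) -> "SignalRecording":
        return SignalRecording(
            self.data.copy(), self.fs, list(self.channel_names),
            list(self.channel_roles), list(self.units),
        )


@dataclass
class Hypnogram:
    """Scored sleep stages in fixed 20 s epochs."""

    stages: list[str]
    epoch_duration: float = EPOCH_S

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_duration

    def stage_at(self, t: float) -> str:
        i = int(t // self.epoch_duration)
        i = min(max(i, 0), self.n_epochs - 1)
        return self.stages[i]

    def sample_stages(self, fs: float, n_samples: int) -> np.ndarray:
        """Stage label for every sample of a recording at rate ``fs``."""
        idx = (np.arange(n_samples) / fs // self.epoch_duration).astype(int)
        idx = np.clip(idx, 0, self.n_epochs - 1)
        return np.asarray(self.stages, dtype=object)[idx]

    def mask(self, fs: float, n_samples: int, stages) -> np.ndarray:
        labels = self.sample_stages(fs, n_samples)
        return np.isin(labels, list(stages))


def bandpass_fir(
    x: np.ndarray, fs: float, lo: float, hi: float,
    trans: float | None = None,
) -> np.ndarray:
    """Zero-phase FIR band-pass.

    A linear-phase windowed-sinc kernel (Hamming) applied with a centered
    FFT convolution, so the net filter is zero phase.  The transition
    width defaults to half the lower edge (clamped to [0.25, 2] Hz),
    which keeps the kernel short enough for 0.5 Hz edges at 500 Hz.
    """
    x = np.asarray(x, dtype=float)
    if trans is None:
        trans = float(np.clip(lo / 2.0, 0.25, 2.0))
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1  # Hamming transition rule
    numtaps = min(numtaps, (len(x) // 3) * 2 - 1)
    if numtaps < 11:
        raise ValueError("signal too short for the requested band")
    taps = sps.firwin(numtaps, [lo, hi], pass_zero=False, fs=fs,
                      window="hamming")
    return sps.fftconvolve(x, taps, mode="same")


def analytic_amplitude(x: np.ndarray) -> np.ndarray:
    """Envelope (magnitude of the analytic signal) of a band-limited trace."""
    return np.abs(sps.hilbert(np.asarray(x, dtype=float)))


def sine_phase_deg(x: np.ndarray) -> np.ndarray:
    """Instantaneous sine phase in degrees, in [0, 360).

    For ``x = A sin(theta)`` the analytic signal has angle ``theta - 90``
    deg, so 90 deg is added back to land on the sine convention.
    """
    return np.mod(np.degrees(np.angle(sps.hilbert(x))) + 90.0, 360.0)


def band_power(freqs: np.ndarray, psd: np.ndarray, lo: float,
               hi: float) -> np.ndarray:
    """Integrated power in ``[lo, hi]`` from a PSD (rectangle rule).

    Works on the last axis so stacked spectra integrate in one call.
    """
    freqs = np.asarray(freqs)
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        raise ValueError(f"band {lo}-{hi} Hz has no PSD bins")
    df = freqs[1] - freqs[0]
    return np.sum(np.asarray(psd)[..., sel], axis=-1) * df
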