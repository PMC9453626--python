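"""Formats: EDF signals, CSV events/metrics, YAML/JSON configuration.

EDF reading goes through :mod:`mne`.  Writing uses a small built-in EDF
writer (plain 16-bit EDF, 1 s data records), since the package's own
synthetic recordings must round-trip through the standard interchange
format without extra dependencies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import DetectorConfig, STUDY1_ROSTER, StimWindow, ToneEvent
from .signals import Hypnogram, SignalRecording
from .synth import CardiacParams, IHRKernel, StimResponse, SynthParams

_ROLE_PATTERNS = {
    "ecg": ("ecg", "ekg"),
    "eog": ("eog", "loc", "roc"),
    "eeg": ("eeg", "fp", "fz", "cz", "pz", "oz", "f3", "f4", "c3", "c4",
            "p3", "p4", "o1", "o2"),
}


def infer_role(label: str) -> str | None:
    low = label.lower()
    for role, pats in _ROLE_PATTERNS.items():
        if any(p in low for p in pats):
            return role
    return None


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, rec: SignalRecording) -> None:
    """Write a recording as 16-bit EDF with 1 s data records.

    The sampling rate must therefore be a whole number of samples per
    second.  Physical ranges are taken per channel from the data, so the
    16-bit quantization step adapts to each channel's dynamic range.
    """
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer needs an integer sampling rate")
    ns = rec.data.shape[0]
    n_rec = rec.n_samples // spr
    data = rec.data[:, : n_rec * spr]

    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    flat = pmaxs - pmins < 1e-12
    pmaxs[flat] = pmins[flat] + 1.0
    dmin, dmax = -32768, 32767

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad("Startdate X X X X", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(256 * (1 + ns)), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(ns), 4))
        for name in rec.channel_names:
            f.write(_pad(name, 16))
        for _ in range(ns):
            f.write(_pad("", 80))
        for unit in rec.units:
            f.write(_pad(unit, 8))
        for v in pmins:
            f.write(_pad(f"{v:.6g}"[:8], 8))
        for v in pmaxs:
            f.write(_pad(f"{v:.6g}"[:8], 8))
        for _ in range(ns):
            f.write(_pad(str(dmin), 8))
        for _ in range(ns):
            f.write(_pad(str(dmax), 8))
        for _ in range(ns):
            f.write(_pad("", 80))
        for _ in range(ns):
            f.write(_pad(str(spr), 8))
        for _ in range(ns):
            f.write(_pad("", 32))
        # re-read the printed physical extremes so the scaling matches
        # what a reader will parse from the 8-char ascii fields
        pmin_r = np.array([float(f"{v:.6g}"[:8]) for v in pmins])
        pmax_r = np.array([float(f"{v:.6g}"[:8]) for v in pmaxs])
        gain = (dmax - dmin) / (pmax_r - pmin_r)
        dig = np.clip(
            np.rint((data - pmin_r[:, None]) * gain[:, None] + dmin),
            dmin, dmax,
        ).astype("<i2")
        for r in range(n_rec):
            for ch in range(ns):
                f.write(dig[ch, r * spr:(r + 1) * spr].tobytes())


def read_recording(path) -> SignalRecording:
    """Read an EDF/EDF+ file into a SignalRecording via mne.

    Channel roles are inferred from label patterns; an error listing the
    labels found is raised when no EEG or no ECG/EOG roles can be mapped
    is not fatal — only a missing EEG role is.
    """
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="ERROR")
    fs = float(raw.info["sfreq"])
    names = list(raw.ch_names)
    inferred = [infer_role(n) for n in names]
    if "eeg" not in inferred:
        raise ValueError(
            f"no channel maps to an EEG role; labels found: {names}")
    roles = [r or "eeg" for r in inferred]
    data = raw.get_data()  # volts for eeg/eog/ecg-typed channels
    units = []
    for i, role in enumerate(roles):
        if role == "ecg":
            data[i] *= 1e3   # V -> mV
            units.append("mV")
        else:
            data[i] *= 1e6   # V -> uV
            units.append("uV")
    return SignalRecording(data, fs, names, roles, units)


# ---------------------------------------------------------------------------
# CSV events / hypnogram
# ---------------------------------------------------------------------------

def windows_to_frame(windows, subject: str = "S01") -> pd.DataFrame:
    return pd.DataFrame([
        {"subject": subject, "window": i, "condition": w.condition,
         "on_start": w.on_start, "on_duration": w.on_duration,
         "off_duration": w.off_duration, "valid": w.valid,
         "n_tones": len(w.tones)}
        for i, w in enumerate(windows)
    ])


def tones_to_frame(windows, subject: str = "S01") -> pd.DataFrame:
    rows = []
    for i, w in enumerate(windows):
        for tone in w.tones:
            rows.append({"subject": subject, "window": i,
                         "condition": w.condition, "time": tone.onset,
                         "duration": tone.duration,
                         "volume_db": tone.volume_db})
    return pd.DataFrame(
        rows, columns=["subject", "window", "condition", "time", "duration",
                       "volume_db"])


def frame_to_windows(df: pd.DataFrame,
                     tones: pd.DataFrame | None = None) -> list[StimWindow]:
    windows = []
    for _, row in df.iterrows():
        w = StimWindow(row["condition"], float(row["on_start"]),
                       float(row.get("on_duration", 10.0)),
                       float(row.get("off_duration", 10.0)),
                       valid=bool(row.get("valid", True)))
        windows.append(w)
    if tones is not None and len(tones):
        for _, row in tones.iterrows():
            windows[int(row["window"])].tones.append(
                ToneEvent(float(row["time"]), float(row["duration"]),
                          float(row["volume_db"])))
    return windows


def hypnogram_to_frame(hyp: Hypnogram) -> pd.DataFrame:
    return pd.DataFrame({"epoch": np.arange(hyp.n_epochs),
                         "stage": hyp.stages})


def frame_to_hypnogram(df: pd.DataFrame) -> Hypnogram:
    return Hypnogram(list(df.sort_values("epoch")["stage"]))


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    input_path: str = "synthetic"
    duration_h: float = 1.0
    n_subjects: int = 1
    roster: tuple = STUDY1_ROSTER
    synth: SynthParams = field(default_factory=SynthParams)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    pair_radius_s: float = 300.0
    sub_window_s: float = 5.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roster"] = list(self.roster)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d and isinstance(d["synth"], dict):
            s = dict(d["synth"])
            if isinstance(s.get("stim_response"), dict):
                s["stim_response"] = StimResponse(**s["stim_response"])
            if isinstance(s.get("cardiac"), dict):
                c = dict(s["cardiac"])
                if isinstance(c.get("ihr_kernel"), dict):
                    c["ihr_kernel"] = IHRKernel(**c["ihr_kernel"])
                s["cardiac"] = CardiacParams(**c)
            if isinstance(s.get("spindle_freq_range"), list):
                s["spindle_freq_range"] = tuple(s["spindle_freq_range"])
            d["synth"] = SynthParams(**s)
        if "detector" in d and isinstance(d["detector"], dict):
            det = {k: tuple(v) if isinstance(v, list) else v
                   for k, v in d["detector"].items()}
            d["detector"] = DetectorConfig(**det)
        if "roster" in d:
            d["roster"] = tuple(d["roster"])
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        text = yaml.safe_dump(json.loads(json.dumps(self.to_dict())),
                              sort_keys=True)
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(text.encode()).hexdigest()[:16]
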