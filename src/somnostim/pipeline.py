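"""End-to-end driver: synthesis -> closed loop -> metrics -> statistics.

One "subject" is one synthetic night.  The engine schedules windows on
the un-stimulated EEG (what the online system saw), the slow-wave
response is then injected into the scheduled non-SHAM windows, the RR
series receives the stimulus-locked kernel for the same windows, and the
analysis chain runs on the resulting signals — so every reported effect
was planted with known parameters and recovered, never assumed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ecg import detect_r_peaks_recording, hrv_features, relative_ihr, \
    window_rr
from .eeg import (
    DEFAULT_BANDS, baseline_swa_pairs, detect_spindles, hilbert_dynamics,
    spindle_probability, swa_subwindows,
)
from .engine import run_closed_loop
from .io import RunConfig, hypnogram_to_frame, tones_to_frame, \
    windows_to_frame
from .signals import NREM_STAGES
from .stats import hochberg, paired_contrast, rmcorr
from .synth import generate_eeg, generate_hypnogram, generate_rr, \
    inject_stim_response

log = logging.getLogger("somnostim")


def mark_valid(windows, hyp, movement_events=()) -> None:
    """Validity per the inclusion rule: N2/N3 throughout, artifact-free.

    A window is valid when every epoch it touches is N2 or N3 and no
    movement artifact falls inside it.
    """
    moves = np.asarray(list(movement_events), dtype=float)
    for w in windows:
        e0 = int(w.on_start // hyp.epoch_duration)
        e1 = int((w.end - 1e-9) // hyp.epoch_duration)
        stages_ok = all(
            hyp.stages[min(e, hyp.n_epochs - 1)] in NREM_STAGES
            for e in range(e0, e1 + 1)
        )
        artifact = bool(
            moves.size and np.any((moves >= w.on_start) & (moves < w.end)))
        w.valid = stages_ok and not artifact


def run_subject(cfg: RunConfig, subject_idx: int) -> dict:
    """Simulate and analyse one synthetic night."""
    seed = cfg.seed + 1000 * subject_idx
    subject = f"S{subject_idx + 1:02d}"
    synth = dataclasses.replace(cfg.synth, seed=seed)

    hyp = generate_hypnogram(cfg.duration_h, seed)
    eeg_rec, truth = generate_eeg(hyp, synth)
    engine = run_closed_loop(eeg_rec, cfg.detector, cfg.roster, seed)
    windows = engine.windows
    mark_valid(windows, hyp, truth.movement_events)
    stim_rec = inject_stim_response(eeg_rec, windows, synth)
    rr_truth, ecg_rec = generate_rr(eeg_rec.duration, windows, synth)
    rr = detect_r_peaks_recording(ecg_rec)

    fz = stim_rec.channel(stim_rec.channels_by_role("eeg")[0])
    fs = stim_rec.fs
    valid = [w for w in windows if w.valid]
    sham_on = np.asarray(
        [w.on_start for w in valid if w.condition == "SHAM"])
    by_cond = {
        c: np.asarray([w.on_start for w in valid if w.condition == c])
        for c in cfg.roster
    }

    dyn_rows, hrv_rows, ihr_rows = [], [], []
    for cond in cfg.roster:
        if cond == "SHAM" or by_cond[cond].size == 0 or sham_on.size == 0:
            continue
        trace = hilbert_dynamics(fz, fs, by_cond[cond], sham_on,
                                 condition=cond)
        stride = max(int(fs // 10), 1)  # store at 10 Hz
        for t, m, s in zip(trace.times[::stride], trace.mean[::stride],
                           trace.sem[::stride]):
            dyn_rows.append({"subject": subject, "condition": cond,
                             "time": t, "mean": m, "sem": s,
                             "n": trace.n_windows})
        rel_t, traces = relative_ihr(rr, by_cond[cond], sham_on,
                                     grid_rate=10.0)
        if traces.size:
            mean = traces.mean(axis=0)
            sem = (traces.std(axis=0, ddof=1) / np.sqrt(traces.shape[0])
                   if traces.shape[0] > 1 else np.zeros(rel_t.size))
            for t, m, s in zip(rel_t, mean, sem):
                ihr_rows.append({"subject": subject, "condition": cond,
                                 "time": t, "mean": m, "sem": s,
                                 "n": traces.shape[0]})

    swa_rows = []
    for i, w in enumerate(windows):
        if not w.valid:
            continue
        sub = swa_subwindows(fz, fs, [w.on_start], sub_s=cfg.sub_window_s)[0]
        for j, v in enumerate(sub):
            swa_rows.append({"subject": subject, "window": i,
                             "condition": w.condition, "sub_window": j,
                             "band": "low_swa", "value": v})
        _, rr_ms = window_rr(rr, w.on_start)
        h = hrv_features(rr_ms)
        hrv_rows.append({"subject": subject, "window": i,
                         "condition": w.condition, **dataclasses.asdict(h)})

    spindles = detect_spindles(fz, fs)
    prob = (spindle_probability(spindles, [w.on_start for w in valid])
            if valid else np.full(10, np.nan))
    pairs = baseline_swa_pairs(
        fz, fs, by_cond.get("ISI1_High", np.empty(0)), sham_on,
        pair_radius_s=cfg.pair_radius_s)

    counters = {
        "scheduled": len(windows),
        "valid": len(valid),
        "sham": int(sham_on.size),
        "baseline_pairs": int(pairs.shape[0]),
        "spindles": len(spindles),
        "r_peaks": len(rr),
    }
    log.info("%s: %s", subject, counters)
    return {
        "subject": subject, "hypnogram": hyp, "windows": windows,
        "engine": engine, "truth": truth, "rr": rr, "rr_truth": rr_truth,
        "dynamics": pd.DataFrame(dyn_rows), "ihr": pd.DataFrame(ihr_rows),
        "swa": pd.DataFrame(swa_rows), "hrv": pd.DataFrame(hrv_rows),
        "spindle_probability": prob, "baseline_pairs": pairs,
        "counters": counters,
    }


def _group_stats(subjects: list[dict], roster) -> pd.DataFrame:
    """Desk-scale group inference: paired t contrasts of per-subject mean
    HRV features vs SHAM (Hochberg-adjusted per feature) and the rmcorr
    of baseline SWA vs SWA change across nights."""
    rows = []
    features = ("mean_rr", "longest_rr", "shortest_rr", "rmssd", "sdnn")
    hrv = pd.concat([s["hrv"] for s in subjects], ignore_index=True)
    if hrv.empty:
        hrv = pd.DataFrame(
            columns=["subject", "condition", *features])
    per = hrv.groupby(["subject", "condition"])[list(features)].mean()
    for feat in features:
        conds, ps, ts = [], [], []
        for cond in roster:
            if cond == "SHAM":
                continue
            try:
                wide = per[feat].unstack("condition")[[cond, "SHAM"]].dropna()
            except KeyError:
                continue
            if len(wide) < 2:
                continue
            res = paired_contrast(wide[cond].values, wide["SHAM"].values)
            conds.append(cond)
            ts.append(res.t)
            ps.append(res.p)
        if ps:
            adj = hochberg(ps)
            for c, t, p, pa in zip(conds, ts, ps, adj):
                rows.append({"term": f"{feat}:{c}-SHAM", "estimate": np.nan,
                             "statistic": t, "df": len(subjects) - 1,
                             "p": p, "p_adj": pa})
    xs = [s["baseline_pairs"][:, 0] for s in subjects
          if s["baseline_pairs"].shape[0] >= 2]
    ys = [s["baseline_pairs"][:, 1] for s in subjects
          if s["baseline_pairs"].shape[0] >= 2]
    if len(xs) >= 2:
        try:
            rm = rmcorr(xs, ys)
            rows.append({"term": "rmcorr:baseline_swa~swa_change",
                         "estimate": rm.r_rm, "statistic": np.nan,
                         "df": rm.df, "p": rm.p, "p_adj": rm.p})
        except ValueError:
            pass
    return pd.DataFrame(
        rows, columns=["term", "estimate", "statistic", "df", "p", "p_adj"])


def run_pipeline(cfg: RunConfig, out_dir=None) -> dict:
    """Run the full chain; optionally write tidy CSVs and a manifest.

    Deterministic for a fixed config: re-running with the same seed
    reproduces every output byte for byte (CSV floats use repr
    formatting).
    """
    out = Path(out_dir) if out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__, "seed": cfg.seed,
        "config_hash": cfg.content_hash(), "status": "running",
        "stage": "init",
    }
    subjects = []
    try:
        for i in range(cfg.n_subjects):
            manifest["stage"] = f"subject_{i}"
            subjects.append(run_subject(cfg, i))
        manifest["stage"] = "stats"
        stats = _group_stats(subjects, cfg.roster) if len(subjects) >= 2 \
            else pd.DataFrame(
                columns=["term", "estimate", "statistic", "df", "p", "p_adj"])
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = f"failed: {exc}"
        if out:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    manifest["counters"] = {s["subject"]: s["counters"] for s in subjects}

    bundle = {"config": cfg, "subjects": subjects, "stats": stats,
              "manifest": manifest}
    if out:
        cfg.save(out / "config.yaml")
        pd.concat(
            [windows_to_frame(s["windows"], s["subject"]) for s in subjects],
            ignore_index=True,
        ).to_csv(out / "windows.csv", index=False)
        pd.concat(
            [tones_to_frame(s["windows"], s["subject"]) for s in subjects],
            ignore_index=True,
        ).to_csv(out / "tones.csv", index=False)
        for name in ("dynamics", "ihr", "swa", "hrv"):
            pd.concat([s[name] for s in subjects], ignore_index=True) \
                .to_csv(out / f"{name}.csv", index=False)
        hypnogram_to_frame(subjects[0]["hypnogram"]).to_csv(
            out / "hypnogram_s01.csv", index=False)
        stats.to_csv(out / "stats.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
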