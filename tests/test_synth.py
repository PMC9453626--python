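"""Synthetic polysomnography: structure, determinism, ground truth."""

import numpy as np
import pytest

from somnostim.ecg import detect_r_peaks_recording
from somnostim.engine import StimWindow
from somnostim.signals import Hypnogram, bandpass_fir, analytic_amplitude
from somnostim.synth import (
    CardiacParams, IHRKernel, SynthParams, StimResponse, clean_so_recording,
    generate_eeg, generate_hypnogram, generate_rr, inject_stim_response,
)
from somnostim.eeg import welch_psd
from somnostim.signals import band_power


class TestHypnogram:
    def test_eight_hours_has_1440_epochs(self):
        hyp = generate_hypnogram(8, seed=1)
        assert hyp.n_epochs == 1440
        assert hyp.duration == 8 * 3600

    def test_same_seed_identical(self):
        assert generate_hypnogram(8, 1).stages == generate_hypnogram(8, 1).stages

    def test_contains_long_nrem_run(self):
        # a continuous N2/N3 run of at least 30 epochs (10 min)
        hyp = generate_hypnogram(8, seed=1)
        best = run = 0
        for s in hyp.stages:
            run = run + 1 if s in ("N2", "N3") else 0
            best = max(best, run)
        assert best >= 30

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            generate_hypnogram(0)

    def test_rejects_unknown_stage(self):
        with pytest.raises(ValueError):
            Hypnogram(["N2", "N4"])


class TestGenerateEEG:
    def test_n3_slow_wave_power_dominates(self, n3_recording):
        rec, _, _ = n3_recording
        psd = welch_psd(rec.channel("Fz"), rec.fs)
        low = band_power(psd.frequencies, psd.values, 0.5, 2.0)
        high = band_power(psd.frequencies, psd.values, 20.0, 30.0)
        assert low / high >= 10

    def test_zero_amplitudes_give_pure_noise(self):
        hyp = Hypnogram(["N2"] * 15)
        zero = {s: 0.0 for s in ("WAKE", "N1", "N2", "N3", "REM")}
        p = SynthParams(seed=2, so_amp_by_stage=zero, delta_amp_by_stage=zero,
                        spindle_rate=0.0, movement_rate_per_h=0.0)
        rec, truth = generate_eeg(hyp, p)
        assert truth.spindle_events == []
        assert truth.movement_events == []

    def test_rem_eog_anticorrelated_at_deflections(self):
        hyp = Hypnogram(["REM"] * 30)
        p = SynthParams(seed=3, movement_rate_per_h=0.0)
        rec, truth = generate_eeg(hyp, p)
        assert truth.eog_events, "REM night should contain EOG deflections"
        e1, e2 = rec.channel("EOG1"), rec.channel("EOG2")
        fs = rec.fs
        rs = []
        for t0 in truth.eog_events[:20]:
            i0 = int(t0 * fs)
            i1 = i0 + int(1.2 * fs)
            if i1 > e1.size:
                continue
            rs.append(np.corrcoef(e1[i0:i1], e2[i0:i1])[0, 1])
        assert np.median(rs) < 0

    def test_seed_determinism_bit_identical(self):
        hyp = Hypnogram(["N2"] * 10)
        p = SynthParams(seed=9)
        a, _ = generate_eeg(hyp, p)
        b, _ = generate_eeg(hyp, p)
        np.testing.assert_array_equal(a.data, b.data)

    def test_rejects_empty_hypnogram(self):
        with pytest.raises(ValueError):
            generate_eeg(Hypnogram([]), SynthParams())

    def test_stage_conditional_band_ratio(self):
        # configured N3/N2 slow-wave amplitude ratio is reproduced in PSD
        p = SynthParams(seed=4, spindle_rate=0.0, movement_rate_per_h=0.0)
        recs = {}
        for stage in ("N2", "N3"):
            rec, _ = generate_eeg(Hypnogram([stage] * 45), p)
            psd = welch_psd(rec.channel("Fz"), rec.fs)
            recs[stage] = band_power(psd.frequencies, psd.values, 0.5, 2.0)
        want = (p.so_amp_by_stage["N3"] / p.so_amp_by_stage["N2"]) ** 2
        got = recs["N3"] / recs["N2"]
        assert abs(got - want) / want < 0.35  # noise floor adds to N2


class TestInjectResponse:
    def _windows(self):
        return [StimWindow("ISI1_High", 60.0), StimWindow("SHAM", 120.0)]

    def test_zero_gain_is_identity(self, n3_recording):
        rec, _, _ = n3_recording
        p = SynthParams(seed=5, stim_response=StimResponse(peak_gain=0.0))
        out = inject_stim_response(rec, self._windows(), p)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_sham_window_bit_identical(self, n3_recording):
        rec, _, params = n3_recording
        out = inject_stim_response(rec, self._windows(), params)
        fs = rec.fs
        i0, i1 = int(120.0 * fs), int(140.0 * fs)
        np.testing.assert_array_equal(out.channel("Fz")[i0:i1],
                                      rec.channel("Fz")[i0:i1])

    def test_amplitude_ratio_peaks_near_two(self, n3_recording):
        rec, _, _ = n3_recording
        p = SynthParams(
            seed=5, stim_response=StimResponse(peak_gain=1.0, decay_tau=3.0))
        wins = [StimWindow("UP", 60.0 + 40.0 * k) for k in range(20)]
        out = inject_stim_response(rec, wins, p)
        fs = rec.fs
        env_out = analytic_amplitude(
            bandpass_fir(out.channel("Fz"), fs, 0.5, 2.0))
        env_in = analytic_amplitude(
            bandpass_fir(rec.channel("Fz"), fs, 0.5, 2.0))
        ratios = []
        for w in wins:
            i0 = int(w.on_start * fs)
            seg = env_out[i0:i0 + int(3 * fs)] / env_in[i0:i0 + int(3 * fs)]
            ratios.append(seg.max())
        assert abs(np.median(ratios) - 2.0) < 0.35

    def test_window_outside_recording_rejected(self, n3_recording):
        rec, _, params = n3_recording
        with pytest.raises(ValueError):
            inject_stim_response(
                rec, [StimWindow("UP", rec.duration - 5.0)], params)


class TestGenerateRR:
    def test_no_modulation_constant_rr(self):
        p = SynthParams(seed=1, cardiac=CardiacParams(
            rsa_amp=0.0, drift_amp=0.0, jitter_ms=0.0,
            ihr_kernel=IHRKernel(0, 1, 0, 1)))
        rr, _ = generate_rr(120.0, [], p)
        np.testing.assert_allclose(rr.rr_ms, 1000.0, atol=1e-9)

    def test_base_60_bpm_mean_rr(self):
        p = SynthParams(seed=1, cardiac=CardiacParams(
            jitter_ms=0.0, ihr_kernel=IHRKernel(0, 1, 0, 1)))
        rr, _ = generate_rr(300.0, [], p)
        assert abs(np.mean(rr.rr_ms) - 1000.0) < p.cardiac.rsa_amp

    def test_deceleration_lengthens_stim_window_rr(self):
        wins = []
        t = 20.0
        for i in range(40):
            wins.append(StimWindow("UP", t)); t += 27.0
            wins.append(StimWindow("SHAM", t)); t += 27.0
        p = SynthParams(seed=6, cardiac=CardiacParams(
            ihr_kernel=IHRKernel(0.0, 1.0, 30.0, 6.0)))
        rr, _ = generate_rr(t + 20, wins, p)
        def mean_in(w):
            sel = (rr.r_times[1:] >= w.on_start) & \
                  (rr.r_times[1:] < w.on_start + 20)
            return rr.rr_ms[sel].mean()
        stim = np.mean([mean_in(w) for w in wins if w.condition != "SHAM"])
        sham = np.mean([mean_in(w) for w in wins if w.condition == "SHAM"])
        assert stim > sham

    def test_r_peak_round_trip(self):
        # detection on the rendered ECG recovers >= 99% of truth within 10 ms
        p = SynthParams(seed=8)
        rr, ecg = generate_rr(600.0, [], p)
        det = detect_r_peaks_recording(ecg)
        d = np.abs(det.r_times[:, None] - rr.r_times[None, :]).min(axis=0)
        assert (d < 0.010).mean() >= 0.99

    def test_rejects_excessive_kernel(self):
        p = SynthParams(cardiac=CardiacParams(
            base_hr=60.0, ihr_kernel=IHRKernel(accel_ms=980.0)))
        with pytest.raises(ValueError):
            generate_rr(60.0, [StimWindow("UP", 10.0)], p)

    def test_rejects_out_of_range_hr(self):
        with pytest.raises(ValueError):
            generate_rr(60.0, [], SynthParams(
                cardiac=CardiacParams(base_hr=150.0)))


class TestCleanPreset:
    def test_zero_crossings_match_truth(self):
        rec, truth = clean_so_recording(60.0, noise_sd_frac=0.0, seed=0)
        t0 = truth.so_events[10][0]
        i = int(t0 * rec.fs)
        x = rec.channel("Fz")
        assert abs(x[i]) < 1e-6 or x[i + 1] > x[i]  # rising zero crossing

    def test_params_validation(self):
        with pytest.raises(ValueError):
            SynthParams(sampling_rate=30.0)
        with pytest.raises(ValueError):
            SynthParams(spindle_rate=-1.0)
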