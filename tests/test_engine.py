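"""Closed-loop engine: gates, detector, PLL, scheduling, tone planning."""

import itertools

import numpy as np
import pytest

from somnostim.engine import (
    DetectorConfig, band_power_stream, calibrate_beta_threshold,
    default_conditions, delivery_phases, eog_anticorr_gate,
    measure_delivery_phases, movement_gate, plan_tones, render_audio,
    run_closed_loop, run_pll, schedule_windows, sequence_conditions,
    StimWindow,
)
from somnostim.stats import circular_sd_deg, circular_stats
from somnostim.synth import clean_so_recording

CFG = DetectorConfig()
FS = 500.0


class TestBandPower:
    def test_in_band_tone_dominates(self):
        t = np.arange(int(60 * FS)) / FS
        x = 50 * np.sin(2 * np.pi * 3.0 * t)
        _, p_in = band_power_stream(x, FS, (2, 4), CFG)
        _, p_out = band_power_stream(x, FS, (20, 30), CFG)
        assert np.median(p_in) / max(np.median(p_out), 1e-12) > 100

    def test_zero_signal_zero_power(self):
        _, p = band_power_stream(np.zeros(int(30 * FS)), FS, (2, 4), CFG)
        assert np.all(p == 0)

    def test_quadratic_amplitude_scaling(self, rng):
        x = rng.standard_normal(int(30 * FS))
        _, p1 = band_power_stream(x, FS, (2, 4), CFG)
        _, p2 = band_power_stream(2 * x, FS, (2, 4), CFG)
        np.testing.assert_allclose(p2, 4 * p1, rtol=1e-9)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_power_stream(np.zeros(int(10 * FS)), FS, (200, 300), CFG)

    def test_causal(self, rng):
        x = rng.standard_normal(int(30 * FS))
        t, p = band_power_stream(x, FS, (2, 4), CFG)
        y = x.copy()
        y[int(20 * FS):] += 100.0
        _, q = band_power_stream(y, FS, (2, 4), CFG)
        early = t <= 20.0 - 1e-9
        np.testing.assert_array_equal(p[early], q[early])


class TestBetaThreshold:
    def test_constant_series(self):
        assert calibrate_beta_threshold(np.full(100, 3.0), CFG) == 3.0

    def test_mean_plus_two_sd(self, rng):
        beta = rng.uniform(1, 100, size=500)
        want = beta.mean() + 2 * beta.std()
        assert calibrate_beta_threshold(beta, CFG) == pytest.approx(want)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            calibrate_beta_threshold(np.empty(0), CFG)


class TestEOGGate:
    def test_perfect_anticorrelation_closes(self, rng):
        x = rng.standard_normal(int(30 * FS))
        _, r, open_ = eog_anticorr_gate(x, -x, FS, CFG)
        assert np.allclose(r, -1)
        assert not open_.any()

    def test_perfect_correlation_open(self, rng):
        x = rng.standard_normal(int(30 * FS))
        _, r, open_ = eog_anticorr_gate(x, x, FS, CFG)
        assert np.allclose(r, 1)
        assert open_.all()

    def test_independent_noise_mostly_open(self, rng):
        a = rng.standard_normal(int(120 * FS))
        b = rng.standard_normal(int(120 * FS))
        _, r, open_ = eog_anticorr_gate(a, b, FS, CFG)
        assert open_.mean() >= 0.95

    def test_constant_segment_counts_open(self):
        z = np.zeros(int(10 * FS))
        _, r, open_ = eog_anticorr_gate(z, z, FS, CFG)
        assert np.all(r == 0)
        assert open_.all()


class TestMovementGate:
    def test_spike_closes_for_ten_seconds(self):
        x = np.zeros(int(150 * FS))
        x[int(100 * FS)] = 500.0
        t, open_ = movement_gate(x, FS, CFG)
        closed = t[~open_]
        assert closed.min() == pytest.approx(100.5, abs=CFG.update_step)
        assert closed.max() == pytest.approx(110.0, abs=CFG.update_step)

    def test_quiet_signal_always_open(self):
        _, open_ = movement_gate(np.full(int(60 * FS), 100.0), FS, CFG)
        assert open_.all()

    def test_second_spike_extends_holdoff(self):
        x = np.zeros(int(150 * FS))
        x[int(100 * FS)] = 500.0
        x[int(105 * FS)] = 500.0
        t, open_ = movement_gate(x, FS, CFG)
        closed = t[~open_]
        assert closed.max() == pytest.approx(115.0, abs=CFG.update_step)


class TestPLL:
    def test_clean_sine_hits_up_target(self):
        rec, _ = clean_so_recording(240.0, seed=1)
        ph = measure_delivery_phases(rec, 50.0)
        mean, _ = circular_stats(ph)
        assert abs((mean - 50.0 + 180) % 360 - 180) < 10
        assert circular_sd_deg(ph) < 20

    def test_off_frequency_still_locks_tightly(self):
        rec, _ = clean_so_recording(240.0, so_freq=0.8, seed=2)
        ph = measure_delivery_phases(rec, 50.0)
        assert circular_sd_deg(ph) < 20  # static offset allowed, jitter not

    def test_zero_input_never_locks(self):
        pll = run_pll(np.zeros(int(60 * FS)), FS)
        assert not pll.locked.any()
        assert all(len(v) == 0 for v in pll.triggers.values())

    def test_causality_of_triggers(self):
        rec, _ = clean_so_recording(120.0, seed=3)
        pll_a = run_pll(rec)
        x = rec.data[0].copy()
        x[int(90 * rec.fs):] = 0.0
        pll_b = run_pll(x, rec.fs)
        for tg in (50.0, 230.0):
            a = pll_a.triggers[tg]
            b = pll_b.triggers[tg]
            early_a = a[a < 85.0]
            early_b = b[b < 85.0]
            np.testing.assert_allclose(early_a, early_b)


class TestSequencer:
    def test_every_block_is_a_permutation(self):
        conds = ["A", "B", "C", "D", "E", "F"]
        seq = sequence_conditions(conds, seed=4)
        draws = list(itertools.islice(seq, 60))
        for i in range(0, 60, 6):
            assert sorted(draws[i:i + 6]) == sorted(conds)

    def test_single_condition_constant(self):
        seq = sequence_conditions(["X"], seed=0)
        assert list(itertools.islice(seq, 5)) == ["X"] * 5

    def test_seeded_determinism(self):
        a = list(itertools.islice(sequence_conditions(list("ABC"), 7), 30))
        b = list(itertools.islice(sequence_conditions(list("ABC"), 7), 30))
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            next(sequence_conditions([], 0))


class TestPlanTones:
    def test_isi1_mod_volume_ramp(self):
        spec = default_conditions()["ISI1_Mod"]
        w = StimWindow("ISI1_Mod", 100.0)
        tones = plan_tones(w, spec)
        assert [t.volume_db for t in tones] == [
            40.0, 40.0, 42.5, 42.5, 45.0, 45.0, 45.0, 45.0, 42.5, 42.5]
        assert [t.onset for t in tones] == [100.0 + i for i in range(10)]

    def test_isi1_high_one_hz_rhythm(self):
        spec = default_conditions()["ISI1_High"]
        tones = plan_tones(StimWindow("ISI1_High", 50.0), spec)
        assert len(tones) == 10
        np.testing.assert_allclose(np.diff([t.onset for t in tones]), 1.0)
        assert all(t.volume_db == 45.0 for t in tones)
        assert all(t.onset + t.duration <= 60.0 for t in tones)

    def test_sham_has_no_tones(self):
        spec = default_conditions()["SHAM"]
        assert plan_tones(StimWindow("SHAM", 0.0), spec) == []

    def test_up_tone_per_trigger(self):
        rec, _ = clean_so_recording(120.0, seed=5)
        pll = run_pll(rec)
        spec = default_conditions()["UP"]
        w = StimWindow("UP", 60.0)
        tones = plan_tones(w, spec, pll)
        trig = pll.triggers[50.0]
        n_in = ((trig >= 60.0) & (trig < 70.0 - 0.05)).sum()
        assert len(tones) == n_in
        assert all(60.0 <= t.onset and t.onset + t.duration <= 70.0
                   for t in tones)


class TestRenderAudio:
    def test_binaural_spectral_peaks(self):
        from somnostim.engine import ToneEvent
        tone = ToneEvent(0.0, 10.0, 45.0,
                         {"kind": "binaural", "carrier_hz": 400.0,
                          "beat_hz": 1.0})
        wav = render_audio([tone], 10.0, audio_rate=8000.0)
        freqs = np.fft.rfftfreq(wav.shape[1], 1 / 8000.0)
        for ch, want in ((0, 400.0), (1, 401.0)):
            spec = np.abs(np.fft.rfft(wav[ch]))
            assert abs(freqs[np.argmax(spec)] - want) < 0.2

    def test_empty_plan_is_silence(self):
        wav = render_audio([], 2.0, audio_rate=8000.0)
        assert np.all(wav == 0)

    def test_pink_noise_slope(self):
        from somnostim.engine import ToneEvent
        tone = ToneEvent(0.0, 10.0, 45.0, {"kind": "pink_burst"})
        wav = render_audio([tone], 10.0, audio_rate=8000.0, seed=2)
        from scipy.signal import welch
        f, p = welch(wav[0], fs=8000.0, nperseg=4096)
        sel = (f >= 100) & (f <= 2000)
        slope = np.polyfit(np.log2(f[sel]), 10 * np.log10(p[sel]), 1)[0]
        assert abs(slope - (-3.0)) < 1.0  # dB per octave

    def test_volume_mapping(self):
        from somnostim.engine import db_to_amp
        assert db_to_amp(45.0) == 1.0
        assert db_to_amp(39.0) == pytest.approx(10 ** (-6 / 20))


class TestSchedulerProperties:
    def test_windows_non_overlapping_and_balanced(self, n3_recording):
        rec, _, _ = n3_recording
        result = run_closed_loop(rec, seed=11)
        w = result.windows
        assert len(w) >= 6
        starts = [x.on_start for x in w]
        assert all(b - a >= 20.0 - 1e-9
                   for a, b in zip(starts, starts[1:]))
        counts = {}
        for x in w:
            counts[x.condition] = counts.get(x.condition, 0) + 1
        assert max(counts.values()) - min(counts.values()) <= 1
        for x in w:
            if x.condition == "SHAM":
                assert x.tones == []
            for tone in x.tones:
                assert x.on_start <= tone.onset
                assert tone.onset + tone.duration <= x.on_end + 1e-9

    def test_never_eligible_empty_schedule(self):
        rec, _ = clean_so_recording(120.0, seed=1)
        from somnostim.engine import nrem_state_machine
        det = nrem_state_machine(rec, CFG)  # 2 min < 10 min rule
        pll = run_pll(rec)
        seq = sequence_conditions(["UP"], 0)
        assert schedule_windows(det, pll, seq) == []
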