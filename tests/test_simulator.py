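"""Simulator contracts: template construction, onset trains, channel
projection, noise spectra, exact SNR calibration and case composition."""

import numpy as np
import pytest
from scipy import signal as sps

from fecgdenoise.simulator import (SimulationCase, build_dataset,
                                   generate_beat_template, generate_noise,
                                   generate_rate_profile, mix_at_snr,
                                   simulate_case, snr_in, synthesize_channels)


class TestBeatTemplate:
    def test_deterministic_per_seed(self):
        a = generate_beat_template("fetal", seed=1)
        b = generate_beat_template("fetal", seed=1)
        assert a == b
        assert a != generate_beat_template("fetal", seed=2)

    def test_ectopic_qrs_wider_and_taller(self):
        fetal = generate_beat_template("fetal", seed=1)
        ectopic = generate_beat_template("ectopic", seed=1)
        assert ectopic.qrs_width >= 1.5 * fetal.qrs_width
        assert abs(ectopic.waves[2][0]) > abs(fetal.waves[2][0])

    def test_r_wave_dominates(self):
        for preset in ("fetal", "maternal", "ectopic"):
            tpl = generate_beat_template(preset, seed=3)
            amps = [abs(w[0]) for w in tpl.waves]
            assert max(amps) == abs(tpl.waves[2][0])
            assert all(w[2] > 0 for w in tpl.waves)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            generate_beat_template("adult2", seed=1)


class TestRateProfile:
    def test_onset_count_tracks_rate(self):
        case = SimulationCase(case_id="baseline", duration_s=60.0, seed=5)
        prof = generate_rate_profile(case)
        mean_rr = np.mean(np.diff(prof.times))
        expected = 60.0 / mean_rr
        assert abs(len(prof) - expected) <= 3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_onsets_strictly_increasing(self, seed):
        case = SimulationCase(case_id="case4", duration_s=120.0, seed=seed)
        prof = generate_rate_profile(case)
        assert np.all(np.diff(prof.times) > 0)

    def test_rate_within_physiological_band(self):
        case = SimulationCase(case_id="baseline", duration_s=60.0, seed=9)
        prof = generate_rate_profile(case)
        bpm = 60.0 / np.median(np.diff(prof.times))
        assert 100.0 <= bpm <= 170.0

    def test_case2_acceleration_ramp(self):
        case = SimulationCase(case_id="case2", duration_s=300.0, seed=2)
        prof = generate_rate_profile(case)
        inst_bpm = 60.0 / np.diff(prof.times)
        # smooth out RR jitter before measuring the ramp amplitude
        smooth = np.convolve(inst_bpm, np.ones(9) / 9, mode="valid")
        assert smooth.max() - smooth.min() >= 15.0

    def test_case4_flags_ectopic_beats(self):
        case = SimulationCase(case_id="case4", duration_s=300.0, seed=2)
        prof = generate_rate_profile(case)
        frac = prof.ectopic.mean()
        assert 0.01 <= frac <= 0.12
        # the premature beats arrive on a shortened coupling interval
        rr = np.diff(prof.times)
        ect_idx = np.flatnonzero(prof.ectopic)
        ect_idx = ect_idx[(ect_idx > 0) & (ect_idx < len(rr))]
        assert np.mean(rr[ect_idx - 1]) < np.mean(rr)


class TestSynthesizeChannels:
    def test_single_beat_lands_at_its_onset(self):
        tpl = generate_beat_template("fetal", seed=1)
        fs = 250.0
        out = synthesize_channels(tpl, np.array([1.0, 1.8]), 4, "none", fs, 1)
        peak = np.argmax(np.abs(out[0, :int(1.4 * fs)]))
        assert abs(peak - fs * 1.0) <= 3

    def test_constant_gain_without_movement(self):
        tpl = generate_beat_template("fetal", seed=1)
        onsets = np.arange(0.5, 59.5, 0.45)
        out = synthesize_channels(tpl, onsets, 4, "none", 250.0, 1)
        first = np.max(np.abs(out[:, :250]))
        last = np.max(np.abs(out[:, -500:]))
        assert first == pytest.approx(last, rel=1e-6)

    def test_drift_modulates_amplitude(self):
        tpl = generate_beat_template("fetal", seed=1)
        onsets = np.arange(0.5, 59.5, 0.45)
        out = synthesize_channels(tpl, onsets, 4, "drift", 250.0, 1)
        first = np.max(np.abs(out[:, :250]), axis=-1)
        last = np.max(np.abs(out[:, -500:]), axis=-1)
        assert np.any(np.abs(first / last - 1.0) > 0.05)

    def test_empty_onsets_yield_silence(self):
        tpl = generate_beat_template("fetal", seed=1)
        out = synthesize_channels(tpl, np.array([]), 4, "none", 250.0, 1)
        assert np.all(out == 0)


class TestNoise:
    def test_white_noise_is_centered(self):
        x = generate_noise("white", 60.0, 250.0, seed=4)
        se = x.std(axis=-1) / np.sqrt(x.shape[-1])
        assert np.all(np.abs(x.mean(axis=-1)) <= 4 * se + 1e-12)

    def test_baseline_wander_below_1hz(self):
        x = generate_noise("baseline_wander", 120.0, 250.0, seed=4)
        f, p = sps.periodogram(x[0], fs=250.0)
        assert p[f < 1.0].sum() / p.sum() >= 0.95

    def test_emg_burst_concentrates_energy(self):
        x = generate_noise("emg_burst", 120.0, 250.0, seed=4)
        blocks = x[0][: (x.shape[-1] // 20) * 20].reshape(20, -1)
        v = blocks.var(axis=-1)
        assert v.max() >= 5.0 * np.median(v)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            generate_noise("pink", 10.0, 250.0, seed=1)


class TestMixAtSnr:
    def test_zero_db_equalizes_energy(self, rng):
        clean = rng.standard_normal((4, 1000))
        noise = rng.standard_normal((4, 1000))
        mixed = mix_at_snr(clean, noise, 0.0)
        added = mixed - clean
        assert np.allclose(np.sum(added ** 2, axis=-1),
                           np.sum(clean ** 2, axis=-1), rtol=1e-10)

    def test_minus_20_db_means_100x_noise(self, rng):
        clean = rng.standard_normal((4, 1000))
        noise = rng.standard_normal((4, 1000))
        mixed = mix_at_snr(clean, noise, -20.0)
        added = mixed - clean
        assert np.allclose(np.sum(added ** 2, axis=-1),
                           100.0 * np.sum(clean ** 2, axis=-1), rtol=1e-10)

    @pytest.mark.parametrize("snr_db", [-30, -20, -12, -6, 0, 6, 12])
    def test_roundtrip_recovers_requested_snr(self, snr_db, rng):
        clean = rng.standard_normal((4, 2000))
        noise = rng.standard_normal((4, 2000))
        mixed = mix_at_snr(clean, noise, snr_db)
        assert np.allclose(snr_in(clean, mixed), snr_db, atol=1e-6)

    def test_zero_energy_channel_rejected(self, rng):
        clean = rng.standard_normal((4, 100))
        clean[2] = 0.0
        with pytest.raises(ValueError, match="zero-energy"):
            mix_at_snr(clean, np.ones((4, 100)), 0.0)


class TestSimulateCase:
    def test_seeded_determinism_bitwise(self):
        case = SimulationCase(case_id="case0", snr_db=-6, duration_s=30, seed=3)
        a = simulate_case(case)
        b = simulate_case(case)
        assert np.array_equal(a.clean, b.clean)
        assert np.array_equal(a.noisy, b.noisy)

    def test_snr_calibration_per_channel(self):
        case = SimulationCase(case_id="case0", snr_db=-6, duration_s=30, seed=3)
        rec = simulate_case(case)
        assert np.allclose(snr_in(rec.clean, rec.noisy), -6.0, atol=1e-6)

    def test_baseline_interference_is_maternal_residue(self):
        """Without added noise kinds, the interference energy clusters
        around the maternal beats; with white noise (case0) it spreads."""

        def peak_energy_fraction(rec):
            interference = rec.noisy - rec.clean
            half = int(0.12 * rec.fs)
            mask = np.zeros(interference.shape[-1], dtype=bool)
            for p in rec.maternal_peaks:
                mask[max(p - half, 0):p + half] = True
            total = np.sum(interference ** 2)
            return np.sum(interference[:, mask] ** 2) / total

        base = simulate_case(SimulationCase("baseline", snr_db=0,
                                            duration_s=60, seed=3))
        noisy = simulate_case(SimulationCase("case0", snr_db=0,
                                             duration_s=60, seed=3))
        assert peak_energy_fraction(base) > 0.7
        assert peak_energy_fraction(base) > peak_energy_fraction(noisy)

    def test_case3_burst_raises_short_window_variance(self):
        base = simulate_case(SimulationCase("baseline", snr_db=0,
                                            duration_s=120, seed=5))
        burst = simulate_case(SimulationCase("case3", snr_db=0,
                                             duration_s=120, seed=5))

        def max_block_var_ratio(rec):
            x = rec.noisy - rec.clean
            blocks = x[0][: (x.shape[-1] // 24) * 24].reshape(24, -1)
            v = blocks.var(axis=-1)
            return v.max() / np.median(v)

        assert max_block_var_ratio(burst) > max_block_var_ratio(base)

    def test_record_geometry(self, short_record):
        n = int(60 * 250)
        assert short_record.clean.shape == (4, n)
        assert short_record.noisy.shape == (4, n)
        assert np.all(np.isfinite(short_record.noisy))
        assert short_record.fetal_peaks.max() < n

    def test_invalid_case_id(self):
        with pytest.raises(ValueError, match="case_id"):
            SimulationCase(case_id="case9")


class TestBuildDataset:
    def test_cases_times_repeats(self):
        cases = [SimulationCase(c, snr_db=0, duration_s=10, seed=1)
                 for c in ("baseline", "case0", "case1", "case2", "case3")]
        records = build_dataset(cases, repeats=5)
        assert len(records) == 25

    def test_single_repeat_preserves_order_and_seed(self):
        cases = [SimulationCase("case0", snr_db=0, duration_s=10, seed=1),
                 SimulationCase("case1", snr_db=0, duration_s=10, seed=2)]
        records = build_dataset(cases, repeats=1)
        assert [r.case.case_id for r in records] == ["case0", "case1"]
        direct = simulate_case(cases[0])
        assert np.array_equal(records[0].noisy, direct.noisy)

    def test_repeats_use_distinct_seeds(self):
        case = SimulationCase("case0", snr_db=0, duration_s=10, seed=1)
        records = build_dataset([case], repeats=2)
        assert not np.array_equal(records[0].noisy, records[1].noisy)

    def test_repeats_must_be_positive(self):
        with pytest.raises(ValueError, match="repeats"):
            build_dataset([], repeats=0)
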