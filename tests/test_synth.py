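"""Synthetic cohorts and recordings: known ground truth is recovered."""

import numpy as np
import pytest

from abrffr import ffr
from abrffr.pipeline import ABRConfig, FFRConfig, env_group_delay, measure_abr, measure_ffr
from abrffr.synth import (
    COVARIATES,
    GroundTruth,
    noise_rms_for_component_snr,
    sample_cohort,
    simulate_abr_recording,
    simulate_ffr_recording,
)

SUBJECT = {"subject": "S0", "age": 46.0, "sex": "F", "pta_0p5_2": 0.0}


class TestCohort:
    def test_default_correlations_recovered(self):
        df = sample_cohort(10000, seed=42)
        assert np.corrcoef(df.age, df.pta_4_12)[0, 1] == pytest.approx(
            0.84, abs=0.03
        )
        assert np.corrcoef(df.age, df.pta_0p5_2)[0, 1] == pytest.approx(
            0.37, abs=0.03
        )
        assert np.corrcoef(df.pta_0p5_2, df.pta_4_12)[0, 1] == pytest.approx(
            0.49, abs=0.03
        )

    def test_identity_config_uncorrelated(self):
        df = sample_cohort(10000, correlation=np.eye(5), seed=7)
        for i in range(5):
            for j in range(i + 1, 5):
                r = np.corrcoef(df[COVARIATES[i]], df[COVARIATES[j]])[0, 1]
                assert abs(r) < 0.05

    def test_deterministic_under_seed(self):
        a = sample_cohort(50, seed=3)
        b = sample_cohort(50, seed=3)
        assert a.equals(b)

    def test_non_positive_definite_rejected(self):
        bad = np.eye(5)
        bad[0, 1] = bad[1, 0] = 1.5
        with pytest.raises(ValueError, match="positive definite"):
            sample_cohort(100, correlation=bad, seed=0)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            sample_cohort(1, seed=0)

    def test_marginal_ranges_respect_inclusion_bounds(self):
        df = sample_cohort(5000, seed=1)
        assert df.age.between(18, 73).all()
        assert (df.pta_0p5_2 <= 30.5).all()
        assert set(df.age_group.unique()) == {"young", "middle", "older"}


class TestAbrSimulation:
    def test_noiseless_amplitudes_recovered_exactly(self):
        truth = GroundTruth(noise_rms_v=0.0)
        rec = simulate_abr_recording(
            SUBJECT, {"level": 105, "masking": "quiet"}, truth,
            n_sweeps=8, seed=1, subject_effect=0.0,
        )
        res = measure_abr(rec.recording, 105, ABRConfig(filter_band=None))
        fs = rec.recording.sampling_rate
        for wave in ("I", "V"):
            m = res["measurements"][wave]
            assert m.detected
            assert m.amplitude_nv == pytest.approx(
                rec.manifest["amplitudes_nv"][wave], rel=0.01
            )
            assert m.latency_ms == pytest.approx(
                rec.manifest["latencies_ms"][wave], abs=1e3 / fs
            )

    def test_below_floor_amplitude_censored(self):
        # tiny wave, realistic background noise -> undetected nearly always
        truth = GroundTruth(
            wave_amp_nv={"I": 0.2, "V": 0.5}, noise_rms_v=1e-6
        )
        censored = 0
        n_rep = 100
        for rep in range(n_rep):
            rec = simulate_abr_recording(
                SUBJECT, {"level": 105, "masking": "quiet"}, truth,
                n_sweeps=30, seed=rep, subject_effect=0.0,
            )
            res = measure_abr(rec.recording, 105, ABRConfig(filter_band=None))
            censored += not res["measurements"]["I"].detected
        assert censored >= 0.9 * n_rep

    def test_censoring_monotone_in_true_amplitude(self):
        truth_base = dict(noise_rms_v=1e-6)
        detect_rate = []
        for amp in (5.0, 80.0, 1200.0):
            truth = GroundTruth(
                wave_amp_nv={"I": amp, "V": amp}, **truth_base
            )
            det = 0
            for rep in range(20):
                rec = simulate_abr_recording(
                    SUBJECT, {"level": 105, "masking": "quiet"}, truth,
                    n_sweeps=40, seed=1000 + rep, subject_effect=0.0,
                )
                res = measure_abr(
                    rec.recording, 105, ABRConfig(filter_band=None)
                )
                det += res["measurements"]["I"].detected
            detect_rate.append(det)
        assert detect_rate[0] <= detect_rate[1] <= detect_rate[2]
        assert detect_rate[2] == 20

    def test_trigger_count_and_ear_alternation(self):
        truth = GroundTruth(noise_rms_v=0.0)
        rec = simulate_abr_recording(
            SUBJECT, {"level": 80, "masking": "hp"}, truth,
            n_sweeps=10, seed=0,
        ).recording
        assert len(rec.triggers) == 10
        ears = [c.split("/")[1] for _, c in rec.triggers]
        assert ears == ["L", "R"] * 5

    def test_invalid_condition_rejected(self):
        truth = GroundTruth()
        with pytest.raises(ValueError):
            simulate_abr_recording(
                SUBJECT, {"level": 90, "masking": "quiet"}, truth, 4, 0
            )


class TestFfrSimulation:
    CONFIG = {"low_mf": 93.3, "high_mf": 111.1}

    def test_odd_sweep_count_rejected(self):
        with pytest.raises(ValueError, match="even"):
            simulate_ffr_recording(SUBJECT, self.CONFIG, GroundTruth(), 5, 0)

    def test_polarity_algebra_exact_noiseless(self):
        truth = GroundTruth(noise_rms_v=0.0)
        rec = simulate_ffr_recording(
            SUBJECT, self.CONFIG, truth, n_sweeps=4, seed=0,
            sampling_rate=4096.0,
        )
        res = measure_ffr(
            rec.recording, "LCF_MF1/HCF_MF3", FFRConfig(filter_band=None)
        )
        add, sub = res["addition"].waveform, res["subtraction"].waveform
        # TFS energy absent from addition, ENV absent from subtraction
        fs = 4096.0
        t0 = res["addition"].times[0]
        for f in (600 - 93.3, 600.0, 600 + 93.3):
            c = ffr.component_snr(add, fs, f, t0=t0)
            assert c.signal_power < 1e-6 * max(
                ffr.component_snr(sub, fs, f, t0=t0).signal_power, 1e-300
            )
        env_add = ffr.component_snr(add, fs, 93.3, t0=t0).signal_power
        env_sub = ffr.component_snr(sub, fs, 93.3, t0=t0).signal_power
        assert env_sub < 1e-6 * env_add

    def test_noiseless_group_delay_recovered(self):
        truth = GroundTruth(noise_rms_v=0.0, tau_ms=14.0)
        comps = []
        for sc, (li, hi) in ffr.STIMULUS_CONFIGS.items():
            rec = simulate_ffr_recording(
                SUBJECT,
                {"low_mf": ffr.MODULATION_FREQS[li],
                 "high_mf": ffr.MODULATION_FREQS[hi]},
                truth, n_sweeps=4, seed=0, sampling_rate=4096.0,
            )
            res = measure_ffr(rec.recording, sc, FFRConfig(filter_band=None))
            comps += res["components"]
        est = env_group_delay(comps, 600.0)
        assert est is not None and est.accepted
        # one FFT-bin tolerance on the phase-derived latency
        assert est.latency_ms == pytest.approx(14.0, abs=0.3)

    def test_component_snr_calibration(self):
        """Injected noise calibrated for 20 dB is measured as ~20 dB."""
        target = 20.0
        amp_nv = 40.0
        n_sweeps = 8
        fs = 4096.0
        rms = noise_rms_for_component_snr(
            target, amp_nv * 1e-9, 102.2, n_sweeps, fs
        )
        truth = GroundTruth(
            noise_rms_v=rms, noise_pink_fraction=0.0, env_amp_nv=amp_nv
        )
        config = {"low_mf": 102.2, "high_mf": 120.0,
                  "high_env_amp_nv": 0.0, "tfs_amp_nv": 0.0}
        snrs = []
        for rep in range(50):
            rec = simulate_ffr_recording(
                SUBJECT, config, truth, n_sweeps=n_sweeps, seed=rep,
                sampling_rate=fs,
            )
            res = measure_ffr(
                rec.recording, "LCF_MF2/HCF_MF4", FFRConfig(filter_band=None)
            )
            c = next(
                c for c in res["components"]
                if c.kind == "ENV" and c.mf == 102.2
            )
            snrs.append(c.snr_db)
        assert np.mean(snrs) == pytest.approx(target, abs=2.0)

    def test_deterministic_under_seed(self):
        truth = GroundTruth()
        a = simulate_ffr_recording(SUBJECT, self.CONFIG, truth, 4, 9,
                                   sampling_rate=4096.0)
        b = simulate_ffr_recording(SUBJECT, self.CONFIG, truth, 4, 9,
                                   sampling_rate=4096.0)
        np.testing.assert_array_equal(
            a.recording.channels["HF-C7"], b.recording.channels["HF-C7"]
        )
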