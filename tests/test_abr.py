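"""Wave I/V peak measurement, noise floor, and the censored table."""

import numpy as np
import pandas as pd
import pytest

from abrffr import abr
from abrffr.synth import biphasic_wave
from tests.conftest import make_response

FS = 16384.0


def biphasic_response(amp_nv, latency_ms, width_ms=0.3, t0=-0.003,
                      noise_variance=0.0, dur=0.015):
    n = int(round(dur * FS))
    t = t0 + np.arange(n) / FS
    wave = biphasic_wave(t, latency_ms * 1e-3, width_ms * 1e-3, amp_nv * 1e-9)
    return make_response(wave, FS, t0=t0, noise_variance=noise_variance)


class TestAverageEars:
    def test_identical_inputs(self):
        r = biphasic_response(150, 1.8)
        out = abr.average_ears(r, r)
        np.testing.assert_allclose(out.waveform, r.waveform)
        assert out.n_epochs == 2 * r.n_epochs

    def test_opposite_inputs_cancel(self):
        r = biphasic_response(150, 1.8)
        neg = make_response(-r.waveform, FS, t0=r.times[0])
        out = abr.average_ears(r, neg)
        np.testing.assert_allclose(out.waveform, 0.0, atol=1e-20)

    def test_known_amplitudes_average(self):
        a = biphasic_response(100, 1.8)
        b = biphasic_response(140, 1.8)
        out = abr.average_ears(a, b)
        m = abr.pick_wave(out, "I", (1.0, 3.5))
        assert m.detected
        assert m.amplitude_nv == pytest.approx(120, rel=0.02)


class TestPickWave:
    def test_constructed_deflection_recovered(self):
        r = biphasic_response(150, 1.8)
        m = abr.pick_wave(r, "I", (1.0, 3.5))
        assert m.detected
        assert m.amplitude_nv == pytest.approx(150, rel=0.01)
        # the biphasic shape's max sits slightly before the nominal center
        true_peak = r.times[np.argmax(r.waveform)] * 1e3
        assert m.latency_ms == pytest.approx(true_peak, abs=1e3 / FS)

    def test_flat_response_undetected(self):
        r = make_response(np.zeros(246), FS, t0=-0.003)
        m = abr.pick_wave(r, "I", (1.0, 3.5))
        assert not m.detected
        assert m.amplitude_nv is None

    def test_equal_peaks_earlier_latency_wins(self):
        n = int(0.015 * FS)
        t = -0.003 + np.arange(n) / FS
        x = np.zeros(n)
        # sample-aligned latencies give an exact height tie
        lats = [(74 / FS) - 0.003, (90 / FS) - 0.003]
        for lat in lats:
            x += np.where(
                np.abs(t - lat) < 2.5e-4,
                np.cos(np.pi * (t - lat) / 5e-4) ** 2,
                0.0,
            )
        r = make_response(x * 1e-7, FS, t0=-0.003)
        m = abr.pick_wave(r, "I", (1.0, 3.5))
        assert m.detected
        assert m.latency_ms == pytest.approx(lats[0] * 1e3, abs=1e3 / FS)

    def test_offset_invariance(self):
        r = biphasic_response(150, 1.8)
        shifted = make_response(r.waveform + 5e-8, FS, t0=r.times[0])
        a = abr.pick_wave(r, "I", (1.0, 3.5))
        b = abr.pick_wave(shifted, "I", (1.0, 3.5))
        assert b.amplitude_nv == pytest.approx(a.amplitude_nv, rel=1e-9)

    def test_time_shift_equivariance(self):
        a = abr.pick_wave(biphasic_response(150, 1.8), "I", (1.0, 3.5))
        b = abr.pick_wave(biphasic_response(150, 2.3), "I", (1.0, 3.5))
        assert b.latency_ms - a.latency_ms == pytest.approx(0.5, abs=1e3 / FS)

    def test_window_outside_epoch_rejected(self):
        r = biphasic_response(150, 1.8)
        with pytest.raises(ValueError, match="outside epoch"):
            abr.pick_wave(r, "V", (4.5, 20.0))

    def test_noise_suppresses_detection(self):
        # amplitude below the residual-noise SD -> undetected
        r = biphasic_response(10, 1.8, noise_variance=(50e-9) ** 2)
        m = abr.pick_wave(r, "I", (1.0, 3.5))
        assert not m.detected


class TestNoiseFloor:
    def test_all_zero_responses_unmeasurable(self):
        rs = [make_response(np.zeros(246), FS, t0=-0.003) for _ in range(5)]
        nf = abr.estimate_noise_floor(rs, (-3.0, 0.0))
        assert nf.fraction_unmeasurable == 1.0
        assert np.isnan(nf.geometric_mean_nv)

    def test_monotone_in_noise_rms(self, rng):
        gms = []
        for rms in (20e-9, 60e-9, 180e-9):
            rs = [
                make_response(
                    rng.normal(0, rms, 246), FS, t0=-0.015 + 0.012
                )
                for _ in range(40)
            ]
            # baseline-only responses spanning (-3, 0) ms
            rs = [
                make_response(rng.normal(0, rms, 100), FS, t0=-0.003)
                for _ in range(40)
            ]
            nf = abr.estimate_noise_floor(rs, (-3.0, -0.5))
            gms.append(nf.geometric_mean_nv)
        assert gms[0] < gms[1] < gms[2]

    def test_lognormal_amplitudes_recovered(self, rng):
        # inject dummy deflections with log-normal peak-trough amplitudes
        amps = np.exp(rng.normal(np.log(42.0), np.log(1.9), 200))
        rs = []
        for a in amps:
            n = 100
            t = -0.003 + np.arange(n) / FS
            x = biphasic_wave(t, -2.0e-3, 0.25e-3, a * 1e-9)
            rs.append(make_response(x, FS, t0=-0.003))
        nf = abr.estimate_noise_floor(rs, (-3.0, -0.5))
        assert nf.geometric_mean_nv == pytest.approx(
            np.exp(np.mean(np.log(amps))), rel=0.05
        )
        assert nf.fraction_unmeasurable == 0.0

    def test_post_stimulus_baseline_rejected(self):
        rs = [make_response(np.zeros(246), FS, t0=-0.003)]
        with pytest.raises(ValueError, match="precede"):
            abr.estimate_noise_floor(rs, (-1.0, 2.0))


class TestMeasurementTable:
    @staticmethod
    def row(subject, amp, detected=True, wave="I"):
        m = abr.PeakMeasurement(
            wave, amp if detected else None,
            1.8 if detected else None, detected,
        )
        return {
            "subject": subject, "level": 105, "masking": "quiet",
            "montage": "HF-ITPR", "measurement": m,
        }

    def test_bound_is_min_detected(self):
        rows = [
            self.row("a", 0.38), self.row("b", 10.0),
            self.row("c", None, detected=False),
        ]
        table = abr.assemble_measurement_table(rows)
        cens = table[table["censored"]]
        assert len(cens) == 1
        assert cens["amplitude_nv"].iloc[0] == pytest.approx(0.38)
        assert np.allclose(table["censor_bound_nv"], 0.38)

    def test_no_censored_rows(self):
        table = abr.assemble_measurement_table(
            [self.row("a", 1.0), self.row("b", 2.0)]
        )
        assert not table["censored"].any()

    def test_bound_moves_with_minimum(self):
        rows = [self.row("a", 0.5), self.row("b", 0.9),
                self.row("c", None, detected=False)]
        t1 = abr.assemble_measurement_table(rows)
        t2 = abr.assemble_measurement_table(rows[1:])
        assert t1["censor_bound_nv"].iloc[0] == pytest.approx(0.5)
        assert t2["censor_bound_nv"].iloc[0] == pytest.approx(0.9)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="bound"):
            abr.assemble_measurement_table(
                [self.row("a", None, detected=False)]
            )

    def test_covariates_joined(self):
        cohort = pd.DataFrame(
            {"subject": ["a", "b"], "age": [25.0, 60.0]}
        )
        table = abr.assemble_measurement_table(
            [self.row("a", 1.0), self.row("b", 2.0)], cohort
        )
        assert list(table["age"]) == [25.0, 60.0]
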