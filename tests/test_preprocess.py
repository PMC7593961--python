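"""Continuous-recording operations: triggers, filtering, epoching, averaging."""

import numpy as np
import pytest

from abrffr.preprocess import (
    Recording,
    compensate_trigger_delay,
    epoch,
    fir_bandpass,
    iterative_weighted_average,
)


def make_recording(x, fs, triggers):
    return Recording(channels={"HF": np.asarray(x, float)}, sampling_rate=fs,
                     triggers=triggers)


class TestTriggerDelay:
    def test_shift_and_inverse(self):
        rec = make_recording(np.zeros(100), 100.0, [(0.2, "a"), (1.0, "b")])
        shifted = compensate_trigger_delay(rec, 0.0009)
        assert shifted.triggers[1][0] == pytest.approx(1.0009)
        np.testing.assert_array_equal(
            shifted.channels["HF"], rec.channels["HF"]
        )
        back = [
            (t - 0.0009, c) for t, c in shifted.triggers
        ]
        assert back == pytest.approx([(0.2, "a"), (1.0, "b")]) or all(
            bt == pytest.approx(ot) for (bt, _), (ot, _) in zip(back, rec.triggers)
        )

    def test_zero_delay_identity(self):
        rec = make_recording(np.zeros(10), 10.0, [(0.2, "a")])
        assert compensate_trigger_delay(rec, 0.0).triggers == rec.triggers

    def test_negative_rejected(self):
        rec = make_recording(np.zeros(10), 10.0, [])
        with pytest.raises(ValueError):
            compensate_trigger_delay(rec, -1e-3)


class TestFirBandpass:
    fs = 16384.0

    def _tone(self, freq, dur=1.0, phase=0.0):
        t = np.arange(int(self.fs * dur)) / self.fs
        return np.sin(2 * np.pi * freq * t + phase), t

    def test_passband_amplitude_and_phase(self):
        x, t = self._tone(700.0)
        rec = make_recording(x, self.fs, [])
        y = fir_bandpass(rec, (100.0, 1500.0)).channels["HF"]
        core = slice(2000, -2000)  # avoid filter edge transients
        # zero-phase: filtered output aligned with input
        amp = np.sqrt(2 * np.mean(y[core] ** 2))
        assert amp == pytest.approx(1.0, abs=0.01)
        # phase: project onto quadrature pair
        ref_cos = np.cos(2 * np.pi * 700.0 * t)[core]
        ref_sin = np.sin(2 * np.pi * 700.0 * t)[core]
        phase = np.arctan2(y[core] @ ref_cos, y[core] @ ref_sin)
        assert abs(np.degrees(phase)) < 1.0

    def test_stopband_attenuation(self):
        x, _ = self._tone(7000.0)
        rec = make_recording(x, self.fs, [])
        y = fir_bandpass(rec, (100.0, 700.0)).channels["HF"]
        att = 20 * np.log10(np.std(x) / max(np.std(y[2000:-2000]), 1e-300))
        assert att >= 40

    def test_dc_removed(self):
        rec = make_recording(np.ones(8192), self.fs, [])
        y = fir_bandpass(rec, (100.0, 1500.0)).channels["HF"]
        assert np.abs(y[2000:-2000]).max() < 1e-2  # >= 40 dB down

    def test_band_outside_nyquist_rejected(self):
        rec = make_recording(np.zeros(100), 1000.0, [])
        with pytest.raises(ValueError):
            fir_bandpass(rec, (100.0, 600.0))


class TestEpoch:
    def test_constant_signal_zeroed_by_baseline(self):
        fs = 1000.0
        rec = make_recording(np.full(1000, 5.0), fs, [(0.3, "a"), (0.6, "b")])
        es = epoch(rec, (-0.003, 0.012), (-0.003, 0.0))
        assert es.epochs.shape[0] == 2
        np.testing.assert_allclose(es.epochs, 0.0, atol=1e-12)
        assert es.baseline_corrected

    @pytest.mark.parametrize(
        "window, expected_ms", [((-0.003, 0.012), 15), ((-0.005, 0.450), 455)]
    )
    def test_window_lengths(self, window, expected_ms):
        fs = 2000.0
        rec = make_recording(np.zeros(4000), fs, [(1.0, "a")])
        es = epoch(rec, window, None)
        assert es.epochs.shape[1] == int(round(expected_ms * 1e-3 * fs))

    def test_edge_trigger_dropped(self):
        fs = 1000.0
        rec = make_recording(np.zeros(100), fs, [(0.001, "early"), (0.05, "ok")])
        es = epoch(rec, (-0.003, 0.012), None)
        assert es.epochs.shape[0] == 1
        assert es.n_dropped == 1

    def test_baseline_outside_window_rejected(self):
        rec = make_recording(np.zeros(100), 1000.0, [(0.05, "a")])
        with pytest.raises(ValueError):
            epoch(rec, (-0.003, 0.012), (-0.005, 0.0))


class TestIterativeWeightedAverage:
    def test_equals_mean_under_equal_residual_variance(self):
        # orthogonal, zero-mean, equal-norm noise vectors give exactly
        # equal per-epoch residual variances, hence exactly equal weights
        n = 240
        t = np.arange(n)
        signal = np.sin(2 * np.pi * 3 * t / n)
        noise = np.stack(
            [np.sqrt(2) * np.cos(2 * np.pi * (k + 5) * t / n) for k in range(8)]
        )
        epochs = signal + 0.3 * noise
        res = iterative_weighted_average(epochs)
        rms = np.sqrt(np.mean(res.waveform**2))
        assert np.abs(res.waveform - epochs.mean(0)).max() <= 1e-9 * rms

    def test_beats_plain_average_under_heteroscedasticity(self):
        signal = np.sin(np.linspace(0, 4 * np.pi, 200))
        wins = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            sd = np.r_[np.full(10, 0.5), np.full(10, 5.0)][:, None]
            epochs = signal + sd * rng.standard_normal((20, 200))
            w = iterative_weighted_average(epochs).waveform
            mse_w = np.mean((w - signal) ** 2)
            mse_p = np.mean((epochs.mean(0) - signal) ** 2)
            wins += mse_w <= mse_p
        assert wins >= 95

    def test_order_invariance_block_size_one(self, rng):
        epochs = rng.standard_normal((16, 64))
        a = iterative_weighted_average(epochs)
        b = iterative_weighted_average(epochs[::-1])
        np.testing.assert_allclose(a.waveform, b.waveform, atol=1e-12)

    def test_scale_equivariance(self, rng):
        epochs = 1.0 + rng.standard_normal((12, 50))
        a = iterative_weighted_average(epochs)
        b = iterative_weighted_average(3.0 * epochs)
        np.testing.assert_allclose(b.waveform, 3.0 * a.waveform, rtol=1e-9)

    def test_single_epoch_warns_infinite_variance(self):
        with pytest.warns(UserWarning, match="single epoch"):
            res = iterative_weighted_average(np.ones((1, 10)))
        assert np.isinf(res.noise_variance)
        assert res.n_epochs == 1

    def test_weights_normalized(self, rng):
        epochs = rng.standard_normal((10, 40))
        res = iterative_weighted_average(epochs)
        assert res.weights.min() >= 0
        assert res.weights.sum() == pytest.approx(1.0)


def test_zero_phase_chain_preserves_steady_state_phase():
    """Filter -> epoch on a steady tone leaves component phase unbiased."""
    from abrffr.ffr import component_snr

    fs = 4096.0
    t = np.arange(int(5 * fs)) / fs
    phase_true = 0.7
    x = np.cos(2 * np.pi * 500.0 * t + phase_true)
    rec = make_recording(x, fs, [(1.0, "a"), (2.0, "b"), (3.0, "c")])
    filt = fir_bandpass(rec, (60.0, 1000.0))
    es = epoch(filt, (0.0, 0.5), None)
    avg = iterative_weighted_average(es)
    comp = component_snr(avg.waveform, fs, 500.0, t0=0.0, window="hamming")
    # trigger at integer seconds: tone phase at epoch start = phase_true
    assert comp.phase == pytest.approx(phase_true, abs=0.01)
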