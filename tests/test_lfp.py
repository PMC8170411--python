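"""LFP preprocessing, layer-4 pick, VEP metrics, wavelet band power."""

import numpy as np
import pytest

from oddballv1 import lfp


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestPreprocess:
    def test_60hz_attenuated_by_20db(self):
        t = np.arange(0, 60, 1e-3)
        x = np.sin(2 * np.pi * 60 * t)
        y = lfp.preprocess_lfp(x, 1000.0)
        assert _rms(y) <= 0.1 * _rms(x)

    def test_dc_preserved(self):
        y = lfp.preprocess_lfp(np.full(5000, 2.5), 1000.0)
        assert np.allclose(y, 2.5, atol=0.05)

    def test_downsampling_preserves_10hz_amplitude(self):
        fs = 30_000.0
        t = np.arange(0, 4, 1 / fs)
        x = 3.0 * np.sin(2 * np.pi * 10 * t)
        y = lfp.preprocess_lfp(x, fs)
        assert y.size == 4000
        # fit a 10 Hz sinusoid to the core of the output
        ty = np.arange(y.size) / 1000.0
        core = slice(500, 3500)
        basis = np.column_stack([np.sin(2 * np.pi * 10 * ty[core]),
                                 np.cos(2 * np.pi * 10 * ty[core])])
        coef, *_ = np.linalg.lstsq(basis, y[core], rcond=None)
        assert np.hypot(*coef) == pytest.approx(3.0, rel=0.05)

    def test_channel_count_preserved(self):
        x = np.random.default_rng(0).normal(size=(5, 3000))
        assert lfp.preprocess_lfp(x, 1000.0).shape[0] == 5

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            lfp.preprocess_lfp(np.zeros(100), 500.0)


class TestLayer4:
    def test_planted_sink_channel_found(self):
        times = np.arange(-0.3, 0.5, 1e-3)
        avg = np.zeros((64, times.size))
        sink = -np.exp(-((times - 0.04) ** 2) / (2 * 0.01 ** 2))
        avg[31] += 2.0 * sink
        avg[30] += 1.0 * sink
        assert lfp.find_layer4_channel(avg, times) == 31

    def test_single_channel(self):
        times = np.arange(-0.1, 0.2, 1e-3)
        trace = np.where((times > 0.02) & (times < 0.08), -1.0, 0.0)
        assert lfp.find_layer4_channel(trace, times) == 0

    def test_tie_broken_to_shallower_channel(self):
        times = np.arange(-0.1, 0.2, 1e-3)
        avg = np.zeros((4, times.size))
        dip = np.where((times > 0.02) & (times < 0.08), -1.0, 0.0)
        avg[1] = dip
        avg[2] = dip
        assert lfp.find_layer4_channel(avg, times) == 1

    def test_flat_input_rejected(self):
        times = np.arange(-0.1, 0.2, 1e-3)
        with pytest.raises(ValueError):
            lfp.find_layer4_channel(np.zeros((3, times.size)), times)

    def test_recovers_planted_sink_in_synthetic_session(self, tiny_recording):
        rec, _ = tiny_recording
        onsets = [e.onset_s for e in rec.events.events
                  if e.condition.value != "OMIS"]
        epochs, times, _ = lfp.epoch_lfp(rec.lfp, rec.lfp_fs, onsets)
        ch = lfp.find_layer4_channel(epochs.mean(axis=1), times)
        # planted sink is centered at 420 um
        assert abs(rec.channel_depth_um[ch] - 420.0) < 50.0


class TestVEPMetrics:
    def _times(self):
        return np.arange(-0.3, 0.5, 1e-3)

    def test_flat_trace_gives_zero(self):
        times = self._times()
        out = lfp.vep_metrics(np.zeros((10, times.size)), times, ["STD"] * 10)
        assert out["STD"]["peak_neg"] == 0.0
        assert out["STD"]["late_mean"] == 0.0

    def test_unit_step_late_mean(self):
        times = self._times()
        trace = np.where(times >= 0.2, -1.0, 0.0)
        out = lfp.vep_metrics(np.tile(trace, (5, 1)), times, ["CTR"] * 5)
        assert out["CTR"]["late_mean"] == pytest.approx(-1.0, rel=1e-6)
        assert out["CTR"]["peak_neg"] == pytest.approx(-1.0, rel=1e-6)

    def test_linearity_in_amplitude(self):
        times = self._times()
        rng = np.random.default_rng(0)
        epochs = rng.normal(size=(20, times.size))
        a = lfp.vep_metrics(epochs, times, ["STD"] * 20)["STD"]
        b = lfp.vep_metrics(3.0 * epochs, times, ["STD"] * 20)["STD"]
        assert b["peak_neg"] == pytest.approx(3.0 * a["peak_neg"])
        assert b["late_mean"] == pytest.approx(3.0 * a["late_mean"])

    def test_planted_condition_scaling(self):
        times = self._times()
        vep = -np.exp(-((times - 0.1) ** 2) / (2 * 0.02 ** 2))
        epochs = np.concatenate([np.tile(vep, (10, 1)),
                                 np.tile(0.5 * vep, (10, 1))])
        labels = ["CTR"] * 10 + ["STD"] * 10
        out = lfp.vep_metrics(epochs, times, labels)
        assert out["STD"]["peak_neg"] / out["CTR"]["peak_neg"] == \
            pytest.approx(0.5, abs=0.01)

    def test_missing_condition_skipped(self):
        times = self._times()
        out = lfp.vep_metrics(np.zeros((4, times.size)), times, ["STD"] * 4,
                              conditions=["STD", "DEV"])
        assert "DEV" not in out


class TestWaveletTFR:
    def test_forty_log_spaced_frequencies(self):
        times = np.arange(-1.0, 1.5, 1e-3)
        tfr = lfp.wavelet_tfr(np.random.default_rng(0).normal(size=times.size),
                              times)
        assert tfr.freqs_hz.size == 40
        assert tfr.freqs_hz[0] == pytest.approx(2.0)
        assert tfr.freqs_hz[-1] == pytest.approx(80.0)
        assert np.all(np.diff(np.log(tfr.freqs_hz)) > 0)
        assert np.allclose(np.diff(np.log(tfr.freqs_hz)),
                           np.diff(np.log(tfr.freqs_hz))[0])
        assert tfr.cycles[0] == pytest.approx(3.0)
        assert tfr.cycles[-1] == pytest.approx(10.0)

    def test_sinusoid_power_peaks_at_its_frequency(self):
        times = np.arange(-1.0, 2.0, 1e-3)
        trace = np.sin(2 * np.pi * 10 * times)
        tfr = lfp.wavelet_tfr(trace, times)
        stim = tfr.times_s > 0
        prof = tfr.power[:, stim].mean(axis=1)
        f_at_max = tfr.freqs_hz[np.argmax(prof)]
        nearest = tfr.freqs_hz[np.argmin(np.abs(tfr.freqs_hz - 10.0))]
        assert f_at_max == pytest.approx(nearest)

    def test_baseline_only_signal_is_zero_db(self):
        """A statistically stationary signal self-normalizes to ~0 dB."""
        rng = np.random.default_rng(3)
        times = np.arange(-10.0, 10.0, 1e-3)
        tfr = lfp.wavelet_tfr(rng.normal(size=times.size), times,
                              baseline_window_s=(-10.0, 0.0))
        core = (tfr.times_s > 1.0) & (tfr.times_s < 9.0)
        ratio_db = 10 * np.log10(
            tfr.power[:, core].mean(axis=1)
            / tfr.power[:, times < 0].mean(axis=1))
        assert np.all(np.abs(ratio_db) < 2.0)

    def test_empty_baseline_rejected(self):
        times = np.arange(0.0, 2.0, 1e-3)
        with pytest.raises(ValueError):
            lfp.wavelet_tfr(np.zeros(times.size), times,
                            baseline_window_s=(-0.3, 0.0))


class TestBandPower:
    def _tfr(self, power_db):
        freqs = np.logspace(np.log10(2), np.log10(80), 40)
        times = np.arange(-0.3, 0.6, 1e-3)
        return lfp.TFRResult(freqs, np.linspace(3, 10, 40), times,
                             power_db * np.ones((40, times.size)), (-0.3, 0.0))

    def test_uniform_field(self):
        out = lfp.band_power(self._tfr(3.0))
        assert all(v == pytest.approx(3.0) for v in out.values())
        assert set(out) == {"theta", "alpha", "beta", "low_gamma",
                            "high_gamma"}

    def test_planted_6hz_oscillation_elevates_theta(self):
        times = np.arange(-1.5, 2.0, 1e-3)
        rng = np.random.default_rng(5)
        trace = 0.2 * rng.normal(size=times.size)
        stim = (times >= 0.0) & (times <= 0.6)
        trace[stim] += np.sin(2 * np.pi * 6 * times[stim])
        tfr = lfp.wavelet_tfr(trace, times)
        out = lfp.band_power(tfr)
        assert out["theta"] > max(v for k, v in out.items() if k != "theta")

    def test_out_of_range_band_rejected(self):
        with pytest.raises(ValueError):
            lfp.band_power(self._tfr(0.0), {"bad": (90.0, 100.0)})
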