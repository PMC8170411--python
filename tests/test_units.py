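"""PSTHs, z-scoring, responsiveness, waveform class, laminar assignment."""

import numpy as np
import pytest

from oddballv1 import units
from oddballv1.synth import make_template


def asym_template(ttp_ms: float, width_ms: float,
                  fs: float = 30_000.0) -> np.ndarray:
    """Waveform with independently prescribed trough-to-peak and width."""
    t = np.arange(0.0, 4.0, 1000.0 / fs)
    trough_t = 1.6
    half_right = min(0.25, 0.4 * ttp_ms)
    sl = (width_ms - half_right) / 1.1774
    sr = half_right / 1.1774
    sigma = np.where(t < trough_t, sl, sr)
    wf = -np.exp(-((t - trough_t) ** 2) / (2 * sigma ** 2))
    wf += 0.35 * np.exp(-((t - (trough_t + ttp_ms)) ** 2)
                        / (2 * (0.3 * ttp_ms) ** 2))
    return wf


class TestPSTH:
    def test_single_spike_is_conserved(self):
        psth = units.compute_psth([0.1], [0.0])
        integral = np.sum(psth.rate_hz) * psth.bin_s
        assert integral == pytest.approx(1.0, rel=0.01)

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(0)
        onsets = np.arange(1000) * 2.0
        spikes = np.sort(rng.uniform(0, onsets[-1] + 1.0,
                                     int(10 * (onsets[-1] + 1.0))))
        psth = units.compute_psth(spikes, onsets)
        assert psth.rate_hz.mean() == pytest.approx(10.0, abs=0.5)

    def test_empty_train_gives_zero_rate(self):
        psth = units.compute_psth([], [0.0, 1.0])
        assert np.all(psth.rate_hz == 0)

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            units.compute_psth([0.1], [])

    def test_conservation_many_spikes_after_smoothing(self):
        rng = np.random.default_rng(1)
        onsets = np.arange(50) * 3.0
        spikes = np.sort(np.concatenate(
            [o + rng.uniform(-0.2, 0.4, 20) for o in onsets]))
        raw = units.compute_psth(spikes, onsets, smooth=False)
        smoothed = units.compute_psth(spikes, onsets)
        total = np.sum(raw.rate_hz) * raw.bin_s
        # kernel truncation at the window edges loses < a few percent
        assert np.sum(smoothed.rate_hz) * smoothed.bin_s == \
            pytest.approx(total, rel=0.05)


class TestZScore:
    def _psth(self, rates):
        t = np.arange(-0.3, 0.5, 0.01) + 0.005
        return units.PSTH(t, np.asarray(rates, dtype=float), n_trials=100)

    def test_flat_trace_is_zero(self):
        psth = self._psth(np.full(80, 5.0))
        assert np.allclose(units.zscore_response(psth), 0.0)

    def test_analytic_value(self):
        t = np.arange(-0.3, 0.5, 0.01) + 0.005
        rate = np.where(t < 0, np.tile([3.0, 7.0], 40)[:t.size], 9.0)
        psth = units.PSTH(t, rate, n_trials=100)
        z = units.zscore_response(psth)
        # baseline mean 5, sd 2 -> response 9 maps to z = 2
        assert z[t > 0].mean() == pytest.approx(2.0)

    def test_zero_baseline_sd_is_floored(self):
        psth = self._psth(np.concatenate([np.full(30, 5.0), np.full(50, 9.0)]))
        z = units.zscore_response(psth)
        assert np.all(np.isfinite(z))
        assert z[-1] > 0


class TestResponsiveness:
    def _simulate(self, base_hz, stim_hz, n_trials=100, seed=0):
        rng = np.random.default_rng(seed)
        onsets = np.arange(n_trials) * 3.0 + 1.0
        spikes = []
        for o in onsets:
            nb = rng.poisson(base_hz * 1.0)
            spikes.append(o - 1.0 + rng.uniform(0, 0.95, nb))
            ns = rng.poisson(stim_hz * 0.45)
            spikes.append(o + 0.05 + rng.uniform(0, 0.45, ns))
        return np.sort(np.concatenate(spikes)), onsets

    def test_planted_increase_is_excited(self):
        spikes, onsets = self._simulate(5.0, 15.0)
        assert units.classify_responsive(spikes, onsets) == "excited"

    def test_planted_suppression_is_inhibited(self):
        spikes, onsets = self._simulate(10.0, 2.0, seed=1)
        assert units.classify_responsive(spikes, onsets) == "inhibited"

    def test_identical_counts_are_none(self):
        onsets = np.arange(20) * 3.0 + 1.0
        # one spike in each window on every trial
        spikes = np.sort(np.concatenate([onsets - 0.1, onsets + 0.2]))
        assert units.classify_responsive(spikes, onsets) == "none"

    def test_too_few_trials_flagged(self):
        spikes, onsets = self._simulate(5.0, 15.0, n_trials=5)
        assert units.classify_responsive(spikes, onsets) == "insufficient"


class TestWaveformClassification:
    def test_canonical_templates_recovered(self):
        for cls in ("RS", "FS"):
            feat = units.classify_waveform(make_template(cls), 30_000.0)
            assert feat.cell_class == cls

    @pytest.mark.parametrize("ttp, width, expected", [
        (0.3, 0.9, "FS"),
        (0.7, 1.5, "RS"),
        (0.3, 1.5, "unclassified"),   # mixed features
        (0.7, 0.9, "unclassified"),
    ])
    def test_threshold_rules(self, ttp, width, expected):
        feat = units.classify_waveform(asym_template(ttp, width), 30_000.0)
        assert feat.trough_to_peak_ms == pytest.approx(ttp, abs=0.1)
        assert feat.spike_width_ms == pytest.approx(width, abs=0.15)
        assert feat.cell_class == expected

    def test_monotone_template_rejected(self):
        with pytest.raises(ValueError):
            units.classify_waveform(np.linspace(-1, 0, 90), 30_000.0)


class TestLayerAssignment:
    @pytest.mark.parametrize("depth, layer", [
        (200.0, "L2/3"), (420.0, "L4"), (800.0, "L5/6"),
        (350.0, "L4"),   # boundary goes to the deeper layer (half-open)
        (500.0, "L5/6"),
    ])
    def test_interval_lookup(self, depth, layer):
        assert units.assign_layer(depth) == layer

    def test_outside_span_rejected(self):
        with pytest.raises(ValueError):
            units.assign_layer(1500.0)
        with pytest.raises(ValueError):
            units.assign_layer(-5.0)

    def test_custom_boundaries(self):
        bounds = {"L2/3": (100.0, 350.0), "L4": (350.0, 500.0),
                  "L5/6": (500.0, 1000.0)}
        assert units.assign_layer(200.0, bounds) == "L2/3"


class TestInclusionFilter:
    def test_sparse_units_dropped(self, tiny_recording):
        rec, _ = tiny_recording
        kept = units.filter_units(rec)
        assert 0 < len(kept) <= len(rec.units)
        blocks = sorted({e.block for e in rec.events.events})
        for u in kept:
            assert all(u.n_spikes_per_block[b] > 10 for b in blocks)
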