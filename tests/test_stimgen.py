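"""Stimulus frames and trial sequences."""

import numpy as np
import pytest

from oddballv1 import stimgen
from oddballv1.core import Condition

GEOM = stimgen.ViewingGeometry()
BANDS = stimgen.canonical_bands()


class TestBands:
    def test_six_octave_spaced_non_overlapping_bands(self):
        assert len(BANDS) == 6
        centers = [b.center_cpd for b in BANDS]
        assert centers == sorted(centers)
        assert np.allclose(np.diff(np.log2(centers)), 1.0)
        for lo_band, hi_band in zip(BANDS, BANDS[1:]):
            assert lo_band.high_cpd <= hi_band.low_cpd + 1e-12

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            stimgen.SFBand(0.03, 0.05, 0.06)


class TestSFFrame:
    def test_deterministic_for_fixed_seed(self):
        a = stimgen.make_sf_frame(11, (64, 64), BANDS[3])
        b = stimgen.make_sf_frame(11, (64, 64), BANDS[3])
        assert np.array_equal(a, b)

    def test_different_seeds_differ_pixelwise(self):
        a = stimgen.make_sf_frame(1, (64, 64), BANDS[3])
        b = stimgen.make_sf_frame(2, (64, 64), BANDS[3])
        assert not np.array_equal(a, b)

    def test_luminance_normalization(self):
        img = stimgen.make_sf_frame(5, (128, 128), BANDS[4])
        assert img.min() >= 0.0 and img.max() <= 1.0
        assert img.mean() == pytest.approx(0.5, abs=0.02)

    def test_in_band_energy_dominates_for_order_10(self):
        # full-resolution frame so the low band edges are resolvable
        size = GEOM.resolution_px
        band = BANDS[2]  # 0.03 cpd, the oddball band
        img = stimgen.make_sf_frame(3, size, band)
        frac = stimgen.in_band_energy_fraction(img, band)
        assert frac >= 0.9

    def test_allpass_band_preserves_raw_noise(self):
        band = stimgen.SFBand(GEOM.nyquist_cpd / 2, 1e-5,
                              GEOM.max_radial_cpd * 0.999)
        img = stimgen.make_sf_frame(9, (128, 128), band, design_margin=1.0)
        raw = np.random.default_rng(9).standard_normal((128, 128))
        r = np.corrcoef(img.ravel(), raw.ravel())[0, 1]
        assert r > 0.99

    def test_spectral_centroid_monotone_across_bands(self):
        size = (GEOM.resolution_px[0] // 2, GEOM.resolution_px[1] // 2)
        cents = [stimgen.radial_spectral_centroid(
            stimgen.make_sf_frame(21, size, b)) for b in BANDS]
        assert np.all(np.diff(cents) > 0)

    def test_band_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            stimgen.make_sf_frame(0, (64, 64),
                                  stimgen.SFBand(6.0, 4.0, 9.0))

    def test_tiny_frame_rejected(self):
        with pytest.raises(ValueError):
            stimgen.make_sf_frame(0, (8, 8), BANDS[0])


class TestTuningSequence:
    def test_six_by_twenty_gives_120_trials(self):
        seq = stimgen.make_tuning_sequence(seed=0)
        assert len(seq) == 120

    def test_reps_one_gives_one_per_band(self):
        seq = stimgen.make_tuning_sequence(reps=1, seed=1)
        assert len(seq) == 6
        assert len({e.sf_cpd for e in seq.events}) == 6

    @pytest.mark.parametrize("seed", range(10))
    def test_balanced_counts_any_seed(self, seed):
        seq = stimgen.make_tuning_sequence(reps=5, seed=seed)
        sfs = [e.sf_cpd for e in seq.events]
        assert all(sfs.count(c) == 5 for c in {b.center_cpd for b in BANDS})

    def test_iti_at_least_4s(self):
        seq = stimgen.make_tuning_sequence(seed=2)
        gaps = np.diff(seq.onsets())
        assert gaps.min() >= 0.5 + 4.0

    def test_fresh_frame_seed_every_trial(self):
        seq = stimgen.make_tuning_sequence(seed=3)
        seeds = [e.frame_seed for e in seq.events]
        assert len(set(seeds)) == len(seeds)


class TestOddballSequence:
    def test_trial_counts(self, oddball_sequence):
        conds = [e.condition for e in oddball_sequence.events]
        assert conds.count(Condition.DEV) == 25
        assert conds.count(Condition.STD) == 175

    def test_minimal_sequence_has_one_deviant(self):
        seq = stimgen.make_oddball_sequence(n_trials=8, seed=0)
        assert sum(e.condition is Condition.DEV for e in seq.events) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_gaps_and_deviant_placement(self, seed):
        seq = stimgen.make_oddball_sequence(seed=seed)
        gaps = np.diff(seq.onsets())
        assert gaps.min() >= 1.5 - 1e-9 and gaps.max() <= 2.2 + 1e-9
        conds = [e.condition for e in seq.events]
        assert conds[0] is Condition.STD
        for i in range(1, len(conds)):
            if conds[i] is Condition.DEV:
                assert conds[i - 1] is Condition.STD

    def test_std_texture_frozen_dev_texture_fresh(self, oddball_sequence):
        std_seeds = {e.frame_seed for e in oddball_sequence.events
                     if e.condition is Condition.STD}
        dev_seeds = [e.frame_seed for e in oddball_sequence.events
                     if e.condition is Condition.DEV]
        assert len(std_seeds) == 1
        assert len(set(dev_seeds)) == len(dev_seeds)

    def test_non_integer_deviant_count_rejected(self):
        with pytest.raises(ValueError):
            stimgen.make_oddball_sequence(n_trials=10, p_dev=0.125)


class TestOmissionSequence:
    def test_every_eighth_slot_omitted(self):
        seq = stimgen.make_omission_sequence(seed=0)
        conds = [e.condition for e in seq.events]
        assert conds.count(Condition.OMIS) == 25
        assert len(seq) == 200
        for i, c in enumerate(conds):
            assert (c is Condition.OMIS) == ((i + 1) % 8 == 0)

    def test_short_sequence_has_no_omission(self):
        seq = stimgen.make_omission_sequence(n_trials=7, seed=0)
        assert all(e.condition is not Condition.OMIS for e in seq.events)

    def test_fixed_period(self):
        seq = stimgen.make_omission_sequence(seed=1)
        assert np.allclose(np.diff(seq.onsets()), 2.2)

    def test_omission_events_carry_no_frame(self):
        seq = stimgen.make_omission_sequence(seed=2)
        for e in seq.events:
            if e.condition is Condition.OMIS:
                assert e.frame_seed is None and e.sf_cpd is None


class TestSessionSequence:
    def test_full_session_is_520_trials(self):
        seq = stimgen.make_session_sequence(seed=4)
        assert len(seq) == 520

    def test_bit_reproducible(self):
        a = stimgen.make_session_sequence(seed=5).to_frame()
        b = stimgen.make_session_sequence(seed=5).to_frame()
        assert a.equals(b)
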