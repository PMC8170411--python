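"""Omission classification, k-means motif clustering, elbow selection."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from sklearn.metrics import adjusted_rand_score

from oddballv1 import omission, stimgen, synth


def _omission_unit(motif: str, seed: int, amp: float = 12.0):
    """One simulated unit on a full 200-trial omission block (25 omissions)."""
    u = synth.simulate_units(1, synth.recovery_regime(), seed=seed)[0]
    u = replace(u, omission_motif=motif, motif_amp_hz=amp, r0=3.0,
                inhib_drop=0.85)
    seq = stimgen.make_omission_sequence(n_trials=200, seed=seed)
    regime = replace(synth.recovery_regime(), n_channels=2)
    rec = synth.simulate_session([u], seq, regime, seed=seed + 1000)
    return rec.units[0].spike_times_s, rec.events


class TestClassifyOmission:
    def test_planted_early_motif_is_excited(self):
        spikes, events = _omission_unit("early", seed=1)
        assert omission.classify_omission(spikes, events) == "omis_excited"

    def test_planted_inhibited_motif_is_inhibited(self):
        spikes, events = _omission_unit("inhibited", seed=2)
        assert omission.classify_omission(spikes, events) == "omis_inhibited"

    def test_no_motif_is_mostly_none(self):
        labels = [omission.classify_omission(*_omission_unit("none", seed=s))
                  for s in range(10, 25)]
        assert labels.count("none") >= 13  # ~alpha = 0.05 false positives

    def test_too_few_trials_flagged(self):
        spikes, _ = _omission_unit("early", seed=3)
        seq = stimgen.make_omission_sequence(n_trials=40, seed=3)
        assert omission.classify_omission(spikes, seq) == "insufficient"


class TestClusterOmission:
    def test_two_planted_motifs_perfectly_separated(self):
        X, labels = synth.motif_traces(50, snr=2.0, seed=0,
                                       motifs=("early", "inhibited"))
        pred = omission.cluster_omission(X, 2)
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_labels_independent_of_seed(self):
        X, _ = synth.motif_traces(30, seed=1)
        assert np.array_equal(omission.cluster_omission(X, 4, seed=0),
                              omission.cluster_omission(X, 4, seed=99))

    def test_permutation_equivariance(self):
        X, _ = synth.motif_traces(30, seed=2)
        perm = np.random.default_rng(3).permutation(X.shape[0])
        l1 = omission.cluster_omission(X, 4)
        l2 = omission.cluster_omission(X[perm], 4)
        assert np.array_equal(l1[perm], l2)

    def test_cluster_ids_ordered_by_peak_latency(self):
        X, labels = synth.motif_traces(40, snr=3.0, seed=4)
        pred = omission.cluster_omission(X, 4)
        for cl, motif in enumerate(("early", "mid", "late", "inhibited")):
            majority = pd.Series(labels[pred == cl]).mode()[0]
            assert majority == motif

    @pytest.mark.filterwarnings("ignore::UserWarning")
    def test_identical_rows_do_not_crash(self):
        """Degenerate input collapses to one occupied cluster (documented)."""
        X = np.ones((12, 45))
        labels = omission.cluster_omission(X, 2)
        assert set(labels) <= {0, 1}

    def test_k_above_n_rejected(self):
        X, _ = synth.motif_traces(2, seed=5, motifs=("early",))
        with pytest.raises(ValueError):
            omission.cluster_omission(X, 5)


class TestElbow:
    def test_four_planted_motifs_select_k4(self):
        X, _ = synth.motif_traces(40, snr=2.0, seed=6)
        res = omission.elbow_k(X, k_max=10)
        assert res.k == 4
        assert not res.low_confidence

    def test_two_planted_motifs_select_k2(self):
        X, _ = synth.motif_traces(60, snr=2.0, seed=7,
                                  motifs=("early", "inhibited"))
        assert omission.elbow_k(X, k_max=10).k == 2

    def test_single_blob_low_confidence(self):
        X = np.random.default_rng(8).normal(size=(150, 45))
        res = omission.elbow_k(X, k_max=10)
        assert res.low_confidence
        assert res.k in (1, 2)

    def test_inertia_curve_non_increasing(self):
        X = np.random.default_rng(9).normal(size=(60, 45))
        res = omission.elbow_k(X, k_max=8)
        assert np.all(np.diff(res.inertia_curve) <= 1e-9)
        assert np.all(np.diff(res.distortion_curve) <= 1e-6)

    def test_argument_validation(self):
        X, _ = synth.motif_traces(3, seed=10, motifs=("early",))
        with pytest.raises(ValueError):
            omission.elbow_k(X, k_max=10)
        with pytest.raises(ValueError):
            omission.elbow_k(np.zeros((30, 45)), k_max=2)


class TestCompareOmissionGroups:
    def _population(self, seed, fx_mid_gain=1.0, n=80):
        rng = np.random.default_rng(seed)
        Xw, lw = synth.motif_traces(n // 4, snr=2.0, seed=seed)
        Xf, lf = synth.motif_traces(n // 4, snr=2.0, seed=seed + 500)
        Xf[lf == "mid"] *= fx_mid_gain
        X = np.vstack([Xw, Xf])
        genotype = np.array(["WT"] * Xw.shape[0] + ["FX"] * Xf.shape[0])
        return X, genotype

    def test_planted_stronger_fx_mid_motif_detected(self):
        X, genotype = self._population(0, fx_mid_gain=1.6)
        labels = omission.cluster_omission(X, 4)
        z = X.mean(axis=1)
        cmp = omission.compare_omission_groups(labels, z, z, genotype)
        mid = cmp[(cmp.cluster == 2) & (cmp.response == "omis")].iloc[0]
        assert mid.p_adj < 0.05
        assert mid.mean_a > mid.mean_b  # group_a = FX (sorted labels)

    def test_null_rarely_significant(self):
        clean = 0
        for s in range(20):
            X, genotype = self._population(100 + s)
            labels = omission.cluster_omission(X, 4)
            z = X.mean(axis=1)
            cmp = omission.compare_omission_groups(labels, z, z, genotype)
            if (cmp["p_adj"].dropna() > 0.05).all():
                clean += 1
        assert clean >= 16

    def test_single_genotype_cluster_gives_na(self):
        X, genotype = self._population(3)
        labels = omission.cluster_omission(X, 4)
        genotype[labels == 0] = "WT"  # wipe FX from cluster 1
        cmp = omission.compare_omission_groups(labels, X.mean(1), X.mean(1),
                                               genotype)
        assert cmp[(cmp.cluster == 1)].p_adj.isna().all()
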