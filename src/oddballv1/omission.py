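"""Omission-response classification and temporal-motif clustering.

Units with a significant response at the expected time of a withheld
stimulus (Wilcoxon signed-rank, 0.05-0.35 s vs -0.25-0.05 s per omission
trial) are split into omission-excited and omission-inhibited by the sign
of their mean z-scored response.  Temporal profiles (z-scored trial-averaged
traces, 0.05-0.5 s, resampled to 45 bins) are clustered with k-means using
a deterministic PCA-based initialization; the cluster count is selected by
an automated elbow rule (maximum second difference of log inertia).
Cluster ids are ordered by peak latency of the cluster means, with the
negative-mean (inhibited) cluster last, so "group 1..k" is stable across
runs.  Genotype never enters the clustering; it is only compared within
clusters afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .core import Condition, StimulusSequence, epoch_spike_counts, logger
from .stats import adjust_family, mann_whitney
from .units import PSTH, compute_psth, zscore_response

__all__ = ["classify_omission", "omission_trace", "cluster_omission",
           "elbow_k", "compare_omission_groups", "OmissionClusterResult",
           "CLUSTER_WINDOW_S", "N_CLUSTER_BINS"]

STIM_WINDOW_S = (0.05, 0.35)
BASELINE_WINDOW_S = (-0.25, 0.05)
CLUSTER_WINDOW_S = (0.05, 0.5)
N_CLUSTER_BINS = 45
MIN_TRIALS = 10


def classify_omission(spike_times_s, events: StimulusSequence,
                      alpha: float = 0.05) -> str:
    """``omis_excited`` / ``omis_inhibited`` / ``none`` for one unit.

    Significance: Wilcoxon signed-rank on per-omission-trial spike counts,
    expected-stimulus window vs baseline.  The excited/inhibited split uses
    the sign of the mean z-scored response in the stimulus window.
    """
    from .stats import wilcoxon_signed

    omis = events.select(condition=Condition.OMIS)
    if len(omis) < MIN_TRIALS:
        logger.info("classify_omission: only %d omission trials", len(omis))
        return "insufficient"
    onsets = omis.onsets()
    stim = epoch_spike_counts(spike_times_s, onsets, STIM_WINDOW_S)
    base = epoch_spike_counts(spike_times_s, onsets, BASELINE_WINDOW_S)
    res = wilcoxon_signed(stim.astype(float), base.astype(float))
    if res.p_raw >= alpha:
        return "none"
    z = omission_zscore(spike_times_s, onsets)
    return "omis_excited" if z > 0 else "omis_inhibited"


def omission_zscore(spike_times_s, onsets,
                    window: tuple[float, float] = STIM_WINDOW_S) -> float:
    """Mean z-scored omission response within ``window``."""
    psth = compute_psth(spike_times_s, onsets)
    z = zscore_response(psth)
    mask = (psth.time_s >= window[0]) & (psth.time_s <= window[1])
    return float(z[mask].mean())


def omission_trace(spike_times_s, events: StimulusSequence,
                   window: tuple[float, float] = CLUSTER_WINDOW_S,
                   n_bins: int = N_CLUSTER_BINS) -> np.ndarray:
    """z-scored trial-averaged omission response resampled to ``n_bins``."""
    omis = events.select(condition=Condition.OMIS)
    if len(omis) == 0:
        raise ValueError("no omission trials")
    psth = compute_psth(spike_times_s, omis.onsets())
    z = zscore_response(psth)
    mask = (psth.time_s >= window[0]) & (psth.time_s <= window[1])
    t = psth.time_s[mask]
    grid = np.linspace(window[0], window[1], n_bins)
    return np.interp(grid, t, z[mask])


def _pca_init(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic PCA-based k-means initialization.

    Projects the traces onto their first k principal components and cuts a
    Ward dendrogram of the scores at k groups; the initial centers are the
    group means in trace space.  Fully deterministic (no random seed), so
    k-means labels depend only on the input.
    """
    from sklearn.cluster import AgglomerativeClustering

    n_comp = min(k, min(X.shape) - 1) or 1
    scores = PCA(n_components=n_comp, svd_solver="full").fit_transform(X)
    grp = AgglomerativeClustering(n_clusters=k, linkage="ward"
                                  ).fit_predict(scores)
    return np.stack([X[grp == j].mean(axis=0) for j in range(k)])


def _order_clusters(labels: np.ndarray, X: np.ndarray, k: int) -> np.ndarray:
    """Relabel clusters by mean-trace peak latency; negative-mean last."""
    means = np.stack([X[labels == j].mean(axis=0) if np.any(labels == j)
                      else np.full(X.shape[1], np.inf) for j in range(k)])
    peak_lat = means.argmax(axis=1).astype(float)
    inhibited = means.mean(axis=1) < 0
    orderkey = peak_lat + inhibited * (X.shape[1] + 1)
    new_order = np.argsort(orderkey, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[new_order] = np.arange(k)
    return remap[labels]


def cluster_omission(X: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means partition of unit omission traces (units x time).

    The PCA-based initialization makes labels reproducible for fixed input
    regardless of ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of units")
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    km = KMeans(n_clusters=k, init=_pca_init(X, k), n_init=1,
                random_state=seed)
    labels = km.fit_predict(X)
    return _order_clusters(labels, X, k)


@dataclass
class OmissionClusterResult:
    labels: np.ndarray
    k: int
    inertia_curve: np.ndarray       # within-cluster sum of squares, k=1..kmax
    distortion_curve: np.ndarray    # mean nearest-centroid distance
    k_candidates: np.ndarray
    low_confidence: bool
    cluster_means: np.ndarray       # (k, time)


def elbow_k(X: np.ndarray, k_max: int = 10, seed: int = 0,
            min_elbow_depth: float = 0.1) -> OmissionClusterResult:
    """Select k at the maximum-curvature point of the log-inertia curve.

    Computes inertia (within-cluster sum of squares) and distortion (mean
    nearest-centroid distance) for k = 1..k_max.  The selected k maximizes
    the vertical distance between log inertia and the chord joining its
    endpoints (the kneedle rule) — the point where the slope changes most.
    If no candidate deviates from the chord by more than
    ``min_elbow_depth`` log units there is no real elbow: the result is
    flagged low-confidence and k falls back to 1.
    """
    X = np.asarray(X, dtype=float)
    if k_max >= X.shape[0]:
        raise ValueError("k_max must be below the number of units")
    if k_max < 3:
        raise ValueError("need at least 3 candidate cluster counts")
    ks = np.arange(1, k_max + 1)
    inertia = np.empty(ks.size)
    distortion = np.empty(ks.size)
    for i, k in enumerate(ks):
        if k == 1:
            c = X.mean(axis=0, keepdims=True)
            d = np.linalg.norm(X - c, axis=1)
            inertia[i] = float((d ** 2).sum())
            distortion[i] = float(d.mean())
        else:
            km = KMeans(n_clusters=int(k), init=_pca_init(X, int(k)),
                        n_init=1, random_state=seed).fit(X)
            inertia[i] = float(km.inertia_)
            d = np.linalg.norm(X - km.cluster_centers_[km.labels_], axis=1)
            distortion[i] = float(d.mean())
    log_in = np.log(np.maximum(inertia, 1e-300))
    chord = log_in[0] + (log_in[-1] - log_in[0]) * (ks - 1) / (ks[-1] - 1)
    depth = chord - log_in
    k_sel = int(ks[int(np.argmax(depth))])
    low_conf = bool(depth.max() < min_elbow_depth)
    if low_conf:
        k_sel = 1
    labels = cluster_omission(X, k_sel, seed)
    means = np.stack([X[labels == j].mean(axis=0) for j in range(k_sel)])
    return OmissionClusterResult(labels, k_sel, inertia, distortion, ks,
                                 low_conf, means)


def compare_omission_groups(labels: np.ndarray, std_z: np.ndarray,
                            omis_z: np.ndarray, genotype: np.ndarray
                            ) -> pd.DataFrame:
    """Within-cluster genotype contrasts of mean z-scored responses.

    For each k-means group, Mann-Whitney U on per-unit mean z-scored
    standard and omission responses between the two genotype labels; BH
    adjustment within each response family.  Single-genotype clusters give
    NA rows.
    """
    labels = np.asarray(labels)
    genotype = np.asarray(genotype)
    groups = sorted(np.unique(genotype))
    if len(groups) != 2:
        raise ValueError("need exactly two genotype labels")
    ga, gb = groups
    rows = []
    families = {"std": [], "omis": []}
    for cl in np.unique(labels):
        sel = labels == cl
        for name, vals in (("std", std_z), ("omis", omis_z)):
            a = np.asarray(vals)[sel & (genotype == ga)]
            b = np.asarray(vals)[sel & (genotype == gb)]
            entry = {"cluster": int(cl) + 1, "response": name,
                     "n_a": a.size, "n_b": b.size,
                     "mean_a": float(a.mean()) if a.size else np.nan,
                     "mean_b": float(b.mean()) if b.size else np.nan}
            if a.size < 2 or b.size < 2:
                entry["res"] = None
            else:
                res = mann_whitney(a, b, f"omission:cluster{cl + 1}:{name}")
                families[name].append(res)
                entry["res"] = res
            rows.append(entry)
    for fam in families.values():
        adjust_family(fam)
    out = []
    for entry in rows:
        res = entry.pop("res")
        entry["p_raw"] = res.p_raw if res else np.nan
        entry["p_adj"] = res.p_adjusted if res else np.nan
        out.append(entry)
    return pd.DataFrame(out)
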