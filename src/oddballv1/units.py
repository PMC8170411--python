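"""Single-unit metrics: PSTHs, z-scoring, responsiveness, waveform class,
laminar assignment, and the minimum-spikes inclusion filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .core import Recording, UnitRecord, epoch_spike_counts, logger
from .stats import wilcoxon_signed

__all__ = ["PSTH", "WaveformFeatures", "compute_psth", "zscore_response",
           "classify_responsive", "classify_waveform", "assign_layer",
           "filter_units", "DEFAULT_LAYER_BOUNDARIES_UM"]

PSTH_BIN_S = 0.010
#: Gaussian smoothing kernel width, defined as FWHM (seconds).
PSTH_KERNEL_FWHM_S = 0.100
EPOCH_WINDOW_S = (-0.3, 0.5)

RESPONSIVE_BASELINE_S = (-0.25, 0.05)
RESPONSIVE_STIM_S = (0.05, 0.35)
RESPONSIVE_ALPHA = 0.05
MIN_TRIALS = 10

#: Trough-to-peak (ms) and spike-width (ms) cutoffs separating fast-spiking
#: from regular-spiking units.
FS_TTP_MS = 0.45
FS_WIDTH_MS = 1.2

DEFAULT_LAYER_BOUNDARIES_UM = {"L2/3": (0.0, 350.0), "L4": (350.0, 500.0),
                               "L5/6": (500.0, 1000.0)}

MIN_SPIKES_PER_BLOCK = 10


@dataclass
class PSTH:
    """Smoothed trial-averaged firing rate around stimulus onset."""

    time_s: np.ndarray      # bin centers relative to onset
    rate_hz: np.ndarray
    n_trials: int
    bin_s: float = PSTH_BIN_S
    kernel_fwhm_s: float = PSTH_KERNEL_FWHM_S


def compute_psth(spike_times_s, event_onsets_s,
                 window_s: tuple[float, float] = EPOCH_WINDOW_S,
                 bin_s: float = PSTH_BIN_S,
                 kernel_fwhm_s: float = PSTH_KERNEL_FWHM_S,
                 smooth: bool = True) -> PSTH:
    """Histogram spike times across trials (10 ms bins) and smooth with a
    Gaussian kernel (FWHM 100 ms, sigma = FWHM / 2.355)."""
    onsets = np.asarray(event_onsets_s, dtype=float)
    if onsets.size < 1:
        raise ValueError("at least one trial is required")
    spikes = np.asarray(spike_times_s, dtype=float)
    edges = np.arange(window_s[0], window_s[1] + bin_s / 2, bin_s)
    rel = (spikes[None, :] - onsets[:, None]).ravel()
    counts, _ = np.histogram(rel, bins=edges)
    rate = counts / (onsets.size * bin_s)
    if smooth and kernel_fwhm_s > 0:
        sigma_bins = kernel_fwhm_s / 2.3548 / bin_s
        rate = gaussian_filter1d(rate, sigma_bins, mode="constant", truncate=4.0)
    centers = edges[:-1] + bin_s / 2
    return PSTH(centers, rate, onsets.size, bin_s, kernel_fwhm_s)


def zscore_response(psth: PSTH,
                    baseline_window_s: tuple[float, float] = (-0.3, 0.0)
                    ) -> np.ndarray:
    """z(t) = (R(t) - mean(baseFR)) / sd(baseFR) over the pre-stimulus epoch.

    A silent or constant baseline would give sd = 0; the SD is floored at
    the rate equivalent of one spike in the whole baseline epoch
    (1 / (n_trials * epoch length) Hz) so the output stays finite.
    """
    mask = (psth.time_s >= baseline_window_s[0]) & \
           (psth.time_s < baseline_window_s[1])
    if not mask.any():
        raise ValueError("baseline window outside the PSTH")
    base = psth.rate_hz[mask]
    mu, sd = float(base.mean()), float(base.std())
    floor = 1.0 / (psth.n_trials * (baseline_window_s[1] - baseline_window_s[0]))
    sd = max(sd, floor)
    return (psth.rate_hz - mu) / sd


def classify_responsive(spike_times_s, event_onsets_s,
                        baseline_window_s=RESPONSIVE_BASELINE_S,
                        stim_window_s=RESPONSIVE_STIM_S,
                        alpha: float = RESPONSIVE_ALPHA) -> str:
    """Visual responsiveness by Wilcoxon signed-rank on per-trial counts.

    Baseline (-0.25-0.05 s) vs stimulus (0.05-0.35 s) counts per trial;
    significant increase -> ``"excited"``, significant decrease ->
    ``"inhibited"``, otherwise ``"none"``.  Fewer than 10 trials ->
    ``"insufficient"``.
    """
    onsets = np.asarray(event_onsets_s, dtype=float)
    if onsets.size < MIN_TRIALS:
        logger.info("classify_responsive: only %d trials", onsets.size)
        return "insufficient"
    base = epoch_spike_counts(spike_times_s, onsets, baseline_window_s)
    stim = epoch_spike_counts(spike_times_s, onsets, stim_window_s)
    res = wilcoxon_signed(stim.astype(float), base.astype(float))
    if res.p_raw < alpha:
        return "excited" if stim.mean() > base.mean() else "inhibited"
    return "none"


@dataclass
class WaveformFeatures:
    trough_to_peak_ms: float
    spike_width_ms: float
    cell_class: str  # RS | FS | unclassified


def classify_waveform(template, fs: float) -> WaveformFeatures:
    """RS/FS split from the template waveform.

    Trough-to-peak: time from the global trough to the subsequent maximum.
    Spike width: full width of the trough at half its depth (relative to
    the pre-trough baseline).  FS requires both features below the cutoffs
    (0.45 ms, 1.2 ms); RS both above; boundary or mixed cases are
    unclassified.
    """
    wf = np.asarray(template, dtype=float)
    i_tr = int(np.argmin(wf))
    if i_tr == 0 or i_tr == wf.size - 1 or wf[i_tr] >= 0:
        raise ValueError("template has no interior trough")
    after = wf[i_tr:]
    ttp_ms = float(np.argmax(after) / fs * 1000.0)
    if ttp_ms == 0:
        raise ValueError("no peak after the trough")
    half = wf[i_tr] / 2.0

    def cross(idx_range, reverse=False):
        rng = idx_range[::-1] if reverse else idx_range
        prev = None
        for i in rng:
            if wf[i] >= half:
                if prev is None:
                    return float(i)
                # linear interpolation between samples i and prev
                frac = (half - wf[prev]) / (wf[i] - wf[prev])
                return prev + frac * (i - prev)
            prev = i
        return float(rng[-1])

    left = cross(range(i_tr, -1, -1))
    right = cross(range(i_tr, wf.size))
    width_ms = float(abs(right - left) / fs * 1000.0)
    if ttp_ms < FS_TTP_MS and width_ms < FS_WIDTH_MS:
        cls = "FS"
    elif ttp_ms > FS_TTP_MS and width_ms > FS_WIDTH_MS:
        cls = "RS"
    else:
        cls = "unclassified"
    return WaveformFeatures(ttp_ms, width_ms, cls)


def assign_layer(depth_um: float,
                 boundaries_um: dict[str, tuple[float, float]] | None = None
                 ) -> str:
    """Laminar assignment by half-open depth intervals [lo, hi)."""
    boundaries_um = boundaries_um or DEFAULT_LAYER_BOUNDARIES_UM
    for layer, (lo, hi) in boundaries_um.items():
        if lo <= depth_um < hi:
            return layer
    span = (min(lo for lo, _ in boundaries_um.values()),
            max(hi for _, hi in boundaries_um.values()))
    raise ValueError(f"depth {depth_um} um outside probe span {span}")


def filter_units(recording: Recording,
                 min_spikes: int = MIN_SPIKES_PER_BLOCK) -> list[UnitRecord]:
    """Inclusion filter: more than ``min_spikes`` spikes in every block."""
    blocks = sorted({e.block for e in recording.events.events})
    kept = []
    for u in recording.units:
        counts = u.n_spikes_per_block
        if not counts:
            counts = {}
            for blk in blocks:
                sub = recording.events.select(block=blk)
                lo = sub.events[0].onset_s - 1.0
                hi = sub.events[-1].onset_s + 1.0
                counts[blk] = int(np.sum((u.spike_times_s >= lo)
                                         & (u.spike_times_s < hi)))
        if all(counts.get(blk, 0) > min_spikes for blk in blocks):
            kept.append(u)
    logger.info("filter_units: kept %d / %d units", len(kept),
                len(recording.units))
    return kept
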