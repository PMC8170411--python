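"""LFP preprocessing, layer-4 identification, VEP metrics, and Morlet
time-frequency band power.

Preprocessing decimates to 1 kHz with an anti-aliasing FIR and removes 60 Hz
line noise with a symmetric (zero-phase when centered) linear-phase FIR
notch.  Layer 4 is the channel with the strongest negative deflection within
100 ms of stimulus onset.  The time-frequency representation uses 40 complex
Morlet wavelets log-spaced 2-80 Hz with 3-10 cycles, applied to the
trial-averaged trace, dB-normalized to a pre-stimulus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import logger

__all__ = ["TFRResult", "BANDS", "preprocess_lfp", "find_layer4_channel",
           "vep_metrics", "wavelet_tfr", "band_power", "epoch_lfp"]

TARGET_FS = 1000.0

#: The five LFP frequency bands (Hz).
BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "low_gamma": (30.0, 50.0),
    "high_gamma": (50.0, 80.0),
}

N_WAVELETS = 40
FREQ_RANGE_HZ = (2.0, 80.0)
CYCLE_RANGE = (3.0, 10.0)


def _notch_taps(fs: float, notch_hz: float = 60.0, halfwidth_hz: float = 1.0,
                numtaps: int = 2001) -> np.ndarray:
    return signal.firwin(numtaps,
                         [notch_hz - halfwidth_hz, notch_hz + halfwidth_hz],
                         fs=fs, pass_zero="bandstop")


def preprocess_lfp(raw: np.ndarray, fs: float) -> np.ndarray:
    """Anti-aliased decimation to 1 kHz plus 60 Hz FIR notch.

    The notch is a symmetric linear-phase FIR applied centered (group delay
    compensated), attenuating 60 +/- 1 Hz by well over 20 dB.  Accepts a
    1-D trace or a (channels, samples) array; channel count is preserved.
    """
    if fs < TARGET_FS:
        raise ValueError("sampling rate must be >= 1 kHz")
    x = np.atleast_2d(np.asarray(raw, dtype=float))
    if not np.isclose(fs, TARGET_FS):
        from fractions import Fraction
        frac = Fraction(int(round(TARGET_FS)), int(round(fs)))
        x = signal.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    taps = _notch_taps(TARGET_FS)
    pad = taps.size // 2
    xp = np.pad(x, ((0, 0), (pad, pad)), mode="reflect")
    y = signal.fftconvolve(xp, taps[None, :], mode="same", axes=1)
    y = y[:, pad:-pad]
    return y[0] if np.asarray(raw).ndim == 1 else y


def epoch_lfp(lfp: np.ndarray, fs: float, onsets_s, window_s=(-0.3, 0.5)
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut (channels, trials, time) epochs around onsets.

    Returns ``(epochs, times, kept)``: ``times`` relative to onset and
    ``kept`` the indices of onsets whose epoch lies fully inside the
    recording (others are dropped).
    """
    lfp = np.atleast_2d(lfp)
    i_lo = int(round(window_s[0] * fs))
    i_hi = int(round(window_s[1] * fs))
    n = i_hi - i_lo
    times = (np.arange(n) + i_lo) / fs
    trials, kept = [], []
    for j, t in enumerate(np.asarray(onsets_s, dtype=float)):
        i0 = int(round(t * fs)) + i_lo
        if i0 < 0 or i0 + n > lfp.shape[1]:
            continue
        trials.append(lfp[:, i0:i0 + n])
        kept.append(j)
    if not trials:
        raise ValueError("no complete epochs inside the recording")
    return np.stack(trials, axis=1), times, np.asarray(kept, dtype=int)


def find_layer4_channel(trial_avg_lfp: np.ndarray, times_s: np.ndarray,
                        window_s: tuple[float, float] = (0.0, 0.1)) -> int:
    """Channel with the strongest negative deflection 0-100 ms post-onset.

    Ties are broken toward the lower channel index (the shallower contact
    under the depth-ordered convention).  All-flat input is degenerate.
    """
    avg = np.atleast_2d(trial_avg_lfp)
    mask = (times_s >= window_s[0]) & (times_s <= window_s[1])
    if not mask.any():
        raise ValueError("0-100 ms window not covered by the epoch")
    seg = avg[:, mask]
    if np.allclose(seg, seg.flat[0]):
        raise ValueError("degenerate input: no deflection on any channel")
    return int(np.argmin(seg.min(axis=1)))


def vep_metrics(epochs: np.ndarray, times_s: np.ndarray,
                labels, conditions=None) -> dict[str, dict[str, float]]:
    """Per-condition VEP amplitudes from layer-4 epochs (trials, time).

    After subtracting the pre-onset mean of the trial-averaged trace:
    ``peak_neg`` is the minimum within 0.05-0.5 s and ``late_mean`` the mean
    within 0.2-0.5 s.  Conditions absent from ``labels`` are skipped with a
    log entry.
    """
    epochs = np.asarray(epochs, dtype=float)
    labels = np.asarray(labels)
    if conditions is None:
        conditions = list(dict.fromkeys(labels.tolist()))
    pre = times_s < 0.0
    peak_win = (times_s >= 0.05) & (times_s <= 0.5)
    late_win = (times_s >= 0.2) & (times_s <= 0.5)
    out: dict[str, dict[str, float]] = {}
    for cond in conditions:
        sel = labels == cond
        if not sel.any():
            logger.info("vep_metrics: condition %s missing, skipped", cond)
            continue
        avg = epochs[sel].mean(axis=0)
        avg = avg - avg[pre].mean()
        out[str(cond)] = {"peak_neg": float(avg[peak_win].min()),
                          "late_mean": float(avg[late_win].mean()),
                          "n_trials": int(sel.sum())}
    return out


@dataclass
class TFRResult:
    """Time-frequency power, dB relative to a pre-stimulus baseline."""

    freqs_hz: np.ndarray          # 40 log-spaced centers, 2-80 Hz
    cycles: np.ndarray            # per-frequency wavelet cycles, 3-10
    times_s: np.ndarray
    power_db: np.ndarray          # (freqs, times), dB re baseline
    baseline_window_s: tuple[float, float]
    power: np.ndarray = field(default=None)      # linear power, same shape
    edge_unreliable_s: np.ndarray = field(default=None)  # per-freq half width


def _morlet(f: float, cycles: float, fs: float) -> np.ndarray:
    sd = cycles / (2.0 * np.pi * f)
    half = int(np.ceil(4.0 * sd * fs))
    t = np.arange(-half, half + 1) / fs
    wav = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2 * sd ** 2))
    return wav / np.sum(np.abs(wav))


def wavelet_tfr(trace: np.ndarray, times_s: np.ndarray, fs: float = TARGET_FS,
                baseline_window_s: tuple[float, float] = (-0.3, 0.0)
                ) -> TFRResult:
    """40-wavelet Morlet TFR of one (typically trial-averaged) trace.

    Centers are log-spaced over 2-80 Hz; cycles log-interpolated 3-10.
    Power is ``10*log10(P / mean baseline P per frequency)``.  The trace is
    reflection-padded; the first/last half-wavelet per frequency is flagged
    unreliable via ``edge_unreliable_s``.
    """
    trace = np.asarray(trace, dtype=float)
    freqs = np.logspace(*np.log10(FREQ_RANGE_HZ), N_WAVELETS)
    cycles = np.logspace(*np.log10(CYCLE_RANGE), N_WAVELETS)
    bmask = (times_s >= baseline_window_s[0]) & (times_s < baseline_window_s[1])
    if not bmask.any():
        raise ValueError("baseline window is empty")
    power = np.empty((N_WAVELETS, trace.size))
    edges = np.empty(N_WAVELETS)
    for i, (f, c) in enumerate(zip(freqs, cycles)):
        wav = _morlet(f, c, fs)
        if wav.size > trace.size:
            raise ValueError("trace shorter than the longest wavelet")
        half = wav.size // 2
        padded = np.pad(trace, half, mode="reflect")
        conv = signal.fftconvolve(padded, wav, mode="same")[half:-half]
        power[i] = np.abs(conv) ** 2
        edges[i] = half / fs
    base = power[:, bmask].mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        power_db = 10.0 * np.log10(power / base)
    return TFRResult(freqs, cycles, np.asarray(times_s), power_db,
                     baseline_window_s, power, edges)


def band_power(tfr: TFRResult, bands: dict[str, tuple[float, float]] = None,
               window_s: tuple[float, float] = (0.05, 0.5)
               ) -> dict[str, float]:
    """Mean dB power per band within ``window_s`` (default 0.05-0.5 s)."""
    bands = bands if bands is not None else BANDS
    tmask = (tfr.times_s >= window_s[0]) & (tfr.times_s <= window_s[1])
    if not tmask.any():
        raise ValueError("window outside the epoch")
    out = {}
    for name, (lo, hi) in bands.items():
        if hi <= tfr.freqs_hz[0] or lo >= tfr.freqs_hz[-1] or lo >= hi:
            raise ValueError(f"band {name} ({lo}-{hi} Hz) outside the "
                             f"{tfr.freqs_hz[0]:.0f}-{tfr.freqs_hz[-1]:.0f} Hz "
                             "wavelet range")
        fmask = (tfr.freqs_hz >= lo) & (tfr.freqs_hz <= hi)
        out[name] = float(tfr.power_db[np.ix_(fmask, tmask)].mean())
    return out
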