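"""Spatial-frequency filtered noise stimuli and trial sequences.

Stimuli are white-noise images bandpass filtered in the 2-D Fourier plane
with an isotropic Butterworth magnitude response (order 10), expressed in
cycles/degree through a small-angle pixel-to-degree mapping.  Six octave-wide
bands centered at 0.0075-0.24 cpd tile the tested range without overlap.

Three sequence generators build the session blocks:

* tuning ("many standards"): 6 bands x 20 repeats, pseudorandom order,
  inter-trial interval of at least 4 s, fresh noise frame every trial;
* oddball: one SF (0.03 cpd), frequent standard (p = 0.875) with a frozen
  texture and rare deviant (p = 0.125) whose texture changes every time;
* omission: periodic presentation (0.5 s stimulus + 1.7 s ISI) with every
  eighth slot withheld.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (ODDBALL_SF_CPD, SF_CENTERS_CPD, STIMULUS_DURATION_S,
                   Condition, StimulusEvent, StimulusSequence)

__all__ = ["SFBand", "ViewingGeometry", "canonical_bands", "make_sf_frame",
           "make_tuning_sequence", "make_oddball_sequence",
           "make_omission_sequence", "make_session_sequence"]

MAX_SESSION_TRIALS = 520


@dataclass(frozen=True)
class SFBand:
    """One spatial-frequency band (cycles/degree)."""

    center_cpd: float
    low_cpd: float
    high_cpd: float

    def __post_init__(self) -> None:
        if not 0 < self.low_cpd < self.center_cpd < self.high_cpd:
            raise ValueError("band edges must satisfy 0 < low < center < high")


def canonical_bands() -> list[SFBand]:
    """The six octave-wide bands centered at the canonical SF values.

    With centers spaced one octave apart and edges at center / sqrt(2) and
    center * sqrt(2), adjacent bands touch but do not overlap.
    """
    r = math.sqrt(2.0)
    return [SFBand(c, c / r, c * r) for c in SF_CENTERS_CPD]


@dataclass(frozen=True)
class ViewingGeometry:
    """Monitor geometry for the degree <-> pixel conversion.

    Small-angle mapping at screen center: one pixel subtends
    ``(screen_width_cm / resolution_px[1]) / distance_cm`` radians.
    Defaults describe a 22-inch monitor 17 cm from the eyes.
    """

    distance_cm: float = 17.0
    screen_width_cm: float = 47.6
    resolution_px: tuple[int, int] = (1050, 1680)  # (h, w)

    @property
    def degrees_per_pixel(self) -> float:
        cm_per_px = self.screen_width_cm / self.resolution_px[1]
        return math.degrees(cm_per_px / self.distance_cm)

    @property
    def nyquist_cpd(self) -> float:
        return 0.5 / self.degrees_per_pixel

    @property
    def max_radial_cpd(self) -> float:
        """Largest representable radial frequency (2-D plane corner)."""
        return math.sqrt(2.0) * self.nyquist_cpd


def _butterworth_bandpass(f_cpd: np.ndarray, band: SFBand, order: int
                          ) -> np.ndarray:
    """Isotropic Butterworth bandpass magnitude on a radial frequency grid."""
    with np.errstate(divide="ignore"):
        lowpass = 1.0 / np.sqrt(1.0 + (f_cpd / band.high_cpd) ** (2 * order))
        ratio = np.where(f_cpd > 0, band.low_cpd / np.maximum(f_cpd, 1e-30),
                         np.inf)
        highpass = 1.0 / np.sqrt(1.0 + ratio ** (2 * order))
    highpass = np.where(f_cpd == 0, 0.0, highpass)
    return lowpass * highpass


def make_sf_frame(seed: int, size_px: tuple[int, int], band: SFBand,
                  geometry: ViewingGeometry | None = None, order: int = 10,
                  design_margin: float = 1.15) -> np.ndarray:
    """One SF-bandpass-filtered noise frame, grayscale in [0, 1].

    Deterministic for a fixed ``seed``.  The Butterworth cutoffs are inset
    from the nominal band edges by ``design_margin`` so the half-power
    skirts fall inside the band (>= 90% of non-DC spectral energy stays in
    [low, high] at order 10).  The filtered image is z-scored, mapped so
    that +/-3 SD spans [0, 1] (mean luminance 0.5) and clipped.
    """
    geometry = geometry or ViewingGeometry()
    h, w = size_px
    if h < 16 or w < 16:
        raise ValueError("frame must be at least 16 x 16 pixels")
    if band.high_cpd > geometry.max_radial_cpd:
        raise ValueError(
            f"band upper edge {band.high_cpd} cpd beyond the representable "
            f"range (Nyquist {geometry.nyquist_cpd:.3f} cpd)")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((h, w))
    dpp = geometry.degrees_per_pixel
    fy = np.fft.fftfreq(h, d=dpp)
    fx = np.fft.fftfreq(w, d=dpp)
    f = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    design = SFBand(band.center_cpd, band.low_cpd * design_margin,
                    band.high_cpd / design_margin)
    filt = _butterworth_bandpass(f, design, order)
    img = np.fft.ifft2(np.fft.fft2(noise) * filt).real
    sd = img.std()
    if sd > 0:
        img = (img - img.mean()) / sd
    return np.clip(0.5 + img / 6.0, 0.0, 1.0)


def in_band_energy_fraction(frame: np.ndarray, band: SFBand,
                            geometry: ViewingGeometry | None = None) -> float:
    """Fraction of non-DC 2-D spectral energy inside [low, high] cpd."""
    geometry = geometry or ViewingGeometry()
    h, w = frame.shape
    dpp = geometry.degrees_per_pixel
    fy = np.fft.fftfreq(h, d=dpp)
    fx = np.fft.fftfreq(w, d=dpp)
    f = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    power = np.abs(np.fft.fft2(frame)) ** 2
    power[0, 0] = 0.0
    inside = (f >= band.low_cpd) & (f <= band.high_cpd)
    total = power.sum()
    return float(power[inside].sum() / total) if total > 0 else 0.0


def radial_spectral_centroid(frame: np.ndarray,
                             geometry: ViewingGeometry | None = None) -> float:
    """Power-weighted mean radial frequency (cpd) of a frame's spectrum."""
    geometry = geometry or ViewingGeometry()
    h, w = frame.shape
    dpp = geometry.degrees_per_pixel
    fy = np.fft.fftfreq(h, d=dpp)
    fx = np.fft.fftfreq(w, d=dpp)
    f = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    power = np.abs(np.fft.fft2(frame)) ** 2
    power[0, 0] = 0.0
    return float((f * power).sum() / power.sum())


def _fresh_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def make_tuning_sequence(bands: list[SFBand] | None = None, reps: int = 20,
                         iti_min_s: float = 4.0, seed: int = 0,
                         t_start_s: float = 0.0) -> StimulusSequence:
    """Many-standards tuning block: each band ``reps`` times, shuffled.

    Successive onsets are at least ``duration + iti_min_s`` apart (a small
    uniform jitter up to 0.5 s is added to the minimum gap).  A fresh noise
    seed is drawn for every trial.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    bands = bands if bands is not None else canonical_bands()
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(bands)), reps)
    rng.shuffle(labels)
    events = []
    t = t_start_s
    for lab in labels:
        band = bands[int(lab)]
        events.append(StimulusEvent(t, STIMULUS_DURATION_S, Condition.TUNING,
                                    band.center_cpd, _fresh_seed(rng),
                                    "tuning"))
        t += STIMULUS_DURATION_S + iti_min_s + rng.uniform(0.0, 0.5)
    return StimulusSequence(events, {"block": "tuning", "reps": reps,
                                     "iti_min_s": iti_min_s, "seed": seed})


def make_oddball_sequence(n_trials: int = 200, sf: float = ODDBALL_SF_CPD,
                          p_dev: float = 0.125, seed: int = 0,
                          t_start_s: float = 0.0) -> StimulusSequence:
    """Oddball block: frequent STD, rare DEV at the same spatial frequency.

    Exactly ``n_trials * p_dev`` deviants are placed among slots 1..n-1 with
    no two deviants adjacent, so every DEV is preceded by an STD (needed by
    the pre-DEV trial-matching rule downstream).  The STD texture seed is
    frozen for the whole block; each DEV draws a fresh seed.  Onset-to-onset
    gaps are ``0.5 (stimulus) + 0.5 + U(0.5, 1.2)`` seconds.
    """
    n_dev_f = n_trials * p_dev
    n_dev = int(round(n_dev_f))
    if abs(n_dev_f - n_dev) > 1e-9:
        raise ValueError("n_trials * p_dev must be an integer")
    rng = np.random.default_rng(seed)
    if n_dev > (n_trials - 1 + 1) // 2:
        raise ValueError("too many deviants to avoid adjacency")
    # sample DEV slots from 1..n-1 without adjacency by rejection
    for _ in range(10_000):
        slots = np.sort(rng.choice(np.arange(1, n_trials), size=n_dev,
                                   replace=False))
        if n_dev < 2 or np.all(np.diff(slots) >= 2):
            break
    else:  # pragma: no cover - rejection virtually always succeeds
        raise RuntimeError("failed to place deviants without adjacency")
    is_dev = np.zeros(n_trials, dtype=bool)
    is_dev[slots] = True
    std_seed = _fresh_seed(rng)
    events = []
    t = t_start_s
    for k in range(n_trials):
        if is_dev[k]:
            events.append(StimulusEvent(t, STIMULUS_DURATION_S, Condition.DEV,
                                        sf, _fresh_seed(rng), "oddball"))
        else:
            events.append(StimulusEvent(t, STIMULUS_DURATION_S, Condition.STD,
                                        sf, std_seed, "oddball"))
        t += STIMULUS_DURATION_S + 0.5 + rng.uniform(0.5, 1.2)
    return StimulusSequence(events, {"block": "oddball", "n_trials": n_trials,
                                     "p_dev": p_dev, "sf": sf, "seed": seed})


def make_omission_sequence(n_trials: int = 200, omit_every: int = 8,
                           isi_s: float = 1.7, sf: float = ODDBALL_SF_CPD,
                           seed: int = 0, t_start_s: float = 0.0
                           ) -> StimulusSequence:
    """Omission block: fixed-period stimulation, every ``omit_every``-th slot
    withheld.

    Slots are exactly ``0.5 + isi_s`` seconds apart; slot indices
    ``omit_every, 2*omit_every, ...`` (1-based) are OMIS events with no frame.
    """
    if omit_every < 2:
        raise ValueError("omit_every must be >= 2")
    rng = np.random.default_rng(seed)
    period = STIMULUS_DURATION_S + isi_s
    events = []
    for k in range(n_trials):
        t = t_start_s + k * period
        if (k + 1) % omit_every == 0:
            events.append(StimulusEvent(t, STIMULUS_DURATION_S, Condition.OMIS,
                                        None, None, "omission"))
        else:
            events.append(StimulusEvent(t, STIMULUS_DURATION_S, Condition.STD,
                                        sf, _fresh_seed(rng), "omission"))
    return StimulusSequence(events, {"block": "omission", "n_trials": n_trials,
                                     "omit_every": omit_every, "isi_s": isi_s,
                                     "seed": seed})


def make_session_sequence(seed: int = 0, inter_block_gap_s: float = 10.0,
                          include_omission: bool = True) -> StimulusSequence:
    """Full session: tuning + oddball (+ omission) blocks, <= 520 trials."""
    rng = np.random.default_rng(seed)
    s1, s2, s3 = (int(rng.integers(0, 2**31 - 1)) for _ in range(3))
    tuning = make_tuning_sequence(seed=s1)
    t = tuning.events[-1].onset_s + STIMULUS_DURATION_S + inter_block_gap_s
    oddball = make_oddball_sequence(seed=s2, t_start_s=t)
    seq = tuning + oddball
    if include_omission:
        t = oddball.events[-1].onset_s + STIMULUS_DURATION_S + inter_block_gap_s
        omission = make_omission_sequence(seed=s3, t_start_s=t)
        seq = seq + omission
    if len(seq) > MAX_SESSION_TRIALS:
        raise ValueError("session exceeds the 520-trial layout")
    seq.config["seed"] = seed
    return seq
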