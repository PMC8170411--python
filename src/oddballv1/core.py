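"""Shared data model for laminar V1 oddball sessions.

A session is a :class:`Recording`: a multi-channel LFP array with per-channel
cortical depths, a set of curated single units (:class:`UnitRecord`), and an
ordered event table (:class:`StimulusSequence`) labelling every trial as a
tuning stimulus (TUNING), oddball standard (STD) or deviant (DEV), omission
slot (OMIS), or many-standards control (CTR).  All times are seconds (float),
depths are micrometres with 0 at the pia and increasing downward.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("oddballv1")

#: Duration of every presented stimulus, seconds.
STIMULUS_DURATION_S = 0.5

#: Spatial frequency of the oddball (STD/DEV) stimulus, cycles/degree.
ODDBALL_SF_CPD = 0.03

#: The six octave-spaced spatial-frequency band centers, cycles/degree.
SF_CENTERS_CPD = (0.0075, 0.015, 0.03, 0.06, 0.12, 0.24)


class Condition(str, enum.Enum):
    """Trial condition label."""

    TUNING = "TUNING"
    STD = "STD"
    DEV = "DEV"
    OMIS = "OMIS"
    CTR = "CTR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class StimulusEvent:
    """One trial event.

    Parameters
    ----------
    onset_s : float
        Stimulus onset, seconds from session start.
    duration_s : float
        Presentation duration (0.5 s for all presented stimuli; omission
        slots carry the expected duration of the withheld stimulus).
    condition : Condition
        Trial label.
    sf_cpd : float or None
        Spatial frequency band center in cycles/degree; ``None`` for
        omission slots.
    frame_seed : int or None
        Noise seed used to synthesise the stimulus frame; ``None`` for
        omission slots.
    block : str
        Originating block: ``"tuning"``, ``"oddball"`` or ``"omission"``.
    """

    onset_s: float
    duration_s: float
    condition: Condition
    sf_cpd: float | None
    frame_seed: int | None
    block: str

    def __post_init__(self) -> None:
        if self.condition is Condition.OMIS:
            if self.frame_seed is not None:
                raise ValueError("omission events carry no frame seed")
        elif self.frame_seed is None:
            raise ValueError("presented stimuli require a frame seed")


@dataclass
class StimulusSequence:
    """Ordered trial events plus the generating parameters."""

    events: list[StimulusEvent]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        onsets = np.asarray([e.onset_s for e in self.events])
        if len(onsets) > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def __add__(self, other: "StimulusSequence") -> "StimulusSequence":
        return StimulusSequence(list(self.events) + list(other.events),
                                {**self.config, **other.config})

    def to_frame(self) -> pd.DataFrame:
        """Event table as a DataFrame (one row per trial)."""
        return pd.DataFrame(
            {
                "onset_s": [e.onset_s for e in self.events],
                "duration_s": [e.duration_s for e in self.events],
                "condition": [e.condition.value for e in self.events],
                "sf_cpd": [e.sf_cpd if e.sf_cpd is not None else np.nan
                           for e in self.events],
                "frame_seed": [e.frame_seed if e.frame_seed is not None else -1
                               for e in self.events],
                "block": [e.block for e in self.events],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, config: dict | None = None
                   ) -> "StimulusSequence":
        events = []
        for row in df.itertuples(index=False):
            sf = None if np.isnan(row.sf_cpd) else float(row.sf_cpd)
            seed = None if int(row.frame_seed) < 0 else int(row.frame_seed)
            events.append(StimulusEvent(float(row.onset_s), float(row.duration_s),
                                        Condition(row.condition), sf, seed,
                                        str(row.block)))
        return cls(events, config or {})

    def select(self, *, block: str | None = None,
               condition: Condition | None = None,
               sf_cpd: float | None = None) -> "StimulusSequence":
        """Subset of events matching the given block/condition/SF."""
        ev = self.events
        if block is not None:
            ev = [e for e in ev if e.block == block]
        if condition is not None:
            ev = [e for e in ev if e.condition is condition]
        if sf_cpd is not None:
            ev = [e for e in ev if e.sf_cpd is not None
                  and np.isclose(e.sf_cpd, sf_cpd)]
        # subsets need not start at time zero; bypass the onset check (already valid)
        seq = object.__new__(StimulusSequence)
        seq.events = list(ev)
        seq.config = dict(self.config)
        return seq

    def onsets(self) -> np.ndarray:
        return np.asarray([e.onset_s for e in self.events], dtype=float)


@dataclass
class UnitRecord:
    """A curated single unit.

    ``template`` is the mean spike waveform on the unit's peak channel,
    sampled at ``template_fs`` Hz, trough-dominant.
    """

    unit_id: str
    spike_times_s: np.ndarray
    template: np.ndarray
    template_fs: float
    peak_channel: int
    depth_um: float
    n_spikes_per_block: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if np.any(np.diff(self.spike_times_s) < 0):
            raise ValueError(f"unit {self.unit_id}: spike times must be sorted")
        self.template = np.asarray(self.template, dtype=float)


@dataclass
class Recording:
    """A trial-aligned session: LFP + units + events.

    ``lfp`` has shape (n_channels, n_samples) in volts at ``lfp_fs`` Hz.
    ``channel_depth_um`` gives each channel's cortical depth and must be
    monotone along the probe.
    """

    lfp: np.ndarray
    lfp_fs: float
    channel_depth_um: np.ndarray
    units: list[UnitRecord]
    events: StimulusSequence
    genotype_label: str = ""

    def __post_init__(self) -> None:
        self.lfp = np.asarray(self.lfp)
        self.channel_depth_um = np.asarray(self.channel_depth_um, dtype=float)
        if self.lfp.ndim != 2:
            raise ValueError("lfp must be 2-D (channels x samples)")
        if self.lfp.shape[0] != self.channel_depth_um.size:
            raise ValueError("one depth per LFP channel required")
        d = np.diff(self.channel_depth_um)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("channel depths must be monotone along the probe")
        dur = self.duration_s
        for u in self.units:
            if u.spike_times_s.size and (
                    u.spike_times_s[0] < 0 or u.spike_times_s[-1] > dur):
                raise ValueError(
                    f"unit {u.unit_id}: spikes outside [0, {dur:.3f}] s")

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.lfp_fs

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]


@dataclass
class StatResult:
    """Outcome of one non-parametric comparison."""

    test_name: str
    statistic: float
    p_raw: float
    comparison: str
    n_a: int
    n_b: int
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_raw <= 1.0:
            raise ValueError("p_raw outside [0, 1]")
        if self.p_adjusted is not None:
            if self.p_adjusted < self.p_raw - 1e-12 or self.p_adjusted > 1.0:
                raise ValueError("p_adjusted must satisfy p_raw <= p_adj <= 1")


def epoch_spike_counts(spike_times_s: np.ndarray, onsets_s: Sequence[float],
                       window: tuple[float, float]) -> np.ndarray:
    """Per-trial spike counts in ``window`` (seconds relative to onset)."""
    spikes = np.asarray(spike_times_s, dtype=float)
    onsets = np.asarray(onsets_s, dtype=float)
    lo = np.searchsorted(spikes, onsets + window[0], side="left")
    hi = np.searchsorted(spikes, onsets + window[1], side="right")
    return (hi - lo).astype(int)


def epoch_rates(spike_times_s: np.ndarray, onsets_s: Sequence[float],
                window: tuple[float, float]) -> np.ndarray:
    """Per-trial mean firing rates (Hz) in ``window`` relative to onset."""
    width = window[1] - window[0]
    if width <= 0:
        raise ValueError("window must have positive width")
    return epoch_spike_counts(spike_times_s, onsets_s, window) / width
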