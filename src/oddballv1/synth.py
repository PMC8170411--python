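"""Ground-truth session simulator.

Generates laminar sessions whose units have known ("planted") tuning,
adaptation, mismatch, and omission properties so every analysis stage can be
validated without recorded data.  Two named parameter regimes, "wt" and
"fx", encode the qualitative population structure under study:

* adaptation spreads widely over spatial frequency in the wt regime
  (large octave spread) but is confined near the oddball SF in fx;
* mismatch gain is concentrated in superficial layers in wt but uniform
  across the column (and stronger in L4) in fx;
* the fx regime adds a late-window gain at the two highest SF bands.

The generative rate model is chosen so the analysis-side indices equal the
planted values in expectation.  With planted adaptation index
``s = a * exp(-d_oct^2 / (2 sigma_a^2))`` (``d_oct`` = octave distance from
preferred to oddball SF), standard-trial responses are scaled by
``(1 - s)/(1 + s)``, which makes iSSA = (CTR-STD)/(CTR+STD) = s exactly.
With mismatch boost ``b``, deviant late-window rates are ``(1 + b)`` times
standard late rates, so iMM = b / (2 + b).  Spikes are drawn from the exact
inhomogeneous Poisson process implied by the piecewise rate profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (ODDBALL_SF_CPD, Condition, Recording, StimulusSequence,
                   UnitRecord)
from .stimgen import make_session_sequence
from .tuning import PREF_SF_GRID_CPD, dog_model

__all__ = ["UnitGroundTruth", "RegimeConfig", "wt_regime", "fx_regime",
           "recovery_regime", "simulate_units", "simulate_session",
           "simulate_experiment", "ground_truth_frame", "make_template"]

LAYERS = ("L2/3", "L4", "L5/6")
MOTIFS = ("early", "mid", "late", "inhibited", "none")

#: Peak-latency (s) and width (s) of the three excitatory omission motifs.
MOTIF_LATENCY_S = {"early": 0.12, "mid": 0.27, "late": 0.42}
MOTIF_WIDTH_S = 0.06


@dataclass(frozen=True)
class UnitGroundTruth:
    """Planted generative parameters of one simulated unit."""

    unit_id: str
    r0: float                 # baseline rate, Hz
    ke: float
    ki: float
    mu_e: float
    mu_i: float
    sigma_e: float
    sigma_i: float
    flat_evoked_hz: float     # >0 for SF-flat (untuned-by-construction) units
    pref_sf_cpd: float
    cell_class: str           # RS | FS
    layer: str
    depth_um: float
    adapt_strength: float     # a in [0, 1]
    adapt_spread_oct: float   # sigma_a, octaves
    mm_boost: float           # b >= 0, late-window DEV gain - 1
    late_frac: float          # late/early evoked amplitude ratio
    late_highsf_gain: float   # extra late gain at SF >= 0.12 cpd
    omission_motif: str
    motif_amp_hz: float       # bump amplitude (excitatory motifs)
    inhib_drop: float         # baseline thinning prob. (inhibited motif)

    def evoked_early_hz(self, sf_cpd: float) -> float:
        """Unadapted early-window evoked rate above baseline at ``sf_cpd``."""
        if self.flat_evoked_hz > 0:
            return self.flat_evoked_hz
        val = dog_model(sf_cpd, 0.0, self.ke, self.ki, self.mu_e, self.mu_i,
                        self.sigma_e, self.sigma_i)
        return float(max(val, 0.0))

    def evoked_late_hz(self, sf_cpd: float) -> float:
        gain = self.late_highsf_gain if sf_cpd >= 0.12 else 1.0
        return self.late_frac * gain * self.evoked_early_hz(sf_cpd)

    @property
    def planted_issa(self) -> float:
        d_oct = abs(np.log2(max(self.pref_sf_cpd, 1e-9) / ODDBALL_SF_CPD))
        if self.flat_evoked_hz > 0:
            d_oct = 0.0
        return float(self.adapt_strength
                     * np.exp(-d_oct ** 2 / (2.0 * self.adapt_spread_oct ** 2)))

    @property
    def planted_imm(self) -> float:
        return float(self.mm_boost / (2.0 + self.mm_boost))


@dataclass
class RegimeConfig:
    """Named population-parameter regime (documented defaults)."""

    name: str = "wt"
    fs_fraction: float = 0.2
    flat_fraction: float = 0.22        # SF-flat (untuned) units
    silent_fraction: float = 0.05      # visually unresponsive units
    depth_range_um: tuple[float, float] = (20.0, 950.0)
    layer_boundaries_um: dict = field(default_factory=lambda: {
        "L2/3": (0.0, 350.0), "L4": (350.0, 500.0), "L5/6": (500.0, 1000.0)})
    baseline_rate_hz: tuple[float, float] = (1.5, 5.0)
    evoked_peak_hz: tuple[float, float] = (8.0, 25.0)
    flat_evoked_hz: tuple[float, float] = (5.0, 12.0)
    pref_sf_range_cpd: tuple[float, float] = (0.005, 0.35)
    adapt_strength: tuple[float, float] = (0.4, 0.9)
    adapt_spread_oct_mean: float = 2.0
    adapt_spread_oct_sd: float = 0.3
    mm_boost_by_layer: dict = field(default_factory=lambda: {
        "L2/3": 1.2, "L4": 0.3, "L5/6": 0.3})
    late_frac: float = 0.4
    late_highsf_gain: float = 1.0
    motif_probs: dict = field(default_factory=lambda: {
        "early": 0.18, "mid": 0.12, "late": 0.08, "inhibited": 0.14,
        "none": 0.48})
    motif_amp_hz: dict = field(default_factory=lambda: {
        "early": 9.0, "mid": 6.0, "late": 5.0})
    inhib_drop: float = 0.7
    # LFP parameters
    n_channels: int = 64
    channel_spacing_um: float = 15.5
    l4_depth_um: float = 420.0
    sink_amp_v: float = 150e-6
    sink_sigma_um: float = 120.0
    noise_sd_v: float = 50e-6
    theta_amp_v: float = 10e-6
    theta_hz: float = 6.0
    lfp_fs: float = 1000.0


def wt_regime() -> RegimeConfig:
    """Wild-type-like regime: broad adaptation spread, superficial mismatch."""
    return RegimeConfig(name="wt")


def fx_regime() -> RegimeConfig:
    """Fragile-X-like regime: narrow adaptation spread, column-uniform
    mismatch with stronger L4, late high-SF gain, stronger mid/inhibited
    omission motifs."""
    return RegimeConfig(
        name="fx",
        adapt_spread_oct_mean=0.7,
        adapt_spread_oct_sd=0.15,
        mm_boost_by_layer={"L2/3": 1.0, "L4": 1.0, "L5/6": 1.0},
        late_highsf_gain=1.6,
        motif_probs={"early": 0.10, "mid": 0.16, "late": 0.12,
                     "inhibited": 0.14, "none": 0.48},
        motif_amp_hz={"early": 6.0, "mid": 9.0, "late": 6.0},
        inhib_drop=0.85,
    )


def recovery_regime(name: str = "wt") -> RegimeConfig:
    """Regime for planted-index recovery experiments.

    Every unit is SF-tuned near the oddball frequency (preferred SF within
    roughly one octave of 0.03 cpd) and visually responsive, so its response
    at the oddball SF — and hence its planted iSSA/iMM — is measurable.
    """
    base = wt_regime() if name == "wt" else fx_regime()
    return replace(base, name=name, flat_fraction=0.0, silent_fraction=0.0,
                   pref_sf_range_cpd=(0.018, 0.05),
                   evoked_peak_hz=(20.0, 40.0),
                   baseline_rate_hz=(0.5, 2.0),
                   adapt_strength=(0.2, 0.7),
                   late_frac=0.8,
                   n_channels=8)


def recovery_experiment(n_units: int, seed: int = 0, reps: int = 40,
                        n_oddball: int = 400, name: str = "wt"
                        ) -> tuple[list[UnitGroundTruth], Recording]:
    """Planted-index recovery setup: extended tuning + oddball blocks.

    Uses :func:`recovery_regime` units and a longer sequence (``reps``
    tuning repeats per band, ``n_oddball`` oddball trials) so the per-unit
    index estimates are precise enough to compare against planted values.
    """
    from .stimgen import make_oddball_sequence, make_tuning_sequence
    from .core import STIMULUS_DURATION_S

    rng = np.random.default_rng(seed)
    regime = recovery_regime(name)
    units = simulate_units(n_units, regime, int(rng.integers(2**31)))
    tuning_seq = make_tuning_sequence(reps=reps,
                                      seed=int(rng.integers(2**31)))
    t0 = tuning_seq.events[-1].onset_s + STIMULUS_DURATION_S + 10.0
    oddball_seq = make_oddball_sequence(n_trials=n_oddball,
                                        seed=int(rng.integers(2**31)),
                                        t_start_s=t0)
    rec = simulate_session(units, tuning_seq + oddball_seq, regime,
                           seed=int(rng.integers(2**31)))
    return units, rec


def _assign_layer(depth: float, boundaries: dict) -> str:
    for layer, (lo, hi) in boundaries.items():
        if lo <= depth < hi:
            return layer
    raise ValueError(f"depth {depth} outside layer boundaries")


def simulate_units(n_units: int, regime: RegimeConfig | None = None,
                   seed: int = 0) -> list[UnitGroundTruth]:
    """Draw a population of ground-truth units from a regime."""
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    regime = regime or wt_regime()
    if not np.isclose(sum(regime.motif_probs.values()), 1.0):
        raise ValueError("motif probabilities must sum to 1")
    if not 0.0 <= regime.fs_fraction <= 1.0:
        raise ValueError("fs_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    units = []
    motif_names = list(regime.motif_probs)
    motif_p = np.array([regime.motif_probs[m] for m in motif_names])
    for i in range(n_units):
        depth = rng.uniform(*regime.depth_range_um)
        layer = _assign_layer(depth, regime.layer_boundaries_um)
        cell_class = "FS" if rng.random() < regime.fs_fraction else "RS"
        silent = rng.random() < regime.silent_fraction
        flat = (not silent) and rng.random() < regime.flat_fraction
        r0 = rng.uniform(*regime.baseline_rate_hz)
        if flat or silent:
            ke = ki = 0.0
            mu_e = mu_i = 0.03
            sigma_e = sigma_i = 0.1
            flat_amp = 0.0 if silent else rng.uniform(*regime.flat_evoked_hz)
            pref = 0.03
        else:
            lo, hi = regime.pref_sf_range_cpd
            mu_e = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            sigma_e = min(mu_e * rng.uniform(0.4, 1.2), 1.0)
            ke = rng.uniform(*regime.evoked_peak_hz)
            ki = ke * rng.uniform(0.0, 0.4)
            mu_i = min(mu_e * rng.uniform(1.5, 3.0), 1.0)
            sigma_i = min(sigma_e * rng.uniform(1.5, 3.0), 1.0)
            flat_amp = 0.0
            curve = dog_model(PREF_SF_GRID_CPD, 0.0, ke, ki, mu_e, mu_i,
                              sigma_e, sigma_i)
            pref = float(PREF_SF_GRID_CPD[int(np.argmax(curve))])
        a = rng.uniform(*regime.adapt_strength)
        sigma_a = max(rng.normal(regime.adapt_spread_oct_mean,
                                 regime.adapt_spread_oct_sd), 0.1)
        b_mean = regime.mm_boost_by_layer[layer]
        b = float(rng.gamma(4.0, b_mean / 4.0))
        motif = "none" if silent else str(rng.choice(motif_names, p=motif_p))
        amp = regime.motif_amp_hz.get(motif, 0.0)
        amp = float(rng.gamma(6.0, amp / 6.0)) if amp > 0 else 0.0
        units.append(UnitGroundTruth(
            unit_id=f"{regime.name}_u{i:04d}", r0=r0, ke=ke, ki=ki,
            mu_e=mu_e, mu_i=mu_i, sigma_e=sigma_e, sigma_i=sigma_i,
            flat_evoked_hz=flat_amp, pref_sf_cpd=pref, cell_class=cell_class,
            layer=layer, depth_um=depth, adapt_strength=a,
            adapt_spread_oct=sigma_a, mm_boost=b, late_frac=regime.late_frac,
            late_highsf_gain=regime.late_highsf_gain, omission_motif=motif,
            motif_amp_hz=amp, inhib_drop=regime.inhib_drop))
    return units


def make_template(cell_class: str, fs: float = 30_000.0) -> np.ndarray:
    """Canonical RS/FS spike waveform (4 ms, trough-dominant).

    The trough is asymmetric (slow descent, fast repolarization) so
    trough-to-peak time and trough half-depth width are independently
    controllable.  RS: trough-to-peak 0.7 ms, trough FWHM ~1.6 ms;
    FS: 0.3 ms and ~0.8 ms.
    """
    if cell_class == "RS":
        ttp_ms, width_ms = 0.7, 1.6
    elif cell_class == "FS":
        ttp_ms, width_ms = 0.3, 0.8
    else:
        raise ValueError(f"unknown cell class {cell_class!r}")
    t = np.arange(0.0, 4.0, 1000.0 / fs)  # ms
    trough_t = 1.6
    half_right = min(0.25, 0.4 * ttp_ms)
    sigma_l = (width_ms - half_right) / 1.1774
    sigma_r = half_right / 1.1774
    sigma = np.where(t < trough_t, sigma_l, sigma_r)
    wf = -np.exp(-((t - trough_t) ** 2) / (2 * sigma ** 2))
    sigma_p = 0.3 * ttp_ms
    wf += 0.35 * np.exp(-((t - (trough_t + ttp_ms)) ** 2) / (2 * sigma_p ** 2))
    return wf


def _event_arrays(sequence: StimulusSequence):
    df = sequence.to_frame()
    return (df["onset_s"].to_numpy(), df["condition"].to_numpy(),
            df["sf_cpd"].to_numpy(), df["block"].to_numpy())


def _adaptation_multipliers(conditions: np.ndarray, blocks: np.ndarray,
                            s: float, tau_trials: float = 2.0) -> np.ndarray:
    """Per-event multiplicative adaptation factor.

    Within the oddball and omission blocks the factor decays from 1 (first
    trial) towards the steady state ``(1 - s)/(1 + s)`` with a time constant
    of ``tau_trials`` presented trials; the tuning block (ITI >= 4 s) is
    unadapted.
    """
    m_ss = (1.0 - s) / (1.0 + s)
    mult = np.ones(conditions.size)
    for block in ("oddball", "omission"):
        idx = np.flatnonzero((blocks == block)
                             & (conditions != Condition.OMIS.value))
        k = np.arange(idx.size, dtype=float)
        mult[idx] = m_ss + (1.0 - m_ss) * np.exp(-k / tau_trials)
    return mult


def _unit_spikes(unit: UnitGroundTruth, sequence: StimulusSequence,
                 duration_s: float, rng: np.random.Generator) -> np.ndarray:
    onsets, conds, sfs, blocks = _event_arrays(sequence)
    spikes = []

    # homogeneous baseline
    n_base = rng.poisson(unit.r0 * duration_s)
    base = rng.uniform(0.0, duration_s, size=n_base)

    s = unit.planted_issa
    adapt = _adaptation_multipliers(conds, blocks, s)

    presented = conds != Condition.OMIS.value
    e_amp = np.array([unit.evoked_early_hz(sf) if p else 0.0
                      for sf, p in zip(sfs, presented)])
    l_amp = np.array([unit.evoked_late_hz(sf) if p else 0.0
                      for sf, p in zip(sfs, presented)])
    e_amp = e_amp * adapt
    l_amp = l_amp * adapt
    l_amp[conds == Condition.DEV.value] *= (1.0 + unit.mm_boost)

    # early window [0.05, 0.2), late [0.2, 0.5): exact piecewise-constant
    # Poisson sampling (counts + uniform times)
    n_early = rng.poisson(e_amp * 0.15)
    n_late = rng.poisson(l_amp * 0.30)
    for k in np.flatnonzero(n_early + n_late):
        if n_early[k]:
            spikes.append(onsets[k] + rng.uniform(0.05, 0.2, n_early[k]))
        if n_late[k]:
            spikes.append(onsets[k] + rng.uniform(0.2, 0.5, n_late[k]))

    # omission motifs
    omis_idx = np.flatnonzero(conds == Condition.OMIS.value)
    if unit.omission_motif in MOTIF_LATENCY_S and omis_idx.size:
        t0 = MOTIF_LATENCY_S[unit.omission_motif]
        area = unit.motif_amp_hz * MOTIF_WIDTH_S * np.sqrt(2 * np.pi)
        counts = rng.poisson(area, size=omis_idx.size)
        for k, c in zip(omis_idx, counts):
            if c:
                tt = rng.normal(t0, MOTIF_WIDTH_S, c)
                tt = tt[(tt >= 0.0) & (tt <= 0.5)]
                spikes.append(onsets[k] + tt)
    elif unit.omission_motif == "inhibited" and omis_idx.size:
        keep = np.ones(base.size, dtype=bool)
        for k in omis_idx:
            in_win = (base >= onsets[k] + 0.05) & (base <= onsets[k] + 0.45)
            drop = in_win & (rng.random(base.size) < unit.inhib_drop)
            keep &= ~drop
        base = base[keep]

    spikes.append(base)
    out = np.concatenate(spikes) if spikes else np.empty(0)
    out = out[(out >= 0.0) & (out <= duration_s)]
    return np.sort(out)


def _lfp_kernel(fs: float) -> np.ndarray:
    """Biphasic evoked LFP kernel (unit peak-negative amplitude)."""
    t = np.arange(0.0, 0.2, 1.0 / fs)
    tau1, tau2 = 0.030, 0.050
    sink = -(t / tau1) * np.exp(1.0 - t / tau1)
    src = 0.35 * ((t - 0.08) / tau2) * np.exp(1.0 - (t - 0.08) / tau2)
    src[t < 0.08] = 0.0
    k = sink + src
    return k / np.abs(k.min())


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    from scipy import fft as sfft

    nfast = sfft.next_fast_len(n, real=True)
    white = rng.standard_normal(nfast)
    spec = sfft.rfft(white)
    f = np.fft.rfftfreq(nfast, d=1.0)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    pink = sfft.irfft(spec * scale, n=nfast)[:n]
    sd = pink.std()
    return pink / sd if sd > 0 else pink


def simulate_session(units: list[UnitGroundTruth],
                     sequence: StimulusSequence | None = None,
                     regime: RegimeConfig | None = None,
                     seed: int = 0) -> Recording:
    """Assemble a full Recording for a unit population.

    LFP: per-channel pink noise + ongoing theta + a stimulus-evoked biphasic
    kernel whose (negative) amplitude is a Gaussian of depth centered on the
    planted L4 depth.  Spike trains follow the generative rate model (module
    docstring).  Reproducible for a fixed master seed: per-unit and LFP
    streams are spawned from it.
    """
    if not units:
        raise ValueError("unit list must not be empty")
    regime = regime or wt_regime()
    master = np.random.default_rng(seed)
    if sequence is None:
        sequence = make_session_sequence(seed=int(master.integers(2**31)))
    duration = float(sequence.events[-1].onset_s + 3.0)
    fs = regime.lfp_fs
    n_samples = int(round(duration * fs))

    depths = regime.channel_spacing_um * np.arange(regime.n_channels) + 20.0
    lfp = np.empty((regime.n_channels, n_samples), dtype=np.float32)
    lfp_rng = np.random.default_rng(master.integers(2**31))
    phase = lfp_rng.uniform(0, 2 * np.pi)
    tvec = np.arange(n_samples) / fs
    theta = regime.theta_amp_v * np.sin(2 * np.pi * regime.theta_hz * tvec
                                        + phase)
    for ch in range(regime.n_channels):
        lfp[ch] = (regime.noise_sd_v * _pink_noise(n_samples, lfp_rng)
                   + theta).astype(np.float32)

    kernel = _lfp_kernel(fs)
    depth_profile = regime.sink_amp_v * np.exp(
        -((depths - regime.l4_depth_um) ** 2) / (2 * regime.sink_sigma_um ** 2))
    cond_gain = {Condition.TUNING.value: 1.0, Condition.CTR.value: 1.0,
                 Condition.STD.value: 0.6, Condition.DEV.value: 0.8}
    onsets, conds, _, _ = _event_arrays(sequence)
    for onset, cond in zip(onsets, conds):
        if cond == Condition.OMIS.value:
            continue
        i0 = int(round(onset * fs))
        i1 = min(i0 + kernel.size, n_samples)
        lfp[:, i0:i1] += (cond_gain[cond]
                          * depth_profile[:, None]
                          * kernel[: i1 - i0]).astype(np.float32)

    records = []
    block_windows = _block_windows(sequence)
    for unit in units:
        u_rng = np.random.default_rng(master.integers(2**31))
        spikes = _unit_spikes(unit, sequence, duration, u_rng)
        template = make_template(unit.cell_class)
        peak_ch = int(np.argmin(np.abs(depths - unit.depth_um)))
        n_per_block = {blk: int(np.sum((spikes >= lo) & (spikes < hi)))
                       for blk, (lo, hi) in block_windows.items()}
        records.append(UnitRecord(unit.unit_id, spikes, template, 30_000.0,
                                  peak_ch, unit.depth_um, n_per_block))

    return Recording(lfp, fs, depths, records, sequence,
                     genotype_label=regime.name.upper())


def _block_windows(sequence: StimulusSequence) -> dict:
    df = sequence.to_frame()
    out = {}
    for blk, grp in df.groupby("block"):
        out[blk] = (float(grp["onset_s"].min()) - 1.0,
                    float(grp["onset_s"].max()) + 1.0)
    return out


def simulate_experiment(n_units: int = 200, seed: int = 0
                        ) -> tuple[Recording, Recording,
                                   list[UnitGroundTruth],
                                   list[UnitGroundTruth]]:
    """One wt-like and one fx-like session with matched unit counts."""
    rng = np.random.default_rng(seed)
    wt_units = simulate_units(n_units, wt_regime(), int(rng.integers(2**31)))
    fx_units = simulate_units(n_units, fx_regime(), int(rng.integers(2**31)))
    wt = simulate_session(wt_units, regime=wt_regime(),
                          seed=int(rng.integers(2**31)))
    fx = simulate_session(fx_units, regime=fx_regime(),
                          seed=int(rng.integers(2**31)))
    return wt, fx, wt_units, fx_units


def motif_traces(n_per_motif: int, snr: float = 3.0, seed: int = 0,
                 motifs: tuple[str, ...] = ("early", "mid", "late",
                                            "inhibited"),
                 n_bins: int = 45,
                 window_s: tuple[float, float] = (0.05, 0.5)
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Noisy omission-trace population built from the temporal motifs.

    Each row emulates a z-scored, trial-averaged, kernel-smoothed PSTH on
    the clustering grid: a unit-peak motif template (Gaussian bump at the
    motif latency; negative plateau for "inhibited") times an amplitude
    jitter, plus white noise of pre-smoothing SD ``1/snr``; both signal and
    noise are then smoothed with the PSTH kernel (FWHM 100 ms), as the
    analysis pipeline's traces are.  Returns ``(traces, motif_labels)``.
    """
    from scipy.ndimage import gaussian_filter1d

    rng = np.random.default_rng(seed)
    t = np.linspace(window_s[0], window_s[1], n_bins)
    dt = (window_s[1] - window_s[0]) / (n_bins - 1)
    sigma_bins = 0.100 / 2.3548 / dt
    templates = {}
    for m in motifs:
        if m == "inhibited":
            tpl = -1.0 / (1.0 + np.exp(-(t - 0.15) / 0.03))
        elif m == "none":
            tpl = np.zeros_like(t)
        else:
            tpl = np.exp(-((t - MOTIF_LATENCY_S[m]) ** 2)
                         / (2 * MOTIF_WIDTH_S ** 2))
        templates[m] = gaussian_filter1d(tpl, sigma_bins, mode="nearest")
    rows, labels = [], []
    for m in motifs:
        for _ in range(n_per_motif):
            amp = rng.uniform(0.7, 1.3)
            noise = gaussian_filter1d(rng.normal(0.0, 1.0 / snr, n_bins),
                                      sigma_bins, mode="nearest")
            rows.append(amp * templates[m] + noise)
            labels.append(m)
    return np.asarray(rows), np.asarray(labels)


def ground_truth_frame(units: list[UnitGroundTruth]) -> pd.DataFrame:
    """Planted parameters as a table (written beside sessions for tests)."""
    rows = []
    for u in units:
        rows.append({
            "unit_id": u.unit_id, "r0": u.r0, "ke": u.ke, "ki": u.ki,
            "mu_e": u.mu_e, "mu_i": u.mu_i, "sigma_e": u.sigma_e,
            "sigma_i": u.sigma_i, "flat_evoked_hz": u.flat_evoked_hz,
            "pref_sf_cpd": u.pref_sf_cpd, "cell_class": u.cell_class,
            "layer": u.layer, "depth_um": u.depth_um,
            "adapt_strength": u.adapt_strength,
            "adapt_spread_oct": u.adapt_spread_oct, "mm_boost": u.mm_boost,
            "omission_motif": u.omission_motif,
            "planted_issa": u.planted_issa, "planted_imm": u.planted_imm,
        })
    return pd.DataFrame(rows)
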