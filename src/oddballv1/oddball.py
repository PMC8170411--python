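"""Stimulus-specific adaptation (iSSA) and mismatch (iMM) indices.

For each visually excited unit::

    iSSA = (CTR - STD) / (CTR + STD)            windows 0.05-0.5 s
    iMM  = (DEVlate - STDlate) / (DEVlate + STDlate)   windows 0.2-0.5 s

where CTR is the baseline-corrected mean rate on the 0.03 cpd trials of the
many-standards tuning block, STD uses only the standard trials immediately
preceding each deviant (equalizing STD/DEV trial counts), and the late
quantities use the 0.2-0.5 s window.  Rows whose index denominator falls
below a floor are flagged and excluded from index statistics.  Group
contrasts (tuning group x layer x cell class x genotype) use Mann-Whitney
(magnitudes) and two-sample KS (distributions) with Benjamini-Hochberg
adjustment within each contrast family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (ODDBALL_SF_CPD, Condition, StimulusSequence, epoch_rates,
                   logger)
from .stats import StatResult, adjust_family, ks_two_sample, mann_whitney

__all__ = ["select_std_trials", "control_response", "compute_indices",
           "compare_indices", "ModulationIndexRow", "FULL_WINDOW_S",
           "LATE_WINDOW_S", "BASELINE_WINDOW_S", "DENOMINATOR_FLOOR_HZ"]

FULL_WINDOW_S = (0.05, 0.5)
LATE_WINDOW_S = (0.2, 0.5)
BASELINE_WINDOW_S = (-0.25, 0.05)
DENOMINATOR_FLOOR_HZ = 0.1


@dataclass
class ModulationIndexRow:
    """Per-unit modulation indices with stratification labels."""

    unit_id: str
    issa: float
    imm: float
    ctr_hz: float
    std_hz: float
    std_late_hz: float
    dev_late_hz: float
    issa_valid: bool
    imm_valid: bool
    tuning_group: str = ""
    layer: str = ""
    cell_class: str = ""
    genotype_label: str = ""


def select_std_trials(events: StimulusSequence) -> StimulusSequence:
    """The standard trials immediately preceding each deviant.

    Guarantees |STD subset| = |DEV trials|.  Raises if any deviant lacks a
    preceding standard (cannot happen with the in-package generator; guards
    external data).
    """
    oddball = events.select(block="oddball")
    ev = oddball.events
    picked = []
    for i, e in enumerate(ev):
        if e.condition is Condition.DEV:
            if i == 0 or ev[i - 1].condition is not Condition.STD:
                raise ValueError(
                    f"deviant at index {i} has no preceding standard")
            picked.append(ev[i - 1])
    sub = object.__new__(StimulusSequence)
    sub.events = picked
    sub.config = dict(oddball.config)
    return sub


def _baseline_corrected_rate(spike_times_s, onsets, window) -> float:
    evoked = epoch_rates(spike_times_s, onsets, window)
    base = epoch_rates(spike_times_s, onsets, BASELINE_WINDOW_S)
    return float(np.mean(evoked) - np.mean(base))


def control_response(spike_times_s, events: StimulusSequence,
                     sf: float = ODDBALL_SF_CPD,
                     window: tuple[float, float] = FULL_WINDOW_S) -> float:
    """Baseline-corrected mean rate on the tuning-block trials at the
    oddball SF (the many-standards control)."""
    ctr = events.select(block="tuning", sf_cpd=sf)
    if len(ctr) == 0:
        raise ValueError(f"no tuning trials at {sf} cpd")
    return _baseline_corrected_rate(spike_times_s, ctr.onsets(), window)


def modulation_index(a: float, b: float,
                     floor: float = DENOMINATOR_FLOOR_HZ
                     ) -> tuple[float, bool]:
    """(a - b) / (a + b) with a denominator floor.

    Returns ``(value, valid)``; ``valid`` is False when |a + b| < floor
    (the value is still reported for inspection, as nan if undefined).
    """
    denom = a + b
    if abs(denom) < floor:
        return (np.nan, False)
    return ((a - b) / denom, True)


def compute_indices(unit_id: str, spike_times_s, events: StimulusSequence,
                    sf: float = ODDBALL_SF_CPD) -> ModulationIndexRow:
    """iSSA and iMM for one unit from a session's event table."""
    std_pre_dev = select_std_trials(events)
    dev = events.select(block="oddball", condition=Condition.DEV)
    if len(dev) == 0:
        raise ValueError("no deviant trials in the oddball block")
    ctr = control_response(spike_times_s, events, sf)
    std = _baseline_corrected_rate(spike_times_s, std_pre_dev.onsets(),
                                   FULL_WINDOW_S)
    std_late = _baseline_corrected_rate(spike_times_s, std_pre_dev.onsets(),
                                        LATE_WINDOW_S)
    dev_late = _baseline_corrected_rate(spike_times_s, dev.onsets(),
                                        LATE_WINDOW_S)
    issa, issa_ok = modulation_index(ctr, std)
    imm, imm_ok = modulation_index(dev_late, std_late)
    return ModulationIndexRow(unit_id, issa, imm, ctr, std, std_late,
                              dev_late, issa_ok, imm_ok)


def index_table(rows: list[ModulationIndexRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def compare_indices(table: pd.DataFrame, stratum_col: str,
                    value_col: str = "issa",
                    group_col: str = "genotype_label",
                    min_n: int = 2) -> pd.DataFrame:
    """Pairwise group contrasts of an index within each stratum.

    For every stratum level, compares the two genotype groups with a
    Mann-Whitney U test (magnitudes) and a two-sample KS test
    (distributions); BH adjustment is applied within each test family
    across strata.  Strata with fewer than ``min_n`` valid units per side
    yield NA rows.
    """
    valid_col = f"{value_col}_valid"
    groups = sorted(table[group_col].dropna().unique())
    df = table
    if valid_col in df.columns:
        df = df[df[valid_col]]
    if len(groups) != 2:
        raise ValueError(f"need exactly two {group_col} groups, "
                         f"found {groups}")
    ga, gb = groups
    rows = []
    mw_family: list[StatResult] = []
    ks_family: list[StatResult] = []
    for stratum in sorted(df[stratum_col].dropna().unique()):
        sub = df[df[stratum_col] == stratum]
        a = sub.loc[sub[group_col] == ga, value_col].dropna().to_numpy()
        b = sub.loc[sub[group_col] == gb, value_col].dropna().to_numpy()
        entry = {"stratum": stratum, "value": value_col,
                 "group_a": ga, "group_b": gb,
                 "n_a": a.size, "n_b": b.size,
                 "median_a": float(np.median(a)) if a.size else np.nan,
                 "median_b": float(np.median(b)) if b.size else np.nan}
        if a.size < min_n or b.size < min_n:
            logger.info("compare_indices: stratum %s has insufficient units",
                        stratum)
            entry.update({"mw": None, "ks": None})
        else:
            mw = mann_whitney(a, b, f"{value_col}:{stratum}:{ga}-vs-{gb}")
            ks = ks_two_sample(a, b, f"{value_col}:{stratum}:{ga}-vs-{gb}")
            mw_family.append(mw)
            ks_family.append(ks)
            entry.update({"mw": mw, "ks": ks})
        rows.append(entry)
    adjust_family(mw_family)
    adjust_family(ks_family)
    out = []
    for entry in rows:
        mw, ks = entry.pop("mw"), entry.pop("ks")
        entry["mw_stat"] = mw.statistic if mw else np.nan
        entry["mw_p_raw"] = mw.p_raw if mw else np.nan
        entry["mw_p_adj"] = mw.p_adjusted if mw else np.nan
        entry["ks_stat"] = ks.statistic if ks else np.nan
        entry["ks_p_raw"] = ks.p_raw if ks else np.nan
        entry["ks_p_adj"] = ks.p_adjusted if ks else np.nan
        out.append(entry)
    return pd.DataFrame(out)
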