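"""Session- and experiment-level orchestration of all analysis stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import decoding, lfp, oddball, omission, tuning, units
from .core import Condition, Recording, logger

__all__ = ["analyze_unit_table", "analyze_lfp", "analyze_session",
           "analyze_experiment"]


def analyze_unit_table(rec: Recording) -> tuple[pd.DataFrame, dict]:
    """Per-unit metrics for one session.

    Applies the inclusion filter (>10 spikes per block), then computes for
    every kept unit: laminar assignment, RS/FS class, visual responsiveness
    (tuning-block trials), the DoG tuning fit and tuning group, oddball
    modulation indices (excited units only), and the omission label/trace
    when an omission block is present.

    Returns the table and a dict of per-unit omission traces.
    """
    kept = units.filter_units(rec)
    ev = rec.events
    tuning_trials = ev.select(block="tuning", condition=Condition.TUNING)
    has_omission = len(ev.select(condition=Condition.OMIS)) > 0
    rows = []
    traces = {}
    for u in kept:
        wf = units.classify_waveform(u.template, u.template_fs)
        responsive = units.classify_responsive(u.spike_times_s,
                                               tuning_trials.onsets())
        row = {
            "unit_id": u.unit_id,
            "depth_um": u.depth_um,
            "layer": units.assign_layer(u.depth_um),
            "cell_class": wf.cell_class,
            "trough_to_peak_ms": wf.trough_to_peak_ms,
            "spike_width_ms": wf.spike_width_ms,
            "responsive": responsive,
            "n_spikes": int(u.spike_times_s.size),
            "genotype_label": rec.genotype_label,
        }
        sfs, curve = tuning.tuning_curve(u.spike_times_s, ev)
        fit = tuning.fit_dog(sfs, curve)
        _, late = tuning.late_response(u.spike_times_s, ev)
        row.update({
            "pref_sf_cpd": fit.pref_sf_cpd, "fit_error": fit.fit_error,
            "q_factor": fit.q_factor,
            "tuning_group": tuning.assign_tuning_group(fit),
        })
        for sf, r_early, r_late in zip(sfs, curve, late):
            row[f"rate_early_{sf:g}"] = r_early
            row[f"rate_late_{sf:g}"] = r_late
        if responsive == "excited":
            idx = oddball.compute_indices(u.unit_id, u.spike_times_s, ev)
            row.update({"issa": idx.issa, "imm": idx.imm,
                        "issa_valid": idx.issa_valid,
                        "imm_valid": idx.imm_valid,
                        "ctr_hz": idx.ctr_hz, "std_hz": idx.std_hz,
                        "std_late_hz": idx.std_late_hz,
                        "dev_late_hz": idx.dev_late_hz})
        else:
            row.update({"issa": np.nan, "imm": np.nan, "issa_valid": False,
                        "imm_valid": False})
        if has_omission:
            row["omission_label"] = omission.classify_omission(
                u.spike_times_s, ev)
            traces[u.unit_id] = omission.omission_trace(u.spike_times_s, ev)
            std_omis = ev.select(block="omission", condition=Condition.STD)
            row["omission_std_z"] = omission.omission_zscore(
                u.spike_times_s, std_omis.onsets(), omission.CLUSTER_WINDOW_S)
            omis_tr = ev.select(condition=Condition.OMIS)
            row["omission_omis_z"] = omission.omission_zscore(
                u.spike_times_s, omis_tr.onsets(), omission.CLUSTER_WINDOW_S)
        rows.append(row)
    table = pd.DataFrame(rows)
    logger.info("analyze_unit_table: %d units analyzed (%s)", len(table),
                rec.genotype_label)
    return table, traces


def analyze_lfp(rec: Recording) -> dict:
    """Layer-4 VEP metrics and band power for one session."""
    data = lfp.preprocess_lfp(rec.lfp, rec.lfp_fs)
    fs = lfp.TARGET_FS
    ev = rec.events
    presented = [e for e in ev.events if e.condition is not Condition.OMIS]
    onsets = np.asarray([e.onset_s for e in presented])
    epochs, times, kept = lfp.epoch_lfp(data, fs, onsets)
    presented = [presented[j] for j in kept]
    onsets = onsets[kept]
    l4 = lfp.find_layer4_channel(epochs.mean(axis=1), times)

    # condition labels: oddball STD/DEV plus the 0.03 cpd tuning trials (CTR)
    labels = []
    for e in presented:
        if e.block == "oddball":
            labels.append(e.condition.value)
        elif e.block == "tuning" and np.isclose(e.sf_cpd, 0.03):
            labels.append("CTR")
        else:
            labels.append("other")
    labels = np.asarray(labels)
    vep = lfp.vep_metrics(epochs[l4], times, labels,
                          conditions=["STD", "DEV", "CTR"])

    # wider epochs for the TFR: the lowest-frequency wavelet (2 Hz, 3
    # cycles) spans ~1.9 s
    wide, wide_t, wide_kept = lfp.epoch_lfp(data[l4], fs, onsets,
                                            window_s=(-1.0, 1.5))
    wide_labels = labels[wide_kept]
    band_db = {}
    for cond in ("STD", "DEV", "CTR"):
        sel = wide_labels == cond
        if not sel.any():
            continue
        avg = wide[0][sel].mean(axis=0)
        tfr = lfp.wavelet_tfr(avg, wide_t, fs)
        band_db[cond] = lfp.band_power(tfr)
    return {"l4_channel": int(l4),
            "l4_depth_um": float(rec.channel_depth_um[l4]),
            "vep": vep, "band_power_db": band_db}


def analyze_session(rec: Recording, seed: int = 0) -> dict:
    """All single-session analyses: unit table, LFP metrics, decoding."""
    table, traces = analyze_unit_table(rec)
    lfp_res = analyze_lfp(rec)
    kept = units.filter_units(rec)
    spikes = [u.spike_times_s for u in kept]
    dec = decoding.decode_windows(spikes, rec.events, seed=seed)
    return {"unit_table": table, "omission_traces": traces,
            "lfp": lfp_res, "decoding": dec,
            "genotype_label": rec.genotype_label}


def session_summary(res: dict) -> str:
    """Human-readable digest of an analyze_session result."""
    tab = res["unit_table"]
    ex = tab[tab["responsive"] == "excited"]
    vep = res["lfp"]["vep"]
    lines = [
        f"units kept: {len(tab)}",
        f"responsive: {tab['responsive'].value_counts().to_dict()}",
        f"tuning groups: {tab['tuning_group'].value_counts().to_dict()}",
        f"L4 channel depth: {res['lfp']['l4_depth_um']:.0f} um",
        "VEP peak (uV): " + ", ".join(
            f"{c} {vep[c]['peak_neg'] * 1e6:.1f}" for c in vep),
        f"median iSSA {ex[ex['issa_valid']]['issa'].median():.3f}, "
        f"median iMM {ex[ex['imm_valid']]['imm'].median():.3f}",
    ]
    for r in res["decoding"]:
        lines.append(f"decoding {r.window_s[0]:.2f}-{r.window_s[1]:.2f} s: "
                     f"error {100 * r.error_rate:.1f} "
                     f"+/- {100 * r.error_sem:.1f} %")
    return "\n".join(lines)


def analyze_experiment(wt: Recording, fx: Recording, seed: int = 0) -> dict:
    """Two-regime comparison: pooled index contrasts, omission clustering
    across genotypes, and per-genotype decoding."""
    res_a = analyze_session(wt, seed=seed)
    res_b = analyze_session(fx, seed=seed)
    table = pd.concat([res_a["unit_table"], res_b["unit_table"]],
                      ignore_index=True)

    excited = table[table["responsive"] == "excited"]
    comparisons = {}
    for value in ("issa", "imm"):
        for stratum in ("tuning_group", "layer", "cell_class"):
            comparisons[f"{value}_by_{stratum}"] = oddball.compare_indices(
                excited, stratum, value_col=value)

    omis = None
    traces = {**res_a["omission_traces"], **res_b["omission_traces"]}
    if traces:
        ids = list(traces)
        X = np.stack([traces[i] for i in ids])
        cluster = omission.elbow_k(X, k_max=min(10, X.shape[0] - 1),
                                   seed=seed)
        sub = table.set_index("unit_id").loc[ids]
        omis_cmp = omission.compare_omission_groups(
            cluster.labels, sub["omission_std_z"].to_numpy(),
            sub["omission_omis_z"].to_numpy(),
            sub["genotype_label"].to_numpy())
        omis = {"cluster": cluster, "unit_ids": ids, "contrasts": omis_cmp}

    return {"unit_table": table, "comparisons": comparisons,
            "omission": omis,
            "decoding": {res_a["genotype_label"]: res_a["decoding"],
                         res_b["genotype_label"]: res_b["decoding"]},
            "lfp": {res_a["genotype_label"]: res_a["lfp"],
                    res_b["genotype_label"]: res_b["lfp"]}}
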