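"""Results manifest assembly: summary tables for a full two-regime run.

The headline product is a contrast-summary matrix in the style of a
results table: for each analysis family (indices by tuning group, indices
by layer, omission responses by k-means group) one cell per stratum coding
direction and significance of the second group relative to the first
("ns", or an up/down arrow with a significance glyph on the adjusted p).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import logger
from .stats import significance_glyph

__all__ = ["contrast_cell", "table1_analog", "build_report"]


def contrast_cell(p_adj: float | None, delta: float) -> str:
    """Direction + significance glyph for one contrast.

    ``delta`` is group_b minus group_a (e.g. FX-like minus WT-like);
    non-significant contrasts are "ns" regardless of direction.
    """
    glyph = significance_glyph(p_adj)
    if glyph in ("ns", "NA"):
        return glyph
    arrow = "+" if delta > 0 else "-"
    return f"{arrow}{glyph}"


def _cells_from_comparison(cmp: pd.DataFrame, use_median: bool = True
                           ) -> dict[str, str]:
    cells = {}
    for row in cmp.itertuples(index=False):
        if np.isnan(row.mw_p_adj):
            cells[str(row.stratum)] = "NA"
        else:
            delta = (row.median_b - row.median_a) if use_median else 0.0
            cells[str(row.stratum)] = contrast_cell(row.mw_p_adj, delta)
    return cells


def table1_analog(comparisons: dict[str, pd.DataFrame],
                  omission_contrasts: pd.DataFrame | None = None
                  ) -> pd.DataFrame:
    """Contrast-outcome matrix across analyses.

    Rows are (family, index) pairs; columns are strata.  Cells code the
    sign and adjusted significance of group-b vs group-a (e.g. fx vs wt).
    """
    rows = []
    for value in ("issa", "imm"):
        for family, stratum in (("pref_sf", "tuning_group"),
                                ("layer", "layer")):
            key = f"{value}_by_{stratum}"
            if key not in comparisons:
                continue
            cells = _cells_from_comparison(comparisons[key])
            rows.append({"family": family, "measure": value.upper(), **cells})
    if omission_contrasts is not None:
        for resp in ("std", "omis"):
            sub = omission_contrasts[omission_contrasts["response"] == resp]
            cells = {}
            for row in sub.itertuples(index=False):
                if np.isnan(row.p_adj):
                    cells[f"group{row.cluster}"] = "NA"
                else:
                    cells[f"group{row.cluster}"] = contrast_cell(
                        row.p_adj, row.mean_b - row.mean_a)
            rows.append({"family": "omission_kmeans", "measure": resp.upper(),
                         **cells})
    return pd.DataFrame(rows)


def build_report(experiment: dict, out_dir: str | Path) -> dict:
    """Write CSV tables + a JSON manifest for an analyze_experiment result.

    Missing sections (e.g. no omission block, no decoding) are flagged in
    the manifest rather than failing.  Inputs are not modified.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"tables": {}, "missing": [], "parameters": {}}

    table = experiment.get("unit_table")
    if table is not None:
        p = out / "unit_table.csv"
        table.to_csv(p, index=False)
        manifest["tables"]["unit_table"] = p.name
        manifest["parameters"]["n_units"] = int(len(table))
        counts = table.groupby("genotype_label")["responsive"] \
            .value_counts().to_dict()
        manifest["parameters"]["responsive_counts"] = \
            {f"{g}:{r}": int(n) for (g, r), n in counts.items()}
    else:
        manifest["missing"].append("unit_table")

    comparisons = experiment.get("comparisons") or {}
    for name, cmp in comparisons.items():
        p = out / f"contrast_{name}.csv"
        cmp.to_csv(p, index=False)
        manifest["tables"][f"contrast_{name}"] = p.name
    if not comparisons:
        manifest["missing"].append("comparisons")

    omis = experiment.get("omission")
    omis_cmp = None
    if omis is not None:
        omis_cmp = omis["contrasts"]
        p = out / "omission_contrasts.csv"
        omis_cmp.to_csv(p, index=False)
        manifest["tables"]["omission_contrasts"] = p.name
        cl = omis["cluster"]
        assign = pd.DataFrame({"unit_id": omis["unit_ids"],
                               "cluster": cl.labels + 1})
        p = out / "omission_clusters.csv"
        assign.to_csv(p, index=False)
        manifest["tables"]["omission_clusters"] = p.name
        manifest["parameters"]["omission_k"] = int(cl.k)
        manifest["parameters"]["omission_low_confidence"] = bool(
            cl.low_confidence)
    else:
        manifest["missing"].append("omission")

    dec = experiment.get("decoding")
    if dec:
        rows = []
        for label, results in dec.items():
            for r in results:
                rows.append({"genotype_label": label,
                             "window_lo_s": r.window_s[0],
                             "window_hi_s": r.window_s[1],
                             "error_mean": r.error_rate,
                             "error_sem": r.error_sem,
                             "n_units": r.n_units, "n_trials": r.n_trials})
        p = out / "decoding.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        manifest["tables"]["decoding"] = p.name
    else:
        manifest["missing"].append("decoding")

    lfp_res = experiment.get("lfp")
    if lfp_res:
        p = out / "lfp_metrics.json"
        p.write_text(json.dumps(lfp_res, indent=2, default=float))
        manifest["tables"]["lfp_metrics"] = p.name
    else:
        manifest["missing"].append("lfp")

    summary = table1_analog(comparisons, omis_cmp)
    p = out / "table1_analog.csv"
    summary.to_csv(p, index=False)
    manifest["tables"]["table1_analog"] = p.name

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("report written to %s (%d tables, %d missing sections)",
                out, len(manifest["tables"]), len(manifest["missing"]))
    return manifest
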