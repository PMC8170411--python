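"""Session container I/O.

One HDF5 file per session with this layout::

    /lfp/data            (n_channels, n_samples) float32, volts
    /lfp/fs              scalar, Hz
    /lfp/channel_depth_um (n_channels,) float64
    /units/<unit_id>/spike_times_s, template, attrs: template_fs,
                     peak_channel, depth_um, n_spikes_per_block (JSON)
    /events              structured table mirroring the CSV event columns
    attrs: genotype_label, format_version

Event tables can be mirrored to CSV for inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import Recording, StimulusSequence, UnitRecord, logger

__all__ = ["write_recording", "read_recording", "write_events_csv",
           "read_events_csv", "FormatError"]

FORMAT_VERSION = 1
EVENT_COLUMNS = ["onset_s", "duration_s", "condition", "sf_cpd",
                 "frame_seed", "block"]


class FormatError(RuntimeError):
    """The file does not conform to the documented session layout."""


def write_recording(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["genotype_label"] = rec.genotype_label
        g = f.create_group("lfp")
        g.create_dataset("data", data=rec.lfp.astype(np.float32),
                         compression="gzip", compression_opts=1)
        g.create_dataset("fs", data=float(rec.lfp_fs))
        g.create_dataset("channel_depth_um", data=rec.channel_depth_um)
        ug = f.create_group("units")
        for u in rec.units:
            gu = ug.create_group(u.unit_id)
            gu.create_dataset("spike_times_s", data=u.spike_times_s)
            gu.create_dataset("template", data=u.template)
            gu.attrs["template_fs"] = float(u.template_fs)
            gu.attrs["peak_channel"] = int(u.peak_channel)
            gu.attrs["depth_um"] = float(u.depth_um)
            gu.attrs["n_spikes_per_block"] = json.dumps(u.n_spikes_per_block)
        df = rec.events.to_frame()
        ev = f.create_group("events")
        for col in EVENT_COLUMNS:
            data = df[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            ev.create_dataset(col, data=data)
        ev.attrs["config"] = json.dumps(rec.events.config, default=str)
    logger.info("wrote session %s: %d channels, %d units, %d events",
                path, rec.n_channels, len(rec.units), len(rec.events))
    return path


def read_recording(path: str | Path) -> Recording:
    """Read and validate a session container.

    Raises :class:`FormatError` on missing groups and ``ValueError`` on
    invariant violations (non-monotone depths, unsorted spikes, ...).
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        for key in ("lfp", "units", "events"):
            if key not in f:
                raise FormatError(f"{path}: missing '/{key}' group")
        g = f["lfp"]
        for key in ("data", "fs", "channel_depth_um"):
            if key not in g:
                raise FormatError(f"{path}: missing '/lfp/{key}' dataset")
        lfp = g["data"][()]
        fs = float(g["fs"][()])
        depths = g["channel_depth_um"][()]
        ev = f["events"]
        cols = {}
        for col in EVENT_COLUMNS:
            if col not in ev:
                raise FormatError(f"{path}: events table lacks '{col}'")
            data = ev[col][()]
            if data.dtype.kind == "S":
                data = data.astype(str)
            cols[col] = data
        config = json.loads(ev.attrs.get("config", "{}"))
        events = StimulusSequence.from_frame(pd.DataFrame(cols), config)
        units = []
        for uid in sorted(f["units"]):
            gu = f["units"][uid]
            units.append(UnitRecord(
                uid, gu["spike_times_s"][()], gu["template"][()],
                float(gu.attrs["template_fs"]), int(gu.attrs["peak_channel"]),
                float(gu.attrs["depth_um"]),
                json.loads(gu.attrs.get("n_spikes_per_block", "{}"))))
        genotype = str(f.attrs.get("genotype_label", ""))
    return Recording(lfp, fs, depths, units, events, genotype)


def write_events_csv(events: StimulusSequence, path: str | Path) -> Path:
    path = Path(path)
    events.to_frame().to_csv(path, index=False)
    return path


def read_events_csv(path: str | Path) -> StimulusSequence:
    return StimulusSequence.from_frame(pd.read_csv(path))
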