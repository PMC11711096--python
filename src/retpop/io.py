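"""HDF5 container for stimuli and spike rasters, plus CSV table helpers.

Layout: group ``/stimulus`` (datasets ``frames``, ``schedule`` columns;
attributes ``kind``, ``pixel_pitch``, ``frame_rate``, ``seed``) and one
group ``/spikes/<cell_id>`` per cell (dataset ``counts``; attributes
``bin_width``, ``t0``).
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .synthkit import SpikeRaster, StimulusSet

__all__ = ["save_container", "load_rasters", "load_stimulus"]


def save_container(path, stim: StimulusSet | None = None,
                   rasters: dict | None = None) -> None:
    with h5py.File(path, "w") as h5:
        if stim is not None:
            g = h5.create_group("stimulus")
            g.create_dataset("frames", data=stim.frames, compression="gzip")
            for col in stim.schedule.columns:
                v = stim.schedule[col].to_numpy()
                if v.dtype == object:
                    v = v.astype("S")
                g.create_dataset(f"schedule/{col}", data=v)
            g.attrs["kind"] = stim.kind
            g.attrs["pixel_pitch"] = stim.pixel_pitch
            g.attrs["frame_rate"] = stim.frame_rate
            if "seed" in stim.meta:
                g.attrs["seed"] = stim.meta["seed"]
        if rasters:
            for cid, r in rasters.items():
                g = h5.create_group(f"spikes/{cid}")
                g.create_dataset("counts", data=r.counts, compression="gzip")
                g.attrs["bin_width"] = r.bin_width
                g.attrs["t0"] = r.t0


def load_stimulus(path) -> StimulusSet:
    with h5py.File(path, "r") as h5:
        g = h5["stimulus"]
        cols = {}
        for col in g["schedule"]:
            v = g[f"schedule/{col}"][()]
            if v.dtype.kind == "S":
                v = v.astype(str)
            cols[col] = v
        return StimulusSet(kind=str(g.attrs["kind"]), frames=g["frames"][()],
                           pixel_pitch=float(g.attrs["pixel_pitch"]),
                           frame_rate=float(g.attrs["frame_rate"]),
                           schedule=pd.DataFrame(cols),
                           meta={"seed": int(g.attrs.get("seed", -1))})


def load_rasters(path) -> dict:
    out = {}
    with h5py.File(path, "r") as h5:
        if "spikes" not in h5:
            return out
        for cid in h5["spikes"]:
            g = h5[f"spikes/{cid}"]
            out[cid] = SpikeRaster(counts=np.asarray(g["counts"][()], dtype=np.int64),
                                   bin_width=float(g.attrs["bin_width"]),
                                   t0=float(g.attrs["t0"]), cell_id=cid)
    return out
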