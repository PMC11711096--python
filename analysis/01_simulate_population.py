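#!/usr/bin/env python
"""Simulate the synthetic recording that the later analyses consume.

Builds a natural-like gaze-shifted video (two-component scenes, fixational
jitter plus one saccade per image), a mosaic of rectified-subunit cells and
a matched mosaic of near-linear DoG LN cells, and Poisson spike rasters.
Writes the stimulus/spike container to ``results/population.h5`` and a
per-cell summary table to ``results/cells.csv``.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from retpop import experiments as ex
from retpop import io, synthkit as sk

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results")
OUT.mkdir(exist_ok=True)

imgs = sk.make_scene_images(40, (96, 96), seed=SEED)
stim, trace = sk.make_gaze_video(
    imgs, sk.GazeModel(jitter_sd_um=3.0, saccades_per_image=1,
                       saccade_amp_um=(150.0, 250.0)),
    seed=SEED + 1, frame_rate=75.0, pad_um=300.0, pixel_pitch=7.5)
frames = sk.rendered_video_frames(stim)

xs = [-105.0, -35.0, 35.0, 105.0]
cells, rows = {}, []
for i, x in enumerate(xs):
    cells[f"rect{i}"] = ex._bandpass_subunit_encoder((x, -35.0))
    rows.append({"cell_id": f"rect{i}", "type": "rectified_subunit",
                 "x_um": x, "y_um": -35.0})
    cells[f"lin{i}"] = ex._linear_encoder((x, 70.0))
    rows.append({"cell_id": f"lin{i}", "type": "linear_ln",
                 "x_um": x, "y_um": 70.0})

pop = sk.GroundTruthPopulation(
    cells=list(cells.values()),
    centres=np.array([[r["x_um"], r["y_um"]] for r in rows]), rng_seed=SEED)
rasters = {}
for i, (cid, enc) in enumerate(cells.items()):
    rate = enc.rate(frames, stim.pixel_pitch)
    rasters[cid] = sk.rate_to_raster(rate, stim.frame_rate,
                                     1 / stim.frame_rate, 30,
                                     np.random.default_rng((SEED, 1, i)), cid)
    rows[[r["cell_id"] for r in rows].index(cid)].update(
        mean_rate_hz=float(rate.mean()), peak_rate_hz=float(rate.max()),
        total_spikes=int(rasters[cid].counts.sum()))

io.save_container(OUT / "population.h5", stim, rasters)
np.save(OUT / "gaze_positions.npy", trace.positions)
pd.DataFrame(rows).to_csv(OUT / "cells.csv", index=False)
print(f"simulated {len(cells)} cells x {stim.n_frames} frames x 30 trials "
      f"-> {OUT/'population.h5'}")
print(pd.DataFrame(rows).to_string(index=False))
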