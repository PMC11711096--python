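"""Shared fixtures: small grating batteries and planted ground-truth cells."""

import numpy as np
import pytest

from retpop import gratmodels as gm
from retpop import synthkit as sk


@pytest.fixture(scope="session")
def battery_params():
    """Parameter arrays of a 1,200-grating flashed battery (25 x 12 x 4)."""
    freqs = sk.default_frequencies(25)
    oris = np.arange(12) * np.pi / 12
    phases = np.arange(4) * np.pi / 2
    combos = np.array([(f, t, p) for f in freqs for t in oris for p in phases])
    return combos[:, 0], combos[:, 1], combos[:, 2]


@pytest.fixture(scope="session")
def true_sg_cell():
    """Ground-truth 7-subunit cell: sigma 15 um, rectifying logistic.

    Subunits sit on a 32-um sub-lattice of the 16-um fitting grid, the
    natural mosaic for a synthetic cell that the grid model can represent.
    """
    centre = (10.0, -5.0)
    grid = gm.hex_grid(centre, 16.0, 1200)
    d = np.hypot(grid[:, 0] - centre[0], grid[:, 1] - centre[1])
    c0 = grid[np.argmin(d)]
    ang = np.arange(6) * np.pi / 3 + np.pi / 6
    sites = [int(np.argmin(d))]
    for x, y in zip(c0[0] + 32 * np.cos(ang), c0[1] + 32 * np.sin(ang)):
        sites.append(int(np.argmin(np.hypot(grid[:, 0] - x, grid[:, 1] - y))))
    params = gm.SubunitGridParams(
        centres=grid[sites], w=np.ones(7), sigma=15.0, k_s=2.0, w_surr=0.25,
        beta=4.0, gamma=-2.0, out=gm.NakaRushton(a=25.0, b=0.5, n=1.0, k=1.5))
    return params, centre, grid


@pytest.fixture(scope="session")
def true_dog_cell():
    return gm.DoGLNParams(
        spatial=gm.DoGSpatialParams(30.0, -20.0, 40.0, 60.0, 0.2, 2.0, 0.3),
        beta=4.0, gamma=-1.0, a=8.0)
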