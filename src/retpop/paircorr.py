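"""Pairwise response correlations, fixation segmentation and decompositions.

Fixations are delimited by image transitions and by high-velocity gaze
peaks (saccades); per fixation, the spatial contrast inside a cell's
receptive field and its linear activation are summarized by medians over
fixation frames.  Pairwise Pearson correlations over the test video are
decomposed additively into partial correlations over frame subsets (high vs
low spatial contrast; linear vs nonlinear fixations), so that
``r_pair = r_high + r_low`` and ``r_pair = r_linear + r_nonlinear`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .synthkit import GazeTrace

__all__ = [
    "FixationTable", "CorrSplit", "DSMetrics",
    "detect_fixations", "spatial_contrast_and_activation",
    "split_by_spatial_contrast", "partial_correlation", "corr_split",
    "correlation_vs_distance", "stimulus_pixel_correlation", "decorrelation",
    "direction_selectivity",
    "MAGNIFICATION_UM_PER_DEG",
]

#: retinal magnification factors (um of retina per degree of visual angle)
MAGNIFICATION_UM_PER_DEG = {"marmoset": 100.0, "mouse": 31.0}


@dataclass
class FixationTable:
    """Per-fixation [start, end) frame boundaries tiling the video."""

    boundaries: np.ndarray          # (n_fix, 2) int
    source: np.ndarray              # 'image' or 'saccade' per boundary start
    spatial_contrast: pd.DataFrame | None = None   # fixations x cells
    linear_activation: pd.DataFrame | None = None

    @property
    def n_fixations(self) -> int:
        return len(self.boundaries)

    def frames_of(self, idx) -> np.ndarray:
        a, b = self.boundaries[idx]
        return np.arange(a, b)


@dataclass
class CorrSplit:
    r_pair: float
    r_a: float
    r_b: float
    label_a: str
    label_b: str
    n_frames: int
    stats: dict = field(default_factory=dict)


@dataclass
class DSMetrics:
    dsi: float
    preferred_direction: float
    p_perm: float
    on_off_index: float | None = None


def detect_fixations(trace: GazeTrace, min_interval_ms: float,
                     min_amplitude_deg_s: float,
                     magnification_um_per_deg: float) -> FixationTable:
    """Segment a gaze trace into fixations.

    Image transitions always start a new fixation.  Within an image, the
    instantaneous speed is the displacement between consecutive positions
    times the frame rate; local speed maxima above the amplitude threshold
    (deg/s, converted through the retinal magnification) split fixations,
    with only the taller of two peaks closer than the minimum interval
    retained.
    """
    pos = np.asarray(trace.positions, float)
    if pos.size == 0:
        raise ValueError("empty gaze trace")
    n = len(pos)
    speed = np.zeros(n)
    speed[1:] = np.hypot(*np.diff(pos, axis=0).T) * trace.frame_rate   # um/s
    thresh = min_amplitude_deg_s * magnification_um_per_deg            # um/s
    min_dist = max(1, int(round(min_interval_ms / 1000.0 * trace.frame_rate)))

    onsets = set(int(i) for i in trace.image_onsets)
    splits = set(onsets)
    # peaks are searched within images so a transition never masks a saccade
    bounds = sorted(onsets | {0, n})
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < 3:
            continue
        pk, _ = find_peaks(speed[a:b], height=thresh, distance=min_dist)
        splits.update(int(a + p) for p in pk)
    splits = sorted(splits | {0})
    edges = splits + [n]
    boundaries, source = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        if b > a:
            boundaries.append((a, b))
            source.append("image" if a in onsets or a == 0 else "saccade")
    return FixationTable(boundaries=np.asarray(boundaries, int),
                         source=np.asarray(source, object))


def spatial_contrast_and_activation(frames: np.ndarray, fixations: FixationTable,
                                    rf_profiles: dict, pixel_pitch: float = 1.0
                                    ) -> FixationTable:
    """Per-fixation spatial contrast and linear activation for each cell.

    ``rf_profiles`` maps cell id to a spatial filter on the frame grid.  The
    spatial contrast of a frame is the weighted SD of its pixels, the weight
    being the positive part of the normalized filter; the linear activation
    is the filter output.  Per fixation both are medians over frames.
    """
    n_frames = len(frames)
    if fixations.boundaries[:, 1].max() > n_frames:
        raise ValueError("fixation extends beyond the video")
    flat = frames.reshape(n_frames, -1)
    sc, act = {}, {}
    for cid, rf in rf_profiles.items():
        wpos = np.maximum(np.asarray(rf, float).ravel(), 0.0)
        s = wpos.sum()
        if s <= 0:
            raise ValueError(f"receptive-field profile of {cid} has no positive part")
        wpos = wpos / s
        mu = flat @ wpos
        ex2 = (flat**2) @ wpos
        sc_frame = np.sqrt(np.maximum(ex2 - mu**2, 0.0))
        act_frame = flat @ np.asarray(rf, float).ravel() * pixel_pitch**2
        sc[cid] = [float(np.median(sc_frame[a:b])) for a, b in fixations.boundaries]
        act[cid] = [float(np.median(act_frame[a:b])) for a, b in fixations.boundaries]
    fixations.spatial_contrast = pd.DataFrame(sc)
    fixations.linear_activation = pd.DataFrame(act)
    return fixations


def split_by_spatial_contrast(fixations: FixationTable, cell_a, cell_b):
    """Split fixations into high/low spatial-contrast groups, balanced on
    linear activation.

    Fixations are sorted by the pair-averaged linear activation, neighbours
    in the sorted list are paired (an odd trailing fixation is dropped), and
    within each pair the fixation with the higher pair-averaged spatial
    contrast joins the high group (ties go to the earlier fixation index).
    Returns ``(high_idx, low_idx)``.
    """
    if fixations.n_fixations < 2:
        raise ValueError("need at least 2 fixations to split")
    la = fixations.linear_activation
    sc = fixations.spatial_contrast
    act = 0.5 * (la[cell_a].to_numpy() + la[cell_b].to_numpy())
    scm = 0.5 * (sc[cell_a].to_numpy() + sc[cell_b].to_numpy())
    order = np.argsort(act, kind="stable")
    n_pairs = len(order) // 2
    high, low = [], []
    for p in range(n_pairs):
        i, j = order[2 * p], order[2 * p + 1]
        if scm[i] > scm[j] or (scm[i] == scm[j] and i < j):
            high.append(i), low.append(j)
        else:
            high.append(j), low.append(i)
    return np.asarray(sorted(high)), np.asarray(sorted(low))


def partial_correlation(x: np.ndarray, y: np.ndarray, subset) -> float:
    """Additive component of the Pearson correlation from a frame subset.

    ``sum_{i in subset} (x_i - xbar)(y_i - ybar) / ((N - 1) sigma_X sigma_Y)``
    with means and SDs over the full vectors, so components over
    complementary subsets sum exactly to the full Pearson r.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("partial correlation undefined for zero global variance")
    subset = np.asarray(subset, int)
    if subset.size == 0:
        return 0.0
    num = np.sum((x[subset] - x.mean()) * (y[subset] - y.mean()))
    return float(num / ((len(x) - 1) * sx * sy))


def corr_split(x, y, frames_a, frames_b, label_a="high", label_b="low") -> CorrSplit:
    """Full pair correlation and its two additive partial components."""
    ra = partial_correlation(x, y, frames_a)
    rb = partial_correlation(x, y, frames_b)
    return CorrSplit(r_pair=ra + rb, r_a=ra, r_b=rb, label_a=label_a,
                     label_b=label_b, n_frames=len(np.asarray(x)),
                     stats={"x_mean": float(np.mean(x)), "y_mean": float(np.mean(y)),
                            "x_sd": float(np.std(x, ddof=1)),
                            "y_sd": float(np.std(y, ddof=1))})


def fixation_frames(fixations: FixationTable, fix_idx) -> np.ndarray:
    """All frame indices belonging to the given fixations."""
    return np.concatenate([fixations.frames_of(i) for i in np.asarray(fix_idx)]) \
        if len(np.atleast_1d(fix_idx)) else np.empty(0, int)


def correlation_vs_distance(rates: dict, centres: dict, pairs=None,
                            pairs_per_bin: int = 20) -> pd.DataFrame:
    """Pairwise Pearson correlations of trial-averaged rates vs RF distance.

    Returns a per-pair table plus binned means with Student-t 95% CIs over
    groups of ``pairs_per_bin`` pairs sorted by ascending distance.
    Constant-rate cells are excluded (flagged in the ``excluded`` attr).
    """
    ids = sorted(rates)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
    rows, excluded = [], []
    for a, b in pairs:
        xa, xb = np.asarray(rates[a], float), np.asarray(rates[b], float)
        if xa.std() == 0 or xb.std() == 0:
            excluded.append((a, b))
            continue
        d = float(np.hypot(*(np.asarray(centres[a]) - np.asarray(centres[b]))))
        rows.append({"cell_a": a, "cell_b": b, "distance_um": d,
                     "r_pair": float(np.corrcoef(xa, xb)[0, 1])})
    df = pd.DataFrame(rows).sort_values("distance_um", ignore_index=True)
    df.attrs["excluded"] = excluded
    if len(df):
        g = np.arange(len(df)) // pairs_per_bin
        from scipy import stats as sps
        agg = df.groupby(g).agg(distance_um=("distance_um", "mean"),
                                r_mean=("r_pair", "mean"),
                                r_sd=("r_pair", "std"),
                                n=("r_pair", "size"))
        ci = sps.t.ppf(0.975, np.maximum(agg["n"] - 1, 1)) * agg["r_sd"] / np.sqrt(agg["n"])
        agg["ci95"] = ci
        df.attrs["binned"] = agg.reset_index(drop=True)
    return df


def stimulus_pixel_correlation(frames: np.ndarray, pixel_pitch: float,
                               n_pixels: int = 5000, seed: int = 0,
                               n_bins: int = 20) -> pd.DataFrame:
    """Pairwise light-intensity correlations of randomly selected pixels.

    Returns a binned correlation-vs-distance table on which a pair's
    stimulus correlation can be interpolated at its centre distance.
    """
    rng = np.random.default_rng(seed)
    T = len(frames)
    flat = frames.reshape(T, -1)
    h, w = frames.shape[1:]
    n_pixels = min(n_pixels, flat.shape[1])
    sel = rng.choice(flat.shape[1], n_pixels, replace=False)
    x = flat[:, sel]
    sd = x.std(axis=0)
    ok = sd > 0
    x, sel = x[:, ok], sel[ok]
    xc = (x - x.mean(axis=0)) / x.std(axis=0)
    C = (xc.T @ xc) / (T - 1)
    rows_px, cols_px = np.unravel_index(sel, (h, w))
    dy = rows_px[:, None] - rows_px[None, :]
    dx = cols_px[:, None] - cols_px[None, :]
    D = np.hypot(dx, dy) * pixel_pitch
    iu = np.triu_indices(len(sel), k=1)
    d, c = D[iu], C[iu]
    edges = np.quantile(d, np.linspace(0, 1, n_bins + 1))
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    out = pd.DataFrame({
        "distance_um": [d[which == i].mean() for i in range(n_bins)],
        "rho_stim": [c[which == i].mean() for i in range(n_bins)],
    }).dropna()
    return out


def interp_stimulus_correlation(stim_curve: pd.DataFrame, distance_um: float) -> float:
    return float(np.interp(distance_um, stim_curve["distance_um"],
                           stim_curve["rho_stim"]))


def decorrelation(r_response: float, rho_stim_at_distance: float) -> float:
    """Relative loss of correlation: (rho_stim - r_response) / rho_stim."""
    if rho_stim_at_distance == 0:
        raise ValueError("stimulus correlation is zero at this distance")
    return float(1.0 - r_response / rho_stim_at_distance)


def direction_selectivity(responses_by_direction: np.ndarray, directions=None,
                          n_perm: int = 1000, seed: int = 0,
                          onset_offset: tuple | None = None) -> DSMetrics:
    """Direction-selectivity index and permutation significance.

    ``responses_by_direction`` is (n_directions, n_trials) of spike counts.
    DSI = |sum_th r_th e^{i th}| / sum_th r_th over trial-mean responses;
    the p-value shuffles trial responses across directions.  When
    ``onset_offset = (onset_counts, offset_counts)`` is given, the ON-OFF
    index (onset - offset)/(onset + offset) is included.
    """
    r = np.atleast_2d(np.asarray(responses_by_direction, float))
    n_dir = r.shape[0]
    if n_dir < 4:
        raise ValueError("need at least 4 directions")
    if np.all(r == 0):
        raise ValueError("all-zero responses")
    if directions is None:
        directions = np.arange(n_dir) * 2 * np.pi / n_dir
    directions = np.asarray(directions, float)

    def dsi_of(mean_r):
        z = np.sum(mean_r * np.exp(1j * directions))
        s = np.sum(mean_r)
        return (abs(z) / s if s > 0 else 0.0), np.angle(z)

    dsi, pref = dsi_of(r.mean(axis=1))
    rng = np.random.default_rng(seed)
    flat = r.ravel()
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(flat).reshape(r.shape)
        d, _ = dsi_of(perm.mean(axis=1))
        if d >= dsi:
            count += 1
    p = (count + 1) / (n_perm + 1)
    ooi = None
    if onset_offset is not None:
        on, off = (float(np.sum(v)) for v in onset_offset)
        ooi = (on - off) / (on + off) if (on + off) > 0 else None
    return DSMetrics(dsi=float(dsi), preferred_direction=float(pref % (2 * np.pi)),
                     p_perm=float(p), on_off_index=ooi)
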