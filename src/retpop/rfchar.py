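"""White-noise receptive-field characterization and response quality.

The spike-triggered average (STA) over a 500 ms lag window estimates the
linear spatiotemporal filter under checkerboard white noise.  The temporal
filter is the mean time course of stixels whose absolute peak exceeds 4.5
robust standard deviations (1.4826 x MAD) of all STA elements; the spatial
filter is the projection of the STA onto the unit-normalized temporal
filter.  Receptive-field outlines are extracted as the 25%-of-maximum level
set of the blurred, upsampled spatial filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from ._util import robust_sd, symmetrized_r2  # noqa: F401  (re-exported)
from .synthkit import SpikeRaster, StimulusSet

__all__ = [
    "ReceptiveFieldFit", "QualityMetrics", "compute_sta", "separate_filters",
    "extract_contour", "characterize_rf", "symmetrized_r2",
    "fano_per_fixation", "spike_train_autocorrelation",
]


@dataclass
class ReceptiveFieldFit:
    spatial_filter: np.ndarray
    temporal_filter: np.ndarray
    contour: np.ndarray | None = None      # (n, 2) closed polygon, um
    centre: tuple | None = None
    area: float | None = None
    autocorrelation: np.ndarray | None = None
    pixel_pitch: float = 1.0


@dataclass
class QualityMetrics:
    sym_r2: float | None = None
    fano_weighted: float | None = None
    per_fixation_fano: np.ndarray = field(default_factory=lambda: np.empty(0))
    per_fixation_mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    included: np.ndarray = field(default_factory=lambda: np.empty(0, bool))


def compute_sta(stim: StimulusSet, raster: SpikeRaster,
                window_s: float = 0.5) -> np.ndarray:
    """Spatiotemporal STA: spike-weighted mean stimulus over the lag window.

    ``raster`` must be binned at the stimulus frame rate.  ``sta[lag, i, j]``
    is the average stimulus ``lag`` frames before the spike bin (lag 0 = the
    spike bin itself); only spikes with a full history window are used.
    Raises ``ValueError`` when no usable spike exists.
    """
    frames = stim.frames
    n_lags = int(round(window_s * stim.frame_rate))
    y = raster.counts.sum(axis=0).astype(float)
    if y.size != len(frames):
        raise ValueError("raster bins must match stimulus frames")
    y = y.copy()
    y[:n_lags - 1] = 0.0          # spikes without full history are unusable
    n_sp = y.sum()
    if n_sp <= 0:
        raise ValueError("no usable spikes after the first 500 ms")
    sta = np.zeros((n_lags,) + frames.shape[1:])
    flat = frames.reshape(len(frames), -1)
    for lag in range(n_lags):
        sta[lag] = (y[lag:] @ flat[:len(frames) - lag]).reshape(frames.shape[1:]) / n_sp
    return sta


def separate_filters(sta: np.ndarray, threshold_sd: float = 4.5):
    """Split a spatiotemporal STA into temporal and spatial filters.

    Temporal filter: mean time course of stixels whose absolute peak exceeds
    ``threshold_sd`` robust SDs of all STA elements, normalized to unit norm
    with its extremum positive.  Spatial filter: projection of the STA onto
    the temporal filter (it carries the residual sign and amplitude).
    """
    if not np.all(np.isfinite(sta)):
        raise ValueError("STA contains non-finite values")
    rsd = robust_sd(sta)
    peak = np.max(np.abs(sta), axis=0)
    if rsd == 0:
        raise ValueError("degenerate STA: robust SD of elements is 0")
    mask = peak > threshold_sd * rsd
    if not np.any(mask):
        raise ValueError(
            f"no stixel exceeds {threshold_sd} robust SDs ({threshold_sd * rsd:.3g})")
    courses = sta.reshape(sta.shape[0], -1)[:, mask.ravel()]
    temporal = courses.mean(axis=1)
    ext = temporal[np.argmax(np.abs(temporal))]
    if ext < 0:
        temporal = -temporal
    temporal = temporal / np.linalg.norm(temporal)
    spatial = np.tensordot(temporal, sta, axes=(0, 0))
    return spatial, temporal


def extract_contour(spatial_filter: np.ndarray, pixel_pitch: float,
                    upsample: int = 4, blur_sigma_px: float = 4.0,
                    level_frac: float = 0.25, triage_sd: float = 20.0):
    """Receptive-field outline from a spatial filter.

    Upsamples to single-pixel resolution (bilinear), blurs with a circular
    Gaussian (sigma in upsampled pixels), takes the level set at
    ``level_frac`` of the maximum, keeps the contour enclosing the peak, and
    triages contour points whose neighbour distance exceeds ``triage_sd``
    robust SDs of all neighbour distances.  Returns ``(contour_um, centre_um,
    area_um2)`` with the contour a closed (n, 2) polygon of (x, y) in um.
    """
    sf = np.asarray(spatial_filter, float)
    if sf.max() <= sf.min():
        raise ValueError("spatial filter needs a strict maximum")
    # grid_mode resampling scales by exactly `upsample` (image-resize
    # semantics), keeping the um-per-upsampled-pixel conversion exact
    up = ndimage.zoom(sf, upsample, order=1, grid_mode=True, mode="nearest")
    up = ndimage.gaussian_filter(up, blur_sigma_px)
    level = level_frac * up.max()
    contours = measure.find_contours(up, level)
    if not contours:
        raise ValueError("empty level set at the requested contour level")
    peak_rc = np.unravel_index(np.argmax(up), up.shape)
    chosen = None
    for cont in contours:
        if measure.points_in_poly(np.array([peak_rc]), cont)[0]:
            chosen = cont
            break
    if chosen is None:     # open contour clipped at the border: take largest
        chosen = max(contours, key=len)

    d = np.linalg.norm(np.diff(chosen, axis=0), axis=1)
    rsd = robust_sd(d)
    if rsd > 0:
        big = d > triage_sd * rsd
        # a point flanked by two oversized neighbour gaps is the outlier
        gap_next = np.append(big, False)
        gap_prev = np.insert(big, 0, False)
        chosen = chosen[~(gap_next & gap_prev)]

    # upsampled pixel i sits at original-grid coordinate (i + 0.5)/u - 0.5
    h0, w0 = sf.shape
    col = (chosen[:, 1] + 0.5) / upsample - 0.5
    row = (chosen[:, 0] + 0.5) / upsample - 0.5
    xy = np.empty_like(chosen)
    xy[:, 0] = (col - (w0 - 1) / 2) * pixel_pitch
    xy[:, 1] = (row - (h0 - 1) / 2) * pixel_pitch
    centre = (float(np.median(xy[:, 0])), float(np.median(xy[:, 1])))
    x, y = xy[:, 0], xy[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return xy, centre, float(area)


def characterize_rf(stim: StimulusSet, raster: SpikeRaster,
                    window_s: float = 0.5, threshold_sd: float = 4.5
                    ) -> ReceptiveFieldFit:
    """Full white-noise characterization: STA, filters, contour, centre."""
    sta = compute_sta(stim, raster, window_s)
    spatial, temporal = separate_filters(sta, threshold_sd)
    contour, centre, area = extract_contour(spatial, stim.pixel_pitch)
    return ReceptiveFieldFit(spatial_filter=spatial, temporal_filter=temporal,
                             contour=contour, centre=centre, area=area,
                             pixel_pitch=stim.pixel_pitch)


def spike_train_autocorrelation(raster: SpikeRaster, max_lag_s: float = 0.1
                                ) -> np.ndarray:
    """Spike-train autocorrelation over positive lags, normalized to unit sum."""
    n_lags = int(round(max_lag_s / raster.bin_width))
    ac = np.zeros(n_lags)
    for trial in raster.counts:
        x = trial.astype(float)
        for lag in range(1, n_lags + 1):
            ac[lag - 1] += np.dot(x[:-lag], x[lag:])
    s = ac.sum()
    return ac / s if s > 0 else ac


def fano_per_fixation(raster: SpikeRaster, boundaries,
                      min_mean_spikes: float = 3.0) -> QualityMetrics:
    """Across-trial Fano factors of fixation spike counts.

    ``boundaries`` is an iterable of ``[start_bin, end_bin)`` pairs.  Per
    fixation, Fano = variance / mean of the per-trial total count; fixations
    with a mean below ``min_mean_spikes`` are excluded; the summary is the
    mean weighted by the fixation's mean spike count.
    """
    if raster.n_trials < 2:
        raise ValueError("Fano factors need at least 2 trials")
    fanos, means = [], []
    for (a, b) in boundaries:
        tot = raster.counts[:, a:b].sum(axis=1).astype(float)
        mu = tot.mean()
        means.append(mu)
        fanos.append(tot.var(ddof=1) / mu if mu > 0 else np.nan)
    fanos = np.asarray(fanos)
    means = np.asarray(means)
    inc = (means >= min_mean_spikes) & np.isfinite(fanos)
    qm = QualityMetrics(per_fixation_fano=fanos, per_fixation_mean=means,
                        included=inc)
    if np.any(inc):
        qm.fano_weighted = float(np.sum(fanos[inc] * means[inc]) / np.sum(means[inc]))
    return qm
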