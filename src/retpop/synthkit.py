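"""Synthetic stimuli and ground-truth Poisson responses.

Generates every stimulus class the downstream analyses consume —
checkerboard white noise, flashed and flickering sinusoidal gratings,
natural-like videos built from static images displaced by gaze traces with
fixations and saccades — together with Poisson spike trains from known LN /
subunit-grid encoders arranged in receptive-field mosaics.  Every generator
is a pure function of its configuration and seed.

Coordinate conventions: x rightward, y downward, origin at the image centre;
all geometry in micrometres on the retina, converted through ``pixel_pitch``
(um/pixel).  Contrast is Weber contrast (dimensionless, mean-zero relative to
the background), clipped to [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import shift as ndi_shift

from ._util import substream
from .gratmodels import (DoGLNParams, SubunitGridParams, dog_filter_image,
                         sg_predict_image)
from .gratmodels._dog import _logistic

__all__ = [
    "GratingSpec", "StimulusSet", "GazeTrace", "SpikeRaster", "GazeModel",
    "GroundTruthPopulation", "DoGLNEncoder", "SubunitEncoder",
    "render_grating", "make_grating_battery", "make_checkerboard",
    "make_natural_images", "make_gaze_video", "simulate_responses",
    "rate_to_raster",
]


@dataclass(frozen=True)
class GratingSpec:
    """Sinusoidal grating: spatial frequency f (cycles/um), orientation theta
    (rad, [0, pi)), spatial phase phi (rad, [0, 2 pi))."""

    f: float
    theta: float
    phi: float

    def __post_init__(self):
        if not np.all(np.isfinite([self.f, self.theta, self.phi])):
            raise ValueError("non-finite grating parameters")
        if self.f < 0:
            raise ValueError("spatial frequency must be >= 0")


@dataclass
class StimulusSet:
    """A stimulus: unique frames plus a per-presented-frame schedule.

    ``frames`` holds the distinct images (n_images, H, W); ``schedule`` has
    one row per presented frame with columns ``image_index`` (-1 = grey),
    ``dx_um``/``dy_um`` gaze displacement, ``segment`` ('train'/'test'), and
    stimulus bookkeeping columns specific to the kind.
    """

    kind: str
    frames: np.ndarray
    pixel_pitch: float
    frame_rate: float
    schedule: pd.DataFrame
    table: pd.DataFrame | None = None     # per-presentation parameters
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.frames is not None and len(self.frames):
            if np.nanmax(np.abs(self.frames)) > 1 + 1e-9:
                raise ValueError("contrast must lie in [-1, 1]")

    @property
    def n_frames(self) -> int:
        return len(self.schedule)

    def presented_frame(self, i: int) -> np.ndarray:
        """Render presented frame i (grey background where image_index < 0)."""
        row = self.schedule.iloc[i]
        k = int(row["image_index"])
        if k < 0:
            return np.zeros(self.frames.shape[1:])
        img = self.frames[k]
        dx = int(round(row.get("dx_um", 0.0) / self.pixel_pitch))
        dy = int(round(row.get("dy_um", 0.0) / self.pixel_pitch))
        if dx or dy:
            # nearest-pixel translation with edge padding
            img = ndi_shift(img, (dy, dx), order=0, mode="nearest")
        return img


@dataclass
class GazeTrace:
    """Per-frame gaze displacement (um) with ground-truth saccade onsets."""

    positions: np.ndarray            # (n_frames, 2)
    saccade_times: np.ndarray        # frame indices, sorted
    image_onsets: np.ndarray         # frame indices of image transitions
    frame_rate: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("gaze positions must be finite")
        st = np.asarray(self.saccade_times)
        if st.size and (np.any(np.diff(st) <= 0) or st.max() >= len(self.positions)):
            raise ValueError("saccade_times must be sorted and within trace")


@dataclass
class SpikeRaster:
    """Binned spike counts, trials x time-bins; bins half-open [t, t+dt)."""

    counts: np.ndarray
    bin_width: float
    t0: float = 0.0
    cell_id: str = ""

    def __post_init__(self):
        c = np.asarray(self.counts)
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    def rate(self) -> np.ndarray:
        """Trial-averaged firing rate (spikes/s) per bin."""
        return self.counts.mean(axis=0) / self.bin_width


def render_grating(spec: GratingSpec, shape, pixel_pitch: float) -> np.ndarray:
    """Contrast matrix C(x, y) = sin(2 pi f (x cos th + y sin th) + phi),
    evaluated at pixel centres in um."""
    if pixel_pitch <= 0 or min(shape) <= 0:
        raise ValueError("shape and pixel_pitch must be positive")
    h, w = shape
    x = (np.arange(w) - (w - 1) / 2) * pixel_pitch
    y = (np.arange(h) - (h - 1) / 2) * pixel_pitch
    xx, yy = np.meshgrid(x, y)
    return np.sin(2 * np.pi * spec.f * (xx * np.cos(spec.theta) + yy * np.sin(spec.theta))
                  + spec.phi)


def default_frequencies(n: int = 25, half_period_min: float = 15.0,
                        half_period_max: float = 1200.0) -> np.ndarray:
    """Roughly log-spaced spatial frequencies from half-periods in um."""
    hp = np.geomspace(half_period_min, half_period_max, n)
    return 1.0 / (2.0 * hp)


def make_grating_battery(frequencies, orientations, phases, layout: str = "flashed",
                         n_repeats: int = 1, frame_rate: float = 85.0,
                         flash_s: float = 0.2, gap_s: float = 0.8,
                         frozen_every: int = 0, frozen_len: int = 0,
                         seed: int = 0, render: bool = False,
                         shape=(64, 64), pixel_pitch: float = 7.5) -> StimulusSet:
    """Battery of sinusoidal gratings.

    ``flashed``: each grating is shown for ``flash_s`` followed by a grey gap,
    in pseudorandom order, ``n_repeats`` times.  ``flicker``: a new grating
    every frame in pseudorandom order; if ``frozen_every > 0``, a fixed
    ``frozen_len``-frame sequence is interleaved every ``frozen_every`` frames
    and repeated verbatim.
    """
    frequencies = np.asarray(frequencies, float)
    orientations = np.asarray(orientations, float)
    phases = np.asarray(phases, float)
    if min(frequencies.size, orientations.size, phases.size) < 1:
        raise ValueError("need at least one frequency, orientation and phase")
    combos = np.array([(f, th, ph) for f in frequencies for th in orientations
                       for ph in phases])
    rng = substream(seed, 0)
    n_g = len(combos)

    if layout == "flashed":
        flash_frames = max(1, int(round(flash_s * frame_rate)))
        gap_frames = max(0, int(round(gap_s * frame_rate)))
        rows, tab = [], []
        frame = 0
        for rep in range(n_repeats):
            order = rng.permutation(n_g)
            for g in order:
                f, th, ph = combos[g]
                tab.append({"f": f, "theta": th, "phi": ph, "grating_id": g,
                            "trial": rep, "onset_frame": frame})
                for _ in range(flash_frames):
                    rows.append({"image_index": g, "dx_um": 0.0, "dy_um": 0.0,
                                 "segment": "train"})
                    frame += 1
                for _ in range(gap_frames):
                    rows.append({"image_index": -1, "dx_um": 0.0, "dy_um": 0.0,
                                 "segment": "train"})
                    frame += 1
        schedule = pd.DataFrame(rows)
        table = pd.DataFrame(tab)
    elif layout == "flicker":
        frozen_rng = substream(seed, 1)
        frozen_ids = (frozen_rng.integers(0, n_g, frozen_len)
                      if frozen_every > 0 else np.empty(0, int))
        rows, tab = [], []
        frame = 0
        n_total = n_repeats * n_g
        emitted = 0
        while emitted < n_total:
            block = min(frozen_every if frozen_every > 0 else n_total - emitted,
                        n_total - emitted)
            for g in rng.integers(0, n_g, block):
                f, th, ph = combos[g]
                rows.append({"image_index": int(g), "dx_um": 0.0, "dy_um": 0.0,
                             "segment": "train"})
                tab.append({"f": f, "theta": th, "phi": ph, "grating_id": int(g),
                            "trial": 0, "onset_frame": frame})
                frame += 1
                emitted += 1
            if frozen_every > 0 and emitted < n_total:
                for g in frozen_ids:
                    f, th, ph = combos[g]
                    rows.append({"image_index": int(g), "dx_um": 0.0,
                                 "dy_um": 0.0, "segment": "test"})
                    tab.append({"f": f, "theta": th, "phi": ph,
                                "grating_id": int(g), "trial": -1,
                                "onset_frame": frame})
                    frame += 1
        schedule = pd.DataFrame(rows)
        table = pd.DataFrame(tab)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    frames = (np.stack([render_grating(GratingSpec(*c), shape, pixel_pitch)
                        for c in combos])
              if render else np.zeros((0,) + tuple(shape)))
    return StimulusSet(kind=f"{layout}_gratings", frames=frames,
                       pixel_pitch=pixel_pitch, frame_rate=frame_rate,
                       schedule=schedule, table=table,
                       meta={"seed": seed, "combos": combos})


def make_checkerboard(square_size_um: float, n_frames: int, seed: int = 0,
                      shape_squares=(26, 26), frame_rate: float = 30.0,
                      frozen_test_frames: int = 0, pixel_pitch: float | None = None
                      ) -> StimulusSet:
    """Binary +/-1 checkerboard white noise at stixel resolution.

    Frames are stored one pixel per stixel with ``pixel_pitch`` equal to the
    stixel side (um); when a finer display pitch is given it must divide the
    square size evenly.
    """
    if pixel_pitch is not None:
        ratio = square_size_um / pixel_pitch
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("square size must be a multiple of pixel pitch")
    rng = substream(seed, 0)
    frames = rng.integers(0, 2, size=(n_frames,) + tuple(shape_squares)) * 2.0 - 1.0
    seg = np.array(["train"] * n_frames, dtype=object)
    if frozen_test_frames > 0:
        test = substream(seed, 1).integers(
            0, 2, size=(frozen_test_frames,) + tuple(shape_squares)) * 2.0 - 1.0
        frames = np.concatenate([frames, test])
        seg = np.concatenate([seg, np.array(["test"] * frozen_test_frames,
                                            dtype=object)])
    schedule = pd.DataFrame({"image_index": np.arange(len(frames)),
                             "dx_um": 0.0, "dy_um": 0.0, "segment": seg})
    return StimulusSet(kind="checkerboard", frames=frames,
                       pixel_pitch=square_size_um, frame_rate=frame_rate,
                       schedule=schedule, meta={"seed": seed})


def make_natural_images(n_images: int, shape=(128, 128), seed: int = 0,
                        rms_contrast=0.45, beta: float = 1.0) -> np.ndarray:
    """Synthetic natural-like images: 1/f-spectrum Gaussian noise.

    The amplitude spectrum falls as 1/f^beta; each image is scaled to a
    target RMS Weber contrast before clipping to [-1, 1].  ``rms_contrast``
    may be a scalar (~45% RMS matches natural-image ensembles) or a
    ``(low, high)`` range sampled log-uniformly per image, emulating the
    right-skewed (approximately log-normal) spread of local contrast across
    natural scenes.
    """
    rng = substream(seed, 0)
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    fr = np.hypot(fy, fx)
    fr[0, 0] = np.inf
    amp = 1.0 / fr**beta
    imgs = []
    for _ in range(n_images):
        if np.ndim(rms_contrast):
            lo, hi = rms_contrast
            c = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            c = float(rms_contrast)
        spec = amp * (rng.normal(size=shape) + 1j * rng.normal(size=shape))
        img = np.fft.ifft2(spec).real
        img = img / img.std() * c
        imgs.append(np.clip(img - img.mean(), -1, 1))
    return np.stack(imgs)


def make_scene_images(n_images: int, shape=(96, 96), seed: int = 0,
                      lum_contrast=(0.05, 0.35), texture_contrast=(0.02, 0.5),
                      split_scale_px: float = 10.0) -> np.ndarray:
    """Natural-like scenes with independent luminance and texture content.

    Each image is the sum of a low-pass 1/f "luminance" component (coarse
    structure beyond ``split_scale_px``) and a high-pass "texture" component,
    with RMS amplitudes drawn independently and log-uniformly from the given
    ranges.  This mimics the quasi-independence of local mean luminance and
    local spatial contrast across natural scenes: a patch can be bright and
    flat (sky) or mid-grey and highly textured (foliage).
    """
    rng = substream(seed, 7)
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    fr = np.hypot(fy, fx)
    fr[0, 0] = np.inf
    amp = 1.0 / fr
    f_split = 1.0 / split_scale_px
    lo_mask = fr <= f_split
    out = []
    for _ in range(n_images):
        spec = amp * (rng.normal(size=shape) + 1j * rng.normal(size=shape))
        low = np.fft.ifft2(spec * lo_mask).real
        high = np.fft.ifft2(spec * ~lo_mask).real
        a_l = np.exp(rng.uniform(*np.log(lum_contrast)))
        a_t = np.exp(rng.uniform(*np.log(texture_contrast)))
        img = a_l * low / low.std() + a_t * high / high.std()
        out.append(np.clip(img - img.mean(), -1, 1))
    return np.stack(out)


@dataclass
class GazeModel:
    """Synthetic gaze statistics within each 1-s image presentation.

    ``jitter_sd_um``: per-frame SD of the fixational random walk;
    ``saccades_per_image``: planted high-velocity gaze shifts per image;
    ``saccade_amp_um``: amplitude range (um) of a one-frame saccadic step;
    ``orientations_deg``: when set, the 1-D trace direction is drawn from
    this set per image (``resample_per_trial`` controls whether redraws
    happen across repeats).
    """

    jitter_sd_um: float = 4.0
    saccades_per_image: int = 1
    saccade_amp_um: tuple = (100.0, 250.0)
    orientations_deg: tuple | None = None
    resample_per_trial: bool = False


def make_gaze_video(images: np.ndarray, gaze_model: GazeModel, seed: int = 0,
                    frame_rate: float = 75.0, s_per_image: float = 1.0,
                    pad_um: float = 300.0, pixel_pitch: float = 7.5,
                    segment: str = "test") -> tuple[StimulusSet, GazeTrace]:
    """Natural-like video: images shown s_per_image each, jittered by gaze.

    Displacement is applied by nearest-pixel translation; the images must
    leave ``pad_um`` of headroom (an error is raised when a displacement
    exceeds the padding).  Ground-truth saccade frames are recorded in the
    returned :class:`GazeTrace`.
    """
    images = np.asarray(images, float)
    rng = substream(seed, 0)
    fpi = int(round(s_per_image * frame_rate))
    n_img = len(images)
    pos = np.zeros((n_img * fpi, 2))
    sacc = []
    onsets = np.arange(n_img) * fpi
    for i in range(n_img):
        p = np.zeros(2)
        if gaze_model.orientations_deg is not None:
            ang = np.deg2rad(rng.choice(gaze_model.orientations_deg))
            axis = np.array([np.cos(ang), np.sin(ang)])
        else:
            axis = None
        sac_frames = (rng.choice(np.arange(5, fpi - 5),
                                 size=gaze_model.saccades_per_image,
                                 replace=False)
                      if gaze_model.saccades_per_image > 0 else [])
        sac_frames = np.sort(np.asarray(sac_frames, int))
        for t in range(fpi):
            if axis is None:
                step = rng.normal(0, gaze_model.jitter_sd_um, 2)
            else:
                step = axis * rng.normal(0, gaze_model.jitter_sd_um)
            if t in sac_frames:
                amp = rng.uniform(*gaze_model.saccade_amp_um)
                direction = (axis if axis is not None
                             else np.array([np.cos(a := rng.uniform(0, 2 * np.pi)),
                                            np.sin(a)]))
                step = step + amp * direction * rng.choice([-1.0, 1.0])
                sacc.append(i * fpi + t)
            p = p + step
            if np.max(np.abs(p)) > pad_um:
                p = np.clip(p, -pad_um, pad_um)
            pos[i * fpi + t] = p
    if np.max(np.abs(pos)) > pad_um + 1e-9:
        raise ValueError("gaze displacement exceeds image padding")

    schedule = pd.DataFrame({
        "image_index": np.repeat(np.arange(n_img), fpi),
        "dx_um": pos[:, 0], "dy_um": pos[:, 1],
        "segment": segment,
        "new_image": np.isin(np.arange(n_img * fpi), onsets),
    })
    stim = StimulusSet(kind="video", frames=images, pixel_pitch=pixel_pitch,
                       frame_rate=frame_rate, schedule=schedule,
                       meta={"seed": seed, "pad_um": pad_um})
    trace = GazeTrace(positions=pos, saccade_times=np.asarray(sorted(set(sacc)), int),
                      image_onsets=onsets, frame_rate=frame_rate)
    return stim, trace


def rendered_video_frames(stim: StimulusSet) -> np.ndarray:
    """Materialize all presented frames of a video (nearest-pixel shifts)."""
    return np.stack([stim.presented_frame(i) for i in range(stim.n_frames)])


# ---------------------------------------------------------------------------
# ground-truth encoders

class DoGLNEncoder:
    """LN encoder: pixel-space DoG filter + logistic nonlinearity.

    ``rate_scale`` is the peak firing rate in spikes/s (the `a` of the LN
    stage applied to continuous streams).
    """

    def __init__(self, params: DoGLNParams, rate_scale: float | None = None):
        self.params = params
        self.rate_scale = rate_scale if rate_scale is not None else params.a

    def rate(self, frames: np.ndarray, pixel_pitch: float) -> np.ndarray:
        filt = dog_filter_image(self.params.spatial, frames.shape[1:], pixel_pitch)
        drive = frames.reshape(len(frames), -1) @ filt.ravel() * pixel_pitch**2
        r = self.rate_scale * _logistic(self.params.beta * drive + self.params.gamma)
        self._check(r)
        return r

    def linear_drive(self, frames: np.ndarray, pixel_pitch: float) -> np.ndarray:
        filt = dog_filter_image(self.params.spatial, frames.shape[1:], pixel_pitch)
        return frames.reshape(len(frames), -1) @ filt.ravel() * pixel_pitch**2

    @staticmethod
    def _check(r):
        if np.any(~np.isfinite(r)) or np.any(r < 0):
            raise ValueError("encoder produced an invalid (negative/non-finite) rate")


class SubunitEncoder:
    """Subunit-grid encoder: rectified subunit pool + Naka-Rushton output."""

    def __init__(self, params: SubunitGridParams, rate_scale: float = 1.0):
        self.params = params
        self.rate_scale = rate_scale

    def rate(self, frames: np.ndarray, pixel_pitch: float) -> np.ndarray:
        r = self.rate_scale * sg_predict_image(self.params, frames, pixel_pitch)
        DoGLNEncoder._check(r)
        return r


@dataclass
class GroundTruthPopulation:
    """Encoders at mosaic centres; the synthetic stand-in for a recording."""

    cells: list
    centres: np.ndarray
    rng_seed: int = 0

    def __post_init__(self):
        c = np.asarray(self.centres, float)
        if len(np.unique(c.round(6), axis=0)) != len(c):
            raise ValueError("mosaic centres must be unique")


def rate_to_raster(rate_per_frame: np.ndarray, frame_rate: float,
                   bin_width: float, n_trials: int, rng: np.random.Generator,
                   cell_id: str = "") -> SpikeRaster:
    """Poisson spikes from a frame-rate signal at a finer bin width.

    The rate is held constant within each stimulus frame; counts are drawn
    independently per bin and trial with mean rate*bin_width.
    """
    upsample = max(1, int(round(1.0 / (bin_width * frame_rate))))
    lam = np.repeat(rate_per_frame, upsample) * bin_width
    counts = rng.poisson(lam[None, :].repeat(n_trials, axis=0))
    return SpikeRaster(counts=counts.astype(np.int64), bin_width=bin_width,
                       cell_id=cell_id)


def simulate_responses(pop: GroundTruthPopulation, stim: StimulusSet,
                       n_trials: int, seed: int, bin_width: float | None = None,
                       frames: np.ndarray | None = None) -> dict:
    """Poisson rasters for every cell of the population.

    ``bin_width`` defaults to one stimulus frame.  Per-cell/per-trial RNG
    streams are derived from the global seed, so adding cells does not
    reshuffle existing ones.  Returns ``{cell_id: SpikeRaster}``.
    """
    if frames is None:
        frames = rendered_video_frames(stim)
    if bin_width is None:
        bin_width = 1.0 / stim.frame_rate
    out = {}
    for ci, enc in enumerate(pop.cells):
        rate = enc.rate(frames, stim.pixel_pitch)
        rng = substream(pop.rng_seed if seed is None else seed, 100 + ci)
        out[f"cell{ci:03d}"] = rate_to_raster(rate, stim.frame_rate, bin_width,
                                              n_trials, rng, f"cell{ci:03d}")
    return out
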