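"""Analytic difference-of-Gaussians (DoG) grating responses and the DoG LN model.

A DoG receptive field is a unit-integral elliptical centre Gaussian minus
``w_surr`` times a unit-integral surround Gaussian whose widths are scaled by
``k_s``.  Its inner product with a sinusoidal grating
``C(x, y) = sin(2 pi f (x cos th + y sin th) + phi)`` has the closed form

    r_DoG = A_DoG(f) * cos(Theta_DoG)

with amplitude

    A_DoG = exp(-c sigma_DoG^2 f^2) - w_surr * exp(-c (k_s sigma_DoG)^2 f^2)

where ``sigma_DoG^2 = sigma_x^2 cos^2(th + th_DoG) + sigma_y^2 sin^2(th + th_DoG)``
is the effective Gaussian width along the grating's wave vector, and phase

    Theta_DoG = 2 pi f sqrt(x0^2 + y0^2) cos(th - atan2(y0, x0)) + phi - pi/2.

Two exponent conventions are supported.  The exact Fourier transform of a
unit-integral Gaussian gives ``c = 2 pi^2`` ("exact", the default, validated
against pixel-space quadrature); an alternative convention with ``c = 2 pi``
("printed") is selectable for comparison with legacy parameter values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "DoGSpatialParams",
    "GratingActivation",
    "DoGLNParams",
    "dog_grating_response",
    "dog_filter_image",
    "dog_ln_rate",
    "fit_dog_ln",
]

_EXPONENT_C = {"exact": 2.0 * np.pi**2, "printed": 2.0 * np.pi}

#: lower bound on Gaussian SDs (um), half the native pixel size of the display
SIGMA_MIN = 7.5


@dataclass
class DoGSpatialParams:
    """Spatial parameters of an elliptical DoG receptive field (all in um).

    ``theta`` is the ellipse orientation (rad, constrained to (-pi/4, pi/4)),
    ``k_s`` the surround size scale (1 < k_s < 6) and ``w_surr`` the relative
    surround strength (0 <= w_surr < 1).
    """

    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    theta: float = 0.0
    k_s: float = 2.0
    w_surr: float = 0.0

    def validate(self) -> None:
        vals = [self.x0, self.y0, self.sigma_x, self.sigma_y, self.theta,
                self.k_s, self.w_surr]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite DoG parameters")
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x, sigma_y must be positive")
        if not (1.0 < self.k_s < 6.0):
            raise ValueError("k_s must lie in (1, 6)")
        if not (0.0 <= self.w_surr < 1.0):
            raise ValueError("w_surr must lie in [0, 1)")


@dataclass
class GratingActivation:
    """Amplitude/phase decomposition of a DoG grating response."""

    amplitude: np.ndarray
    phase: np.ndarray
    sigma_eff: np.ndarray

    @property
    def response(self) -> np.ndarray:
        return self.amplitude * np.cos(self.phase)


def _check_grating(f, theta, phi):
    f = np.asarray(f, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if not (np.all(np.isfinite(f)) and np.all(np.isfinite(theta))
            and np.all(np.isfinite(phi))):
        raise ValueError("non-finite grating parameters")
    if np.any(f < 0):
        raise ValueError("spatial frequency must be >= 0")
    return np.broadcast_arrays(f, theta, phi)


def dog_grating_response(spatial: DoGSpatialParams, f, theta, phi,
                         mode: str = "exact") -> GratingActivation:
    """Closed-form response of a DoG receptive field to sinusoidal gratings.

    Parameters are broadcast, so arrays of grating parameters are evaluated
    in one call.  A centred field (``x0 = y0 = 0``) has phase
    ``phi - pi/2`` (the distance term vanishes); the ``atan2`` in the phase
    handles every quadrant of the centre offset.
    """
    c = _EXPONENT_C[mode]
    f, theta, phi = _check_grating(f, theta, phi)
    ang = theta + spatial.theta
    sig2 = spatial.sigma_x**2 * np.cos(ang) ** 2 + spatial.sigma_y**2 * np.sin(ang) ** 2
    amp = (np.exp(-c * sig2 * f**2)
           - spatial.w_surr * np.exp(-c * spatial.k_s**2 * sig2 * f**2))
    d = np.hypot(spatial.x0, spatial.y0)
    if d == 0:
        phase = np.broadcast_to(phi - np.pi / 2, amp.shape).copy()
    else:
        phase = (2 * np.pi * f * d * np.cos(theta - np.arctan2(spatial.y0, spatial.x0))
                 + phi - np.pi / 2)
    return GratingActivation(amplitude=amp, phase=phase, sigma_eff=np.sqrt(sig2))


def _gauss2d(shape, pixel_pitch, x0, y0, sigma_x, sigma_y, theta):
    """Unit-integral anisotropic Gaussian sampled at pixel centres.

    Coordinates: x rightward, y downward, origin at the image centre.  The
    ellipse's x axis is rotated by ``-theta`` so that the discrete filter
    agrees with the analytic amplitude exponent in ``theta + th_grating``.
    """
    h, w = shape
    x = (np.arange(w) - (w - 1) / 2) * pixel_pitch
    y = (np.arange(h) - (h - 1) / 2) * pixel_pitch
    xx, yy = np.meshgrid(x, y)
    ca, sa = np.cos(-theta), np.sin(-theta)
    u = (xx - x0) * ca + (yy - y0) * sa
    v = -(xx - x0) * sa + (yy - y0) * ca
    g = np.exp(-0.5 * (u**2 / sigma_x**2 + v**2 / sigma_y**2))
    return g / (2 * np.pi * sigma_x * sigma_y)


def dog_filter_image(spatial: DoGSpatialParams, shape, pixel_pitch: float) -> np.ndarray:
    """Pixel-space DoG filter (continuous density sampled at pixel centres).

    The dot product of this filter with an image, times ``pixel_pitch**2``,
    approximates the continuous-space inner product used by the analytic
    grating formula.
    """
    centre = _gauss2d(shape, pixel_pitch, spatial.x0, spatial.y0,
                      spatial.sigma_x, spatial.sigma_y, spatial.theta)
    surr = _gauss2d(shape, pixel_pitch, spatial.x0, spatial.y0,
                    spatial.k_s * spatial.sigma_x, spatial.k_s * spatial.sigma_y,
                    spatial.theta)
    return centre - spatial.w_surr * surr


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class DoGLNParams:
    """DoG LN model: R = a * logistic(beta * r_DoG + gamma).

    ``a`` is the rate scale in spikes per flash (or spikes/s when applied to
    continuous streams); ``beta`` and ``gamma`` set the steepness and
    threshold of the logistic output nonlinearity.
    """

    spatial: DoGSpatialParams
    beta: float
    gamma: float
    a: float
    nll: float | None = field(default=None, compare=False)
    mode: str = "exact"


def dog_ln_rate(params: DoGLNParams, f, theta, phi) -> np.ndarray:
    act = dog_grating_response(params.spatial, f, theta, phi, mode=params.mode)
    return params.a * _logistic(params.beta * act.response + params.gamma)


def _poisson_nll(rate, counts):
    rate = np.maximum(rate, 1e-12)
    return float(np.sum(rate - counts * np.log(rate)))


def _pack(sp: DoGSpatialParams, beta, gamma, a):
    return np.array([sp.x0, sp.y0, sp.sigma_x, sp.sigma_y, sp.theta,
                     sp.k_s, sp.w_surr, beta, gamma, a])


def _unpack(v, mode="exact"):
    sp = DoGSpatialParams(*v[:7])
    return DoGLNParams(spatial=sp, beta=v[7], gamma=v[8], a=v[9], mode=mode)


def fit_dog_ln(f, theta, phi, counts, init: DoGLNParams | None = None,
               centre_init=(0.0, 0.0), mode: str = "exact",
               n_starts: int = 3, seed: int = 0,
               maxiter: int = 600) -> DoGLNParams:
    """Fit a DoG LN model to flashed-grating spike counts by constrained
    maximum likelihood (negative Poisson log-likelihood, L-BFGS-B).

    Each presentation (trial) enters the likelihood independently.  Bound
    constraints: ``sigma_x, sigma_y > 7.5 um``, ``|theta| < pi/4``,
    ``1 < k_s < 6``, ``0 <= w_surr < 1``, ``a > 0``.
    """
    f, theta, phi = _check_grating(f, theta, phi)
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("no spikes in data: DoG LN fit is undefined")

    span = 1.05 * float(np.max(np.hypot(*centre_init)) + 300.0)
    bounds = [(-span, span), (-span, span),
              (SIGMA_MIN + 1e-6, 500.0), (SIGMA_MIN + 1e-6, 500.0),
              (-np.pi / 4 + 1e-6, np.pi / 4 - 1e-6),
              (1.0 + 1e-6, 6.0 - 1e-6), (0.0, 1.0 - 1e-6),
              (-200.0, 200.0), (-20.0, 20.0), (1e-6, None)]

    def nll(v):
        p = _unpack(v, mode)
        return _poisson_nll(dog_ln_rate(p, f, theta, phi), counts)

    rng = np.random.default_rng(seed)
    mean_count = counts.mean()
    if init is not None:
        x0s = [_pack(init.spatial, init.beta, init.gamma, init.a)]
    else:
        x0s = []
    base = np.array([centre_init[0], centre_init[1], 60.0, 60.0, 0.0, 2.0, 0.2,
                     4.0, 0.0, max(4 * mean_count, 0.5)])
    x0s.append(base)
    for _ in range(max(0, n_starts - len(x0s))):
        j = base.copy()
        j[:2] += rng.normal(0, 20, 2)
        j[2:4] *= rng.uniform(0.5, 1.8, 2)
        j[7] *= rng.uniform(0.5, 2.0)
        x0s.append(j)

    lo = [b[0] if b[0] is not None else -np.inf for b in bounds]
    hi = [b[1] if b[1] is not None else np.inf for b in bounds]
    # stage 1 pins the surround off: the centre Gaussian is well identified
    # before the (nearly cancelling) surround pair (k_s -> 1, w_surr -> 1)
    # is allowed in, which avoids a degenerate likelihood ridge
    bounds_stage1 = list(bounds)
    bounds_stage1[6] = (0.0, 1e-9)
    best = None
    for x0 in x0s:
        x0 = np.clip(x0, lo, hi)
        x1 = x0.copy()
        x1[6] = 0.0
        res1 = minimize(nll, x1, method="L-BFGS-B", bounds=bounds_stage1,
                        options={"maxiter": maxiter})
        x2 = res1.x.copy()
        x2[5], x2[6] = 2.0, 0.2
        for start in (x2, np.clip(x0, lo, hi)):
            res = minimize(nll, start, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": maxiter})
            if best is None or res.fun < best.fun:
                best = res
    out = _unpack(best.x, mode)
    out.nll = float(best.fun)
    # canonical sign: positive beta (OFF polarity is carried by the phase of
    # the fitted centre/offsets only when beta is pinned negative by the data)
    return out


def refit_output_nonlinearity(params: DoGLNParams, f, theta, phi, counts,
                              maxiter: int = 200) -> DoGLNParams:
    """Refit only (beta, gamma, a) of a DoG LN model, spatial part frozen."""
    act = dog_grating_response(params.spatial, f, theta, phi, mode=params.mode)
    r = act.response
    counts = np.asarray(counts, dtype=float)

    def nll(v):
        return _poisson_nll(v[2] * _logistic(v[0] * r + v[1]), counts)

    res = minimize(nll, [params.beta, params.gamma, params.a], method="L-BFGS-B",
                   bounds=[(-200, 200), (-20, 20), (1e-6, None)],
                   options={"maxiter": maxiter})
    out = replace(params, beta=res.x[0], gamma=res.x[1], a=res.x[2])
    out.nll = float(res.fun)
    return out
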