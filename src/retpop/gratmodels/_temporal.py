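"""Spatiotemporal model variants fitted to rapidly flickering gratings.

Temporal integration over a 500 ms history window is parameterized by ten
basis functions: two single-frame boxcars for the two frames immediately
before the response bin (capturing the response delay) and eight raised
cosines with peaks spanning 0-250 ms.  Centre and surround of the receptive
field carry separate temporal filters; the centre activation history r_C and
the surround activation history r_S (unit-integral Gaussians; the surround's
sign and strength live entirely in its temporal coefficients) are combined as

    R = a * N(r_C^T k_Ct + r_S^T k_St + b)                (DoG LN)
    R = G( sum_s w_s N(r_Cs^T k_Ct + r_Ss^T k_St + gamma) )   (subunit grid)

with the same density regularizer, ADAM schedule and pruning machinery as the
flashed fits (batch size 2000 and peak learning rate 0.02 for the grid).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import minimize

from ._dog import DoGSpatialParams, _logistic, _poisson_nll, _EXPONENT_C, SIGMA_MIN
from ._subunit import (NakaRushton, FitConfig, hex_grid, _pair_inv_d2,
                       _subunit_phase, _nr_forward)

__all__ = [
    "TemporalBasis", "build_temporal_basis",
    "STDoGLNParams", "st_dog_ln_rate", "fit_st_dog_ln",
    "STSubunitGridParams", "st_sg_rate", "fit_st_sg",
]


@dataclass
class TemporalBasis:
    """Ten temporal basis vectors over a lag window.

    ``matrix`` has shape (10, n_lags) where lag ``l`` (column ``l-1``) is the
    ``l``-th frame before the response bin.  Rows 0-1 are the single-frame
    boxcars; rows 2-9 the raised cosines.
    """

    matrix: np.ndarray
    frame_rate: float
    lag_times: np.ndarray

    @property
    def n_lags(self) -> int:
        return self.matrix.shape[1]

    def kernel(self, coef: np.ndarray) -> np.ndarray:
        """Temporal filter over lags for basis coefficients ``coef`` (10,)."""
        return np.asarray(coef, float) @ self.matrix


def build_temporal_basis(frame_rate: float, window_s: float = 0.5,
                         n_cos: int = 8, peak_max_s: float = 0.25) -> TemporalBasis:
    n_lags = int(round(window_s * frame_rate))
    if n_lags < n_cos + 2:
        raise ValueError("frame rate too low for the requested basis")
    # lag l (1-based) sits at time (l-1)/rate before the response bin start
    t = np.arange(n_lags) / frame_rate
    B = np.zeros((2 + n_cos, n_lags))
    B[0, 0] = 1.0
    B[1, 1] = 1.0
    peaks = np.linspace(0.0, peak_max_s, n_cos)
    width = 2.0 * (peak_max_s / (n_cos - 1))
    for j, mu in enumerate(peaks):
        arg = (t - mu) / width
        mask = np.abs(arg) <= 1.0
        B[2 + j, mask] = 0.5 * (1 + np.cos(np.pi * arg[mask]))
    return TemporalBasis(matrix=B, frame_rate=frame_rate, lag_times=t)


def _centre_surround_series(x0, y0, sigma_x, sigma_y, theta_dog, k_s,
                            f, th, phi, mode):
    """Per-frame centre and surround grating activations (unit-integral)."""
    c = _EXPONENT_C[mode]
    ang = th + theta_dog
    sig2 = sigma_x**2 * np.cos(ang) ** 2 + sigma_y**2 * np.sin(ang) ** 2
    d = np.hypot(x0, y0)
    if d == 0:
        ph = phi - np.pi / 2
    else:
        ph = 2 * np.pi * f * d * np.cos(th - np.arctan2(y0, x0)) + phi - np.pi / 2
    cosp = np.cos(ph)
    rc = np.exp(-c * sig2 * f**2) * cosp
    rs = np.exp(-c * k_s**2 * sig2 * f**2) * cosp
    return rc, rs


def _basis_features(series: np.ndarray, basis: TemporalBasis) -> np.ndarray:
    """Project the lagged history of ``series`` onto the basis.

    Returns (n_frames, 10); rows with t < n_lags are zero (insufficient
    history) and should be excluded from fitting.
    """
    L = basis.n_lags
    T = series.shape[0]
    out = np.zeros((T, basis.matrix.shape[0]))
    if T <= L:
        return out
    Brev = basis.matrix[:, ::-1]   # window index L-l  <->  lag l
    win = sliding_window_view(series, L, axis=0)   # win[i] = series[i:i+L]
    out[L:] = np.einsum("jl,tl->tj", Brev, win[:T - L])
    return out


@dataclass
class STDoGLNParams:
    spatial: DoGSpatialParams
    k_ct: np.ndarray
    k_st: np.ndarray
    b: float
    a: float
    basis: TemporalBasis
    mode: str = "exact"
    nll: float | None = field(default=None, compare=False)


def st_dog_ln_rate(params: STDoGLNParams, f, theta, phi) -> np.ndarray:
    """Predicted rate for a flicker sequence; first n_lags frames are b-level."""
    sp = params.spatial
    rc, rs = _centre_surround_series(sp.x0, sp.y0, sp.sigma_x, sp.sigma_y,
                                     sp.theta, sp.k_s,
                                     np.asarray(f, float), np.asarray(theta, float),
                                     np.asarray(phi, float), params.mode)
    gc = _basis_features(rc, params.basis)
    gs = _basis_features(rs, params.basis)
    act = gc @ params.k_ct + gs @ params.k_st + params.b
    return params.a * _logistic(act)


def fit_st_dog_ln(f, theta, phi, counts, basis: TemporalBasis,
                  centre_init=(0.0, 0.0), mode: str = "exact",
                  init: STDoGLNParams | None = None,
                  maxiter: int = 300) -> STDoGLNParams:
    """Fit the spatiotemporal DoG LN model by constrained maximum likelihood.

    ``counts`` are per-frame spike counts of one continuous flicker stream;
    the first ``n_lags`` frames (insufficient history) are excluded.
    """
    f = np.asarray(f, float)
    theta = np.asarray(theta, float)
    phi = np.asarray(phi, float)
    y = np.asarray(counts, float)
    L = basis.n_lags
    valid = slice(L, None)
    nb = basis.matrix.shape[0]

    def unpack(v):
        sp = DoGSpatialParams(v[0], v[1], v[2], v[3], v[4], v[5], 0.0)
        return STDoGLNParams(sp, v[6:6 + nb], v[6 + nb:6 + 2 * nb],
                             v[6 + 2 * nb], v[7 + 2 * nb], basis, mode)

    def nll(v):
        p = unpack(v)
        R = st_dog_ln_rate(p, f, theta, phi)[valid]
        return _poisson_nll(R, y[valid])

    if init is not None:
        sp = init.spatial
        x0 = np.concatenate([[sp.x0, sp.y0, sp.sigma_x, sp.sigma_y, sp.theta,
                              sp.k_s], init.k_ct, init.k_st, [init.b, init.a]])
    else:
        x0 = np.concatenate([[centre_init[0], centre_init[1], 50.0, 50.0, 0.0,
                              2.0], 0.5 * np.ones(nb), -0.1 * np.ones(nb),
                             [0.0, max(4 * y.mean(), 0.5)]])
    span = float(np.max(np.abs(centre_init)) + 300.0)
    bounds = ([(-span, span)] * 2
              + [(SIGMA_MIN + 1e-6, 500.0)] * 2
              + [(-np.pi / 4 + 1e-6, np.pi / 4 - 1e-6), (1.0 + 1e-6, 6.0 - 1e-6)]
              + [(-50, 50)] * (2 * nb) + [(-20, 20), (1e-6, None)])
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter})
    out = unpack(res.x)
    out.nll = float(res.fun)
    return out


@dataclass
class STSubunitGridParams:
    """Spatiotemporal subunit grid; the Naka-Rushton stage has no baseline."""

    centres: np.ndarray
    w: np.ndarray
    sigma: float
    k_s: float
    k_ct: np.ndarray
    k_st: np.ndarray
    gamma: float
    out: NakaRushton
    basis: TemporalBasis
    mode: str = "exact"
    nll: float | None = field(default=None, compare=False)

    @property
    def n_sub(self) -> int:
        return int(np.sum(self.w > 0))

    def active(self) -> "STSubunitGridParams":
        m = self.w > 0
        return STSubunitGridParams(self.centres[m].copy(), self.w[m].copy(),
                                   self.sigma, self.k_s, self.k_ct.copy(),
                                   self.k_st.copy(), self.gamma,
                                   copy.copy(self.out), self.basis, self.mode,
                                   self.nll)


def _st_sg_subunit_drive(params: STSubunitGridParams, f, theta, phi):
    """Per-frame, per-subunit pre-nonlinearity drive (frames x subunits)."""
    c = _EXPONENT_C[params.mode]
    act = params.active()
    cosT = np.cos(_subunit_phase(act.centres, f, theta, phi))
    Ac = np.exp(-c * act.sigma**2 * f**2)
    As = np.exp(-c * (act.k_s * act.sigma) ** 2 * f**2)
    gc = _basis_features_2d(Ac[:, None] * cosT, params.basis)
    gs = _basis_features_2d(As[:, None] * cosT, params.basis)
    return gc @ act.k_ct + gs @ act.k_st + act.gamma, act


def _basis_features_2d(U, basis):
    """Basis features of a (frames x subunits) series: (T, S, 10)."""
    L = basis.n_lags
    T, S = U.shape
    out = np.zeros((T, S, basis.matrix.shape[0]))
    if T <= L:
        return out
    Brev = basis.matrix[:, ::-1]
    win = sliding_window_view(U, L, axis=0)    # (T-L+1, S, L)
    out[L:] = np.einsum("jl,tsl->tsj", Brev, win[:T - L])
    return out


def st_sg_rate(params: STSubunitGridParams, f, theta, phi) -> np.ndarray:
    f = np.asarray(f, float)
    u, act = _st_sg_subunit_drive(params, f, np.asarray(theta, float),
                                  np.asarray(phi, float))
    v = _logistic(u) @ act.w
    return act.out(v)


def fit_st_sg(f, theta, phi, counts, centre_init=(0.0, 0.0),
              config: FitConfig | None = None, grid: np.ndarray | None = None,
              basis: TemporalBasis | None = None, frame_rate: float = 85.0,
              sigma_init: float = 12.0, mode: str = "exact"
              ) -> STSubunitGridParams:
    """Fit the spatiotemporal subunit-grid model with minibatch ADAM.

    Same cost structure as the flashed fit (spike-normalized Poisson NLL plus
    the density regularizer); gradients of the temporal coefficients, weights
    and output stage are analytic, the two shared spatial scalars (sigma,
    k_s) use central differences on the batch loss.
    """
    cfg = config or FitConfig(batch=2000, eta_max=0.02)
    basis = basis or build_temporal_basis(frame_rate)
    f = np.asarray(f, float)
    theta = np.asarray(theta, float)
    phi = np.asarray(phi, float)
    y = np.asarray(counts, float)
    T = y.size
    L = basis.n_lags
    n_sp = float(y.sum())
    if n_sp <= 0:
        raise ValueError("no spikes: fit undefined")
    c = _EXPONENT_C[mode]

    centres = grid if grid is not None else hex_grid(centre_init)
    S = len(centres)
    cosT = np.cos(_subunit_phase(centres, f, theta, phi))
    inv_d2 = _pair_inv_d2(centres)
    Brev = basis.matrix[:, ::-1]
    nb = basis.matrix.shape[0]
    f2 = f**2

    rng = np.random.default_rng(cfg.seed)
    d = np.hypot(centres[:, 0] - centre_init[0], centres[:, 1] - centre_init[1])
    w = 0.3 * np.exp(-0.5 * d**2 / (4 * 16.0) ** 2) * rng.uniform(0.9, 1.1, S)
    params = {"w": w, "sigma": float(sigma_init), "k_s": 2.0,
              "k_ct": 0.5 * np.ones(nb), "k_st": -0.1 * np.ones(nb),
              "gamma": 0.0,
              "a": float(max(2.0 * (y.max() - y.mean()), 1.0)),
              "n": 1.5, "k": float(max(w.sum() * 0.4, 1e-3))}
    names = list(params)
    m = {k_: np.zeros_like(np.asarray(v, float)) for k_, v in params.items()}
    v2 = {k_: np.zeros_like(np.asarray(v, float)) for k_, v in params.items()}

    n_epochs = cfg.epochs_for(T)
    mu_s, sd_s = n_epochs / 2.0, n_epochs / 5.0
    valid = np.arange(L, T)
    t_step = 0

    def project(p):
        p["w"] = np.maximum(p["w"], 0.0)
        p["sigma"] = float(np.clip(p["sigma"], *cfg.sigma_bounds))
        p["k_s"] = float(np.clip(p["k_s"], 1.0 + 1e-3, 6.0 - 1e-3))
        p["a"] = float(max(p["a"], 1e-6))
        p["n"] = float(np.clip(p["n"], 0.2, 8.0))
        p["k"] = float(max(p["k"], 1e-6))
        return p

    params = project(params)
    win = sliding_window_view(cosT, L, axis=0)     # (T-L+1, S, L)

    def batch_loss_and_interm(idx, sigma, k_s, want_interm=True):
        Ac = np.exp(-c * sigma**2 * f2)
        As = np.exp(-c * (k_s * sigma) ** 2 * f2)
        Wb = win[idx - L]                          # (B, S, L) = cosT[t-L:t]
        # history of A*cosT over the same window; reversing the window axis
        # maps ascending time to lag order 1..L (basis columns)
        hist_idx = idx[:, None] - np.arange(L, 0, -1)[None, :]   # t-L .. t-1
        Ac_h = Ac[hist_idx]                        # (B, L)
        As_h = As[hist_idx]
        gc = np.einsum("jl,bsl->bsj", basis.matrix,
                       (Wb * Ac_h[:, None, :])[..., ::-1])
        gs = np.einsum("jl,bsl->bsj", basis.matrix,
                       (Wb * As_h[:, None, :])[..., ::-1])
        u = gc @ params["k_ct"] + gs @ params["k_st"] + params["gamma"]
        z = _logistic(u)
        v = z @ params["w"]
        R, p_, kn, q = _nr_forward(v, params["a"], 0.0, params["n"], params["k"])
        R = np.maximum(R, 1e-9)
        loss = float(np.sum(R - y[idx] * np.log(R)))
        if not want_interm:
            return loss
        return loss, (gc, gs, u, z, v, R, p_, kn, q)

    for epoch in range(n_epochs):
        eta = cfg.eta_max * np.exp(-0.5 * ((epoch - mu_s) / sd_s) ** 2)
        order = rng.permutation(valid)
        for start in range(0, order.size, cfg.batch):
            idx = order[start:start + cfg.batch]
            B = idx.size
            scale = valid.size / (B * n_sp)
            loss, (gc, gs, u, z, v, R, p_, kn, q) = batch_loss_and_interm(
                idx, params["sigma"], params["k_s"])
            gR = scale * (1.0 - y[idx] / R)
            g = {}
            g["a"] = float(np.sum(gR * p_ / q))
            vv = np.maximum(v, 1e-12)
            g["n"] = float(np.sum(gR * params["a"] * kn * p_
                                  * (np.log(vv) - np.log(params["k"])) / q**2))
            g["k"] = float(np.sum(gR * (-params["a"] * p_ * params["n"]
                                        * params["k"] ** (params["n"] - 1) / q**2)))
            gv = gR * params["a"] * params["n"] * kn * p_ / (vv * q**2)
            g["w"] = z.T @ gv + 2.0 * cfg.lam * (inv_d2 @ params["w"])
            gz = (gv[:, None] * params["w"][None, :]) * z * (1.0 - z)
            g["gamma"] = float(np.sum(gz))
            g["k_ct"] = np.einsum("bs,bsj->j", gz, gc)
            g["k_st"] = np.einsum("bs,bsj->j", gz, gs)
            # central differences for the two shared spatial scalars
            hs = 1e-3 * max(params["sigma"], 1.0)
            lp = batch_loss_and_interm(idx, params["sigma"] + hs, params["k_s"],
                                       want_interm=False)
            lm = batch_loss_and_interm(idx, params["sigma"] - hs, params["k_s"],
                                       want_interm=False)
            g["sigma"] = scale * (lp - lm) / (2 * hs)
            hk = 1e-3 * params["k_s"]
            lp = batch_loss_and_interm(idx, params["sigma"], params["k_s"] + hk,
                                       want_interm=False)
            lm = batch_loss_and_interm(idx, params["sigma"], params["k_s"] - hk,
                                       want_interm=False)
            g["k_s"] = scale * (lp - lm) / (2 * hk)

            t_step += 1
            b1c = 1 - cfg.beta1**t_step
            b2c = 1 - cfg.beta2**t_step
            for nm in names:
                m[nm] = cfg.beta1 * m[nm] + (1 - cfg.beta1) * g[nm]
                v2[nm] = cfg.beta2 * v2[nm] + (1 - cfg.beta2) * np.square(g[nm])
                params[nm] = params[nm] - eta * (m[nm] / b1c) / (np.sqrt(v2[nm] / b2c) + cfg.eps)
            params = project(params)

    fitted = STSubunitGridParams(
        centres=centres, w=params["w"], sigma=params["sigma"], k_s=params["k_s"],
        k_ct=params["k_ct"], k_st=params["k_st"], gamma=params["gamma"],
        out=NakaRushton(params["a"], 0.0, params["n"], params["k"]),
        basis=basis, mode=mode)
    R = st_sg_rate(fitted, f, theta, phi)[L:]
    fitted.nll = _poisson_nll(R, y[L:])
    return fitted
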