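"""Subunit-grid model: hexagonal lattice of identical circular DoG subunits.

The ganglion-cell response to a grating is

    R_SG = G( sum_s w_s * N(beta * r_s + gamma) )

where ``r_s`` is the analytic circular-DoG grating activation of subunit
``s`` (sigma_x = sigma_y = sigma), ``N`` is a logistic nonlinearity shared by
all subunits, ``w_s >= 0`` are subunit weights over a hexagonal grid of
candidate locations, and ``G`` is a Naka-Rushton output nonlinearity.

Fitting minimises the spike-normalized negative Poisson log-likelihood plus a
density regularizer ``lambda * sum_s w_s sum_{i != s} w_i / d_si^2`` that
penalizes spatially crowded non-zero weights, using minibatch ADAM with a
Gaussian learning-rate schedule and projection onto the constraint set after
every step.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._dog import DoGSpatialParams, _gauss2d, _logistic, _poisson_nll, _EXPONENT_C

__all__ = [
    "NakaRushton", "SubunitGridParams", "FitConfig", "ModelDiagnostics",
    "hex_grid", "subunit_grating_activations", "sg_predict_gratings",
    "sg_predict_image", "subunit_filter_bank", "fit_sg", "polish_sg",
    "prune_and_refit", "select_model", "bic", "coverage",
    "nonlinearity_asymmetry",
]

GRID_SPACING = 16.0   # um between neighbouring candidate subunit sites
GRID_SITES = 1200


@dataclass
class NakaRushton:
    """Saturating output nonlinearity G(x) = a x^n / (x^n + k^n) + b.

    The baseline ``b`` is present in the flashed-grating variant and absent
    (zero) in the spatiotemporal variant.  All parameters are non-negative.
    """

    a: float
    b: float = 0.0
    n: float = 1.0
    k: float = 1.0

    def __call__(self, x):
        x = np.maximum(np.asarray(x, dtype=float), 1e-12)
        p = x**self.n
        return self.a * p / (p + self.k**self.n) + self.b


@dataclass
class SubunitGridParams:
    """Parameter bundle of a (flashed) subunit-grid model.

    ``centres`` are candidate subunit locations (um); ``w`` the non-negative
    weights; ``sigma`` the shared centre-Gaussian SD (um); ``k_s``/``w_surr``
    the shared surround scale and strength; ``beta``/``gamma`` the shared
    logistic subunit nonlinearity; ``out`` the Naka-Rushton output stage.
    """

    centres: np.ndarray
    w: np.ndarray
    sigma: float
    k_s: float
    w_surr: float
    beta: float
    gamma: float
    out: NakaRushton
    mode: str = "exact"
    nll: float | None = field(default=None, compare=False)

    @property
    def n_sub(self) -> int:
        return int(np.sum(self.w > 0))

    def active(self) -> "SubunitGridParams":
        """Copy retaining only subunits with non-zero weight."""
        m = self.w > 0
        return SubunitGridParams(self.centres[m].copy(), self.w[m].copy(),
                                 self.sigma, self.k_s, self.w_surr, self.beta,
                                 self.gamma, copy.copy(self.out), self.mode,
                                 self.nll)


def hex_grid(centre=(0.0, 0.0), spacing: float = GRID_SPACING,
             n_sites: int = GRID_SITES) -> np.ndarray:
    """Hexagonal lattice of candidate subunit sites around ``centre`` (um).

    Returns the ``n_sites`` sites closest to the centre, ordered by distance.
    """
    n_ring = int(np.ceil(np.sqrt(n_sites / 3.0))) + 2
    pts = []
    for q in range(-n_ring, n_ring + 1):
        for r in range(-n_ring, n_ring + 1):
            x = spacing * (q + 0.5 * r)
            y = spacing * (np.sqrt(3) / 2.0) * r
            pts.append((x, y))
    pts = np.asarray(pts)
    d = np.hypot(pts[:, 0], pts[:, 1])
    order = np.argsort(d, kind="stable")[:n_sites]
    return pts[order] + np.asarray(centre)


def subunit_grating_activations(centres, sigma, k_s, w_surr, f, theta, phi,
                                mode="exact"):
    """Analytic activations r_s of circular DoG subunits for gratings.

    Returns an array of shape ``(n_gratings, n_subunits)``.  Because the
    subunits are circular, the amplitude depends only on f and the shared
    shape parameters; the subunit position enters through the phase only.
    """
    c = _EXPONENT_C[mode]
    f = np.atleast_1d(np.asarray(f, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    phi = np.atleast_1d(np.asarray(phi, dtype=float))
    amp = (np.exp(-c * sigma**2 * f**2)
           - w_surr * np.exp(-c * (k_s * sigma) ** 2 * f**2))
    ph = _subunit_phase(centres, f, theta, phi)
    return amp[:, None] * np.cos(ph)


def _subunit_phase(centres, f, theta, phi):
    """Phase matrix Theta_s, shape (n_gratings, n_subunits)."""
    centres = np.atleast_2d(centres)
    proj = (np.cos(theta)[:, None] * centres[None, :, 0]
            + np.sin(theta)[:, None] * centres[None, :, 1])
    return 2 * np.pi * f[:, None] * proj + (phi - np.pi / 2)[:, None]


def sg_predict_gratings(params: SubunitGridParams, f, theta, phi) -> np.ndarray:
    """Predicted firing rate of the subunit-grid model for gratings."""
    act = params.active() if np.any(params.w == 0) else params
    r = subunit_grating_activations(act.centres, act.sigma, act.k_s,
                                    act.w_surr, f, theta, phi, act.mode)
    u = _logistic(act.beta * r + act.gamma) @ act.w
    return act.out(u)


def subunit_filter_bank(params: SubunitGridParams, shape, pixel_pitch,
                        origin=(0.0, 0.0)) -> np.ndarray:
    """Pixel-space DoG filters of the active subunits, shape (n_sub, H*W).

    ``origin`` shifts the image-centre coordinate frame (um), letting a small
    image patch be placed anywhere in stimulus space.
    """
    act = params.active()
    filts = []
    for (cx, cy) in act.centres:
        sp = DoGSpatialParams(cx - origin[0], cy - origin[1], act.sigma,
                              act.sigma, 0.0, act.k_s, act.w_surr)
        c = _gauss2d(shape, pixel_pitch, sp.x0, sp.y0, sp.sigma_x, sp.sigma_y, 0.0)
        s = _gauss2d(shape, pixel_pitch, sp.x0, sp.y0, act.k_s * act.sigma,
                     act.k_s * act.sigma, 0.0)
        filts.append((c - act.w_surr * s).ravel())
    return np.asarray(filts)


def sg_predict_image(params: SubunitGridParams, images, pixel_pitch,
                     origin=(0.0, 0.0), apply_output: bool = True) -> np.ndarray:
    """Subunit-grid response to images (continuous-space inner products).

    ``images`` is (n, H, W) or (H, W) in Weber contrast.  With
    ``apply_output=False`` the summed weighted subunit-nonlinearity output is
    returned without the Naka-Rushton stage (the generator signal).
    """
    images = np.asarray(images, dtype=float)
    if images.ndim == 2:
        images = images[None]
    act = params.active()
    bank = subunit_filter_bank(params, images.shape[1:], pixel_pitch, origin)
    r = images.reshape(images.shape[0], -1) @ bank.T * pixel_pitch**2
    u = _logistic(act.beta * r + act.gamma) @ act.w
    return act.out(u) if apply_output else u


@dataclass
class FitConfig:
    """Optimizer configuration for subunit-grid fitting.

    ``n_epochs`` defaults to ``4e5 / N_trials`` (N_trials = number of grating
    presentations used for fitting); the learning rate follows a Gaussian
    schedule over epochs with mean ``N_epochs/2`` and SD ``N_epochs/5``.
    """

    lam: float = 1e-5
    eta_max: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-6
    batch: int = 64
    n_epochs: int | None = None
    seed: int = 0
    sigma_bounds: tuple = (4.0, 200.0)

    def epochs_for(self, n_trials: int) -> int:
        if self.n_epochs is not None:
            return max(1, int(self.n_epochs))
        return max(1, int(round(4e5 / n_trials)))


@dataclass
class ModelDiagnostics:
    n_sub: int
    coverage: float | None
    bic: float
    asymmetry: float
    lnl: float
    lam: float


def bic(n_sub: int, n_data: int, lnl: float) -> float:
    """Bayesian information criterion: N_sub ln(N_data) - 2 ln L."""
    return n_sub * np.log(n_data) - 2.0 * lnl


def _pair_inv_d2(centres):
    """Inverse squared pairwise distances, in grid-spacing units.

    Distances are normalized by the smallest pairwise spacing so nearest
    grid neighbours contribute 1/1^2: the regularization ladder then spans
    weak-to-strong independently of the metric units of the lattice.
    """
    d2 = ((centres[:, None, :] - centres[None, :, :]) ** 2).sum(-1)
    off = d2[d2 > 0]
    if off.size:
        d2 = d2 / off.min()
    with np.errstate(divide="ignore"):
        inv = 1.0 / d2
    np.fill_diagonal(inv, 0.0)
    return inv


def _nr_forward(u, a, b, n, k):
    u = np.maximum(u, 1e-12)
    p = u**n
    kn = k**n
    q = p + kn
    R = a * p / q + b
    return R, p, kn, q


def _sg_nll_and_grad(v, centres, cosT, f2, y, c, lam=0.0, inv_d2=None,
                     n_sp=1.0):
    """Full-batch regularized cost and analytic gradient (polish stage).

    ``v`` packs [sigma, k_s, w_surr, beta, gamma, a, b, n, k, w...].  The
    cost matches the stochastic stage: NLL / N_sp plus the density penalty.
    """
    sg, ks, ws, beta, gamma, a, b, n_, k_ = v[:9]
    w = v[9:]
    Ac = np.exp(-c * sg**2 * f2)
    As = np.exp(-c * (ks * sg) ** 2 * f2)
    r = (Ac - ws * As)[:, None] * cosT
    z = beta * r + gamma
    Nz = _logistic(z)
    u = Nz @ w
    R, p_, kn, q = _nr_forward(u, a, b, n_, k_)
    R = np.maximum(R, 1e-9)
    nll = float(np.sum(R - y * np.log(R)))
    gR = 1.0 - y / R
    uu = np.maximum(u, 1e-12)
    g = np.empty_like(v)
    g[5] = np.sum(gR * p_ / q)
    g[6] = np.sum(gR)
    g[7] = np.sum(gR * a * kn * p_ * (np.log(uu) - np.log(k_)) / q**2)
    g[8] = np.sum(gR * (-a * p_ * n_ * k_ ** (n_ - 1) / q**2))
    gu = gR * a * n_ * kn * p_ / (uu * q**2)
    g[9:] = Nz.T @ gu
    gz = (gu[:, None] * w[None, :]) * Nz * (1.0 - Nz)
    g[3] = np.sum(gz * r)
    g[4] = np.sum(gz)
    gA = np.sum(gz * beta * cosT, axis=1)
    dAc = -2 * c * sg * f2 * Ac
    dAs = -2 * c * ks**2 * sg * f2 * As
    g[0] = np.sum(gA * (dAc - ws * dAs))
    g[1] = np.sum(gA * (ws * 2 * c * ks * sg**2 * f2 * As))
    g[2] = np.sum(gA * (-As))
    cost = nll / n_sp
    g /= n_sp
    if lam > 0 and inv_d2 is not None:
        cost += lam * float(w @ inv_d2 @ w)
        g[9:] += 2.0 * lam * (inv_d2 @ w)
    return cost, g


def polish_sg(params: SubunitGridParams, f, theta, phi, counts,
              lam: float = 0.0, threshold_starts=(1.0, 2.0, 4.0),
              sigma_bounds=(4.0, 200.0), maxiter: int = 400,
              support_frac: float = 0.01) -> SubunitGridParams:
    """Deterministic full-batch refinement of an ADAM-fitted model.

    L-BFGS-B with analytic gradients over the shared parameters and the
    weights above ``support_frac`` of the maximum (the stochastic stage
    leaves a long tail of negligible weights), on the same regularized cost
    as the stochastic stage.  The stochastic optimizer equilibrates in a
    shallow valley of the subunit-nonlinearity threshold, so several starts
    with rescaled thresholds (weights rescaled to preserve the mean pool
    drive) are polished and the best cost wins.
    """
    if np.any(params.w > 0) and support_frac > 0:
        w_cut = params.w.copy()
        w_cut[w_cut < support_frac * w_cut.max()] = 0.0
        full_centres, full_w = params.centres, w_cut
        m = w_cut > 0
        params = SubunitGridParams(params.centres[m], w_cut[m], params.sigma,
                                   params.k_s, params.w_surr, params.beta,
                                   params.gamma, copy.copy(params.out),
                                   params.mode)
    else:
        full_centres, full_w = params.centres, params.w
        m = np.ones(len(params.w), bool)
    f = np.asarray(f, float)
    y = np.asarray(counts, float)
    n_sp = float(y.sum())
    c = _EXPONENT_C[params.mode]
    cosT = np.cos(_subunit_phase(params.centres, f, np.asarray(theta, float),
                                 np.asarray(phi, float)))
    f2 = f**2
    inv_d2 = _pair_inv_d2(params.centres) if lam > 0 else None
    r0 = (np.exp(-c * params.sigma**2 * f2)
          - params.w_surr * np.exp(-c * (params.k_s * params.sigma) ** 2 * f2)
          )[:, None] * cosT
    bounds = ([sigma_bounds, (1.0 + 1e-3, 6.0 - 1e-3), (0.0, 0.95),
               (-200, 200), (-20, 20), (1e-6, None), (0.0, None),
               (0.2, 8.0), (1e-6, None)] + [(0.0, None)] * len(params.w))
    best = None
    for gmul in threshold_starts:
        g2 = params.gamma * gmul if params.gamma != 0 else -(gmul - 1.0)
        u_old = (_logistic(params.beta * r0 + params.gamma) @ params.w).mean()
        u_new = (_logistic(params.beta * r0 + g2) @ params.w).mean()
        wsc = params.w * (u_old / max(abs(u_new), 1e-9))
        v0 = np.r_[params.sigma, params.k_s, params.w_surr, params.beta, g2,
                   params.out.a, params.out.b, params.out.n, params.out.k, wsc]
        res = minimize(_sg_nll_and_grad, v0, jac=True,
                       args=(params.centres, cosT, f2, y, c, lam, inv_d2, n_sp),
                       method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": maxiter})
        if best is None or res.fun < best.fun:
            best = res
    v = best.x
    w_out = np.zeros(len(full_w))
    w_out[m] = v[9:]
    out = SubunitGridParams(full_centres, w_out, v[0], v[1], v[2], v[3],
                            v[4], NakaRushton(v[5], v[6], v[7], v[8]),
                            params.mode)
    out.nll = _poisson_nll(sg_predict_gratings(out, f, theta, phi), y) \
        if out.n_sub else np.inf
    return out


def fit_sg(f, theta, phi, counts, centre_init=(0.0, 0.0),
           config: FitConfig | None = None, grid: np.ndarray | None = None,
           init: SubunitGridParams | None = None, sigma_init: float | None = None,
           mode: str = "exact") -> tuple[SubunitGridParams, ModelDiagnostics]:
    """Fit a flashed subunit-grid model with minibatch ADAM.

    The cost is ``-(1/N_sp) ln L + lam * w^T (1/d^2) w`` with N_sp the total
    spike count.  Constraints (w >= 0, sigma/k_s/w_surr and output-stage
    bounds) are enforced by projection after every ADAM step.  Deterministic
    given ``config.seed``.
    """
    cfg = config or FitConfig()
    f = np.asarray(f, float)
    theta = np.asarray(theta, float)
    phi = np.asarray(phi, float)
    y = np.asarray(counts, float)
    n_trials = y.size
    n_sp = float(y.sum())
    if n_sp <= 0:
        raise ValueError("no spikes: subunit-grid fit is undefined")
    c = _EXPONENT_C[mode]

    centres = grid if grid is not None else hex_grid(centre_init)
    n_sub = len(centres)
    cosT = np.cos(_subunit_phase(centres, f, theta, phi))   # (N, n_sub)
    inv_d2 = _pair_inv_d2(centres)

    rng = np.random.default_rng(cfg.seed)
    if init is not None:
        w = init.w.astype(float).copy()
        sigma, k_s, w_surr = init.sigma, init.k_s, init.w_surr
        beta, gamma = init.beta, init.gamma
        a, b, n_exp, k_half = init.out.a, init.out.b, init.out.n, init.out.k
    else:
        d = np.hypot(centres[:, 0] - centre_init[0], centres[:, 1] - centre_init[1])
        sc = sigma_init if sigma_init is not None else 12.0
        w = 0.3 * np.exp(-0.5 * d**2 / (4 * GRID_SPACING) ** 2)
        w *= rng.uniform(0.9, 1.1, n_sub)
        sigma = float(sc)
        k_s, w_surr = 2.0, 0.2
        beta, gamma = 2.0, 0.0
        a = float(max(2.0 * (y.max() - y.mean()), 1.0))
        b = float(max(np.quantile(y, 0.05), 1e-3))
        n_exp = 1.5
        k_half = float(max(w.sum() * 0.4, 1e-3))

    names = ["w", "sigma", "k_s", "w_surr", "beta", "gamma", "a", "b", "n", "k"]
    params = {"w": w, "sigma": sigma, "k_s": k_s, "w_surr": w_surr,
              "beta": beta, "gamma": gamma, "a": a, "b": b, "n": n_exp,
              "k": k_half}
    m = {k_: np.zeros_like(np.asarray(v, float)) for k_, v in params.items()}
    v2 = {k_: np.zeros_like(np.asarray(v, float)) for k_, v in params.items()}

    n_epochs = cfg.epochs_for(n_trials)
    sched_mu, sched_sd = n_epochs / 2.0, n_epochs / 5.0
    t_step = 0
    f2 = f**2

    def project(p):
        p["w"] = np.maximum(p["w"], 0.0)
        p["sigma"] = float(np.clip(p["sigma"], *cfg.sigma_bounds))
        p["k_s"] = float(np.clip(p["k_s"], 1.0 + 1e-3, 6.0 - 1e-3))
        p["w_surr"] = float(np.clip(p["w_surr"], 0.0, 0.95))
        p["a"] = float(max(p["a"], 1e-6))
        p["b"] = float(max(p["b"], 0.0))
        p["n"] = float(np.clip(p["n"], 0.2, 8.0))
        p["k"] = float(max(p["k"], 1e-6))
        return p

    params = project(params)

    for epoch in range(n_epochs):
        eta = cfg.eta_max * np.exp(-0.5 * ((epoch - sched_mu) / sched_sd) ** 2)
        order = rng.permutation(n_trials)
        for start in range(0, n_trials, cfg.batch):
            idx = order[start:start + cfg.batch]
            B = idx.size
            scale = n_trials / (B * n_sp)

            sg, ks, ws = params["sigma"], params["k_s"], params["w_surr"]
            Ac = np.exp(-c * sg**2 * f2[idx])
            As = np.exp(-c * (ks * sg) ** 2 * f2[idx])
            A = Ac - ws * As
            r = A[:, None] * cosT[idx]
            z = params["beta"] * r + params["gamma"]
            Nz = _logistic(z)
            u = Nz @ params["w"]
            R, p_, kn, q = _nr_forward(u, params["a"], params["b"],
                                       params["n"], params["k"])
            R = np.maximum(R, 1e-9)

            gR = scale * (1.0 - y[idx] / R)
            # Naka-Rushton gradients
            g = {}
            g["a"] = float(np.sum(gR * p_ / q))
            g["b"] = float(np.sum(gR))
            uu = np.maximum(u, 1e-12)
            g["n"] = float(np.sum(gR * params["a"] * kn * p_
                                  * (np.log(uu) - np.log(params["k"])) / q**2))
            g["k"] = float(np.sum(gR * (-params["a"] * p_ * params["n"]
                                        * params["k"] ** (params["n"] - 1) / q**2)))
            gu = gR * params["a"] * params["n"] * kn * p_ / (uu * q**2)
            g["w"] = Nz.T @ gu + 2.0 * cfg.lam * (inv_d2 @ params["w"])
            gz = (gu[:, None] * params["w"][None, :]) * Nz * (1.0 - Nz)
            g["beta"] = float(np.sum(gz * r))
            g["gamma"] = float(np.sum(gz))
            gA = np.sum(gz * params["beta"] * cosT[idx], axis=1)
            dAc = -2 * c * sg * f2[idx] * Ac
            dAs = -2 * c * ks**2 * sg * f2[idx] * As
            g["sigma"] = float(np.sum(gA * (dAc - ws * dAs)))
            g["k_s"] = float(np.sum(gA * (-ws * (-2 * c * ks * sg**2 * f2[idx] * As))))
            g["w_surr"] = float(np.sum(gA * (-As)))

            t_step += 1
            b1c = 1 - cfg.beta1**t_step
            b2c = 1 - cfg.beta2**t_step
            for nm in names:
                m[nm] = cfg.beta1 * m[nm] + (1 - cfg.beta1) * g[nm]
                v2[nm] = cfg.beta2 * v2[nm] + (1 - cfg.beta2) * np.square(g[nm])
                step = eta * (m[nm] / b1c) / (np.sqrt(v2[nm] / b2c) + cfg.eps)
                params[nm] = params[nm] - step
            params = project(params)
            if not np.all(np.isfinite(params["w"])):
                raise FloatingPointError("subunit-grid optimization diverged")

    fitted = SubunitGridParams(
        centres=centres, w=params["w"], sigma=params["sigma"],
        k_s=params["k_s"], w_surr=params["w_surr"], beta=params["beta"],
        gamma=params["gamma"],
        out=NakaRushton(params["a"], params["b"], params["n"], params["k"]),
        mode=mode)
    lnl = -_poisson_nll(sg_predict_gratings(fitted, f, theta, phi), y)
    fitted.nll = -lnl
    diag = ModelDiagnostics(
        n_sub=fitted.n_sub, coverage=coverage(fitted, allow_undefined=True),
        bic=bic(fitted.n_sub, n_trials, lnl),
        asymmetry=nonlinearity_asymmetry(fitted.beta, fitted.gamma),
        lnl=lnl, lam=cfg.lam)
    return fitted, diag


def prune_and_refit(params: SubunitGridParams, f, theta, phi, counts,
                    weight_frac: float = 0.05, sd_cut: float = 2.5,
                    refit_baseline: bool = True) -> SubunitGridParams:
    """Prune weak or stray subunits, then rescale the output stage.

    1. Zero every weight below ``weight_frac`` (5%) of the maximum weight.
    2. Fit a 2-D Gaussian (weighted moments) to the weight-summed subunit
       receptive field and zero subunits lying more than ``sd_cut`` (2.5)
       SDs outside it.
    3. Refit the Naka-Rushton output parameters together with a global
       scaling factor of the weights by maximum likelihood.
    """
    if not np.any(params.w > 0):
        raise ValueError("prune requires at least one non-zero weight")
    w = params.w.copy()
    w[w < weight_frac * w.max()] = 0.0
    act = w > 0
    if np.any(act):
        mu = np.average(params.centres[act], weights=w[act], axis=0)
        dc = params.centres[act] - mu
        cov = (w[act][:, None, None] * (dc[:, :, None] * dc[:, None, :])).sum(0) / w[act].sum()
        cov += params.sigma**2 * np.eye(2)   # subunit extent
        try:
            ci = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            ci = np.linalg.pinv(cov)
        d = params.centres - mu
        maha = np.sqrt(np.einsum("ni,ij,nj->n", d, ci, d))
        w[maha > sd_cut] = 0.0
    if not np.any(w > 0):
        pruned = SubunitGridParams(params.centres, w, params.sigma, params.k_s,
                                   params.w_surr, params.beta, params.gamma,
                                   copy.copy(params.out), params.mode)
        pruned.nll = np.inf
        return pruned

    pruned = SubunitGridParams(params.centres, w, params.sigma, params.k_s,
                               params.w_surr, params.beta, params.gamma,
                               copy.copy(params.out), params.mode)
    y = np.asarray(counts, float)
    r = subunit_grating_activations(pruned.centres[w > 0], pruned.sigma,
                                    pruned.k_s, pruned.w_surr, f, theta, phi,
                                    pruned.mode)
    Nz = _logistic(pruned.beta * r + pruned.gamma)
    w_act = w[w > 0]

    def nll(v):
        s, a, b, n_, k_ = v
        u = Nz @ (s * w_act)
        R, _, _, _ = _nr_forward(u, a, b, n_, k_)
        return _poisson_nll(R, y)

    o = pruned.out
    res = minimize(nll, [1.0, o.a, o.b, o.n, o.k], method="L-BFGS-B",
                   bounds=[(1e-6, None), (1e-6, None),
                           (0.0, None) if refit_baseline else (o.b, o.b),
                           (0.2, 8.0), (1e-6, None)],
                   options={"maxiter": 300})
    s, a, b, n_, k_ = res.x
    out_w = w.copy()
    out_w[w > 0] = s * w_act
    refit = SubunitGridParams(params.centres, out_w, pruned.sigma, pruned.k_s,
                              pruned.w_surr, pruned.beta, pruned.gamma,
                              NakaRushton(a, b, n_, k_), pruned.mode)
    refit.nll = float(res.fun)
    return refit


def coverage(params: SubunitGridParams, allow_undefined: bool = False):
    """Receptive-field coverage: subunit diameter over mean neighbour spacing.

    A = 4 sigma (subunit diameter); B = mean nearest-neighbour distance of
    active subunits, weighted by each pair's average weight.  Undefined for
    fewer than three active subunits.
    """
    act = params.active()
    if act.n_sub < 3:
        if allow_undefined:
            return None
        raise ValueError("coverage undefined for fewer than 3 subunits")
    cen, w = act.centres, act.w
    d = np.hypot(cen[:, None, 0] - cen[None, :, 0],
                 cen[:, None, 1] - cen[None, :, 1])
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    nn_d = d[np.arange(len(cen)), nn]
    pw = 0.5 * (w + w[nn])
    B = float(np.sum(pw * nn_d) / np.sum(pw))
    return 4.0 * params.sigma / B


def nonlinearity_asymmetry(beta: float, gamma: float, n_grid: int = 2001) -> float:
    """Asymmetry (1 - M)/(1 + M) of the subunit nonlinearity on [-1, 1].

    The logistic is offset so that input 0 maps to 0 and scaled so its
    maximum over [-1, 1] is unity; M is |min| of the result.  0 for an
    odd-symmetric (linear-like) nonlinearity, 1 for full rectification.
    """
    x = np.linspace(-1.0, 1.0, n_grid)
    nl = _logistic(beta * x + gamma) - _logistic(gamma)
    mx = nl.max()
    if mx <= 0:
        nl = nl / max(abs(nl.min()), 1e-12)
    else:
        nl = nl / mx
    M = abs(float(nl.min()))
    return (1.0 - M) / (1.0 + M)


#: regularization strengths of the standard six-model ladder
LAMBDA_LADDER = (1e-6, 1e-5, 5e-5, 1e-4, 2.5e-4, 5e-4)


def fit_sg_ladder(f, theta, phi, counts, centre_init=(0.0, 0.0),
                  lambdas=LAMBDA_LADDER, seed: int = 0, eta_max: float = 0.02,
                  sigma_init: float = 20.0, grid: np.ndarray | None = None,
                  n_epochs: int | None = None, mode: str = "exact",
                  criterion: str = "bic"):
    """Full subunit-grid pipeline: ladder fits, polish, prune, selection.

    For each regularization strength: minibatch ADAM from a common
    initialization, a deterministic regularized polish, the printed pruning
    rules with an output-stage refit, and a second polish/prune round.  The
    eligible candidate (>= 3 subunits, coverage < 3) minimizing the BIC (or
    maximizing training likelihood with ``criterion='lnl'``) is returned as
    ``(best, lam, candidates)``; ``best`` is None when every candidate is
    ineligible.
    """
    if grid is None:
        grid = hex_grid(centre_init)
    counts = np.asarray(counts, float)
    cands = []
    for lam in lambdas:
        cfg = FitConfig(lam=lam, seed=seed, eta_max=eta_max, n_epochs=n_epochs)
        fitted, _ = fit_sg(f, theta, phi, counts, centre_init=centre_init,
                           config=cfg, grid=grid, sigma_init=sigma_init,
                           mode=mode)
        polished = polish_sg(fitted, f, theta, phi, counts, lam=lam)
        pruned = prune_and_refit(polished, f, theta, phi, counts)
        if pruned.n_sub:
            polished = polish_sg(pruned, f, theta, phi, counts, lam=lam)
            pruned = prune_and_refit(polished, f, theta, phi, counts)
        cands.append((lam, pruned))
    best, lam = select_model(cands, n_data=len(counts), criterion=criterion)
    return best, lam, cands


def select_model(candidates, n_data: int | None = None, max_coverage: float = 3.0,
                 min_subunits: int = 3, criterion: str = "bic"):
    """Select over a regularization ladder.

    ``candidates`` is a list of ``(lam, params)`` with ``params.nll`` set on
    the training data.  Eligibility requires at least ``min_subunits`` active
    subunits and coverage below ``max_coverage``.  Among eligible candidates
    the BIC (flashed fits, needs ``n_data``) or the training log-likelihood
    (``criterion='lnl'``; natural-video selection) decides; ties go to the
    smaller lambda.  Returns ``(params, lam)`` or ``(None, None)`` when no
    candidate is eligible ("excluded").
    """
    best, best_lam, best_score = None, None, np.inf
    for lam, par in sorted(candidates, key=lambda t: t[0]):
        if par is None or par.nll is None or not np.isfinite(par.nll):
            continue
        if par.n_sub < min_subunits:
            continue
        cov = coverage(par, allow_undefined=True)
        if cov is None or cov >= max_coverage:
            continue
        lnl = -par.nll
        if criterion == "bic":
            if n_data is None:
                raise ValueError("BIC selection needs n_data")
            score = bic(par.n_sub, n_data, lnl)
        elif criterion == "lnl":
            score = -lnl
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if score < best_score:   # strict: ties keep the smaller lambda
            best, best_lam, best_score = par, lam, score
    return best, best_lam
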