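"""Natural-image and natural-video response prediction and scoring.

White-noise LN, DoG LN and subunit-grid models produce a generator signal
per stimulus frame; for videos the output nonlinearity is estimated on the
training segment — as an equal-population histogram map (40 bins, linear
interpolation at test) for LN models, or by Poisson maximum likelihood of
the parametric output stage for grating-fitted models — and performance is
the fraction of explained variance (R^2, negatives clipped to zero) on the
trial-averaged test rates.  Flashed-image performance is the Spearman rank
correlation between the raw generator signal and the trial-mean spike
counts, which is invariant to any monotone output transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.optimize import minimize

__all__ = [
    "PredictionResult", "DifferentiatingFixations", "HistogramNonlinearity",
    "fit_histogram_nonlinearity", "r2_explained_variance", "predict_images",
    "predict_video", "fit_output_nonlinearity_poisson",
    "differentiating_fixations",
]


@dataclass
class HistogramNonlinearity:
    """Equal-population histogram map from generator signal to spike count.

    Each of the ``n_bins`` bins contains (up to a remainder of 1) the same
    number of training samples; application interpolates linearly between
    bin (mean signal, mean count) nodes and clamps to the end bins outside
    the training range.
    """

    bin_signal: np.ndarray
    bin_count: np.ndarray

    def __call__(self, signal):
        return np.interp(np.asarray(signal, float), self.bin_signal, self.bin_count)


def fit_histogram_nonlinearity(signal, counts, n_bins: int = 40
                               ) -> HistogramNonlinearity:
    signal = np.asarray(signal, float)
    counts = np.asarray(counts, float)
    if signal.size < n_bins:
        raise ValueError("fewer samples than bins")
    order = np.argsort(signal, kind="stable")
    chunks = np.array_split(order, n_bins)
    bs = np.array([signal[c].mean() for c in chunks])
    bc = np.array([counts[c].mean() for c in chunks])
    keep = np.concatenate([[True], np.diff(bs) > 0])
    return HistogramNonlinearity(bin_signal=bs[keep], bin_count=bc[keep])


@dataclass
class PredictionResult:
    predicted_rate: np.ndarray
    performance_r2: float | None = None
    performance_rho: float | None = None
    nonlinearity: object = None
    flags: list = field(default_factory=list)


def r2_explained_variance(prediction, rate, clip: bool = True) -> float:
    """Fraction of explained variance 1 - SS_res/SS_tot (clipped at 0)."""
    prediction = np.asarray(prediction, float)
    rate = np.asarray(rate, float)
    sst = np.sum((rate - rate.mean()) ** 2)
    if sst == 0:
        raise ValueError("R^2 undefined for constant rate")
    r2 = 1.0 - np.sum((rate - prediction) ** 2) / sst
    return float(max(r2, 0.0)) if clip else float(r2)


def predict_images(model_signal: np.ndarray, mean_counts: np.ndarray
                   ) -> PredictionResult:
    """Score a model's flashed-image generator signal by Spearman rho.

    ``model_signal`` is the model output without an explicit output
    nonlinearity (LN/DoG filter output, or the summed weighted nonlinear
    subunit outputs).  A constant signal leaves rho undefined; it is
    reported as 0 with a flag.
    """
    model_signal = np.asarray(model_signal, float)
    mean_counts = np.asarray(mean_counts, float)
    if model_signal.shape != mean_counts.shape:
        raise ValueError("model/response geometry mismatch")
    res = PredictionResult(predicted_rate=model_signal)
    if np.std(model_signal) == 0 or np.std(mean_counts) == 0:
        res.performance_rho = 0.0
        res.flags.append("degenerate: constant input to rank correlation")
        return res
    rho = sps.spearmanr(model_signal, mean_counts).statistic
    res.performance_rho = float(rho)
    return res


def fit_output_nonlinearity_poisson(signal, counts, form: str = "logistic",
                                    maxiter: int = 300):
    """ML (Poisson) scalar output nonlinearity on the training segment.

    ``logistic``: R = a / (1 + exp(-(b x + c))); ``naka_rushton``:
    R = a x^n / (x^n + k^n) + b on the non-negative signal.  Returns a
    callable.
    """
    x = np.asarray(signal, float)
    y = np.asarray(counts, float)

    if form == "logistic":
        sd = x.std() or 1.0

        def make(v):
            return lambda s: v[0] / (1 + np.exp(-np.clip(v[1] * (np.asarray(s) - x.mean()) / sd + v[2], -500, 500)))
        x0 = [max(y.max(), 1e-2), 1.0, 0.0]
        bounds = [(1e-6, None), (-100, 100), (-20, 20)]
    elif form == "naka_rushton":
        x = np.maximum(x, 0.0)
        scale = np.quantile(x, 0.9) or 1.0

        def make(v):
            def g(s):
                s = np.maximum(np.asarray(s, float), 1e-12) / scale
                p = s ** v[2]
                return v[0] * p / (p + v[3] ** v[2]) + v[1]
            return g
        x0 = [max(y.max(), 1e-2), max(y.min(), 1e-3), 1.5, 1.0]
        bounds = [(1e-6, None), (0, None), (0.2, 8), (1e-6, None)]
    else:
        raise ValueError(f"unknown form {form!r}")

    def nll(v):
        r = np.maximum(make(v)(x), 1e-9)
        return float(np.sum(r - y * np.log(r)))

    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter})
    return make(res.x)


def predict_video(signal_train, counts_train, signal_test, rate_test,
                  nonlinearity: str = "histogram", n_bins: int = 40
                  ) -> PredictionResult:
    """Predict test-segment firing rates from a generator signal.

    The nonlinearity ('histogram' for white-noise LN models, 'logistic' or
    'naka_rushton' for grating-fitted models) is estimated on the disjoint
    training segment; R^2 is computed against the trial-averaged test rate
    with negatives clipped to zero.
    """
    if len(np.asarray(signal_train)) == 0:
        raise ValueError("empty training segment")
    if nonlinearity == "histogram":
        nl = fit_histogram_nonlinearity(signal_train, counts_train, n_bins)
    else:
        nl = fit_output_nonlinearity_poisson(signal_train, counts_train,
                                             form=nonlinearity)
    pred = nl(signal_test)
    return PredictionResult(predicted_rate=pred,
                            performance_r2=r2_explained_variance(pred, rate_test),
                            nonlinearity=nl)


@dataclass
class DifferentiatingFixations:
    scores: np.ndarray
    top_set: np.ndarray
    nonlinear_set: np.ndarray
    linear_set: np.ndarray
    flags: list = field(default_factory=list)


def differentiating_fixations(pred_a_by_cell, pred_b_by_cell, response_range,
                              boundaries) -> DifferentiatingFixations:
    """Rank fixations by how much two models' predictions diverge.

    Per cell and fixation, the deviation is the mean over fixation frames of
    |pred_a - pred_b| normalized by the cell's overall response range
    (max - min over the test segment); the score averages the two cells.
    The top set is the ceil(20%) highest-scoring fixations; the nonlinear /
    linear sets split the descending ranking in half.  Selection uses only
    the model predictions, never the measured responses; ties break by
    fixation index.
    """
    cells = list(pred_a_by_cell)
    n_fix = len(boundaries)
    scores = np.zeros(n_fix)
    for cid in cells:
        pa = np.asarray(pred_a_by_cell[cid], float)
        pb = np.asarray(pred_b_by_cell[cid], float)
        if pa.shape != pb.shape:
            raise ValueError("model predictions must be frame-aligned")
        rng_ = response_range[cid]
        if rng_ <= 0:
            raise ValueError(f"non-positive response range for {cid}")
        dev = np.abs(pa - pb) / rng_
        scores += np.array([dev[a:b].mean() for a, b in boundaries]) / len(cells)

    order = np.lexsort((np.arange(n_fix), -scores))   # descending, index ties
    n_top = int(np.ceil(0.2 * n_fix))
    flags = []
    if n_fix < 5:
        flags.append("degenerate: fewer than 5 fixations, top set unreliable")
    if np.allclose(scores, scores[0]):
        flags.append("uninformative: identical model predictions")
    half = n_fix // 2
    return DifferentiatingFixations(
        scores=scores,
        top_set=np.sort(order[:n_top]),
        nonlinear_set=np.sort(order[:half]),
        linear_set=np.sort(order[half:]),
        flags=flags)
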