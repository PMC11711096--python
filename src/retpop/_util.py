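"""Shared numerical helpers: robust statistics and reproducible RNG streams."""

from __future__ import annotations

import numpy as np

#: scale factor that makes the median absolute deviation a consistent
#: estimator of the standard deviation for normal data
MAD_SCALE = 1.4826


def robust_sd(x: np.ndarray) -> float:
    """Robust standard deviation: 1.4826 x median absolute deviation."""
    x = np.asarray(x, dtype=float).ravel()
    med = np.median(x)
    return MAD_SCALE * float(np.median(np.abs(x - med)))


def substream(seed: int, *ids) -> np.random.Generator:
    """Derive an independent RNG stream from a global seed and integer ids.

    Streams are a pure function of ``(seed, *ids)``: adding new cells or
    trials never reshuffles the draws of existing ones.
    """
    key = tuple(int(abs(hash(i)) % (2**31)) if not isinstance(i, (int, np.integer)) else int(i)
                for i in ids)
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + key))


def symmetrized_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetrized coefficient of determination between two rate profiles.

    Mean of R^2(a predicts b) and R^2(b predicts a), where
    R^2 = 1 - SS_res / SS_tot.  May be negative for anti-correlated or very
    noisy inputs.  Raises ``ValueError`` on zero-variance input, where the
    quantity is undefined.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 samples")
    va = np.sum((a - a.mean()) ** 2)
    vb = np.sum((b - b.mean()) ** 2)
    if va == 0 or vb == 0:
        raise ValueError("symmetrized R^2 undefined for zero-variance input")
    ss = np.sum((a - b) ** 2)
    return 0.5 * float((1 - ss / vb) + (1 - ss / va))
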