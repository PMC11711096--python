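"""Frequency-domain spike-train information rates and fractional redundancy.

Spike trains binned at 0.4 ms are cut into 0.8-s non-overlapping sections
per trial and Fourier transformed; the real (cosine) and imaginary (sine)
coefficients of every frequency up to a 200 Hz cutoff are treated as samples
of a Gaussian whose entropy is computed analytically.  Signal entropy uses
the variance over sections (averaged over trials), noise entropy the
variance over trials (averaged over sections); the information rate is the
entropy difference summed over frequencies and divided by the section
length.  For a cell pair the 4x4 covariance over (cos1, sin1, cos2, sin2)
replaces the per-cell variances.

Two entropy conventions are provided.  ``"printed"`` sums the variances (or
the four pair eigenvalues) inside a single logarithm,
``H = 1/2 log2[2 pi e (V_cos + V_sin)]``; it satisfies the duplicated-cell
identity I_pair = I_single exactly but assigns C = 1 even to two independent
cells with identical statistics.  The default ``"det"`` mode uses the full
Gaussian entropy ``H = 1/2 sum_k log2(2 pi e lambda_k)`` (log-determinant),
which is additive over independent cells (C -> 0) and approaches C -> 1 for
duplicated signals with independent noise as the signal-to-noise ratio
grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthkit import SpikeRaster

__all__ = [
    "SectionedFourier", "EntropySpectrum", "RedundancyResult",
    "section_and_transform", "entropy_spectrum", "information_rate",
    "pair_information", "fractional_redundancy", "cell_information",
]

BIN_WIDTH = 4e-4          # s
SECTION_LENGTH = 0.8      # s
CUTOFF_HZ = 200.0

_LOG2_2PIE = np.log2(2 * np.pi * np.e)


@dataclass
class SectionedFourier:
    """DFT coefficients per (trial, section, frequency); DC excluded."""

    c_cos: np.ndarray          # (trials, sections, F)
    c_sin: np.ndarray
    freqs: np.ndarray          # Hz
    bin_width: float
    section_length: float


@dataclass
class EntropySpectrum:
    h_signal: np.ndarray       # bits per mode, per frequency
    h_noise: np.ndarray
    freqs: np.ndarray
    section_length: float
    mode: str

    @property
    def info_per_freq(self) -> np.ndarray:
        """Per-frequency information rate contribution (bits/s)."""
        return (self.h_signal - self.h_noise) / self.section_length


@dataclass
class RedundancyResult:
    i_single: dict
    i_pair: float
    c_frac: float


def section_and_transform(raster: SpikeRaster,
                          section_length: float = SECTION_LENGTH,
                          cutoff_hz: float = CUTOFF_HZ) -> SectionedFourier:
    """Cut each trial into non-overlapping sections and Fourier transform.

    Sections are cut from the trial start; a leftover tail shorter than one
    section is dropped.  The unnormalized forward DFT is used (any
    multiplicative constant cancels in the signal-noise entropy difference);
    DC is excluded and frequencies retained up to the cutoff.
    """
    n_bins = int(round(section_length / raster.bin_width))
    n_sections = raster.counts.shape[1] // n_bins
    if n_sections < 2 or raster.n_trials < 2:
        raise ValueError("need at least 2 sections and 2 trials")
    x = raster.counts[:, :n_sections * n_bins].reshape(
        raster.n_trials, n_sections, n_bins).astype(float)
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(n_bins, raster.bin_width)
    keep = (freqs > 0) & (freqs <= cutoff_hz + 1e-9)
    return SectionedFourier(c_cos=spec.real[..., keep], c_sin=-spec.imag[..., keep],
                            freqs=freqs[keep], bin_width=raster.bin_width,
                            section_length=n_bins * raster.bin_width)


def _cov_stack(coeffs, over: str):
    """Per-frequency covariance of stacked coefficients.

    ``coeffs``: (trials, sections, F, D).  ``over='sections'`` takes the
    covariance across sections per trial and averages over trials (signal);
    ``over='trials'`` the transpose (noise).  Returns (F, D, D).
    """
    if over == "trials":
        coeffs = coeffs.swapaxes(0, 1)
    T, S, F, D = coeffs.shape
    mu = coeffs.mean(axis=1, keepdims=True)
    dc = coeffs - mu
    cov = np.einsum("tsfi,tsfj->tfij", dc, dc) / (S - 1)
    return cov.mean(axis=0)


def _entropy_from_cov(cov: np.ndarray, mode: str) -> np.ndarray:
    """Gaussian entropy per frequency from (F, D, D) covariances (bits/mode).

    ``printed``: 1/2 log2[2 pi e * trace]; ``det``: 1/2 sum log2(2 pi e
    lambda_k).  Degenerate (non-positive) variances give -inf sentinels.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if mode == "printed":
            tr = np.trace(cov, axis1=1, axis2=2)
            h = 0.5 * np.where(tr > 0, np.log2(tr) + _LOG2_2PIE, -np.inf)
        elif mode == "det":
            lam = np.linalg.eigvalsh(cov)
            # eigenvalues at relative machine noise mark a degenerate mode
            tol = 1e-10 * np.maximum(lam.max(axis=1, keepdims=True), 1e-300)
            bad = np.any(lam <= tol, axis=1)
            lam_safe = np.where(lam > tol, lam, 1.0)
            h = 0.5 * np.sum(np.log2(lam_safe) + _LOG2_2PIE, axis=1)
            h = np.where(bad, -np.inf, h)
        else:
            raise ValueError(f"unknown entropy mode {mode!r}")
    return h


def entropy_spectrum(sf: SectionedFourier, mode: str = "det") -> EntropySpectrum:
    """Per-frequency signal and noise entropies of a single cell."""
    stack = np.stack([sf.c_cos, sf.c_sin], axis=-1)    # (T, S, F, 2)
    cov_sig = _cov_stack(stack, "sections")
    cov_noi = _cov_stack(stack, "trials")
    return EntropySpectrum(h_signal=_entropy_from_cov(cov_sig, mode),
                           h_noise=_entropy_from_cov(cov_noi, mode),
                           freqs=sf.freqs, section_length=sf.section_length,
                           mode=mode)


def information_rate(es: EntropySpectrum) -> float:
    """Total information rate in bits/s (sum over retained frequencies).

    Frequencies where either entropy is a -inf sentinel (zero variance) are
    propagated: a zero noise variance with non-zero signal gives +inf (the
    estimator ceiling for a noise-free response).
    """
    contrib = es.info_per_freq
    if np.any(np.isneginf(es.h_noise) & np.isfinite(es.h_signal)):
        return np.inf
    return float(np.sum(contrib[np.isfinite(contrib)]))


def cell_information(raster: SpikeRaster, mode: str = "det",
                     section_length: float = SECTION_LENGTH,
                     cutoff_hz: float = CUTOFF_HZ) -> float:
    """Convenience: information rate of a single raster."""
    return information_rate(entropy_spectrum(
        section_and_transform(raster, section_length, cutoff_hz), mode))


def pair_information(sf_a: SectionedFourier, sf_b: SectionedFourier,
                     mode: str = "det") -> float:
    """Joint information rate of a cell pair (bits/s).

    Per frequency, the 4x4 covariance of (cos_a, sin_a, cos_b, sin_b) over
    sections (averaged over trials) and over trials (averaged over sections)
    gives the pair signal and noise entropies via the four eigenvalues.
    """
    if (sf_a.freqs.shape != sf_b.freqs.shape
            or not np.allclose(sf_a.freqs, sf_b.freqs)
            or sf_a.c_cos.shape != sf_b.c_cos.shape):
        raise ValueError("pair requires matched sectioning and frequency grids")
    stack = np.stack([sf_a.c_cos, sf_a.c_sin, sf_b.c_cos, sf_b.c_sin], axis=-1)
    cov_sig = _cov_stack(stack, "sections")
    cov_noi = _cov_stack(stack, "trials")
    es = EntropySpectrum(h_signal=_entropy_from_cov(cov_sig, mode),
                         h_noise=_entropy_from_cov(cov_noi, mode),
                         freqs=sf_a.freqs, section_length=sf_a.section_length,
                         mode=mode)
    return information_rate(es)


def fractional_redundancy(i_a: float, i_b: float, i_ab: float) -> float:
    """C = (I_a + I_b - I_ab) / min(I_a, I_b).

    0 for independent information, 1 when one cell adds nothing; negative
    values (synergy) and values above 1 are possible and returned as-is.
    Undefined (ValueError) when the smaller single-cell information is not
    positive.
    """
    lo = min(i_a, i_b)
    if not np.isfinite(lo) or lo <= 0:
        raise ValueError("fractional redundancy needs positive single-cell information")
    return float((i_a + i_b - i_ab) / lo)


def pair_redundancy(raster_a: SpikeRaster, raster_b: SpikeRaster,
                    mode: str = "det") -> RedundancyResult:
    """Single-cell rates, pair rate and fractional redundancy in one call."""
    sa = section_and_transform(raster_a)
    sb = section_and_transform(raster_b)
    ia = information_rate(entropy_spectrum(sa, mode))
    ib = information_rate(entropy_spectrum(sb, mode))
    iab = pair_information(sa, sb, mode)
    return RedundancyResult(i_single={raster_a.cell_id or "a": ia,
                                      raster_b.cell_id or "b": ib},
                            i_pair=iab, c_frac=fractional_redundancy(ia, ib, iab))
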