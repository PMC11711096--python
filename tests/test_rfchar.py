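"""Spike-triggered averaging, filter separation, contours, quality metrics."""

import numpy as np
import pytest

from retpop import rfchar, synthkit as sk
from retpop._util import robust_sd


def _stim_frames(n, shape, seed):
    return sk.make_checkerboard(30.0, n, seed=seed, shape_squares=shape)


class TestComputeSta:
    def test_single_spike_returns_snippet(self):
        stim = _stim_frames(40, (6, 6), 0)
        counts = np.zeros((1, 40), dtype=np.int64)
        counts[0, 30] = 1
        r = sk.SpikeRaster(counts, 1 / 30.0)
        sta = rfchar.compute_sta(stim, r, window_s=0.5)
        n_lags = sta.shape[0]
        for lag in range(n_lags):
            assert np.array_equal(sta[lag], stim.frames[30 - lag])

    def test_random_spikes_average_to_zero(self):
        rng = np.random.default_rng(1)
        stim = _stim_frames(3000, (5, 5), 1)
        counts = rng.poisson(0.5, (1, 3000)).astype(np.int64)
        r = sk.SpikeRaster(counts, 1 / 30.0)
        sta = rfchar.compute_sta(stim, r, window_s=0.2)
        # CLT bound: sd of mean of ~1,500 +/-1 values
        assert np.max(np.abs(sta)) < 5 / np.sqrt(counts.sum())

    def test_no_spikes_rejected(self):
        stim = _stim_frames(40, (4, 4), 2)
        r = sk.SpikeRaster(np.zeros((1, 40), dtype=np.int64), 1 / 30.0)
        with pytest.raises(ValueError):
            rfchar.compute_sta(stim, r)

    def test_linearity_in_rasters(self):
        """STA of a summed raster is the spike-weighted mean of part STAs."""
        stim = _stim_frames(500, (4, 4), 3)
        rng = np.random.default_rng(4)
        c1 = rng.poisson(0.3, (1, 500)).astype(np.int64)
        c2 = rng.poisson(0.6, (1, 500)).astype(np.int64)
        s1 = rfchar.compute_sta(stim, sk.SpikeRaster(c1, 1 / 30.0), 0.1)
        s2 = rfchar.compute_sta(stim, sk.SpikeRaster(c2, 1 / 30.0), 0.1)
        s12 = rfchar.compute_sta(stim, sk.SpikeRaster(c1 + c2, 1 / 30.0), 0.1)
        n_lags = s1.shape[0]
        w1 = c1[0, n_lags - 1:].sum()
        w2 = c2[0, n_lags - 1:].sum()
        assert np.allclose(s12, (w1 * s1 + w2 * s2) / (w1 + w2), atol=1e-12)


class TestSeparateFilters:
    def test_rank_one_recovery(self):
        """An outer-product STA separates exactly up to scale and sign."""
        t = np.array([0.1, 0.4, 1.0, -0.6, 0.05])
        x = np.arange(7) - 3
        s = np.exp(-(x[:, None] ** 2 + x[None] ** 2) / 3.0)
        sta = t[:, None, None] * s[None]
        spatial, temporal = rfchar.separate_filters(sta, threshold_sd=4.5)
        ct = np.corrcoef(temporal, t)[0, 1]
        assert abs(ct) > 0.9999
        cs = np.corrcoef(spatial.ravel(), s.ravel())[0, 1]
        assert abs(cs) > 0.9999
        # sign convention: temporal extremum positive
        assert temporal[np.argmax(np.abs(temporal))] > 0

    def test_degenerate_mad_flagged(self):
        """All-zero STA has zero robust SD: rejected with a clear error."""
        assert robust_sd(np.array([0, 0, 0, 1.0])) == 0.0
        with pytest.raises(ValueError):
            rfchar.separate_filters(np.zeros((5, 4, 4)))

    def test_noisy_rank_one(self):
        rng = np.random.default_rng(5)
        t = np.sin(np.linspace(0, np.pi, 10))
        s = np.exp(-((np.arange(9) - 4)[:, None] ** 2
                     + (np.arange(9) - 4)[None] ** 2) / 4.0)
        sta = t[:, None, None] * s[None] + rng.normal(0, 0.02, (10, 9, 9))
        spatial, temporal = rfchar.separate_filters(sta)
        assert np.corrcoef(spatial.ravel(), s.ravel())[0, 1] > 0.9


class TestExtractContour:
    def test_gaussian_area_closed_form(self):
        """25%-level area of a blurred Gaussian matches pi r^2."""
        sig_px = 3.0
        x = np.arange(31) - 15
        sf = np.exp(-(x[:, None] ** 2 + x[None] ** 2) / (2 * sig_px**2))
        pitch, up, blur = 7.5, 8, 4.0
        contour, centre, area = rfchar.extract_contour(sf, pitch, upsample=up,
                                                       blur_sigma_px=blur)
        sig_up = np.hypot(sig_px * up, blur)   # blur adds in quadrature
        r_um = sig_up * np.sqrt(2 * np.log(4)) * pitch / up
        assert area == pytest.approx(np.pi * r_um**2, rel=0.02)
        assert centre[0] == pytest.approx(0.0, abs=pitch / 2)
        assert centre[1] == pytest.approx(0.0, abs=pitch / 2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        x = np.arange(21) - 10
        sf = np.exp(-(x[:, None] ** 2 + x[None] ** 2) / 18.0)
        sf += rng.normal(0, 0.01, sf.shape)
        _, _, a1 = rfchar.extract_contour(sf, 7.5)
        _, _, a2 = rfchar.extract_contour(3.7 * sf, 7.5)
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_flat_filter_rejected(self):
        with pytest.raises(ValueError):
            rfchar.extract_contour(np.ones((8, 8)), 7.5)


class TestCharacterizeRf:
    def test_pipeline_returns_consistent_fit(self):
        """The one-call characterization bundles STA filters and contour."""
        stim = _stim_frames(2000, (12, 12), 11)
        from retpop import gratmodels as gm
        sp = gm.DoGSpatialParams(0.0, 0.0, 45.0, 45.0, 0.0, 2.0, 0.2)
        enc = sk.DoGLNEncoder(gm.DoGLNParams(sp, beta=24.0, gamma=-1.0, a=80.0))
        rate = enc.rate(stim.frames, stim.pixel_pitch)
        raster = sk.rate_to_raster(rate, 30.0, 1 / 30.0, 1,
                                   np.random.default_rng(12))
        fit = rfchar.characterize_rf(stim, raster, window_s=0.2)
        assert fit.spatial_filter.shape == (12, 12)
        assert fit.area > 0 and len(fit.contour) > 4
        assert np.hypot(*fit.centre) < 60.0


class TestSymmetrizedR2:
    def test_identical_traces(self):
        x = np.sin(np.linspace(0, 7, 50))
        assert rfchar.symmetrized_r2(x, x) == pytest.approx(1.0)

    def test_noise_dominated(self):
        """b = a + large noise: symmetrized R^2 collapses towards zero."""
        rng = np.random.default_rng(7)
        a = np.sin(np.linspace(0, 20, 2000))
        b = a + rng.normal(0, 10, 2000)
        # analytic: R^2(a->b) ~ SNR/(1+SNR) with SNR = var(a)/var(noise)
        assert rfchar.symmetrized_r2(a, b) <= 0.1

    def test_symmetry_and_zero_variance(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=(2, 100))
        assert rfchar.symmetrized_r2(a, b) == rfchar.symmetrized_r2(b, a)
        with pytest.raises(ValueError):
            rfchar.symmetrized_r2(np.ones(10), b[:10])


class TestFanoPerFixation:
    def test_poisson_weighted_fano_near_one(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(5.0, (200, 100)).astype(np.int64)
        r = sk.SpikeRaster(counts, 0.01)
        bounds = [(i * 10, (i + 1) * 10) for i in range(10)]
        qm = rfchar.fano_per_fixation(r, bounds)
        assert qm.fano_weighted == pytest.approx(1.0, abs=0.15)

    def test_deterministic_trials_zero(self):
        counts = np.tile(np.arange(10, dtype=np.int64), (4, 1))
        qm = rfchar.fano_per_fixation(sk.SpikeRaster(counts, 0.01),
                                      [(0, 10)])
        assert qm.fano_weighted == pytest.approx(0.0)

    def test_low_count_fixations_excluded(self):
        """A fixation with mean < 3 spikes is dropped from the summary."""
        rng = np.random.default_rng(10)
        big = rng.poisson(20.0, (50, 10))
        # second fixation: mean spike count exactly 2.9 (< 3)
        small = np.zeros((50, 10), dtype=np.int64)
        small[:45, 0] = 3
        small[45:, 0] = 2
        counts = np.concatenate([big, small], axis=1).astype(np.int64)
        qm = rfchar.fano_per_fixation(sk.SpikeRaster(counts, 0.01),
                                      [(0, 10), (10, 20)])
        assert qm.included.tolist() == [True, False]
        assert np.isfinite(qm.fano_weighted)
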