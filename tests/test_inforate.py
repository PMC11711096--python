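"""Frequency-domain information rates and fractional redundancy."""

import numpy as np
import pytest

from retpop import inforate as ir
from retpop.synthkit import SpikeRaster


def modulated_raster(rng, n_trials=24, n_sections=24, rate_hz=120.0,
                     mod_hz=10.0, mod_depth=0.9, bin_width=ir.BIN_WIDTH,
                     phase_per_section=True):
    """Poisson raster with a sinusoidal rate whose phase varies by section."""
    n_bins = int(round(ir.SECTION_LENGTH / bin_width))
    t = np.arange(n_bins) * bin_width
    lam = np.empty((n_sections, n_bins))
    for s in range(n_sections):
        ph = rng.uniform(0, 2 * np.pi) if phase_per_section else 0.0
        lam[s] = rate_hz * (1 + mod_depth * np.sin(2 * np.pi * mod_hz * t + ph))
    lam = lam.reshape(-1) * bin_width
    counts = rng.poisson(lam[None, :].repeat(n_trials, axis=0))
    return SpikeRaster(counts=counts.astype(np.int64), bin_width=bin_width)


class TestSectioning:
    def test_grid_arithmetic(self):
        """0.8 s at 0.4 ms: 2,000 bins, 1.25 Hz spacing, 160 kept frequencies."""
        rng = np.random.default_rng(0)
        r = modulated_raster(rng, n_trials=3, n_sections=3)
        sf = ir.section_and_transform(r)
        assert sf.c_cos.shape == (3, 3, 160)
        assert sf.freqs[0] == pytest.approx(1.25)
        assert sf.freqs[-1] == pytest.approx(200.0)

    def test_sinusoid_energy_concentrates(self):
        """A 10 Hz rate modulation puts its energy at the 10 Hz coefficient."""
        rng = np.random.default_rng(1)
        r = modulated_raster(rng, n_trials=30, n_sections=10, mod_depth=0.95)
        sf = ir.section_and_transform(r)
        power = (sf.c_cos**2 + sf.c_sin**2).mean(axis=(0, 1))
        k10 = np.argmin(np.abs(sf.freqs - 10.0))
        noise_floor = np.median(power)
        assert power[k10] > 20 * noise_floor

    def test_parseval(self):
        """Coefficient power accounts for section variance (DFT convention)."""
        rng = np.random.default_rng(2)
        r = modulated_raster(rng, n_trials=2, n_sections=2)
        n_bins = 2000
        x = r.counts[0, :n_bins].astype(float)
        spec = np.fft.rfft(x)
        total = np.sum(np.abs(spec[1:]) ** 2 * np.where(
            np.arange(1, len(spec)) == n_bins // 2, 1.0, 2.0)) / n_bins
        assert total == pytest.approx(np.sum((x - x.mean()) ** 2), rel=1e-9)

    def test_too_short_rejected(self):
        r = SpikeRaster(counts=np.zeros((3, 100), dtype=np.int64),
                        bin_width=ir.BIN_WIDTH)
        with pytest.raises(ValueError):
            ir.section_and_transform(r)


class TestEntropies:
    def test_gaussian_closed_form_printed_mode(self):
        """i.i.d. Gaussian coefficients: H -> 1/2 log2(2 pi e (Vc + Vs))."""
        rng = np.random.default_rng(3)
        V = 2.5
        sf = ir.SectionedFourier(
            c_cos=rng.normal(0, np.sqrt(V), (40, 40, 3)),
            c_sin=rng.normal(0, np.sqrt(V), (40, 40, 3)),
            freqs=np.array([1.25, 2.5, 3.75]), bin_width=ir.BIN_WIDTH,
            section_length=0.8)
        es = ir.entropy_spectrum(sf, mode="printed")
        expect = 0.5 * np.log2(2 * np.pi * np.e * 2 * V)
        assert np.allclose(es.h_signal, expect, atol=0.15)
        assert np.allclose(es.h_noise, expect, atol=0.15)

    def test_identical_sections_sentinel(self):
        """Zero variance across sections and trials gives -inf sentinels."""
        c = np.ones((4, 5, 2))
        sf = ir.SectionedFourier(c, c, np.array([1.25, 2.5]), ir.BIN_WIDTH, 0.8)
        es = ir.entropy_spectrum(sf, mode="printed")
        assert np.all(np.isneginf(es.h_signal))

    def test_count_doubling_shifts_both_entropies_one_bit(self):
        rng = np.random.default_rng(4)
        r = modulated_raster(rng, n_trials=12, n_sections=12)
        sf = ir.section_and_transform(r)
        doubled = ir.SectionedFourier(2 * sf.c_cos, 2 * sf.c_sin, sf.freqs,
                                      sf.bin_width, sf.section_length)
        for mode, bits in [("printed", 1.0), ("det", 2.0)]:
            e1 = ir.entropy_spectrum(sf, mode)
            e2 = ir.entropy_spectrum(doubled, mode)
            assert np.allclose(e2.h_signal - e1.h_signal, bits, atol=1e-9)
            assert np.allclose(e2.h_noise - e1.h_noise, bits, atol=1e-9)
            # and the information rate is unchanged by any rescaling
            assert ir.information_rate(e2) == pytest.approx(
                ir.information_rate(e1), rel=1e-9)


class TestPairInformation:
    def test_duplicated_cell_identity_printed_mode(self):
        """Pairing a raster with itself: I_pair = I_single exactly (printed)."""
        rng = np.random.default_rng(5)
        r = modulated_raster(rng, n_trials=16, n_sections=16)
        sf = ir.section_and_transform(r)
        i_single = ir.information_rate(ir.entropy_spectrum(sf, "printed"))
        i_pair = ir.pair_information(sf, sf, "printed")
        assert i_pair == pytest.approx(i_single, rel=1e-9)

    def test_independent_cells_additive_det_mode(self):
        """Independent cells with identical statistics: I_pair = I_a + I_b."""
        rng = np.random.default_rng(6)
        diffs, scale = [], []
        for _ in range(12):
            ra = modulated_raster(rng, n_trials=20, n_sections=20)
            rb = modulated_raster(rng, n_trials=20, n_sections=20)
            sa, sb = ir.section_and_transform(ra), ir.section_and_transform(rb)
            ia = ir.information_rate(ir.entropy_spectrum(sa, "det"))
            ib = ir.information_rate(ir.entropy_spectrum(sb, "det"))
            iab = ir.pair_information(sa, sb, "det")
            diffs.append(iab - ia - ib)
            scale.append(min(ia, ib))
        assert abs(np.mean(diffs)) / np.mean(scale) < 0.05

    def test_fractional_redundancy_arithmetic(self):
        assert ir.fractional_redundancy(2.0, 3.0, 4.0) == pytest.approx(0.5)
        assert ir.fractional_redundancy(2.0, 3.0, 5.0) == pytest.approx(0.0)
        assert ir.fractional_redundancy(2.0, 3.0, 3.0) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            ir.fractional_redundancy(0.0, 1.0, 1.0)

    def test_duplicated_signal_high_redundancy_det_mode(self):
        """Same strong signal, independent Poisson noise: C_frac near 1."""
        rng = np.random.default_rng(7)
        n_bins = int(round(ir.SECTION_LENGTH / ir.BIN_WIDTH))
        t = np.arange(n_bins) * ir.BIN_WIDTH
        n_sections, n_trials = 30, 30
        lam = np.empty((n_sections, n_bins))
        for s in range(n_sections):
            ph = rng.uniform(0, 2 * np.pi)
            lam[s] = 25000.0 * (1 + 0.99 * np.sin(2 * np.pi * 10.0 * t + ph))
        lam = lam.reshape(-1) * ir.BIN_WIDTH
        ra = SpikeRaster(rng.poisson(lam[None].repeat(n_trials, 0)).astype(np.int64),
                         ir.BIN_WIDTH)
        rb = SpikeRaster(rng.poisson(lam[None].repeat(n_trials, 0)).astype(np.int64),
                         ir.BIN_WIDTH)
        res = ir.pair_redundancy(ra, rb, "det")
        assert 0.9 <= res.c_frac <= 1.0


class TestBiasStability:
    def test_half_trials_within_ten_percent(self):
        """Information rate on 50% vs 100% of trials differs by < 10%."""
        rng = np.random.default_rng(8)
        r = modulated_raster(rng, n_trials=40, n_sections=24)
        sf_full = ir.section_and_transform(r)
        half = SpikeRaster(r.counts[:20], r.bin_width)
        sf_half = ir.section_and_transform(half)
        i_full = ir.information_rate(ir.entropy_spectrum(sf_full, "det"))
        i_half = ir.information_rate(ir.entropy_spectrum(sf_half, "det"))
        assert abs(i_half - i_full) / i_full < 0.10
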