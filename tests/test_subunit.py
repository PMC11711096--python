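"""Subunit-grid model: prediction, regularizer, pruning, selection,
parameter characterization."""

import numpy as np
import pytest

from retpop import gratmodels as gm
from retpop.gratmodels._subunit import _pair_inv_d2


def small_sg(w=None, beta=4.0, gamma=-2.0, out=None):
    grid = gm.hex_grid((0.0, 0.0), 16.0, 19)
    w = np.ones(len(grid)) if w is None else w
    return gm.SubunitGridParams(
        centres=grid, w=w, sigma=10.0, k_s=2.0, w_surr=0.2, beta=beta,
        gamma=gamma, out=out or gm.NakaRushton(10.0, 0.7, 2.0, 1.0))


class TestSgPredict:
    def test_all_zero_weights_give_baseline(self):
        p = small_sg(w=np.zeros(19))
        r = gm.sg_predict_gratings(p, [0.01], [0.0], [0.0])
        assert r[0] == pytest.approx(p.out.b)

    def test_weight_monotonicity(self):
        """Increasing any single weight never decreases the response."""
        rng = np.random.default_rng(0)
        p = small_sg(w=rng.uniform(0, 1, 19))
        f, th, ph = [0.002, 0.01], [0.3, 1.2], [0.5, 4.0]
        base = gm.sg_predict_gratings(p, f, th, ph)
        for i in [0, 7, 18]:
            q = small_sg(w=p.w.copy())
            q.w[i] += 0.5
            assert np.all(gm.sg_predict_gratings(q, f, th, ph) >= base - 1e-12)

    def test_single_subunit_small_signal_matches_dog_ln(self):
        """beta -> 0 linearizes the subunit: response proportional to the
        matched DoG LN drive plus a constant."""
        grid = np.array([[5.0, -3.0]])
        eps = 1e-4
        p = gm.SubunitGridParams(grid, np.ones(1), 12.0, 2.0, 0.3, eps, 0.0,
                                 gm.NakaRushton(1.0, 0.0, 1.0, 1e6))
        f = np.linspace(1e-4, 0.01, 20)
        th = np.full(20, 0.7)
        ph = np.linspace(0, 2 * np.pi, 20)
        u = gm.sg_predict_gratings(p, f, th, ph)
        sp = gm.DoGSpatialParams(5.0, -3.0, 12.0, 12.0, 0.0, 2.0, 0.3)
        drive = gm.dog_grating_response(sp, f, th, ph).response
        # u ~ (1/k^n-ish scaling) * N(eps r) ~ const + eps r / 4
        resid = u - (u.mean() + eps * (drive - drive.mean()) / 4 * 1e6 / 1e6)
        slope = np.polyfit(drive, u, 1)[0]
        assert slope == pytest.approx(eps / 4 * p.out.a / p.out.k, rel=1e-3)

    def test_image_and_grating_paths_agree(self):
        """Pixel-space image projection of a rendered grating matches the
        analytic grating activation."""
        from retpop import synthkit as sk
        p = small_sg()
        spec = sk.GratingSpec(1 / 300.0, 0.4, 1.0)
        img = sk.render_grating(spec, (401, 401), 2.0)
        u_img = gm.sg_predict_image(p, img, 2.0, apply_output=False)
        r = gm.subunit_grating_activations(p.centres, p.sigma, p.k_s, p.w_surr,
                                           [spec.f], [spec.theta], [spec.phi])
        from retpop.gratmodels._dog import _logistic
        u_ana = (_logistic(p.beta * r + p.gamma) @ p.w).item()
        assert u_img[0] == pytest.approx(u_ana, rel=1e-3)


class TestRegularizer:
    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        grid = gm.hex_grid((0, 0), 16.0, 30)
        w = rng.uniform(0, 1, 30)
        pen = w @ _pair_inv_d2(grid) @ w
        perm = rng.permutation(30)
        pen2 = w[perm] @ _pair_inv_d2(grid[perm]) @ w[perm]
        assert pen == pytest.approx(pen2, rel=1e-12)

    def test_decreasing_in_distance(self):
        """The penalty kernel is strictly decreasing in pairwise distance
        (distances are normalized to the smallest spacing per layout, so the
        ordering within a layout is what matters)."""
        c1 = np.array([[0.0, 0], [16.0, 0], [48.0, 0], [200.0, 0]])
        inv = _pair_inv_d2(c1)
        assert inv[0, 1] > inv[0, 2] > inv[0, 3] > 0
        # nearest neighbours contribute exactly 1
        assert inv[0, 1] == pytest.approx(1.0)


class TestPruneAndSelect:
    def test_five_percent_rule(self, battery_params):
        """Weights {1.0, 0.04, 0.8}: the 4% weight is zeroed."""
        f, th, ph = battery_params
        grid = np.array([[0.0, 0.0], [32.0, 0.0], [0.0, 32.0]])
        p = gm.SubunitGridParams(grid, np.array([1.0, 0.04, 0.8]), 12.0, 2.0,
                                 0.2, 4.0, -1.0, gm.NakaRushton(10.0, 0.5, 1.0, 1.0))
        y = np.random.default_rng(0).poisson(gm.sg_predict_gratings(p, f, th, ph))
        pruned = gm.prune_and_refit(p, f, th, ph, y)
        assert pruned.w[1] == 0.0
        assert pruned.n_sub == 2

    def test_stray_subunit_removed(self, battery_params):
        """An above-5% subunit planted far outside the cluster is removed by
        the 2.5-SD rule."""
        f, th, ph = battery_params
        ang = np.arange(6) * np.pi / 3
        cluster = np.vstack([[0, 0], np.c_[32 * np.cos(ang), 32 * np.sin(ang)]])
        grid = np.vstack([cluster, [400.0, 0.0]])
        w = np.r_[np.ones(7), 0.2]
        p = gm.SubunitGridParams(grid, w, 12.0, 2.0, 0.2, 4.0, -1.0,
                                 gm.NakaRushton(10.0, 0.5, 1.0, 1.0))
        y = np.random.default_rng(1).poisson(gm.sg_predict_gratings(p, f, th, ph))
        pruned = gm.prune_and_refit(p, f, th, ph, y)
        assert pruned.w[-1] == 0.0
        assert pruned.n_sub == 7

    def test_no_prune_keeps_weights(self, battery_params):
        f, th, ph = battery_params
        ang = np.arange(6) * np.pi / 3
        grid = np.vstack([[0, 0], np.c_[32 * np.cos(ang), 32 * np.sin(ang)]])
        p = gm.SubunitGridParams(grid, np.ones(7), 12.0, 2.0, 0.2, 4.0, -1.0,
                                 gm.NakaRushton(10.0, 0.5, 1.0, 1.0))
        y = np.random.default_rng(2).poisson(gm.sg_predict_gratings(p, f, th, ph))
        pruned = gm.prune_and_refit(p, f, th, ph, y)
        # weights unchanged up to the global scaling factor of the refit
        ratio = pruned.w / p.w
        assert np.allclose(ratio, ratio[0])
        # refit does not worsen the training likelihood materially
        from retpop.gratmodels._dog import _poisson_nll
        nll0 = _poisson_nll(gm.sg_predict_gratings(p, f, th, ph), y)
        assert pruned.nll <= nll0 + 1e-6 * y.sum()

    def test_bic_arithmetic(self):
        """N_sub = 5, N_data = 1200, ln L = -3000 -> ~6035.45."""
        assert gm.bic(5, 1200, -3000.0) == pytest.approx(
            5 * np.log(1200) + 6000.0, abs=1e-9)

    def test_eligibility_gate_and_tiebreak(self):
        ang = np.arange(6) * np.pi / 3
        good_grid = np.vstack([[0, 0], np.c_[40 * np.cos(ang), 40 * np.sin(ang)]])
        def cand(nll, grid=None, w=None, sigma=8.0):
            g = grid if grid is not None else good_grid
            p = gm.SubunitGridParams(g, w if w is not None else np.ones(len(g)),
                                     sigma, 2.0, 0.2, 4.0, -1.0,
                                     gm.NakaRushton(10, 0.5, 1, 1))
            p.nll = nll
            return p
        # two-subunit candidate is ineligible regardless of likelihood
        two = cand(-1e9, grid=np.array([[0.0, 0], [40.0, 0]]), w=np.ones(2))
        # high-coverage candidate (sigma huge) ineligible
        wide = cand(-1e9, sigma=50.0)
        ok = cand(-1000.0)
        best, lam = gm.select_model([(1e-6, two), (1e-5, wide), (1e-4, ok)],
                                    n_data=1200)
        assert best is ok and lam == 1e-4
        # equal BIC: the smaller lambda wins
        ok2 = cand(-1000.0)
        best, lam = gm.select_model([(1e-5, ok), (1e-4, ok2)], n_data=1200)
        assert lam == 1e-5
        # nothing eligible -> excluded
        best, lam = gm.select_model([(1e-5, two)], n_data=1200)
        assert best is None and lam is None


class TestCharacterization:
    def test_coverage_regular_grid(self):
        """Hexagonal spacing 16, equal weights, sigma 4 -> coverage 1."""
        grid = gm.hex_grid((0, 0), 16.0, 19)
        p = gm.SubunitGridParams(grid, np.ones(19), 4.0, 2.0, 0.2, 4.0, -1.0,
                                 gm.NakaRushton(1, 0, 1, 1))
        assert gm.coverage(p) == pytest.approx(1.0, rel=1e-9)

    def test_coverage_undefined_below_three(self):
        p = gm.SubunitGridParams(np.array([[0.0, 0], [16.0, 0]]), np.ones(2),
                                 4.0, 2.0, 0.2, 4.0, -1.0,
                                 gm.NakaRushton(1, 0, 1, 1))
        with pytest.raises(ValueError):
            gm.coverage(p)
        assert gm.coverage(p, allow_undefined=True) is None

    def test_asymmetry_fixtures(self):
        """Odd-symmetric -> 0; fully rectified -> 1; M = 0.5 -> 1/3."""
        # steep logistic centred at 0 is odd-symmetric after offsetting
        assert gm.nonlinearity_asymmetry(2.0, 0.0) == pytest.approx(0.0, abs=1e-9)
        # strong threshold: nothing below zero input passes
        assert gm.nonlinearity_asymmetry(60.0, -30.0) == pytest.approx(1.0, abs=1e-3)
        # M = 0.5 arithmetic
        M = 0.5
        assert (1 - M) / (1 + M) == pytest.approx(1 / 3)

    def test_naka_rushton_at_zero(self):
        g = gm.NakaRushton(a=7.0, b=1.3, n=2.0, k=0.5)
        assert g(0.0) == pytest.approx(1.3, abs=1e-9)


class TestHexGrid:
    def test_spacing_and_count(self):
        grid = gm.hex_grid((5.0, -2.0), 16.0, 1200)
        assert grid.shape == (1200, 2)
        d = np.hypot(grid[:, 0] - grid[0, 0], grid[:, 1] - grid[0, 1])
        assert np.min(d[d > 0]) == pytest.approx(16.0, rel=1e-9)
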