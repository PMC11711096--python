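"""Fixation segmentation, correlation decompositions and DSI."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retpop import paircorr as pc
from retpop.synthkit import GazeTrace


def make_trace(n_images=10, fpi=75, frame_rate=75.0, steps=None):
    n = n_images * fpi
    pos = np.zeros((n, 2))
    if steps:
        for t, dx in steps.items():
            pos[t:, 0] += dx
    return GazeTrace(positions=pos, saccade_times=np.asarray(sorted(steps or []), int),
                     image_onsets=np.arange(n_images) * fpi, frame_rate=frame_rate)


class TestDetectFixations:
    def test_transitions_only(self):
        """A motionless trace splits only at image transitions."""
        ft = pc.detect_fixations(make_trace(), 53.0, 300.0, 31.0)
        assert ft.n_fixations == 10
        assert np.all(ft.boundaries[:, 1] - ft.boundaries[:, 0] == 75)

    def test_planted_saccade_splits_image(self):
        """One velocity peak above threshold splits its image in two."""
        # 400 deg/s at 31 um/deg, 75 Hz -> step of 400*31/75 um in one frame
        step = 400 * 31.0 / 75.0
        ft = pc.detect_fixations(make_trace(steps={150 + 37: step}),
                                 53.0, 300.0, 31.0)
        assert ft.n_fixations == 11
        assert [150 + 37] == [a for a, _ in ft.boundaries
                              if a not in range(0, 750, 75)]

    def test_close_peaks_keep_taller(self):
        """Two peaks 30 ms apart (min interval 53 ms): only the taller splits."""
        fr, mag = 500.0, 31.0
        t1 = 120
        t2 = t1 + int(round(0.030 * fr))
        amp = lambda v: v * mag / fr
        n = 2 * 500
        pos = np.zeros((n, 2))
        pos[t1:, 0] += amp(400.0)        # one-frame velocity pulses
        pos[t2:, 0] += amp(500.0)
        tr = GazeTrace(pos, np.array([t1, t2]), np.array([0, 500]), fr)
        ft = pc.detect_fixations(tr, 53.0, 300.0, mag)
        saccade_starts = [a for a, s in zip(ft.boundaries[:, 0], ft.source)
                          if s == "saccade"]
        assert saccade_starts == [t2]

    def test_round_trip_planted_saccades(self):
        """Planted 2x-threshold saccades are recovered with P = R = 1."""
        from retpop.synthkit import GazeModel, make_gaze_video, make_natural_images
        imgs = make_natural_images(5, (64, 64), seed=3)
        stim, trace = make_gaze_video(
            imgs, GazeModel(jitter_sd_um=2.0, saccades_per_image=1,
                            saccade_amp_um=(250.0, 350.0)),
            seed=5, frame_rate=75.0, pad_um=2000.0)
        # threshold at half the minimum planted amplitude (in deg/s)
        thr_deg_s = 0.5 * 250.0 * 75.0 / 31.0
        ft = pc.detect_fixations(trace, 53.0, thr_deg_s, 31.0)
        detected = {a for a, s in zip(ft.boundaries[:, 0], ft.source)
                    if s == "saccade"}
        assert detected == set(trace.saccade_times)


class TestPartialCorrelation:
    def test_full_subset_equals_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 200))
        r = pc.partial_correlation(x, y, np.arange(200))
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_empty_subset_is_zero(self):
        assert pc.partial_correlation([1, 2, 3], [3, 1, 2], []) == 0.0

    def test_hand_computed_value_and_complement(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        # frames 1, 2 (0-based): ((2-2.5)(3-2.5)+(3-2.5)(2-2.5)) / (3*sx*sy)
        sx = x.std(ddof=1)
        expect = ((-0.5 * 0.5) + (0.5 * -0.5)) / (3 * sx * sx)
        got = pc.partial_correlation(x, y, [1, 2])
        assert got == pytest.approx(expect, abs=1e-12)
        comp = pc.partial_correlation(x, y, [0, 3])
        assert got + comp == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_decomposition_identity(self, seed):
        """r_pair = r_A + r_B to a few ulp for any complementary split."""
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 200)
        x, y = rng.normal(size=(2, n))
        mask = rng.random(n) < rng.random()
        ra = pc.partial_correlation(x, y, np.where(mask)[0])
        rb = pc.partial_correlation(x, y, np.where(~mask)[0])
        r = np.corrcoef(x, y)[0, 1]
        assert abs((ra + rb) - r) <= 4 * np.spacing(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pc.partial_correlation([1, 1, 1], [1, 2, 3], [0])


class TestSpatialContrastSplit:
    def _fixture(self, n_fix=80, seed=0):
        import pandas as pd
        rng = np.random.default_rng(seed)
        ft = pc.FixationTable(
            boundaries=np.array([(i, i + 1) for i in range(n_fix)]),
            source=np.array(["image"] * n_fix, object))
        ft.linear_activation = pd.DataFrame(
            {"a": rng.normal(size=n_fix), "b": rng.normal(size=n_fix)})
        ft.spatial_contrast = pd.DataFrame(
            {"a": rng.uniform(0, 1, n_fix), "b": rng.uniform(0, 1, n_fix)})
        return ft

    def test_even_split_sizes(self):
        ft = self._fixture(80)
        hi, lo = pc.split_by_spatial_contrast(ft, "a", "b")
        assert len(hi) == len(lo) == 40
        assert set(hi) & set(lo) == set()

    def test_high_set_recovers_planted_labels(self):
        """SC labels independent of activation are recovered exactly."""
        import pandas as pd
        n = 40
        rng = np.random.default_rng(1)
        act = rng.normal(size=n)
        order = np.argsort(act, kind="stable")
        sc = np.zeros(n)
        planted_high = []
        for p in range(n // 2):
            i, j = order[2 * p], order[2 * p + 1]
            sc[i], sc[j] = 1.0, 0.0
            planted_high.append(i)
        ft = pc.FixationTable(np.array([(i, i + 1) for i in range(n)]),
                              np.array(["image"] * n, object))
        ft.linear_activation = pd.DataFrame({"a": act, "b": act})
        ft.spatial_contrast = pd.DataFrame({"a": sc, "b": sc})
        hi, lo = pc.split_by_spatial_contrast(ft, "a", "b")
        assert sorted(planted_high) == list(hi)

    def test_activation_balanced(self):
        """Mean linear activation of the two groups stays balanced."""
        ft = self._fixture(200, seed=2)
        hi, lo = pc.split_by_spatial_contrast(ft, "a", "b")
        act = 0.5 * (ft.linear_activation["a"] + ft.linear_activation["b"]).to_numpy()
        assert abs(act[hi].mean() - act[lo].mean()) < 0.1 * act.std()


class TestDirectionSelectivity:
    def test_single_direction_gives_unity(self):
        r = np.zeros((8, 5))
        r[0] = 4
        m = pc.direction_selectivity(r, n_perm=50, seed=0)
        assert m.dsi == pytest.approx(1.0)
        assert m.preferred_direction == pytest.approx(0.0)

    def test_uniform_gives_zero(self):
        m = pc.direction_selectivity(np.ones((8, 3)), n_perm=50, seed=0)
        assert m.dsi == pytest.approx(0.0, abs=1e-12)

    def test_printed_arithmetic_example(self):
        """r = (2,1,0,1) over 0/90/180/270 deg -> DSI 0.5, preferred 0."""
        r = np.array([[2.0], [1.0], [0.0], [1.0]])
        m = pc.direction_selectivity(r, n_perm=200, seed=0)
        assert m.dsi == pytest.approx(0.5)
        assert m.preferred_direction == pytest.approx(0.0, abs=1e-12)

    def test_tuned_cell_significant(self):
        rng = np.random.default_rng(3)
        rates = 2 + 20 * np.exp(np.cos(np.arange(8) * np.pi / 4) - 1)
        r = rng.poisson(rates[:, None], (8, 10))
        m = pc.direction_selectivity(r, n_perm=500, seed=0,
                                     onset_offset=([30], [10]))
        assert m.p_perm < 0.01
        assert m.on_off_index == pytest.approx(0.5)


class TestCorrelationVsDistance:
    def test_duplicate_independent_and_constant_cells(self):
        rng = np.random.default_rng(0)
        base = rng.normal(10, 3, 600)
        rates = {"a": base, "b": base.copy(),
                 "c": rng.normal(10, 3, 600), "d": np.full(600, 5.0)}
        centres = {"a": (0, 0), "b": (0, 0), "c": (300, 0), "d": (600, 0)}
        df = pc.correlation_vs_distance(rates, centres, pairs_per_bin=2)
        pair = df.set_index(["cell_a", "cell_b"])["r_pair"]
        assert pair[("a", "b")] == pytest.approx(1.0)
        assert abs(pair[("a", "c")]) < 0.15
        # constant-rate cell is excluded with a flag, not silently dropped
        assert all("d" in p for p in df.attrs["excluded"])
        assert len(df.attrs["excluded"]) == 3


class TestDecorrelation:
    def test_duplicated_cell_zero_decorrelation(self):
        assert pc.decorrelation(1.0, 1.0) == 0.0

    def test_independent_cells_full_decorrelation(self):
        assert pc.decorrelation(0.0, 0.6) == pytest.approx(1.0)

    def test_stimulus_pixel_correlation_decreases(self):
        """Translating 1/f images: pixel correlation falls with distance and
        matches a brute-force computation on a subsample."""
        from retpop.synthkit import make_natural_images
        rng = np.random.default_rng(0)
        imgs = make_natural_images(30, (48, 48), seed=4)
        frames = imgs + 0.01 * rng.normal(size=imgs.shape)
        curve = pc.stimulus_pixel_correlation(frames, 7.5, n_pixels=150,
                                              seed=1, n_bins=8)
        assert curve["rho_stim"].iloc[0] > curve["rho_stim"].iloc[-1]
        # brute force on the same subsample definition
        flat = frames.reshape(len(frames), -1)
        sel = np.random.default_rng(1).choice(flat.shape[1], 150, replace=False)
        sub = flat[:, sel]
        C = np.corrcoef(sub.T)
        assert curve["rho_stim"].max() <= np.nanmax(C[np.triu_indices(150, 1)]) + 1e-9
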