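"""Fixation-density heatmaps: windowing, accumulation, smoothing, averaging."""

import numpy as np
import pandas as pd
import pytest

from gazecam import (FixationDensityMap, HeatmapConfig,
                     accumulate_density, average_participants,
                     participant_heatmaps, select_in_image, simulate_scanpath,
                     smooth_and_normalize, smooth_density, window_samples)


def _frame(t, x, y):
    return pd.DataFrame({"t_ms": t, "x_px": x, "y_px": y})


class TestSelectInImage:
    def test_origin_maps_to_zero(self, geometry):
        ox, oy = geometry.image_origin
        out = select_in_image(_frame([0.0], [ox], [oy]), geometry)
        assert len(out) == 1
        assert out.iloc[0]["col_img"] == 0 and out.iloc[0]["row_img"] == 0

    def test_half_open_upper_bound_excluded(self, geometry):
        ox, oy = geometry.image_origin
        d = geometry.image_display_size
        out = select_in_image(_frame([0.0, 1.0], [ox + d, ox + d - 1e-9],
                                     [oy, oy]), geometry)
        assert len(out) == 1  # exactly-at-edge sample excluded

    def test_matches_brute_force_membership(self, geometry, rng):
        n = 1000
        x = rng.uniform(0, 1920, n)
        y = rng.uniform(0, 1080, n)
        out = select_in_image(_frame(np.arange(n, dtype=float), x, y), geometry)
        ox, oy = geometry.image_origin
        d, s = geometry.image_display_size, geometry.scale_factor
        expected = []
        for i in range(n):  # brute-force rectangle test
            if ox <= x[i] < ox + d and oy <= y[i] < oy + d:
                expected.append((i, int((x[i] - ox) // s), int((y[i] - oy) // s)))
        assert len(out) == len(expected)
        got = list(zip(out.index, out["col_img"], out["row_img"]))
        assert got == expected


class TestWindowing:
    def test_twenty_windows_over_one_second(self):
        cfg = HeatmapConfig(window_ms=50, horizon_ms=1000)
        groups = window_samples(_frame([], [], []), cfg)
        assert len(groups) == 20

    def test_single_window(self):
        cfg = HeatmapConfig(window_ms=50, horizon_ms=50)
        assert len(window_samples(_frame([10.0], [0], [0]), cfg)) == 1

    def test_non_multiple_horizon_rejected(self):
        cfg = HeatmapConfig(window_ms=50, horizon_ms=1010)
        with pytest.raises(ValueError, match="multiple"):
            window_samples(_frame([], [], []), cfg)

    def test_matches_brute_force_binning(self, rng):
        t = np.sort(rng.uniform(0, 1200, 500))
        t[:4] = [0.0, 49.999, 50.0, 999.999]  # boundary straddlers
        t = np.sort(t)
        df = _frame(t, np.zeros_like(t), np.zeros_like(t))
        cfg = HeatmapConfig(window_ms=50, horizon_ms=1000)
        groups = window_samples(df, cfg)
        for k, g in enumerate(groups):  # brute-force interval test
            expected = {i for i, ti in enumerate(t)
                        if k * 50 <= ti < (k + 1) * 50}
            assert set(g.index) == expected

    def test_cumulative_mode_pools_prefixes(self):
        t = np.array([10.0, 60.0, 110.0])
        df = _frame(t, t, t)
        cfg = HeatmapConfig(window_ms=50, horizon_ms=150, cumulative=True)
        groups = window_samples(df, cfg)
        assert [len(g) for g in groups] == [1, 2, 3]

    def test_full_presentation_single_group(self):
        t = np.array([10.0, 600.0, 1400.0])
        cfg = HeatmapConfig(full_presentation=True)
        groups = window_samples(_frame(t, t, t), cfg)
        assert len(groups) == 1 and len(groups[0]) == 3


class TestAccumulation:
    def test_empty_group_all_zero(self):
        raw = accumulate_density(pd.DataFrame({"row_img": [], "col_img": []}), 16)
        assert raw.shape == (16, 16) and raw.sum() == 0

    def test_counts_repeats(self):
        g = pd.DataFrame({"row_img": [3, 3, 3], "col_img": [5, 5, 5]})
        raw = accumulate_density(g, 16)
        assert raw[3, 5] == 3 and raw.sum() == 3

    def test_matches_brute_force_tally(self, rng):
        rows = rng.integers(0, 32, 400)
        cols = rng.integers(0, 32, 400)
        raw = accumulate_density(pd.DataFrame({"row_img": rows, "col_img": cols}), 32)
        expected = np.zeros((32, 32), dtype=int)
        for r, c in zip(rows, cols):  # brute-force histogram
            expected[r, c] += 1
        assert np.array_equal(raw, expected)

    def test_out_of_range_rejected(self):
        g = pd.DataFrame({"row_img": [40], "col_img": [0]})
        with pytest.raises(ValueError, match="out of range"):
            accumulate_density(g, 32)


class TestSmoothing:
    def test_all_zero_stays_zero(self):
        cfg = HeatmapConfig(smoothing_sd_px=5.0)
        m = smooth_and_normalize(np.zeros((32, 32)), cfg)
        assert m.values.sum() == 0 and m.normalization == "none"

    def test_impulse_response_peaks_at_impulse(self):
        cfg = HeatmapConfig(smoothing_sd_px=3.0)
        raw = np.zeros((48, 48))
        raw[24, 30] = 1
        m = smooth_and_normalize(raw, cfg)
        assert m.values[24, 30] == 1.0
        assert m.normalization == "peak"
        # proportional to a 2-D Gaussian near the impulse
        for d in (1, 3, 6):
            expected = np.exp(-0.5 * (d / 3.0) ** 2)
            assert m.values[24, 30 + d] == pytest.approx(expected, rel=1e-3)

    def test_mass_conserved_before_normalization(self, rng):
        cfg = HeatmapConfig(smoothing_sd_px=20.0)
        raw = rng.poisson(2.0, (64, 64)).astype(float)
        smoothed = smooth_density(raw, cfg)
        assert smoothed.sum() == pytest.approx(raw.sum(), rel=1e-6)

    def test_peak_normalization_idempotent(self, rng):
        cfg = HeatmapConfig(smoothing_sd_px=4.0)
        raw = rng.poisson(1.0, (32, 32)).astype(float)
        m1 = smooth_and_normalize(raw, cfg)
        m2 = smooth_and_normalize(m1.values, HeatmapConfig(smoothing_sd_px=1e-12))
        assert np.allclose(m1.values, m2.values)


class TestAveraging:
    @staticmethod
    def _map(values, image_id="im0", window=0):
        return FixationDensityMap(image_id, window, 0.0, 50.0, values,
                                  "peak" if values.max() > 0 else "none")

    def test_single_participant_identity(self, rng):
        v = rng.random((16, 16))
        v /= v.max()
        out = average_participants([self._map(v)])
        assert np.allclose(out.values, v)

    def test_two_identical_maps(self, rng):
        v = rng.random((16, 16))
        v /= v.max()
        out = average_participants([self._map(v), self._map(v.copy())])
        assert np.allclose(out.values, v)

    def test_matches_brute_force_mean(self, rng):
        maps = []
        raw = []
        for _ in range(5):
            v = rng.random((8, 8))
            v /= v.max()
            raw.append(v)
            maps.append(self._map(v))
        out = average_participants(maps)
        mean = sum(raw) / 5.0  # brute-force mean + renormalize
        assert np.allclose(out.values, mean / mean.max())

    def test_mismatched_inputs_rejected(self, rng):
        a = self._map(rng.random((8, 8)) + 0.5)
        b = self._map(rng.random((9, 9)) + 0.5)
        with pytest.raises(ValueError):
            average_participants([a, b])
        c = self._map(rng.random((8, 8)) + 0.5, window=3)
        with pytest.raises(ValueError):
            average_participants([a, c])


class TestPipelineProperties:
    def test_windows_equal_independent_computation(self, small_stimuli, geometry,
                                                   gaze_params):
        """Per-window maps equal maps computed from pre-filtered samples."""
        df = simulate_scanpath(small_stimuli[0], gaze_params, geometry, "p0")
        cfg = HeatmapConfig(smoothing_sd_px=5.0)
        maps = participant_heatmaps(df, geometry, cfg, "im", 64)
        assert len(maps) == 20
        for k in (0, 4, 19):
            sub = df[(df["t_ms"] >= k * 50) & (df["t_ms"] < (k + 1) * 50)].copy()
            sub["t_ms"] -= k * 50  # re-anchor the clock for the solo window
            solo = participant_heatmaps(sub, geometry,
                                        HeatmapConfig(window_ms=50, horizon_ms=50,
                                                      smoothing_sd_px=5.0),
                                        "im", 64)[0]
            assert np.allclose(maps[k].values, solo.values)
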