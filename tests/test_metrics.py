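"""Similarity, face index, bootstrap summaries and the trade-off table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazecam import (DegenerateMapError, RoiSpec, face_detection_index,
                     group_summary, pearson_fisher, similarity_table,
                     tradeoff_curve)


class TestPearsonFisher:
    def test_self_correlation_clamped(self, rng):
        m = rng.random((8, 8))
        r, z = pearson_fisher(m, m)
        assert r == pytest.approx(1.0)
        assert z == pytest.approx(np.arctanh(1 - 1e-7))

    def test_affine_anticorrelation(self, rng):
        m = rng.random((8, 8))
        r, z = pearson_fisher(m, 1.0 - m)
        assert r == pytest.approx(-1.0)
        assert z == pytest.approx(-np.arctanh(1 - 1e-7))

    def test_matches_hand_computed_covariance(self):
        a = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=float)
        b = np.array([[2, 1, 4], [3, 6, 5], [9, 7, 8]], dtype=float)
        # brute-force covariance formula
        am, bm = a.mean(), b.mean()
        num = ((a - am) * (b - bm)).sum()
        den = np.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum())
        r, z = pearson_fisher(a, b)
        assert r == pytest.approx(num / den)
        assert z == pytest.approx(np.arctanh(num / den))

    def test_symmetry(self, rng):
        a, b = rng.random((6, 6)), rng.random((6, 6))
        assert pearson_fisher(a, b) == pearson_fisher(b, a)

    def test_zero_variance_rejected(self, rng):
        with pytest.raises(DegenerateMapError):
            pearson_fisher(np.ones((4, 4)), rng.random((4, 4)))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(0.1, 50.0), st.floats(-5, 5))
    def test_invariant_under_positive_affine_rescaling(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        a, b = rng.random((5, 5)), rng.random((5, 5))
        r0, _ = pearson_fisher(a, b)
        r1, _ = pearson_fisher(scale * a + shift, b)
        assert r0 == pytest.approx(r1, abs=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_fisher_transform_strictly_monotone(self, seed):
        rng = np.random.default_rng(seed)
        pairs = [pearson_fisher(rng.random((4, 4)), rng.random((4, 4)))
                 for _ in range(8)]
        rs = np.array([p[0] for p in pairs])
        zs = np.array([p[1] for p in pairs])
        assert np.array_equal(np.argsort(rs), np.argsort(zs))


class TestFaceIndex:
    def test_uniform_map_gives_area_ratio(self):
        roi = np.zeros((8, 8), dtype=bool)
        roi[:4, :4] = True  # 25% of pixels
        idx = face_detection_index(np.ones((8, 8)), roi)
        assert idx.value == pytest.approx(1.0 / 3.0)
        assert not idx.capped

    def test_all_mass_inside_roi_is_capped(self):
        roi = np.zeros((8, 8), dtype=bool)
        roi[2:5, 2:5] = True
        m = np.zeros((8, 8))
        m[3, 3] = 5.0
        idx = face_detection_index(m, roi)
        assert idx.capped
        assert idx.value > 1e6

    def test_matches_brute_force_masked_sums(self, rng):
        m = rng.random((16, 16))
        roi = rng.random((16, 16)) > 0.7
        if not roi.any():
            roi[0, 0] = True
        inside = sum(m[r, c] for r, c in np.ndindex(16, 16) if roi[r, c])
        outside = sum(m[r, c] for r, c in np.ndindex(16, 16) if not roi[r, c])
        idx = face_detection_index(m, roi)
        assert idx.value == pytest.approx(inside / outside)

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty face ROI"):
            face_detection_index(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))


class TestRoiSpec:
    def test_smoothed_mask_binarizes_back_to_core(self):
        spec = RoiSpec()
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:22, 10:22] = True
        soft = spec.smoothed(mask)
        assert soft.max() == pytest.approx(1.0)
        core = spec.binarized(soft)
        assert core[15, 15] and not core[2, 2]


class TestSimilarityTable:
    @pytest.fixture()
    def inputs(self, rng):
        image_ids = [f"im{i}" for i in range(4)]
        info = pd.DataFrame({"image_id": image_ids,
                             "category": ["a", "a", "b", "b"],
                             "animate": [True, True, False, False],
                             "has_face": [True, False, False, False]}
                            ).set_index("image_id")
        gaze = {iid: {w: rng.random((8, 8)) for w in list(range(20)) + ["all"]}
                for iid in image_ids}
        sal = {f"r{k}": {iid: rng.random((8, 8)) for iid in image_ids}
               for k in range(3)}
        return sal, gaze, info

    def test_cardinality(self, inputs):
        sal, gaze, info = inputs
        df = similarity_table(sal, gaze, info)
        assert len(df) == 3 * 4 * 21  # runs x images x (20 windows + all)

    def test_identical_runs_give_identical_records(self, inputs):
        sal, gaze, info = inputs
        sal["r1"] = {iid: v.copy() for iid, v in sal["r0"].items()}
        df = similarity_table(sal, gaze, info)
        a = df[df.run_id == "r0"].drop(columns="run_id").reset_index(drop=True)
        b = df[df.run_id == "r1"].drop(columns="run_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_degenerate_maps_reported_in_skip_list(self, inputs):
        sal, gaze, info = inputs
        gaze["im0"][3] = np.zeros((8, 8))
        df = similarity_table(sal, gaze, info)
        skipped = df.attrs["skipped"]
        assert len(skipped) == 3  # one per run
        assert (skipped["reason"] == "zero variance").all()

    def test_mean_z_matches_brute_force_recompute(self, inputs):
        sal, gaze, info = inputs
        df = similarity_table(sal, gaze, info)
        got = df[df.window == "all"]["z"].mean()
        expected = np.mean([pearson_fisher(sal[r][i], gaze[i]["all"])[1]
                            for r in sal for i in gaze])
        assert got == pytest.approx(expected)


class TestGroupSummary:
    def test_identical_values_zero_width_ci(self):
        df = pd.DataFrame({"mode": "STD", "z": [0.4] * 10})
        out = group_summary(df, "none")
        row = out.iloc[0]
        assert row["mean"] == row["median"] == 0.4
        assert row["ci_low"] == row["ci_high"] == 0.4

    def test_disjoint_cells_nonoverlapping_cis(self, rng):
        df = pd.DataFrame({
            "mode": ["A"] * 40 + ["B"] * 40,
            "z": np.concatenate([rng.uniform(0, 0.2, 40),
                                 rng.uniform(0.8, 1.0, 40)])})
        out = group_summary(df, "none").set_index("mode")
        assert out.loc["A", "ci_high"] < out.loc["B", "ci_low"]

    def test_matches_independent_bootstrap(self, rng):
        """Percentile CI endpoints agree with a second implementation."""
        values = rng.normal(0.5, 0.2, 60)
        df = pd.DataFrame({"mode": "STD", "z": values})
        out = group_summary(df, "none", n_boot=4000, seed=1).iloc[0]
        rng2 = np.random.default_rng(999)  # independent resampling stream
        stats = [np.mean(rng2.choice(values, size=60, replace=True))
                 for _ in range(4000)]
        lo, hi = np.percentile(stats, [2.5, 97.5])
        se = values.std() / np.sqrt(60)
        assert out["ci_low"] == pytest.approx(lo, abs=0.4 * se)
        assert out["ci_high"] == pytest.approx(hi, abs=0.4 * se)

    def test_small_cells_reported_missing(self):
        df = pd.DataFrame({"mode": ["A", "B", "B"], "z": [0.1, 0.2, 0.3]})
        out = group_summary(df, "none").set_index("mode")
        assert np.isnan(out.loc["A", "mean"])
        assert not np.isnan(out.loc["B", "mean"])


class TestTradeoffCurve:
    @staticmethod
    def _records(ratios, n_runs=4, rng=None):
        acc_rows, sim_rows = [], []
        for ratio in ratios:
            for k in range(n_runs):
                rid = f"AS{ratio}_r{k}"
                acc_rows.append({"mode": "AS", "ratio_percent": ratio,
                                 "run_id": rid,
                                 "accuracy": 80 + 0.1 * ratio + rng.normal(0, 1)})
                for i in range(5):
                    sim_rows.append({"mode": "AS", "ratio_percent": ratio,
                                     "run_id": rid, "image_id": f"im{i}",
                                     "window": "all",
                                     "z": 0.3 + rng.normal(0, 0.05)})
        return pd.DataFrame(acc_rows), pd.DataFrame(sim_rows)

    def test_eleven_ratio_points(self, rng):
        acc, sim = self._records(range(0, 101, 10), rng=rng)
        curve = tradeoff_curve(acc, sim)
        assert len(curve) == 11
        assert (curve["n_runs"] == 4).all()

    def test_cis_bracket_means(self, rng):
        acc, sim = self._records([0, 50, 100], rng=rng)
        curve = tradeoff_curve(acc, sim)
        assert (curve["accuracy_ci_low"] <= curve["accuracy_mean"]).all()
        assert (curve["accuracy_ci_high"] >= curve["accuracy_mean"]).all()
        assert (curve["z_ci_low"] <= curve["z_mean"]).all()
        assert (curve["z_ci_high"] >= curve["z_mean"]).all()
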