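"""Human-likeness metrics: saliency–gaze similarity, face index, trade-off.

The central measurement is the per-image Pearson correlation between a
model's Grad-CAM saliency map and the participant-averaged fixation
density map, Fisher-Z transformed (z = atanh r) for linear comparability,
computed for the full-presentation map and for each 50 ms time window.
Correlations are computed per image and then aggregated — never pooled
across images.  A face-detection index (attention mass inside a face ROI
over mass outside it) quantifies face bias; group summaries use seeded
percentile bootstrap confidence intervals; the accuracy-vs-similarity
trade-off table aggregates runs across manipulation ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

from ._util import windowed_gaussian_filter

R_CLAMP = 1.0 - 1e-7


class DegenerateMapError(ValueError):
    """A map with zero pixel variance cannot enter a Pearson correlation."""


def pearson_fisher(map_a: np.ndarray, map_b: np.ndarray) -> tuple[float, float]:
    """Pearson r over flattened pixels and its Fisher-Z transform.

    r is clamped to ±(1 − 1e−7) before atanh so that perfectly correlated
    maps yield a finite z.  Raises :class:`DegenerateMapError` when either
    map has zero variance.
    """
    a = np.asarray(map_a, dtype=np.float64).ravel()
    b = np.asarray(map_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("maps must share a shape")
    a = a - a.mean()
    b = b - b.mean()
    va, vb = float(a @ a), float(b @ b)
    if va <= 0.0 or vb <= 0.0:
        raise DegenerateMapError("zero-variance map in correlation")
    r = float(a @ b / np.sqrt(va * vb))
    r = float(np.clip(r, -1.0, 1.0))
    z = float(np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP)))
    return r, z


class FaceIndex(NamedTuple):
    value: float
    capped: bool


def face_detection_index(map_values: np.ndarray, face_roi: np.ndarray,
                         eps_rel: float = 1e-9) -> FaceIndex:
    """Attention mass inside the face ROI over mass outside it.

    A uniform map yields area_in/area_out; all mass inside the ROI hits
    the ε floor (ε = eps_rel × total mass) and is flagged as capped.
    Raises on an empty ROI — such images are excluded from face analyses.
    """
    roi = np.asarray(face_roi).astype(bool)
    if not roi.any():
        raise ValueError("empty face ROI: image excluded from face analyses")
    m = np.asarray(map_values, dtype=np.float64)
    if (m < 0).any():
        raise ValueError("map must be nonnegative")
    total = float(m.sum())
    inside = float(m[roi].sum())
    outside = total - inside
    floor = eps_rel * total
    if total == 0.0:
        return FaceIndex(0.0, False)
    if outside <= floor:
        return FaceIndex(inside / max(floor, np.finfo(float).tiny), True)
    return FaceIndex(inside / outside, False)


@dataclass(frozen=True)
class RoiSpec:
    """ROI handling: export smoothing (W = 10, SD = 5) and binarization."""

    smoothing_window: int = 10
    smoothing_sd: float = 5.0
    binarize_threshold: float = 0.5

    def smoothed(self, mask: np.ndarray) -> np.ndarray:
        """Soft ROI weight map for export/visualization."""
        sm = windowed_gaussian_filter(mask.astype(np.float64),
                                      self.smoothing_window, self.smoothing_sd)
        peak = sm.max()
        return sm / peak if peak > 0 else sm

    def binarized(self, soft: np.ndarray) -> np.ndarray:
        return soft >= self.binarize_threshold


def similarity_table(saliency_by_run: Mapping[str, Mapping[str, np.ndarray]],
                     gaze_maps: Mapping[str, Mapping], image_info: pd.DataFrame,
                     run_meta: Optional[Mapping[str, Mapping]] = None) -> pd.DataFrame:
    """Per (run, image, window) similarity records.

    ``saliency_by_run``: run_id -> image_id -> saliency map.
    ``gaze_maps``: image_id -> {window ("all" or int) -> density map array}.
    ``image_info``: indexed by image_id with category/animate/has_face
    columns.  ``run_meta`` optionally maps run_id to dict(mode, ratio).
    Degenerate (zero-variance) maps are dropped and listed in the attached
    ``skipped`` attribute.
    """
    records, skipped = [], []
    for run_id, sal_maps in saliency_by_run.items():
        meta = (run_meta or {}).get(run_id, {})
        for image_id, sal in sal_maps.items():
            if image_id not in gaze_maps:
                skipped.append({"run_id": run_id, "image_id": image_id,
                                "window": None, "reason": "missing gaze maps"})
                continue
            info = image_info.loc[image_id]
            for window, gmap in gaze_maps[image_id].items():
                values = getattr(gmap, "values", gmap)
                try:
                    r, z = pearson_fisher(sal, values)
                except DegenerateMapError:
                    skipped.append({"run_id": run_id, "image_id": image_id,
                                    "window": window, "reason": "zero variance"})
                    continue
                records.append({
                    "mode": meta.get("mode", "STD"),
                    "ratio_percent": meta.get("ratio_percent", 100),
                    "run_id": run_id, "image_id": image_id, "window": window,
                    "r": r, "z": z, "category": info["category"],
                    "animate": bool(info["animate"]),
                    "has_face": bool(info["has_face"]),
                })
    df = pd.DataFrame(records)
    df.attrs["skipped"] = pd.DataFrame(skipped)
    return df


def _bootstrap_ci(values: np.ndarray, stat, n_boot: int,
                  rng: np.random.Generator, level: float = 0.95):
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    stats = stat(values[idx], axis=1)
    lo, hi = np.percentile(stats, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def group_summary(records: pd.DataFrame, split: str = "none",
                  value_col: str = "z", n_boot: int = 2000,
                  seed: int = 0, level: float = 0.95) -> pd.DataFrame:
    """Per-cell mean/median with percentile bootstrap CIs on the mean.

    ``split`` is one of none | animacy | face | category and is always
    crossed with the model mode.  Cells with fewer than two records are
    reported with NaN statistics rather than silently dropped.
    """
    split_col = {"none": None, "animacy": "animate", "face": "has_face",
                 "category": "category"}[split]
    keys = ["mode"] + ([split_col] if split_col else [])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    rows = []
    for cell, group in records.groupby(keys, sort=True):
        cell = cell if isinstance(cell, tuple) else (cell,)
        values = group[value_col].to_numpy(dtype=float)
        row = dict(zip(keys, cell))
        row["n"] = len(values)
        if len(values) < 2:
            row.update({"mean": np.nan, "median": np.nan,
                        "ci_low": np.nan, "ci_high": np.nan})
        else:
            lo, hi = _bootstrap_ci(values, np.mean, n_boot, rng, level)
            row.update({"mean": float(values.mean()),
                        "median": float(np.median(values)),
                        "ci_low": lo, "ci_high": hi})
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TradeoffPoint:
    """Aggregate accuracy and similarity at one (mode, ratio)."""

    mode: str
    ratio_percent: int
    n_runs: int
    accuracy_mean: float
    accuracy_ci: tuple[float, float]
    z_mean: float
    z_ci: tuple[float, float]


def tradeoff_curve(accuracy_records: pd.DataFrame,
                   similarity_records: pd.DataFrame,
                   n_boot: int = 2000, seed: int = 0) -> pd.DataFrame:
    """One row per (mode, ratio): mean accuracy and mean z over runs + CIs.

    ``accuracy_records`` needs mode/ratio_percent/run_id/accuracy columns;
    ``similarity_records`` the similarity table (the "all"-window rows are
    used, averaged per run before bootstrapping over runs).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF]))
    sim_all = similarity_records[similarity_records["window"] == "all"]
    per_run_z = (sim_all.groupby(["mode", "ratio_percent", "run_id"])["z"]
                 .mean().reset_index())
    rows = []
    for (mode, ratio), acc_group in accuracy_records.groupby(["mode", "ratio_percent"]):
        acc = acc_group["accuracy"].to_numpy(dtype=float)
        zg = per_run_z[(per_run_z["mode"] == mode)
                       & (per_run_z["ratio_percent"] == ratio)]["z"].to_numpy()
        if len(acc) == 0 or len(zg) == 0:
            continue
        acc_ci = _bootstrap_ci(acc, np.mean, n_boot, rng) if len(acc) > 1 \
            else (float(acc[0]), float(acc[0]))
        z_ci = _bootstrap_ci(zg, np.mean, n_boot, rng) if len(zg) > 1 \
            else (float(zg[0]), float(zg[0]))
        rows.append({"mode": mode, "ratio_percent": int(ratio),
                     "n_runs": len(acc),
                     "accuracy_mean": float(acc.mean()),
                     "accuracy_ci_low": acc_ci[0], "accuracy_ci_high": acc_ci[1],
                     "z_mean": float(zg.mean()),
                     "z_ci_low": z_ci[0], "z_ci_high": z_ci[1]})
    return pd.DataFrame(rows).sort_values(["mode", "ratio_percent"]).reset_index(drop=True)
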