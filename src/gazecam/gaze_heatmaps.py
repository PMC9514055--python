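"""Fixation-density heatmaps from gaze sample streams.

Gaze samples recorded at the display resolution are filtered to those
inside the displayed image, mapped to image-pixel coordinates, grouped
into non-overlapping time windows (50 ms by default, 20 windows over the
first 1,000 ms), accumulated into per-pixel sample counts (dwell time at
the sampling rate), smoothed with a Gaussian, peak-normalized, and
averaged over participants.  A ``full_presentation`` mode pools every
in-image sample of the whole trial into a single map — this is the map
that drives the spotlight image manipulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic_data import DisplayGeometry


@dataclass(frozen=True)
class HeatmapConfig:
    """Windowing and smoothing parameters for fixation-density maps.

    ``smoothing_sd_px`` is the Gaussian SD at image resolution (default
    20 px for 227 px images; see :func:`scaled_smoothing_sd` for other
    resolutions).  ``cumulative`` makes window k pool everything up to its
    offset instead of only its own 50 ms; ``full_presentation`` pools all
    in-image samples of the trial regardless of the horizon.
    """

    window_ms: float = 50.0
    horizon_ms: float = 1000.0
    smoothing_sd_px: float = 20.0
    cumulative: bool = False
    full_presentation: bool = False

    def __post_init__(self):
        if self.window_ms <= 0:
            raise ValueError("window_ms must be > 0")
        if self.horizon_ms <= 0:
            raise ValueError("horizon_ms must be > 0")

    @property
    def n_windows(self) -> int:
        ratio = self.horizon_ms / self.window_ms
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("horizon_ms must be a multiple of window_ms")
        return int(round(ratio))


def scaled_smoothing_sd(image_size: int, base_sd: float = 20.0,
                        base_size: int = 227) -> float:
    """Smoothing SD scaled proportionally from the 227 px reference."""
    return base_sd * image_size / base_size


@dataclass
class FixationDensityMap:
    """A smoothed, peak-normalized attention map for one image and window.

    ``window_index`` is a 0-based window number or ``"all"`` for the
    pooled full-presentation map.  ``normalization`` records whether peak
    normalization was applied ("peak") or the map was all-zero ("none").
    """

    image_id: str
    window_index: Union[int, str]
    window_onset_ms: float
    window_offset_ms: float
    values: np.ndarray
    normalization: str = "peak"

    def __post_init__(self):
        if (self.values < 0).any():
            raise ValueError("density values must be nonnegative")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def select_in_image(samples: pd.DataFrame, geometry: DisplayGeometry) -> pd.DataFrame:
    """Keep samples inside the displayed image; add image-local coordinates.

    Membership uses the half-open rectangle [origin, origin + display_size)
    in both axes.  Image coordinates are ``floor((screen - origin) / scale)``
    so they land in [0, H)×[0, W): ``col_img`` from x, ``row_img`` from y.
    """
    ox, oy = geometry.image_origin
    d = geometry.image_display_size
    x = samples["x_px"].to_numpy(dtype=float)
    y = samples["y_px"].to_numpy(dtype=float)
    inside = (x >= ox) & (x < ox + d) & (y >= oy) & (y < oy + d)
    out = samples.loc[inside].copy()
    out["col_img"] = np.floor((out["x_px"].to_numpy(dtype=float) - ox)
                              / geometry.scale_factor).astype(np.int64)
    out["row_img"] = np.floor((out["y_px"].to_numpy(dtype=float) - oy)
                              / geometry.scale_factor).astype(np.int64)
    return out


def window_samples(samples: pd.DataFrame, config: HeatmapConfig) -> list[pd.DataFrame]:
    """Group time-sorted samples into the config's presentation-time windows.

    Returns exactly ``horizon/window`` groups (possibly empty).  Windows are
    half-open [k·w, (k+1)·w) on the presentation clock; out-of-image samples
    should already have been dropped and do not shift window boundaries.
    In ``full_presentation`` mode a single group holding every sample is
    returned.  In ``cumulative`` mode group k pools windows 0..k.
    """
    if config.full_presentation:
        return [samples]
    n = config.n_windows  # validates divisibility
    t = samples["t_ms"].to_numpy(dtype=float)
    groups = []
    for k in range(n):
        lo = 0.0 if config.cumulative else k * config.window_ms
        hi = (k + 1) * config.window_ms
        groups.append(samples.loc[(t >= lo) & (t < hi)])
    return groups


def accumulate_density(sample_group: pd.DataFrame, image_size: int) -> np.ndarray:
    """Per-pixel sample counts for one window (dwell time at 1 kHz).

    Rejects out-of-range coordinates: those indicate an upstream bug, since
    :func:`select_in_image` guarantees [0, H)×[0, W).
    """
    raw = np.zeros((image_size, image_size), dtype=np.int64)
    if len(sample_group) == 0:
        return raw
    rows = sample_group["row_img"].to_numpy(dtype=np.int64)
    cols = sample_group["col_img"].to_numpy(dtype=np.int64)
    if rows.min() < 0 or rows.max() >= image_size or cols.min() < 0 or cols.max() >= image_size:
        raise ValueError("image-local coordinates out of range; run select_in_image first")
    np.add.at(raw, (rows, cols), 1)
    return raw


def smooth_density(raw: np.ndarray, config: HeatmapConfig) -> np.ndarray:
    """Gaussian smoothing of a raw count matrix (pre-normalization).

    SD ``config.smoothing_sd_px``, truncated at 4 SD, reflective borders:
    total mass is conserved.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if (raw < 0).any():
        raise ValueError("raw counts must be nonnegative")
    return ndimage.gaussian_filter(raw, config.smoothing_sd_px,
                                   mode="reflect", truncate=4.0)


def smooth_and_normalize(raw: np.ndarray, config: HeatmapConfig,
                         image_id: str = "", window_index: Union[int, str] = "all",
                         window_onset_ms: float = 0.0,
                         window_offset_ms: float = 0.0) -> FixationDensityMap:
    """Gaussian-smooth a raw count matrix and peak-normalize it.

    Smoothing uses SD ``config.smoothing_sd_px`` truncated at 4 SD with
    reflective borders (mass-conserving).  All-zero input stays all-zero
    and is recorded with ``normalization="none"``.
    """
    smoothed = smooth_density(raw, config)
    peak = smoothed.max()
    if peak > 0:
        values, norm = smoothed / peak, "peak"
    else:
        values, norm = smoothed, "none"
    return FixationDensityMap(image_id=image_id, window_index=window_index,
                              window_onset_ms=window_onset_ms,
                              window_offset_ms=window_offset_ms,
                              values=values, normalization=norm)


def average_participants(maps: Sequence[FixationDensityMap]) -> FixationDensityMap:
    """Element-wise mean of per-participant maps, then peak-normalized.

    All maps must refer to the same image and window and share a shape.
    """
    if len(maps) == 0:
        raise ValueError("need at least one map")
    first = maps[0]
    for m in maps[1:]:
        if m.values.shape != first.values.shape:
            raise ValueError("mismatched map shapes")
        if m.image_id != first.image_id or m.window_index != first.window_index:
            raise ValueError("maps must refer to the same image and window")
    mean = np.mean([m.values for m in maps], axis=0)
    peak = mean.max()
    if peak > 0:
        return FixationDensityMap(first.image_id, first.window_index,
                                  first.window_onset_ms, first.window_offset_ms,
                                  mean / peak, "peak")
    return FixationDensityMap(first.image_id, first.window_index,
                              first.window_onset_ms, first.window_offset_ms,
                              mean, "none")


def participant_heatmaps(samples: pd.DataFrame, geometry: DisplayGeometry,
                         config: HeatmapConfig, image_id: str,
                         image_size: int | None = None) -> list[FixationDensityMap]:
    """One participant's density maps for one image, one per window."""
    if image_size is None:
        image_size = geometry.image_size
    local = select_in_image(samples, geometry)
    maps = []
    for k, group in enumerate(window_samples(local, config)):
        raw = accumulate_density(group, image_size)
        if config.full_presentation:
            widx, onset, offset = "all", 0.0, float(samples["t_ms"].max()) if len(samples) else 0.0
        else:
            widx = k
            onset = (0.0 if config.cumulative else k * config.window_ms)
            offset = (k + 1) * config.window_ms
        maps.append(smooth_and_normalize(raw, config, image_id=image_id,
                                         window_index=widx, window_onset_ms=onset,
                                         window_offset_ms=offset))
    return maps


def mass_in_roi(map_values: np.ndarray, roi: np.ndarray) -> float:
    """Fraction of a map's total mass inside a binary ROI (0 if empty map)."""
    total = float(map_values.sum())
    if total <= 0:
        return 0.0
    return float(map_values[roi.astype(bool)].sum()) / total
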