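"""Human-Spotlight / Anti-Spotlight image manipulation.

Fixation-density maps are thresholded at the first tertile of the
peak-normalized value range: pixels below the threshold are blurred, those
above stay sharp (Human-Spotlight, HS).  The Anti-Spotlight (AS) condition
inverts the binary mask.  Blurring uses a windowed Gaussian (W = 30,
SD = 7 at 227 px), and the binary keep mask is softened with a second
Gaussian edge taper (W = 35, SD = 9) before alpha-compositing sharp over
blurred.  The threshold is on the *value* range, not a pixel percentile:
a focal density map therefore blurs most of the image in HS (~76% in the
reference conditions) and little of it in AS.

``build_training_set`` assembles fine-tuning datasets in which a seeded
fraction of each category's images (the manipulation ratio) is replaced
by its manipulated version.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import windowed_gaussian_filter
from .gaze_heatmaps import FixationDensityMap
from .synthetic_data import StimulusImage

MODES = ("STD", "HS", "AS")


@dataclass(frozen=True)
class ManipulationSpec:
    """Threshold, blur and taper parameters of the spotlight manipulation.

    Window sizes (``*_window``) are square Gaussian kernel sizes in pixels
    with the stated SD; borders are reflected.  ``taper_target`` records
    that the taper softens the binary mask (alpha compositing) rather than
    the composited seam.
    """

    mode: str = "HS"
    threshold: float = 1.0 / 3.0
    blur_window: int = 30
    blur_sd: float = 7.0
    taper_window: int = 35
    taper_sd: float = 9.0
    taper_target: str = "mask"

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.blur_window < 1 or self.taper_window < 1:
            raise ValueError("kernel windows must be positive")
        if self.blur_sd <= 0 or self.taper_sd <= 0:
            raise ValueError("kernel SDs must be positive")

    def scaled_for(self, image_size: int, base_size: int = 227) -> "ManipulationSpec":
        """Rescale kernel sizes/SDs proportionally for another resolution."""
        f = image_size / base_size
        return replace(self,
                       blur_window=max(3, int(round(self.blur_window * f))),
                       blur_sd=max(0.5, self.blur_sd * f),
                       taper_window=max(3, int(round(self.taper_window * f))),
                       taper_sd=max(0.5, self.taper_sd * f))


@dataclass
class SpotlightMask:
    """Keep/blur mask derived from one density map.

    ``binary_keep`` is the pre-taper thresholded mask (True = sharp);
    ``keep`` is its tapered [0, 1] version; ``blur_fraction`` the
    proportion of pixels with ``binary_keep`` False.
    """

    image_id: str
    keep: np.ndarray
    binary_keep: np.ndarray
    blur_fraction: float

    def __post_init__(self):
        if self.keep.min() < 0 or self.keep.max() > 1:
            raise ValueError("keep must lie in [0, 1]")
        if not 0.0 <= self.blur_fraction <= 1.0:
            raise ValueError("blur_fraction must lie in [0, 1]")


def tertile_mask(density: FixationDensityMap, spec: ManipulationSpec) -> SpotlightMask:
    """Threshold a peak-normalized density map into a keep/blur mask.

    HS keeps pixels with density >= threshold; AS keeps the complement;
    STD keeps everything.  The taper Gaussian softens the binary mask into
    the [0, 1] ``keep`` alpha.
    """
    values = density.values
    if spec.mode == "STD":
        binary = np.ones(values.shape, dtype=bool)
    elif spec.mode == "HS":
        binary = values >= spec.threshold
    else:  # AS
        binary = values < spec.threshold
    if not binary.any():
        warnings.warn(f"degenerate density map for {density.image_id!r}: "
                      f"{spec.mode} mask keeps nothing", stacklevel=2)
        keep = np.zeros(values.shape, dtype=np.float64)
    elif binary.all():
        keep = np.ones(values.shape, dtype=np.float64)
    else:
        keep = np.clip(windowed_gaussian_filter(binary.astype(np.float64),
                                                spec.taper_window, spec.taper_sd),
                       0.0, 1.0)
    return SpotlightMask(image_id=density.image_id, keep=keep, binary_keep=binary,
                         blur_fraction=float(1.0 - binary.mean()))


def blur_image(pixels: np.ndarray, spec: ManipulationSpec) -> np.ndarray:
    """Per-channel windowed Gaussian blur of an H×W×3 image."""
    out = np.empty_like(pixels, dtype=np.float64)
    for ch in range(pixels.shape[2]):
        out[:, :, ch] = windowed_gaussian_filter(pixels[:, :, ch],
                                                 spec.blur_window, spec.blur_sd)
    return out


def apply_spotlight(image: StimulusImage, mask: SpotlightMask,
                    spec: ManipulationSpec) -> np.ndarray:
    """Composite the sharp image over its blurred version under the mask.

    output = keep ⊙ image + (1 − keep) ⊙ blurred, per channel.  STD mode
    returns the input pixels unchanged, bit-exact.
    """
    if spec.mode == "STD":
        return image.pixels.copy()
    if mask.keep.shape != image.pixels.shape[:2]:
        raise ValueError("mask and image shapes differ")
    pixels = image.pixels.astype(np.float64)
    blurred = blur_image(pixels, spec)
    keep = mask.keep[:, :, None]
    out = keep * pixels + (1.0 - keep) * blurred
    return out.astype(image.pixels.dtype)


@dataclass
class TrainingSet:
    """A fine-tuning dataset: per-image pixels plus a provenance manifest."""

    mode: str
    ratio_percent: int
    images: dict            # image_id -> H×W×3 pixels actually used for training
    manifest: pd.DataFrame  # image_id, category, animate, has_face, manipulated, blur_fraction

    @property
    def labels(self) -> pd.Series:
        return self.manifest.set_index("image_id")["category"]


def build_training_set(stimuli: Sequence[StimulusImage],
                       density_maps: Mapping[str, FixationDensityMap],
                       mode: str, ratio_percent: int, seed: int,
                       spec: ManipulationSpec | None = None) -> TrainingSet:
    """Assemble a ratio-mixed fine-tuning dataset.

    Within each category, ``round(ratio/100 × n)`` images (seeded draw) are
    replaced by their ``mode``-manipulated versions; the rest stay STD.
    Ratio 0 is the all-STD dataset regardless of mode; ratio 100 manipulates
    every image.
    """
    if ratio_percent not in range(0, 101, 10):
        raise ValueError("ratio_percent must be one of 0, 10, ..., 100")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if spec is None:
        spec = ManipulationSpec(mode=mode)
    else:
        spec = replace(spec, mode=mode)

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, ratio_percent]))
    by_category: dict[str, list[StimulusImage]] = {}
    for im in stimuli:
        by_category.setdefault(im.category, []).append(im)

    images, rows = {}, []
    for category in sorted(by_category):
        members = by_category[category]
        n_manip = int(round(ratio_percent / 100.0 * len(members)))
        chosen = set(rng.choice(len(members), size=n_manip, replace=False)) \
            if (mode != "STD" and n_manip > 0) else set()
        for j, im in enumerate(members):
            manipulated = j in chosen
            if manipulated:
                if im.image_id not in density_maps:
                    raise ValueError(f"missing density map for {im.image_id!r}")
                m = tertile_mask(density_maps[im.image_id], spec)
                images[im.image_id] = apply_spotlight(im, m, spec)
                blur_fraction = m.blur_fraction
            else:
                images[im.image_id] = im.pixels.copy()
                blur_fraction = 0.0
            rows.append({"image_id": im.image_id, "category": im.category,
                         "animate": im.animate, "has_face": im.has_face,
                         "manipulated": manipulated, "blur_fraction": blur_fraction})
    manifest = pd.DataFrame(rows)
    return TrainingSet(mode=mode, ratio_percent=ratio_percent,
                       images=images, manifest=manifest)


def ratio_sweep(stimuli: Sequence[StimulusImage],
                density_maps: Mapping[str, FixationDensityMap],
                mode: str, seed: int,
                spec: ManipulationSpec | None = None,
                ratios: Sequence[int] = tuple(range(100, -1, -10))) -> list[TrainingSet]:
    """Datasets for a full manipulation-ratio sweep (100 → 0 in steps of 10)."""
    return [build_training_set(stimuli, density_maps, mode, r, seed, spec)
            for r in ratios]
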