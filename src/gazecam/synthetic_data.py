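"""Synthetic stimuli and simulated gaze recordings.

This module generates (i) category-discriminative stimulus images with
object and face regions of interest and (ii) simulated 1 kHz gaze sample
streams over those images, so that the whole downstream pipeline —
fixation-density heatmaps, spotlight manipulations, CNN fine-tuning and
saliency comparison — can be exercised and tested without access to an eye
tracker or a natural-image corpus.

The gaze model is deliberately minimal: a two-state renewal process in
which the eye rests near the screen center (the fixation-cross position)
until a saccade latency of ~150-200 ms has elapsed, then lands on the face
region (with a configurable bias) or elsewhere on the object, and
refixates at a fixed rate for the remainder of the presentation.  Pupil
size, blinks, smooth pursuit and microsaccades are out of scope.

Stimulus images carry their category identity in partially redundant
cues: a body color (hue, the primary cue), a body shape, and a fine
grating patch whose orientation weakly encodes the category — placed at
the face (animate images with a face) or at the body centroid otherwise,
i.e. exactly where simulated gaze concentrates.  Fixated detail is
therefore only *partially* class-discriminative: blurring it (the
Anti-Spotlight manipulation) removes a secondary cue at small accuracy
cost while removing the features human gaze dwells on, at a large
human-likeness cost.
"""

from __future__ import annotations

import colorsys
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from ._util import substream

logger = logging.getLogger(__name__)

ANIMATE_NAMES = ("human", "dog", "cat", "bird", "fish", "snake")
INANIMATE_NAMES = ("car", "train", "house", "bed", "flower", "ball")

GAZE_CSV_COLUMNS = ["participant_id", "image_id", "t_ms", "x_px", "y_px"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of a synthetic stimulus set.

    ``face_probability`` is the probability that an image of an animate
    category contains a face region (default 0.74, i.e. roughly 133 faces
    in a 360-image set with six animate categories).
    """

    n_categories: int = 12
    n_images_per_category: int = 30
    image_size: int = 227
    animate_fraction: float = 0.5
    face_probability: float = 0.74
    seed: int = 0
    id_prefix: str = ""

    def __post_init__(self):
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        if self.image_size < 32:
            raise ValueError(
                "image_size must be >= 32: smaller canvases cannot hold an "
                "object body plus a resolvable face patch"
            )
        if not 0.0 <= self.face_probability <= 1.0:
            raise ValueError("face_probability must be in [0, 1]")
        if not 0.0 <= self.animate_fraction <= 1.0:
            raise ValueError("animate_fraction must be in [0, 1]")
        if self.n_images_per_category < 1:
            raise ValueError("n_images_per_category must be >= 1")


@dataclass
class StimulusImage:
    """A stimulus with its category label and ROI masks.

    ``pixels`` is H×W×3 float32 in [0, 1]; ``object_roi`` and ``face_roi``
    are boolean H×W masks.  ``face_roi`` is all-False when no face is
    present, and is always a subset of ``object_roi``.
    """

    image_id: str
    category: str
    animate: bool
    pixels: np.ndarray
    object_roi: np.ndarray
    face_roi: np.ndarray
    has_face: bool

    def __post_init__(self):
        if not self.object_roi.any():
            raise ValueError("object_roi must be non-empty")
        if self.has_face != bool(self.face_roi.any()):
            raise ValueError("has_face must match face_roi non-emptiness")
        if (self.face_roi & ~self.object_roi).any():
            raise ValueError("face_roi must be a subset of object_roi")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class GazeModelParams:
    """Parameters of the simulated scanpath.

    ``central_onset_ms`` is the mean latency of the first saccade away
    from the central fixation (the ~150-200 ms programming latency);
    ``face_bias`` the probability that an object-directed saccade targets
    the face ROI rather than the object at large.  Noise terms are in
    screen pixels.
    """

    sampling_rate: float = 1000.0
    presentation_ms: float = 1500.0
    central_onset_ms: float = 175.0
    central_onset_jitter_ms: float = 25.0
    saccade_noise_px: float = 8.0
    face_bias: float = 0.85
    fixation_jitter_px: float = 3.0
    refixation_rate: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.presentation_ms <= 0:
            raise ValueError("presentation_ms must be > 0")
        if not 0.0 <= self.face_bias <= 1.0:
            raise ValueError("face_bias must be in [0, 1]")


@dataclass(frozen=True)
class DisplayGeometry:
    """Placement of the stimulus image on the presentation screen.

    ``image_origin`` is the (x, y) screen coordinate of the displayed
    image's top-left corner; ``scale_factor`` is display pixels per image
    pixel (the display shows the image scaled up while analysis runs at
    the original resolution).
    """

    screen_w: int = 1920
    screen_h: int = 1080
    image_display_size: int = 454
    image_origin: tuple[int, int] = (733, 313)
    scale_factor: float = 2.0

    def __post_init__(self):
        ox, oy = self.image_origin
        if ox < 0 or oy < 0 or ox + self.image_display_size > self.screen_w \
                or oy + self.image_display_size > self.screen_h:
            raise ValueError("displayed image must lie fully inside the screen")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")

    @property
    def image_size(self) -> int:
        return int(round(self.image_display_size / self.scale_factor))

    @classmethod
    def centered(cls, image_size: int, scale_factor: float = 2.0,
                 screen_w: int = 1920, screen_h: int = 1080) -> "DisplayGeometry":
        disp = int(round(image_size * scale_factor))
        ox = (screen_w - disp) // 2
        oy = (screen_h - disp) // 2
        return cls(screen_w=screen_w, screen_h=screen_h, image_display_size=disp,
                   image_origin=(ox, oy), scale_factor=scale_factor)

    def image_to_screen(self, row: np.ndarray, col: np.ndarray):
        """Map image-pixel coordinates to the screen center of each pixel."""
        ox, oy = self.image_origin
        x = ox + (np.asarray(col, dtype=float) + 0.5) * self.scale_factor
        y = oy + (np.asarray(row, dtype=float) + 0.5) * self.scale_factor
        return x, y


# ---------------------------------------------------------------------------
# Stimulus generation
# ---------------------------------------------------------------------------

def _category_names(n_categories: int, n_animate: int) -> tuple[list[str], list[bool]]:
    names, animate = [], []
    for i in range(n_animate):
        base = ANIMATE_NAMES[i % len(ANIMATE_NAMES)]
        names.append(base if i < len(ANIMATE_NAMES) else f"{base}{i}")
        animate.append(True)
    for i in range(n_categories - n_animate):
        base = INANIMATE_NAMES[i % len(INANIMATE_NAMES)]
        names.append(base if i < len(INANIMATE_NAMES) else f"{base}{i}")
        animate.append(False)
    return names, animate


def _category_color(index: int, n_animate: int, n_categories: int) -> np.ndarray:
    # Categories come in hue pairs (warm hues for animate, cool for
    # inanimate); within a pair the body color matches and the members are
    # told apart by the contrast of their fine-texture patch — the detail
    # human gaze fixates and the spotlight blur removes.
    if index < n_animate:
        n_slots = max((n_animate + 1) // 2, 1)
        hue = 0.02 + (index // 2) / n_slots * 0.45
    else:
        j = index - n_animate
        n_slots = max((n_categories - n_animate + 1) // 2, 1)
        hue = 0.52 + (j // 2) / n_slots * 0.45
    return np.array(colorsys.hsv_to_rgb(hue % 1.0, 0.9, 0.85), dtype=np.float64)


def _body_mask(shape_kind: int, size: int, cr: float, cc: float,
               rng: np.random.Generator) -> np.ndarray:
    mask = np.zeros((size, size), dtype=bool)
    a = size * rng.uniform(0.30, 0.34)   # vertical half-extent
    b = size * rng.uniform(0.21, 0.25)   # horizontal half-extent
    if shape_kind == 0:  # ellipse
        rr, cc_ = skdraw.ellipse(cr, cc, a, b, shape=mask.shape,
                                 rotation=rng.uniform(-0.3, 0.3))
    elif shape_kind == 1:  # rectangle
        r0, r1 = cr - a, cr + a
        c0, c1 = cc - b, cc + b
        rr, cc_ = skdraw.polygon([r0, r0, r1, r1], [c0, c1, c1, c0], shape=mask.shape)
    elif shape_kind == 2:  # triangle
        rr, cc_ = skdraw.polygon([cr - a, cr + a, cr + a],
                                 [cc, cc - b, cc + b], shape=mask.shape)
    else:  # diamond
        rr, cc_ = skdraw.polygon([cr - a, cr, cr + a, cr],
                                 [cc, cc + b, cc, cc - b], shape=mask.shape)
    mask[rr, cc_] = True
    return mask


def generate_stimulus_image(spec: StimulusSpec, category_index: int,
                            image_index: int) -> StimulusImage:
    """Draw a single synthetic stimulus; deterministic for fixed spec seed."""
    size = spec.image_size
    n_animate = int(round(spec.n_categories * spec.animate_fraction))
    names, animate_flags = _category_names(spec.n_categories, n_animate)
    category = names[category_index]
    animate = animate_flags[category_index]
    rng = substream(spec.seed, "images", category_index, image_index)

    # Background: mid-gray with smooth chromatic noise plus fine pixel noise.
    img = np.full((size, size, 3), 0.5, dtype=np.float64)
    for ch in range(3):
        low = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), size * 0.06)
        img[:, :, ch] += 0.05 * low / max(low.std(), 1e-9)
    img += rng.normal(0.0, 0.008, img.shape)

    # Object body: category hue + shape.  The body is displaced laterally
    # (photographer bias is imperfect) and slightly downward so that the
    # central fixation onset does not trivially coincide with the face,
    # which sits at the top of the body.
    side = 1.0 if rng.random() < 0.5 else -1.0
    cr = size * (0.58 + rng.uniform(-0.04, 0.08))
    cc = size * (0.5 + side * rng.uniform(0.08, 0.18))
    # Animate bodies are blobby (ellipse) and rely on hue + face texture;
    # inanimate ones get angular shapes, so color-plus-shape identifies every
    # category while the face stays a genuine secondary cue on animates.
    shape_kind = 0 if animate else 1 + (category_index % 3)
    body = _body_mask(shape_kind, size, cr, cc, rng)
    hue_jitter = rng.uniform(-0.018, 0.018)
    base = _category_color(category_index, n_animate, spec.n_categories)
    h, sv, v = colorsys.rgb_to_hsv(*base)
    color = np.array(colorsys.hsv_to_rgb((h + hue_jitter) % 1.0,
                                         sv * rng.uniform(0.92, 1.0),
                                         v * rng.uniform(0.9, 1.05)))
    color = np.clip(color, 0, 1)
    tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (size, size)), 2.0)
    tex = 0.05 * tex / max(tex.std(), 1e-9)
    # Soft-edged (anti-aliased) compositing: the body boundary contributes
    # little high-spatial-frequency energy, so fine-texture channels respond
    # at the face patch rather than at silhouette edges.
    alpha = ndimage.gaussian_filter(body.astype(np.float64), 1.0)[:, :, None]
    body_layer = color[None, None, :] + tex[:, :, None]
    img = (1.0 - alpha) * img + alpha * body_layer

    # Face patch: an achromatic high-spatial-frequency grating whose
    # orientation carries (partial) category identity; shared texture family
    # across all animate categories.
    face = np.zeros((size, size), dtype=bool)
    has_face = bool(animate and rng.random() < spec.face_probability)

    def _draw_grating_patch(center_r, center_c, radius):
        """Fine grating disk (orientation encodes category, weakly)."""
        patch = np.zeros((size, size), dtype=bool)
        rr, cc_ = skdraw.disk((center_r, center_c), radius, shape=patch.shape)
        patch[rr, cc_] = True
        patch &= body
        if not patch.any():
            return patch
        theta = np.pi * category_index / max(spec.n_categories, 1) \
            + rng.uniform(-0.08, 0.08)
        freq = 0.2  # cycles per pixel: destroyed by the spotlight blur
        # hue-pair members differ in patch contrast: a first-order texture
        # energy cue the classifier can read and the blur genuinely removes
        contrast = (0.08 if category_index % 2 == 0 else 0.50) \
            + rng.uniform(-0.02, 0.02)
        gr, gc = np.nonzero(patch)
        phase = rng.uniform(0, 2 * np.pi)
        grating = np.sin(2 * np.pi * freq
                         * (gc * np.cos(theta) + gr * np.sin(theta)) + phase)
        img[gr, gc, :] = (0.5 + contrast * grating)[:, None]
        return patch

    if has_face:
        radius = max(size * 0.12, 2.0)
        rows_body, cols_body = np.nonzero(body)
        top_r = np.percentile(rows_body, 8)
        fr = top_r + radius * 1.0
        fc = np.median(cols_body[rows_body <= np.percentile(rows_body, 25)]) \
            + rng.uniform(-0.02, 0.02) * size
        face = _draw_grating_patch(fr, fc, radius)
        has_face = bool(face.any())
    if not has_face:
        # Faceless objects still carry an informative fine-detail patch at
        # the body centroid — the location first saccades land on — so the
        # fixated region is information-rich for every image.
        rows_body, cols_body = np.nonzero(body)
        _draw_grating_patch(rows_body.mean(), cols_body.mean(),
                            max(size * 0.12, 2.0))

    pixels = np.clip(img, 0.0, 1.0).astype(np.float32)
    return StimulusImage(
        image_id=f"{spec.id_prefix}{category}_{image_index:03d}",
        category=category,
        animate=animate,
        pixels=pixels,
        object_roi=body,
        face_roi=face,
        has_face=has_face,
    )


def generate_stimulus_set(spec: StimulusSpec) -> list[StimulusImage]:
    """Generate the full stimulus set described by ``spec``.

    Deterministic for a fixed seed; every image carries a discriminative
    body color/shape signature and animate-category images contain a face
    patch with probability ``spec.face_probability``.
    """
    images = []
    for ci in range(spec.n_categories):
        for ii in range(spec.n_images_per_category):
            images.append(generate_stimulus_image(spec, ci, ii))
    return images


# ---------------------------------------------------------------------------
# Scanpath simulation
# ---------------------------------------------------------------------------

def _roi_centroid(mask: np.ndarray) -> tuple[float, float]:
    """ROI centroid, snapped to the nearest mask pixel if it falls outside
    (concave ROIs, e.g. a face disk clipped by the body boundary)."""
    rows, cols = np.nonzero(mask)
    r, c = rows.mean(), cols.mean()
    if mask[int(round(r)), int(round(c))]:
        return float(r), float(c)
    j = np.argmin((rows - r) ** 2 + (cols - c) ** 2)
    return float(rows[j]), float(cols[j])


def simulate_scanpath_arrays(image: StimulusImage, params: GazeModelParams,
                             geometry: DisplayGeometry,
                             rng: np.random.Generator):
    """Core scanpath simulator returning (t_ms, x_px, y_px) arrays.

    Two-state renewal process: central fixation until a jittered saccade
    latency, then object/face fixations with refixations at
    ``refixation_rate`` per second.  All coordinates are screen pixels and
    may fall outside the image.
    """
    dt = 1000.0 / params.sampling_rate
    n = int(round(params.presentation_ms / dt))
    t = np.arange(n) * dt

    latency = rng.normal(params.central_onset_ms, params.central_onset_jitter_ms)
    latency = float(np.clip(latency, 2 * dt, params.presentation_ms))

    # Fixation onset times: central onset, first saccade landing, then
    # exponential refixation intervals.
    onsets = [0.0, latency]
    scale_ms = 1000.0 / max(params.refixation_rate, 1e-9)
    tcur = latency
    while params.refixation_rate > 0:
        tcur = tcur + rng.exponential(scale_ms)
        if tcur >= params.presentation_ms:
            break
        onsets.append(tcur)

    use_face = image.has_face
    if params.face_bias >= 1.0 and not use_face:
        logger.debug("image %s: face_bias=1 but no face ROI; falling back to object",
                     image.image_id)
    obj_centroid = _roi_centroid(image.object_roi)
    face_centroid = _roi_centroid(image.face_roi) if use_face else obj_centroid
    obj_rows, obj_cols = np.nonzero(image.object_roi)

    cx = geometry.screen_w / 2.0
    cy = geometry.screen_h / 2.0
    fx, fy = [cx], [cy]  # central fixation at the fixation-cross position
    for k in range(1, len(onsets)):
        if use_face and rng.random() < params.face_bias:
            r, c = face_centroid
        elif k == 1:
            r, c = obj_centroid
        else:  # refixations explore the object at large
            j = rng.integers(len(obj_rows))
            r, c = float(obj_rows[j]), float(obj_cols[j])
        x, y = geometry.image_to_screen(r, c)
        fx.append(float(x) + rng.normal(0.0, params.saccade_noise_px))
        fy.append(float(y) + rng.normal(0.0, params.saccade_noise_px))

    idx = np.searchsorted(np.asarray(onsets), t, side="right") - 1
    x = np.asarray(fx)[idx] + rng.normal(0.0, params.fixation_jitter_px, n)
    y = np.asarray(fy)[idx] + rng.normal(0.0, params.fixation_jitter_px, n)
    return t, x, y


def simulate_scanpath(image: StimulusImage, params: GazeModelParams,
                      geometry: DisplayGeometry, participant_id: str,
                      rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Simulate one trial; returns a tidy gaze-sample DataFrame.

    Columns: participant_id, image_id, t_ms, x_px, y_px (screen pixels,
    origin top-left, x = column).
    """
    if rng is None:
        rng = substream(params.seed, "trial", participant_id, image.image_id)
    t, x, y = simulate_scanpath_arrays(image, params, geometry, rng)
    return pd.DataFrame({
        "participant_id": participant_id,
        "image_id": image.image_id,
        "t_ms": t,
        "x_px": x,
        "y_px": y,
    })


def perturb_params(params: GazeModelParams, rng: np.random.Generator) -> GazeModelParams:
    """Draw participant-level parameters around the cohort means."""
    return GazeModelParams(
        sampling_rate=params.sampling_rate,
        presentation_ms=params.presentation_ms,
        central_onset_ms=float(np.clip(rng.normal(params.central_onset_ms, 20.0), 80.0, 400.0)),
        central_onset_jitter_ms=params.central_onset_jitter_ms,
        saccade_noise_px=float(params.saccade_noise_px * rng.lognormal(0.0, 0.2)),
        face_bias=float(np.clip(rng.normal(params.face_bias, 0.05), 0.0, 1.0)),
        fixation_jitter_px=float(params.fixation_jitter_px * rng.lognormal(0.0, 0.2)),
        refixation_rate=float(params.refixation_rate * rng.lognormal(0.0, 0.2)),
        seed=params.seed,
    )


@dataclass
class Cohort:
    """A simulated participant cohort: one gaze stream per (participant, image)."""

    manifest: dict
    frames: Optional[dict] = None   # participant_id -> DataFrame (in-memory mode)
    paths: Optional[dict] = None    # participant_id -> CSV path (on-disk mode)


def simulate_cohort(stimuli: Sequence[StimulusImage], n_participants: int,
                    params: GazeModelParams, geometry: DisplayGeometry,
                    out_dir: Optional[str | Path] = None,
                    participant_ids: Optional[Sequence[str]] = None) -> Cohort:
    """Simulate a cohort; one stream per (participant, image).

    Per-participant parameters are perturbed around the cohort means; the
    manifest records the master seed, every participant's derived seed and
    perturbed parameters.  With ``out_dir`` set, one CSV per participant
    plus ``manifest.json`` are written; otherwise streams are returned
    in-memory.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if participant_ids is None:
        participant_ids = [f"p{k:03d}" for k in range(n_participants)]
    if len(set(participant_ids)) != len(participant_ids):
        raise ValueError("duplicate participant ids")
    if len(participant_ids) != n_participants:
        raise ValueError("participant_ids length must equal n_participants")

    manifest = {"master_seed": params.seed, "n_participants": n_participants,
                "participants": {}}
    frames = {} if out_dir is None else None
    paths = {} if out_dir is not None else None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    for k, pid in enumerate(participant_ids):
        prng = substream(params.seed, "participant", k)
        pparams = perturb_params(params, prng)
        manifest["participants"][pid] = {
            "index": k,
            "central_onset_ms": pparams.central_onset_ms,
            "face_bias": pparams.face_bias,
            "saccade_noise_px": pparams.saccade_noise_px,
            "fixation_jitter_px": pparams.fixation_jitter_px,
            "refixation_rate": pparams.refixation_rate,
        }
        chunks = []
        for image in stimuli:
            trng = substream(params.seed, "trial", k, image.image_id)
            t, x, y = simulate_scanpath_arrays(image, pparams, geometry, trng)
            chunks.append(pd.DataFrame({
                "participant_id": pid, "image_id": image.image_id,
                "t_ms": t, "x_px": x, "y_px": y,
            }))
        frame = pd.concat(chunks, ignore_index=True)
        if out_dir is None:
            frames[pid] = frame
        else:
            path = out_dir / f"gaze_{pid}.csv"
            frame.to_csv(path, index=False)
            paths[pid] = str(path)

    if out_dir is not None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return Cohort(manifest=manifest, frames=frames, paths=paths)


def write_stimulus_set(stimuli: Sequence[StimulusImage], out_dir: str | Path) -> Path:
    """Write PNG images, 0/255 ROI mask PNGs and a label manifest CSV."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in stimuli:
        Image.fromarray((im.pixels * 255).astype(np.uint8)).save(out_dir / f"{im.image_id}.png")
        Image.fromarray(im.object_roi.astype(np.uint8) * 255).save(
            out_dir / f"{im.image_id}_object_roi.png")
        if im.has_face:
            Image.fromarray(im.face_roi.astype(np.uint8) * 255).save(
                out_dir / f"{im.image_id}_face_roi.png")
        rows.append({"image_id": im.image_id, "category": im.category,
                     "animate": im.animate, "has_face": im.has_face})
    manifest = out_dir / "stimuli.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
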