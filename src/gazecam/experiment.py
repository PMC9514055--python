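"""End-to-end experiment orchestration.

Runs the full pipeline on synthetic materials: generate a training and a
held-out testing stimulus set, simulate a gaze cohort over each, build
participant-averaged fixation density maps (full presentation for the
spotlight manipulation; 50 ms windows for the time-resolved comparison),
derive STD/HS/AS fine-tuning datasets, fine-tune repeated seeded runs,
extract Grad-CAM saliency maps on the testing set, and measure
accuracy, saliency–gaze similarity (overall and per window) and the
face-detection index.  A ratio-sweep variant produces the
accuracy-vs-similarity trade-off table.

The default problem size (12 categories × 30 images at 64×64 px, 23
simulated participants, 10 runs per condition) keeps a complete run on a
single CPU in the minutes range; kernel sizes and smoothing SDs are
scaled proportionally from their 227 px reference values.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import substream
from .gaze_heatmaps import (FixationDensityMap, HeatmapConfig,
                            participant_heatmaps, scaled_smoothing_sd)
from .gradcam import gradcam_batch
from .metrics import face_detection_index, similarity_table, tradeoff_curve
from .model_training import (BackboneSpec, ConvNet, ModelRun, TrainingConfig,
                             compute_features, derived_seed, evaluate_accuracy,
                             fine_tune)
from .spotlight import ManipulationSpec, build_training_set
from .synthetic_data import (DisplayGeometry, GazeModelParams, StimulusImage,
                             StimulusSpec, generate_stimulus_set, perturb_params)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for a synthetic end-to-end run."""

    seed: int = 0
    n_categories: int = 12
    n_images_per_category: int = 30
    image_size: int = 64
    face_probability: float = 0.74
    n_participants: int = 23
    face_bias: float = 0.85
    n_runs: int = 10
    backbone: str = "small"
    horizon_ms: float = 1000.0
    window_ms: float = 50.0

    def stimulus_spec(self, stream: str) -> StimulusSpec:
        return StimulusSpec(n_categories=self.n_categories,
                            n_images_per_category=self.n_images_per_category,
                            image_size=self.image_size,
                            face_probability=self.face_probability,
                            seed=derived_seed(self.seed, zlib.crc32(stream.encode()) & 0xFFFF),
                            id_prefix=f"{stream}:")

    def gaze_params(self, stream_index: int) -> GazeModelParams:
        return GazeModelParams(face_bias=self.face_bias,
                               seed=derived_seed(self.seed, 1000 + stream_index))

    def geometry(self) -> DisplayGeometry:
        return DisplayGeometry.centered(self.image_size)

    def heatmap_config(self, full: bool) -> HeatmapConfig:
        return HeatmapConfig(window_ms=self.window_ms, horizon_ms=self.horizon_ms,
                             smoothing_sd_px=scaled_smoothing_sd(self.image_size),
                             full_presentation=full)

    def manipulation_spec(self, mode: str) -> ManipulationSpec:
        return ManipulationSpec(mode=mode).scaled_for(self.image_size)

    def training_config(self, seed: int) -> TrainingConfig:
        return TrainingConfig(seed=seed)


def cohort_average_maps(stimuli: Sequence[StimulusImage], n_participants: int,
                        params: GazeModelParams, geometry: DisplayGeometry,
                        config: HeatmapConfig,
                        window_config: Optional[HeatmapConfig] = None
                        ) -> dict[str, dict]:
    """Participant-averaged density maps for every stimulus.

    Per participant and image a scanpath is simulated, per-window maps are
    smoothed and peak-normalized, and the normalized maps are averaged
    across participants and re-normalized.  Returns
    ``image_id -> {"all": FixationDensityMap, 0: ..., 1: ...}`` (window
    entries only when ``window_config`` is given).
    """
    from .synthetic_data import simulate_scanpath_arrays

    size = geometry.image_size
    n_win = window_config.n_windows if window_config is not None else 0
    acc = {im.image_id: {"all": np.zeros((size, size), dtype=np.float64),
                         "all_norms": 0,
                         "win": np.zeros((n_win, size, size), dtype=np.float32),
                         "win_norms": np.zeros(n_win, dtype=np.int64)}
           for im in stimuli}

    for k in range(n_participants):
        prng = substream(params.seed, "participant", k)
        pparams = perturb_params(params, prng)
        for im in stimuli:
            trng = substream(params.seed, "trial", k, im.image_id)
            t, x, y = simulate_scanpath_arrays(im, pparams, geometry, trng)
            samples = pd.DataFrame({"t_ms": t, "x_px": x, "y_px": y})
            full_map = participant_heatmaps(samples, geometry, config,
                                            im.image_id, size)[0]
            a = acc[im.image_id]
            if full_map.normalization == "peak":
                a["all"] += full_map.values
                a["all_norms"] += 1
            if window_config is not None:
                for w, wmap in enumerate(participant_heatmaps(
                        samples, geometry, window_config, im.image_id, size)):
                    if wmap.normalization == "peak":
                        a["win"][w] += wmap.values.astype(np.float32)
                        a["win_norms"][w] += 1

    out: dict[str, dict] = {}
    for im in stimuli:
        a = acc[im.image_id]
        maps: dict = {}
        mean = a["all"] / max(a["all_norms"], 1)
        peak = mean.max()
        maps["all"] = FixationDensityMap(im.image_id, "all", 0.0,
                                         params.presentation_ms,
                                         mean / peak if peak > 0 else mean,
                                         "peak" if peak > 0 else "none")
        if window_config is not None:
            for w in range(n_win):
                mean = a["win"][w].astype(np.float64) / max(a["win_norms"][w], 1)
                peak = mean.max()
                maps[w] = FixationDensityMap(
                    im.image_id, w, w * window_config.window_ms,
                    (w + 1) * window_config.window_ms,
                    mean / peak if peak > 0 else mean,
                    "peak" if peak > 0 else "none")
        out[im.image_id] = maps
    return out


@dataclass
class Materials:
    """Everything a set of fine-tuning conditions shares."""

    config: ExperimentConfig
    stimuli_train: list[StimulusImage]
    stimuli_test: list[StimulusImage]
    train_density: dict            # image_id -> FixationDensityMap ("all")
    test_maps: dict                # image_id -> {window: FixationDensityMap}
    image_info: pd.DataFrame       # indexed by test image_id
    backbone: ConvNet
    test_conv_act: dict            # image_id -> last-conv activations


def prepare_materials(config: ExperimentConfig,
                      with_windows: bool = True) -> Materials:
    """Generate stimuli and gaze cohorts; precompute shared model inputs."""
    logger.info("generating stimulus sets (%d x %d images at %d px)",
                config.n_categories, config.n_images_per_category,
                config.image_size)
    stimuli_train = generate_stimulus_set(config.stimulus_spec("train"))
    stimuli_test = generate_stimulus_set(config.stimulus_spec("test"))
    geometry = config.geometry()

    logger.info("simulating training cohort (%d participants)", config.n_participants)
    train_maps = cohort_average_maps(stimuli_train, config.n_participants,
                                     config.gaze_params(0), geometry,
                                     config.heatmap_config(full=True))
    train_density = {iid: maps["all"] for iid, maps in train_maps.items()}

    logger.info("simulating testing cohort")
    test_maps = cohort_average_maps(
        stimuli_test, config.n_participants, config.gaze_params(1), geometry,
        config.heatmap_config(full=True),
        config.heatmap_config(full=False) if with_windows else None)

    image_info = pd.DataFrame(
        [{"image_id": im.image_id, "category": im.category,
          "animate": im.animate, "has_face": im.has_face}
         for im in stimuli_test]).set_index("image_id")

    backbone = BackboneSpec(architecture=config.backbone,
                            input_size=config.image_size,
                            n_classes=config.n_categories,
                            weights_seed=derived_seed(config.seed, 7)).build()
    test_conv_act, _ = compute_features(
        backbone, {im.image_id: im.pixels for im in stimuli_test})
    return Materials(config, stimuli_train, stimuli_test, train_density,
                     test_maps, image_info, backbone, test_conv_act)


def run_condition(materials: Materials, mode: str, ratio_percent: int,
                  n_runs: int, seed_offset: int = 0) -> tuple[list[ModelRun], dict]:
    """Fine-tune ``n_runs`` seeded runs of one (mode, ratio) condition.

    Returns the runs (with accuracy evaluated on the held-out set) and a
    run_id -> {image_id -> saliency map} dict of Grad-CAM maps.
    """
    cfg = materials.config
    train_set = build_training_set(
        materials.stimuli_train, materials.train_density, mode, ratio_percent,
        seed=derived_seed(cfg.seed, 50 + ratio_percent),
        spec=cfg.manipulation_spec(mode if mode != "STD" else "HS"))
    _, features = compute_features(materials.backbone, train_set.images)

    class_to_idx = {c: i for i, c in enumerate(sorted(
        materials.image_info["category"].unique()))}
    test_ids = list(materials.image_info.index)
    acts = np.stack([materials.test_conv_act[i] for i in test_ids])
    true_idx = np.array([class_to_idx[materials.image_info.loc[i, "category"]]
                         for i in test_ids])

    runs, saliency = [], {}
    for k in range(n_runs):
        run_seed = derived_seed(cfg.seed, 10_000 + seed_offset + k)
        run = fine_tune(materials.backbone, train_set,
                        cfg.training_config(run_seed),
                        run_id=f"{mode}{ratio_percent}_r{k:02d}", mode=mode,
                        features=features)
        evaluate_accuracy(run, materials.stimuli_test,
                          conv_act=materials.test_conv_act)
        maps, _ = gradcam_batch(run.model, acts, true_idx,
                                out_size=cfg.image_size)
        saliency[run.run_id] = {iid: maps[j] for j, iid in enumerate(test_ids)}
        runs.append(run)
    return runs, saliency


@dataclass
class DirectionalResult:
    """Outputs of the STD/HS/AS comparison on one synthetic cohort."""

    materials: Materials
    runs: list[ModelRun]
    accuracy: pd.DataFrame          # one row per run
    similarity: pd.DataFrame        # per (run, image, window) records
    face_index_model: pd.DataFrame  # per (run, image) on face images
    face_index_human: pd.DataFrame  # per (image, window) on face images
    window_curve: pd.DataFrame      # mean z per (mode, window)
    blur_fractions: pd.DataFrame    # per (mode, image)


def _human_face_index(materials: Materials) -> pd.DataFrame:
    rows = []
    face_images = [im for im in materials.stimuli_test if im.has_face]
    for im in face_images:
        for window, dmap in materials.test_maps[im.image_id].items():
            if dmap.values.sum() <= 0:
                continue
            idx = face_detection_index(dmap.values, im.face_roi)
            rows.append({"image_id": im.image_id, "window": window,
                         "index": idx.value, "capped": idx.capped})
    return pd.DataFrame(rows)


def _model_face_index(materials: Materials, saliency_by_run: Mapping,
                      run_meta: Mapping) -> pd.DataFrame:
    face_rois = {im.image_id: im.face_roi for im in materials.stimuli_test
                 if im.has_face}
    rows = []
    for run_id, maps in saliency_by_run.items():
        meta = run_meta[run_id]
        for image_id, roi in face_rois.items():
            sal = maps[image_id]
            if sal.sum() <= 0:
                continue
            idx = face_detection_index(sal, roi)
            rows.append({"mode": meta["mode"],
                         "ratio_percent": meta["ratio_percent"],
                         "run_id": run_id, "image_id": image_id,
                         "index": idx.value, "capped": idx.capped})
    return pd.DataFrame(rows)


def _blur_fractions(materials: Materials) -> pd.DataFrame:
    from .spotlight import tertile_mask

    rows = []
    for mode in ("HS", "AS"):
        spec = materials.config.manipulation_spec(mode)
        for iid, dmap in materials.train_density.items():
            mask = tertile_mask(dmap, spec)
            rows.append({"mode": mode, "image_id": iid,
                         "blur_fraction": mask.blur_fraction})
    return pd.DataFrame(rows)


def run_directional_experiment(config: ExperimentConfig,
                               modes: Sequence[str] = ("STD", "HS", "AS"),
                               materials: Optional[Materials] = None
                               ) -> DirectionalResult:
    """The core reproduction: STD vs HS vs AS at ratio 100 on one cohort."""
    if materials is None:
        materials = prepare_materials(config, with_windows=True)

    all_runs, saliency_by_run, run_meta = [], {}, {}
    for mi, mode in enumerate(modes):
        logger.info("fine-tuning %s condition (%d runs)", mode, config.n_runs)
        runs, saliency = run_condition(materials, mode, 100 if mode != "STD" else 0,
                                       config.n_runs, seed_offset=1000 * mi)
        all_runs.extend(runs)
        saliency_by_run.update(saliency)
        for r in runs:
            run_meta[r.run_id] = {"mode": r.mode, "ratio_percent": r.ratio_percent}

    accuracy = pd.DataFrame([{"mode": r.mode, "ratio_percent": r.ratio_percent,
                              "run_id": r.run_id, "accuracy": r.accuracy}
                             for r in all_runs])
    logger.info("computing similarity records")
    similarity = similarity_table(saliency_by_run, materials.test_maps,
                                  materials.image_info, run_meta)
    window_rows = similarity[similarity["window"] != "all"]
    window_curve = (window_rows.groupby(["mode", "window"])["z"]
                    .mean().reset_index())
    result = DirectionalResult(
        materials=materials,
        runs=all_runs,
        accuracy=accuracy,
        similarity=similarity,
        face_index_model=_model_face_index(materials, saliency_by_run, run_meta),
        face_index_human=_human_face_index(materials),
        window_curve=window_curve,
        blur_fractions=_blur_fractions(materials),
    )
    return result


def run_tradeoff(config: ExperimentConfig, mode: str = "AS",
                 ratios: Sequence[int] = (100, 50, 0), n_runs: int = 5,
                 materials: Optional[Materials] = None) -> pd.DataFrame:
    """Scaled-down accuracy-vs-similarity trade-off across ratios."""
    if materials is None:
        materials = prepare_materials(config, with_windows=False)
    acc_rows, sal_by_run, run_meta = [], {}, {}
    for ri, ratio in enumerate(ratios):
        runs, saliency = run_condition(materials, mode, ratio, n_runs,
                                       seed_offset=500 * (ri + 10))
        sal_by_run.update(saliency)
        for r in runs:
            run_meta[r.run_id] = {"mode": mode, "ratio_percent": ratio}
            acc_rows.append({"mode": mode, "ratio_percent": ratio,
                             "run_id": r.run_id, "accuracy": r.accuracy})
    gaze_all = {iid: {"all": maps["all"]} for iid, maps in materials.test_maps.items()}
    similarity = similarity_table(sal_by_run, gaze_all, materials.image_info,
                                  run_meta)
    return tradeoff_curve(pd.DataFrame(acc_rows), similarity,
                          seed=derived_seed(config.seed, 99))
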