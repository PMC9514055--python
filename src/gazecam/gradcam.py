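"""Grad-CAM saliency maps from the last convolutional layer.

For an input image and its *true* class label (misclassified images
included), channel weights are the spatial mean of the gradient of the
class score with respect to the last conv layer's activations; the map is
the rectified, channel-weighted sum of those activations, bilinearly
upsampled to the input resolution and min–max normalized to [0, 1].  The
gradient target defaults to the pre-softmax logit (invariant to adding a
constant to all logits); the softmax probability is available as an
option.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.transform import resize

from .model_training import ConvNet


@dataclass
class SaliencyMap:
    """A normalized Grad-CAM map for one (run, image, true class).

    ``values`` is H×W in [0, 1]; ``degenerate`` flags a map whose
    pre-normalization values were identically zero (kept all-zero).
    """

    image_id: str
    run_id: str
    target_class: str
    values: np.ndarray
    source_layer: str
    degenerate: bool = False

    def __post_init__(self):
        if (self.values < 0).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("saliency values must lie in [0, 1]")


def channel_weights(model: ConvNet, conv_act: np.ndarray, class_idx,
                    target: str = "logit") -> np.ndarray:
    """Grad-CAM channel weights: spatially pooled class-score gradients."""
    grads = model.grad_wrt_last_conv(conv_act, class_idx, target=target)
    return grads.mean(axis=(2, 3))


def _normalize_cam(cam: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = float(cam.min()), float(cam.max())
    if hi <= 0.0:
        return np.zeros_like(cam), True
    if hi - lo < 1e-300:
        return np.ones_like(cam), False
    return (cam - lo) / (hi - lo), False


def gradcam_batch(model: ConvNet, conv_act: np.ndarray,
                  class_idx: np.ndarray, out_size: Optional[int] = None,
                  target: str = "logit") -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Grad-CAM over a batch of precomputed conv activations.

    Returns (maps (N, out, out) in [0, 1], degenerate flags (N,)).
    """
    if out_size is None:
        out_size = model.input_size
    alpha = channel_weights(model, conv_act, class_idx, target=target)
    cam = np.maximum(np.einsum("nc,nchw->nhw", alpha, conv_act), 0.0)
    maps = np.empty((cam.shape[0], out_size, out_size))
    degenerate = np.zeros(cam.shape[0], dtype=bool)
    for i in range(cam.shape[0]):
        up = resize(cam[i], (out_size, out_size), order=1, mode="edge",
                    anti_aliasing=False)
        maps[i], degenerate[i] = _normalize_cam(up)
    return maps, degenerate


def gradcam(model: ConvNet, image_pixels: np.ndarray, true_class_idx: int,
            image_id: str = "", run_id: str = "",
            target_class: str = "", target: str = "logit") -> SaliencyMap:
    """Grad-CAM map for a single image and its true class label."""
    conv_act = model.conv_forward(image_pixels[None])
    maps, degenerate = gradcam_batch(model, conv_act,
                                     np.array([true_class_idx]), target=target)
    return SaliencyMap(image_id=image_id, run_id=run_id,
                       target_class=target_class or str(true_class_idx),
                       values=maps[0], source_layer=model.last_conv_name,
                       degenerate=bool(degenerate[0]))


def occlusion_score_drop(model: ConvNet, image_pixels: np.ndarray,
                         true_class_idx: int, saliency: np.ndarray,
                         quantile: float = 0.9,
                         rng: Optional[np.random.Generator] = None) -> tuple[float, float]:
    """Faithfulness check: logit drop when occluding top-saliency pixels.

    Occludes (sets to the image mean) the pixels above the given saliency
    quantile and an equal-area random region; returns the two true-class
    logit drops (saliency-guided, random).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    base = model.forward(image_pixels[None])[0, true_class_idx]
    thresh = np.quantile(saliency, quantile)
    top = saliency >= thresh
    n_occ = int(top.sum())
    flat = rng.choice(saliency.size, size=n_occ, replace=False)
    rand = np.zeros(saliency.size, dtype=bool)
    rand[flat] = True
    rand = rand.reshape(saliency.shape)

    fill = image_pixels.mean(axis=(0, 1))
    occ_top = image_pixels.copy()
    occ_top[top] = fill
    occ_rand = image_pixels.copy()
    occ_rand[rand] = fill
    drop_top = float(base - model.forward(occ_top[None])[0, true_class_idx])
    drop_rand = float(base - model.forward(occ_rand[None])[0, true_class_idx])
    return drop_top, drop_rand
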