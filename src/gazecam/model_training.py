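"""CNN backbones and the freeze-and-replace fine-tuning recipe.

The transfer-learning discipline here mirrors common practice: a
convolutional feature extractor plus dense layers, of which only the
final classification layer (the "head") is replaced and trained — every
earlier layer stays frozen.  Because no gradient ever has to flow
*through* the frozen stack during training, the networks are implemented
directly in NumPy: convolution by im2col/einsum, and the head trained
with stochastic gradient descent with momentum (SGDM) on softmax
cross-entropy.  The analytic gradient of a class logit with respect to
the last convolutional activations — the quantity Grad-CAM needs — flows
only through the dense layers and is computed in closed form.

Training defaults follow a fixed recipe: SGDM with momentum 0.9,
mini-batch size 42, base learning rate 1e-4 with a ×20 factor on the
replaced head, at most 30 epochs with a validation patience of five
epochs, and no data augmentation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .synthetic_data import StimulusImage

# preset -> (conv layers [(out_channels, kernel, stride)...], frozen fc widths)
ARCHITECTURES = {
    # 3 conv + 2 fully connected: desk-scale default
    "small": ([(24, 5, 2), (48, 3, 2), (96, 3, 2)], [256]),
    # 5 conv + 3 fully connected, AlexNet-shaped (a config option, not a
    # pretrained AlexNet)
    "alexnet-like": ([(16, 7, 4), (32, 5, 2), (48, 3, 1), (48, 3, 1), (32, 3, 2)],
                     [512, 256]),
}


@dataclass(frozen=True)
class BackboneSpec:
    """Architecture choice for the classifier backbone.

    ``weights_seed`` determines the frozen random weights; runs that share
    a spec share the identical frozen backbone (as fine-tuning runs of one
    pretrained model would).  ``pretrained_weights`` optionally points to
    an ``.npz`` produced by :meth:`ConvNet.save`.
    """

    architecture: str = "small"
    input_size: int = 64
    n_classes: int = 12
    weights_seed: int = 0
    pretrained_weights: Optional[str] = None

    def build(self) -> "ConvNet":
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        conv_specs, fc_hidden = ARCHITECTURES[self.architecture]
        net = ConvNet(conv_specs, fc_hidden, self.input_size, self.n_classes,
                      seed=self.weights_seed)
        if self.pretrained_weights:
            net.load(self.pretrained_weights)
        return net


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
    """Valid convolution of NCHW input with OIkk weights via im2col."""
    k = w.shape[2]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    out = np.einsum("nchwij,ocij->nohw", win, w, optimize=True)
    return out + b[None, :, None, None]


class ConvNet:
    """A compact CNN: frozen conv + frozen dense layers, trainable head.

    Layers are named ``conv1..convN`` and ``fc1..fcM`` plus ``head``; the
    last conv layer (``last_conv_name``) is the Grad-CAM source layer and
    is left untouched by head replacement.
    """

    INPUT_MEAN = 0.5  # images are in [0, 1]; centering keeps layers well-scaled

    def __init__(self, conv_specs: Sequence[tuple[int, int, int]],
                 fc_hidden: Sequence[int], input_size: int, n_classes: int,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        self.input_size = int(input_size)
        self.n_classes = int(n_classes)
        self.conv_specs = [tuple(s) for s in conv_specs]
        self.conv_w, self.conv_b = [], []
        c_in, size = 3, self.input_size
        for (c_out, k, stride) in self.conv_specs:
            if size < k:
                raise ValueError("input too small for the conv stack")
            fan_in = c_in * k * k
            self.conv_w.append(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                          (c_out, c_in, k, k)))
            self.conv_b.append(np.zeros(c_out))
            size = (size - k) // stride + 1
            c_in = c_out
        self.conv_out_shape = (c_in, size, size)

        # global average pooling between the conv stack and the dense layers:
        # channel energies are position-invariant, and the Grad-CAM gradient
        # is constant per channel (the classical GAP-CAM setting)
        dim = c_in
        self.fc_w, self.fc_b = [], []
        for width in fc_hidden:
            self.fc_w.append(rng.normal(0.0, np.sqrt(2.0 / dim), (width, dim)))
            self.fc_b.append(np.zeros(width))
            dim = width
        self.feature_dim = dim
        self.head_w = rng.normal(0.0, 0.01, (self.n_classes, dim))
        self.head_b = np.zeros(self.n_classes)
        self._calibrate(rng)

    FC_SCALE = 4.0  # dense pre-activation SD target (head-training conditioning)

    def _probe_images(self, rng: np.random.Generator, n_probe: int) -> np.ndarray:
        """Generic smooth chromatic blobs used to calibrate layer scales."""
        from scipy import ndimage

        probes = []
        for _ in range(n_probe):
            img = 0.5 + np.stack(
                [ndimage.gaussian_filter(rng.normal(0, 1, (self.input_size,) * 2),
                                         self.input_size * 0.08)
                 for _ in range(3)], axis=2)
            img *= rng.uniform(0.5, 1.5)
            img += 0.25 * rng.uniform(-1, 1, 3)[None, None, :]
            probes.append(np.clip(img, 0.0, 1.0))
        return np.stack(probes)

    def _calibrate(self, rng: np.random.Generator, n_probe: int = 32):
        """Layer-sequential rescaling of the frozen random weights.

        Seeded smooth-image probes are run through the stack; each conv
        layer is rescaled (scale only) to unit pre-activation SD — conv
        biases stay zero, so a mean-gray background yields zero activations
        and stays silent — and each dense layer is standardized per unit
        with SD target ``FC_SCALE``, which conditions the fixed-recipe head
        training.  The rescaled weights are part of the seeded frozen
        backbone (an LSUV-style initialization).
        """
        probe = self._probe_images(rng, n_probe)
        x = np.transpose(probe - self.INPUT_MEAN, (0, 3, 1, 2))
        for i, (w, b, (c_out, k, stride)) in enumerate(
                zip(self.conv_w, self.conv_b, self.conv_specs)):
            z = _conv2d(x, w, b, stride)
            sd = max(z.std(), 1e-8)
            self.conv_w[i] = w / sd
            x = np.maximum(z / sd, 0.0)
        h = x.mean(axis=(2, 3))
        for i, (w, b) in enumerate(zip(self.fc_w, self.fc_b)):
            z = h @ w.T + b
            mu = z.mean(axis=0)
            sd = np.maximum(z.std(axis=0), 1e-8) / self.FC_SCALE
            self.fc_w[i] = w / sd[:, None]
            self.fc_b[i] = (b - mu) / sd
            h = np.maximum((z - mu) / sd, 0.0)

    # -- structure ---------------------------------------------------------
    @property
    def last_conv_name(self) -> str:
        return f"conv{len(self.conv_w)}"

    def copy_with_head(self, head_w: np.ndarray, head_b: np.ndarray) -> "ConvNet":
        """Shallow copy sharing the frozen stack but with its own head."""
        net = object.__new__(ConvNet)
        net.__dict__.update(self.__dict__)
        net.head_w = head_w.copy()
        net.head_b = head_b.copy()
        return net

    def replace_head(self, rng: np.random.Generator, n_classes: Optional[int] = None):
        """Re-initialize the classification head (the replaced layer)."""
        if n_classes is not None:
            self.n_classes = int(n_classes)
        self.head_w = rng.normal(0.0, 0.01, (self.n_classes, self.feature_dim))
        self.head_b = np.zeros(self.n_classes)

    def frozen_checksum(self) -> str:
        """Digest of every frozen (non-head) parameter, for freeze contracts."""
        h = hashlib.sha256()
        for arr in (*self.conv_w, *self.conv_b, *self.fc_w, *self.fc_b):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def save(self, path: str):
        arrays = {}
        for i, (w, b) in enumerate(zip(self.conv_w, self.conv_b)):
            arrays[f"conv{i}_w"], arrays[f"conv{i}_b"] = w, b
        for i, (w, b) in enumerate(zip(self.fc_w, self.fc_b)):
            arrays[f"fc{i}_w"], arrays[f"fc{i}_b"] = w, b
        arrays["head_w"], arrays["head_b"] = self.head_w, self.head_b
        np.savez(path, **arrays)

    def load(self, path: str):
        data = np.load(path)
        for i in range(len(self.conv_w)):
            self.conv_w[i] = data[f"conv{i}_w"]
            self.conv_b[i] = data[f"conv{i}_b"]
        for i in range(len(self.fc_w)):
            self.fc_w[i] = data[f"fc{i}_w"]
            self.fc_b[i] = data[f"fc{i}_b"]
        self.head_w, self.head_b = data["head_w"], data["head_b"]

    # -- forward -----------------------------------------------------------
    def conv_forward(self, images: np.ndarray) -> np.ndarray:
        """NHWC [0,1] images -> last-conv ReLU activations (N, C, h, w)."""
        x = np.transpose(np.asarray(images, dtype=np.float64) - self.INPUT_MEAN,
                         (0, 3, 1, 2))
        for w, b, (c_out, k, stride) in zip(self.conv_w, self.conv_b, self.conv_specs):
            x = np.maximum(_conv2d(x, w, b, stride), 0.0)
        return x

    def frozen_features(self, conv_act: np.ndarray) -> np.ndarray:
        """Average-pool last-conv activations, then the frozen dense layers."""
        h = conv_act.mean(axis=(2, 3))
        for w, b in zip(self.fc_w, self.fc_b):
            h = np.maximum(h @ w.T + b, 0.0)
        return h

    def head_logits(self, features: np.ndarray) -> np.ndarray:
        return features @ self.head_w.T + self.head_b

    def logits_from_conv(self, conv_act: np.ndarray) -> np.ndarray:
        return self.head_logits(self.frozen_features(conv_act))

    def forward(self, images: np.ndarray) -> np.ndarray:
        return self.logits_from_conv(self.conv_forward(images))

    # -- analytic gradient for Grad-CAM ------------------------------------
    def grad_wrt_last_conv(self, conv_act: np.ndarray, class_idx: np.ndarray,
                           target: str = "logit") -> np.ndarray:
        """d(target of the given class)/d(last-conv activations), per sample.

        ``target="logit"`` uses the pre-softmax class score (the default,
        invariant to a constant shift of all logits); ``"probability"``
        uses the softmax output.
        """
        n = conv_act.shape[0]
        class_idx = np.atleast_1d(np.asarray(class_idx, dtype=int))
        if class_idx.shape[0] == 1 and n > 1:
            class_idx = np.repeat(class_idx, n)

        # Re-run the dense stack, keeping pre-activations for the backward pass.
        h = conv_act.mean(axis=(2, 3))
        pre = []
        for w, b in zip(self.fc_w, self.fc_b):
            z = h @ w.T + b
            pre.append(z)
            h = np.maximum(z, 0.0)

        if target == "logit":
            g = self.head_w[class_idx]                       # (n, feature_dim)
        elif target == "probability":
            logits = self.head_logits(h)
            logits = logits - logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            pc = p[np.arange(n), class_idx][:, None]
            dlogits = -p * pc
            dlogits[np.arange(n), class_idx] += pc[:, 0]
            g = dlogits @ self.head_w
        else:
            raise ValueError("target must be 'logit' or 'probability'")

        for w, z in zip(reversed(self.fc_w), reversed(pre)):
            g = (g * (z > 0)) @ w
        # backward through the average pool: gradient is uniform per channel
        _, _, hh, ww = conv_act.shape
        return np.broadcast_to(g[:, :, None, None] / (hh * ww),
                               conv_act.shape).copy()


@dataclass(frozen=True)
class TrainingConfig:
    """Fine-tuning hyperparameters (see module docstring for the recipe)."""

    momentum: float = 0.9
    batch_size: int = 42
    learn_rate: float = 1e-4
    head_lr_factor: float = 20.0
    max_epochs: int = 30
    validation_patience: int = 5
    augmentation: str = "none"
    val_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs > 0 and self.validation_patience > self.max_epochs:
            raise ValueError("validation_patience must not exceed max_epochs")
        if self.augmentation != "none":
            raise ValueError("augmentation must be 'none' to match the recipe")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class ModelRun:
    """One fine-tuned model plus its split, history and (later) accuracy."""

    run_id: str
    mode: str
    ratio_percent: int
    seed: int
    model: ConvNet
    classes: list[str]
    train_ids: list[str]
    val_ids: list[str]
    best_epoch: int
    history: pd.DataFrame
    val_accuracy: float
    accuracy: Optional[float] = None          # filled by evaluate_accuracy (%)
    per_image: Optional[pd.DataFrame] = None


def _softmax_ce(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and dL/dlogits for integer labels."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.mean(np.log(np.clip(p[np.arange(n), y], 1e-12, None)))
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, g / n


def _stratified_split(labels: pd.Series, val_fraction: float,
                      rng: np.random.Generator):
    """Category-stratified train/validation split of image ids."""
    train_ids, val_ids = [], []
    for cat, group in labels.groupby(labels):
        ids = list(group.index)
        rng.shuffle(ids)
        n_val = int(round(val_fraction * len(ids)))
        n_val = min(n_val, len(ids) - 1)  # keep every class in training
        val_ids.extend(ids[:n_val])
        train_ids.extend(ids[n_val:])
    return sorted(train_ids), sorted(val_ids)


def compute_features(model: ConvNet, pixels_by_id: Mapping[str, np.ndarray]):
    """Frozen-stack features for a set of images, keyed by image id.

    Returns (conv activations dict, dense features dict); computing these
    once per dataset makes repeated fine-tuning runs cheap.
    """
    ids = list(pixels_by_id)
    batch = np.stack([pixels_by_id[i] for i in ids])
    conv = model.conv_forward(batch)
    feats = model.frozen_features(conv)
    return ({i: conv[k] for k, i in enumerate(ids)},
            {i: feats[k] for k, i in enumerate(ids)})


def fine_tune(model: ConvNet, train_set, config: TrainingConfig,
              run_id: str = "run0", mode: Optional[str] = None,
              features: Optional[Mapping[str, np.ndarray]] = None) -> ModelRun:
    """Train a fresh classification head on a dataset, frozen stack untouched.

    ``train_set`` is a :class:`~gazecam.spotlight.TrainingSet`.  Training
    stops at ``max_epochs`` or when validation loss has not improved for
    ``validation_patience`` consecutive epochs; the best-validation head is
    kept.  ``features`` may carry precomputed frozen dense features for the
    dataset's image ids (they are validated to match the dataset).
    """
    labels = train_set.labels
    classes = sorted(labels.unique())
    class_to_idx = {c: i for i, c in enumerate(classes)}
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF]))

    if features is None:
        _, features = compute_features(model, train_set.images)
    missing = [i for i in labels.index if i not in features]
    if missing:
        raise ValueError(f"missing features for {len(missing)} images")

    train_ids, val_ids = _stratified_split(labels, config.val_fraction, rng)
    train_cats = set(labels.loc[train_ids])
    if train_cats != set(classes):
        raise ValueError("every class must appear in the training split")

    x_tr = np.stack([features[i] for i in train_ids])
    y_tr = np.array([class_to_idx[labels[i]] for i in train_ids])
    x_va = np.stack([features[i] for i in val_ids])
    y_va = np.array([class_to_idx[labels[i]] for i in val_ids])

    net = model.copy_with_head(model.head_w, model.head_b)
    net.replace_head(rng, n_classes=len(classes))
    lr = config.learn_rate * config.head_lr_factor
    vw = np.zeros_like(net.head_w)
    vb = np.zeros_like(net.head_b)

    def val_metrics():
        logits = net.head_logits(x_va)
        loss, _ = _softmax_ce(logits, y_va)
        acc = float(np.mean(logits.argmax(axis=1) == y_va))
        return loss, acc

    best = {"loss": np.inf, "w": net.head_w.copy(), "b": net.head_b.copy(),
            "epoch": 0}
    history = []
    since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_ids))
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net.head_logits(x_tr[idx])
            loss, dlogits = _softmax_ce(logits, y_tr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            gw = dlogits.T @ x_tr[idx]
            gb = dlogits.sum(axis=0)
            vw = config.momentum * vw - lr * gw
            vb = config.momentum * vb - lr * gb
            net.head_w += vw
            net.head_b += vb
            epoch_loss += loss * len(idx)
        vloss, vacc = val_metrics()
        history.append({"epoch": epoch, "train_loss": epoch_loss / len(train_ids),
                        "val_loss": vloss, "val_accuracy": vacc})
        if vloss < best["loss"] - 1e-12:
            best = {"loss": vloss, "w": net.head_w.copy(), "b": net.head_b.copy(),
                    "epoch": epoch}
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.validation_patience:
                break

    if config.max_epochs > 0:
        net.head_w, net.head_b = best["w"], best["b"]
    vloss, vacc = val_metrics()
    return ModelRun(
        run_id=run_id,
        mode=mode if mode is not None else getattr(train_set, "mode", "STD"),
        ratio_percent=getattr(train_set, "ratio_percent", 0),
        seed=config.seed,
        model=net,
        classes=classes,
        train_ids=list(train_ids),
        val_ids=list(val_ids),
        best_epoch=best["epoch"],
        history=pd.DataFrame(history),
        val_accuracy=vacc,
    )


@dataclass
class AccuracyReport:
    """Top-1 accuracy (in %) overall and by group, plus the confusion matrix."""

    overall: float
    per_category: pd.Series
    per_animacy: pd.Series
    per_face: pd.Series
    confusion: pd.DataFrame
    per_image: pd.DataFrame


def evaluate_accuracy(run: ModelRun, test_images: Sequence[StimulusImage],
                      conv_act: Optional[Mapping[str, np.ndarray]] = None) -> AccuracyReport:
    """Evaluate a run on held-out images; refuses train/test overlap.

    ``conv_act`` may carry precomputed last-conv activations keyed by
    image id (shared across runs with a common frozen backbone).
    """
    seen = set(run.train_ids) | set(run.val_ids)
    overlap = seen & {im.image_id for im in test_images}
    if overlap:
        raise ValueError(f"{len(overlap)} test images were used in training")
    unknown = {im.category for im in test_images} - set(run.classes)
    if unknown:
        raise ValueError(f"unknown labels in test manifest: {sorted(unknown)}")

    if conv_act is not None:
        acts = np.stack([conv_act[im.image_id] for im in test_images])
    else:
        acts = run.model.conv_forward(np.stack([im.pixels for im in test_images]))
    logits = run.model.logits_from_conv(acts)
    pred_idx = logits.argmax(axis=1)
    pred = [run.classes[i] for i in pred_idx]

    rows = pd.DataFrame({
        "image_id": [im.image_id for im in test_images],
        "category": [im.category for im in test_images],
        "animate": [im.animate for im in test_images],
        "has_face": [im.has_face for im in test_images],
        "predicted": pred,
    })
    rows["correct"] = rows["predicted"] == rows["category"]

    confusion = pd.crosstab(rows["category"], rows["predicted"],
                            dropna=False).reindex(index=run.classes,
                                                  columns=run.classes,
                                                  fill_value=0)
    report = AccuracyReport(
        overall=float(rows["correct"].mean() * 100.0),
        per_category=rows.groupby("category")["correct"].mean() * 100.0,
        per_animacy=rows.groupby("animate")["correct"].mean() * 100.0,
        per_face=rows.groupby("has_face")["correct"].mean() * 100.0,
        confusion=confusion,
        per_image=rows,
    )
    run.accuracy = report.overall
    run.per_image = rows
    return report


def derived_seed(master_seed: int, k: int) -> int:
    """Run-k seed derived from a master seed (stable, below 2**31)."""
    return int(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, k])
               .generate_state(1)[0] & 0x7FFFFFFF)


def repeat_runs(model: ConvNet,
                dataset_builder: Union[Callable[[int], object], object],
                config: TrainingConfig, n_runs: int,
                mode: Optional[str] = None,
                features: Optional[Mapping[str, np.ndarray]] = None) -> list[ModelRun]:
    """Fine-tune ``n_runs`` times with derived seeds (init + split shuffles).

    ``dataset_builder`` is either a fixed TrainingSet or a callable mapping
    the run index to one.  The reference analysis uses 23 runs per
    condition and 10 per ratio in the trade-off sweep.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs = []
    for k in range(n_runs):
        ts = dataset_builder(k) if callable(dataset_builder) else dataset_builder
        cfg = TrainingConfig(**{**config.__dict__, "seed": derived_seed(config.seed, k)})
        runs.append(fine_tune(model, ts, cfg, run_id=f"run{k:02d}", mode=mode,
                              features=features))
    return runs


def summarize_runs(runs: Sequence[ModelRun]) -> pd.DataFrame:
    """Mean/SD of evaluated accuracy per (mode, ratio) over runs."""
    rows = [{"mode": r.mode, "ratio_percent": r.ratio_percent,
             "run_id": r.run_id, "accuracy": r.accuracy} for r in runs]
    df = pd.DataFrame(rows)
    return (df.groupby(["mode", "ratio_percent"])["accuracy"]
              .agg(["mean", "std", "count"]).reset_index())
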