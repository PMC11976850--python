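"""Peak-selection segmentation and confidence scoring.

A precursor activation image is turned into a fixed-size multi-channel
network input: channel 1 the min-max-scaled activation, channel 2 the
min-max-scaled log10(activation + 1), channel 3 a hint channel carrying +1
at the candidate's predicted (RT, 1/K0) pixel and -1 at each isobaric
competitor's predicted pixel (values add where hints coincide).  The
scoring model receives a fourth channel: the segmentation output.

The segmentation network is a UNet (contracting/expansive paths of conv +
batch-norm + ReLU blocks with skip connections) trained with a combo loss
(1 x BCE + 4 x dice + 1 x focal); the scorer reuses the encoder followed by
adaptive average pooling and a linear head, trained with binary
cross-entropy on target-vs-decoy labels.  Both use Adam with a one-cycle
learning-rate schedule, an 8:1:1 seeded split and early stopping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from . import _nn
from .activation import PrecursorImage
from .config import RunConfig

logger = logging.getLogger("swaps")


# ------------------------------------------------------- coordinate maps


def _fractional_index(coords: np.ndarray, value: float) -> float:
    """Physical coordinate -> fractional native index (clipped to range)."""
    if len(coords) == 1:
        return 0.0
    return float(np.interp(value, coords, np.arange(len(coords))))


def _resized_axis_positions(n_native: int, size: int) -> np.ndarray:
    """Fractional native index of each resized pixel (align-corners map)."""
    if n_native == 1 or size == 1:
        return np.zeros(size)
    return np.arange(size) * (n_native - 1) / (size - 1)


def _bilinear_resize(mat: np.ndarray, size: int) -> np.ndarray:
    m, n = mat.shape
    fi = _resized_axis_positions(m, size)
    fj = _resized_axis_positions(n, size)
    i0 = np.clip(np.floor(fi).astype(int), 0, max(m - 2, 0))
    j0 = np.clip(np.floor(fj).astype(int), 0, max(n - 2, 0))
    di = (fi - i0)[:, None]
    dj = (fj - j0)[None, :]
    i1 = np.minimum(i0 + 1, m - 1)
    j1 = np.minimum(j0 + 1, n - 1)
    return (mat[np.ix_(i0, j0)] * (1 - di) * (1 - dj)
            + mat[np.ix_(i1, j0)] * di * (1 - dj)
            + mat[np.ix_(i0, j1)] * (1 - di) * dj
            + mat[np.ix_(i1, j1)] * di * dj)


def _minmax(mat: np.ndarray) -> np.ndarray:
    lo, hi = float(mat.min()), float(mat.max())
    if hi <= lo:
        return np.zeros_like(mat)
    return (mat - lo) / (hi - lo)


def hint_pixel(image: PrecursorImage, rt: float, im: float, size: int) -> tuple[int, int]:
    """Map a physical (RT, 1/K0) hint to its nearest resized pixel.

    Hints outside the crop clip to the border pixel.
    """
    m, n = image.matrix.shape
    fi = _fractional_index(image.rt_coords, rt)
    fj = _fractional_index(image.im_coords, im)
    u = int(round(fi * (size - 1) / max(m - 1, 1))) if m > 1 else (size - 1) // 2
    v = int(round(fj * (size - 1) / max(n - 1, 1))) if n > 1 else (size - 1) // 2
    return min(max(u, 0), size - 1), min(max(v, 0), size - 1)


@dataclass
class ModelInput:
    """Fixed-size network input for one candidate."""

    channels: np.ndarray   # (3 or 4, size, size)
    candidate_id: int = -1

    @property
    def size(self) -> int:
        return self.channels.shape[-1]


def build_model_input(
    image: PrecursorImage,
    target_hint: tuple[float, float],
    competitor_hints: Sequence[tuple[float, float]] = (),
    seg_output: np.ndarray | None = None,
    image_size: int = 258,
) -> ModelInput:
    """Assemble the (3 or 4)-channel input for one activation image.

    Channels 1-2 are scaled per image; a constant image scales to all
    zeros.  Hints are placed directly on the resized grid (never
    resampled), +1 for the target and -1 per competitor, summed where they
    collide.
    """
    act = _bilinear_resize(image.matrix, image_size)
    ch1 = _minmax(act)
    ch2 = _minmax(np.log10(act + 1.0))
    ch3 = np.zeros((image_size, image_size))
    u, v = hint_pixel(image, *target_hint, image_size)
    ch3[u, v] += 1.0
    for hint in competitor_hints:
        u, v = hint_pixel(image, *hint, image_size)
        ch3[u, v] -= 1.0
    channels = [ch1, ch2, ch3]
    if seg_output is not None:
        channels.append(np.asarray(seg_output, dtype=float))
    return ModelInput(np.stack(channels), candidate_id=image.candidate_id)


@dataclass
class LabelRect:
    """Ground-truth peak rectangle in physical coordinates."""

    rt_start: float
    rt_end: float
    im_lo: float
    im_hi: float

    def __post_init__(self) -> None:
        if self.rt_start > self.rt_end or self.im_lo > self.im_hi:
            raise ValueError("degenerate label rectangle")


@dataclass
class SegmentationMask:
    """Binary peak mask at resized and native resolution."""

    resized: np.ndarray          # (size, size) bool
    native: np.ndarray           # (m_p, n_p) bool
    provenance: str = "predicted"  # "predicted" | "label"


def rasterize_label(rect: LabelRect, image: PrecursorImage, image_size: int = 258) -> SegmentationMask:
    """Render a label rectangle directly on the resized grid: a pixel is on
    iff its (RT, 1/K0) center lies inside the rectangle."""
    m, n = image.matrix.shape
    fi = _resized_axis_positions(m, image_size)
    fj = _resized_axis_positions(n, image_size)
    rt_centers = np.interp(fi, np.arange(m), image.rt_coords)
    im_centers = np.interp(fj, np.arange(n), image.im_coords)
    row_in = (rt_centers >= rect.rt_start) & (rt_centers <= rect.rt_end)
    col_in = (im_centers >= rect.im_lo) & (im_centers <= rect.im_hi)
    resized = row_in[:, None] & col_in[None, :]
    if not resized.any():
        logger.warning("label rectangle disjoint from crop of candidate %d", image.candidate_id)
    native = project_mask_to_native(resized, (m, n))
    return SegmentationMask(resized=resized, native=native, provenance="label")


def project_mask_to_native(resized: np.ndarray, native_shape: tuple[int, int]) -> np.ndarray:
    """Map a resized binary mask back to native resolution.

    Each resized pixel is assigned to its nearest native pixel; a native
    pixel is on iff at least half of its assigned resized pixels are on
    (majority-area rule).  Native pixels receiving no resized pixel sample
    the nearest resized pixel instead.
    """
    size = resized.shape[0]
    m, n = native_shape

    def axis_assign(n_native: int):
        fu = _resized_axis_positions(n_native, size)
        return np.round(fu).astype(int)

    rows = axis_assign(m)
    cols = axis_assign(n)
    sums = np.zeros((m, n))
    counts = np.zeros((m, n))
    np.add.at(sums, (rows[:, None], cols[None, :]), resized.astype(float))
    np.add.at(counts, (rows[:, None], cols[None, :]), 1.0)
    native = np.zeros((m, n), dtype=bool)
    filled = counts > 0
    native[filled] = (sums[filled] / counts[filled]) >= 0.5
    if not filled.all():
        # native finer than resized: nearest-pixel sampling
        ui = np.round(np.arange(m) * (size - 1) / max(m - 1, 1)).astype(int)
        vj = np.round(np.arange(n) * (size - 1) / max(n - 1, 1)).astype(int)
        sampled = resized[np.ix_(ui, vj)]
        native[~filled] = sampled[~filled]
    return native


def weighted_iou(mask_pred: np.ndarray, mask_true: np.ndarray,
                 intensity_image: np.ndarray) -> float:
    """Intensity-weighted intersection-over-union of two binary masks.

    Sum of intensity over (pred AND true) divided by the sum over
    (pred OR true); 0 when the union carries no intensity.  Symmetric,
    bounded in [0, 1], equal to plain IoU for uniform intensity.
    """
    mask_pred = np.asarray(mask_pred, dtype=bool)
    mask_true = np.asarray(mask_true, dtype=bool)
    intensity = np.asarray(intensity_image, dtype=float)
    if mask_pred.shape != mask_true.shape or mask_pred.shape != intensity.shape:
        raise ValueError("mask/intensity shapes differ")
    union = intensity[mask_pred | mask_true].sum()
    if union <= 0:
        return 0.0
    return float(intensity[mask_pred & mask_true].sum() / union)


def evaluate_scorer(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based ROC AUC with ties averaged; requires both classes."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------- training


@dataclass
class TrainReport:
    epochs_run: int
    best_val_metric: float
    split_sizes: tuple[int, int, int]
    seed: int
    loss_curve: list[float] = field(default_factory=list)
    val_curve: list[float] = field(default_factory=list)


def _split_indices(n: int, split: tuple[float, float, float], rng: np.random.Generator):
    idx = rng.permutation(n)
    n_train = int(round(n * split[0]))
    n_val = int(round(n * split[1]))
    return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]


def _snapshot(params: list[np.ndarray]) -> list[np.ndarray]:
    return [p.copy() for p in params]


def _restore(params: list[np.ndarray], snap: list[np.ndarray]) -> None:
    for p, s in zip(params, snap):
        p[...] = s


def train_segmentation(
    pool: Sequence[tuple[ModelInput, np.ndarray]],
    config: RunConfig,
) -> tuple[_nn.UNet, TrainReport]:
    """Train the peak-selection UNet on (input, label-mask) pairs.

    The pool must come from candidates with known label rectangles (the
    experiment library and its decoys).  Deterministic given
    ``config.random_seed``.
    """
    if len(pool) < 10:
        raise ValueError("segmentation training needs at least 10 items")
    seed = config.sub_seed("train_segmentation")
    rng = np.random.default_rng(seed)
    model = _nn.UNet(c_in=3, base=config.unet_base_channels,
                     depth=config.unet_depth, rng=rng)
    x = np.stack([p[0].channels for p in pool])
    y = np.stack([np.asarray(p[1], dtype=float) for p in pool])
    tr, va, te = _split_indices(len(pool), config.split, rng)
    opt = _nn.Adam(model.params, model.grads, lr=config.max_learning_rate)
    steps_per_epoch = max(1, int(np.ceil(len(tr) / config.batch_size)))
    total_steps = steps_per_epoch * config.epochs

    def val_metric() -> float:
        # weighted IoU over validation items with a nonempty label (a
        # zero-intensity union is defined as 0, so empty-label decoy
        # images would only dilute the metric)
        ious = []
        for i in va:
            if not (y[i] >= 0.5).any():
                continue
            prob = _nn.sigmoid(model.forward(x[i][None]))[0]
            pred = prob >= config.mask_probability_threshold
            ious.append(weighted_iou(pred, y[i] >= 0.5, x[i][0]))
        return float(np.mean(ious)) if ious else 0.0

    report = TrainReport(0, -np.inf, (len(tr), len(va), len(te)), seed)
    best_snap = _snapshot(model.state)
    best_metric, since_best = -np.inf, 0
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(tr)
        epoch_loss = 0.0
        for k in range(0, len(order), config.batch_size):
            batch = order[k:k + config.batch_size]
            opt.zero_grad()
            opt.lr = _nn.one_cycle_lr(step, total_steps, config.max_learning_rate)
            z = model.forward(x[batch], train=True)
            loss, dz = _nn.combo_loss(z, y[batch], config.loss_weights)
            model.backward(dz)
            opt.step()
            epoch_loss += loss * len(batch)
            step += 1
        report.loss_curve.append(epoch_loss / len(tr))
        metric = val_metric()
        report.val_curve.append(metric)
        report.epochs_run = epoch + 1
        if metric > best_metric + 1e-6:
            best_metric, since_best = metric, 0
            best_snap = _snapshot(model.state)
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    _restore(model.state, best_snap)
    report.best_val_metric = best_metric
    logger.info("stage=train_segmentation pool=%d epochs=%d best_val_wiou=%.3f",
                len(pool), report.epochs_run, best_metric)
    return model, report


def predict_mask_and_intensity(
    model: _nn.UNet,
    model_input: ModelInput,
    image: PrecursorImage,
    threshold: float = 0.5,
) -> tuple[SegmentationMask, float]:
    """Apply the segmentation model and sum native activation over the
    predicted peak pixels."""
    prob = _nn.sigmoid(model.forward(model_input.channels[:3][None]))[0]
    resized = prob >= threshold
    native = project_mask_to_native(resized, image.matrix.shape)
    intensity = float(image.matrix[native].sum())
    return SegmentationMask(resized=resized, native=native, provenance="predicted"), intensity


def segmentation_probability(model: _nn.UNet, model_input: ModelInput) -> np.ndarray:
    """Raw probability map (the scorer's fourth channel)."""
    return _nn.sigmoid(model.forward(model_input.channels[:3][None]))[0]


def train_scorer(
    pool: Sequence[tuple[ModelInput, int]],
    config: RunConfig,
) -> tuple[_nn.EncoderClassifier, TrainReport]:
    """Train the confidence scorer on 4-channel inputs labelled
    target (1) / decoy (0).  sigmoid(logit) is the confidence score."""
    labels = np.array([int(p[1]) for p in pool])
    if len(np.unique(labels)) < 2:
        raise ValueError("scorer training needs both targets and decoys")
    seed = config.sub_seed("train_scorer")
    rng = np.random.default_rng(seed)
    model = _nn.EncoderClassifier(c_in=4, base=config.unet_base_channels,
                                  depth=config.unet_depth, rng=rng)
    x = np.stack([p[0].channels for p in pool])
    y = labels.astype(float)
    tr, va, te = _split_indices(len(pool), config.split, rng)
    opt = _nn.Adam(model.params, model.grads, lr=config.max_learning_rate)
    steps_per_epoch = max(1, int(np.ceil(len(tr) / config.batch_size)))
    total_steps = steps_per_epoch * config.epochs

    def val_metric() -> float:
        if len(va) < 2 or len(np.unique(y[va])) < 2:
            return 0.0
        scores = [float(_nn.sigmoid(model.forward(x[i][None]))[0]) for i in va]
        return evaluate_scorer(scores, y[va].astype(int))

    report = TrainReport(0, -np.inf, (len(tr), len(va), len(te)), seed)
    best_snap = _snapshot(model.state)
    best_metric, since_best = -np.inf, 0
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(tr)
        epoch_loss = 0.0
        for k in range(0, len(order), config.batch_size):
            batch = order[k:k + config.batch_size]
            opt.zero_grad()
            opt.lr = _nn.one_cycle_lr(step, total_steps, config.max_learning_rate)
            z = model.forward(x[batch], train=True)
            loss, dz = _nn.bce_with_logits(z, y[batch])
            model.backward(dz)
            opt.step()
            epoch_loss += loss * len(batch)
            step += 1
        report.loss_curve.append(epoch_loss / len(tr))
        metric = val_metric()
        report.val_curve.append(metric)
        report.epochs_run = epoch + 1
        if metric > best_metric + 1e-6:
            best_metric, since_best = metric, 0
            best_snap = _snapshot(model.state)
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    _restore(model.state, best_snap)
    report.best_val_metric = best_metric
    logger.info("stage=train_scorer pool=%d epochs=%d best_val_auc=%.3f",
                len(pool), report.epochs_run, best_metric)
    return model, report


def confidence_score(model: _nn.EncoderClassifier, model_input: ModelInput) -> float:
    return float(_nn.sigmoid(np.atleast_1d(model.forward(model_input.channels[None]))[0]))
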