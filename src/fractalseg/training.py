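"""Pretext pretraining and segmentation fine-tuning.

The experimental protocol: patient-level fourfold cross-validation (each fold
63 training / 15 validation / 26 test cases for a 104-case cohort), on-the-fly
augmentation of the 64 x 64 ROI pairs, Adam with batch size 8 for up to 50
epochs under a linear learning-rate warm-up (2e-5 at epoch 1 rising to 1e-4 by
epoch 5, then constant), and selection of the epoch with the lowest validation
loss.  The validation set is used only for that epoch selection, never for
hyperparameter tuning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import exposure, transform as sktransform
from skimage.color import hsv2rgb, rgb2hsv

from . import nn
from .fractaldb import load_batches
from .roi import CaseROIs, resize_nearest

__all__ = ["FoldSplit", "ScheduleConfig", "AugmentationPolicy", "ModelSpec",
           "make_folds", "warmup_lr", "augment_pair", "pretext_train",
           "finetune", "select_best_epoch", "predict_mask", "FinetuneResult"]


# ---------------------------------------------------------------------------
# folds


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        all_ids = self.train_ids + self.val_ids + self.test_ids
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("fold subsets overlap")


def make_folds(
    case_ids: list[str],
    k: int = 4,
    sizes: tuple[int, int, int] = (63, 15, 26),
    seed: int = 0,
) -> list[FoldSplit]:
    """Patient-level k-fold splits with disjoint, exhaustive test sets.

    The cohort is shuffled once, cut into k equal test blocks; each fold's
    remaining cases are re-shuffled into train and validation of the requested
    sizes.  Everything is deterministic under ``seed``.
    """
    n = len(case_ids)
    n_train, n_val, n_test = sizes
    if n_train + n_val + n_test != n:
        raise ValueError(f"sizes {sizes} do not sum to cohort size {n}")
    if k * n_test != n:
        raise ValueError(
            f"cohort of {n} does not divide into {k} test sets of {n_test} "
            f"(remainder {n - k * n_test})"
        )
    rng = np.random.default_rng(seed)
    order = [case_ids[i] for i in rng.permutation(n)]
    folds = []
    for f in range(k):
        test = order[f * n_test : (f + 1) * n_test]
        rest = [c for c in order if c not in test]
        sub = rng.permutation(len(rest))
        train = [rest[i] for i in sub[:n_train]]
        val = [rest[i] for i in sub[n_train:]]
        folds.append(FoldSplit(fold_id=f, train_ids=tuple(train),
                               val_ids=tuple(val), test_ids=tuple(test)))
    return folds


# ---------------------------------------------------------------------------
# schedule


@dataclass(frozen=True)
class ScheduleConfig:
    lr_start: float = 2e-5
    lr_target: float = 1e-4
    warmup_end_epoch: int = 5
    max_epochs: int = 50
    batch_size: int = 8
    optimizer_name: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.lr_start < self.lr_target:
            raise ValueError("need lr_start < lr_target")
        if not 1 <= self.warmup_end_epoch <= self.max_epochs:
            raise ValueError("need 1 <= warmup_end_epoch <= max_epochs")


def warmup_lr(epoch: int, sched: ScheduleConfig) -> float:
    """Per-epoch linear warm-up: lr_start at epoch 1, lr_target from the
    warm-up end epoch onward, linear interpolation between."""
    if epoch < 1:
        raise ValueError("epochs are 1-based")
    if epoch >= sched.warmup_end_epoch:
        return sched.lr_target
    frac = (epoch - 1) / (sched.warmup_end_epoch - 1)
    return sched.lr_start + frac * (sched.lr_target - sched.lr_start)


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentationPolicy:
    """The on-the-fly augmentation recipe, applied in order with the listed
    firing probabilities.  Geometric transforms hit image and mask identically;
    photometric ones touch the image only, so the mask stays binary."""

    p_hflip: float = 0.5
    p_shift_scale: float = 1.0
    scale_limit: float = 0.5
    shift_limit: float = 0.1
    rotate_limit: float = 0.0
    p_gauss_noise: float = 0.2
    noise_sd_range: tuple[float, float] = (0.02, 0.07)
    p_perspective: float = 0.5
    perspective_scale: tuple[float, float] = (0.05, 0.10)
    p_contrast_group: float = 0.9  # one of: CLAHE, brightness/contrast, gamma
    p_sharpen_group: float = 0.9   # one of: sharpen, blur, motion blur
    blur_limit: int = 3
    p_color_group: float = 0.9     # one of: brightness/contrast, hue/saturation/value


def _shift_scale_rotate(img, msk, rng, policy):
    scale = 1.0 + rng.uniform(-policy.scale_limit, policy.scale_limit)
    shift_r = rng.uniform(-policy.shift_limit, policy.shift_limit) * img.shape[0]
    shift_c = rng.uniform(-policy.shift_limit, policy.shift_limit) * img.shape[1]
    angle = np.deg2rad(rng.uniform(-policy.rotate_limit, policy.rotate_limit))
    center = (np.asarray(img.shape) - 1) / 2.0
    cos, sin = math.cos(angle), math.sin(angle)
    lin = np.array([[cos, -sin], [sin, cos]]) / scale
    offset = center - lin @ (center + np.array([shift_r, shift_c]))
    img2 = ndimage.affine_transform(img, lin, offset=offset, order=1,
                                    mode="constant", cval=float(img.min()))
    msk2 = ndimage.affine_transform(msk.astype(np.float64), lin, offset=offset,
                                    order=0, mode="constant", cval=0.0)
    return img2, msk2.astype(np.uint8)


def _perspective(img, msk, rng, policy):
    side = img.shape[0]
    jitter = rng.uniform(*policy.perspective_scale) * side
    src = np.array([[0, 0], [side - 1, 0], [side - 1, side - 1], [0, side - 1]],
                   dtype=float)
    dst = src + rng.uniform(-jitter, jitter, size=(4, 2))
    tform = sktransform.ProjectiveTransform.from_estimate(dst, src)
    if not tform:
        return img, msk
    img2 = sktransform.warp(img, tform, order=1, mode="constant",
                            cval=float(img.min()), preserve_range=True)
    msk2 = sktransform.warp(msk.astype(float), tform, order=0, mode="constant",
                            cval=0.0, preserve_range=True)
    return img2, msk2.astype(np.uint8)


def _contrast_op(img, rng):
    which = rng.integers(3)
    if which == 0:  # CLAHE on the [0, 1] image
        return exposure.equalize_adapthist(np.clip(img, 0, 1), kernel_size=16)
    if which == 1:  # random brightness/contrast
        alpha = 1.0 + rng.uniform(-0.2, 0.2)
        beta = rng.uniform(-0.2, 0.2)
        return np.clip(alpha * (img - 0.5) + 0.5 + beta, 0, 1)
    gamma = np.exp(rng.uniform(np.log(0.8), np.log(1.25)))
    return np.clip(img, 0, 1) ** gamma


def _sharpen_blur_op(img, rng, blur_limit):
    which = rng.integers(3)
    if which == 0:  # unsharp sharpen
        blurred = ndimage.gaussian_filter(img, sigma=1.0)
        amount = rng.uniform(0.2, 0.5)
        return np.clip(img + amount * (img - blurred), 0, 1)
    if which == 1:  # box blur, kernel size <= blur_limit
        k = int(rng.integers(3, blur_limit + 1))
        return ndimage.uniform_filter(img, size=k)
    # motion blur: 1D kernel along a random axis
    k = max(blur_limit, 3)
    axis = int(rng.integers(2))
    size = (1, k) if axis else (k, 1)
    return ndimage.uniform_filter(img, size=size)


def _color_op(img, rng):
    which = rng.integers(2)
    if which == 0:
        alpha = 1.0 + rng.uniform(-0.2, 0.2)
        beta = rng.uniform(-0.2, 0.2)
        return np.clip(alpha * (img - 0.5) + 0.5 + beta, 0, 1)
    # hue/saturation/value on the grayscale image replicated to 3 channels
    rgb = np.repeat(np.clip(img, 0, 1)[..., None], 3, axis=-1)
    hsv = rgb2hsv(rgb)
    hsv[..., 0] = np.mod(hsv[..., 0] + rng.uniform(-0.05, 0.05), 1.0)
    hsv[..., 1] = np.clip(hsv[..., 1] + rng.uniform(-0.1, 0.1), 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] + rng.uniform(-0.1, 0.1), 0, 1)
    return hsv2rgb(hsv).mean(axis=-1)


def augment_pair(
    image: np.ndarray,
    mask: np.ndarray,
    policy: AugmentationPolicy,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the policy's transforms in order with their probabilities.

    Images are expected in [0, 1]; masks binary.  Returns the transformed pair;
    the mask changes only when a geometric transform fires.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    img = image.astype(np.float64)
    msk = mask.astype(np.uint8)
    if rng.random() < policy.p_hflip:
        img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()
    if rng.random() < policy.p_shift_scale:
        img, msk = _shift_scale_rotate(img, msk, rng, policy)
    if rng.random() < policy.p_gauss_noise:
        img = img + rng.normal(0, rng.uniform(*policy.noise_sd_range), img.shape)
    if rng.random() < policy.p_perspective:
        img, msk = _perspective(img, msk, rng, policy)
    if rng.random() < policy.p_contrast_group:
        img = _contrast_op(img, rng)
    if rng.random() < policy.p_sharpen_group:
        img = _sharpen_blur_op(img, rng, policy.blur_limit)
    if rng.random() < policy.p_color_group:
        img = _color_op(img, rng)
    return img, msk


# ---------------------------------------------------------------------------
# model spec


@dataclass(frozen=True)
class ModelSpec:
    """What to train: encoder family, input side, and weight initialization.

    ``init_source`` is "scratch", a path to a pretext checkpoint (NPZ), or
    "external:<file>" for an opaque externally pretrained encoder archive.
    """

    encoder_id: str = "small-cnn"
    decoder_id: str = "skip-decoder"
    input_side: int = 64
    init_source: str = "scratch"
    widths: tuple[int, ...] = nn.DEFAULT_WIDTHS
    in_channels: int = 1


def _resolve_init(model: nn.SegNet, spec: ModelSpec) -> None:
    src = spec.init_source
    if src == "scratch":
        return
    path = src.split("external:", 1)[1] if src.startswith("external:") else src
    state, _meta = nn.load_checkpoint(path)
    model.load_encoder_state(state)


# ---------------------------------------------------------------------------
# pretext training


def pretext_train(
    manifest: pd.DataFrame,
    db_dir,
    model_spec: ModelSpec,
    epochs: int,
    seed: int,
    lr: float = 3e-3,
    batch_size: int = 8,
    val_fraction: float = 0.1,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Train the category classifier on pseudo-labels; export encoder weights.

    Returns (encoder state dict, log) where the log has per-epoch training loss
    and held-out pretext accuracy.  A held-out slice of the manifest
    (``val_fraction``, stratified by shuffled order) measures accuracy; with
    ``epochs == 0`` the freshly initialized encoder is returned untouched.
    """
    n_classes = int(manifest["category_id"].max()) + 1
    if manifest["category_id"].nunique() < 2:
        raise ValueError("pretext task needs at least 2 categories")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(manifest))
    n_val = max(1, int(round(val_fraction * len(manifest)))) if len(manifest) > 1 else 0
    val_rows = manifest.iloc[perm[:n_val]].reset_index(drop=True)
    train_rows = manifest.iloc[perm[n_val:]].reset_index(drop=True)
    model = nn.FractalClassifier(n_classes, in_channels=model_spec.in_channels,
                                 widths=model_spec.widths, seed=seed,
                                 input_side=model_spec.input_side)
    opt = nn.Adam(model.params())
    records = []
    for epoch in range(1, epochs + 1):
        losses = []
        shuffle_seed = int(rng.integers(0, 2**31 - 1))
        for images, labels in load_batches(train_rows, db_dir, batch_size,
                                           shuffle_seed=shuffle_seed):
            logits = model.forward(images, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels)
            model.backward(dlogits)
            opt.step(model.grads(), lr)
            losses.append(loss)
        correct = total = 0
        for images, labels in load_batches(val_rows, db_dir, batch_size):
            pred = model.forward(images, train=False).argmax(axis=1)
            correct += int((pred == labels).sum())
            total += len(labels)
        records.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_accuracy": correct / total if total else float("nan")})
    return model.encoder_state(), pd.DataFrame(records)


# ---------------------------------------------------------------------------
# fine-tuning


@dataclass(frozen=True)
class FinetuneResult:
    model: nn.SegNet
    val_losses: tuple[float, ...]  # one per epoch
    lr_trace: tuple[float, ...]
    best_epoch: int
    best_state: dict[str, np.ndarray] = field(repr=False, default=None)


def select_best_epoch(val_losses: list[float]) -> int:
    """1-based index of the minimum validation loss; ties go to the earliest."""
    if len(val_losses) == 0:
        raise ValueError("empty validation-loss list")
    return int(np.argmin(val_losses)) + 1


def _slice_arrays(roi_data: dict[str, CaseROIs], ids) -> tuple[np.ndarray, np.ndarray]:
    imgs, msks = [], []
    for cid in ids:
        cr = roi_data[cid]
        imgs.append(cr.images)
        msks.append(cr.masks)
    return np.concatenate(imgs).astype(np.float32), np.concatenate(msks).astype(np.float32)


def _forward_loss(model, images, masks, side):
    x = images[:, None]
    t = masks[:, None]
    if side != images.shape[1]:
        x = np.stack([resize_nearest(im, side) for im in images])[:, None]
        t = np.stack([resize_nearest(m, side) for m in masks])[:, None]
    logits = model.forward(x, train=False)
    loss, _ = nn.dice_bce_loss(logits, t)
    return loss


def finetune(
    model_spec: ModelSpec,
    fold: FoldSplit,
    roi_data: dict[str, CaseROIs],
    sched: ScheduleConfig = ScheduleConfig(),
    policy: AugmentationPolicy | None = AugmentationPolicy(),
    seed: int = 0,
) -> FinetuneResult:
    """Fine-tune the full segmentation model on one fold.

    All weights train (no freezing).  Each epoch shuffles the training slices,
    augments on the fly, steps Adam at the warm-up learning rate, then records
    the validation loss; the lowest-validation-loss epoch's weights are kept.
    """
    missing = [cid for cid in fold.train_ids + fold.val_ids if cid not in roi_data]
    if missing:
        raise KeyError(f"fold references cases without ROI data: {missing[:5]}")
    tr_imgs, tr_msks = _slice_arrays(roi_data, fold.train_ids)
    if tr_imgs.shape[1] != 64 and model_spec.input_side == 64:
        raise ValueError(f"ROI side {tr_imgs.shape[1]} does not match model input")
    model = nn.SegNet(in_channels=model_spec.in_channels, widths=model_spec.widths,
                      seed=seed)
    _resolve_init(model, model_spec)
    opt = nn.Adam(model.params())
    rng = np.random.default_rng(seed)
    side = model_spec.input_side
    n = len(tr_imgs)
    val_losses: list[float] = []
    lr_trace: list[float] = []
    best_state = model.state()
    best_loss = np.inf
    for epoch in range(1, sched.max_epochs + 1):
        lr = warmup_lr(epoch, sched)
        lr_trace.append(lr)
        order = rng.permutation(n)
        for start in range(0, n, sched.batch_size):
            idx = order[start : start + sched.batch_size]
            batch_i, batch_m = [], []
            for j in idx:
                if policy is not None:
                    im, mk = augment_pair(tr_imgs[j], tr_msks[j], policy, rng)
                else:
                    im, mk = tr_imgs[j], tr_msks[j]
                if side != im.shape[0]:
                    im = resize_nearest(im, side)
                    mk = resize_nearest(mk, side)
                batch_i.append(im)
                batch_m.append(mk)
            x = np.stack(batch_i)[:, None].astype(np.float32)
            t = np.stack(batch_m)[:, None].astype(np.float32)
            logits = model.forward(x, train=True)
            _, dlogits = nn.dice_bce_loss(logits, t)
            model.backward(dlogits)
            opt.step(model.grads(), lr)
        v_imgs, v_msks = _slice_arrays(roi_data, fold.val_ids)
        vloss = _forward_loss(model, v_imgs, v_msks, side)
        val_losses.append(vloss)
        if vloss < best_loss:
            best_loss = vloss
            best_state = model.state()
    best = select_best_epoch(val_losses)
    model.load_state(best_state)
    return FinetuneResult(model=model, val_losses=tuple(val_losses),
                         lr_trace=tuple(lr_trace), best_epoch=best,
                         best_state=best_state)


def predict_mask(model: nn.SegNet, roi_image: np.ndarray,
                 input_side: int = 64, threshold: float = 0.5) -> np.ndarray:
    """Predict a binary 64x64 mask for one ROI image.

    When the model consumes a larger side, the image is nearest-neighbour
    upsampled on the way in and the predicted mask downsampled on the way out.
    Foreground where sigmoid(logit) > threshold.
    """
    native = roi_image.shape[0]
    x = roi_image
    if input_side != native:
        x = resize_nearest(roi_image, input_side)
    logits = model.forward(x[None, None].astype(np.float32), train=False)
    prob = nn.sigmoid(logits[0, 0])
    mask = (prob > threshold).astype(np.uint8)
    if input_side != native:
        mask = resize_nearest(mask, native)
    return mask
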