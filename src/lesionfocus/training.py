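"""Training protocol: augmentation, schedule, early stopping, TTA.

Defaults reproduce the full-scale protocol — AdamW (lr 1.5e-4, weight
decay 1e-2), cosine schedule with ~800-step warm-up, gradient clipping at
1.0, batch 3, at most 24 epochs, early stopping on validation hole Dice
(8 warm-up epochs, patience 5, minimum improvement 0.002), light
augmentations (z-jitter p=0.20, channel dropout p=0.10, speckle σ=0.02
p=0.50, affine rotation ≤5° / translation ≤3% / scale 0.97–1.03 /
shear ≤1.5°, horizontal flip p=0.50) and horizontal-flip test-time
augmentation.  The desk-scale smoke configuration used in the tests keeps
the same machinery at smaller sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from skimage.transform import AffineTransform, warp

from .image_io import LABELS, SliceRecord, build_stack_25d, zscore_normalize
from .losses import LossConfig, cosine_warmup_schedule, total_loss, total_loss_grad
from .model import ModelSpec, UNet
from .nn import AdamW, clip_global_norm

__all__ = [
    "AugmentConfig",
    "TrainConfig",
    "augment",
    "tta_predict",
    "EarlyStopping",
    "class_weights_from_masks",
    "train_model",
    "predict_volume",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class AugmentConfig:
    z_jitter_p: float = 0.20
    channel_dropout_p: float = 0.10
    speckle_sigma: float = 0.02
    speckle_p: float = 0.50
    affine_p: float = 1.0
    max_rotation_deg: float = 5.0
    max_translation_frac: float = 0.03
    scale_range: tuple[float, float] = (0.97, 1.03)
    max_shear_deg: float = 1.5
    hflip_p: float = 0.50

    def __post_init__(self) -> None:
        for name in ("z_jitter_p", "channel_dropout_p", "speckle_p",
                     "affine_p", "hflip_p"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1.5e-4
    weight_decay: float = 1e-2
    warmup_steps: int = 800
    grad_clip: float = 1.0
    batch_size: int = 3
    max_epochs: int = 24
    es_warmup_epochs: int = 8
    es_patience: int = 5
    es_min_delta: float = 0.002
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    seed: int = 42


def augment(stack: np.ndarray, mask: np.ndarray, config: AugmentConfig,
            rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Apply the augmentation policy to one (stack, mask) pair.

    Geometric transforms hit stack and mask identically (mask resampled
    nearest-neighbor); intensity transforms (speckle, channel dropout)
    touch the stack only.  With every probability at 0 the pair is
    returned unchanged.  z-jitter operates at stack-assembly time (it
    re-centers the 3-slice window) and is handled by the training loop.
    """
    stack = np.asarray(stack, dtype=np.float32).copy()
    mask = np.asarray(mask).copy()
    if rng.uniform() < config.affine_p:
        h, w = mask.shape
        rot = np.deg2rad(rng.uniform(-1, 1) * config.max_rotation_deg)
        shear = np.deg2rad(rng.uniform(-1, 1) * config.max_shear_deg)
        scale = rng.uniform(*config.scale_range)
        ty = rng.uniform(-1, 1) * config.max_translation_frac * h
        tx = rng.uniform(-1, 1) * config.max_translation_frac * w
        center = np.array([w / 2, h / 2])
        tform = (
            AffineTransform(translation=-center)
            + AffineTransform(rotation=rot, shear=shear,
                              scale=(scale, scale))
            + AffineTransform(translation=center + np.array([tx, ty]))
        )
        if not np.allclose(tform.params, np.eye(3)):
            for c in range(stack.shape[0]):
                stack[c] = warp(stack[c], tform.inverse, order=1,
                                mode="edge", preserve_range=True)
            mask = warp(mask.astype(np.float64), tform.inverse, order=0,
                        mode="edge", preserve_range=True).astype(mask.dtype)
    if rng.uniform() < config.hflip_p:
        stack = stack[:, :, ::-1].copy()
        mask = mask[:, ::-1].copy()
    if rng.uniform() < config.speckle_p and config.speckle_sigma > 0:
        stack += rng.normal(0, config.speckle_sigma,
                            size=stack.shape).astype(np.float32)
    if rng.uniform() < config.channel_dropout_p:
        stack[int(rng.integers(0, stack.shape[0]))] = 0.0
    return stack, mask


def tta_predict(model_fn: Callable[[np.ndarray], np.ndarray],
                stack: np.ndarray) -> np.ndarray:
    """Average the model output and the unflipped output on the
    horizontally flipped input; a simplex in stays a simplex out."""
    plain = model_fn(stack)
    flipped = model_fn(np.ascontiguousarray(stack[..., ::-1]))
    return 0.5 * (plain + flipped[..., ::-1])


@dataclass
class EarlyStopping:
    """Patience counter on validation hole Dice.

    Never stops before ``warmup_epochs``; an epoch counts as improved
    when the metric reaches ``best + min_delta``; stopping triggers after
    ``patience`` consecutive non-improving epochs past warm-up.
    """

    warmup_epochs: int = 8
    patience: int = 5
    min_delta: float = 0.002
    best: float = -np.inf
    best_epoch: int = 0
    bad_epochs: int = 0

    def update(self, epoch: int, value: float) -> bool:
        """Record epoch (1-based) and return True when training should stop."""
        if value >= self.best + self.min_delta or not np.isfinite(self.best):
            self.best = max(self.best, value)
            self.best_epoch = epoch
            self.bad_epochs = 0
            return False
        if epoch <= self.warmup_epochs:
            self.best = max(self.best, value)
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def class_weights_from_masks(masks: Sequence[np.ndarray],
                             n_classes: int = 5) -> tuple[float, ...]:
    """Inverse pixel-frequency weights, normalized to mean 1."""
    counts = np.zeros(n_classes, dtype=np.float64)
    for m in masks:
        counts += np.bincount(np.asarray(m, dtype=np.int64).ravel(),
                              minlength=n_classes)
    freq = counts / counts.sum()
    w = 1.0 / np.clip(freq, 1e-4, None)  # frequency floor caps rare-class weight
    w /= w.mean()
    return tuple(float(x) for x in w)


def _onehot(mask: np.ndarray, n_classes: int = 5) -> np.ndarray:
    return (np.arange(n_classes)[:, None, None] == mask[None]).astype(np.float32)


def _group_volumes(records: Sequence[SliceRecord]) -> dict[str, list[SliceRecord]]:
    eyes: dict[str, list[SliceRecord]] = {}
    for rec in records:
        eyes.setdefault(rec.eye_id, []).append(rec)
    for recs in eyes.values():
        recs.sort(key=lambda r: r.slice_index)
    return eyes


def _make_stack(eye: list[SliceRecord], index: int) -> np.ndarray:
    volume = [r.image for r in eye]
    return zscore_normalize(build_stack_25d(volume, index))


def hole_dice(pred_labels: np.ndarray, gt_labels: np.ndarray,
              eps: float = 1e-6) -> float:
    a = pred_labels == LABELS["hole"]
    b = gt_labels == LABELS["hole"]
    return float((2 * (a & b).sum() + eps) / (a.sum() + b.sum() + eps))


def train_model(
    train_records: Sequence[SliceRecord],
    val_records: Sequence[SliceRecord],
    model_spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
) -> tuple[UNet, list[dict]]:
    """Train a UNet on slice records; returns the model and an epoch log.

    The model snapshot with the best validation hole Dice is restored
    before returning.
    """
    config = config or TrainConfig()
    model = UNet(model_spec or ModelSpec(seed=config.seed))
    rng = np.random.default_rng(config.seed)
    optimizer = AdamW(model.parameters(), lr=config.lr,
                      weight_decay=config.weight_decay)
    weights = class_weights_from_masks([r.mask for r in train_records])
    loss_cfg = replace(config.loss, class_weights=weights)

    train_eyes = _group_volumes(train_records)
    val_eyes = _group_volumes(val_records)
    samples = [(eye_id, i) for eye_id, recs in train_eyes.items()
               for i in range(len(recs))]
    steps_per_epoch = int(np.ceil(len(samples) / config.batch_size))
    total_steps = max(config.max_epochs * steps_per_epoch,
                      config.warmup_steps + 1)

    stopper = EarlyStopping(config.es_warmup_epochs, config.es_patience,
                            config.es_min_delta)
    history: list[dict] = []
    best_state = model.state_dict()
    step = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(samples))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = [samples[j] for j in order[start : start + config.batch_size]]
            stacks, onehots = [], []
            for eye_id, i in batch:
                eye = train_eyes[eye_id]
                center = i
                if rng.uniform() < config.augment.z_jitter_p:
                    center = int(np.clip(i + rng.choice([-1, 1]), 0,
                                         len(eye) - 1))
                stack = _make_stack(eye, center)
                stack, mask = augment(stack, eye[i].mask, config.augment, rng)
                stacks.append(stack)
                onehots.append(_onehot(mask))
            x = np.stack(stacks)
            y = np.stack(onehots)
            prob = model.forward(x)
            losses.append(total_loss(prob, y, loss_cfg))
            dprob = total_loss_grad(prob, y, loss_cfg)
            model.zero_grad()
            model.backward(dprob=dprob)
            grads = model.gradients()
            clip_global_norm(grads, config.grad_clip)
            optimizer.step(grads, lr_scale=cosine_warmup_schedule(
                step, config.warmup_steps, total_steps))
            step += 1
        # validation hole Dice (plain forward, macro over slices)
        dices = []
        for eye_id, recs in val_eyes.items():
            for i, rec in enumerate(recs):
                prob = model.forward(_make_stack(recs, i)[None])[0]
                dices.append(hole_dice(prob.argmax(axis=0), rec.mask))
        val_hole = float(np.mean(dices)) if dices else float("nan")
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_dice_hole": val_hole})
        if val_hole >= stopper.best:
            best_state = model.state_dict()
        if stopper.update(epoch, val_hole):
            break
    model.load_state_dict(best_state)
    return model, history


def predict_volume(model: UNet, volume: Sequence[np.ndarray],
                   tta: bool = True) -> list[np.ndarray]:
    """Per-slice (5, H, W) probability maps with optional flip-TTA."""
    out = []
    for i in range(len(volume)):
        stack = zscore_normalize(build_stack_25d(volume, i))
        fn = lambda s: model.forward(s[None])[0]
        out.append(tta_predict(fn, stack) if tta else fn(stack))
    return out


def save_checkpoint(model: UNet, path) -> None:
    spec = model.spec
    np.savez_compressed(
        path,
        __spec__=np.array([spec.in_channels, spec.n_classes, *spec.widths,
                           spec.norm_groups, spec.seed], dtype=np.int64),
        **model.state_dict(),
    )


def load_checkpoint(path) -> UNet:
    data = np.load(path)
    s = data["__spec__"]
    spec = ModelSpec(in_channels=int(s[0]), n_classes=int(s[1]),
                     widths=tuple(int(v) for v in s[2:6]),
                     norm_groups=int(s[6]), seed=int(s[7]))
    model = UNet(spec)
    model.load_state_dict({k: data[k] for k in data.files if k != "__spec__"})
    return model
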