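"""Raster I/O, palette-mask decoding, 2.5D stacking and leakage-safe splits.

OCT B-scans arrive as grayscale rasters paired with RGB palette masks in
which each tissue class is painted with a saturated primary color
(red = macular hole, blue = intraretinal cyst, green = retina,
yellow = choroid, black = background).  This module converts those rasters
into integer class masks, assembles the three-channel 2.5D network input
(center slice plus its two neighbors, reflect-padded at volume ends),
normalizes intensities, resizes image/mask pairs consistently, and splits
eyes into train/validation/test subsets in a per-patient, hole-stage-
balanced way so that no patient leaks across subsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "PALETTE",
    "LESION_CLASSES",
    "SliceRecord",
    "decode_palette_mask",
    "encode_palette_mask",
    "build_stack_25d",
    "zscore_normalize",
    "resize_pair",
    "split_by_patient",
    "save_partition",
]

#: Integer labels of the five-class mask.
LABELS: Mapping[str, int] = {
    "background": 0,
    "retina": 1,
    "hole": 2,
    "cyst": 3,
    "choroid": 4,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}
LESION_CLASSES = ("hole", "cyst")

#: RGB palette of the mask rasters (saturated primaries).
PALETTE: Mapping[str, tuple[int, int, int]] = {
    "hole": (255, 0, 0),
    "cyst": (0, 0, 255),
    "retina": (0, 255, 0),
    "choroid": (255, 255, 0),
    "background": (0, 0, 0),
}

# Nearest-color ties are broken in favor of lesions: hole > cyst > retina >
# choroid > background.
_PRIORITY = ("hole", "cyst", "retina", "choroid", "background")

N_CLASSES = len(LABELS)


@dataclass
class SliceRecord:
    """One B-scan with its mask and bookkeeping metadata."""

    eye_id: str
    patient_id: str
    slice_index: int
    image: np.ndarray
    mask: np.ndarray
    stage: str = "unknown"
    quality_flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image shape {self.image.shape} != mask shape {self.mask.shape}"
            )


def decode_palette_mask(
    rgb: np.ndarray,
    palette: Mapping[str, tuple[int, int, int]] | None = None,
    tolerance: float = 30.0,
) -> tuple[np.ndarray, int]:
    """Map an RGB mask raster to integer class labels.

    Each pixel is assigned the nearest palette color in Euclidean RGB
    distance; pixels farther than ``tolerance`` from every palette entry
    fall back to background.  Ties at equal distance resolve by class
    priority (lesions win).

    Returns ``(labels, n_out_of_gamut)`` where the second element counts
    fallback pixels.
    """
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError("expected an H x W x 3 RGB raster")
    palette = dict(PALETTE if palette is None else palette)
    colors = np.array([palette[name] for name in _PRIORITY], dtype=np.float64)
    flat = rgb.reshape(-1, 3).astype(np.float64)
    # (N, 5) distances in priority order; argmin picks the first minimum,
    # which implements the tie-break.
    d2 = ((flat[:, None, :] - colors[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(flat.shape[0]), nearest])
    labels = np.array([LABELS[name] for name in _PRIORITY], dtype=np.int64)[nearest]
    out_of_gamut = dist > tolerance
    labels[out_of_gamut] = LABELS["background"]
    return labels.reshape(rgb.shape[:2]), int(out_of_gamut.sum())


def encode_palette_mask(
    labels: np.ndarray,
    palette: Mapping[str, tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Inverse of :func:`decode_palette_mask` for exact palette colors."""
    palette = dict(PALETTE if palette is None else palette)
    lut = np.zeros((N_CLASSES, 3), dtype=np.uint8)
    for name, value in LABELS.items():
        lut[value] = palette[name]
    return lut[np.asarray(labels, dtype=np.int64)]


def _reflect_index(j: int, n: int) -> int:
    # Reflection without repeating the edge sample (numpy 'reflect' mode).
    if n == 1:
        return 0
    period = 2 * n - 2
    j = abs(j) % period
    return period - j if j >= n else j


def build_stack_25d(volume: Sequence[np.ndarray], center_index: int) -> np.ndarray:
    """Assemble the 3-channel 2.5D input for one center slice.

    Channels are the slices at reflect-padded indices ``(i-1, i, i+1)``;
    a single-slice volume yields three identical channels.
    """
    n = len(volume)
    if n == 0:
        raise ValueError("empty volume")
    if not 0 <= center_index < n:
        raise IndexError(f"center_index {center_index} out of range for {n} slices")
    idx = [_reflect_index(center_index + o, n) for o in (-1, 0, 1)]
    return np.stack([np.asarray(volume[j], dtype=np.float32) for j in idx], axis=0)


def zscore_normalize(stack: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-channel z-score standardization; constant channels map to zero."""
    stack = np.asarray(stack, dtype=np.float32)
    mean = stack.mean(axis=(-2, -1), keepdims=True)
    sd = stack.std(axis=(-2, -1), keepdims=True)
    return np.where(sd > eps, (stack - mean) / np.maximum(sd, eps), 0.0).astype(
        np.float32
    )


def resize_pair(
    image: np.ndarray, mask: np.ndarray, target: tuple[int, int] = (512, 512)
) -> tuple[np.ndarray, np.ndarray]:
    """Resize an image (bilinear) and its mask (nearest-neighbor) together.

    Nearest-neighbor resampling can only drop labels, never invent them.
    """
    if image.shape[:2] == tuple(target):
        return image, mask
    img = _sk_resize(
        np.asarray(image, dtype=np.float64),
        target,
        order=1,
        anti_aliasing=image.shape[0] > target[0],
        preserve_range=True,
    ).astype(np.float32)
    msk = _sk_resize(
        np.asarray(mask),
        target,
        order=0,
        anti_aliasing=False,
        preserve_range=True,
    ).astype(np.asarray(mask).dtype)
    return img, msk


def _largest_remainder_counts(n: int, ratios: Sequence[float]) -> list[int]:
    raw = [n * r for r in ratios]
    counts = [int(np.floor(x)) for x in raw]
    remainders = [x - c for x, c in zip(raw, counts)]
    for _ in range(n - sum(counts)):
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1.0
    return counts


def split_by_patient(
    records: Sequence[SliceRecord],
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    stage_key: str = "stage",
    seed: int = 42,
) -> dict[str, list[str]]:
    """Stage-balanced 70/15/15 split at the patient level.

    All eyes (and hence all slices) of a patient land in exactly one
    subset.  Within each hole stage, patients are shuffled and dealt to
    subsets with largest-remainder rounding of the target ratios, so eye
    counts per subset deviate from the targets by at most one.

    Returns ``{"train"|"val"|"test": [eye ids]}``.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    patients: dict[str, dict] = {}
    for rec in records:
        info = patients.setdefault(
            rec.patient_id, {"stage": getattr(rec, stage_key), "eyes": set()}
        )
        info["eyes"].add(rec.eye_id)
    if len(patients) < 3:
        raise ValueError("need at least as many patients as subsets")

    rng = np.random.default_rng(seed)
    subsets: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    stages = sorted({info["stage"] for info in patients.values()})
    for stage in stages:
        pids = sorted(p for p, info in patients.items() if info["stage"] == stage)
        rng.shuffle(pids)
        counts = _largest_remainder_counts(len(pids), ratios)
        cursor = 0
        for name, k in zip(("train", "val", "test"), counts):
            for pid in pids[cursor : cursor + k]:
                subsets[name].extend(sorted(patients[pid]["eyes"]))
            cursor += k
    return subsets


def save_partition(partition: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        json.dump({k: list(v) for k, v in partition.items()}, fh, indent=2)
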