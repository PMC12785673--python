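"""Anatomy-constrained cleanup of predicted label maps.

Raw per-slice predictions are polished in four stages, in order:

1. intraretinal constraint — lesion pixels outside the filled retina
   region are reassigned to background;
2. morphology — binary opening then closing for holes, closing only for
   cysts (closing may only add pixels inside the filled retina);
3. neighborhood-slice consistency — a lesion pixel survives only if it is
   lesion in at least 2 of the 3 reflect-padded slices {i−1, i, i+1};
4. fragment suppression — connected components (8-connectivity) smaller
   than a fraction of the image area are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import closing as _closing
from skimage.morphology import disk
from skimage.morphology import opening as _opening

from .image_io import LABELS, LESION_CLASSES

__all__ = [
    "PostprocessConfig",
    "apply_anatomical_constraint",
    "morphological_cleanup",
    "slice_consistency_filter",
    "remove_small_fragments",
    "postprocess_volume",
]


@dataclass(frozen=True)
class PostprocessConfig:
    """Radius of the disk structuring element (px) and per-class minimum
    component area as a fraction of H*W."""

    structuring_radius: int = 1
    min_area_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"hole": 2e-4, "cyst": 1e-4}
    )
    slice_consistency: bool = True

    def __post_init__(self) -> None:
        if self.structuring_radius < 1:
            raise ValueError("structuring radius must be >= 1")
        for name, frac in self.min_area_fraction.items():
            if not 0.0 <= frac <= 0.01:
                raise ValueError(f"min_area_fraction[{name}] outside [0, 0.01]")


def _filled_retina(labelmap: np.ndarray) -> np.ndarray:
    """Retina region filled per column span.

    The span is taken from retina-class pixels only, so lesion islands in
    the choroid or vitreous cannot extend it; columns where a
    full-thickness hole replaces the whole retina inherit the span
    interpolated from the nearest retina-bearing columns.
    """
    retina = labelmap == LABELS["retina"]
    h, w = retina.shape
    rows = np.arange(h)[:, None]
    has_retina = retina.any(axis=0)
    if not has_retina.any():
        return np.zeros_like(retina)
    top = np.where(retina, rows, h).min(axis=0).astype(float)
    bottom = np.where(retina, rows, -1).max(axis=0).astype(float)
    cols = np.arange(w)
    valid = np.flatnonzero(has_retina)
    top = np.interp(cols, valid, top[valid])
    bottom = np.interp(cols, valid, bottom[valid])
    # bridge narrow notches where a lesion locally ate the boundary rows
    # (1-D closing of the column envelopes)
    win = max(5, w // 16)
    top = ndimage.minimum_filter1d(top, size=win, mode="nearest")
    bottom = ndimage.maximum_filter1d(bottom, size=win, mode="nearest")
    return (rows >= np.floor(top)[None, :]) & (rows <= np.ceil(bottom)[None, :])


def apply_anatomical_constraint(labelmap: np.ndarray) -> np.ndarray:
    """Drop lesion pixels outside the filled retina region (to background)."""
    out = np.asarray(labelmap).copy()
    inside = _filled_retina(out)
    for name in LESION_CLASSES:
        stray = (out == LABELS[name]) & ~inside
        out[stray] = LABELS["background"]
    return out


def morphological_cleanup(
    labelmap: np.ndarray,
    lesion_class: str,
    config: PostprocessConfig | None = None,
) -> np.ndarray:
    """Opening+closing for holes, closing for cysts; other classes untouched.

    Pixels added by closing are admitted only inside the filled retina, so
    cleanup can never create extra-retinal lesion tissue.
    """
    config = config or PostprocessConfig()
    out = np.asarray(labelmap).copy()
    value = LABELS[lesion_class]
    binary = out == value
    selem = disk(config.structuring_radius)
    if lesion_class == "hole":
        cleaned = _closing(_opening(binary, selem), selem)
    elif lesion_class == "cyst":
        cleaned = _closing(binary, selem)
    else:
        return out
    cleaned &= binary | _filled_retina(out)
    out[binary & ~cleaned] = LABELS["background"]
    out[cleaned & ~binary] = value
    return out


def slice_consistency_filter(
    volume: Sequence[np.ndarray],
) -> list[np.ndarray]:
    """Majority vote over the reflect-padded ±1-slice window, per pixel.

    A lesion pixel at slice i is kept iff that pixel is the same lesion
    class in at least 2 of {i−1, i, i+1}.  With a single slice the
    reflected window is unanimous and the volume is returned unchanged.
    """
    n = len(volume)
    if n == 0:
        raise ValueError("empty volume")
    maps = [np.asarray(m) for m in volume]
    out = [m.copy() for m in maps]
    if n == 1:
        return out

    def _reflect(j: int) -> int:
        return -j if j < 0 else (2 * n - 2 - j if j >= n else j)

    for i in range(n):
        window = [maps[_reflect(i + o)] for o in (-1, 0, 1)]
        for name in LESION_CLASSES:
            value = LABELS[name]
            votes = sum((w == value).astype(np.int8) for w in window)
            drop = (maps[i] == value) & (votes < 2)
            out[i][drop] = LABELS["background"]
    return out


def remove_small_fragments(
    labelmap: np.ndarray, config: PostprocessConfig | None = None
) -> np.ndarray:
    """Suppress lesion components below ``fraction * H * W`` pixels."""
    config = config or PostprocessConfig()
    out = np.asarray(labelmap).copy()
    h, w = out.shape
    for name in LESION_CLASSES:
        frac = config.min_area_fraction.get(name, 0.0)
        if frac <= 0:
            continue
        threshold = frac * h * w
        binary = out == LABELS[name]
        comps = cc_label(binary, connectivity=2)
        for comp_id in range(1, comps.max() + 1):
            comp = comps == comp_id
            if comp.sum() < threshold:
                out[comp] = LABELS["background"]
    return out


def postprocess_volume(
    volume: Sequence[np.ndarray], config: PostprocessConfig | None = None
) -> list[np.ndarray]:
    """Full cleanup pipeline: constraint → morphology → ±1-slice vote →
    fragment suppression."""
    config = config or PostprocessConfig()
    staged = [apply_anatomical_constraint(m) for m in volume]
    for name in LESION_CLASSES:
        staged = [morphological_cleanup(m, name, config) for m in staged]
    if config.slice_consistency:
        staged = slice_consistency_filter(staged)
    return [remove_small_fragments(m, config) for m in staged]
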