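"""Synthetic OCT-like fixtures: volumes, masks, probability maps, heatmaps.

Real macular-hole OCT volumes are large and access-controlled, so every
stage of the pipeline is exercised on synthetic B-scans with known ground
truth: a curved bright retina band over a choroid band, with dark
elliptical hole/cyst lesions strictly inside the retina.  The generator
also produces per-pixel class-probability maps with controllable
calibration and attribution heatmaps drawn from three parametric focus
regimes (retina-dominant diffuse, peri-lesion ring, narrow off-lesion
blob) that mimic the qualitative explanation patterns seen on real scans.

Everything is deterministic under ``FixtureSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt

from .image_io import LABELS, LESION_CLASSES, SliceRecord

__all__ = [
    "LesionParams",
    "FixtureSpec",
    "REGIMES",
    "make_synthetic_volume",
    "make_synthetic_dataset",
    "make_synthetic_attribution",
    "make_calibrated_probmap",
    "regime_lesion_params",
    "make_regime_cases",
]

REGIMES = ("retina_dominant", "peri_lesion", "narrow_coverage")

QUALITY_FLAGS = ("signal_shield", "image_blur", "low_signal_strength")


@dataclass(frozen=True)
class LesionParams:
    """Geometry of one lesion class: ``count`` ellipses with semi-axes drawn
    from ``radius`` (px); ``fragmentation`` splits each into 3 small pieces."""

    count: int = 1
    radius: tuple[float, float] = (6.0, 12.0)
    fragmentation: bool = False


def _default_lesions() -> dict[str, LesionParams]:
    return {
        "hole": LesionParams(count=1, radius=(15.0, 45.0)),
        "cyst": LesionParams(count=2, radius=(8.0, 25.0)),
    }


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic eye.

    ``image_size`` defaults to the native 512x512 working resolution;
    tests run at 64x64.  ``retina_band`` gives the vertical extent of the
    retina as fractions of the image height.  ``noise_sigma`` is additive
    Gaussian intensity noise on [0, 1] images; ``calibration_temperature``
    scales the probability-map logits (1 = calibrated).
    """

    image_size: tuple[int, int] = (512, 512)
    n_slices: int = 20
    retina_band: tuple[float, float] = (0.30, 0.62)
    lesion_params: dict[str, LesionParams] = field(default_factory=_default_lesions)
    regime: str = "retina_dominant"
    noise_sigma: float = 0.03
    calibration_temperature: float = 1.0
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.image_size) < 16:
            raise ValueError("image_size must be at least 16 px")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")


_INTENSITY = {
    LABELS["background"]: 0.05,
    LABELS["retina"]: 0.75,
    LABELS["hole"]: 0.10,
    LABELS["cyst"]: 0.28,
    LABELS["choroid"]: 0.45,
}


def _band_rows(spec: FixtureSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column top/bottom row of the retina band and choroid bottom."""
    h, w = spec.image_size
    x = np.arange(w)
    phase = rng.uniform(0, 2 * np.pi)
    curve = 0.03 * h * np.sin(2 * np.pi * x / w + phase)
    r0 = np.clip(spec.retina_band[0] * h + curve, 1, h - 3).astype(int)
    r1 = np.clip(spec.retina_band[1] * h + curve, r0 + 2, h - 2).astype(int)
    r2 = np.clip(r1 + int(0.12 * h) + 1, r1 + 1, h - 1).astype(int)
    return r0, r1, r2


def _draw_ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float,
                  rot: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(rot), np.sin(rot)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / max(rx, 1e-6)) ** 2 + (v / max(ry, 1e-6)) ** 2 <= 1.0


def _place_lesions(labels: np.ndarray, spec: FixtureSpec,
                   rng: np.random.Generator) -> None:
    h, w = labels.shape
    retina_interior = labels == LABELS["retina"]
    # strict interior: erode the band by one pixel so lesions never touch
    # the band boundary
    interior = distance_transform_edt(retina_interior) > 1.5
    band_height = (spec.retina_band[1] - spec.retina_band[0]) * h
    for name in LESION_CLASSES:
        params = spec.lesion_params.get(name)
        if params is None or params.count == 0:
            continue
        if params.radius[0] * 2 >= band_height:
            raise ValueError(
                f"{name} lesion radius {params.radius} exceeds retina band "
                f"height {band_height:.1f} px"
            )
        for _ in range(params.count):
            r = rng.uniform(*params.radius)
            pieces = 3 if params.fragmentation else 1
            cy0 = None
            for p in range(pieces):
                ry = min(r / (1.6 if pieces > 1 else 1.0), band_height / 2 - 2)
                rx = ry * rng.uniform(1.0, 1.8)
                cx = rng.uniform(0.15 * w, 0.85 * w)
                cy_lo = spec.retina_band[0] * h + ry + 2
                cy_hi = spec.retina_band[1] * h - ry - 2
                cy = rng.uniform(cy_lo, max(cy_lo + 1, cy_hi))
                if pieces > 1 and cy0 is not None:
                    # fragments scatter around the first piece
                    cx = np.clip(cx0 + rng.uniform(-3 * r, 3 * r), 2, w - 3)
                    cy = np.clip(cy0 + rng.uniform(-ry, ry), cy_lo, cy_hi)
                else:
                    cy0, cx0 = cy, cx
                blob = _draw_ellipse(h, w, cy, cx, ry, rx, rng.uniform(0, np.pi))
                labels[blob & interior] = LABELS[name]


def make_synthetic_volume(
    spec: FixtureSpec, eye_id: str = "eye000"
) -> tuple[list[np.ndarray], list[np.ndarray], list[dict]]:
    """Generate one synthetic eye: per-slice images, masks, and metadata.

    Lesion geometry is held fixed across the slices of an eye (adjacent
    B-scans image the same lesion) while intensity noise varies per slice.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    r0, r1, r2 = _band_rows(spec, rng)
    labels = np.zeros((h, w), dtype=np.int64)
    rows = np.arange(h)[:, None]
    labels[(rows >= r0[None, :]) & (rows < r1[None, :])] = LABELS["retina"]
    labels[(rows >= r1[None, :]) & (rows < r2[None, :])] = LABELS["choroid"]
    _place_lesions(labels, spec, rng)

    base = np.vectorize(_INTENSITY.get)(labels).astype(np.float32)
    base += 0.04 * (rows / h).astype(np.float32)  # mild depth gradient

    images, masks, metadata = [], [], []
    for i in range(spec.n_slices):
        noise = rng.normal(0.0, spec.noise_sigma, size=(h, w)).astype(np.float32)
        images.append(np.clip(base + noise, 0.0, 1.0))
        masks.append(labels.copy())
        metadata.append(
            {
                "eye_id": eye_id,
                "slice_index": i,
                "stage": "unknown",
                "quality_flags": [],
                "regime": spec.regime,
            }
        )
    return images, masks, metadata


def make_synthetic_dataset(
    n_eyes: int,
    spec: FixtureSpec,
    flag_probability: float = 0.10,
) -> list[SliceRecord]:
    """Generate a multi-eye dataset of :class:`SliceRecord`.

    Each eye gets an independent sub-seed.  A synthetic "stage" label is
    assigned as the quartile (Q1-Q4) of total lesion area across eyes,
    which is enough to exercise the stage-balanced split; quality flags
    are sprinkled at ``flag_probability`` per slice.
    """
    rng = np.random.default_rng(spec.seed)
    eyes = []
    for e in range(n_eyes):
        sub = replace(spec, seed=int(rng.integers(0, 2**31 - 1)))
        eye_id = f"eye{e:03d}"
        images, masks, meta = make_synthetic_volume(sub, eye_id=eye_id)
        area = int(np.isin(masks[0], [LABELS["hole"], LABELS["cyst"]]).sum())
        eyes.append((eye_id, images, masks, meta, area))

    areas = np.array([e[-1] for e in eyes], dtype=float)
    qs = np.quantile(areas, [0.25, 0.5, 0.75]) if n_eyes > 1 else [0, 0, 0]
    records: list[SliceRecord] = []
    for eye_id, images, masks, meta, area in eyes:
        stage = "Q" + str(1 + int(np.searchsorted(qs, area, side="right")))
        patient_id = "pat" + eye_id[3:]
        for img, msk, m in zip(images, masks, meta):
            flags: tuple[str, ...] = ()
            if rng.uniform() < flag_probability:
                flags = (QUALITY_FLAGS[int(rng.integers(0, 2))],)
            records.append(
                SliceRecord(
                    eye_id=eye_id,
                    patient_id=patient_id,
                    slice_index=m["slice_index"],
                    image=img,
                    mask=msk,
                    stage=stage,
                    quality_flags=flags,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Attribution heatmaps per focus regime
# ---------------------------------------------------------------------------

def _retina_domain(mask: np.ndarray) -> np.ndarray:
    return np.isin(mask, [LABELS["retina"], LABELS["hole"], LABELS["cyst"]])


def make_synthetic_attribution(
    mask: np.ndarray,
    lesion_class: str,
    regime: str,
    seed: int = 42,
    noise_floor: float = 0.02,
) -> np.ndarray:
    """Draw a nonnegative attribution heatmap from one focus regime.

    retina_dominant
        Broad diffuse mass over the retina centered near the lesion; the
        lesion itself responds, but no more than surrounding tissue, so
        precision is low while recall and centering stay high.
    peri_lesion
        A ring hugging the lesion boundary (mostly just outside it) with
        an angular asymmetry that drags the attribution center of mass
        off the lesion center.
    narrow_coverage
        A small blob displaced from the (small) lesion; almost none of
        the top-ranked pixels fall inside the lesion.

    Raises ``ValueError`` when the lesion class is absent (present-only
    rule).
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    lesion = mask == LABELS[lesion_class]
    if not lesion.any():
        raise ValueError(
            f"present-only violation: mask contains no {lesion_class!r} pixels"
        )
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    domain = _retina_domain(mask)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = np.argwhere(lesion).mean(axis=0)
    lp = float(lesion.sum())
    r_eq = np.sqrt(lp / np.pi)  # equivalent lesion radius

    heat = noise_floor * rng.uniform(0.0, 1.0, size=(h, w))
    domain_size = float(domain.sum())
    # radius of the disk a top-20% selection of the domain would fill;
    # regime footprints are parameterized against it so the generated
    # phenomenology is resolution-independent
    sel_r = np.sqrt(0.20 * domain_size / np.pi)

    if regime == "retina_dominant":
        # broad diffuse mass near (not on) the lesion: high recall, low
        # precision, short COM distance
        sigma = 0.75 * sel_r
        offset = rng.uniform(0.4, 1.0) * max(r_eq, 1.5)
        angle = rng.uniform(0, 2 * np.pi)
        g = np.exp(
            -(((yy - cy - offset * np.sin(angle)) ** 2)
              + (xx - cx - offset * np.cos(angle)) ** 2) / (2 * sigma**2)
        )
        g = np.where(lesion, 0.75 * g, g)  # lesion responds, but no more
        heat += g
    elif regime == "peri_lesion":
        d_out = distance_transform_edt(~lesion)
        d_in = distance_transform_edt(lesion)
        signed = np.where(lesion, -d_in, d_out)
        ring_w = max(0.8 * r_eq, 2.0)
        ring = np.exp(-(signed**2) / (2 * ring_w**2))
        theta0 = rng.uniform(0, 2 * np.pi)
        theta = np.arctan2(yy - cy, xx - cx)
        ring *= 1.0 + 1.0 * np.cos(theta - theta0)  # drags COM off-center
        heat += ring
    else:  # narrow_coverage
        offset_r = rng.uniform(1.5, 2.5) * max(r_eq, 2.0) + 2.0
        angle = rng.uniform(0, 2 * np.pi)
        by = np.clip(cy + offset_r * np.sin(angle), 2, h - 3)
        bx = np.clip(cx + offset_r * np.cos(angle), 2, w - 3)
        sigma = max(0.8 * r_eq, 1.5)
        g = np.exp(-(((yy - by) ** 2) + (xx - bx) ** 2) / (2 * sigma**2))
        g[lesion] = 0.0  # blob misses the lesion
        heat += g

    heat *= domain
    return heat.astype(np.float64)


def regime_lesion_params(
    regime: str, image_size: tuple[int, int] = (64, 64)
) -> dict[str, LesionParams]:
    """Characteristic lesion geometry per focus regime.

    Mirrors the sizes seen in practice: narrow-coverage failures hit tiny
    lesions, the peri-lesion ring pattern accompanies large lesions, and
    the retina-dominant pattern sits in between.  Radii scale linearly
    with resolution (reference 64 px).
    """
    u = min(image_size) / 64.0
    radii = {
        "narrow_coverage": (1.5 * u, 2.5 * u),
        "retina_dominant": (2.0 * u, 3.5 * u),
        "peri_lesion": (4.0 * u, 6.5 * u),
    }
    if regime not in radii:
        raise ValueError(f"unknown regime {regime!r}")
    return {"hole": LesionParams(count=1, radius=radii[regime])}


def make_regime_cases(
    n_per_regime: int,
    image_size: tuple[int, int] = (64, 64),
    seed: int = 42,
    lesion_class: str = "hole",
    mode: str = "gt",
):
    """Generate attribution cases with planted regime labels.

    Each case gets its own mask (lesion size drawn from the regime's
    characteristic range) and heatmap; returns ``(cases, planted)`` where
    ``cases`` feed :func:`lesionfocus.xai.build_xai_table` and
    ``planted`` is the list of true regime names, row-aligned.
    """
    from .xai import AttributionCase

    rng = np.random.default_rng(seed)
    cases, planted = [], []
    i = 0
    for regime in REGIMES:
        lesions = regime_lesion_params(regime, image_size)
        made = 0
        while made < n_per_regime:
            sub = FixtureSpec(
                image_size=image_size, n_slices=1,
                lesion_params=dict(lesions), regime=regime,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            _, masks, _ = make_synthetic_volume(sub)
            mask = masks[0]
            if not (mask == LABELS[lesion_class]).any():
                continue  # lesion clipped away by the band; redraw
            heat = make_synthetic_attribution(
                mask, lesion_class, regime,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            cases.append(AttributionCase(
                slice_id=f"synth{i:04d}", lesion_class=lesion_class,
                mode=mode, processed=heat,
                lesion_mask=mask == LABELS[lesion_class],
                domain_mask=_retina_domain(mask),
            ))
            planted.append(regime)
            made += 1
            i += 1
    return cases, planted


# ---------------------------------------------------------------------------
# Calibrated probability maps
# ---------------------------------------------------------------------------

def make_calibrated_probmap(
    mask: np.ndarray,
    temperature: float = 1.0,
    seed: int = 42,
    evidence: float = 2.0,
) -> np.ndarray:
    """Per-pixel class-probability simplex with controllable calibration.

    Each pixel emits a noisy class score ``o_c = evidence * 1[c == y] + N(0, 1)``
    and the map is the exact Bayes posterior ``softmax(log pi_c + evidence * o_c)``
    under the empirical class prior ``pi`` — calibrated by construction at
    ``temperature == 1``.  Dividing the logits by a temperature above 1
    flattens the posterior away from the Bayes rule and degrades
    calibration.

    Returns a ``(5, H, W)`` float64 array summing to 1 per pixel.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    n_classes = len(LABELS)
    counts = np.bincount(np.asarray(mask, dtype=np.int64).ravel(), minlength=n_classes)
    prior = (counts + 1e-12) / counts.sum()
    onehot = (np.arange(n_classes)[:, None, None] == mask[None]).astype(np.float64)
    obs = evidence * onehot + rng.normal(0.0, 1.0, size=(n_classes, h, w))
    logits = np.log(prior)[:, None, None] + evidence * obs
    logits /= temperature
    logits -= logits.max(axis=0, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=0, keepdims=True)
    return p
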