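"""Top-τ attribution coverage metrics and derived focus features.

An attribution heatmap is compared with a lesion mask by ranking pixels by
attribution magnitude inside a ranking domain (the retina by default),
keeping the top τ% as a binary mask A_τ, and scoring its overlap with the
lesion L:

    APIL_τ = |A_τ ∩ L| / |A_τ|       (precision: attributions inside lesion)
    ARIL_τ = |A_τ ∩ L| / |L|         (recall: lesion covered)
    Dice_τ = 2|A_τ ∩ L| / (|A_τ| + |L|)
    Leak_τ = 1 − APIL_τ              (attributions leaking outside)

Spatial focus is tracked by the center-of-mass distance (COM-dist) between
the attribution-weighted centroid of the heatmap and the lesion centroid,
its size-normalized form nCOM = COM-dist / √LP, Focus Proximity
FP = −nCOM, Focus Concentration FC = APIL5 / APIL20, the total positive
attribution mass PAM, and the lesion pixel count LP.  All metrics follow
the present-only rule: rows exist only for slice/class pairs whose
reference lesion mask is non-empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TopTauMask",
    "AttributionCase",
    "top_tau_mask",
    "coverage_metrics",
    "leakage_from_precision",
    "center_of_mass_distance",
    "derived_features",
    "build_xai_table",
    "XAI_COLUMNS",
]

DEFAULT_TAUS = (5, 10, 20)

XAI_COLUMNS = (
    ["slice_id", "class", "mode"]
    + [f"{m}{t}" for t in DEFAULT_TAUS for m in ("APIL", "ARIL", "Dice", "Leak")]
    + ["COM_dist", "nCOM", "FP", "FC", "PAM", "LP"]
)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class TopTauMask:
    """Binary mask of the top-τ% attribution pixels within a ranking domain."""

    mask: np.ndarray
    tau: float
    k: int
    domain_size: int

    @property
    def is_empty(self) -> bool:
        return self.k == 0


def top_tau_mask(
    processed: np.ndarray, tau: float, domain_mask: np.ndarray
) -> TopTauMask:
    """Select the ``k = round(τ% · |domain|)`` highest-attribution pixels.

    Ties at the cutoff value are broken by row-major pixel order, so the
    selection is deterministic.  ``k == 0`` yields an empty-mask marker.
    """
    if not 0 < tau < 100:
        raise ValueError("tau must be in (0, 100)")
    domain_mask = np.asarray(domain_mask, dtype=bool)
    if not domain_mask.any():
        raise ValueError("ranking domain is empty")
    flat_idx = np.flatnonzero(domain_mask.ravel())
    values = np.asarray(processed, dtype=np.float64).ravel()[flat_idx]
    k = _round_half_away(tau / 100.0 * flat_idx.size)
    out = np.zeros(domain_mask.shape, dtype=bool)
    if k > 0:
        # stable argsort on negated values: descending, row-major tie-break
        order = np.argsort(-values, kind="stable")[:k]
        out.ravel()[flat_idx[order]] = True
    return TopTauMask(mask=out, tau=tau, k=k, domain_size=int(flat_idx.size))


class PresentOnlyViolation(ValueError):
    """Raised when a metric is requested for an absent lesion class."""


def coverage_metrics(top: TopTauMask, lesion: np.ndarray) -> dict[str, float]:
    """APIL/ARIL/Dice/Leak of a top-τ mask against a non-empty lesion mask.

    An empty top-τ mask yields NaN markers (undefined rather than zero).
    """
    lesion = np.asarray(lesion, dtype=bool)
    n_lesion = int(lesion.sum())
    if n_lesion == 0:
        raise PresentOnlyViolation("lesion mask is empty")
    if top.is_empty:
        return {"APIL": float("nan"), "ARIL": float("nan"),
                "Dice": float("nan"), "Leak": float("nan")}
    n_top = int(top.mask.sum())
    n_inter = int((top.mask & lesion).sum())
    apil = n_inter / n_top
    return {
        "APIL": apil,
        "ARIL": n_inter / n_lesion,
        "Dice": 2.0 * n_inter / (n_top + n_lesion),
        "Leak": leakage_from_precision(apil),
    }


def leakage_from_precision(apil: float) -> float:
    """Leakage is the complement of attribution precision: Leak_τ = 1 − APIL_τ."""
    return 1.0 - apil


def center_of_mass_distance(processed: np.ndarray, lesion: np.ndarray) -> float:
    """Euclidean distance (px) between the attribution-weighted centroid of
    the heatmap and the unweighted lesion centroid.

    NaN when the heatmap carries no positive mass.
    """
    lesion = np.asarray(lesion, dtype=bool)
    if not lesion.any():
        raise PresentOnlyViolation("lesion mask is empty")
    w = np.clip(np.asarray(processed, dtype=np.float64), 0.0, None)
    total = w.sum()
    if total <= 0:
        return float("nan")
    yy, xx = np.mgrid[0 : w.shape[0], 0 : w.shape[1]]
    ay, ax = (w * yy).sum() / total, (w * xx).sum() / total
    ly, lx = np.argwhere(lesion).mean(axis=0)
    return float(np.hypot(ay - ly, ax - lx))


def derived_features(
    com_dist: float, lesion_pixels: int, apil5: float, apil20: float, pam: float
) -> dict[str, float]:
    """Size-normalized focus features.

    nCOM = COM-dist / √LP; FP = −nCOM; FC = APIL5 / APIL20 (NaN when
    APIL20 = 0, excluded from summaries); PAM passes through (total
    clipped positive attribution, pre-normalization); LP is the lesion
    pixel count.
    """
    if lesion_pixels <= 0:
        raise PresentOnlyViolation("lesion has no pixels")
    ncom = com_dist / math.sqrt(lesion_pixels)
    fc = float("nan")
    if apil20 and not math.isnan(apil20):
        fc = apil5 / apil20
    return {"nCOM": ncom, "FP": -ncom, "FC": fc,
            "PAM": float(pam), "LP": float(lesion_pixels)}


@dataclass
class AttributionCase:
    """One slice × class × mode unit entering the XAI table.

    ``processed`` is the clipped, positive, optionally retina-restricted
    heatmap; ``pam`` its total mass before max-normalization;
    ``lesion_mask`` the reference lesion (clinical mask in GT mode, model
    segmentation in Pred mode); ``domain_mask`` the top-τ ranking domain.
    """

    slice_id: str
    lesion_class: str
    mode: str
    processed: np.ndarray
    lesion_mask: np.ndarray
    domain_mask: np.ndarray
    pam: float | None = None
    extra: dict = field(default_factory=dict)


def build_xai_table(
    cases: Iterable[AttributionCase],
    taus: Sequence[int] = DEFAULT_TAUS,
    skip_absent: bool = True,
) -> pd.DataFrame:
    """Assemble one XAI record per (slice, class, mode) case.

    Cases whose lesion mask is empty are silently dropped when
    ``skip_absent`` (the present-only rule); otherwise they raise.
    Column names follow the field's abbreviations (APIL20, Leak10, ...).
    """
    taus = tuple(taus)
    rows = []
    for case in cases:
        lesion = np.asarray(case.lesion_mask, dtype=bool)
        if not lesion.any():
            if skip_absent:
                continue
            raise PresentOnlyViolation(
                f"{case.slice_id}/{case.lesion_class}: empty lesion mask"
            )
        row: dict[str, object] = {
            "slice_id": case.slice_id,
            "class": case.lesion_class,
            "mode": case.mode,
        }
        cov_by_tau = {}
        for tau in taus:
            top = top_tau_mask(case.processed, tau, case.domain_mask)
            cov = coverage_metrics(top, lesion)
            cov_by_tau[tau] = cov
            for name, value in cov.items():
                row[f"{name}{tau}"] = value
        com = center_of_mass_distance(case.processed, lesion)
        pam = case.pam if case.pam is not None else float(
            np.clip(case.processed, 0, None).sum()
        )
        row["COM_dist"] = com
        row.update(
            derived_features(
                com_dist=com,
                lesion_pixels=int(lesion.sum()),
                apil5=cov_by_tau.get(5, {"APIL": float("nan")})["APIL"],
                apil20=cov_by_tau.get(20, {"APIL": float("nan")})["APIL"],
                pam=pam,
            )
        )
        row.update(case.extra)
        rows.append(row)
    columns = (
        ["slice_id", "class", "mode"]
        + [f"{m}{t}" for t in taus for m in ("APIL", "ARIL", "Dice", "Leak")]
        + ["COM_dist", "nCOM", "FP", "FC", "PAM", "LP"]
    )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=columns)
    extra_cols = [c for c in df.columns if c not in columns]
    return df[columns + extra_cols]
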