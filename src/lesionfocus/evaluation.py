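"""Segmentation quality metrics: Dice/IoU, HD95, ECE, effect sizes.

Per-slice hard-mask Dice and IoU use dual smoothing so that a class absent
from both prediction and reference contributes a neutral value of 1;
present-only mode drops such slices instead.  Boundary accuracy is the
95th-percentile symmetric Hausdorff distance (HD95) between mask
boundaries, calibration is the expected calibration error (ECE) over
equal-width confidence bins, and group contrasts are summarized with
pooled-SD Cohen's d and stratified mean tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .image_io import LABELS

__all__ = [
    "EvalConfig",
    "dice_iou_per_slice",
    "hd95",
    "expected_calibration_error",
    "cohens_d",
    "stratify_summary",
    "macro_summary",
]


@dataclass(frozen=True)
class EvalConfig:
    smoothing: float = 1e-6
    present_only: bool = False
    ece_bins: int = 15
    include_background: bool = False
    classes: tuple[str, ...] = ("retina", "hole", "cyst", "choroid")

    def __post_init__(self) -> None:
        if self.ece_bins < 2:
            raise ValueError("ece_bins must be >= 2")


def dice_iou_per_slice(
    pred: np.ndarray, gt: np.ndarray, config: EvalConfig | None = None
) -> dict[str, dict[str, float]]:
    """Hard-mask Dice and IoU per class for one slice.

    Dice = (2|A∩B| + ε) / (|A| + |B| + ε) and IoU = (|A∩B| + ε) /
    (|A∪B| + ε); with ε in both numerator and denominator an
    absent-absent class scores a neutral 1.  In present-only mode classes
    absent from the reference return NaN so callers can drop them.
    """
    config = config or EvalConfig()
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt shapes differ")
    eps = config.smoothing
    names = config.classes
    if config.include_background:
        names = ("background",) + tuple(c for c in names if c != "background")
    out: dict[str, dict[str, float]] = {}
    for name in names:
        value = LABELS[name]
        a = pred == value
        b = gt == value
        if config.present_only and not b.any():
            out[name] = {"dice": float("nan"), "iou": float("nan")}
            continue
        inter = float((a & b).sum())
        na, nb = float(a.sum()), float(b.sum())
        out[name] = {
            "dice": (2 * inter + eps) / (na + nb + eps),
            "iou": (inter + eps) / (na + nb - inter + eps),
        }
    return out


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Pixels of the mask with at least one 4-neighbor outside it."""
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, mode="constant")
    interior = (
        padded[:-2, 1:-1]
        & padded[2:, 1:-1]
        & padded[1:-1, :-2]
        & padded[1:-1, 2:]
    )
    return mask & ~interior


def hd95(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Symmetric 95th-percentile Hausdorff distance between mask boundaries.

    Directed distance = 95th percentile (linear interpolation) of each
    boundary pixel's nearest-neighbor distance to the other boundary; the
    symmetric value is the max of the two directions.  NaN if either mask
    is empty (undefined, excluded from means).
    """
    a = np.argwhere(_boundary(mask_a))
    b = np.argwhere(_boundary(mask_b))
    if a.size == 0 or b.size == 0:
        return float("nan")
    d_ab = cKDTree(b).query(a, k=1)[0]
    d_ba = cKDTree(a).query(b, k=1)[0]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


def expected_calibration_error(
    probmaps: Sequence[np.ndarray],
    gts: Sequence[np.ndarray],
    config: EvalConfig | None = None,
) -> float:
    """Binned confidence-accuracy gap of max-class probabilities.

    Pixels of all supplied slices are pooled, binned by max-class
    confidence into equal-width bins on [0, 1], and scored as
    ECE = Σ_b (n_b / N) |acc_b − conf_b|.  Callers are expected to pass
    only slices whose reference contains a lesion.
    """
    config = config or EvalConfig()
    confs, corrects = [], []
    for p, y in zip(probmaps, gts):
        p = np.asarray(p, dtype=np.float64)
        conf = p.max(axis=0)
        pred = p.argmax(axis=0)
        confs.append(conf.ravel())
        corrects.append((pred == np.asarray(y)).ravel())
    if not confs:
        raise ValueError("no slices supplied to ECE")
    conf = np.concatenate(confs)
    correct = np.concatenate(corrects).astype(np.float64)
    edges = np.linspace(0.0, 1.0, config.ece_bins + 1)
    # right-inclusive top bin
    bin_idx = np.clip(np.digitize(conf, edges[1:-1], right=False), 0,
                      config.ece_bins - 1)
    n = conf.size
    ece = 0.0
    for b in range(config.ece_bins):
        sel = bin_idx == b
        nb = int(sel.sum())
        if nb == 0:
            continue
        ece += nb / n * abs(correct[sel].mean() - conf[sel].mean())
    return float(ece)


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Pooled-SD Cohen's d between two groups from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    if pooled_var <= 0:
        return float("nan")
    return (mean1 - mean2) / float(np.sqrt(pooled_var))


def stratify_summary(
    records: pd.DataFrame,
    metrics: Sequence[str],
    group_key: str | None = None,
    quartile_of: str | None = None,
    flag_key: str | None = None,
) -> pd.DataFrame:
    """Per-group mean/sd/count table for the requested metrics.

    Exactly one grouping mode applies: an existing categorical column
    (``group_key``), quartiles Q1-Q4 computed from a metric column
    (``quartile_of``), or a boolean flag column (``flag_key``) which also
    reports the flagged-minus-clean difference Δ per metric.  Empty
    groups are omitted.
    """
    modes = [m for m in (group_key, quartile_of, flag_key) if m is not None]
    if len(modes) != 1:
        raise ValueError("specify exactly one of group_key/quartile_of/flag_key")
    df = records.copy()
    if quartile_of is not None:
        df["_group"] = pd.qcut(
            df[quartile_of], 4, labels=["Q1", "Q2", "Q3", "Q4"], duplicates="drop"
        )
    elif flag_key is not None:
        df["_group"] = np.where(df[flag_key].astype(bool), "flagged", "clean")
    else:
        df["_group"] = df[group_key]
    grouped = df.groupby("_group", observed=True)
    rows = []
    for name, g in grouped:
        row: dict[str, object] = {"group": name, "n": len(g)}
        for m in metrics:
            row[f"{m}_mean"] = g[m].mean()
            row[f"{m}_sd"] = g[m].std(ddof=1) if len(g) > 1 else 0.0
        rows.append(row)
    out = pd.DataFrame(rows)
    if flag_key is not None and {"flagged", "clean"} <= set(out["group"]):
        flagged = out.loc[out["group"] == "flagged"].iloc[0]
        clean = out.loc[out["group"] == "clean"].iloc[0]
        delta = {"group": "delta", "n": int(flagged["n"])}
        for m in metrics:
            delta[f"{m}_mean"] = flagged[f"{m}_mean"] - clean[f"{m}_mean"]
            delta[f"{m}_sd"] = float("nan")
        out = pd.concat([out, pd.DataFrame([delta])], ignore_index=True)
    return out


def macro_summary(
    per_slice: Sequence[Mapping[str, Mapping[str, float]]],
) -> dict[str, dict[str, float]]:
    """Macro per-slice averages of dice/iou tables, ignoring NaN entries."""
    classes: dict[str, dict[str, list[float]]] = {}
    for table in per_slice:
        for name, vals in table.items():
            bucket = classes.setdefault(name, {"dice": [], "iou": []})
            for key in ("dice", "iou"):
                if not np.isnan(vals[key]):
                    bucket[key].append(vals[key])
    out = {
        name: {k: float(np.mean(v)) if v else float("nan") for k, v in b.items()}
        for name, b in classes.items()
    }
    out["macro"] = {
        k: float(np.mean([out[c][k] for c in classes if not np.isnan(out[c][k])]))
        for k in ("dice", "iou")
    }
    return out
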