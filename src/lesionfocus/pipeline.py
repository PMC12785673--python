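"""End-to-end orchestration: synthesize → train → predict → postprocess →
evaluate → explain → XAI metrics → regimes → report.

The pipeline mirrors the full study workflow at a configurable scale so
the whole chain can run on a desktop CPU against synthetic eyes.  Every
stage is also callable on its own; `run_pipeline` wires them together,
seeds all randomness from one root seed, and writes a run manifest with
content hashes of the artifacts it produced.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .attribution import (AttributionConfig, gradient_shap,
                          postprocess_attribution)
from .evaluation import EvalConfig, dice_iou_per_slice, expected_calibration_error, hd95, macro_summary
from .image_io import LABELS, LESION_CLASSES, encode_palette_mask, split_by_patient
from .model import ModelSpec
from .postprocess import PostprocessConfig, postprocess_volume
from .synthetic import FixtureSpec, LesionParams, make_synthetic_dataset
from .training import TrainConfig, predict_volume, train_model, _group_volumes
from .xai import AttributionCase, build_xai_table
from .regimes import fit_regimes

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


def _desk_fixture(seed: int) -> FixtureSpec:
    """64x64 fixture with lesion sizes scaled to the small raster."""
    return FixtureSpec(
        image_size=(64, 64),
        n_slices=20,
        lesion_params={
            "hole": LesionParams(count=1, radius=(4.0, 8.0)),
            "cyst": LesionParams(count=1, radius=(3.0, 6.0)),
        },
        seed=seed,
    )


@dataclass
class PipelineConfig:
    """Desk-scale defaults: 2 eyes × 20 slices at 64×64, a short reduced
    training run, and reduced attribution sampling."""

    n_eyes: int = 2
    seed: int = 42
    fixture: FixtureSpec | None = None
    model: ModelSpec = field(default_factory=lambda: ModelSpec())
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        lr=3e-3, batch_size=1, warmup_steps=10, max_epochs=5,
        es_warmup_epochs=5))
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    attribution: AttributionConfig = field(default_factory=lambda: AttributionConfig(
        n_samples=8, n_baselines=4))
    explain_max_slices: int = 6
    taus: tuple[int, ...] = (5, 10, 20)
    regime_seed: int = 42


def _retina_domain(mask: np.ndarray) -> np.ndarray:
    return np.isin(mask, [LABELS["retina"], LABELS["hole"], LABELS["cyst"]])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def explain_records(model, eyes: dict, config: PipelineConfig,
                    mode: str, pred_volumes: dict) -> list[AttributionCase]:
    """GradientSHAP cases for eligible (slice, class) pairs of one mode."""
    cases: list[AttributionCase] = []
    n_done = 0
    from .image_io import build_stack_25d, zscore_normalize

    for eye_id, recs in eyes.items():
        volume = [r.image for r in recs]
        for i, rec in enumerate(recs):
            if n_done >= config.explain_max_slices:
                break
            ref_mask = rec.mask if mode == "gt" else pred_volumes[eye_id][i]
            lesions_here = [c for c in LESION_CLASSES
                            if (ref_mask == LABELS[c]).any()]
            if not lesions_here:
                continue
            stack = zscore_normalize(build_stack_25d(volume, i))
            retina = _retina_domain(ref_mask)
            for cls in lesions_here:
                lesion = ref_mask == LABELS[cls]
                oracle = lambda pt, c=LABELS[cls], m=lesion: (
                    model.input_gradient(pt, c, m))
                tag = zlib.crc32(f"{eye_id}/{i}/{cls}".encode())
                rng = np.random.default_rng(
                    (config.seed * 1_000_003 + tag) % 2**31)
                raw = gradient_shap(oracle, stack, config.attribution, rng=rng)
                res = postprocess_attribution(raw, retina, config.attribution)
                cases.append(AttributionCase(
                    slice_id=f"{eye_id}_{i:03d}", lesion_class=cls,
                    mode=mode, processed=res.processed, lesion_mask=lesion,
                    domain_mask=retina, pam=res.pam))
            n_done += 1
    return cases


def run_pipeline(config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Execute the full synthetic pipeline; returns the run manifest.

    The manifest carries the config snapshot, seeds, package version,
    per-stage outputs (metric summaries, XAI table path, regime
    prevalences) and artifact hashes.
    """
    config = config or PipelineConfig()
    t0 = time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    fixture = config.fixture or _desk_fixture(config.seed)
    records = make_synthetic_dataset(config.n_eyes, fixture)
    eyes = _group_volumes(records)

    # leakage-safe split; tiny smoke runs fall back to one train / one val eye
    patient_ids = {r.patient_id for r in records}
    if len(patient_ids) >= 3:
        partition = split_by_patient(records, seed=config.seed)
    else:
        eye_ids = sorted(eyes)
        partition = {"train": eye_ids[:1], "val": eye_ids[1:], "test": eye_ids[1:]}
    train_recs = [r for r in records if r.eye_id in partition["train"]]
    val_recs = [r for r in records if r.eye_id in partition["val"]]
    eval_recs = [r for r in records if r.eye_id in partition["test"]] or val_recs

    model, history = train_model(train_recs, val_recs, config.model, config.train)

    # inference + post-processing on the evaluation eyes
    eval_eyes = _group_volumes(eval_recs)
    prob_volumes: dict[str, list[np.ndarray]] = {}
    pred_volumes: dict[str, list[np.ndarray]] = {}
    for eye_id, recs in eval_eyes.items():
        probs = predict_volume(model, [r.image for r in recs], tta=True)
        prob_volumes[eye_id] = probs
        labels = [p.argmax(axis=0).astype(np.int64) for p in probs]
        pred_volumes[eye_id] = postprocess_volume(labels, config.postprocess)

    # evaluation
    eval_cfg = EvalConfig()
    per_slice, hd95_values, ece_probs, ece_gts = [], [], [], []
    for eye_id, recs in eval_eyes.items():
        for i, rec in enumerate(recs):
            pred = pred_volumes[eye_id][i]
            per_slice.append(dice_iou_per_slice(pred, rec.mask, eval_cfg))
            has_lesion = False
            for cls in LESION_CLASSES:
                a, b = pred == LABELS[cls], rec.mask == LABELS[cls]
                if b.any():
                    has_lesion = True
                if a.any() and b.any():
                    hd95_values.append(hd95(a, b))
            if has_lesion:
                ece_probs.append(prob_volumes[eye_id][i])
                ece_gts.append(rec.mask)
    metrics = macro_summary(per_slice)
    metrics["hd95_lesion_mean"] = (float(np.nanmean(hd95_values))
                                   if hd95_values else float("nan"))
    metrics["ece"] = (expected_calibration_error(ece_probs, ece_gts, eval_cfg)
                      if ece_probs else float("nan"))

    # explanation + XAI table, both modes
    cases = []
    for mode in ("gt", "pred"):
        cases.extend(explain_records(model, eval_eyes, config, mode,
                                     pred_volumes))
    xai_table = build_xai_table(cases, taus=config.taus)

    # regimes per mode (when enough rows)
    regimes_out = {}
    for mode in ("gt", "pred"):
        sub = xai_table[xai_table["mode"] == mode].dropna(
            subset=["FC"])
        k = min(3, len(sub))
        if k >= 2:
            try:
                rm = fit_regimes(sub, k=k, seed=config.regime_seed)
                regimes_out[mode] = {"prevalence": rm.prevalence,
                                     "n": int(len(sub))}
            except ValueError:
                regimes_out[mode] = {"prevalence": {}, "n": int(len(sub))}

    manifest = {
        "package_version": _pkg_version,
        "seed": config.seed,
        "config": {
            "n_eyes": config.n_eyes,
            "image_size": list(fixture.image_size),
            "n_slices": fixture.n_slices,
            "train": {k: v for k, v in asdict(config.train).items()
                      if not isinstance(v, dict)},
        },
        "partition": partition,
        "history": history,
        "metrics": metrics,
        "n_xai_records": int(len(xai_table)),
        "regimes": regimes_out,
        "runtime_s": round(time.time() - t0, 1),
    }

    if out is not None:
        xai_table.to_csv(out / "xai.csv", index=False)
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, default=float)
        render_report(out / "report", xai_table, cases, eval_eyes)
        artifacts = {}
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.suffix in {".csv", ".json", ".png"}:
                artifacts[str(p.relative_to(out))] = _sha256(p)
        manifest["artifacts"] = artifacts
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest


def render_report(report_dir: str | Path, xai_table: pd.DataFrame,
                  cases: list[AttributionCase], eyes: dict,
                  max_cases: int = 4) -> list[Path]:
    """Per-case PNG triptychs (mask | top-10% overlay | heatmap) + tables.

    Overlay convention: green = lesion mask, red = top-10% attribution,
    yellow = their intersection.
    """
    from imageio.v3 import imwrite
    from .xai import top_tau_mask

    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    xai_table.to_csv(report_dir / "xai_summary.csv", index=False)
    written = []
    for case in cases[:max_cases]:
        lesion = np.asarray(case.lesion_mask, dtype=bool)
        top10 = top_tau_mask(case.processed, 10, case.domain_mask).mask
        h, w = lesion.shape
        overlay = np.zeros((h, w, 3), dtype=np.uint8)
        overlay[lesion] = (0, 200, 0)
        overlay[top10] = (220, 0, 0)
        overlay[lesion & top10] = (230, 230, 0)
        heat = (255 * np.clip(case.processed, 0, 1)).astype(np.uint8)
        heatmap = np.stack([heat, (0.4 * heat).astype(np.uint8),
                            255 - heat], axis=-1)
        eye_id, idx = case.slice_id.rsplit("_", 1)
        mask_rgb = np.zeros((h, w, 3), dtype=np.uint8)
        if eye_id in eyes:
            rec = eyes[eye_id][int(idx)]
            mask_rgb = encode_palette_mask(rec.mask)
        trip = np.concatenate([mask_rgb, overlay, heatmap], axis=1)
        path = report_dir / f"{case.slice_id}_{case.lesion_class}_{case.mode}.png"
        imwrite(path, trip)
        written.append(path)
    return written
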