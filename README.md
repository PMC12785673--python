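# lesionfocus

Quantitative explainability for OCT macular-hole and cyst segmentation.

Segmentation masks say *where* a model thinks a lesion is, but not *why* —
nor whether the prediction deserves trust. `lesionfocus` implements a
full pipeline for retinal OCT B-scan volumes that (a) segments macular
holes and intraretinal cysts with a 2.5D U-Net and (b) turns GradientSHAP
attribution heatmaps into **numbers**: coverage and leakage of the
attribution mass with respect to the lesion, spatial focus statistics,
and data-driven *explanation regimes* that work as case-level
reliability flags. It is written for researchers in medical image
analysis who want attribution–mask agreement as a measurable quantity
rather than a picture.

Everything runs on CPU: the U-Net (training, inference, and the gradient
oracle behind GradientSHAP) is implemented in NumPy with hand-derived
backprop, and all experiments use synthetic OCT-like fixtures with known
ground truth, so the whole chain is testable without any data download.

## The metrics

Given a processed attribution map and a lesion mask `L`, pixels inside
the ranking domain (the retina, by default) are ranked by attribution
magnitude and the top τ% form a binary mask `A_τ`:

```
APIL_τ = |A_τ ∩ L| / |A_τ|            attribution precision in lesion
ARIL_τ = |A_τ ∩ L| / |L|              attribution recall in lesion
Dice_τ = 2|A_τ ∩ L| / (|A_τ| + |L|)
Leak_τ = 1 − APIL_τ                   attribution leakage
```

Spatial focus: `COM-dist` is the Euclidean distance between the
attribution-weighted centroid and the lesion centroid (px);
`nCOM = COM-dist / √LP` normalizes by lesion size; `FP = −nCOM` (focus
proximity), `FC = APIL5 / APIL20` (focus concentration), `PAM` is the
total clipped positive attribution mass, and `LP` the lesion pixel
count. Metrics are computed in GT mode (against the clinical mask) and
Pred mode (against the model's own post-processed segmentation),
present-only.

The records are standardized, projected on three principal components,
and clustered with k-means (k = 3) in the PC1–PC2 plane; clusters are
named by a deterministic rule into **retina-dominant** (diffuse
intra-retinal focus near the lesion), **peri-lesion** (ring around the
lesion rim), and **narrow-coverage** (small off-lesion focus — the
"review this case" signal).

## The segmentation model

A 2.5D UNet-48: each center slice is stacked with its two neighbors
(reflect-padded) into a 3-channel input, z-scored per channel; encoder
widths 48→96→192→384, Group Normalization (8 groups), bilinear
upsampling with skip concatenation, 1×1 head to 5 classes (background,
retina, hole, cyst, choroid) — 4,383,173 trainable parameters. Training
minimizes `L = (2/3)·L_Dice + (1/3)·L_FT` where `L_FT` is the
Focal–Tversky loss (α = 0.7, β = 0.3, γ = 1.5) with inverse-frequency
class weights, AdamW, cosine schedule with warm-up, light augmentations,
early stopping on validation hole Dice, and horizontal-flip TTA at
inference. Predictions pass an anatomy-constrained cleanup
(intraretinal constraint, per-class morphology, ±1-slice majority vote,
area-proportional fragment suppression).

## Worked example

```python
import numpy as np
from lesionfocus import (FixtureSpec, LesionParams, make_synthetic_volume,
                         make_synthetic_attribution, build_xai_table,
                         AttributionCase, fit_regimes, make_regime_cases)
from lesionfocus.image_io import LABELS

# one synthetic eye with a small macular hole
spec = FixtureSpec(image_size=(64, 64), n_slices=1,
                   lesion_params={"hole": LesionParams(1, (3.0, 5.0))}, seed=5)
_, masks, _ = make_synthetic_volume(spec)
mask = masks[0]
heat = make_synthetic_attribution(mask, "hole", "peri_lesion", seed=1)
domain = np.isin(mask, [LABELS["retina"], LABELS["hole"], LABELS["cyst"]])
case = AttributionCase("eye000_000", "hole", "gt", heat,
                       mask == LABELS["hole"], domain)
print(build_xai_table([case])[["APIL20", "ARIL20", "Leak20", "COM_dist", "LP"]]
      .round(3).to_string(index=False))

# regime analysis on 300 planted records
cases, planted = make_regime_cases(100, seed=11)
model = fit_regimes(build_xai_table(cases), seed=3)
print(model.prevalence)
```

prints

```
 APIL20  ARIL20  Leak20  COM_dist   LP
  0.257    0.72   0.743     2.419 93.0
{'retina_dominant': 36.3, 'peri_lesion': 33.6, 'narrow_coverage': 30.1}
```

i.e. for this ring-focused case, 25.7% of the top-20% attribution mass
lies inside the 93-px lesion (leakage 0.743) while 72% of the lesion is
covered, with the attribution center ~2.4 px from the lesion center;
over the planted population the three regimes are recovered in roughly
equal shares, matching how they were generated.

The full chain (synthesize → train → predict → postprocess → evaluate →
explain → xai-metrics → regimes → report) is available both as a library
call (`lesionfocus.run_pipeline`) and as a CLI:

```bash
lesionfocus run --seed 42 --out runs/demo     # desk-scale end-to-end run
lesionfocus --help                            # individual stages
```

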