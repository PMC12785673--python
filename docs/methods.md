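# Methods

This note documents the models, conventions and numerical choices behind
`lesionfocus`, and what the synthetic fixtures do and do not establish.

## Data model

Masks are 5-class integer rasters (0 background, 1 retina, 2 macular
hole, 3 intraretinal cyst, 4 choroid), decoded from RGB palette images
by nearest-color matching (saturated primaries: red = hole, blue = cyst,
green = retina, yellow = choroid, black = background; Euclidean RGB
tolerance 30, out-of-gamut pixels fall to background and are counted).
Nearest-color ties resolve by the priority hole > cyst > retina >
choroid > background — when in doubt, lesion recall wins. Coordinates
are 0-based, row-major, origin top-left; areas are pixel counts and
distances pixel units.

The network input is a 2.5D stack: slices (i−1, i, i+1) of an eye
volume, reflect-padded at volume ends, z-scored per channel (population
SD, guard ε = 1e-8 maps constant channels to zero). Images resize
bilinearly, masks nearest-neighbor (labels can disappear, never appear).

Train/validation/test splitting is per patient and stage-balanced:
patients are grouped by hole stage, shuffled under the run seed, and
dealt to 70/15/15 subsets by largest-remainder rounding. All eyes and
slices of one patient land in one subset.

## Segmentation network and training

UNet-48 in NumPy: DoubleConv blocks (two 3×3 convolutions, each followed
by GroupNorm with 8 groups and ReLU), encoder widths 48→96→192→384 with
2×2 max pooling, decoder with 2× bilinear upsampling + skip
concatenation, 1×1 convolution to 5 channels, channel softmax. Spatial
sizes must be divisible by 8 (three pooling stages), which admits
desk-scale 64×64 inputs alongside the native 512×512. Forward, backward
and input gradients are explicit NumPy code; backprop is verified
against central finite differences (float64, ≤ 1e-4 relative on a
directional derivative through the whole network).

The loss is `λ·L_Dice + (1−λ)·L_FT` with λ = 2/3. Per class,
`Dice(c) = (2Σyp + ε)/(Σy + Σp + ε)` and the Tversky index
`TI(c) = (Σyp + ε)/(Σyp + 0.7·Σ(1−y)p + 0.3·Σy(1−p) + ε)` with
`L_FT = mean_c w_c (1−TI(c))^1.5`. The smoothing constant ε = 1e-6 sits
in **both** numerator and denominator: an absent class then scores a
neutral 1 (zero loss, and — unlike denominator-only smoothing — a
nonvanishing gradient against false positives of absent classes), and a
perfect prediction reaches exactly zero loss. Class weights are inverse
pixel frequencies on the training set (frequency floored at 1e-4 so
absent classes cannot dominate), normalized to mean 1, and multiply both
loss terms symmetrically.

Optimization: AdamW (lr 1.5e-4, weight decay 1e-2), cosine decay with
linear warm-up (~800 steps at full scale), global gradient-norm clip at
1.0, batch 3, ≤ 24 epochs, early stopping on validation hole Dice
(8 warm-up epochs, patience 5, an epoch counts as improved when it
reaches best + 0.002). Augmentations: z-jitter (the 3-slice window
re-centers on a neighbor slice with p = 0.20 — applied where the volume
is available, at stack-assembly time), channel dropout (one of the three
slice channels zeroed, p = 0.10), speckle noise (σ = 0.02, p = 0.50),
small affine transforms (rotation ≤ 5°, translation ≤ 3%, scale
0.97–1.03, shear ≤ 1.5°; stack bilinear, mask nearest), horizontal flip
(p = 0.50). Inference averages the plain output with the unflipped
output of the flipped input (flip TTA), which preserves the simplex.

The desk-scale smoke configuration — 2 eyes × 20 slices at 64×64,
batch 1, lr 3e-3, 10-step warm-up, ≤ 5 epochs, 8 GradientSHAP samples
over 4 baselines, ≤ 6 explained slices per mode — is the package's
reduced study condition for end-to-end runs; it reaches validation hole
Dice ≥ 0.9 in well under a minute of training and keeps the whole
pipeline around 1–2 minutes on one CPU core.

## Post-processing

Stage order: intraretinal constraint → morphology → ±1-slice consistency
→ fragment suppression. The "filled retina" region is the per-column
span between the first and last retina-class pixel, with two guards:
columns whose retina was entirely replaced by a full-thickness hole
inherit the span interpolated from the nearest retina-bearing columns,
and narrow notches where a lesion ate the boundary rows are bridged by a
1-D closing of the column envelopes (window max(5, W/16) columns).
Morphology uses a radius-1 disk: opening+closing for holes,
closing-only for cysts; pixels added by closing are admitted only inside
the filled retina, so cleanup never creates extra-retinal lesion tissue.
The slice-consistency vote is per pixel (kept iff lesion in ≥ 2 of the
reflect-padded {i−1, i, i+1}); component-level voting was considered and
rejected as a less literal reading of a majority rule. Fragment
thresholds are fractions of the image area (hole 2e-4, cyst 1e-4 —
a 512×512 threshold of ~52 / ~26 px), with 8-connected components.

## Evaluation

Hard-mask Dice/IoU per slice with ε = 1e-6 dual smoothing (absent–absent
→ neutral 1) or present-only NaN; macro averages exclude background by
default (a with-background variant exists). HD95 is the max of the two
directed 95th-percentile boundary distances; boundaries are pixels with
a 4-neighbor outside the mask, percentiles use linear interpolation, and
empty masks yield an undefined marker excluded from means. ECE pools
pixels of lesion-containing slices, bins max-class confidence into 15
equal-width bins, and averages |accuracy − confidence| weighted by bin
occupancy. Cohen's d uses the pooled SD. Stratified summaries support
categorical keys, metric quartiles (Q1–Q4), and flagged-vs-clean deltas.

## Attribution

GradientSHAP: n = 128 path samples over 16 baselines (desk scale: 8/4);
each sample evaluates the model gradient at `b + α(x−b)`, α ~ U(0,1),
weights it by `(x−b)`, and channels are summed into one 2D map.
Baselines are Gaussian-blurred copies of the input (σ = 0.8) plus noise
scaled to the per-channel SD — intensity statistics are kept, edges
attenuated, avoiding the spurious contours of black baselines. The
explained scalar is the sum of the target class's pre-softmax logits
over the reference lesion pixels (clinical mask in GT mode, model
segmentation in Pred mode); this lesion-summed class score is the
standard scalarization for dense segmentation outputs, and alternatives
plug in through the gradient-oracle interface.

Post-processing: negatives zeroed; strictly positive values clipped to
their [0.1, 99.9] percentile range (zeros stay zero — saturating zeros
up to the low percentile would paint the background with spurious
mass); suppression outside the retina (GT retina in GT mode, predicted
retina in Pred mode); division by the post-clip maximum. PAM is
recorded after clipping and suppression, before max-normalization.

## XAI metrics

The top-τ ranking domain is the retina-restricted processed map — the
anatomically meaningful competition is among retinal pixels; a
full-image domain is available via the domain-mask argument and each
record carries its mode. k = round(τ%·|domain|) with
round-half-away-from-zero; ties at the cutoff break by row-major order,
making selections deterministic. COM-dist uses the attribution-weighted
centroid of the full processed map, not the binary top-τ mask, since the
attribution center is a property of the map. τ is expressed in percent
(5, 10, 20). Undefined values are explicit NaN markers: empty top-τ
masks, FC when APIL20 = 0, COM-dist at zero mass; summaries skip them.
Invariants (APIL + Leak = 1, the Dice harmonic identity, ARIL
monotonicity in τ, FP = −nCOM) are enforced by tests on every emitted
table.

## Regime analysis

Features APIL20, Dice20, Leak20, ARIL20, FP, LP, PAM, FC, COM-dist are
standardized (population SD, constants guarded to zero, FC-undefined
rows dropped with a count), reduced by 3-component PCA (sign convention:
the largest-magnitude loading of each component is positive), and
clustered by k-means (k = 3, k-means++ init, 10 restarts, fixed seed) in
PC1–PC2. Cluster naming is a deterministic rule on cluster means:
highest APIL20 → peri-lesion; of the rest, higher ARIL20 →
retina-dominant (ties to the lower COM-dist); remainder →
narrow-coverage (absent with two non-empty clusters). GT and Pred modes
are clustered separately, and per class where sample sizes allow.

## Synthetic fixtures

Volumes: a sinusoidally curved bright retina band (fractions 0.30–0.62
of height) over a choroid band, dark elliptical lesions strictly inside
the band (fragmentation = several small pieces), per-label intensities
plus a mild depth gradient and Gaussian noise (σ = 0.03). Lesion
geometry is constant across the slices of an eye — adjacent B-scans see
the same lesion — which makes the ±1-slice consistency filter exact on
clean masks. A synthetic "stage" is the quartile of per-eye lesion
area; it exists to exercise the stage-balanced split, not to model
clinical staging.

Probability maps are exact Bayes posteriors of a Gaussian
observation model under the empirical class prior, hence calibrated by
construction at temperature 1; dividing logits by T > 1 degrades
calibration monotonically. This gives the ECE machinery a ground truth.

Regime heatmaps are parametric: retina-dominant is a broad Gaussian
(σ = 0.75 of the radius a top-20% selection would fill) centered just
off the lesion with the lesion response damped to 0.75; peri-lesion is
a boundary-hugging ring (width 0.8 lesion radii) with a cos-shaped
angular asymmetry that drags the center of mass outward;
narrow-coverage is a small blob displaced 1.5–2.5 lesion radii with the
lesion itself zeroed. A uniform noise floor (amplitude 0.02) fills the
rest of the domain. Lesion sizes are regime-typical (narrow-coverage
1.5–2.5 px radius, retina-dominant 2–3.5, peri-lesion 4–6.5 at 64 px),
mirroring the real-data association between regime and lesion size.
Footprints scale with the domain, so the phenomenology is
resolution-independent.

What the fixtures do **not** emulate: OCT speckle physics,
device-specific noise, annotation subjectivity, anatomical layer
substructure, or attribution maps of a real trained network on real
pathology. Passing tests therefore establish the correctness of the
metric, clustering and training machinery under known ground truth —
not clinical performance.

## Problem sizes

The test suite and the end-to-end runs use 64×64 rasters, 2-eye volumes
of 20 slices, 300-record regime populations, and reduced training and
attribution sampling as described above; these are the package's chosen
desk-scale study conditions. Full-scale defaults (512×512, 128/16
attribution sampling, lr 1.5e-4 with 800-step warm-up, 24 epochs) remain
the library defaults for real data.

## Known limitations

* The NumPy U-Net is single-threaded BLAS-bound; full-scale 512×512
  training is possible but slow — the implementation targets method
  fidelity and testability, not throughput.
* k-means with k = 3 can split a genuinely two-regime population into
  three clusters; the labeling rule tolerates it, but prevalences near
  zero should be read as "regime absent".
* The percentile-clipping and ranking-domain conventions follow one
  consistent reading of common practice; both are configurable, and the
  active convention is recorded in outputs.
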