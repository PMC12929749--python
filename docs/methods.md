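# Methods

## Problem and approach

Retropharyngeal edema (RPE) appears on fat-suppressed T2-weighted neck MRI
as one contiguous band of high signal in the retropharyngeal space — thin
anteroposteriorly, wide left–right, extended across many axial slices. Its
volume is a candidate quantitative marker of disease severity, which makes
automated segmentation worthwhile. The segmentation problem is extreme
needle-in-haystack: the lesion occupies roughly 0.0023–0.31% of the voxels
of a volume of 26–60 axial slices at ~0.5 mm in-plane / ~4.8 mm
between-slice spacing. A U-Net trained directly on whole slices fails to
converge in this regime, so the pipeline is coarse-to-fine:

1. **Slice classification.** Every coronal, sagittal, and axial slice is
   resized to 128×128, min–max normalized with the whole-volume intensity
   extrema, and scored by a per-view encoder CNN (four paired-convolution +
   max-pool stages, then four dense layers; 565,873 parameters at reference
   widths). Scores along each view form an ordered series; a centered
   moving average (window 3 by default) suppresses isolated errors, and the
   series is binarized at the cutpoint maximizing Youden's
   J = sensitivity + specificity − 1 over the *training-set* predictions.
2. **Bounding region.** A voxel (z, y, x) is positive iff its axial slice
   z, coronal slice y, and sagittal slice x were all classified positive —
   the product of the three positive index sets. Gapped index runs are kept
   as a set product, not bridged into a contiguous box, following the
   conjunction definition literally.
3. **Tile segmentation.** 64×64 tiles are sampled on a stride-32 lattice
   (one edge-clamped square per axis when the slice size is not a lattice
   multiple) over every slice meeting the region. A tile is kept iff it
   contains at least ⅓ of the region's cross-section on that slice or at
   least an absolute minimum count of region pixels (1,000 at the native
   288–640 px scale). Coronal/sagittal slices of volumes with fewer than 64
   axial slices are first stretched along z to 64 rows (linear for
   intensities, nearest-neighbor for masks) and the stretch is inverted
   after reassembly. A per-view U-Net (two-level encoder–decoder with two
   skip concatenations; 116,753 parameters at reference widths) segments
   the tiles; predictions are inserted into a zero-initialized 3D array,
   overlaps fused by per-voxel mean (max is available), and the map is
   binarized at 0.5.
4. **2.5D fusion.** The fourth mask is the per-voxel 2-of-3 majority vote
   of the coronal, sagittal, and axial masks.

Training: classifier — binary cross-entropy, Adam with learning rate
0.001, 5 epochs; U-Net — soft Dice loss 1 − (2Σpq + ε)/(Σp + Σq + ε) with
ε = 1, Adam 0.001, 30 epochs. Evaluation is patient-wise: accuracy,
sensitivity, specificity, precision, AUROC per view for classification;
Dice 2|X∩Y|/(|X|+|Y|) per view and for the 2.5D mask; and Pearson r, mean
absolute error (mm³), and mean relative error (%) between true and
predicted (axial-mask) volumes. Cross-validation is five-fold over
lesion-positive patients, split by seeded permutation and round-robin
assignment; training and test id sets are asserted disjoint every fold.

## Network implementation

No deep-learning framework is used; the two CNNs run on a small numpy layer
stack (`rpeseg._nn`) with hand-derived backpropagation: stride-1
convolutions (valid and same padding) computed tap-by-tap as BLAS matmuls,
2×2 max pooling (floor semantics, odd trailing row/col cropped), 2×2
stride-2 transposed convolutions, dense layers, ReLU, sigmoid, and Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e−7). Weights are Glorot-uniform from
per-layer generators spawned off one seed, so a rebuild with the same seed
is bit-identical and single-threaded runs reproduce exactly. Gradients are
verified against central differences in the test suite on the smooth
layers; ReLU layers are validated by loss-descent tests (finite differences
are unreliable at the kink).

Architectural details were resolved against the two reference parameter
totals, which both builds reproduce exactly:

* classifier: 3×3 valid-padding convolutions at widths 16/16/32/32/64/64/
  128/128, pooling to 4×4×128, dense 128/64/32/1 → 565,873;
* U-Net: 3×3 same-padding convolutions at widths 16/32/64, transposed-conv
  upsampling, skip concatenations at both levels, 1×1 sigmoid head
  → 116,753.

## Phantom generator

Real patient MRI is not distributable, so the package ships a generator
that reproduces the *geometry and sparsity* of the clinical cohort, not MR
physics. Per phantom: slice count uniform on [26, 60]; slice gap
dz ~ N(4.80, 0.228) clipped to [3.98, 5.96] mm; in-plane spacing
dy = dx ~ N(0.528, 0.149) clipped to [0.375, 0.694] mm. The lesion is the
top-k voxel set of a sum of three overlapping anisotropic Gaussian blobs
(physical extent ratio y : x : z = 1 : 3 : 4, centered near the anterior
midline at ~40% of the AP axis), with k chosen so the mask volume matches a
target drawn log-uniformly from 234–31,490 mm³ scaled by
(in_plane_size/512)²; the largest 26-connected component is kept. Because
slice count, spacing, and volume are sampled independently, raw draws can
leave the clinical positive-fraction band [0.0023%, 0.31%]; k is therefore
clamped into that band with a 10% interior margin, which keeps ≥95% of
default-spec phantoms inside it. The background is a fixed axial cartoon —
dark airway column, moderate vertebral body, brighter canal, paraspinal
muscle slab — modulated mildly along z, plus additive Gaussian noise
(σ = 0.05). Lesion intensity is `lesion_contrast` × the mean background
level (default contrast 2.5), with a smooth ±15% within-lesion profile, so
the lesion exceeds the brightest background structure and a plain intensity
threshold inside the true bounding box reaches Dice > 0.7: the task is
learnable by construction.

What the phantoms deliberately lack: scanner bias fields, Dixon fat/water
chemistry, coil profiles, anatomic variability, multi-focal or
ill-defined lesions, and pediatric scaling. Passing the desk-scale
experiment therefore demonstrates that the *pipeline mechanics* (region
construction, tile bookkeeping, training loops, fusion, evaluation) work
end-to-end on data with the right geometry and sparsity — it is not
evidence about performance on clinical images.

## Desk-scale experiment defaults

The default `ExperimentConfig` is sized for minutes-scale runs on one CPU:
25 phantoms at 128² in-plane with lesion contrast 3.0, five folds,
width-reduced networks (classifier convolutions 4/8/16/32 with dense
32/16/8/1; U-Net 4/8/16), balanced training-slice subsampling (all positive
slices plus an equal number of negatives, at most 320 slices per view per
fold), Youden thresholds estimated from the full score series of 6 training
patients, U-Net tiles harvested from 6 training patients and capped at 128
per view, and the absolute tile-selection minimum scaled to
1000 × (128/512)² = 62 region pixels. Reference-width networks remain the
`build_classifier`/`build_unet` defaults. Epochs, learning rates, losses,
the stride-32/64×64 tile grammar, the ⅓-surface rule, the moving-average +
Youden post-processing, and the 2-of-3 vote are unchanged from the
full-scale method.

## Numerical choices and edge rules

* Normalization scope is per *volume* (not per slice): per-slice min–max
  would erase the between-slice brightness cue that marks edematous
  slices. Tiles are cut from the same per-volume-normalized grid.
* Resizes: bilinear for intensities, nearest-neighbor wherever masks are
  resampled (masks must stay binary). Axial stretching uses center-aligned
  coordinates; nearest-neighbor round trips are exact at integer factors.
* Moving average: centered, window must be odd, shrinking at the series
  ends; window 1 is the identity.
* Youden candidates: midpoints between adjacent sorted unique scores plus
  one candidate below the minimum and one above the maximum; the decision
  rule is score ≥ threshold (ties positive); equal-J ties break toward the
  lower threshold. Constant volumes (max = min) normalize to all-zero.
* Dice with an empty ground truth raises an error (only lesion-positive
  patients are evaluated); an empty *prediction* scores 0.
* Accuracy is (TP+TN)/(TP+FN+FP+TN); a printed variant omitting FP exists
  in circulation and is available as `accuracy_formula="as_printed"` for
  audit only. Metrics with zero denominators are marked NaN and excluded
  from cohort means, not imputed.
* AUROC uses the rank (Mann–Whitney) formulation with ties counted ½, and
  is computed on smoothed scores by default (`auroc_scores="raw"`
  available).
* Per-view masks are binarized at 0.5 *before* the majority vote.

## Known limitations

* The numpy training loop is single-threaded BLAS-bound; reference-width
  training at full clinical resolution is possible but slow — the desk
  widths exist for that reason.
* The ⅓-surface rule is interpreted per slice (region pixels within the
  square vs on the whole slice cross-section), and the 1,000-pixel
  absolute rule counts 2D region pixels on the slice; other readings of
  both rules exist.
* Whether five-fold cross-validation should be repeated five times is
  ambiguous in the source description; the default runs each fold once
  (`repeats` raises it).
* The phantom intensity model is a cartoon; lesion contrast on real
  fat-suppressed T2 is not claimed or modeled from data.
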