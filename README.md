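# rpeseg

Coarse-to-fine deep-learning segmentation of **retropharyngeal edema
(RPE)** in anisotropic 3D neck MRI, with a synthetic phantom benchmark so
the entire method can be trained, tested, and audited without patient
data.

RPE is a reactive fluid pattern in the retropharyngeal space seen on
fat-suppressed T2-weighted MRI in acute neck infections; its volume is a
candidate quantitative severity marker. Segmenting it automatically is
hard because the lesion occupies only ~0.002–0.3% of the voxels of a
strongly anisotropic volume (~0.5 mm in-plane, ~4.8 mm between axial
slices). This package implements the full coarse-to-fine pipeline:

1. **Slice classification** — per-view encoder CNNs (axial, coronal,
   sagittal) score every 128×128-normalized slice; score series are
   smoothed with a centered moving average and binarized at the Youden
   cutpoint (max J = sensitivity + specificity − 1) fixed on training-set
   predictions.
2. **3D bounding region** — voxel (z, y, x) is positive iff all three of
   its slices were classified positive (a product of positive index sets).
3. **Tile segmentation** — 64×64 tiles on a stride-32 lattice around the
   region (kept if they hold ≥ ⅓ of the region's slice cross-section or an
   absolute pixel minimum) are segmented by per-view U-Nets trained with
   the soft Dice loss 1 − (2Σpq + ε)/(Σp + Σq + ε); predictions are
   reinserted into a zero-initialized volume, mean-fused, binarized.
4. **2.5D fusion** — a per-voxel 2-of-3 majority vote over the three
   per-view masks.

Evaluation is patient-wise: accuracy, sensitivity, specificity, precision,
AUROC per view; Dice 2|X∩Y|/(|X|+|Y|) per view and fused; Pearson r, MAE
(mm³), and MRE (%) between true and predicted lesion volumes — all under
five-fold cross-validation with leak-free patient splits.

The two networks are built to fixed reference architectures: the encoder
classifier has exactly **565,873** trainable parameters and the U-Net
**116,753**. Both run on a compact numpy layer stack with hand-derived
backpropagation (no deep-learning framework dependency); see
`docs/methods.md` for architectures, numerical choices, and the phantom
generator's scope.

## Worked example

Generate a phantom cohort and run the default desk-scale experiment
(25 high-contrast phantoms at 128² in-plane, five folds):

```sh
rpeseg phantom generate -n 5 -o cohort/ --seed 3
rpeseg experiment run -o run1/ --seed 1
```

The experiment prints the per-view classification summary (mean ± SD over
patients), the Dice summary, and the volume agreement, and writes the same
tables as CSV under `run1/`. With seed 1 the run prints (accuracy/AUROC
columns shown):

```
    view  accuracy_mean  accuracy_sd  ...  auroc_mean  auroc_sd
 coronal       0.986563     0.014409  ...    0.972868  0.050585
sagittal       0.891563     0.044046  ...    0.971797  0.066921
   axial       0.971392     0.017354  ...    0.997952  0.006377

    view  dice_mean  dice_sd  dice_min  dice_median  dice_max  zero_dice_patients
 coronal   0.700758 0.269938       0.0     0.818182  0.905579                   3
sagittal   0.653719 0.279115       0.0     0.778947  0.884120                   3
   axial   0.684299 0.299921       0.0     0.800000  0.963504                   3
    2.5d   0.739322 0.290866       0.0     0.860870  0.956098                   3

volume agreement: r=0.705 MAE=157.6 mm³ MRE=41.1%
```

Read this as: the slice classifiers rank edematous slices with mean
patient-wise AUROC ≥ 0.97 in every view; the axial segmentation recovers
the lesion with a mean Dice of 0.68 (three patients with the smallest
lesions are missed entirely, Dice 0 — the smallest volumes are the hardest
cases); and predicted volumes track true volumes
with Pearson r = 0.71 at a mean relative error of ~41%. Desk-scale phantom
lesions are ~16× smaller in mm³ than clinical ones (area-scaled to the
128² grid), so MAE is correspondingly smaller.

Everything is importable as a library, e.g.:

```python
from rpeseg import PhantomSpec, generate_phantom
from rpeseg.classify import build_classifier
case = generate_phantom(PhantomSpec(seed=7))      # volume + truth mask
model = build_classifier(seed=0)                  # 565,873 parameters
```

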