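# hipposeg

Two-stage hippocampus segmentation for T1-weighted MRI: an atlas-based
region-of-interest (ROI) localization followed by a 3D fully-convolutional
voxel classifier, with synthetic brain phantoms for training and validation
and the accuracy / test-retest evaluation protocols used in hippocampal
volumetry.

## Who this is for

Hippocampal atrophy is an early, measurable imaging biomarker of dementia,
and measuring it requires segmentations that are accurate *and* reproducible
across repeated scans. The hard part is anatomy: at its anterior and medial
boundaries the hippocampus is continuous with other gray matter (notably the
amygdala) at the same voxel intensity, so pure intensity rules fail. This
package is for researchers who want a transparent, fully inspectable
implementation of the combined atlas + CNN approach: every stage is a plain
Python function over NumPy arrays and NIfTI files, the network is
implemented from scratch (no deep-learning framework), and every claim the
package makes is backed by a measurable experiment on phantoms with exact
ground truth.

## Method

**Stage 1 — ROI localization.** An atlas reference image is registered to
the subject with an affine transform followed by a dense non-linear
refinement (correlation-metric registration via SimpleITK). The transform
warps a probabilistic hippocampus map into subject space; the map's non-zero
support is dilated by 2 voxels (26-connected 3×3×3 element) and the image is
cropped to the mask's bounding box plus a 2-voxel safety margin. Left and
right sides give two independent crops.

**Stage 2 — voxel classification.** A feed-forward stack of unpadded 3×3×3
convolutions with ReLU (no pooling, no striding) ends in a 1×1×1 convolution
to two classes with per-voxel softmax. The reference configuration has nine
hidden layers with feature maps 20, 25, …, 60, receptive field 19 and
373,622 parameters. Voxels with foreground probability > 0.5 *inside the
dilated mask* become foreground:

    seg(x) = [ p_fg(x) > 0.5 ] · [ x ∈ dilated mask ]

Training minimizes voxel-wise cross-entropy + L1/L2 penalties
(10⁻⁶, 10⁻⁴) with mini-batch SGD (batch 20, momentum 0.9), patches sampled
1:1 from foreground/background-centered locations, Gaussian-blur
augmentation (σ = 0.5, 1.0 mm), and a learning rate halved when validation
Dice plateaus. Evaluation: Dice `2|A∩B|/(|A|+|B|)`, volumes in mL, a rigid
co-registration test-retest protocol, and two-sided Wilcoxon rank-sum
comparisons (exact for small tie-free samples).

Because clinical training data cannot be shipped, the package includes an
analytic phantom generator: brain-like volumes with two curved,
gray-matter-intensity hippocampi (exact labels), an adjacent same-intensity
amygdala-like confuser, bias field, noise, per-subject affine variability
and same-session retest pairs. See `docs/methods.md` for the full model
description and what phantom results do and do not show.

## Worked example

```bash
# 1. simulate a small labelled cohort + toy atlas (64 mm cube phantoms)
hipposeg simulate data/ --n 8 --shape 64 --split 0.5 0.25 0.25 --seed 3

# 2. train the scaled-down classifier
hipposeg train data/ model.ckpt --epochs 10 --batches-per-epoch 15 --seed 3

# 3. segment a held-out phantom and score it
hipposeg segment data/subj007.nii.gz --atlas-dir data/atlas \
    --checkpoint model.ckpt --out-dir seg/
hipposeg evaluate seg/subj007_seg.nii.gz --truth data/subj007_labels.nii.gz
```

The `train` step reports its model selection
(`trained 10 epochs; best validation Dice 0.765; checkpoint: model.ckpt`)
and the `evaluate` step prints one row per side:

```
               subject session  side   method     dice  volume_ml_a  volume_ml_b  abs_volume_diff_ml
seg/subj007_seg.nii.gz          left hipposeg 0.787421        2.731        2.834               0.103
seg/subj007_seg.nii.gz         right hipposeg 0.782434        2.626        2.839               0.213
```

`dice` is the overlap with ground truth (1.0 = perfect), `volume_ml_a/b` are
the segmented and true hippocampus volumes in mL, and their absolute
difference is the volumetric error — the quantity that matters for atrophy
studies. This quick demo trains on only four phantoms, which lands near
Dice 0.78; the full 20-phantom study run by the acceptance script below
reaches about 0.94, with test-retest Dice around 0.95.

The same workflow is available as library calls (`generate_cohort`,
`run_train`, `segment_volume`, `run_retest`); the CLI is a thin layer over
them.

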