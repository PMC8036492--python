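# Methods

## The segmentation problem

The hippocampus is a small, bilateral gray-matter structure whose atrophy is
an early imaging biomarker of dementia. Delineating it on T1-weighted MRI is
hard for exactly one reason that dominates all others: at its medial and
anterior boundaries it is continuous with other gray matter (most notably
the amygdala) at essentially identical voxel intensity, so no intensity
threshold separates it. `hipposeg` attacks this with a two-stage design:

1. **Atlas stage** — a reference brain with probabilistic left/right
   hippocampus maps is registered to the subject (affine, then a dense
   non-linear refinement). The warped maps are binarized at their non-zero
   support, dilated by 2 voxels, and each side is cropped to its bounding
   box plus a 2-voxel safety margin. The result is a small volume of
   interest that is guaranteed (by the dilation + margin slack) to contain
   the structure, and inside which foreground/background are far better
   balanced than in the whole head.
2. **Classification stage** — a 3D fully-convolutional network assigns a
   foreground probability to every voxel of the crop; voxels above 0.5
   *and* inside the dilated mask become foreground. Left and right crops are
   processed independently and merged back into a single label map
   (1 = left, 2 = right) on the subject grid.

## Pre-processing

Intensities are standardized to mean 0 / population SD 1 over the brain
(non-zero voxels; the pipeline assumes brain-extracted input, and the
phantom generator produces exactly that). Statistics over an arbitrary
region can be forced with an explicit mask. The transform is applied inside
the region only, which makes standardization idempotent.

One subtlety matters for precision: the pipeline's `preprocess` computes the
statistics over the 2-voxel-*eroded* brain interior while standardizing the
whole brain. A co-registered (linearly resampled) scan carries a 1–2 voxel
partial-volume ramp at its brain edge; statistics over the raw support are
then inflated relative to the un-resampled scan of the same anatomy (about
30% in SD on the phantoms), which shifts the z-scored gray matter by several
tenths of a standard deviation between the two scans of a retest pair and
destroys segmentation consistency. Interior statistics make the two scans
standardize identically to within a few hundredths of a sigma. Volumes are
resampled to 1 mm isotropic with cubic splines (nearest-neighbour for
labels); the output grid keeps the input's world origin and directions, with
shape `round(shape x spacing / target)` per axis.

## Registration

Registration contracts are implemented on SimpleITK:

* **Affine and rigid**: `ImageRegistrationMethod` with the correlation
  metric, linear interpolation, physical-shift parameter scaling and a
  three-level multi-resolution pyramid (shrink 4/2/1, smoothing 2/1/0 mm).
  The optimizer is regular-step gradient descent (step 2.0 halving to 1e-4,
  gradient-magnitude tolerance 1e-6); the tight tolerance matters — with the
  ITK defaults the rotation parameters stop about 1 degree short of the
  optimum while translations converge, which is invisible in the metric but
  fails sub-degree recovery. If optimization degrades the similarity
  relative to the centered initialization, the initialization is returned
  with a warning rather than a worse transform.
* **Non-linear**: a fast symmetric-forces demons filter run on the affinely
  pre-aligned pair, two levels (shrink 2/1, 24 and 12 iterations), with
  1.5–2 mm field smoothing as regularization. Demons is driven by intensity
  differences rather than cross-correlation; on intensity-standardized
  same-modality images the two coincide in practice, and any engine meeting
  the recovery and smoothness contracts is considered conforming. The dense
  refinement is kept only when it does not reduce cross-correlation,
  otherwise the affine-only transform is used.

Transforms map fixed-image world points to moving-image points (resampling
convention): `T(x) = A(x + u(x))` with `u` a displacement field on the fixed
grid. Probability maps are warped with B-spline interpolation, clamped to
[0, 1]; values below 1e-6 are treated as zero so that "non-zero support"
does not inflate with spline ringing.

Dilation uses the full 26-connected 3x3x3 structuring element iterated
`dilation_voxels` times — the smallest element guaranteeing coverage growth
of the stated number of voxels in every direction, diagonals included.
Dilation (2 voxels) and the bounding-box safety margin (2 voxels) are
applied sequentially, as two distinct guarantees: the first admits atlas
imprecision into the classification task, the second keeps full network
context available for voxels at the mask edge.

## Network

The classifier is a plain feed-forward stack of unpadded 3x3x3 convolutions
with ReLU, no pooling and no striding, closed by a 1x1x1 convolution to two
classes and a per-voxel softmax. The reference configuration has nine hidden
layers with feature maps 20, 25, ..., 60 (funnel), receptive field 19 and
373,622 parameters (`sum_l 27 c_{l-1} c_l + c_l` plus the pointwise
classifier). Dense inference reflect-pads the crop by half the receptive
field, so the output grid equals the crop grid; a tiled mode produces
identical results under bounded memory.

The implementation is pure NumPy. Convolutions are computed as 27 shifted
GEMMs (per kernel offset, a `(voxels, C_in) @ (C_in, C_out)` product), which
avoids im2col buffers and runs close to BLAS speed; forward and backward
passes are exact (checked against central finite differences at 1e-6 in
float64). Default arithmetic is float32.

Training minimizes mean voxel-wise cross-entropy plus `l1 |W| + l2 W^2`
(defaults 1e-6 and 1e-4) with mini-batch SGD, momentum 0.9 (Adam available
behind the config). Batches hold 20 patches sampled 1:1 from
foreground-centered and background-centered locations, pooled across crops;
patch side is `receptive_field + output_side - 1` (training output side 17
by default here, i.e. 27-cube inputs for the scaled network). Images are
reflect-padded at crop borders, targets zero-padded; truth outside the
dilated mask is forced to background before sampling, matching the in-mask
task definition. The initial learning rate 0.006 is halved whenever
validation Dice fails to improve by more than 1e-3 for 2 consecutive epochs
("steady diminishing until plateau" made concrete), and the weights with the
best validation Dice are returned. Every random draw flows through one
seeded generator, so training is bit-reproducible on CPU.

Dropout (rate 0.5 on the last two hidden layers, the convention of the
framework this architecture derives from) is part of the reference
configuration. The scaled-down configuration used for CPU-scale experiments
(5 hidden layers, maps 8-24, ~30k parameters) disables it: at that size the
model is far from the overfitting regime and dropout at 0.5 visibly stalls
convergence. The 1x1x1 classifier reading of the architecture's "1D kernel"
classification layer is the only one consistent with a fully-convolutional
voxel classifier.

## Evaluation protocols

* **Accuracy**: Dice `2|A∩B| / (|A|+|B|)` per side, plus volumes in mL
  (voxel count x voxel volume / 1000). Dice of two empty masks is reported
  as missing, not 1.0 — the ratio is undefined and silently scoring it
  perfect would inflate precision.
* **Test-retest precision**: for each same-session pair, scan 2 is rigidly
  registered to scan 1 (normalized cross-correlation, linear interpolation),
  both co-registered images are segmented independently, and per-side Dice
  and |ΔV| are reported with across-session means ± SD. Segmenting the
  co-registered image (rather than segmenting natively and warping labels)
  follows the published ordering of the protocol this mirrors. The brain
  mask travels with the scan: after resampling, voxels whose interpolated
  non-zero support falls below 0.5 are reset to background. This matters
  more than it sounds: on a brain-extracted image, linear interpolation
  leaks sub-tissue values into the background rim, which standardization
  maps to z-scores darker than the hippocampus itself — a halo that only
  the resampled scan of the pair has, and that a confident voxel classifier
  partly labels foreground (about +0.4 mL on the phantoms). Carrying the
  mask through the transform removes the asymmetry.
* **Method comparison**: two-sided Wilcoxon rank-sum, exact by enumeration
  of all `C(n+m, n)` rank assignments when `n+m <= 12` and the pooled sample
  is tie-free, otherwise the tie-corrected normal approximation. The
  rank-sum (unpaired) form is the default because that is how such
  comparisons are usually published, even on paired designs; a signed-rank
  variant is available behind `paired=True`.

## Synthetic phantoms

The generator emulates the aspects of multi-site T1 data that the pipeline
actually exercises, with exact ground truth:

* an ellipsoidal brain (semi-axes ~0.8 of the half field of view) with a
  3 mm gray-matter shell, white-matter interior and two CSF ventricles;
  background is exactly zero (brain-extracted);
* two mirrored hippocampi: tubes along a quadratic Bezier centerline
  (3 control points) with radius tapering 6 to 4 mm — head, body, tail —
  about 2.4 mL each before subject scaling (human range 1.5–5 mL);
* an amygdala-like ellipsoid abutting each anterior hippocampal head at
  *identical* intensity, unlabeled — the gray-matter-continuity confuser
  that makes the real problem hard;
* tissue means 30/70/110 (CSF/GM/WM, arbitrary units), additive Gaussian
  noise (SD 8) inside the brain, and a multiplicative quadratic bias field
  (amplitude 0.15);
* per-subject affine variability (translation <= 4 mm, rotation <= 5 deg,
  scale 0.9–1.1) and retest rigid motion (<= 3 mm, <= 3 deg) with fresh
  noise and the same anatomy and bias.

All anatomy is analytic: a subject volume is the canonical scene evaluated
at inverse-mapped voxel centers, so ground-truth labels are voxel-exact and
the applied transform is known exactly — this is what makes the
registration-recovery and containment guarantees measurable. The toy atlas
is the unjittered noiseless scene; its probability maps average the true
labels of 20 jittered subjects, the first of them unjittered so the map
support always covers the canonical structure.

What the phantoms do *not* model: Rician noise statistics (noise is
Gaussian), partial-volume averaging at tissue boundaries (rasterization is
binary at voxel centers), gyral/sulcal cortical geometry, real hippocampal
internal architecture, pathology, and scanner-specific artifacts beyond a
smooth bias field. Passing the phantom suite therefore demonstrates that
the pipeline's machinery is correct and stable — not that the shipped
configuration reaches clinical-grade accuracy on patient data, which
requires training on manually annotated MRI.

## Problem sizes and numerical choices

End-to-end experiments run on 64 mm-cube phantoms with a cohort of 28
(20 train / 3 val / 5 test), 10 epochs of 25 batches, and 20 retest pairs;
for the scaled configuration the initial learning rate is raised to 0.02:
the reference 0.006 is tuned to the 9-layer network on clinical cohorts and
leaves the small network visibly unconverged within a 10-epoch budget,
whereas 0.02 converges cleanly (the plateau-halving schedule is unchanged);
registration-recovery checks use 10 pairs each. These sizes keep a full
study in the tens of minutes on one CPU core while leaving every measured
property far from its threshold. Binarization of warped maps uses the 1e-6
support floor; segmentation thresholds foreground strictly above 0.5 (ties
to background); bounding boxes are 0-based half-open in the subject voxel
grid. Left/right crops are segmented independently; should restored sides
ever overlap (impossible with a disjoint-support atlas), left wins and a
warning is logged.

## Known limitations

* The reference 9-layer configuration is implemented and verified
  structurally (parameter count, receptive field, gradient correctness) but
  is not trained here — CPU-scale studies use the 5-layer configuration.
* Demons-based refinement assumes matched intensity distributions; it is
  run after standardization and guarded by a similarity check, but it is not
  a cross-correlation optimizer in the strict sense.
* The rank-sum exact branch enumerates combinations and is exponential;
  it is capped at n+m <= 12 by design.
* Phantom realism limits are listed above; no claim transfers to clinical
  MRI without retraining.
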