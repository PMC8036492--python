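"""Atlas-based region-of-interest localization.

The first stage of the pipeline finds a volume of interest guaranteed to
contain the hippocampus: an atlas reference image is registered to the
subject (affine, then a dense non-linear refinement), the registration is
applied to a probabilistic hippocampus map, the warped map is binarized
(non-zero support) and dilated by two voxels, and the image is cropped to the
mask's bounding box padded by a two-voxel safety margin.  Left and right
hippocampi are processed as two independent crops, each a binary foreground /
background task, merged again by :func:`restore_to_full`.

Registration is delegated to SimpleITK: a correlation-metric gradient-descent
affine (and rigid) registration, and a fast symmetric-forces demons filter
for the dense refinement of the affinely pre-aligned pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume import LabelMap, Volume, LABEL_LEFT, LABEL_RIGHT

#: warped probability values below this are interpolation halo, not support
PROB_SUPPORT_EPS = 1e-6


@dataclass
class RoiConfig:
    """Mask dilation and bounding-box margin (voxels)."""

    dilation_voxels: int = 2
    margin_voxels: int = 2

    def __post_init__(self) -> None:
        if self.dilation_voxels < 0 or self.margin_voxels < 0:
            raise ValueError("dilation and margin must be non-negative")


@dataclass
class Atlas:
    """Reference image plus left/right probabilistic hippocampus maps."""

    reference: Volume
    prob_left: Volume
    prob_right: Volume

    def __post_init__(self) -> None:
        for p in (self.prob_left, self.prob_right):
            if p.data.min() < -1e-9 or p.data.max() > 1 + 1e-9:
                raise ValueError("probability maps must lie in [0, 1]")
            if not p.same_grid(self.reference):
                raise ValueError("probability maps must share the reference grid")
        overlap = (self.prob_left.data > PROB_SUPPORT_EPS) & (
            self.prob_right.data > PROB_SUPPORT_EPS
        )
        if overlap.any():
            raise ValueError("left and right probability maps must have disjoint support")

    def prob_map(self, side: str) -> Volume:
        if side == "left":
            return self.prob_left
        if side == "right":
            return self.prob_right
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")


@dataclass
class SpatialTransform:
    """Resampling transform mapping fixed-image world points to moving-image points.

    ``affine`` is a 4x4 world-space map; ``deformation``, when present, is a
    dense displacement field (mm) on the fixed grid applied before the affine:
    ``T(x) = A(x + u(x))``.
    """

    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    deformation: np.ndarray | None = None  # (X, Y, Z, 3) mm, fixed grid
    fixed_grid_affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("transform affine must be an invertible 4x4 map")
        if self.deformation is not None and self.fixed_grid_affine is None:
            raise ValueError("a deformation field needs its fixed-grid affine")

    def to_sitk(self) -> sitk.Transform:
        aff = sitk.AffineTransform(3)
        aff.SetMatrix(self.affine[:3, :3].ravel())
        aff.SetTranslation(self.affine[:3, 3])
        if self.deformation is None:
            return aff
        disp = _displacement_to_sitk(self.deformation, self.fixed_grid_affine)
        comp = sitk.CompositeTransform(3)
        comp.AddTransform(aff)
        comp.AddTransform(sitk.DisplacementFieldTransform(disp))  # applied first
        return comp


@dataclass
class RoiCrop:
    """A cropped sub-volume plus the bookkeeping to restore it to native space."""

    image: Volume
    dilated_mask: np.ndarray  # bool, crop grid
    bbox_lo: tuple[int, int, int]
    parent_shape: tuple[int, int, int]
    side: str

    def __post_init__(self) -> None:
        self.dilated_mask = np.asarray(self.dilated_mask).astype(bool)
        if self.dilated_mask.shape != self.image.shape:
            raise ValueError("dilated mask must live on the crop grid")
        if not self.dilated_mask.any():
            raise ValueError("RoiCrop with empty mask")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        lo = np.asarray(self.bbox_lo)
        hi = lo + np.asarray(self.image.shape)
        if np.any(lo < 0) or np.any(hi > np.asarray(self.parent_shape)):
            raise ValueError("bounding box does not fit inside the parent volume")

    @property
    def bbox_hi(self) -> tuple[int, int, int]:
        return tuple(int(l + s) for l, s in zip(self.bbox_lo, self.image.shape))


# --------------------------------------------------------------------------
# SimpleITK conversion
# --------------------------------------------------------------------------

def _to_sitk(v: Volume) -> sitk.Image:
    """Volume -> SimpleITK image; sitk index (x,y,z) == our array index (i,j,k)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(v.data.astype(np.float64).transpose(2, 1, 0)))
    spacing = v.spacing
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in v.origin))
    direction = v.affine[:3, :3] / spacing
    img.SetDirection(tuple(direction.ravel()))
    return img


def _from_sitk(img: sitk.Image, id: str = "") -> Volume:
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    spacing = np.asarray(img.GetSpacing())
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    affine = np.eye(4)
    affine[:3, :3] = direction * spacing
    affine[:3, 3] = img.GetOrigin()
    return Volume(data, affine, id)


def _displacement_to_sitk(deformation: np.ndarray, grid_affine: np.ndarray) -> sitk.Image:
    field = sitk.GetImageFromArray(
        np.ascontiguousarray(deformation.astype(np.float64).transpose(2, 1, 0, 3)),
        isVector=True,
    )
    spacing = np.linalg.norm(grid_affine[:3, :3], axis=0)
    field.SetSpacing(tuple(float(s) for s in spacing))
    field.SetOrigin(tuple(float(o) for o in grid_affine[:3, 3]))
    field.SetDirection(tuple((grid_affine[:3, :3] / spacing).ravel()))
    return field


def _sitk_affine_to_matrix(t) -> np.ndarray:
    """Matrix+center+translation transform (affine or rigid) -> 4x4 world map."""
    a = np.eye(4)
    a[:3, :3] = np.asarray(t.GetMatrix()).reshape(3, 3)
    center = np.asarray(t.GetCenter())
    a[:3, 3] = np.asarray(t.GetTranslation()) + center - a[:3, :3] @ center
    return a


def _normalized_cc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


def _check_registerable(moving: Volume, fixed: Volume) -> None:
    for name, v in (("moving", moving), ("fixed", fixed)):
        if np.ptp(v.data) == 0:
            raise ValueError(f"cannot register a constant {name} image")


def resample_through(moving: Volume, t: SpatialTransform, target: Volume,
                     interpolator=sitk.sitkLinear, default: float = 0.0) -> Volume:
    """Resample ``moving`` onto ``target``'s grid through transform ``t``."""
    out = sitk.Resample(_to_sitk(moving), _to_sitk(target), t.to_sitk(),
                        interpolator, float(default))
    return Volume(_from_sitk(out).data, target.affine.copy(), moving.id)


# --------------------------------------------------------------------------
# registration
# --------------------------------------------------------------------------

def _run_registration(moving: Volume, fixed: Volume, initial: sitk.Transform,
                      iterations: int = 150, precise: bool = True) -> sitk.Transform:
    # the tight gradient tolerance is what buys sub-degree rotation recovery;
    # ROI localization has voxels of slack and can stop much earlier
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=2.0,
        minStep=1e-4,
        numberOfIterations=iterations if precise else min(iterations, 100),
        relaxationFactor=0.5,
        gradientMagnitudeTolerance=1e-6 if precise else 1e-4,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(initial, inPlace=True)
    try:
        reg.Execute(_to_sitk(fixed), _to_sitk(moving))
    except RuntimeError as exc:  # optimizer failure: keep best-so-far / initial
        warnings.warn(f"registration did not converge cleanly: {exc}")
    return initial  # updated in place


def register_affine(moving: Volume, fixed: Volume,
                    precise: bool = True) -> SpatialTransform:
    """Affine registration (correlation metric, multi-resolution).

    Returns the world-space affine that resamples ``moving`` onto ``fixed``.
    If optimization fails to beat the centered initialization, the
    initialization is returned with a warning rather than a worse transform.
    ``precise=False`` relaxes the stopping tolerance for callers that only
    need sub-voxel (not sub-tenth-voxel) alignment, at roughly half the cost.
    """
    _check_registerable(moving, fixed)
    fixed_img, moving_img = _to_sitk(fixed), _to_sitk(moving)
    initial = sitk.CenteredTransformInitializer(
        fixed_img, moving_img, sitk.AffineTransform(3),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    init_mat = _sitk_affine_to_matrix(sitk.AffineTransform(initial))
    result = _run_registration(moving, fixed, sitk.AffineTransform(initial),
                               precise=precise)
    mat = _sitk_affine_to_matrix(result)

    before = _normalized_cc(
        resample_through(moving, SpatialTransform(init_mat), fixed).data, fixed.data
    )
    after = _normalized_cc(
        resample_through(moving, SpatialTransform(mat), fixed).data, fixed.data
    )
    if after + 1e-9 < before:
        warnings.warn("affine registration degraded similarity; keeping initialization")
        mat = init_mat
    return SpatialTransform(mat)


def register_nonlinear(moving: Volume, fixed: Volume, init: SpatialTransform,
                       iterations: tuple[int, ...] = (24, 12),
                       smoothing_sigma_mm: float = 2.0) -> SpatialTransform:
    """Dense non-parametric refinement of an affine pre-alignment.

    The moving image is first resampled through ``init``; a symmetric-forces
    demons filter then estimates a smooth displacement field on the fixed
    grid.  The refinement is kept only if it does not decrease the
    cross-correlation with the fixed image.
    """
    _check_registerable(moving, fixed)
    pre = resample_through(moving, init, fixed)
    fixed_img, moving_img = _to_sitk(fixed), _to_sitk(pre)

    demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
    demons.SetSmoothDisplacementField(True)
    demons.SetStandardDeviations(smoothing_sigma_mm)
    field = None
    for level, n_iter in enumerate(iterations):
        shrink = 2 ** (len(iterations) - 1 - level)
        f = fixed_img if shrink == 1 else sitk.Shrink(fixed_img, [shrink] * 3)
        m = moving_img if shrink == 1 else sitk.Shrink(moving_img, [shrink] * 3)
        demons.SetNumberOfIterations(n_iter)
        if field is None:
            field = demons.Execute(f, m)
        else:
            field = demons.Execute(f, m, sitk.Resample(field, f))
    field = sitk.Resample(field, fixed_img)
    disp = sitk.GetArrayFromImage(field).transpose(2, 1, 0, 3)

    candidate = SpatialTransform(init.affine.copy(), disp, fixed.affine.copy())
    cc_affine = _normalized_cc(pre.data, fixed.data)
    cc_dense = _normalized_cc(resample_through(moving, candidate, fixed).data, fixed.data)
    if cc_dense + 1e-9 < cc_affine:
        warnings.warn("non-linear refinement degraded similarity; keeping affine only")
        return SpatialTransform(init.affine.copy())
    return candidate


def register_rigid(moving: Volume, fixed: Volume) -> SpatialTransform:
    """6-parameter rigid registration (normalized cross-correlation, linear interp)."""
    _check_registerable(moving, fixed)
    fixed_img, moving_img = _to_sitk(fixed), _to_sitk(moving)
    initial = sitk.CenteredTransformInitializer(
        fixed_img, moving_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    result = _run_registration(moving, fixed, sitk.Euler3DTransform(initial))
    euler = sitk.Euler3DTransform(result)
    a = np.eye(4)
    a[:3, :3] = np.asarray(euler.GetMatrix()).reshape(3, 3)
    center = np.asarray(euler.GetCenter())
    a[:3, 3] = np.asarray(euler.GetTranslation()) + center - a[:3, :3] @ center
    return SpatialTransform(a)


# --------------------------------------------------------------------------
# transform serialization
# --------------------------------------------------------------------------

def save_transform(t: SpatialTransform, prefix) -> None:
    """Write a transform as ``<prefix>.affine.txt`` (plain-text 4x4) and,
    when a dense deformation exists, ``<prefix>.field.nii.gz`` (3-component
    displacement in mm on the fixed grid)."""
    import nibabel as nib

    prefix = str(prefix)
    np.savetxt(prefix + ".affine.txt", t.affine, fmt="%.12g")
    if t.deformation is not None:
        img = nib.Nifti1Image(t.deformation.astype(np.float32),
                              t.fixed_grid_affine)
        nib.save(img, prefix + ".field.nii.gz")


def load_transform(prefix) -> SpatialTransform:
    """Read a transform written by :func:`save_transform`."""
    import os

    import nibabel as nib

    prefix = str(prefix)
    affine = np.loadtxt(prefix + ".affine.txt")
    field_path = prefix + ".field.nii.gz"
    if os.path.exists(field_path):
        img = nib.load(field_path)
        return SpatialTransform(affine,
                                np.asanyarray(img.dataobj).astype(float),
                                np.asarray(img.affine, dtype=float))
    return SpatialTransform(affine)


# --------------------------------------------------------------------------
# probability-map warping, dilation, cropping
# --------------------------------------------------------------------------

def warp_probability_map(prob: Volume, t: SpatialTransform, target: Volume) -> Volume:
    """Warp an atlas-space probability map onto the subject grid.

    Spline interpolation, then clamping to [0, 1]; sub-``PROB_SUPPORT_EPS``
    values (spline ringing) are zeroed so "non-zero support" stays meaningful.
    """
    out = resample_through(prob, t, target, interpolator=sitk.sitkBSpline)
    data = np.clip(out.data, 0.0, 1.0)
    data[data < PROB_SUPPORT_EPS] = 0.0
    return Volume(data, target.affine.copy(), prob.id)


def binarize_and_dilate(prob: Volume, cfg: RoiConfig) -> Volume:
    """Non-zero support of a probability map, dilated by the configured radius.

    Dilation uses the full 26-connected 3x3x3 structuring element, iterated
    ``cfg.dilation_voxels`` times (a Chebyshev ball), so coverage grows by the
    stated number of voxels in every direction including diagonals.
    """
    support = prob.data > PROB_SUPPORT_EPS
    if not support.any():
        raise ValueError("atlas registration produced empty hippocampus map")
    if cfg.dilation_voxels > 0:
        support = ndimage.binary_dilation(
            support, structure=np.ones((3, 3, 3), bool), iterations=cfg.dilation_voxels
        )
    return Volume(support.astype(np.uint8), prob.affine.copy(), prob.id)


def extract_roi(image: Volume, dilated_mask: Volume | np.ndarray,
                cfg: RoiConfig, side: str) -> RoiCrop:
    """Crop the image to the mask's bounding box plus the safety margin."""
    mdata = dilated_mask.data if isinstance(dilated_mask, Volume) else dilated_mask
    mdata = np.asarray(mdata).astype(bool)
    if mdata.shape != image.data.shape:
        raise ValueError("mask is not grid-aligned with the image")
    if not mdata.any():
        raise ValueError("cannot crop around an empty mask")
    idx = np.argwhere(mdata)
    lo = np.maximum(idx.min(axis=0) - cfg.margin_voxels, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + cfg.margin_voxels, image.data.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    sub_affine = image.affine.copy()
    sub_affine[:3, 3] = image.affine[:3, :3] @ lo + image.affine[:3, 3]
    sub = Volume(image.data[sl].copy(), sub_affine, image.id)
    return RoiCrop(sub, mdata[sl].copy(), tuple(int(x) for x in lo),
                   tuple(image.data.shape), side)


def restore_to_full(seg: np.ndarray, crop: RoiCrop) -> np.ndarray:
    """Place a crop-grid binary segmentation back into the parent grid.

    Foreground voxels get label 1 (left) or 2 (right) according to the crop's
    side; everything outside the bounding box is background.
    """
    seg = np.asarray(seg)
    if seg.shape != crop.image.shape:
        raise ValueError(
            f"segmentation shape {seg.shape} does not match crop {crop.image.shape}"
        )
    full = np.zeros(crop.parent_shape, dtype=np.uint8)
    label = LABEL_LEFT if crop.side == "left" else LABEL_RIGHT
    sl = tuple(slice(l, h) for l, h in zip(crop.bbox_lo, crop.bbox_hi))
    full[sl][seg > 0] = label
    return full
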