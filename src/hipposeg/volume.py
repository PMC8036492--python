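"""Volume data model, NIfTI I/O and pre-processing.

A :class:`Volume` is a 3D scalar image together with its voxel-to-world
geometry (a 4x4 affine, nibabel convention).  All stages of the segmentation
pipeline exchange volumes on a 1 mm isotropic grid with intensities
standardized to zero mean and unit variance over the brain, which is what the
two pre-processing operations here produce.

Conventions used throughout the package:

* voxel indices are 0-based; bounding boxes are half-open ``[lo, hi)``;
* voxel spacing is read off the column norms of the affine;
* label maps use 0 = background, 1 = left hippocampus, 2 = right hippocampus
  and are always interpolated with nearest-neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

VALID_LABELS = (0, 1, 2)
LABEL_LEFT = 1
LABEL_RIGHT = 2


@dataclass
class Volume:
    """A 3D scalar image with rigid world geometry.

    Parameters
    ----------
    data:
        3D array of intensities (arbitrary units).
    affine:
        4x4 voxel-to-world map (must be invertible).
    id:
        Free-text provenance string.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("voxel-to-world map is not invertible")
        if np.any(self.spacing <= 0):
            raise ValueError("voxel spacing must be positive on every axis")

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def origin(self) -> np.ndarray:
        return self.affine[:3, 3].copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume", tol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )

    def with_data(self, data: np.ndarray, id: str | None = None) -> "Volume":
        """New volume on the same grid with different voxel values."""
        return Volume(data, self.affine.copy(), self.id if id is None else id)


@dataclass
class LabelMap:
    """Integer segmentation aligned to a :class:`Volume` grid.

    0 = background, 1 = left hippocampus, 2 = right hippocampus.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D label map, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label map must hold integers")
            self.data = rounded.astype(np.uint8)
        bad = np.setdiff1d(np.unique(self.data), VALID_LABELS)
        if bad.size:
            raise ValueError(f"invalid label values {bad.tolist()}; allowed {VALID_LABELS}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("label map needs an invertible 4x4 affine")

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def mask(self, label: int) -> np.ndarray:
        return self.data == label

    def as_volume(self) -> Volume:
        return Volume(self.data.astype(np.uint8), self.affine.copy(), self.id)


# --------------------------------------------------------------------------
# NIfTI I/O
# --------------------------------------------------------------------------

def read_volume(path) -> Volume:
    """Read a 3D NIfTI-1 image (.nii / .nii.gz)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - message wrapping
        raise IOError(f"cannot read NIfTI volume {path!r}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path!r}")
    return Volume(data, np.asarray(img.affine, dtype=float), id=str(path))


def write_volume(v: Volume, path) -> None:
    """Write a volume as NIfTI-1, preserving dtype bit-exactly."""
    img = nib.Nifti1Image(v.data, v.affine)
    img.set_data_dtype(v.data.dtype)
    nib.save(img, str(path))


def read_labelmap(path) -> LabelMap:
    v = read_volume(path)
    return LabelMap(np.rint(v.data).astype(np.uint8), v.affine, v.id)


def write_labelmap(m: LabelMap, path) -> None:
    write_volume(Volume(m.data.astype(np.uint8), m.affine, m.id), path)


# --------------------------------------------------------------------------
# Intensity standardization
# --------------------------------------------------------------------------

def normalize_intensity(v: Volume, mask: np.ndarray | Volume | None = None,
                        stats_mask: np.ndarray | None = None) -> Volume:
    """Standardize intensities to zero mean and unit (population) SD.

    Statistics are computed over the normalization region: an explicit binary
    ``mask``, or by default the non-zero voxels (the phantoms and real
    pipelines alike operate on brain-extracted images, so non-zero == brain).
    Voxels outside the region are left at zero, which makes the operation
    idempotent.  Pass an all-ones mask for whole-volume statistics.

    ``stats_mask`` optionally restricts the *statistics* to a sub-region
    while still standardizing the whole region — used by the pipeline to
    ignore partial-volume voxels at the brain edge after resampling.
    """
    if mask is None:
        region = v.data != 0
        if not region.any():
            raise ValueError("cannot normalize an all-zero volume")
    else:
        mdata = mask.data if isinstance(mask, Volume) else np.asarray(mask)
        if mdata.shape != v.data.shape:
            raise ValueError("mask is not grid-aligned with the volume")
        region = mdata.astype(bool)
        if not region.any():
            raise ValueError("empty normalization mask")
    stats_region = region
    if stats_mask is not None:
        stats_region = np.asarray(stats_mask).astype(bool) & region
        if not stats_region.any():
            raise ValueError("empty statistics mask")
    vals = v.data[stats_region].astype(float)
    mu = vals.mean()
    sd = vals.std()  # population SD (divide by N)
    if sd <= 0:
        raise ValueError("constant intensity over the normalization region (std = 0)")
    out = np.zeros(v.data.shape, dtype=float)
    out[region] = (v.data[region].astype(float) - mu) / sd
    return v.with_data(out)


def brain_interior_mask(v: Volume, erosion_voxels: int = 2,
                        min_voxels: int = 500) -> np.ndarray | None:
    """Erode the non-zero support to exclude brain-edge partial volume.

    Linear resampling smears the brain boundary into a 1-2 voxel ramp of
    intermediate intensities; statistics over the raw support are then
    inflated relative to an un-resampled scan of the same anatomy.  Returns
    ``None`` when erosion would leave too few voxels to be reliable.
    """
    region = v.data != 0
    if not region.any():
        return None
    interior = ndimage.binary_erosion(
        region, structure=np.ones((3, 3, 3), bool), iterations=erosion_voxels
    )
    return interior if interior.sum() >= min_voxels else None


def robust_brain_standardize(v: Volume, erosion_voxels: int = 4,
                             smooth_sigma_mm: float = 1.0) -> Volume:
    """Standardize brain intensities with resampling-insensitive statistics.

    Mean and SD are estimated on a lightly smoothed copy of the image over
    the deeply eroded brain interior, then applied to the raw intensities of
    the whole brain.  Smoothing makes the scale estimate reflect tissue
    contrast rather than the (acquisition- and resampling-dependent) noise
    level, and the erosion keeps boundary ramps and smoothing tails out of
    the estimate — so a scan and its rigidly resampled copy standardize
    identically to within a few hundredths of a standard deviation.  Falls
    back to plain :func:`normalize_intensity` on images too small to erode.
    """
    interior = brain_interior_mask(v, erosion_voxels)
    if interior is None:
        return normalize_intensity(v)
    region = v.data != 0
    src = v.data.astype(float)
    if smooth_sigma_mm > 0:
        src = ndimage.gaussian_filter(src, smooth_sigma_mm / v.spacing)
    vals = src[interior]
    mu = vals.mean()
    sd = vals.std()
    if sd <= 0:
        raise ValueError("constant intensity over the brain interior (std = 0)")
    out = np.zeros(v.data.shape, dtype=float)
    out[region] = (v.data[region].astype(float) - mu) / sd
    return v.with_data(out)


# --------------------------------------------------------------------------
# Isotropic resampling
# --------------------------------------------------------------------------

def _resample_grid(v_shape, v_spacing, target_spacing):
    out_shape = np.maximum(
        1, np.rint(np.asarray(v_shape) * np.asarray(v_spacing) / target_spacing)
    ).astype(int)
    return tuple(out_shape)


def resample_isotropic(v: Volume, target_spacing: float = 1.0, order: int = 3) -> Volume:
    """Resample to an isotropic grid (default 1 mm, cubic interpolation).

    The output grid shares the input's world origin and axis directions; the
    new shape per axis is ``round(shape * spacing / target)`` (minimum 1).
    ``order`` 0 is nearest-neighbour (labels), 1 linear, 3 cubic spline.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    if order not in (0, 1, 3):
        raise ValueError("interpolation order must be 0, 1 or 3")
    spacing = v.spacing
    out_shape = _resample_grid(v.shape, spacing, target_spacing)
    if tuple(v.shape) == out_shape and np.allclose(spacing, target_spacing):
        return v.with_data(v.data.copy())
    # output voxel i samples input voxel coordinate i * target / spacing
    coords = np.meshgrid(
        *[
            np.arange(out_shape[ax]) * (target_spacing / spacing[ax])
            for ax in range(3)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(
        v.data.astype(float), np.stack(coords), order=order, mode="nearest"
    )
    new_affine = v.affine.copy()
    dirs = v.affine[:3, :3] / spacing  # unit columns
    new_affine[:3, :3] = dirs * target_spacing
    return Volume(out, new_affine, v.id)


def resample_labelmap(m: LabelMap, target_spacing: float = 1.0) -> LabelMap:
    """Nearest-neighbour isotropic resampling of a label map."""
    v = resample_isotropic(Volume(m.data.astype(np.uint8), m.affine, m.id),
                           target_spacing, order=0)
    return LabelMap(np.rint(v.data).astype(np.uint8), v.affine, m.id)
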