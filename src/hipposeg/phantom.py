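"""Synthetic brain phantoms with ground-truth hippocampus labels.

Real T1-weighted training data (multi-site dementia cohorts, a single-subject
test-retest series) cannot be redistributed, so this module generates
brain-like volumes that exercise every stage of the pipeline:

* an ellipsoidal "brain" with a gray-matter shell, white-matter interior and
  CSF ventricles, already brain-extracted (zero background);
* two mirrored curved-tube hippocampi (quadratic Bezier centerline with a
  tapering radius) at gray-matter intensity, voxel-exact ground truth labels;
* an amygdala-like confuser blob abutting each hippocampal head at the same
  intensity — the classic difficulty of delineating contiguous gray matter;
* a smooth multiplicative bias field, additive Gaussian noise, per-subject
  affine variability, and same-anatomy retest pairs differing only by a small
  rigid motion and fresh noise.

All anatomy is defined analytically in a canonical coordinate frame and
evaluated at inverse-mapped voxel positions, so subject variability introduces
no interpolation artifacts and the labels are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume import LabelMap, Volume, LABEL_LEFT, LABEL_RIGHT


@dataclass
class PhantomSpec:
    """Parameters of the synthetic brain phantom.

    Intensities are arbitrary units; geometry is mm in a canonical frame whose
    origin sits at the volume center.  The brain ellipsoid scales with the
    field of view; the hippocampi have a fixed absolute size (about 2.4 mL
    each before subject scaling, within the plausible human 1.5-5 mL range).
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: float = 1.0  # mm, isotropic

    # tissue mean intensities (arbitrary units); background is 0
    csf_mean: float = 30.0
    gm_mean: float = 70.0
    wm_mean: float = 110.0
    hippo_mean: float = 70.0  # gray-matter-like
    noise_sd: float = 8.0
    bias_amplitude: float = 0.15  # multiplicative low-order polynomial

    # brain ellipsoid semi-axes as fractions of the half field of view
    brain_axes_frac: tuple[float, float, float] = (0.80, 0.90, 0.76)
    gm_shell_mm: float = 3.0
    ventricle_center: tuple[float, float, float] = (7.0, -2.0, 9.0)  # mirrored in x
    ventricle_axes: tuple[float, float, float] = (4.0, 13.0, 5.0)

    # hippocampus: quadratic Bezier control points for the LEFT side (x < 0),
    # mirrored in x for the right side; radius tapers head -> tail
    hippo_p0: tuple[float, float, float] = (-15.0, 16.0, -2.0)  # anterior head
    hippo_p1: tuple[float, float, float] = (-17.0, 0.0, 5.0)
    hippo_p2: tuple[float, float, float] = (-12.0, -14.0, 1.0)  # posterior tail
    hippo_r_head: float = 6.0
    hippo_r_tail: float = 4.0

    # amygdala-like confuser abutting the anterior hippocampal head
    confuser_offset: tuple[float, float, float] = (0.0, 11.5, 0.0)  # from p0
    confuser_axes: tuple[float, float, float] = (5.0, 5.0, 4.5)

    # per-subject affine variability
    max_translation_mm: float = 4.0
    max_rotation_deg: float = 5.0
    scale_range: tuple[float, float] = (0.9, 1.1)

    # retest rigid motion
    retest_max_translation_mm: float = 3.0
    retest_max_rotation_deg: float = 3.0

    def half_extent(self) -> np.ndarray:
        return np.asarray(self.shape) * self.spacing / 2.0

    def grid_affine(self) -> np.ndarray:
        """Voxel-to-world affine placing the world origin at the volume center."""
        a = np.eye(4)
        a[:3, :3] *= self.spacing
        a[:3, 3] = -(np.asarray(self.shape) - 1) * self.spacing / 2.0
        return a


@dataclass
class RetestPair:
    """Two scans of the same anatomy separated by a small rigid motion."""

    scan1: Volume
    scan2: Volume
    labels: LabelMap  # ground truth in scan1's frame
    motion: np.ndarray  # 4x4 rigid world map taking scan1 points to scan2 points


# --------------------------------------------------------------------------
# analytic anatomy
# --------------------------------------------------------------------------

def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _affine4(linear: np.ndarray, translation: np.ndarray) -> np.ndarray:
    a = np.eye(4)
    a[:3, :3] = linear
    a[:3, 3] = translation
    return a


def _draw_subject_affine(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    t = rng.uniform(-spec.max_translation_mm, spec.max_translation_mm, 3)
    r = _rotation_matrix(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg, 3))
    s = np.diag(rng.uniform(*spec.scale_range, 3))
    return _affine4(r @ s, t)


def _draw_rigid(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    t = rng.uniform(-spec.retest_max_translation_mm, spec.retest_max_translation_mm, 3)
    r = _rotation_matrix(
        rng.uniform(-spec.retest_max_rotation_deg, spec.retest_max_rotation_deg, 3)
    )
    return _affine4(r, t)


def _bezier_samples(spec: PhantomSpec, side: str, n: int = 64):
    """Centerline sample points and local radii for one hippocampus."""
    def mirror(p):
        p = np.asarray(p, float).copy()
        if side == "right":
            p[0] = -p[0]
        return p

    p0, p1, p2 = mirror(spec.hippo_p0), mirror(spec.hippo_p1), mirror(spec.hippo_p2)
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
    radii = spec.hippo_r_head + (spec.hippo_r_tail - spec.hippo_r_head) * t[:, 0]
    return pts, radii


def _tube_mask(points_mm: np.ndarray, spec: PhantomSpec, side: str) -> np.ndarray:
    """Boolean membership of canonical points in one hippocampal tube.

    points_mm: (N, 3) canonical coordinates.  Distance to the sampled
    centerline is compared with the local radius; evaluation is restricted to
    a bounding box around the tube for speed.
    """
    pts, radii = _bezier_samples(spec, side)
    lo = pts.min(axis=0) - spec.hippo_r_head - 1.0
    hi = pts.max(axis=0) + spec.hippo_r_head + 1.0
    out = np.zeros(len(points_mm), dtype=bool)
    cand = np.all((points_mm >= lo) & (points_mm <= hi), axis=1)
    if not cand.any():
        return out
    p = points_mm[cand]  # (M, 3)
    # min over centerline samples of (distance - local radius)
    inside = np.zeros(len(p), dtype=bool)
    for c, r in zip(pts, radii):
        d2 = ((p - c) ** 2).sum(axis=1)
        inside |= d2 <= r * r
    out[cand] = inside
    return out


def _ellipsoid(points_mm, center, axes) -> np.ndarray:
    q = (points_mm - np.asarray(center)) / np.asarray(axes)
    return (q**2).sum(axis=1) <= 1.0


def _render_canonical(spec: PhantomSpec, points_mm: np.ndarray):
    """Noiseless tissue intensity and labels at canonical coordinates."""
    half = spec.half_extent()
    brain_axes = np.asarray(spec.brain_axes_frac) * half
    n = len(points_mm)
    tissue = np.zeros(n)
    labels = np.zeros(n, dtype=np.uint8)

    brain = _ellipsoid(points_mm, (0, 0, 0), brain_axes)
    inner = _ellipsoid(points_mm, (0, 0, 0), np.maximum(brain_axes - spec.gm_shell_mm, 1.0))
    tissue[brain] = spec.gm_mean  # cortical shell
    tissue[inner] = spec.wm_mean

    vc = np.asarray(spec.ventricle_center)
    for sgn in (-1.0, 1.0):
        vent = _ellipsoid(points_mm, vc * np.array([sgn, 1, 1]), spec.ventricle_axes)
        tissue[vent & inner] = spec.csf_mean

    for side, lab in (("left", LABEL_LEFT), ("right", LABEL_RIGHT)):
        tube = _tube_mask(points_mm, spec, side)
        tube &= brain
        tissue[tube] = spec.hippo_mean
        labels[tube] = lab
        # confuser: same intensity, never labeled, clipped against the tube
        p0 = np.asarray(spec.hippo_p0, float)
        if side == "right":
            p0[0] = -p0[0]
        off = np.asarray(spec.confuser_offset, float)
        if side == "right":
            off = off * np.array([-1, 1, 1])
        blob = _ellipsoid(points_mm, p0 + off, spec.confuser_axes)
        tissue[blob & brain & ~tube] = spec.hippo_mean
    return tissue, labels


def _bias_field(spec: PhantomSpec, points_mm: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Multiplicative quadratic bias evaluated at world coordinates."""
    if spec.bias_amplitude == 0:
        return np.ones(len(points_mm))
    u = points_mm / spec.half_extent()  # roughly [-1, 1]
    x, y, z = u[:, 0], u[:, 1], u[:, 2]
    basis = np.stack([x, y, z, x * y, x * z, y * z, x * x, y * y, z * z], axis=1)
    q = basis @ coeffs
    peak = np.abs(q).max()
    if peak > 0:
        q = q / peak
    return 1.0 + spec.bias_amplitude * q


def _voxel_world_coords(spec: PhantomSpec) -> np.ndarray:
    affine = spec.grid_affine()
    idx = np.indices(spec.shape).reshape(3, -1).T.astype(float)
    return idx * spec.spacing + affine[:3, 3]


def _rasterize(spec: PhantomSpec, anatomy_affine: np.ndarray,
               bias_coeffs: np.ndarray | None,
               noise_rng: np.random.Generator | None):
    """Render one scan: anatomy pushed through ``anatomy_affine``.

    The subject image is canon(A^-1 x) so the anatomy (including the bias
    field, which rides along with it) moves rigidly/affinely as a whole.
    """
    world = _voxel_world_coords(spec)
    inv = np.linalg.inv(anatomy_affine)
    canon = world @ inv[:3, :3].T + inv[:3, 3]
    tissue, labels = _render_canonical(spec, canon)
    img = tissue
    if bias_coeffs is not None and spec.bias_amplitude > 0:
        img = img * _bias_field(spec, canon, bias_coeffs)
    if noise_rng is not None and spec.noise_sd > 0:
        # scans are brain-extracted: noise exists only inside the head mask
        img = img + noise_rng.normal(0.0, spec.noise_sd, img.shape) * (tissue > 0)
    shape = spec.shape
    return img.reshape(shape), labels.reshape(shape)


def _check_in_bounds(spec: PhantomSpec, anatomy_affine: np.ndarray) -> None:
    half = spec.half_extent()
    for side in ("left", "right"):
        pts, radii = _bezier_samples(spec, side)
        moved = pts @ anatomy_affine[:3, :3].T + anatomy_affine[:3, 3]
        reach = np.abs(moved) + radii[:, None] * 1.15  # allow for scale
        if np.any(reach > half):
            raise ValueError(
                "hippocampus tube out of bounds for this field of view; "
                "enlarge PhantomSpec.shape or reduce variability"
            )


# --------------------------------------------------------------------------
# public generators
# --------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec, seed: int) -> tuple[Volume, LabelMap]:
    """One synthetic subject: affine-jittered anatomy + bias + noise."""
    rng = np.random.default_rng(seed)
    A = _draw_subject_affine(spec, rng)
    _check_in_bounds(spec, A)
    coeffs = rng.normal(size=9)
    img, lab = _rasterize(spec, A, coeffs, rng)
    affine = spec.grid_affine()
    vid = f"phantom-{seed}"
    return Volume(img, affine, vid), LabelMap(lab, affine, vid)


def generate_atlas(spec: PhantomSpec, n_jitter: int = 20, seed: int = 0):
    """Toy atlas: canonical noiseless phantom + probabilistic hippocampus maps.

    The probability maps average the true labels of ``n_jitter`` affinely
    jittered subjects; the first member is the unjittered anatomy so the map
    support always covers the canonical structure.
    """
    from .atlas import Atlas  # local import to avoid a cycle

    affine = spec.grid_affine()
    img, _ = _rasterize(spec, np.eye(4), None, None)
    reference = Volume(img, affine, "atlas-reference")

    rng = np.random.default_rng(seed)
    acc_l = np.zeros(spec.shape)
    acc_r = np.zeros(spec.shape)
    for i in range(n_jitter):
        A = np.eye(4) if i == 0 else _draw_subject_affine(spec, rng)
        _, lab = _rasterize(spec, A, None, None)
        acc_l += lab == LABEL_LEFT
        acc_r += lab == LABEL_RIGHT
    prob_l = Volume(acc_l / n_jitter, affine, "atlas-prob-left")
    prob_r = Volume(acc_r / n_jitter, affine, "atlas-prob-right")
    return Atlas(reference, prob_l, prob_r)


def split_cohort(n: int, fractions=(0.8, 0.1, 0.1)):
    """Deterministic train/val/test index split.

    Train and validation sizes are floored; the remainder goes to test.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_train = int(np.floor(n * fractions[0]))
    n_val = int(np.floor(n * fractions[1]))
    idx = np.arange(n)
    return idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :]


def generate_cohort(spec: PhantomSpec, n: int, seed: int):
    """``n`` independent phantoms with per-subject affine and noise draws."""
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF
    return [generate_phantom(spec, int(s)) for s in seeds]


def generate_retest_pair(spec: PhantomSpec, seed: int) -> RetestPair:
    """Same-session scan pair: identical anatomy, small rigid motion, fresh noise."""
    rng = np.random.default_rng(seed)
    A = _draw_subject_affine(spec, rng)
    R = _draw_rigid(spec, rng)
    _check_in_bounds(spec, A)
    _check_in_bounds(spec, R @ A)
    coeffs = rng.normal(size=9)
    img1, lab1 = _rasterize(spec, A, coeffs, rng)
    img2, _ = _rasterize(spec, R @ A, coeffs, rng)
    affine = spec.grid_affine()
    pid = f"retest-{seed}"
    return RetestPair(
        Volume(img1, affine, pid + "-s1"),
        Volume(img2, affine, pid + "-s2"),
        LabelMap(lab1, affine, pid),
        R,
    )
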