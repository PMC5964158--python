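"""Synthetic head phantoms with known ground truth.

The canonical ("template") head is a set of nested ellipsoidal tissue shells
with a cylindrical neck stub, plus one parametric coronal sulcus: a laterally
curved groove carved as a CSF cleft into the gray-matter shell, separating a
"pre-" from a "post-central" strip.  An "individual" head is the same
geometry evaluated through a known affine, so the true individual->template
matrix and the true sulcus polyline are available for every downstream test.

All label geometry is a pure function of world coordinates, which is what
makes warped individuals exact: ``labels_individual(x) = labels_canonical(A x)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from repe.core import (
    FiducialSet,
    IntensityVolume,
    LabeledHeadVolume,
    PhantomTruth,
    SulcusTrace,
    Tissue,
    apply_affine,
)
from repe.errors import ParameterError, TransformError

# Arbitrary per-tissue intensity means (a.u.); enough contrast for
# threshold-based segmentation, deliberately not scanner-realistic.
TISSUE_INTENSITY = {
    Tissue.AIR: 0.0,
    Tissue.SKIN: 80.0,
    Tissue.FAT: 110.0,
    Tissue.SKULL: 30.0,
    Tissue.CSF: 20.0,
    Tissue.GRAY: 60.0,
    Tissue.WHITE: 90.0,
}
INTENSITY_NOISE_SD = 5.0


@dataclass
class GridSpec:
    """Voxel grid: ``shape`` cubes of ``voxel_size`` mm, centred on the origin."""

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size: float = 2.0

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ParameterError("voxel_size must be positive")
        self.shape = tuple(int(n) for n in self.shape)

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] *= self.voxel_size
        aff[:3, 3] = -(np.asarray(self.shape) - 1) * self.voxel_size / 2.0
        return aff

    def world_points(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (n_voxels, 3)."""
        axes = [
            np.arange(n) * self.voxel_size - (n - 1) * self.voxel_size / 2.0
            for n in self.shape
        ]
        grid = np.meshgrid(*axes, indexing="ij")
        return np.stack([g.ravel() for g in grid], axis=1)


@dataclass
class HeadShapeParams:
    """Ellipsoidal shell head with a neck stub.

    ``skin_axes`` are the outer semi-axes (x lateral, y anterior, z superior);
    each shell boundary is the skin ellipsoid with every semi-axis reduced by
    the cumulative thickness, so shells are strictly nested by construction.
    """

    center: tuple[float, float, float] = (0.0, 0.0, 18.0)
    skin_axes: tuple[float, float, float] = (72.0, 82.0, 60.0)
    skin_mm: float = 5.0
    fat_mm: float = 4.0
    skull_mm: float = 7.0
    csf_mm: float = 5.0
    gray_mm: float = 7.0
    neck_radius: float = 30.0
    neck_center_xy: tuple[float, float] = (0.0, -8.0)
    neck_bottom: float = -84.0
    # Brain base: gray/white stop on a tilted plane below the head centre and
    # CSF fills the rest of the cranial cavity.  Besides looking more like a
    # skull base, the plane removes the ellipsoid's continuous "elliptic
    # rotation" symmetry, without which the template affine would not be
    # identifiable from the brain surface.
    brain_base_mm: float = 22.0
    brain_base_tilt_deg: float = 12.0

    def __post_init__(self):
        for name in ("skin_mm", "fat_mm", "skull_mm", "csf_mm", "gray_mm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"layer thickness {name} must be positive")
        cum = self.skin_mm + self.fat_mm + self.skull_mm + self.csf_mm + self.gray_mm
        if cum >= min(self.skin_axes):
            raise ParameterError("layer thicknesses exceed the smallest semi-axis")
        if self.neck_radius <= 0:
            raise ParameterError("neck_radius must be positive")

    def shell_axes(self) -> list[tuple[int, np.ndarray]]:
        """(label, semi-axes) from outermost (skin) to innermost (white)."""
        axes = np.asarray(self.skin_axes, dtype=float)
        out = []
        cum = 0.0
        for lab, thick in [
            (Tissue.SKIN, self.skin_mm),
            (Tissue.FAT, self.fat_mm),
            (Tissue.SKULL, self.skull_mm),
            (Tissue.CSF, self.csf_mm),
            (Tissue.GRAY, self.gray_mm),
        ]:
            out.append((int(lab), axes - cum))
            cum += thick
        out.append((int(Tissue.WHITE), axes - cum))
        return out

    @property
    def gray_axes(self) -> np.ndarray:
        """Outer semi-axes of the gray-matter shell."""
        off = self.skin_mm + self.fat_mm + self.skull_mm + self.csf_mm
        return np.asarray(self.skin_axes, dtype=float) - off


@dataclass
class SulcusParams:
    """Parametric coronal groove on the gray shell.

    The midline runs left->right over the crown; ``curvature`` bows the
    lateral ends anteriorly (in units of the unit-sphere y component), which
    is what makes a straight strip electrode miss the lateral target.
    ``depth_mm`` is how far the CSF cleft is carved radially into the head.
    """

    n_points: int = 123
    depth_mm: float = 12.0
    curvature: float = 0.25
    lateral_extent_deg: float = 70.0
    y_center: float = -0.05
    cleft_halfwidth_mm: float = 2.0

    def __post_init__(self):
        if self.n_points < 2:
            raise ParameterError("n_points must be >= 2")
        if self.depth_mm < 0:
            raise ParameterError("depth_mm must be >= 0")


def _canonical_labels(points: np.ndarray, shape: HeadShapeParams) -> np.ndarray:
    """Tissue label for each canonical-space point (vectorised, pure)."""
    pts = np.asarray(points, dtype=float)
    rel = pts - np.asarray(shape.center)
    labels = np.zeros(len(pts), dtype=np.int16)
    for lab, axes in shape.shell_axes():
        inside = np.einsum("ij,ij->i", rel / axes, rel / axes) <= 1.0
        labels[inside] = lab
    tilt = np.radians(shape.brain_base_tilt_deg)
    normal = np.array([0.0, np.sin(tilt), np.cos(tilt)])
    q = rel @ normal
    white = labels == int(Tissue.WHITE)
    # keep a gray rind under the white matter so white stays gray-enclosed
    labels[white & (q < -shape.brain_base_mm + shape.gray_mm)] = int(Tissue.GRAY)
    brainish = (labels == int(Tissue.GRAY)) | (labels == int(Tissue.WHITE))
    labels[brainish & (q < -shape.brain_base_mm)] = int(Tissue.CSF)
    # Neck stub: radial skin/fat shells around a muscle-like (skin sigma) core.
    nx, ny = shape.neck_center_xy
    r = np.hypot(pts[:, 0] - nx, pts[:, 1] - ny)
    in_neck = (
        (labels == 0)
        & (r <= shape.neck_radius)
        & (pts[:, 2] >= shape.neck_bottom)
        & (pts[:, 2] <= shape.center[2])
    )
    labels[in_neck] = int(Tissue.SKIN)
    fat_ring = in_neck & (r <= shape.neck_radius - shape.skin_mm) & (
        r > shape.neck_radius - shape.skin_mm - shape.fat_mm
    )
    labels[fat_ring] = int(Tissue.FAT)
    return labels


def sulcus_midline(
    t: np.ndarray, shape: HeadShapeParams, sulcus: SulcusParams
) -> np.ndarray:
    """Canonical-space midline points on the gray surface for t in [-1, 1]."""
    t = np.asarray(t, dtype=float)
    alpha = np.radians(sulcus.lateral_extent_deg) * t
    n = np.stack(
        [
            np.sin(alpha),
            np.full_like(alpha, sulcus.y_center) + sulcus.curvature * t**2,
            np.cos(alpha),
        ],
        axis=-1,
    )
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    return np.asarray(shape.center) + shape.gray_axes * n


def _carve_cleft(
    labels: np.ndarray,
    grid: GridSpec,
    shape: HeadShapeParams,
    sulcus: SulcusParams,
    canonical_to_world: np.ndarray,
) -> None:
    """Turn gray voxels near the swept midline surface into CSF, in place."""
    if sulcus.depth_mm == 0:
        return
    t = np.linspace(-1, 1, 600)
    surface = sulcus_midline(t, shape, sulcus)
    center = np.asarray(shape.center)
    depths = np.arange(0.0, sulcus.depth_mm + 1e-9, grid.voxel_size / 2.0)
    rel = surface - center
    radii = np.linalg.norm(rel, axis=1, keepdims=True)
    # Sweep each midline point radially inward to build the cleft sheet.
    sheet = np.concatenate(
        [center + rel * (1.0 - d / radii) for d in depths], axis=0
    )
    sheet_world = apply_affine(canonical_to_world, sheet)
    vox = np.linalg.solve(
        grid.affine, np.c_[sheet_world, np.ones(len(sheet_world))].T
    ).T[:, :3]
    radius_vox = sulcus.cleft_halfwidth_mm / grid.voxel_size
    reach = int(np.ceil(radius_vox))
    offsets = np.array(
        [
            (i, j, k)
            for i in range(-reach, reach + 1)
            for j in range(-reach, reach + 1)
            for k in range(-reach, reach + 1)
        ]
    )
    base = np.floor(vox + 0.5).astype(int)
    for off in offsets:
        cand = base + off
        ok = np.all((cand >= 0) & (cand < np.asarray(grid.shape)), axis=1)
        cand = cand[ok]
        dist = np.linalg.norm(cand - vox[ok], axis=1)
        cand = cand[dist <= radius_vox]
        sel = labels[cand[:, 0], cand[:, 1], cand[:, 2]] == int(Tissue.GRAY)
        hit = cand[sel]
        labels[hit[:, 0], hit[:, 1], hit[:, 2]] = -1  # provisional cleft marker
    # keep the cleft strictly inside the gray shell: carved voxels that touch
    # white matter revert to gray so white never borders CSF
    cleft = labels == -1
    touches_white = np.zeros_like(cleft)
    white = labels == int(Tissue.WHITE)
    for ax in range(3):
        for shift in (1, -1):
            touches_white |= cleft & np.roll(white, shift, axis=ax)
    labels[cleft & touches_white] = int(Tissue.GRAY)
    labels[cleft & ~touches_white] = int(Tissue.CSF)


def generate_head_phantom(
    shape_params: HeadShapeParams | None = None,
    sulcus_params: SulcusParams | None = None,
    seed: int = 0,
    grid: GridSpec | None = None,
    world_to_canonical: np.ndarray | None = None,
) -> tuple[IntensityVolume, LabeledHeadVolume, PhantomTruth]:
    """Generate one synthetic head with intensity, labels and ground truth.

    Parameters
    ----------
    shape_params, sulcus_params, grid
        Geometry of the head, groove and voxel grid; defaults are desk-scale
        (96^3 voxels at 2 mm).
    seed
        Fixes the intensity noise; identical seeds give bit-identical output.
    world_to_canonical
        Optional 4x4 matrix mapping this phantom's world frame into the
        canonical (template) frame.  Identity produces the template itself;
        a non-trivial matrix produces a warped "individual" whose true
        individual->template affine is exactly this matrix.

    Returns
    -------
    (IntensityVolume, LabeledHeadVolume, PhantomTruth)
        ``PhantomTruth.sulcus_gt`` holds the ordered groove midline in this
        phantom's world frame and ``template_affine_gt`` the matrix above.
    """
    shape_params = shape_params or HeadShapeParams()
    sulcus_params = sulcus_params or SulcusParams()
    grid = grid or GridSpec()
    M = np.eye(4) if world_to_canonical is None else np.asarray(world_to_canonical, float)
    det = np.linalg.det(M[:3, :3])
    if abs(det) < 1e-12:
        raise TransformError("world_to_canonical affine is singular")
    Minv = np.linalg.inv(M)

    pts_world = grid.world_points()
    labels_flat = _canonical_labels(apply_affine(M, pts_world), shape_params)
    labels = labels_flat.reshape(grid.shape)
    _carve_cleft(labels, grid, shape_params, sulcus_params, Minv)

    rng = np.random.default_rng(seed)
    means = np.zeros(max(TISSUE_INTENSITY) + 1)
    for tissue, mean in TISSUE_INTENSITY.items():
        means[int(tissue)] = mean
    values = means[labels] + rng.normal(0.0, INTENSITY_NOISE_SD, size=labels.shape)

    t = np.linspace(-1, 1, sulcus_params.n_points)
    sulcus_world = apply_affine(Minv, sulcus_midline(t, shape_params, sulcus_params))
    cx, cy, cz = shape_params.center
    ay = shape_params.skin_axes[1]
    nasion = apply_affine(Minv, np.array([cx, cy + ay, cz]))
    inion = apply_affine(Minv, np.array([cx, cy - ay, cz]))

    truth = PhantomTruth(
        sulcus_gt=SulcusTrace(sulcus_world, "individual"),
        template_affine_gt=M,
        fiducials=FiducialSet(nasion, inion),
    )
    vol = IntensityVolume(values, grid.affine)
    lab = LabeledHeadVolume(labels, grid.affine)
    return vol, lab, truth


@dataclass
class PerturbParams:
    """A known 12-dof affine: scale, shear, rotation (deg), translation (mm)."""

    scales: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shears: tuple[float, float, float] = (0.0, 0.0, 0.0)  # xy, xz, yz
    rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def matrix(self) -> np.ndarray:
        """Compose T @ R @ Sh @ Sc as a 4x4 individual->template affine."""
        sx, sy, sz = self.scales
        if min(abs(sx), abs(sy), abs(sz)) < 1e-12:
            raise ParameterError("zero scale makes the perturbation singular")
        scale = np.diag([sx, sy, sz])
        hxy, hxz, hyz = self.shears
        shear = np.array([[1.0, hxy, hxz], [0.0, 1.0, hyz], [0.0, 0.0, 1.0]])
        rx, ry, rz = np.radians(self.rotations_deg)
        cx, sx_ = np.cos(rx), np.sin(rx)
        cy, sy_ = np.cos(ry), np.sin(ry)
        cz, sz_ = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx_], [0, sx_, cx]])
        Ry = np.array([[cy, 0, sy_], [0, 1, 0], [-sy_, 0, cy]])
        Rz = np.array([[cz, -sz_, 0], [sz_, cz, 0], [0, 0, 1]])
        lin = Rz @ Ry @ Rx @ shear @ scale
        out = np.eye(4)
        out[:3, :3] = lin
        out[:3, 3] = self.translation_mm
        if abs(np.linalg.det(lin)) < 1e-12:
            raise ParameterError("perturbation affine is singular")
        return out


@dataclass
class TemplatePair:
    """A template head plus a warped individual with known linking affine."""

    template_labels: LabeledHeadVolume
    template_sulcus: SulcusTrace
    individual_intensity: IntensityVolume
    individual_labels: LabeledHeadVolume
    truth: PhantomTruth


def generate_template_pair(
    base_params: HeadShapeParams | None = None,
    perturb_params: PerturbParams | None = None,
    seed: int = 0,
    sulcus_params: SulcusParams | None = None,
    grid: GridSpec | None = None,
) -> TemplatePair:
    """Generate a template head and an affinely warped individual.

    The individual is the canonical geometry evaluated through the known
    affine (plus independent intensity noise), so
    ``truth.template_affine_gt`` is exactly the applied matrix and the
    template sulcus has exactly ``sulcus_params.n_points`` (default 123)
    ordered points in template space.
    """
    base_params = base_params or HeadShapeParams()
    sulcus_params = sulcus_params or SulcusParams()
    perturb = perturb_params or PerturbParams()
    grid = grid or GridSpec()
    A = perturb.matrix()  # individual -> template

    _, tpl_labels, tpl_truth = generate_head_phantom(
        base_params, sulcus_params, seed=seed, grid=grid
    )
    template_sulcus = SulcusTrace(tpl_truth.sulcus_gt.points, "template")

    ind_int, ind_labels, ind_truth = generate_head_phantom(
        base_params, sulcus_params, seed=seed + 1, grid=grid, world_to_canonical=A
    )
    return TemplatePair(
        template_labels=tpl_labels,
        template_sulcus=template_sulcus,
        individual_intensity=ind_int,
        individual_labels=ind_labels,
        truth=ind_truth,
    )


def three_shell_sphere(
    radii_mm: tuple[float, float, float] = (70.0, 78.0, 86.0),
    labels_out_to_in: tuple[int, int, int] = (Tissue.SKIN, Tissue.SKULL, Tissue.GRAY),
    grid: GridSpec | None = None,
) -> LabeledHeadVolume:
    """Concentric three-shell sphere (brain/skull/scalp) for solver validation."""
    r_in, r_mid, r_out = radii_mm
    if not 0 < r_in < r_mid < r_out:
        raise ParameterError("radii must be strictly increasing and positive")
    grid = grid or GridSpec()
    pts = grid.world_points()
    r = np.linalg.norm(pts, axis=1).reshape(grid.shape)
    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[r <= r_out] = int(labels_out_to_in[0])
    labels[r <= r_mid] = int(labels_out_to_in[1])
    labels[r <= r_in] = int(labels_out_to_in[2])
    return LabeledHeadVolume(labels, grid.affine)


def check_tissue_nesting(labels: LabeledHeadVolume) -> bool:
    """True when no white voxel is 6-adjacent to air (outside-in nesting)."""
    lab = labels.labels
    white = lab == int(Tissue.WHITE)
    air = np.pad(lab == int(Tissue.AIR), 1, constant_values=True)
    for ax in range(3):
        for sl in (slice(0, -2), slice(2, None)):
            idx = [slice(1, -1)] * 3
            idx[ax] = sl
            if np.any(white & air[tuple(idx)]):
                return False
    return True


def default_individual(seed: int = 0, grid: GridSpec | None = None) -> TemplatePair:
    """Convenience: a template pair with a mild, representative perturbation."""
    perturb = PerturbParams(
        scales=(1.06, 0.95, 1.03),
        shears=(0.03, 0.0, -0.02),
        rotations_deg=(4.0, -3.0, 5.0),
        translation_mm=(4.0, -6.0, 3.0),
    )
    return generate_template_pair(perturb_params=perturb, seed=seed, grid=grid)
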