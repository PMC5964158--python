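"""Brain/scalp extraction and affine normalisation to the template.

The registration is deliberately two-stage: a closed-form moment match
(centroid + principal axes + per-axis scale) followed by a Nelder-Mead polish
of all 12 parameters on a smoothed mask-overlap loss.  Point mapping is an
exact matrix multiply; no volume is ever resampled.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, optimize
from skimage.filters import threshold_multiotsu, threshold_otsu

from repe.core import AffineTransform, BinaryMask, IntensityVolume, SulcusTrace
from repe.errors import RegistrationError, SegmentationError


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        raise SegmentationError("mask is empty")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def extract_brain_and_scalp(
    vol: IntensityVolume,
    air_threshold: float | str = "auto",
    brain_threshold: float | str = "auto",
) -> tuple[BinaryMask, BinaryMask]:
    """Segment the head (iScalp) and the brain (iBrain) from an intensity image.

    ``iScalp`` is the filled largest non-air connected component after
    morphological closing.  ``iBrain`` is the deepest bright component inside
    it: thresholding above skull/CSF intensity splits the head into an outer
    skin/fat shell and the gray+white core, which are separated by the
    skull+CSF gap; the component with the greatest mean depth below the scalp
    surface is the brain.

    Thresholds may be numbers or ``"auto"`` (Otsu / multi-Otsu).
    """
    data = vol.values
    if air_threshold == "auto":
        air_threshold = float(threshold_otsu(data))
    head = data > air_threshold
    if not head.any():
        raise SegmentationError("no voxels above the air threshold")
    head = ndimage.binary_closing(head, structure=np.ones((3, 3, 3)), iterations=1)
    head = _largest_component(head)
    head = ndimage.binary_fill_holes(head)
    iscalp = BinaryMask(head, vol.affine, role_tag="iScalp")

    inside = data[head]
    if brain_threshold == "auto":
        # First of three multi-Otsu cuts separates the dark CSF/skull gap
        # from the gray-and-brighter tissues without clipping the gray mode.
        brain_threshold = float(threshold_multiotsu(inside, classes=4)[0])
    bright = head & (data > brain_threshold)
    if not bright.any():
        raise SegmentationError("no voxels above the brain threshold")
    bright = ndimage.binary_opening(bright, structure=_ball(1))
    lab, n = ndimage.label(bright)
    if n == 0:
        raise SegmentationError("brain thresholding left no connected component")
    depth = ndimage.distance_transform_edt(head, sampling=vol.voxel_size)
    best, best_score = 0, -np.inf
    for comp in range(1, n + 1):
        m = lab == comp
        size = m.sum()
        if size < 50:
            continue
        score = float(depth[m].mean())
        if score > best_score:
            best, best_score = comp, score
    if best == 0:
        raise SegmentationError("no candidate brain component of plausible size")
    brain = ndimage.binary_fill_holes(lab == best)
    if not np.all(head[brain]):
        raise SegmentationError("brain mask escapes the scalp mask")
    return BinaryMask(brain, vol.affine, role_tag="iBrain"), iscalp


def _ball(r: int) -> np.ndarray:
    g = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (g**2).sum(axis=0) <= r * r


def _moments(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = points.mean(axis=0)
    centered = points - mu
    cov = centered.T @ centered / len(points)
    return mu, cov


def _principal_frame(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvectors (columns, sign-fixed, sorted by descending eigenvalue)."""
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    for k in range(3):
        j = int(np.argmax(np.abs(v[:, k])))
        if v[j, k] < 0:
            v[:, k] = -v[:, k]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return w, v


def _moment_affine(moving_pts: np.ndarray, fixed_pts: np.ndarray) -> np.ndarray:
    """Closed-form affine (moving -> fixed) matching centroid and covariance."""
    mu_m, cov_m = _moments(moving_pts)
    mu_f, cov_f = _moments(fixed_pts)
    w_m, v_m = _principal_frame(cov_m)
    w_f, v_f = _principal_frame(cov_f)
    if np.any(w_m <= 0) or np.any(w_f <= 0):
        raise RegistrationError("degenerate mask: coplanar or collinear support")
    lin = v_f @ np.diag(np.sqrt(w_f / w_m)) @ v_m.T
    out = np.eye(4)
    out[:3, :3] = lin
    out[:3, 3] = mu_f - lin @ mu_m
    return out


def _boundary_points(mask: BinaryMask, max_points: int) -> np.ndarray:
    """World coordinates of boundary *face centres* of the mask.

    Face centres (between a mask voxel and an outside 6-neighbour) sit on the
    voxelised surface itself, matching the zero level of a signed distance
    field built from a voxel mask; voxel centres would be biased half a voxel
    inward.
    """
    m = np.pad(mask.mask, 1)
    pts = []
    for ax in range(3):
        for sign in (1, -1):
            neighbour = np.roll(m, -sign, axis=ax)
            faces = np.argwhere((m & ~neighbour)[1:-1, 1:-1, 1:-1]).astype(float)
            faces[:, ax] += 0.5 * sign
            pts.append(faces)
    pts = np.concatenate(pts, axis=0)
    if len(pts) > max_points:
        pts = pts[:: int(np.ceil(len(pts) / max_points))]
    return mask.voxel_to_world(pts)


class _SignedDistanceResiduals:
    """Residuals for affine refinement: signed distance (mm) of mapped
    moving-boundary points to the fixed mask's boundary.

    Surface-to-surface matching constrains all 12 parameters (no volume
    plateau as with plain overlap scores), and least squares averages away
    the +-half-voxel quantisation noise of both boundaries.
    """

    def __init__(self, moving: BinaryMask, fixed: BinaryMask, max_points: int = 20000):
        inside = ndimage.distance_transform_edt(fixed.mask, sampling=fixed.voxel_size)
        outside = ndimage.distance_transform_edt(~fixed.mask, sampling=fixed.voxel_size)
        self.sdf = (outside - inside).astype(np.float32)
        self.world_to_voxel = np.linalg.inv(fixed.affine)
        self.pts = _boundary_points(moving, max_points)

    def __call__(self, params: np.ndarray) -> np.ndarray:
        mat = params.reshape(3, 4)
        mapped = self.pts @ mat[:, :3].T + mat[:, 3]
        vox = mapped @ self.world_to_voxel[:3, :3].T + self.world_to_voxel[:3, 3]
        return ndimage.map_coordinates(self.sdf, vox.T, order=1, mode="nearest")


def fit_affine(
    moving: BinaryMask,
    fixed: BinaryMask,
    refine: bool = True,
    max_points: int = 20000,
) -> AffineTransform:
    """Estimate the 12-parameter world-mm affine mapping ``moving`` onto ``fixed``.

    Two stages: closed-form moment matching (exact up to an orthogonal
    ambiguity when shears are present) then Levenberg-Marquardt refinement of
    all 12 parameters on signed boundary distances.

    Raises
    ------
    RegistrationError
        If either mask is empty or has degenerate (coplanar) support.
    """
    if moving.n_voxels == 0 or fixed.n_voxels == 0:
        raise RegistrationError("cannot register an empty mask")
    init = _moment_affine(moving.world_points(), fixed.world_points())
    if not refine:
        return AffineTransform(init)
    residuals = _SignedDistanceResiduals(moving, fixed, max_points=max_points)
    res = optimize.least_squares(
        residuals, init[:3, :4].ravel(), method="lm", xtol=1e-12, ftol=1e-12
    )
    out = np.eye(4)
    out[:3, :4] = res.x.reshape(3, 4)
    return AffineTransform(out)


def map_template_sulcus(mni_cs: SulcusTrace, tm: AffineTransform) -> SulcusTrace:
    """Map a template-space sulcus into individual space through TM^-1.

    Order and count are preserved exactly (123 points in, 123 points out).
    """
    if mni_cs.space_tag != "template":
        raise ValueError("map_template_sulcus expects a template-space trace")
    inv = tm.inverse()
    return SulcusTrace(inv.apply(mni_cs.points), "individual")
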