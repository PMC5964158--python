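"""Shared spatial data structures.

Conventions used throughout the package:

* world frame is RAS-oriented, in millimetres;
* voxel indices are 0-based; ``world = affine @ (i, j, k, 1)``;
* affine matrices are 4x4 homogeneous, acting on world coordinates unless
  stated otherwise.
"""

from __future__ import annotations

import gzip
import io
import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import nibabel as nib
import numpy as np

from repe.errors import ParameterError, TransformError


class Tissue(IntEnum):
    """Label values of a :class:`LabeledHeadVolume`, nested outside-in."""

    AIR = 0
    SKIN = 1
    FAT = 2
    SKULL = 3
    CSF = 4
    GRAY = 5
    WHITE = 6
    GEL = 7  # electrode contact gel, added by the fields module


def apply_affine(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 homogeneous matrix to an (n, 3) array of points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = pts @ matrix[:3, :3].T + matrix[:3, 3]
    return out.reshape(np.shape(points))


def _check_affine(matrix: np.ndarray, what: str = "affine") -> np.ndarray:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise TransformError(f"{what} must be 4x4, got {matrix.shape}")
    det = np.linalg.det(matrix[:3, :3])
    if not np.isfinite(det) or abs(det) < 1e-12:
        raise TransformError(f"{what} is singular (det={det!r})")
    return matrix


@dataclass
class AffineTransform:
    """A 12-parameter world-mm affine (by convention individual -> template)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = _check_affine(self.matrix, "AffineTransform.matrix")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1]):
            raise TransformError("bottom row of an affine must be (0, 0, 0, 1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return apply_affine(self.matrix, points)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def save(self, path: str | Path) -> None:
        """Write as a plain-text 4x4 matrix (one row per line)."""
        np.savetxt(path, self.matrix, fmt="%.17g")

    @classmethod
    def load(cls, path: str | Path) -> "AffineTransform":
        return cls(np.loadtxt(path).reshape(4, 4))

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))


@dataclass
class _GriddedVolume:
    """Mixin-style base for arrays living on a voxel grid with a world affine."""

    affine: np.ndarray = field(init=False, repr=False)

    def _init_grid(self, affine: np.ndarray) -> None:
        self.affine = _check_affine(affine)

    @property
    def voxel_size(self) -> np.ndarray:
        """Millimetres per voxel along each axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        return apply_affine(self.affine, np.asarray(indices, dtype=float))

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        return apply_affine(np.linalg.inv(self.affine), points)


@dataclass
class IntensityVolume(_GriddedVolume):
    """A scalar intensity image (synthetic stand-in for a T1 head scan)."""

    values: np.ndarray

    def __init__(self, values: np.ndarray, affine: np.ndarray):
        self.values = np.asarray(values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ParameterError("IntensityVolume.values must be 3D")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("IntensityVolume.values must be finite")
        self._init_grid(affine)

    def save(self, path: str | Path) -> None:
        save_nifti(self.values, self.affine, path)

    @classmethod
    def load(cls, path: str | Path) -> "IntensityVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=np.float32), img.affine)


@dataclass
class LabeledHeadVolume(_GriddedVolume):
    """Voxel grid of tissue labels (see :class:`Tissue`) with a world affine."""

    labels: np.ndarray

    def __init__(self, labels: np.ndarray, affine: np.ndarray):
        self.labels = np.asarray(labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ParameterError("labels must be integer-typed")
        self.labels = self.labels.astype(np.int16, copy=False)
        if self.labels.ndim != 3:
            raise ParameterError("LabeledHeadVolume.labels must be 3D")
        self._init_grid(affine)

    def mask(self, *tissues: Tissue | int) -> np.ndarray:
        return np.isin(self.labels, [int(t) for t in tissues])

    @property
    def head_mask(self) -> np.ndarray:
        return self.labels > 0

    def save(self, path: str | Path) -> None:
        save_nifti(self.labels, self.affine, path)

    @classmethod
    def load(cls, path: str | Path) -> "LabeledHeadVolume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj).astype(np.int16), img.affine)


@dataclass
class BinaryMask(_GriddedVolume):
    """Boolean voxel mask (brain or scalp extraction result)."""

    mask: np.ndarray
    role_tag: str = ""

    def __init__(self, mask: np.ndarray, affine: np.ndarray, role_tag: str = ""):
        self.mask = np.asarray(mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ParameterError("BinaryMask.mask must be 3D")
        self.role_tag = role_tag
        self._init_grid(affine)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def world_points(self) -> np.ndarray:
        """World coordinates (n, 3) of the set voxel centres."""
        idx = np.argwhere(self.mask)
        return self.voxel_to_world(idx)

    def save(self, path: str | Path) -> None:
        save_nifti(self.mask.astype(np.uint8), self.affine, path)


SPACE_TAGS = ("template", "individual", "scalp", "plane")


@dataclass
class SulcusTrace:
    """Ordered 3D polyline carried through the pipeline.

    ``space_tag`` records which coordinate frame the points live in:
    ``template`` (the shared atlas phantom), ``individual`` (subject world mm),
    ``scalp`` (on the scalp surface) or ``plane`` (flattened; z == 0).
    """

    points: np.ndarray
    space_tag: str

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.space_tag not in SPACE_TAGS:
            raise ParameterError(
                f"space_tag must be one of {SPACE_TAGS}, got {self.space_tag!r}"
            )
        if len(self.points) < 2:
            raise ParameterError("a trace needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("trace points must be finite")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if not np.any(seg > 0):
            raise ParameterError("trace has zero total length")
        # Zero-length segments are tolerated (minimal-distance projection can
        # send neighbouring points to the same surface point while preserving
        # point count); use dedupe() before operations that require strictly
        # distinct consecutive points.
        if self.space_tag == "plane" and np.any(self.points[:, 2] != 0):
            raise ParameterError("planar traces must have zero third coordinate")

    def __len__(self) -> int:
        return len(self.points)

    def has_duplicates(self) -> bool:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return bool(np.any(seg == 0))

    def dedupe(self) -> "SulcusTrace":
        """Collapse consecutive duplicate points (keeps the first of each run)."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        keep = np.concatenate([[True], seg > 0])
        return SulcusTrace(self.points[keep], self.space_tag)

    @property
    def length(self) -> float:
        """Total polyline length in mm."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def arc_lengths(self) -> np.ndarray:
        """Cumulative chord length at each point, starting at 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def resample(self, spacing_mm: float) -> np.ndarray:
        """Points at uniform arc-length spacing along the polyline (n, 3)."""
        s = self.arc_lengths()
        target = np.arange(0.0, s[-1] + spacing_mm / 2, spacing_mm)
        target = np.clip(target, 0.0, s[-1])
        out = np.empty((len(target), 3))
        for ax in range(3):
            out[:, ax] = np.interp(target, s, self.points[:, ax])
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"space_tag": self.space_tag, "points_mm": self.points.tolist()},
                indent=1,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "SulcusTrace":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["points_mm"]), d["space_tag"])


@dataclass
class FiducialSet:
    """Nasion and inion world coordinates (mm), on the scalp surface."""

    nasion: np.ndarray
    inion: np.ndarray

    def __post_init__(self):
        self.nasion = np.asarray(self.nasion, dtype=float).reshape(3)
        self.inion = np.asarray(self.inion, dtype=float).reshape(3)


@dataclass
class PhantomTruth:
    """Ground truth attached to a synthetic head: sulcus, affine, fiducials."""

    sulcus_gt: SulcusTrace
    template_affine_gt: np.ndarray
    fiducials: FiducialSet

    def __post_init__(self):
        self.template_affine_gt = _check_affine(
            self.template_affine_gt, "template_affine_gt"
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "sulcus_gt": {
                        "space_tag": self.sulcus_gt.space_tag,
                        "points_mm": self.sulcus_gt.points.tolist(),
                    },
                    "template_affine_gt": self.template_affine_gt.tolist(),
                    "fiducials": {
                        "nasion_mm": self.fiducials.nasion.tolist(),
                        "inion_mm": self.fiducials.inion.tolist(),
                    },
                },
                indent=1,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            SulcusTrace(
                np.asarray(d["sulcus_gt"]["points_mm"]), d["sulcus_gt"]["space_tag"]
            ),
            np.asarray(d["template_affine_gt"]),
            FiducialSet(
                np.asarray(d["fiducials"]["nasion_mm"]),
                np.asarray(d["fiducials"]["inion_mm"]),
            ),
        )


def save_nifti(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    """Write a NIfTI-1 file; ``.nii.gz`` output is byte-deterministic.

    The standard library gzip header embeds a timestamp, which would make
    repeated runs produce different bytes; we pin ``mtime=0`` so that
    identical arrays yield identical files (pipeline manifests rely on it).
    """
    img = nib.Nifti1Image(np.asarray(data), np.asarray(affine, dtype=float))
    path = Path(path)
    raw = img.to_bytes()
    if path.name.endswith(".gz"):
        buf = io.BytesIO()
        with gzip.GzipFile(fileobj=buf, mode="wb", mtime=0) as fh:
            fh.write(raw)
        path.write_bytes(buf.getvalue())
    else:
        path.write_bytes(raw)
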