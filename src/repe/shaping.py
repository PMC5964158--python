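"""Sulcus-to-scalp projection and printable electrode construction.

Pipeline: triangulate the scalp mask (marching cubes), replace each sulcus
point by its closest point on the surface (exact point-triangle minimum over
all triangles), unroll the scalp trace to a plane by arc length, offset it by
the electrode width and close the polygon, then export at true scale as SVG
(1 user unit = 1 mm).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.spatial import cKDTree
from skimage import measure

from repe.core import BinaryMask, SulcusTrace
from repe.errors import GeometryError, ParameterError, ProjectionError


@dataclass
class ScalpSurface:
    """Closed triangulated surface in world mm with outward-oriented normals."""

    vertices: np.ndarray
    triangles: np.ndarray
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)

    # -- topology -----------------------------------------------------------
    def edges(self) -> np.ndarray:
        """Unique undirected edges (E, 2), sorted vertex pairs."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def euler_characteristic(self) -> int:
        return len(self.vertices) - len(self.edges()) + len(self.triangles)

    def is_closed_manifold(self) -> bool:
        """Every undirected edge is used by exactly two triangles."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        _, counts = np.unique(np.sort(e, axis=1), axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    # -- geometry -----------------------------------------------------------
    def triangle_corners(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        v = self.vertices
        t = self.triangles
        return v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]

    def face_normals(self) -> np.ndarray:
        """Unit normals oriented away from the surface centroid (outward for
        star-shaped scalps)."""
        a, b, c = self.triangle_corners()
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        n = n / np.where(norm == 0, 1.0, norm)
        centers = (a + b + c) / 3.0
        outward = np.einsum("ij,ij->i", n, centers - self.vertices.mean(axis=0))
        n[outward < 0] *= -1
        return n

    def area(self) -> float:
        a, b, c = self.triangle_corners()
        return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())

    def vertex_tree(self) -> cKDTree:
        if self._tree is None:
            self._tree = cKDTree(self.vertices)
        return self._tree

    def edge_graph(self):
        """Sparse symmetric vertex graph weighted by edge length (for geodesics)."""
        e = self.edges()
        w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        n = len(self.vertices)
        g = coo_matrix(
            (np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(n, n),
        )
        return g.tocsr()


def surface_from_mask(iscalp: BinaryMask, smoothing_voxels: float = 1.0) -> ScalpSurface:
    """Marching-cubes triangulation of a binary mask boundary, in world mm.

    The mask is padded by one voxel so the result is always a closed surface.
    A light Gaussian smoothing of the indicator field (default 1 voxel)
    removes the staircase bias of a raw binary triangulation while moving the
    surface by well under a voxel.
    """
    if iscalp.n_voxels == 0:
        raise GeometryError("cannot build a surface from an empty mask")
    padded = np.pad(iscalp.mask, 2).astype(np.float32)
    if smoothing_voxels > 0:
        from scipy.ndimage import gaussian_filter

        padded = gaussian_filter(padded, sigma=smoothing_voxels)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    verts -= 1.0  # second padding layer; first is handled below
    verts = (verts - 1.0) @ iscalp.affine[:3, :3].T + iscalp.affine[:3, 3]
    surf = ScalpSurface(verts, faces)
    if not surf.is_closed_manifold():
        raise GeometryError("marching cubes produced a non-manifold surface")
    return surf


def closest_point_on_triangles(p: np.ndarray, a, b, c):
    """Closest point to ``p`` on each triangle (a, b, c): (points, sq_dists).

    Vectorised over triangles; standard barycentric region classification.
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    result = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    reg = (d1 <= 0) & (d2 <= 0)  # vertex a
    result[reg] = a[reg]
    done |= reg
    reg = ~done & (d3 >= 0) & (d4 <= d3)  # vertex b
    result[reg] = b[reg]
    done |= reg
    reg = ~done & (d6 >= 0) & (d5 <= d6)  # vertex c
    result[reg] = c[reg]
    done |= reg

    vc = d1 * d4 - d3 * d2
    reg = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge ab
    v = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1, d1 - d3), 0.0)
    result[reg] = a[reg] + v[reg, None] * ab[reg]
    done |= reg

    vb = d5 * d2 - d1 * d6
    reg = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge ac
    w = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1, d2 - d6), 0.0)
    result[reg] = a[reg] + w[reg, None] * ac[reg]
    done |= reg

    va = d3 * d6 - d5 * d4
    reg = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge bc
    denom = (d4 - d3) + (d5 - d6)
    w = np.where(denom != 0, (d4 - d3) / np.where(denom == 0, 1, denom), 0.0)
    result[reg] = b[reg] + w[reg, None] * (c[reg] - b[reg])
    done |= reg

    inside = ~done  # interior
    denom = va + vb + vc
    denom = np.where(denom == 0, 1.0, denom)
    v = vb / denom
    w = vc / denom
    result[inside] = (
        a[inside] + v[inside, None] * ab[inside] + w[inside, None] * ac[inside]
    )
    d = result - p
    return result, np.einsum("ij,ij->i", d, d)


def closest_points_on_surface(
    surf: ScalpSurface, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact nearest surface point for each query: (points, distances, tri_idx).

    Brute force over all triangles per query (ties broken by lowest triangle
    index, the behaviour ``np.argmin`` gives for free).
    """
    a, b, c = surf.triangle_corners()
    points = np.atleast_2d(np.asarray(points, dtype=float))
    out_pts = np.empty((len(points), 3))
    out_d = np.empty(len(points))
    out_tri = np.empty(len(points), dtype=np.int64)
    for i, p in enumerate(points):
        cand, d2 = closest_point_on_triangles(p, a, b, c)
        j = int(np.argmin(d2))
        out_pts[i] = cand[j]
        out_d[i] = np.sqrt(d2[j])
        out_tri[i] = j
    return out_pts, out_d, out_tri


def is_inside_surface(surf: ScalpSurface, points: np.ndarray) -> np.ndarray:
    """Inside test via the sign of (p - closest point) against the face normal."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    closest, dist, tri = closest_points_on_surface(surf, points)
    normals = surf.face_normals()[tri]
    side = np.einsum("ij,ij->i", points - closest, normals)
    return (side < 0) | (dist < 1e-9)


def project_to_scalp(
    ics: SulcusTrace, surf: ScalpSurface, check_inside: bool = True
) -> SulcusTrace:
    """Minimal-distance projection of an individual-space trace onto the scalp.

    Each point is replaced by its exact nearest point on the triangulated
    surface; order and count are preserved.  Points outside the surface raise
    :class:`ProjectionError`.
    """
    if check_inside:
        inside = is_inside_surface(surf, ics.points)
        if not np.all(inside):
            k = int(np.argmin(inside))
            raise ProjectionError(
                f"trace point {k} at {ics.points[k]} lies outside the scalp surface"
            )
    projected, _, _ = closest_points_on_surface(surf, ics.points)
    return SulcusTrace(projected, "scalp")


def flatten_trace(icss: SulcusTrace) -> SulcusTrace:
    """Arc-length unrolling: point i maps to (cumulative chord length, 0, 0).

    Isometric along the trace, so the printed electrode wraps the scalp with
    the correct along-trace length; total planar length equals the 3D
    polyline length exactly.  Consecutive duplicate points are rejected
    (``SulcusTrace.dedupe`` first).
    """
    if icss.has_duplicates():
        raise ParameterError("duplicate consecutive points; dedupe the trace first")
    s = icss.arc_lengths()
    flat = np.zeros((len(s), 3))
    flat[:, 0] = s
    return SulcusTrace(flat, "plane")


@dataclass
class ElectrodeOutline:
    """Printable electrode polygon (planar, mm) plus its scalp footprint."""

    plane_polygon: np.ndarray  # (n, 2) closed implicitly (last != first)
    scalp_footprint: np.ndarray  # (m, 3) the 3D scalp points of the sulcus edge
    width_mm: float
    area_mm2: float


def polygon_area(poly: np.ndarray) -> float:
    """Shoelace area (positive regardless of orientation)."""
    x, y = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def _segments_intersect(p, q, r, s) -> bool:
    def orient(a, b, c):
        return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

    return (
        orient(p, q, r) != orient(p, q, s)
        and orient(r, s, p) != orient(r, s, q)
    )


def polygon_is_simple(poly: np.ndarray) -> bool:
    """True when no two non-adjacent polygon edges intersect (O(n^2) scan)."""
    n = len(poly)
    edges = [(poly[i], poly[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue
            if _segments_intersect(*edges[i], *edges[j]):
                return False
    return True


def build_electrode_outline(
    icssp: SulcusTrace,
    width_mm: float = 20.0,
    scalp_footprint: np.ndarray | None = None,
) -> ElectrodeOutline:
    """Offset the flattened trace by ``width_mm`` and close it into a polygon.

    The parallel copy is placed on the negative-y side (anterior when worn,
    so the original trace is the electrode's sulcus-side border); the two
    traces are joined by straight lateral segments.  After arc-length
    flattening the trace lies on the x-axis, so the polygon is a rectangle
    with area = trace length x width exactly.
    """
    if icssp.space_tag != "plane":
        raise ParameterError("build_electrode_outline expects a flattened trace")
    if width_mm <= 0:
        raise GeometryError("electrode width must be positive")
    top = icssp.points[:, :2]
    bottom = top[::-1].copy()
    bottom[:, 1] -= width_mm
    poly = np.concatenate([top, bottom], axis=0)
    if not polygon_is_simple(poly):
        raise GeometryError("electrode outline is self-intersecting")
    area = polygon_area(poly)
    if area <= 0:
        raise GeometryError("electrode outline has zero area")
    return ElectrodeOutline(
        plane_polygon=poly,
        scalp_footprint=(
            np.asarray(scalp_footprint, dtype=float)
            if scalp_footprint is not None
            else np.empty((0, 3))
        ),
        width_mm=float(width_mm),
        area_mm2=area,
    )


SVG_NS = "http://www.w3.org/2000/svg"
RULER_MM = 100.0


def export_outline(outline: ElectrodeOutline, path: str | Path) -> Path:
    """Write the outline as true-scale SVG (1 user unit = 1 mm).

    Includes a horizontal 100 mm calibration ruler below the polygon so a
    printout can be verified before cutting.
    """
    poly = outline.plane_polygon
    xmin, ymin = poly.min(axis=0) - 10
    xmax, ymax = poly.max(axis=0) + 10
    ymax += 20  # room for the ruler
    w, h = xmax - xmin, ymax - ymin

    ET.register_namespace("", SVG_NS)
    svg = ET.Element(
        "svg",
        {
            "xmlns": SVG_NS,
            "width": f"{w}mm",
            "height": f"{h}mm",
            "viewBox": f"{xmin} {ymin} {w} {h}",
        },
    )
    pts = " ".join(f"{x:.9f},{y:.9f}" for x, y in poly)
    ET.SubElement(
        svg,
        "polygon",
        {"points": pts, "fill": "none", "stroke": "black", "stroke-width": "0.5"},
    )
    y_r = poly[:, 1].max() + 12
    x_r = poly[:, 0].min()
    ET.SubElement(
        svg,
        "line",
        {
            "id": "ruler",
            "x1": f"{x_r}",
            "y1": f"{y_r}",
            "x2": f"{x_r + RULER_MM}",
            "y2": f"{y_r}",
            "stroke": "black",
            "stroke-width": "0.5",
        },
    )
    text = ET.SubElement(
        svg, "text", {"x": f"{x_r}", "y": f"{y_r + 5}", "font-size": "4"}
    )
    text.text = f"{RULER_MM:.0f} mm ruler"
    path = Path(path)
    ET.ElementTree(svg).write(path, xml_declaration=True, encoding="unicode")
    return path


def parse_outline_svg(path: str | Path) -> tuple[np.ndarray, float]:
    """Read back (polygon vertices (n, 2), ruler length) from an exported SVG."""
    root = ET.parse(str(path)).getroot()
    polygon = root.find(f"{{{SVG_NS}}}polygon")
    if polygon is None:
        raise GeometryError("SVG contains no polygon")
    pts = np.array(
        [[float(v) for v in pair.split(",")] for pair in polygon.get("points").split()]
    )
    ruler = root.find(f"{{{SVG_NS}}}line[@id='ruler']")
    length = abs(float(ruler.get("x2")) - float(ruler.get("x1")))
    return pts, length
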