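"""Quasi-static volume-conductor solver and montage dosimetry.

The potential obeys ``div(sigma grad V) = 0`` with insulating (Neumann)
outer boundaries and electrode current injection.  Discretisation is a
7-point voxel finite-volume stencil with harmonic-mean face conductivities,
solved by Jacobi-preconditioned conjugate gradients.  The pure-Neumann
problem has a constant nullspace; the gauge is fixed by removing the mean
potential over the conducting domain.

Electrode patches live on the scalp shell (outermost head voxels).  Patch
geometry (personalised bands, straight strips, pads, rings) is built with
on-surface distances computed by Dijkstra over the 26-connected shell voxel
graph.  Each patch gets a 2-voxel conductive-gel cap dilated into the air
above it, and the total current is divided uniformly over the gel contact
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.sparse.linalg import cg
from scipy.spatial import cKDTree

from repe.core import FiducialSet, LabeledHeadVolume, SulcusTrace, Tissue
from repe.errors import ConfigError, ParameterError, PlacementError, SolverError

#: Tissue conductivities in S/m.
DEFAULT_SIGMA = {
    int(Tissue.AIR): 1e-4,
    int(Tissue.SKIN): 0.465,
    int(Tissue.FAT): 0.025,
    int(Tissue.SKULL): 0.01,
    int(Tissue.CSF): 1.65,
    int(Tissue.GRAY): 0.276,
    int(Tissue.WHITE): 0.126,
    int(Tissue.GEL): 0.3,
}

ANODE = "anode"
CATHODE = "cathode"


@dataclass
class ConductivityVolume:
    """Per-voxel conductivity (S/m) plus the solved (conducting) domain."""

    sigma: np.ndarray
    affine: np.ndarray
    active: np.ndarray  # bool: voxels included in the solve

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


def conductivity_from_labels(
    labels: LabeledHeadVolume, tissue_model: dict[int, float] | None = None
) -> ConductivityVolume:
    """Elementwise conductivity lookup; exterior air is excluded from the domain.

    Air that is *enclosed* by the head keeps its (tiny) conductivity and stays
    in the domain; the exterior air component touching the grid boundary is
    excluded entirely (insulating Neumann boundary at the head surface).
    """
    model = DEFAULT_SIGMA if tissue_model is None else tissue_model
    present = np.unique(labels.labels)
    missing = [int(v) for v in present if int(v) not in model]
    if missing:
        raise ConfigError(f"no conductivity defined for labels {missing}")
    for lab, s in model.items():
        if s <= 0:
            raise ConfigError(f"conductivity for label {lab} must be positive")
    lut = np.zeros(max(model) + 1)
    for lab, s in model.items():
        lut[lab] = s
    sigma = lut[labels.labels]

    air = labels.labels == int(Tissue.AIR)
    comp, n = ndimage.label(air)
    exterior = np.zeros_like(air)
    if n:
        border_labels = np.unique(
            np.concatenate(
                [
                    comp[0].ravel(), comp[-1].ravel(),
                    comp[:, 0].ravel(), comp[:, -1].ravel(),
                    comp[:, :, 0].ravel(), comp[:, :, -1].ravel(),
                ]
            )
        )
        exterior = np.isin(comp, border_labels[border_labels > 0])
    return ConductivityVolume(sigma=sigma, affine=labels.affine, active=~exterior)


@dataclass
class ElectrodePatch:
    """A set of scalp voxels injecting (or returning) current.

    ``voxels`` are scalp-shell voxel indices; ``injection_voxels`` (filled in
    by :func:`add_gel_layers`, defaulting to the scalp voxels themselves) are
    where the per-voxel current loads are applied.  ``area_cm2`` is the
    design contact area used for current-density bookkeeping.
    """

    voxels: np.ndarray
    polarity: str
    current_ma: float
    area_cm2: float
    name: str = ""
    injection_voxels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)
        if len(self.voxels) == 0:
            raise PlacementError(f"electrode patch {self.name!r} is empty")
        if self.polarity not in (ANODE, CATHODE):
            raise ParameterError("polarity must be 'anode' or 'cathode'")
        if (self.polarity == ANODE) != (self.current_ma > 0):
            raise ParameterError("anode current must be > 0, cathode < 0")

    @property
    def sites(self) -> np.ndarray:
        return self.voxels if self.injection_voxels is None else self.injection_voxels


ANODE_SHIFTS_MM = (0, 5, 10, 15)


@dataclass
class MontageSpec:
    """Anode + cathode with an anterior anode shift in {0, 5, 10, 15} mm."""

    anode: ElectrodePatch
    cathode: ElectrodePatch
    anode_shift_mm: int = 0
    name: str = ""

    def __post_init__(self):
        if self.anode_shift_mm not in ANODE_SHIFTS_MM:
            raise ParameterError(f"anode shift must be one of {ANODE_SHIFTS_MM} mm")
        if abs(self.anode.current_ma + self.cathode.current_ma) > 1e-12:
            raise ParameterError("anode and cathode currents must sum to zero")
        a = {tuple(v) for v in self.anode.voxels}
        c = {tuple(v) for v in self.cathode.voxels}
        if a & c:
            raise PlacementError("anode and cathode patches overlap")


def concentric_sphere_conductivity(
    radii_mm: tuple[float, ...],
    sigmas: tuple[float, ...],
    grid,
    subsamples: int = 4,
    sigma_air: float = 1e-4,
) -> ConductivityVolume:
    """Anti-aliased conductivity for a concentric-sphere benchmark phantom.

    Each voxel's conductivity is the arithmetic mean over ``subsamples``^3
    subvoxel positions of the analytic layered sphere (partial-volume
    averaging).  This removes most of the first-order staircase error of a
    hard-labelled sphere and is the recommended way to validate the solver
    against the analytic series solution.  ``grid`` is a phantom GridSpec.
    """
    radii = np.asarray(radii_mm, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ParameterError("radii must be strictly increasing")
    if len(sigmas) != len(radii):
        raise ParameterError("need one conductivity per layer")
    table = np.array(list(sigmas) + [sigma_air])
    h = grid.voxel_size
    n = grid.shape
    axes = [np.arange(m) * h - (m - 1) * h / 2 for m in n]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    offs = ((np.arange(subsamples) + 0.5) / subsamples - 0.5) * h
    acc = np.zeros(n)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                r = np.sqrt((X + ox) ** 2 + (Y + oy) ** 2 + (Z + oz) ** 2)
                acc += table[np.searchsorted(radii, r)]
    sigma = acc / subsamples**3
    r_c = np.sqrt(X**2 + Y**2 + Z**2)
    active = r_c <= radii[-1]
    return ConductivityVolume(
        sigma=np.where(active, sigma, sigma_air), affine=grid.affine, active=active
    )


# ---------------------------------------------------------------------------
# Scalp shell geometry
# ---------------------------------------------------------------------------

def scalp_shell(labels: LabeledHeadVolume) -> np.ndarray:
    """Boolean mask of head voxels 6-adjacent to outside (the scalp shell)."""
    head = labels.head_mask
    interior = ndimage.binary_erosion(head, border_value=0)
    return head & ~interior


class ShellGraph:
    """26-connected graph over scalp-shell voxels with mm edge weights."""

    def __init__(self, labels: LabeledHeadVolume):
        self.labels = labels
        self.shell = scalp_shell(labels)
        self.idx = np.argwhere(self.shell)
        self.world = labels.voxel_to_world(self.idx)
        self.tree = cKDTree(self.world)
        node = -np.ones(labels.labels.shape, dtype=np.int64)
        node[tuple(self.idx.T)] = np.arange(len(self.idx))
        rows, cols, weights = [], [], []
        h = labels.voxel_size
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) > (0, 0, 0)
        ]
        shape = np.asarray(labels.labels.shape)
        for off in offsets:
            nb = self.idx + off
            ok = np.all((nb >= 0) & (nb < shape), axis=1)
            tgt = np.full(len(self.idx), -1, dtype=np.int64)
            tgt[ok] = node[tuple(nb[ok].T)]
            has = tgt >= 0
            rows.append(np.arange(len(self.idx))[has])
            cols.append(tgt[has])
            weights.append(
                np.full(has.sum(), float(np.linalg.norm(np.asarray(off) * h)))
            )
        r = np.concatenate(rows)
        c = np.concatenate(cols)
        w = np.concatenate(weights)
        n = len(self.idx)
        self.graph = sparse.coo_matrix(
            (np.r_[w, w], (np.r_[r, c], np.r_[c, r])), shape=(n, n)
        ).tocsr()

    def nearest_node(self, point_mm: np.ndarray, tol_mm: float = 10.0) -> int:
        d, i = self.tree.query(np.asarray(point_mm, dtype=float))
        if d > tol_mm:
            raise PlacementError(f"point {point_mm} is {d:.1f} mm off the scalp")
        return int(i)

    def distances_from(self, nodes: np.ndarray) -> np.ndarray:
        return dijkstra(self.graph, directed=False, indices=nodes, min_only=True)

    def path(self, a: int, b: int) -> np.ndarray:
        """World polyline of the shortest shell path between two nodes."""
        _, pred = dijkstra(
            self.graph, directed=False, indices=a, return_predecessors=True
        )
        chain = [b]
        while chain[-1] != a:
            p = pred[chain[-1]]
            if p < 0:
                raise PlacementError("scalp shell is disconnected")
            chain.append(int(p))
        return self.world[np.array(chain[::-1])]


def ni_midline_path(shell: ShellGraph, fiducials: FiducialSet) -> np.ndarray:
    """Nasion-to-inion shortest path over the scalp shell (world mm)."""
    return shell.path(
        shell.nearest_node(fiducials.nasion), shell.nearest_node(fiducials.inion)
    )


def landmark_at_fraction(path_mm: np.ndarray, fraction: float) -> np.ndarray:
    """Point at a given arc-length fraction along a polyline (0=start, 1=end)."""
    seg = np.linalg.norm(np.diff(path_mm, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = float(fraction) * s[-1]
    out = np.empty(3)
    for ax in range(3):
        out[ax] = np.interp(target, s, path_mm[:, ax])
    return out


# ---------------------------------------------------------------------------
# Patch construction
# ---------------------------------------------------------------------------

def band_patch(
    shell: ShellGraph,
    trace_points: np.ndarray,
    width_mm: float = 20.0,
    shift_mm: float = 0.0,
    polarity: str = ANODE,
    current_ma: float = 1.5,
    name: str = "band",
) -> ElectrodePatch:
    """Scalp band following a trace: the electrode's anterior (+y) border sits
    ``shift_mm`` ahead of the trace and the band extends ``width_mm`` behind it.

    On-surface offsets are Dijkstra distances from the trace ridge over the
    shell graph, signed by the anterior (+y) direction.  Voxels beyond the
    lateral ends of the trace are clipped so the band has square ends.
    """
    trace = SulcusTrace(np.asarray(trace_points, dtype=float), "scalp")
    dense = trace.resample(1.0)
    dtree = cKDTree(dense)
    d_euc, nearest = dtree.query(shell.world)
    h = float(shell.labels.voxel_size.max())
    sources = np.flatnonzero(d_euc <= 0.75 * h)
    if len(sources) == 0:
        raise PlacementError("trace does not touch the scalp shell")
    rho = shell.distances_from(sources)
    sign = np.sign(shell.world[:, 1] - dense[nearest, 1])
    signed = np.where(rho == 0, 0.0, sign * rho)
    interior = (nearest > 0) & (nearest < len(dense) - 1)
    lo, hi = shift_mm - width_mm, shift_mm
    sel = interior & (signed >= lo - h / 2) & (signed <= hi + h / 2)
    if not sel.any():
        raise PlacementError("band selection is empty")
    return ElectrodePatch(
        voxels=shell.idx[sel],
        polarity=polarity,
        current_ma=current_ma,
        area_cm2=trace.length * width_mm / 100.0,
        name=name,
    )


def straight_strip_trace(
    shell: ShellGraph, y_mm: float, length_mm: float
) -> np.ndarray:
    """A straight (coronal-plane) scalp trace at y = ``y_mm``, centred on the
    crown and truncated to ``length_mm`` of arc; the non-personalised strip."""
    h = float(shell.labels.voxel_size.max())
    sel = np.abs(shell.world[:, 1] - y_mm) <= 0.75 * h
    if sel.sum() < 3:
        raise PlacementError("no scalp voxels in the strip plane")
    pts = shell.world[sel]
    center = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 0] - center[0], pts[:, 2] - center[2])
    order = np.argsort(ang)
    poly = SulcusTrace(pts[order] + 0.0, "scalp").resample(1.0)
    # keep the crown-centred stretch of the requested length
    top = int(np.argmax(poly[:, 2]))
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    keep = np.abs(s - s[top]) <= length_mm / 2.0
    return poly[keep]


def disc_patch(
    shell: ShellGraph,
    center_mm: np.ndarray,
    area_cm2: float = 70.0,
    polarity: str = CATHODE,
    current_ma: float = -1.5,
    name: str = "pad",
) -> ElectrodePatch:
    """Circular pad of given area centred on a scalp point (geodesic radius)."""
    radius = np.sqrt(area_cm2 * 100.0 / np.pi)
    rho = shell.distances_from(np.array([shell.nearest_node(center_mm)]))
    sel = rho <= radius
    return ElectrodePatch(shell.idx[sel], polarity, current_ma, area_cm2, name=name)


def ring_patch(
    shell: ShellGraph,
    z_mm: float,
    height_mm: float = 20.0,
    polarity: str = CATHODE,
    current_ma: float = -1.5,
    name: str = "ring",
) -> ElectrodePatch:
    """Horizontal strip girdling the head (or neck) at height ``z_mm``."""
    sel = np.abs(shell.world[:, 2] - z_mm) <= height_mm / 2.0
    if not sel.any():
        raise PlacementError("ring selects no scalp voxels")
    h = float(shell.labels.voxel_size.max())
    area = sel.sum() * h * h / 100.0  # staircase estimate, reporting only
    return ElectrodePatch(shell.idx[sel], polarity, current_ma, area, name=name)


def place_anode(
    shell: ShellGraph,
    footprint_or_trace: np.ndarray,
    shift_mm: int = 0,
    kind: str = "repe",
    width_mm: float = 20.0,
    current_ma: float = 1.5,
) -> ElectrodePatch:
    """Anode band: personalised (follows the scalp sulcus trace) or straight.

    ``shift_mm`` (0/5/10/15) moves the band anteriorly along the surface; the
    anterior border of the unshifted band lies on the trace.
    """
    if shift_mm not in ANODE_SHIFTS_MM:
        raise ParameterError(f"shift must be one of {ANODE_SHIFTS_MM}")
    if kind == "repe":
        trace = np.asarray(footprint_or_trace, dtype=float)
    elif kind == "strip":
        ref = np.asarray(footprint_or_trace, dtype=float)
        length = SulcusTrace(ref, "scalp").length
        y_c = ref[len(ref) // 2, 1]
        trace = straight_strip_trace(shell, y_c, length)
    else:
        raise ParameterError("anode kind must be 'repe' or 'strip'")
    return band_patch(
        shell,
        trace,
        width_mm=width_mm,
        shift_mm=float(shift_mm),
        polarity=ANODE,
        current_ma=current_ma,
        name=f"{kind}_shift{shift_mm}",
    )


REFERENCES = ("oz", "neck", "shoulders", "ring")


def place_reference(
    shell: ShellGraph,
    reference: str,
    fiducials: FiducialSet,
    current_ma: float = -1.5,
    pad_area_cm2: float = 70.0,
) -> ElectrodePatch:
    """Return electrode: occipital pad, neck pad, neck-base ring ("shoulders"
    approximation, the phantom has no shoulders) or a head-girdling strip.

    Scalp landmarks are defined by arc fractions of the nasion-inion midline
    (Oz at 90%), the standard 10-10 convention transplanted to the phantom.
    """
    z = shell.world[:, 2]
    if reference == "oz":
        path = ni_midline_path(shell, fiducials)
        return disc_patch(
            shell, landmark_at_fraction(path, 0.90), pad_area_cm2,
            current_ma=current_ma, name="oz",
        )
    if reference == "neck":
        zmin = z.min()
        center = np.array([0.0, shell.world[z < zmin + 20, 1].min(), zmin + 30.0])
        node = shell.nearest_node(center, tol_mm=40.0)
        return disc_patch(
            shell, shell.world[node], pad_area_cm2, current_ma=current_ma, name="neck"
        )
    if reference == "shoulders":
        return ring_patch(
            shell, z.min() + 10.0, 25.0, current_ma=current_ma, name="shoulders"
        )
    if reference == "ring":
        # girdle the head below the crown (and below the anode band's ends)
        mid = (fiducials.nasion[2] + fiducials.inion[2]) / 2.0 - 25.0
        return ring_patch(shell, mid, 20.0, current_ma=current_ma, name="ring")
    raise ParameterError(f"unknown reference {reference!r}; use one of {REFERENCES}")


def add_gel_layers(
    labels: LabeledHeadVolume, patches: list[ElectrodePatch], n_layers: int = 2
) -> LabeledHeadVolume:
    """Dilate each patch into the air above it as conductive gel.

    Returns a new label volume with gel voxels set to ``Tissue.GEL``; each
    patch's ``injection_voxels`` are replaced by its gel voxels, over which
    the total current is divided uniformly.
    """
    new = labels.labels.copy()
    head = labels.head_mask
    for patch in patches:
        pm = np.zeros(labels.labels.shape, dtype=bool)
        pm[tuple(patch.voxels.T)] = True
        gel = ndimage.binary_dilation(pm, iterations=n_layers) & ~head & (new == 0)
        if not gel.any():
            raise PlacementError(f"no room for gel above patch {patch.name!r}")
        new[gel] = int(Tissue.GEL)
        patch.injection_voxels = np.argwhere(gel)
    return LabeledHeadVolume(new, labels.affine)


# ---------------------------------------------------------------------------
# Finite-volume solve
# ---------------------------------------------------------------------------

@dataclass
class FieldSolution:
    """Node potentials, field magnitude and solver diagnostics."""

    V: np.ndarray  # volts, NaN outside the domain
    E_mag: np.ndarray  # V/m, NaN outside the domain
    residual: float
    active: np.ndarray
    iterations: int = 0


def _assemble(cond: ConductivityVolume):
    active = cond.active
    n = int(active.sum())
    node = -np.ones(active.shape, dtype=np.int64)
    node[active] = np.arange(n)
    h_m = cond.voxel_size / 1000.0  # metres
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        a_act = active[tuple(sl_a)] & active[tuple(sl_b)]
        sa = cond.sigma[tuple(sl_a)][a_act]
        sb = cond.sigma[tuple(sl_b)][a_act]
        # face conductance: harmonic-mean sigma * area / distance = sigma_h * h
        g = (2.0 * sa * sb / (sa + sb)) * h_m[ax]
        ia = node[tuple(sl_a)][a_act]
        ib = node[tuple(sl_b)][a_act]
        rows.extend([ia, ib])
        cols.extend([ib, ia])
        vals.extend([-g, -g])
        np.add.at(diag, ia, g)
        np.add.at(diag, ib, g)
    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return A, node


def solve_potential(
    cond: ConductivityVolume,
    electrodes: list[ElectrodePatch],
    tol: float = 1e-6,
    maxiter: int = 40000,
) -> FieldSolution:
    """Solve the current-injection problem on the conducting domain.

    Currents (mA) are applied as uniform per-voxel loads over each patch's
    injection sites; they must sum to zero.  Conjugate gradients with Jacobi
    preconditioning to relative residual ``tol``; the zero-mean gauge is
    applied afterwards.
    """
    total = sum(e.current_ma for e in electrodes)
    if abs(total) > 1e-9:
        raise ParameterError(f"electrode currents must sum to 0, got {total} mA")
    A, node = _assemble(cond)
    n = A.shape[0]
    b = np.zeros(n)
    for e in electrodes:
        sites = node[tuple(np.asarray(e.sites).T)]
        if np.any(sites < 0):
            raise PlacementError(
                f"patch {e.name!r} has injection sites outside the domain"
            )
        b[sites] += (e.current_ma * 1e-3) / len(sites)
    b -= b.sum() / n  # exact compatibility for the singular Neumann system

    M = sparse.diags(1.0 / A.diagonal())
    v, info = cg(A, b, rtol=tol, atol=0.0, maxiter=maxiter, M=M)
    residual = float(np.linalg.norm(A @ v - b) / np.linalg.norm(b))
    if info != 0:
        raise SolverError(
            f"CG did not converge in {maxiter} iterations", residual=residual
        )
    v -= v.mean()

    V = np.full(cond.active.shape, np.nan)
    V[cond.active] = v
    E = _field_magnitude(V, cond.active, cond.voxel_size / 1000.0)
    return FieldSolution(V=V, E_mag=E, residual=residual, active=cond.active)


def _field_magnitude(V: np.ndarray, active: np.ndarray, h_m: np.ndarray) -> np.ndarray:
    """|grad V| using central differences where both neighbours are in the
    domain, one-sided at domain boundaries, per axis."""
    E2 = np.zeros_like(V)
    for ax in range(3):
        fwd = np.full(V.shape, np.nan)
        bwd = np.full(V.shape, np.nan)
        sl_from = [slice(None)] * 3
        sl_to = [slice(None)] * 3
        sl_from[ax] = slice(1, None)
        sl_to[ax] = slice(0, -1)
        fwd[tuple(sl_to)] = V[tuple(sl_from)]
        bwd[tuple(sl_from)] = V[tuple(sl_to)]
        has_f = np.isfinite(fwd)
        has_b = np.isfinite(bwd)
        g = np.zeros(V.shape)
        both = has_f & has_b
        g[both] = (fwd[both] - bwd[both]) / (2 * h_m[ax])
        only_f = has_f & ~has_b
        g[only_f] = (fwd[only_f] - V[only_f]) / h_m[ax]
        only_b = has_b & ~has_f
        g[only_b] = (V[only_b] - bwd[only_b]) / h_m[ax]
        E2 += g**2
    E = np.sqrt(E2)
    E[~active] = np.nan
    return E


# ---------------------------------------------------------------------------
# ROIs and dosimetry
# ---------------------------------------------------------------------------

SECTION_NAMES = ("L", "mL", "C", "mR", "R")


@dataclass
class RoiDose:
    """Mean field magnitude over one region of interest."""

    roi: str
    ef_ave: float
    n_voxels: int

    def __post_init__(self):
        if self.ef_ave < 0:
            raise ParameterError("mean field magnitude cannot be negative")


def rolandic_rois(
    labels: LabeledHeadVolume,
    cortical_sulcus: SulcusTrace,
    band_mm: float = 15.0,
    max_dist_mm: float = 35.0,
    n_sections: int = 5,
) -> dict[str, np.ndarray]:
    """Gray-matter strips behind (S1) and ahead of (M1) the cortical sulcus.

    Each gray voxel near the sulcus midline is classified by the anterior
    (+y) component of its offset from the nearest midline point; five lateral
    sections (L, mL, C, mR, R) partition each strip by arc position.
    """
    gray = labels.mask(Tissue.GRAY)
    idx = np.argwhere(gray)
    world = labels.voxel_to_world(idx)
    dense = cortical_sulcus.resample(1.0)
    d, nearest = cKDTree(dense).query(world)
    d_ant = world[:, 1] - dense[nearest, 1]
    near = d <= max_dist_mm
    s1 = near & (d_ant < 0) & (d_ant >= -band_mm)
    m1 = near & (d_ant >= 0) & (d_ant <= band_mm)

    frac = nearest / (len(dense) - 1)
    rois: dict[str, np.ndarray] = {}
    for name, sel in (("S1", s1), ("M1", m1)):
        mask = np.zeros(labels.labels.shape, dtype=bool)
        mask[tuple(idx[sel].T)] = True
        rois[name] = mask
        for k in range(n_sections):
            sec = sel & (frac >= k / n_sections) & (
                frac < (k + 1) / n_sections if k < n_sections - 1 else frac <= 1.0
            )
            m = np.zeros(labels.labels.shape, dtype=bool)
            m[tuple(idx[sec].T)] = True
            rois[f"{name}_{SECTION_NAMES[k]}"] = m
    return rois


def roi_dose(
    sol: FieldSolution, rois: dict[str, np.ndarray]
) -> tuple[list[RoiDose], float]:
    """Voxel-mean |E| per ROI and the S1/M1 ratio."""
    doses = []
    by_name = {}
    for name, mask in rois.items():
        vals = sol.E_mag[mask & sol.active]
        ef = float(vals.mean()) if len(vals) else 0.0
        doses.append(RoiDose(roi=name, ef_ave=ef, n_voxels=int(len(vals))))
        by_name[name] = ef
    if by_name.get("M1", 0.0) <= 0:
        raise ParameterError("M1 ROI is empty; cannot form the S1/M1 ratio")
    return doses, by_name["S1"] / by_name["M1"]


def run_montage_study(
    labels: LabeledHeadVolume,
    scalp_trace: SulcusTrace,
    cortical_sulcus: SulcusTrace,
    fiducials: FiducialSet,
    references: tuple[str, ...] = REFERENCES,
    shifts_mm: tuple[int, ...] = ANODE_SHIFTS_MM,
    anode_kinds: tuple[str, ...] = ("repe",),
    current_ma: float = 1.5,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Solve every anode x shift x reference combination and tabulate doses.

    Returns one row per montage with S1/M1 means, their ratio and the five
    lateral section means of each strip.
    """
    shell = ShellGraph(labels)
    rois = rolandic_rois(labels, cortical_sulcus)
    rows = []
    for kind in anode_kinds:
        for reference in references:
            for shift in shifts_mm:
                anode = place_anode(shell, scalp_trace.points, shift, kind=kind,
                                    current_ma=current_ma)
                cathode = place_reference(shell, reference, fiducials,
                                          current_ma=-current_ma)
                montage = MontageSpec(anode, cathode, anode_shift_mm=shift,
                                      name=f"{kind}_{reference}_{shift}")
                gelled = add_gel_layers(labels, [montage.anode, montage.cathode])
                cond = conductivity_from_labels(gelled)
                sol = solve_potential(cond, [montage.anode, montage.cathode], tol=tol)
                doses, ratio = roi_dose(sol, rois)
                row = {
                    "anode": kind,
                    "reference": reference,
                    "shift_mm": shift,
                    "ratio_s1_m1": ratio,
                    "residual": sol.residual,
                }
                for d in doses:
                    row[f"ef_{d.roi}"] = d.ef_ave
                rows.append(row)
    return pd.DataFrame(rows)
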