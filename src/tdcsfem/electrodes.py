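"""Electrode patches, the conventional C3/C4 montage, and candidate grids.

Patches are sets of skin (boundary) facets selected by projecting facet
centroids into a local tangent frame at the patch centre.  The frame's
first axis points toward the nasion (tangentially), fixing the rectangle
orientation — the physical rotation of a square sponge electrode is
otherwise arbitrary, and a fixed convention keeps runs reproducible.

Candidate grids for the optimizer are square lattices laid out in geodesic
(azimuthal-equidistant) coordinates on a sphere fitted to the scalp, then
projected onto the actual mesh surface.  This keeps the nominal 11.11 mm
spacing accurate far from the reference, where a flat tangent-plane lattice
would foreshorten.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import MontageError, PlacementError, ResolutionError
from .head_model import HeadModel, TetMesh, locate_ten_twenty_positions

#: Conventional stimulation parameters.
DEFAULT_CURRENT_MA = 2.0
DEFAULT_PATCH_SIZE = (50.0, 50.0)   # 5 x 5 cm
DEFAULT_GRID_SPACING = 11.11        # mm
DEFAULT_GRID_EXTENT = 44.44         # mm -> 9 x 9 lattice
DEFAULT_OVERLAP_MIN_DISTANCE = 70.0  # mm between anode/cathode centres
DEFAULT_SNAP_TOL = 15.0             # mm


@dataclass
class ElectrodePatch:
    """Skin electrode: centre, size, covered boundary facets, current (mA)."""

    center: np.ndarray
    size: tuple[float, float]
    facet_ids: np.ndarray
    current: float
    area: float
    normal: np.ndarray
    shape: str = "rect"

    def __post_init__(self):
        if self.current == 0:
            raise MontageError("electrode current must be nonzero")


@dataclass
class Montage:
    """Anode/cathode pair with balanced currents."""

    anode: ElectrodePatch
    cathode: ElectrodePatch
    label: str = "custom"  # conventional | optimized | custom

    def __post_init__(self):
        if self.anode.current <= 0 or self.cathode.current >= 0:
            raise MontageError("anode current must be +, cathode -")
        if abs(self.anode.current + self.cathode.current) > 1e-12 * abs(
                self.anode.current):
            raise MontageError("montage currents must sum to zero")
        if np.intersect1d(self.anode.facet_ids,
                          self.cathode.facet_ids).size:
            raise MontageError("anode and cathode facet sets overlap")

    @property
    def separation(self) -> float:
        """Anode-to-cathode centre distance (mm)."""
        return float(np.linalg.norm(self.anode.center - self.cathode.center))


@dataclass
class CandidateGrid:
    points: np.ndarray          # (k, 3) on-surface coordinates
    spacing: float
    reference: np.ndarray

    def __post_init__(self):
        if len(self.points) == 0:
            raise PlacementError("empty candidate grid")


# ---------------------------------------------------------------------------
# surface geometry helpers
# ---------------------------------------------------------------------------

class SurfaceProjector:
    """Nearest-point projection onto the boundary triangulation."""

    def __init__(self, mesh: TetMesh):
        self.mesh = mesh
        self.facets = mesh.boundary_facets
        self.centroids = mesh.nodes[self.facets].mean(axis=1)
        self._node_tree = cKDTree(mesh.nodes[mesh.boundary_nodes()])
        self._bnodes = mesh.boundary_nodes()
        # node -> incident boundary facets
        self._incident: dict[int, list[int]] = {}
        for fi, f in enumerate(self.facets):
            for v in f:
                self._incident.setdefault(int(v), []).append(fi)
        c = mesh.nodes[mesh.boundary_nodes()].mean(axis=0)
        self.sphere_center = c
        self.sphere_radius = float(
            np.linalg.norm(mesh.nodes[self._bnodes] - c, axis=1).mean())

    def project(self, point: np.ndarray) -> tuple[np.ndarray, float]:
        """Closest point on the surface and its distance."""
        point = np.asarray(point, float)
        _, idx = self._node_tree.query(point, k=min(4, len(self._bnodes)))
        cand = set()
        for i in np.atleast_1d(idx):
            cand.update(self._incident[int(self._bnodes[i])])
        best, bd = point, np.inf
        for fi in cand:
            p = _closest_point_on_triangle(point,
                                           self.mesh.nodes[self.facets[fi]])
            d = np.linalg.norm(p - point)
            if d < bd:
                best, bd = p, d
        return best, float(bd)

    def outward_normals(self, facet_ids: np.ndarray) -> np.ndarray:
        # boundary facets are stored outward-oriented for positive tets
        return self.mesh.facet_normals(self.facets[facet_ids])


def _closest_point_on_triangle(p, tri):
    """Closest point on triangle (a, b, c) to p (Ericson's algorithm)."""
    a, b, c = tri
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return a
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0 <= d1 and d3 <= 0:
        return a + ab * (d1 / (d1 - d3))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0 <= d2 and d6 <= 0:
        return a + ac * (d2 / (d2 - d6))
    va = d3 * d6 - d5 * d4
    if va <= 0 and d4 - d3 >= 0 and d5 - d6 >= 0:
        return b + (c - b) * ((d4 - d3) / ((d4 - d3) + (d5 - d6)))
    denom = 1.0 / (va + vb + vc)
    return a + ab * (vb * denom) + ac * (vc * denom)


def tangent_frame(normal: np.ndarray, head: HeadModel,
                  center: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal (t1, t2) with t1 the tangential nasion-ward direction."""
    hints = [head.fiducials.get("nasion"), head.fiducials.get("inion"),
             np.array([1.0, 0, 0]), np.array([0, 1.0, 0])]
    for hint in hints:
        if hint is None:
            continue
        d = np.asarray(hint, float) - center
        t1 = d - (d @ normal) * normal
        n1 = np.linalg.norm(t1)
        if n1 > 1e-6 * max(np.linalg.norm(d), 1.0):
            t1 /= n1
            return t1, np.cross(normal, t1)
    raise PlacementError("cannot build a tangent frame at the patch centre")


# ---------------------------------------------------------------------------
# patches and montages
# ---------------------------------------------------------------------------

def make_patch(
    head: HeadModel,
    center,
    size=DEFAULT_PATCH_SIZE,
    current: float = DEFAULT_CURRENT_MA,
    shape: str = "rect",
    snap_tol: float = DEFAULT_SNAP_TOL,
    band: float | None = None,
    projector: SurfaceProjector | None = None,
) -> ElectrodePatch:
    """Select the skin facets under a rectangular (or disc) electrode.

    The centre is snapped to the surface; facet centroids are projected
    into the tangent frame and kept if they fall inside the electrode
    footprint and within a normal-offset band that absorbs scalp curvature.
    """
    if np.isscalar(size):
        size = (float(size), float(size))
    proj = projector or SurfaceProjector(head.mesh)
    snapped, dist = proj.project(np.asarray(center, float))
    if dist > snap_tol:
        raise PlacementError(
            f"patch centre is {dist:.1f} mm from the skin surface "
            f"(snap tolerance {snap_tol} mm)")
    half = max(size) / 2.0
    # local normal from facets near the snapped centre
    near = np.linalg.norm(proj.centroids - snapped, axis=1) <= max(
        1.5 * half, 10.0)
    if not near.any():
        raise ResolutionError("no boundary facets near the patch centre")
    normals = proj.outward_normals(np.flatnonzero(near))
    normal = normals.mean(axis=0)
    normal /= np.linalg.norm(normal)
    t1, t2 = tangent_frame(normal, head, snapped)

    if band is None:
        half_diag = 0.5 * float(np.hypot(*size))
        sagitta = half_diag**2 / (2.0 * proj.sphere_radius)
        edge = np.sqrt(proj.mesh.facet_areas(proj.facets).mean())
        band = sagitta + 2.0 * edge

    d = proj.centroids - snapped
    u, v, w = d @ t1, d @ t2, d @ normal
    if shape == "rect":
        inside = (np.abs(u) <= size[0] / 2.0) & (np.abs(v) <= size[1] / 2.0)
    elif shape == "disc":
        inside = np.hypot(u, v) <= size[0] / 2.0
    else:
        raise MontageError(f"unknown patch shape {shape!r}")
    inside &= np.abs(w) <= band
    ids = np.flatnonzero(inside)
    if ids.size == 0:
        raise ResolutionError("patch footprint covers no boundary facets")
    area = float(proj.mesh.facet_areas(proj.facets[ids]).sum())
    return ElectrodePatch(snapped, tuple(size), ids, float(current), area,
                          normal, shape)


def conventional_montage(head: HeadModel,
                         current: float = DEFAULT_CURRENT_MA,
                         size=DEFAULT_PATCH_SIZE,
                         projector: SurfaceProjector | None = None) -> Montage:
    """Bi-hemispheric montage: anode over the affected M1 (C3 or C4),
    cathode over the contralesional mirror position."""
    pos = locate_ten_twenty_positions(head)
    anode_label = "C3" if head.affected_side == "left" else "C4"
    cathode_label = "C4" if anode_label == "C3" else "C3"
    proj = projector or SurfaceProjector(head.mesh)
    anode = make_patch(head, pos[anode_label], size, +current,
                       projector=proj)
    cathode = make_patch(head, pos[cathode_label], size, -current,
                         projector=proj)
    return Montage(anode, cathode, label="conventional")


# ---------------------------------------------------------------------------
# candidate grids
# ---------------------------------------------------------------------------

def build_candidate_grid(
    head: HeadModel,
    reference,
    extent: float = DEFAULT_GRID_EXTENT,
    spacing: float = DEFAULT_GRID_SPACING,
    snap_tol: float = DEFAULT_SNAP_TOL,
    projector: SurfaceProjector | None = None,
) -> CandidateGrid:
    """Evenly spaced scalp lattice around a reference electrode position.

    A (2m+1)^2 lattice with the given spacing is laid out in geodesic
    coordinates around the reference and projected onto the skin surface;
    points closer than spacing/2 after projection are deduplicated.  The
    reference itself is always the first grid point.
    """
    if extent < 0:
        raise PlacementError("grid extent must be >= 0")
    proj = projector or SurfaceProjector(head.mesh)
    ref, dist = proj.project(np.asarray(reference, float))
    if dist > snap_tol:
        raise PlacementError(
            f"grid reference is {dist:.1f} mm off the skin surface")
    if extent == 0:
        return CandidateGrid(ref[None, :], spacing, ref)

    c = proj.sphere_center
    radius = proj.sphere_radius
    c_hat = (ref - c) / np.linalg.norm(ref - c)
    t1, t2 = tangent_frame(c_hat, head, ref)
    m = int(np.floor(extent / spacing + 1e-9))
    offsets = [(i * spacing, j * spacing)
               for i in range(-m, m + 1) for j in range(-m, m + 1)]
    offsets.sort(key=lambda o: (np.hypot(*o), o))  # reference (0,0) first
    pts = []
    for u, v in offsets:
        arc = float(np.hypot(u, v))
        if arc == 0.0:
            pts.append(ref)
            continue
        e_hat = (u * t1 + v * t2) / arc
        ang = arc / radius
        p = c + radius * (np.cos(ang) * c_hat + np.sin(ang) * e_hat)
        pts.append(proj.project(p)[0])
    pts = np.asarray(pts)
    keep: list[int] = []
    for i, p in enumerate(pts):
        if all(np.linalg.norm(p - pts[j]) >= spacing / 2.0 for j in keep):
            keep.append(i)
    return CandidateGrid(pts[keep], spacing, ref)
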