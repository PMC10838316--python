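"""Field metrics: ROI summaries, improvement %, montage distances.

The target ROI is a small sphere (default radius 2 mm) of gray-matter
elements around the hand-knob coordinate.  Field strength is the
volume-weighted mean of the per-element |E| over qualifying elements; the
normal component projects each element field onto the outward normal of
the gray-matter surface at the point nearest the ROI centre (the
physiologically polarizing direction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ROIError, TdcsFemError
from .fem import FieldSolution
from .head_model import HeadModel

#: Default target ROI radius in mm.
DEFAULT_ROI_RADIUS = 2.0


@dataclass
class ROISpec:
    """Spherical gray-matter region of interest."""

    center: np.ndarray
    radius: float = DEFAULT_ROI_RADIUS
    tissue_filter: str = "gray"

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0:
            raise ROIError("ROI radius must be > 0")


@dataclass
class ROIFieldSummary:
    mean_magnitude: float       # V/m
    normal_component: float     # V/m, signed
    n_elements: int
    normal_direction: np.ndarray


@dataclass
class MontageDistances:
    """Displacements (mm) between conventional and optimized electrodes."""

    d_anode: float
    d_cathode: float
    d_total: float
    within_conventional: float
    within_optimized: float


def roi_elements(head: HeadModel, roi: ROISpec) -> tuple[np.ndarray, np.ndarray]:
    """Indices and volumes of ROI-qualifying elements (centroid rule)."""
    mesh = head.mesh
    sel = mesh.tissue_label == roi.tissue_filter
    centroids = mesh.tet_centroids()
    d = np.linalg.norm(centroids - roi.center, axis=1)
    idx = np.flatnonzero(sel & (d <= roi.radius))
    if idx.size == 0:
        near = d[sel].min() if sel.any() else np.inf
        raise ROIError(
            f"no {roi.tissue_filter} element centroid within {roi.radius} mm "
            f"of the ROI centre (nearest at {near:.2f} mm)")
    return idx, mesh.tet_volumes()[idx]


def _gray_surface(head: HeadModel) -> tuple[np.ndarray, np.ndarray]:
    """Centroids and outward unit normals of the gray-surface faces.

    Candidate faces separate a gray tet from CSF/skull/skin or the mesh
    exterior (the pial side); where no such face exists (fully enclosed by
    white matter or lesion) any gray-region interface face is used.
    Cached on the head instance, keyed by the label array identity.
    """
    cache = getattr(head, "_gray_surface_cache", None)
    if cache is not None and cache[0] is head.mesh.tissue_label:
        return cache[1], cache[2]
    mesh = head.mesh
    from .head_model import _FACE_LOCAL  # local face numbering

    faces = mesh.tets[:, _FACE_LOCAL].reshape(-1, 3)
    owner = np.repeat(np.arange(mesh.n_tets), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T[::-1])
    ks, fo, oo = key[order], faces[order], owner[order]
    labels = mesh.tissue_label
    is_gray = labels == "gray"
    pial_side = np.isin(labels, ("csf", "skull", "skin"))

    same = np.zeros(len(ks), dtype=bool)
    same[:-1] = (ks[1:] == ks[:-1]).all(axis=1)
    pi = np.flatnonzero(same)                       # interior pairs (i, i+1)
    a, b = oo[pi], oo[pi + 1]
    mixed = is_gray[a] != is_gray[b]
    gi = np.where(is_gray[a[mixed]], pi[mixed], pi[mixed] + 1)
    other = np.where(is_gray[a[mixed]], b[mixed], a[mixed])
    is_pial = pial_side[other]
    # exterior faces owned by gray tets count as pial
    on_bnd = np.ones(len(ks), dtype=bool)
    on_bnd[pi] = False
    on_bnd[pi + 1] = False
    bi = np.flatnonzero(on_bnd & is_gray[oo])
    face_idx = np.concatenate([gi, bi])
    pial = np.concatenate([is_pial, np.ones(len(bi), dtype=bool)])
    if face_idx.size == 0:
        raise ROIError("head model contains no gray-matter surface")
    if pial.any():
        face_idx = face_idx[pial]
    tri = fo[face_idx]
    own = oo[face_idx]
    p = mesh.nodes[tri]
    cent = p.mean(axis=1)
    nrm = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    flip = np.einsum("ij,ij->i", nrm,
                     cent - mesh.tet_centroids()[own]) < 0
    nrm[flip] = -nrm[flip]
    head._gray_surface_cache = (labels, cent, nrm)
    return cent, nrm


def gray_surface_normal(head: HeadModel, point: np.ndarray) -> np.ndarray:
    """Outward gray-surface normal at the surface point nearest ``point``."""
    cent, nrm = _gray_surface(head)
    k = int(np.argmin(np.linalg.norm(cent - np.asarray(point, float), axis=1)))
    return nrm[k]


def roi_summary(solution: FieldSolution, head: HeadModel,
                roi: ROISpec) -> ROIFieldSummary:
    """Volume-weighted ROI mean |E| and signed normal component."""
    idx, vols = roi_elements(head, roi)
    e = solution.field[idx]
    w = vols / vols.sum()
    mags = np.linalg.norm(e, axis=1)
    n_hat = gray_surface_normal(head, roi.center)
    return ROIFieldSummary(
        mean_magnitude=float(w @ mags),
        normal_component=float(w @ (e @ n_hat)),
        n_elements=int(idx.size),
        normal_direction=n_hat,
    )


def improvement_pct(conventional_field: float, optimized_field: float) -> float:
    """((optimized - conventional) / conventional) x 100 %."""
    if conventional_field <= 0:
        raise TdcsFemError(
            "conventional field must be > 0 for a relative improvement")
    return (optimized_field - conventional_field) / conventional_field * 100.0


def montage_distances(conventional, optimized) -> MontageDistances:
    """Euclidean centre-to-centre displacement metrics between montages."""
    d_anode = float(np.linalg.norm(conventional.anode.center
                                   - optimized.anode.center))
    d_cathode = float(np.linalg.norm(conventional.cathode.center
                                     - optimized.cathode.center))
    return MontageDistances(
        d_anode=d_anode,
        d_cathode=d_cathode,
        d_total=d_anode + d_cathode,
        within_conventional=conventional.separation,
        within_optimized=optimized.separation,
    )
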