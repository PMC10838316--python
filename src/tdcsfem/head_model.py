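"""Synthetic multi-layer head models for tDCS field simulation.

The volume conductor is a five-shell sphere (skin, skull, CSF, gray matter,
white matter) discretized into linear tetrahedra.  Nodes are laid out on
concentric spherical shells — one shell exactly at every tissue interface,
intermediate shells at roughly the target edge length — and connected with a
Delaunay tetrahedralization.  Tissue membership is assigned per tetrahedron
from the radius of its centroid, so inserting a spherical stroke lesion is a
pure relabelling that conserves mesh topology and total volume exactly.

Coordinates follow the RAS convention in millimetres with the origin at the
sphere centre: +x right, +y anterior, +z superior.  The scalp fiducials
(nasion, inion, pre-auricular points) sit on the coordinate axes, which makes
the 10-20 positions closed-form on an ideal sphere and testable against
spherical trigonometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .exceptions import (
    FiducialError,
    InvalidGeometryError,
    OutOfDomainError,
    ConfigError,
    ResolutionError,
)

TISSUES = ("skin", "skull", "csf", "gray", "white", "lesion")

#: Isotropic tissue conductivities in S/m.
DEFAULT_CONDUCTIVITIES: dict[str, float] = {
    "gray": 0.265,
    "white": 0.126,
    "csf": 1.65,
    "skull": 0.010,
    "skin": 0.465,
    "lesion": 0.8087,
}

#: Outer radius of each concentric shell in mm (skin, skull, CSF, gray, white).
DEFAULT_LAYER_RADII = (92.0, 86.0, 80.0, 78.0, 70.0)

SHELL_LABELS = ("skin", "skull", "csf", "gray", "white")

#: 10-20 vertex-to-C3/C4 fraction of the full ear-to-ear arc.
_C3_ARC_FRACTION = 0.2

_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


# ---------------------------------------------------------------------------
# mesh container
# ---------------------------------------------------------------------------

@dataclass
class TetMesh:
    """Labeled tetrahedral mesh.

    Attributes
    ----------
    nodes : (n, 3) float array, mm
    tets : (m, 4) int array of node indices, positively oriented
    tissue_label : (m,) array of tissue names from :data:`TISSUES`
    """

    nodes: np.ndarray
    tets: np.ndarray
    tissue_label: np.ndarray
    _boundary: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes (mm^3); positive for a valid mesh."""
        x = self.nodes[self.tets]
        m = x[:, 1:] - x[:, :1]
        return np.linalg.det(m) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def fix_orientation(self) -> None:
        """Swap two vertices of every negatively oriented tet in place."""
        neg = self.tet_volumes() < 0
        self.tets[neg] = self.tets[neg][:, [0, 1, 3, 2]]

    @property
    def boundary_facets(self) -> np.ndarray:
        """(k, 3) node triples of the outer (skin) surface, outward oriented."""
        if self._boundary is None:
            self._boundary = _boundary_facets(self.tets)
        return self._boundary

    def boundary_nodes(self) -> np.ndarray:
        return np.unique(self.boundary_facets)

    def facet_areas(self, facets: np.ndarray) -> np.ndarray:
        p = self.nodes[facets]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def facet_normals(self, facets: np.ndarray) -> np.ndarray:
        """Unit normals with the orientation stored in ``facets``."""
        p = self.nodes[facets]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def validate(self) -> None:
        """Assert the structural mesh invariants; raise on violation."""
        vols = self.tet_volumes()
        if vols.min() <= 0:
            raise InvalidGeometryError(
                f"non-positive tet volume: min={vols.min():.3e} mm^3"
            )
        used = np.zeros(self.n_nodes, dtype=bool)
        used[self.tets] = True
        if not used.all():
            raise InvalidGeometryError(
                f"{np.count_nonzero(~used)} nodes referenced by no tet"
            )
        bad = set(np.unique(self.tissue_label)) - set(TISSUES)
        if bad:
            raise InvalidGeometryError(f"unknown tissue labels: {sorted(bad)}")
        # watertightness: every boundary edge shared by exactly two facets
        f = self.boundary_facets
        edges = np.sort(
            np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if not (counts == 2).all():
            raise InvalidGeometryError("boundary surface is not watertight")


def _boundary_facets(tets: np.ndarray) -> np.ndarray:
    """Extract outward-oriented boundary triangles (faces used once)."""
    faces = tets[:, _FACE_LOCAL].reshape(-1, 3)  # outward for positive tets
    key = np.sort(faces, axis=1)
    order = np.lexsort(key.T[::-1])
    ks = key[order]
    dup = np.ones(len(ks), dtype=bool)
    same = (ks[1:] == ks[:-1]).all(axis=1)
    dup[1:] &= ~same
    dup[:-1] &= ~same
    return faces[order][dup]


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class LesionSpec:
    """Spherical stroke lesion: centre (mm), radius (mm), location class."""

    center: np.ndarray
    radius: float
    location_class: str  # cortical | subcortical | brainstem

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float)
        if self.radius < 0:
            raise InvalidGeometryError("lesion radius must be >= 0")
        if self.location_class not in ("cortical", "subcortical", "brainstem"):
            raise ConfigError(f"unknown lesion class {self.location_class!r}")

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3


@dataclass
class SubjectCovariates:
    subject_id: str
    lesion: LesionSpec
    fma_ue: int
    age: int
    sex: str  # "M" | "F"
    affected_side: str = "left"

    def __post_init__(self):
        if not 0 <= self.fma_ue <= 66:
            raise ConfigError("fma_ue must lie in [0, 66]")


@dataclass
class HeadModel:
    """Labeled head mesh plus conductivities, fiducials and the target."""

    mesh: TetMesh
    conductivities: dict[str, float]
    fiducials: dict[str, np.ndarray]
    target: np.ndarray
    affected_side: str
    layer_radii: tuple[float, ...] = DEFAULT_LAYER_RADII

    def __post_init__(self):
        for name, sigma in self.conductivities.items():
            if sigma <= 0:
                raise ConfigError(f"conductivity for {name!r} must be > 0")

    @property
    def skin_radius(self) -> float:
        return float(self.layer_radii[0])

    def with_labels(self, labels: np.ndarray) -> "HeadModel":
        mesh = TetMesh(self.mesh.nodes, self.mesh.tets, labels,
                       self.mesh._boundary)
        return replace(self, mesh=mesh)


# ---------------------------------------------------------------------------
# sphere sampling
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors via the golden-angle spiral."""
    i = np.arange(n, dtype=float)
    phi = i * (np.pi * (3.0 - np.sqrt(5.0)))
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _shell_radii(layer_radii: Sequence[float], h: float) -> list[float]:
    """Node-shell radii: every interface plus ~h-spaced intermediates."""
    radii = list(layer_radii)
    shells: list[float] = []
    bounds = radii + [0.0]
    for outer, inner in zip(bounds[:-1], bounds[1:]):
        shells.append(outer)
        thick = outer - inner
        k = int(round(thick / h))
        for j in range(1, k):
            shells.append(outer - thick * j / k)
    # innermost shell close to centre is replaced by the centre point itself
    return [r for r in shells if r > 0.6 * h]


def build_layered_sphere_head(
    layer_radii: Sequence[float] = DEFAULT_LAYER_RADII,
    conductivities: Mapping[str, float] | None = None,
    mesh_size: float = 8.0,
    affected_side: str = "left",
    seed: int = 0,
    jitter: float = 0.02,
) -> HeadModel:
    """Build a five-shell spherical head model.

    Parameters
    ----------
    layer_radii : strictly decreasing outer radii (mm) of the skin, skull,
        CSF, gray and white shells.
    mesh_size : target edge length in mm.
    jitter : relative radial node jitter (fraction of ``mesh_size``) used to
        break the exact co-sphericity of shell nodes, which would otherwise
        make the Delaunay triangulation degenerate.
    """
    radii = [float(r) for r in layer_radii]
    if len(radii) != len(SHELL_LABELS):
        raise InvalidGeometryError(
            f"expected {len(SHELL_LABELS)} layer radii, got {len(radii)}"
        )
    if any(a <= b for a, b in zip(radii, radii[1:])):
        raise InvalidGeometryError("layer radii must be strictly decreasing")
    if mesh_size <= 0:
        raise InvalidGeometryError("mesh_size must be > 0")
    thinnest = min(a - b for a, b in zip(radii, radii[1:]))
    if mesh_size > 6.0 * thinnest:
        raise ResolutionError(
            f"mesh_size {mesh_size} cannot resolve the thinnest shell "
            f"({thinnest:.2f} mm); require mesh_size <= {6.0 * thinnest:.2f}"
        )
    if affected_side not in ("left", "right"):
        raise ConfigError("affected_side must be 'left' or 'right'")

    rng = np.random.default_rng(seed)
    interface = set(radii)
    pts = [np.zeros((1, 3))]
    for r in _shell_radii(radii, mesh_size):
        n = max(14, int(round(4.0 * np.pi * r * r / (mesh_size * mesh_size))))
        u = fibonacci_sphere(n) @ _random_rotation(rng).T
        dr = rng.uniform(-jitter, jitter, size=n) * mesh_size
        if r in interface:
            dr *= 0.5  # keep interfaces sharp; still break co-sphericity
        pts.append(u * (r + dr)[:, None])
    nodes = np.ascontiguousarray(np.concatenate(pts))

    tri = Delaunay(nodes)
    mesh = TetMesh(nodes, tri.simplices.astype(np.int64), np.empty(0))
    mesh.fix_orientation()

    # shell k occupies centroid radii in (radii[k+1], radii[k]]; the white
    # core extends to the centre and absorbs the default label
    rc = np.linalg.norm(mesh.tet_centroids(), axis=1)
    labels = np.full(mesh.n_tets, "white", dtype="<U11")
    hi = np.inf
    for lab, lo in zip(SHELL_LABELS[:-1], radii[1:]):
        labels[(rc <= hi) & (rc > lo)] = lab
        hi = lo
    mesh.tissue_label = labels
    mesh.validate()

    r_skin = radii[0]
    fiducials = {
        "nasion": np.array([0.0, r_skin, 0.0]),
        "inion": np.array([0.0, -r_skin, 0.0]),
        "left_preauricular": np.array([-r_skin, 0.0, 0.0]),
        "right_preauricular": np.array([r_skin, 0.0, 0.0]),
    }
    cond = dict(DEFAULT_CONDUCTIVITIES if conductivities is None
                else conductivities)
    head = HeadModel(mesh, cond, fiducials, np.zeros(3), affected_side,
                     tuple(radii))
    head.target = _default_target(head)
    return head


def _default_target(head: HeadModel) -> np.ndarray:
    """Hand-knob proxy: mid-gray point under C3/C4, snapped to the nearest
    gray element centroid so the 2 mm ROI always contains >= 1 element."""
    r_gray, r_white = head.layer_radii[3], head.layer_radii[4]
    theta = _C3_ARC_FRACTION * np.pi  # polar angle of C3/C4 from vertex
    sx = -1.0 if head.affected_side == "left" else 1.0
    direction = np.array([sx * np.sin(theta), 0.0, np.cos(theta)])
    raw = direction * 0.5 * (r_gray + r_white)
    centroids = head.mesh.tet_centroids()
    gray = np.flatnonzero(head.mesh.tissue_label == "gray")
    i = gray[cKDTree(centroids[gray]).query(raw)[1]]
    return centroids[i]


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

def insert_lesion(head: HeadModel, lesion: LesionSpec) -> HeadModel:
    """Relabel every tet whose centroid falls inside the lesion sphere.

    Topology and node positions are untouched, so total mesh volume is
    conserved exactly; only conductivity assignment changes.
    """
    if np.linalg.norm(lesion.center) >= head.skin_radius:
        raise OutOfDomainError(
            f"lesion centre {lesion.center} lies outside the skin surface"
        )
    if lesion.radius == 0:
        return head
    centroids = head.mesh.tet_centroids()
    d = np.linalg.norm(centroids - lesion.center, axis=1)
    labels = head.mesh.tissue_label.copy()
    labels[d <= lesion.radius] = "lesion"
    out = head.with_labels(labels)
    # a lesion may swallow the target's element: re-snap the hand-knob
    # target to the nearest surviving gray centroid (HeadModel invariant)
    gray = np.flatnonzero(labels == "gray")
    if gray.size == 0:
        raise InvalidGeometryError("lesion removed all gray matter")
    i = gray[cKDTree(centroids[gray]).query(head.target)[1]]
    out.target = centroids[i]
    return out


# ---------------------------------------------------------------------------
# synthetic cohort
# ---------------------------------------------------------------------------

#: Cohort generative defaults.  ``fma_k``/``fma_b``/``fma_sd`` parameterize
#: fma = clip(round(45 - k * volume^(1/3) - b * 1[cortical] + N(0, sd)), 0, 66),
#: a monotone-noise model producing the negative impairment-severity
#: association the group statistics exercise.
DEFAULT_EFFECT_PARAMS = {
    "fma_k": 1.0,
    "fma_b": 12.0,
    "fma_sd": 5.0,
    "cortical_radius": (8.0, 18.0),
    "subcortical_radius": (6.0, 14.0),
    "brainstem_radius": (4.0, 8.0),
}

DEFAULT_CLASS_COUNTS = {"cortical": 8, "subcortical": 11, "brainstem": 2}


def generate_cohort_covariates(
    n: int,
    class_counts: Mapping[str, int] | None = None,
    effect_params: Mapping[str, object] | None = None,
    seed: int = 0,
    layer_radii: Sequence[float] = DEFAULT_LAYER_RADII,
) -> list[SubjectCovariates]:
    """Draw per-subject lesion specs and covariates (no meshes built)."""
    counts = dict(DEFAULT_CLASS_COUNTS if class_counts is None else class_counts)
    if sum(counts.values()) != n:
        raise ConfigError(
            f"class_counts sum {sum(counts.values())} != n {n}"
        )
    params = dict(DEFAULT_EFFECT_PARAMS)
    if effect_params:
        params.update(effect_params)
    rng = np.random.default_rng(seed)
    r_gray, r_white = layer_radii[3], layer_radii[4]
    theta = _C3_ARC_FRACTION * np.pi

    classes = [c for c, k in counts.items() for _ in range(k)]
    rng.shuffle(classes)
    subjects = []
    for i, cls in enumerate(classes):
        side = "left" if rng.random() < 0.5 else "right"
        sx = -1.0 if side == "left" else 1.0
        target_dir = np.array([sx * np.sin(theta), 0.0, np.cos(theta)])
        lo, hi = params[f"{cls}_radius"]
        radius = float(rng.uniform(lo, hi))
        if cls == "cortical":
            center = _jitter_direction(rng, target_dir, 25.0) * 0.9 * r_gray
        elif cls == "subcortical":
            center = _jitter_direction(rng, target_dir, 55.0) * 0.5 * r_gray
            radius = min(radius, r_white - 0.5 * r_gray - 2.0)
        else:  # brainstem
            center = (_jitter_direction(rng, np.array([0.0, 0.0, -1.0]), 10.0)
                      * 0.75 * r_white)
        lesion = LesionSpec(center, radius, cls)
        fma = 45.0 - params["fma_k"] * lesion.volume ** (1 / 3)
        fma -= params["fma_b"] * (cls == "cortical")
        fma += rng.normal(0.0, params["fma_sd"])
        subjects.append(SubjectCovariates(
            subject_id=f"S{i + 1:02d}",
            lesion=lesion,
            fma_ue=int(np.clip(round(fma), 0, 66)),
            age=int(np.clip(round(rng.normal(59.0, 10.0)), 30, 85)),
            sex="M" if rng.random() < 0.67 else "F",
            affected_side=side,
        ))
    return subjects


def _jitter_direction(rng, direction, max_deg):
    """Random unit vector within max_deg of ``direction``."""
    while True:
        axis = rng.normal(size=3)
        axis -= axis.dot(direction) * direction
        norm = np.linalg.norm(axis)
        if norm > 1e-12:
            break
    axis /= norm
    ang = np.deg2rad(max_deg) * np.sqrt(rng.random())  # area-uniform in cap
    return direction * np.cos(ang) + axis * np.sin(ang)


def generate_synthetic_cohort(
    n: int,
    class_counts: Mapping[str, int] | None = None,
    effect_params: Mapping[str, object] | None = None,
    seed: int = 0,
    layer_radii: Sequence[float] = DEFAULT_LAYER_RADII,
    mesh_size: float = 8.0,
) -> list[tuple[HeadModel, SubjectCovariates]]:
    """Full synthetic cohort: per-subject lesioned head model + covariates.

    Deterministic for a fixed seed; subject i's mesh seed derives from the
    master seed by a fixed counter scheme (see :func:`subject_seed`).
    """
    covs = generate_cohort_covariates(n, class_counts, effect_params, seed,
                                      layer_radii)
    out = []
    for i, cov in enumerate(covs):
        head = build_layered_sphere_head(
            layer_radii, mesh_size=mesh_size,
            affected_side=cov.affected_side, seed=subject_seed(seed, i),
        )
        out.append((insert_lesion(head, cov.lesion), cov))
    return out


def subject_seed(master_seed: int, index: int) -> int:
    """Per-subject mesh seed derived from the master seed (kept < 2^31)."""
    return (master_seed * 100003 + 7919 * (index + 1)) % (2**31 - 1)


# ---------------------------------------------------------------------------
# 10-20 positions
# ---------------------------------------------------------------------------

def _slerp(a: np.ndarray, b: np.ndarray, t: float) -> np.ndarray:
    """Spherical interpolation between unit vectors a and b."""
    ang = np.arccos(np.clip(a.dot(b), -1.0, 1.0))
    if ang < 1e-12:
        return a
    return (np.sin((1 - t) * ang) * a + np.sin(t * ang) * b) / np.sin(ang)


def locate_ten_twenty_positions(head: HeadModel) -> dict[str, np.ndarray]:
    """Scalp 10-20 positions {Cz, C3, C4, T3, T4} from the four fiducials.

    Cz is the crossing of the 50% nasion-inion and 50% ear-to-ear arcs;
    C3/C4 lie 20% of the ear-to-ear arc from Cz toward the left/right
    pre-auricular point, T3/T4 at 40%.
    """
    required = ("nasion", "inion", "left_preauricular", "right_preauricular")
    for name in required:
        if name not in head.fiducials:
            raise FiducialError(f"missing fiducial {name!r}")
    nas, ini, lpa, rpa = (np.asarray(head.fiducials[k], float)
                          for k in required)
    radius = np.mean([np.linalg.norm(p) for p in (nas, ini, lpa, rpa)])
    n_hat, lpa_hat, rpa_hat = (p / np.linalg.norm(p) for p in (nas, lpa, rpa))
    ear_axis = rpa_hat - lpa_hat
    ear_axis /= np.linalg.norm(ear_axis)
    up = np.cross(ear_axis, n_hat - ini / np.linalg.norm(ini))
    nu = np.linalg.norm(up)
    if nu < 1e-12:
        raise FiducialError("degenerate fiducial configuration")
    cz_hat = up / nu
    if cz_hat.dot(np.cross(ear_axis, n_hat)) < 0:
        cz_hat = -cz_hat

    # ear-to-ear arc angle through the vertex
    total = (np.arccos(np.clip(cz_hat.dot(lpa_hat), -1, 1))
             + np.arccos(np.clip(cz_hat.dot(rpa_hat), -1, 1)))

    def toward(ear_hat, frac):
        ang_to_ear = np.arccos(np.clip(cz_hat.dot(ear_hat), -1, 1))
        return _slerp(cz_hat, ear_hat, frac * total / ang_to_ear)

    pos = {
        "Cz": cz_hat,
        "C3": toward(lpa_hat, _C3_ARC_FRACTION),
        "C4": toward(rpa_hat, _C3_ARC_FRACTION),
        "T3": toward(lpa_hat, 2 * _C3_ARC_FRACTION),
        "T4": toward(rpa_hat, 2 * _C3_ARC_FRACTION),
    }
    return {k: v * radius for k, v in pos.items()}
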