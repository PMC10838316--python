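"""P1 finite-element solver for the tDCS potential.

The stimulation current obeys the quasi-static continuity equation
``div(sigma grad V) = 0`` in the head domain, with uniform-current-density
Neumann patches at the electrodes and natural insulation (``J . n = 0``)
elsewhere on the scalp.  Assembly uses linear tetrahedra with piecewise
constant conductivity; the singular Neumann system is solved either by
Jacobi-preconditioned conjugate gradients on the consistent right-hand side
(zero-mean potential is restored afterwards) or by a sparse LU factorization
with one grounded node.  Both paths yield the same zero-mean solution.

Unit conventions, applied exactly once: coordinates mm, conductivity S/m,
current mA, potential V.  A stiffness entry then carries S/m*mm = mS, so
``K V`` is directly in mA.  Element fields are ``-grad V`` with the mm->m
factor of 1000, giving V/m.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .exceptions import (
    ConfigError,
    ConvergenceError,
    InvalidGeometryError,
    MontageError,
    ShapeError,
)
from .head_model import HeadModel, TetMesh

#: mm -> m gradient conversion: V per mm equals 1000 V/m.
MM_TO_M_FIELD = 1000.0


@dataclass
class AssembledSystem:
    """Stiffness operator, nodal load and grounding description."""

    stiffness: sp.csr_matrix  # entries in S/m*mm (= mS)
    load: np.ndarray          # per-node injected current, mA
    head: HeadModel
    ground: str = "zero-mean"

    @property
    def n_nodes(self) -> int:
        return self.stiffness.shape[0]


@dataclass
class FieldSolution:
    """Nodal potential (V), per-element field (V/m) and solve residual."""

    potential: np.ndarray
    field: np.ndarray
    residual: float


def shape_gradients(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-tet barycentric shape-function gradients and volumes.

    Returns
    -------
    grads : (m, 4, 3) gradients in 1/mm
    vols : (m,) volumes in mm^3
    """
    x = mesh.nodes[mesh.tets]
    m = x[:, 1:] - x[:, :1]              # (m, 3, 3), rows are edge vectors
    vols = np.linalg.det(m) / 6.0
    if vols.min() <= 0:
        raise InvalidGeometryError("degenerate or inverted tetrahedron")
    minv = np.linalg.inv(m)              # d(lambda_{1..3}) / dx as columns
    g = minv.transpose(0, 2, 1)          # (m, 3, 3): grad lambda_1..3 in rows
    g0 = -g.sum(axis=1, keepdims=True)
    return np.concatenate([g0, g], axis=1), vols


def assemble_system(head: HeadModel) -> AssembledSystem:
    """Assemble the P1 stiffness matrix K_ij = sum_e sigma_e |e| gi.gj."""
    mesh = head.mesh
    for lab in np.unique(mesh.tissue_label):
        sigma = head.conductivities.get(str(lab))
        if sigma is None or sigma <= 0:
            raise ConfigError(
                f"missing or non-positive conductivity for label {lab!r}"
            )
    sigmas = np.array([head.conductivities[str(l)]
                       for l in mesh.tissue_label])
    grads, vols = shape_gradients(mesh)
    ke = np.einsum("e,eid,ejd->eij", sigmas * vols, grads, grads)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    k = sp.coo_matrix((ke.ravel(), (rows, cols)),
                      shape=(mesh.n_nodes, mesh.n_nodes)).tocsr()
    return AssembledSystem(k, np.zeros(mesh.n_nodes), head)


def patch_loads(mesh: TetMesh, facet_ids: np.ndarray, current: float,
                boundary: np.ndarray | None = None) -> np.ndarray:
    """Consistent nodal loads (mA) for a uniform current density patch.

    The total current is spread over the patch facets proportionally to
    area; each linear triangle sends a third of its share to each vertex,
    so the loads sum to ``current`` exactly.
    """
    facets = (mesh.boundary_facets if boundary is None else boundary)[facet_ids]
    areas = mesh.facet_areas(facets)
    load = np.zeros(mesh.n_nodes)
    share = current * areas / areas.sum() / 3.0
    for k in range(3):
        np.add.at(load, facets[:, k], share)
    return load


def apply_montage_currents(system: AssembledSystem, montage) -> AssembledSystem:
    """Attach the montage's electrode currents as a nodal load vector."""
    anode, cathode = montage.anode, montage.cathode
    if anode is None or cathode is None:
        raise MontageError("montage requires both an anode and a cathode")
    if abs(anode.current + cathode.current) > 1e-12 * abs(anode.current):
        raise MontageError("anode and cathode currents must sum to zero")
    if np.intersect1d(anode.facet_ids, cathode.facet_ids).size:
        raise MontageError("anode and cathode patches overlap")
    mesh = system.head.mesh
    load = (patch_loads(mesh, anode.facet_ids, anode.current)
            + patch_loads(mesh, cathode.facet_ids, cathode.current))
    return replace(system, load=load)


def element_fields(potential: np.ndarray, mesh: TetMesh,
                   grads: np.ndarray | None = None) -> np.ndarray:
    """Per-element E = -grad V in V/m (constant on each linear tet)."""
    potential = np.asarray(potential, float)
    if potential.shape != (mesh.n_nodes,):
        raise ShapeError(
            f"potential has shape {potential.shape}, expected ({mesh.n_nodes},)"
        )
    if grads is None:
        grads, _ = shape_gradients(mesh)
    return -MM_TO_M_FIELD * np.einsum(
        "eid,ei->ed", grads, potential[mesh.tets]
    )


def solve_potential(system: AssembledSystem, tol: float = 1e-9,
                    max_iter: int | None = None,
                    method: str = "cg") -> FieldSolution:
    """Solve K V = f for the zero-mean potential and element fields.

    ``method="cg"`` runs Jacobi-preconditioned conjugate gradients on the
    consistent singular system; ``method="direct"`` grounds one node and
    back-substitutes through a sparse LU factorization.  Both de-mean the
    result, so they agree to solver tolerance.
    """
    if tol <= 0:
        raise ConfigError("tol must be > 0")
    k, f = system.stiffness, system.load.copy()
    if abs(f.sum()) > 1e-9 * (np.abs(f).max() or 1.0):
        raise MontageError("load vector is not charge-balanced")
    f -= f.mean()  # keep rhs exactly in range(K)
    bnorm = np.linalg.norm(f)
    if bnorm == 0:
        return FieldSolution(np.zeros(system.n_nodes),
                             np.zeros((system.head.mesh.n_tets, 3)), 0.0)

    if method == "direct":
        v = DirectSolver(system).solve(f)
        res = float(np.linalg.norm(k @ v - f) / bnorm)
    elif method == "cg":
        if max_iter is None:
            max_iter = int(40 * np.sqrt(system.n_nodes)) + 100
        d = k.diagonal().copy()
        d[d <= 0] = 1.0
        precond = spla.LinearOperator(k.shape, matvec=lambda x: x / d)
        v, info = spla.cg(k, f, rtol=tol * 0.1, atol=0.0,
                          maxiter=max_iter, M=precond)
        v -= v.mean()
        res = float(np.linalg.norm(k @ v - f) / bnorm)
        if info != 0 or res > tol:
            raise ConvergenceError(
                f"CG did not reach tol={tol} within {max_iter} iterations "
                f"(residual {res:.3e})", residual=res)
    else:
        raise ConfigError(f"unknown solver method {method!r}")
    return FieldSolution(v, element_fields(v, system.head.mesh), res)


class DirectSolver:
    """Shared sparse-LU solver for many right-hand sides on one head.

    Grounds node 0 (symmetric row/column elimination) to lift the Neumann
    null space, then de-means each solution; the result equals the
    zero-mean CG solution up to factorization round-off.
    """

    def __init__(self, system: AssembledSystem):
        k = system.stiffness.tolil(copy=True)
        k[0, :] = 0.0
        k[:, 0] = 0.0
        k[0, 0] = 1.0
        self._lu = spla.splu(k.tocsc())
        self.n_solves = 0

    def solve(self, load: np.ndarray) -> np.ndarray:
        f = load - load.mean()
        f[0] = 0.0
        v = self._lu.solve(f)
        self.n_solves += 1
        return v - v.mean()

    def solve_many(self, loads: np.ndarray) -> np.ndarray:
        """Solve for many load vectors (k, n) at once (batched back-subs)."""
        f = loads - loads.mean(axis=1, keepdims=True)
        f[:, 0] = 0.0
        v = self._lu.solve(f.T).T
        self.n_solves += len(loads)
        return v - v.mean(axis=1, keepdims=True)
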