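"""Montage optimization: lead-field-accelerated grid search with
iterative re-centering.

Because the volume-conduction problem is linear, the field of any
(anode, cathode) pair is the difference of two "lead fields" — each the
solution for one candidate electrode against a fixed reference patch:

    E(a, c) = L(a) - L(c),        L(x) = E(x at +I, reference at -I).

One FEM solve per candidate therefore prices every pair of an NxN search
exactly, instead of N^2 solves.  The search enumerates all admissible
(anode, cathode) candidate pairs, then re-centres both grids on the
incumbent best and repeats until the relative score improvement drops
below ``rel_tol`` or ``max_iterations`` is reached.  The incumbent's
centres are members of every re-centred grid, so the per-iteration best
score is non-decreasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .electrodes import (
    CandidateGrid,
    DEFAULT_CURRENT_MA,
    DEFAULT_OVERLAP_MIN_DISTANCE,
    DEFAULT_PATCH_SIZE,
    ElectrodePatch,
    Montage,
    SurfaceProjector,
    build_candidate_grid,
    make_patch,
)
from .exceptions import MontageError, SearchError
from .fem import (
    AssembledSystem,
    DirectSolver,
    FieldSolution,
    apply_montage_currents,
    assemble_system,
    element_fields,
    patch_loads,
    shape_gradients,
    solve_potential,
)
from .head_model import HeadModel
from .metrics import ROISpec, roi_elements, roi_summary

#: Relative score window treated as a tie during pair selection.
TIE_REL_TOL = 1e-9


@dataclass
class LeadFieldSet:
    """Per-candidate potentials against a shared reference patch."""

    candidates: list[ElectrodePatch]
    reference: ElectrodePatch
    potentials: np.ndarray          # (k, n_nodes), volts
    head: HeadModel
    n_solves: int

    def pair_potential(self, i_anode: int, i_cathode: int) -> np.ndarray:
        """Superposed potential of candidate pair (reference cancels)."""
        return self.potentials[i_anode] - self.potentials[i_cathode]

    def pair_solution(self, i_anode: int, i_cathode: int) -> FieldSolution:
        v = self.pair_potential(i_anode, i_cathode)
        return FieldSolution(v, element_fields(v, self.head.mesh), 0.0)


@dataclass
class OptimizationResult:
    montage: Montage
    score: float                    # ROI mean |E|, V/m
    n_evaluated: int
    iterations: int
    trace: list[float] = field(default_factory=list)
    anode_index: int = -1
    cathode_index: int = -1


def compute_lead_fields(
    head: HeadModel,
    candidates,
    reference: ElectrodePatch,
    current: float = DEFAULT_CURRENT_MA,
    size=DEFAULT_PATCH_SIZE,
    system: AssembledSystem | None = None,
    solver: DirectSolver | None = None,
    projector: SurfaceProjector | None = None,
) -> LeadFieldSet:
    """One solve per candidate (+I candidate, -I reference).

    ``candidates`` is a :class:`CandidateGrid` or a list of patches.  A
    pre-assembled system / factorized solver may be passed to amortize
    work across repeated calls on the same head.
    """
    if isinstance(candidates, CandidateGrid):
        proj = projector or SurfaceProjector(head.mesh)
        patches = [make_patch(head, p, size, current, projector=proj)
                   for p in candidates.points]
    else:
        patches = list(candidates)
    if not patches:
        raise SearchError("no candidate electrodes to solve for")
    for p in patches:
        if np.intersect1d(p.facet_ids, reference.facet_ids).size:
            raise MontageError(
                "candidate electrode overlaps the reference patch")
    if system is None:
        system = assemble_system(head)
    if solver is None:
        solver = DirectSolver(system)
    mesh = head.mesh
    ref_load = patch_loads(mesh, reference.facet_ids, -abs(current))
    loads = np.stack([
        patch_loads(mesh, p.facet_ids, abs(current)) + ref_load
        for p in patches])
    n0 = solver.n_solves
    pots = solver.solve_many(loads)
    return LeadFieldSet(patches, reference, pots, head,
                        solver.n_solves - n0)


def score_montage(head: HeadModel, montage: Montage, roi: ROISpec,
                  solution: FieldSolution | None = None,
                  method: str = "cg", tol: float = 1e-9) -> float:
    """ROI mean |E| (V/m) for a montage; solves unless given a solution."""
    if solution is None:
        system = apply_montage_currents(assemble_system(head), montage)
        solution = solve_potential(system, tol=tol, method=method)
    return roi_summary(solution, head, roi).mean_magnitude


def _roi_gradient_operator(head: HeadModel, roi: ROISpec):
    """(idx, vols, grads) restricted to ROI elements for fast scoring."""
    idx, vols = roi_elements(head, roi)
    grads, _ = shape_gradients(head.mesh)
    return idx, vols, grads[idx]


def _roi_fields(leads: LeadFieldSet, idx, roi_grads) -> np.ndarray:
    """Per-candidate E at ROI elements only: (k, n_roi, 3)."""
    from .fem import MM_TO_M_FIELD

    vloc = leads.potentials[:, leads.head.mesh.tets[idx]]   # (k, nroi, 4)
    return -MM_TO_M_FIELD * np.einsum("eid,kei->ked", roi_grads, vloc)


def optimize_montage(
    head: HeadModel,
    roi: ROISpec,
    anode_grid: CandidateGrid,
    cathode_grid: CandidateGrid,
    current: float = DEFAULT_CURRENT_MA,
    size=DEFAULT_PATCH_SIZE,
    max_iterations: int = 10,
    rel_tol: float = 1e-4,
    overlap_min_distance: float = DEFAULT_OVERLAP_MIN_DISTANCE,
    reference: ElectrodePatch | None = None,
    tie_break_reference: tuple[np.ndarray, np.ndarray] | None = None,
    system: AssembledSystem | None = None,
    solver: DirectSolver | None = None,
    projector: SurfaceProjector | None = None,
) -> OptimizationResult:
    """Exhaustive pair search over candidate grids with re-centering.

    Ties (scores within :data:`TIE_REL_TOL` relative) break toward the
    pair closest to ``tie_break_reference`` centres (conventionally the
    C3/C4 montage), then lexicographic candidate order — reproducible and
    conservative.
    """
    proj = projector or SurfaceProjector(head.mesh)
    if system is None:
        system = assemble_system(head)
    if solver is None:
        solver = DirectSolver(system)
    if reference is None:
        reference = _default_reference(head, anode_grid, cathode_grid,
                                       current, proj)
    idx, vols, roi_grads = _roi_gradient_operator(head, roi)
    w = vols / vols.sum()

    # lead-field cache across iterations, keyed by rounded centre coords
    cache: dict[tuple, tuple[ElectrodePatch, np.ndarray]] = {}

    def leads_for(points: np.ndarray):
        miss_keys, miss_patches = [], []
        seen = set()
        keys = []
        for pt in points:
            key = tuple(np.round(pt, 6))
            keys.append(key)
            if key in cache or key in seen:
                continue
            seen.add(key)
            patch = make_patch(head, pt, size, current, projector=proj)
            if np.intersect1d(patch.facet_ids, reference.facet_ids).size:
                cache[key] = None  # inadmissible: overlaps reference
            else:
                miss_keys.append(key)
                miss_patches.append(patch)
        if miss_patches:  # batched back-substitution for all new candidates
            lf = compute_lead_fields(
                head, miss_patches, reference, current, size,
                system=system, solver=solver, projector=proj)
            e_rois = _roi_fields(lf, idx, roi_grads)
            for key, patch, e_roi in zip(miss_keys, miss_patches, e_rois):
                cache[key] = (patch, e_roi)
        return [cache[k] for k in keys if cache[k] is not None]

    a_pts = np.asarray(anode_grid.points)
    c_pts = np.asarray(cathode_grid.points)
    trace: list[float] = []
    n_evaluated = 0
    best = None  # (score, a_patch, a_eroi, c_patch, c_eroi)
    spacing = anode_grid.spacing

    for iteration in range(1, max_iterations + 1):
        a_entries = leads_for(a_pts)
        c_entries = leads_for(c_pts)
        if not a_entries or not c_entries:
            raise SearchError("no admissible candidates in a grid")
        ea = np.stack([e for _, e in a_entries])        # (ka, nroi, 3)
        ec = np.stack([e for _, e in c_entries])
        a_centers = np.stack([p.center for p, _ in a_entries])
        c_centers = np.stack([p.center for p, _ in c_entries])
        dist = np.linalg.norm(a_centers[:, None] - c_centers[None], axis=2)
        admissible = dist >= overlap_min_distance
        if not admissible.any():
            raise SearchError(
                "all candidate pairs excluded by the overlap guard")
        diff = ea[:, None] - ec[None]                   # (ka, kc, nroi, 3)
        scores = np.linalg.norm(diff, axis=3) @ w       # (ka, kc)
        scores[~admissible] = -np.inf
        n_evaluated += int(admissible.sum())

        smax = scores.max()
        tied = np.argwhere(scores >= smax * (1.0 - TIE_REL_TOL))
        if tie_break_reference is not None:
            ra, rc = tie_break_reference
            dref = (np.linalg.norm(a_centers[tied[:, 0]] - ra, axis=1)
                    + np.linalg.norm(c_centers[tied[:, 1]] - rc, axis=1))
            tied = tied[np.lexsort((tied[:, 1], tied[:, 0],
                                    np.round(dref, 9)))]
        else:
            tied = tied[np.lexsort((tied[:, 1], tied[:, 0]))]
        ia, ic = map(int, tied[0])
        it_best = float(scores[ia, ic])

        improved = best is None or it_best > best[0] * (1.0 + rel_tol)
        if best is None or it_best > best[0]:
            best = (it_best, *a_entries[ia], *c_entries[ic])
            best_idx = (ia, ic)
        trace.append(best[0])
        if not improved:
            break
        # re-centre both grids on the incumbent best, same spacing
        new_a = _recenter(head, best[1].center, anode_grid, proj)
        new_c = _recenter(head, best[3].center, cathode_grid, proj)
        if (_point_keys(new_a) == _point_keys(a_pts)
                and _point_keys(new_c) == _point_keys(c_pts)):
            break  # identical grids cannot improve the incumbent
        a_pts, c_pts = new_a, new_c

    score, a_patch, _, c_patch, _ = best
    anode = ElectrodePatch(a_patch.center, a_patch.size, a_patch.facet_ids,
                           +abs(current), a_patch.area, a_patch.normal,
                           a_patch.shape)
    cathode = ElectrodePatch(c_patch.center, c_patch.size, c_patch.facet_ids,
                             -abs(current), c_patch.area, c_patch.normal,
                             c_patch.shape)
    montage = Montage(anode, cathode, label="optimized")
    return OptimizationResult(montage, score, n_evaluated, len(trace), trace,
                              anode_index=best_idx[0],
                              cathode_index=best_idx[1])


def _point_keys(points: np.ndarray) -> set:
    return {tuple(np.round(p, 6)) for p in points}


def _recenter(head, center, grid: CandidateGrid, proj) -> np.ndarray:
    # after the full first sweep, later iterations explore a local
    # refinement window (up to 2 lattice steps around the incumbent, never
    # wider than the original grid) — the incumbent itself is its first
    # point, so scores stay monotone
    span = np.linalg.norm(np.asarray(grid.points) - grid.reference,
                          axis=1).max()
    extent = min(2.0 * grid.spacing, span)
    return build_candidate_grid(head, center, extent=extent,
                                spacing=grid.spacing,
                                projector=proj).points


def _default_reference(head, anode_grid, cathode_grid, current, proj
                       ) -> ElectrodePatch:
    """Return patch far from both grids (inferior pole opposite the grids)."""
    c = proj.sphere_center
    mean_dir = (anode_grid.reference + cathode_grid.reference) / 2.0 - c
    nrm = np.linalg.norm(mean_dir)
    direction = (-mean_dir / nrm if nrm > 1e-9
                 else np.array([0.0, 0.0, -1.0]))
    point = c + direction * proj.sphere_radius
    return make_patch(head, point, DEFAULT_PATCH_SIZE, -abs(current),
                      projector=proj)
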