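"""FEM assembly, loads, solver and field tests.

The solver's physics invariants — charge conservation, linearity,
reciprocity, rotation equivariance — are checked on coarse heads; the
FEM-vs-analytic oracle at production resolution lives in the acceptance
suite.
"""

import dataclasses

import numpy as np
import pytest

from tdcsfem.electrodes import Montage, SurfaceProjector, make_patch
from tdcsfem.exceptions import ConfigError, MontageError, ShapeError
from tdcsfem.fem import (
    DirectSolver,
    apply_montage_currents,
    assemble_system,
    element_fields,
    patch_loads,
    solve_potential,
)
from tdcsfem.head_model import TetMesh, build_layered_sphere_head


def test_stiffness_rows_sum_to_zero(system8):
    k = system8.stiffness
    rowsum = np.abs(np.asarray(k.sum(axis=1))).max()
    assert rowsum / np.abs(k.data).max() < 1e-10


def test_stiffness_symmetric(system8):
    k = system8.stiffness
    d = k - k.T
    assert np.abs(d.data).max() if d.nnz else 0.0 < 1e-12


def test_reference_tet_local_stiffness_matches_hand_derivation():
    # unit tet (0, e1, e2, e3), sigma = 1: K = 1/6 * G G^T with
    # grad(l0) = (-1,-1,-1), grad(li) = ei  ->  hand-computed 4x4
    nodes = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]),
                   np.array(["gray"]))
    head = _bare_head(mesh, {"gray": 1.0})
    k = assemble_system(head).stiffness.toarray()
    expected = np.array([
        [3, -1, -1, -1],
        [-1, 1, 0, 0],
        [-1, 0, 1, 0],
        [-1, 0, 0, 1]]) / 6.0
    assert np.allclose(k, expected, atol=1e-14)


def _bare_head(mesh, cond):
    from tdcsfem.head_model import HeadModel

    return HeadModel(mesh, cond, {}, np.zeros(3), "left")


def test_zero_conductivity_rejected(head8):
    bad = dataclasses.replace(
        head8, conductivities={**head8.conductivities})
    bad.conductivities["gray"] = 1e-3
    bad.conductivities.pop("skull")
    with pytest.raises(ConfigError):
        assemble_system(bad)


class TestMontageLoads:
    def test_anode_load_sums_to_injected_current(self, head8, system8,
                                                 conventional8):
        sys2 = apply_montage_currents(system8, conventional8)
        positive = sys2.load[sys2.load > 0].sum()
        assert positive == pytest.approx(2.0, rel=1e-12)

    def test_total_load_conserves_charge(self, system8, conventional8):
        sys2 = apply_montage_currents(system8, conventional8)
        assert abs(sys2.load.sum()) <= 1e-12 * 2.0

    def test_loads_only_on_electrode_boundary_nodes(self, head8, system8,
                                                    conventional8):
        sys2 = apply_montage_currents(system8, conventional8)
        loaded = np.flatnonzero(sys2.load)
        facets = head8.mesh.boundary_facets
        electrode_nodes = np.unique(np.concatenate([
            facets[conventional8.anode.facet_ids].ravel(),
            facets[conventional8.cathode.facet_ids].ravel()]))
        assert np.isin(loaded, electrode_nodes).all()

    def test_anode_only_montage_rejected(self, head8, projector8):
        anode = make_patch(head8, [0, 0, 92], current=2.0,
                           projector=projector8)
        with pytest.raises(MontageError):
            Montage(anode, anode)  # same patch twice: overlap and sign

    def test_mismatched_currents_rejected(self, head8, projector8):
        anode = make_patch(head8, [0, 0, 92], current=2.0,
                           projector=projector8)
        cathode = make_patch(head8, [0, 92, 0], current=-1.0,
                             projector=projector8)
        with pytest.raises(MontageError):
            Montage(anode, cathode)


class TestElementFields:
    def test_linear_potential_gives_uniform_field(self, head8):
        # V = x (volts, with x in mm) -> E = (-1000, 0, 0) V/m: the single
        # audited mm->m conversion
        v = head8.mesh.nodes[:, 0]
        e = element_fields(v, head8.mesh)
        assert np.allclose(e, [-1000.0, 0.0, 0.0], atol=1e-6)

    def test_constant_potential_gives_zero_field(self, head8):
        e = element_fields(np.full(head8.mesh.n_nodes, 3.7), head8.mesh)
        assert np.abs(e).max() < 1e-9

    def test_length_mismatch_rejected(self, head8):
        with pytest.raises(ShapeError):
            element_fields(np.zeros(7), head8.mesh)

    def test_rotation_equivariance(self):
        # rigidly rotating the mesh and loads leaves |E| per element intact
        head = build_layered_sphere_head(mesh_size=10.0, seed=6)
        proj = SurfaceProjector(head.mesh)
        a = make_patch(head, [0, 0, 92], current=2.0, projector=proj)
        c = make_patch(head, [0, 0, -92], current=-2.0, projector=proj)
        sys1 = apply_montage_currents(assemble_system(head), Montage(a, c))
        sol1 = solve_potential(sys1, tol=1e-10)

        th = 0.3
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        rhead = dataclasses.replace(
            head,
            mesh=TetMesh(head.mesh.nodes @ rot.T, head.mesh.tets,
                         head.mesh.tissue_label),
            fiducials={k: rot @ v for k, v in head.fiducials.items()},
            target=rot @ head.target)
        sys2 = dataclasses.replace(assemble_system(rhead), load=sys1.load)
        sol2 = solve_potential(sys2, tol=1e-10)
        m1 = np.linalg.norm(sol1.field, axis=1)
        m2 = np.linalg.norm(sol2.field, axis=1)
        assert np.abs(m1 - m2).max() <= 1e-8 * m1.max()


class TestSolver:
    def test_residual_within_tolerance(self, system8, conventional8):
        sol = solve_potential(apply_montage_currents(system8, conventional8),
                              tol=1e-9)
        assert sol.residual <= 1e-9

    def test_doubling_current_doubles_fields(self, head8, system8,
                                             projector8):
        a1 = make_patch(head8, [0, 0, 92], current=2.0, projector=projector8)
        c1 = make_patch(head8, [0, 0, -92], current=-2.0,
                        projector=projector8)
        a2 = dataclasses.replace(a1, current=4.0)
        c2 = dataclasses.replace(c1, current=-4.0)
        s1 = solve_potential(apply_montage_currents(system8, Montage(a1, c1)),
                             tol=1e-10)
        s2 = solve_potential(apply_montage_currents(system8, Montage(a2, c2)),
                             tol=1e-10)
        scale = np.abs(s1.field).max()
        assert np.abs(s2.field - 2.0 * s1.field).max() <= 1e-8 * 2 * scale
        assert np.abs(s2.potential - 2.0 * s1.potential).max() <= (
            1e-8 * 2 * np.abs(s1.potential).max())

    def test_direct_and_cg_agree(self, system8, conventional8):
        loaded = apply_montage_currents(system8, conventional8)
        v_cg = solve_potential(loaded, tol=1e-10, method="cg").potential
        v_lu = solve_potential(loaded, method="direct").potential
        assert np.abs(v_cg - v_lu).max() <= 1e-7 * np.abs(v_lu).max()

    def test_superposition_of_patch_pairs(self, head8, system8, solver8,
                                          projector8):
        # solution(a, c) = solution(a, ref) - solution(c, ref)
        mesh = head8.mesh
        pa = make_patch(head8, [0, 0, 92], current=2.0, projector=projector8)
        pc = make_patch(head8, [0, 92, 0], current=2.0, projector=projector8)
        ref = make_patch(head8, [0, 0, -92], current=2.0,
                         projector=projector8)
        la = patch_loads(mesh, pa.facet_ids, 2.0)
        lc = patch_loads(mesh, pc.facet_ids, 2.0)
        lr = patch_loads(mesh, ref.facet_ids, 2.0)
        v_pair = solver8.solve(la - lc)
        v_sup = solver8.solve(la - lr) - solver8.solve(lc - lr)
        assert np.abs(v_pair - v_sup).max() <= 1e-8 * np.abs(v_pair).max()

    def test_reciprocity_between_patch_pairs(self, head8, system8, solver8,
                                             projector8):
        # <V_PQ injected at RS> equals <V_RS injected at PQ>
        mesh = head8.mesh
        centers = ([0, 0, 92], [0, 92, 0], [-92, 0, 0], [0, -65, 65])
        patches = [make_patch(head8, c, size=30.0, current=2.0,
                              projector=projector8) for c in centers]
        p, q, r, s = (patch_loads(mesh, x.facet_ids, 1.0) for x in patches)
        v1 = solver8.solve(r - s)   # inject at (R, S)
        v2 = solver8.solve(p - q)   # inject at (P, Q)
        lhs = (p - q) @ v1
        rhs = (r - s) @ v2
        assert abs(lhs - rhs) <= 1e-6 * abs(lhs)
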