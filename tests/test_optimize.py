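"""Lead-field optimizer vs brute-force enumeration and direct solves."""

import numpy as np
import pytest

from tdcsfem.electrodes import (
    Montage,
    build_candidate_grid,
    make_patch,
)
from tdcsfem.exceptions import MontageError, SearchError
from tdcsfem.fem import (
    FieldSolution,
    apply_montage_currents,
    element_fields,
)
from tdcsfem.head_model import locate_ten_twenty_positions
from tdcsfem.metrics import ROISpec, roi_summary
from tdcsfem.optimize import (
    compute_lead_fields,
    optimize_montage,
    score_montage,
)


@pytest.fixture(scope="module")
def grids3(head8, projector8):
    pos = locate_ten_twenty_positions(head8)
    ga = build_candidate_grid(head8, pos["C3"], extent=11.11,
                              projector=projector8)
    gc = build_candidate_grid(head8, pos["C4"], extent=11.11,
                              projector=projector8)
    return ga, gc


@pytest.fixture(scope="module")
def roi8(head8):
    return ROISpec(head8.target)


def _direct_pair_score(head, pa, pc, roi, system, solver, proj):
    a = make_patch(head, pa, current=2.0, projector=proj)
    c = make_patch(head, pc, current=-2.0, projector=proj)
    loaded = apply_montage_currents(system, Montage(a, c))
    v = solver.solve(loaded.load)
    sol = FieldSolution(v, element_fields(v, head.mesh), 0.0)
    return roi_summary(sol, head, roi).mean_magnitude


class TestLeadFields:
    def test_one_solve_per_candidate(self, head8, grids3, system8, solver8,
                                     projector8):
        ga, _ = grids3
        ref = make_patch(head8, [0, 0, -92], current=-2.0,
                         projector=projector8)
        lf = compute_lead_fields(head8, ga, ref, system=system8,
                                 solver=solver8, projector=projector8)
        assert lf.n_solves == len(ga.points) == len(lf.candidates)

    def test_candidate_minus_itself_vanishes(self, head8, grids3, system8,
                                             solver8, projector8):
        ga, _ = grids3
        ref = make_patch(head8, [0, 0, -92], current=-2.0,
                         projector=projector8)
        lf = compute_lead_fields(head8, ga, ref, system=system8,
                                 solver=solver8, projector=projector8)
        sol = lf.pair_solution(2, 2)
        assert np.abs(sol.field).max() == 0.0

    def test_superposed_pair_matches_direct_simulation(
            self, head8, grids3, roi8, system8, solver8, projector8):
        ga, gc = grids3
        ref = make_patch(head8, [0, 0, -92], current=-2.0,
                         projector=projector8)
        lfa = compute_lead_fields(head8, ga, ref, system=system8,
                                  solver=solver8, projector=projector8)
        lfc = compute_lead_fields(head8, gc, ref, system=system8,
                                  solver=solver8, projector=projector8)
        v_sup = lfa.potentials[1] - lfc.potentials[3]
        sup = FieldSolution(v_sup, element_fields(v_sup, head8.mesh), 0.0)
        s_sup = roi_summary(sup, head8, roi8).mean_magnitude
        s_dir = _direct_pair_score(head8, ga.points[1], gc.points[3], roi8,
                                   system8, solver8, projector8)
        assert s_sup == pytest.approx(s_dir, rel=1e-6)

    def test_candidate_overlapping_reference_rejected(self, head8, system8,
                                                      solver8, projector8):
        ref = make_patch(head8, [0, 0, 92], current=-2.0,
                         projector=projector8)
        cand = make_patch(head8, [0, 10, 91], current=2.0,
                          projector=projector8)
        with pytest.raises(MontageError):
            compute_lead_fields(head8, [cand], ref, system=system8,
                                solver=solver8, projector=projector8)


class TestOptimizer:
    def test_single_iteration_equals_brute_force_enumeration(
            self, head8, grids3, roi8, system8, solver8, projector8):
        ga, gc = grids3
        res = optimize_montage(head8, roi8, ga, gc, max_iterations=1,
                               system=system8, solver=solver8,
                               projector=projector8)
        best_score, best_pair = -np.inf, None
        n_adm = 0
        for pa in ga.points:
            for pc in gc.points:
                if np.linalg.norm(pa - pc) < 70.0:
                    continue
                n_adm += 1
                s = _direct_pair_score(head8, pa, pc, roi8, system8,
                                       solver8, projector8)
                if s > best_score:
                    best_score, best_pair = s, (pa, pc)
        assert res.n_evaluated == n_adm
        assert res.score == pytest.approx(best_score, rel=1e-6)
        assert np.linalg.norm(res.montage.anode.center - best_pair[0]) < 1e-6
        assert np.linalg.norm(res.montage.cathode.center
                              - best_pair[1]) < 1e-6

    def test_score_consistent_with_returned_montage(
            self, head8, grids3, roi8, system8, solver8, projector8):
        ga, gc = grids3
        res = optimize_montage(head8, roi8, ga, gc, max_iterations=1,
                               system=system8, solver=solver8,
                               projector=projector8)
        direct = score_montage(head8, res.montage, roi8, method="direct")
        assert res.score == pytest.approx(direct, rel=1e-6)

    def test_single_point_grids_return_that_pair(self, head8, roi8, system8,
                                                 solver8, projector8):
        pos = locate_ten_twenty_positions(head8)
        ga = build_candidate_grid(head8, pos["C3"], extent=0.0,
                                  projector=projector8)
        gc = build_candidate_grid(head8, pos["C4"], extent=0.0,
                                  projector=projector8)
        res = optimize_montage(head8, roi8, ga, gc, system=system8,
                               solver=solver8, projector=projector8)
        assert res.iterations <= 2  # one sweep + a refinement that cannot win
        assert np.linalg.norm(res.montage.anode.center - ga.points[0]) < 1e-9

    def test_trace_non_decreasing_and_deterministic(
            self, head8, grids3, roi8, system8, solver8, projector8):
        ga, gc = grids3
        r1 = optimize_montage(head8, roi8, ga, gc, max_iterations=5,
                              system=system8, solver=solver8,
                              projector=projector8)
        r2 = optimize_montage(head8, roi8, ga, gc, max_iterations=5,
                              system=system8, solver=solver8,
                              projector=projector8)
        assert np.all(np.diff(r1.trace) >= 0)
        assert r1.trace == r2.trace
        assert np.array_equal(r1.montage.anode.center,
                              r2.montage.anode.center)

    def test_superset_dominance_over_conventional(
            self, head8, grids3, roi8, conventional8, system8, solver8,
            projector8):
        # conventional centres are the grid references, hence searched
        ga, gc = grids3
        res = optimize_montage(
            head8, roi8, ga, gc, max_iterations=1,
            tie_break_reference=(conventional8.anode.center,
                                 conventional8.cathode.center),
            system=system8, solver=solver8, projector=projector8)
        conv_score = score_montage(head8, conventional8, roi8,
                                   method="direct")
        assert res.score >= conv_score - 1e-12

    def test_all_pairs_excluded_raises(self, head8, roi8, system8, solver8,
                                       projector8):
        pos = locate_ten_twenty_positions(head8)
        ga = build_candidate_grid(head8, pos["C3"], extent=0.0,
                                  projector=projector8)
        gc = build_candidate_grid(head8, pos["C3"], extent=0.0,
                                  projector=projector8)
        with pytest.raises(SearchError):
            optimize_montage(head8, roi8, ga, gc,
                             overlap_min_distance=500.0, system=system8,
                             solver=solver8, projector=projector8)
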