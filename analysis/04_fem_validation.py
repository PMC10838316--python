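#!/usr/bin/env python
"""Validate the FEM solver against the layered-sphere series solution.

Solves antipodal 20 mm disc electrodes (2 mA) on a homogeneous and a
skin/skull/brain three-layer sphere at decreasing mesh edge lengths and
reports the relative L2 error of the scalp potential against the
Legendre-series oracle with a matched spherical-cap source.
"""

import math
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from tdcsfem.analytic import analytic_layered_sphere_potential
from tdcsfem.electrodes import Montage, SurfaceProjector, make_patch
from tdcsfem.fem import apply_montage_currents, assemble_system, \
    solve_potential
from tdcsfem.head_model import build_layered_sphere_head

R = 92.0
EL = np.array([[0.0, 0.0, R], [0.0, 0.0, -R]])
OUT = Path(__file__).resolve().parents[1] / "results"


def rel_l2(mesh_size, sigmas):
    cond = dict(zip(("skin", "skull", "csf", "gray", "white"), sigmas))
    cond["lesion"] = 0.8087
    head = build_layered_sphere_head(mesh_size=mesh_size, seed=1,
                                     conductivities=cond)
    proj = SurfaceProjector(head.mesh)
    a = make_patch(head, EL[0], size=20.0, current=2.0, shape="disc",
                   projector=proj)
    c = make_patch(head, EL[1], size=20.0, current=-2.0, shape="disc",
                   projector=proj)
    sol = solve_potential(
        apply_montage_currents(assemble_system(head), Montage(a, c)),
        tol=1e-8)
    bn = head.mesh.boundary_nodes()
    pts = head.mesh.nodes[bn]
    r = np.linalg.norm(pts, axis=1)
    pts = pts * (np.minimum(r, R) / r)[:, None]
    va = analytic_layered_sphere_potential(
        [92.0, 86.0, 80.0, 78.0, 70.0], sigmas, EL, pts, current=2.0,
        truncation_order=600, cap_half_angle=math.asin(10.0 / R))
    vf = sol.potential[bn]
    va -= va.mean()
    vf -= vf.mean()
    return float(np.linalg.norm(vf - va) / np.linalg.norm(va)), \
        head.mesh.n_tets


def main():
    rows = []
    for label, sigmas in (("homogeneous", [0.3] * 5),
                          ("three-layer", [0.465, 0.010, 0.3, 0.3, 0.3])):
        for h in (8.0, 6.0, 4.0):
            err, ntets = rel_l2(h, sigmas)
            rows.append({"model": label, "mesh_size_mm": h,
                         "n_tets": ntets, "rel_l2_error": err})
            print(f"{label:12s} h={h:.0f} mm  {ntets:7d} tets  "
                  f"relL2 = {err:.4f}")
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "fem_validation.csv", index=False)
    print(f"wrote {OUT / 'fem_validation.csv'}")


if __name__ == "__main__":
    main()
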