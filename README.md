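# tdcsfem

Finite-element simulation and electrode-montage optimization of
transcranial direct-current stimulation (tDCS) electric fields, with a
synthetic stroke cohort for within-subject montage comparisons.

Conventional bi-hemispheric tDCS for upper-limb stroke rehabilitation
places the anode over the affected motor cortex at C3/C4 of the 10–20
system and the cathode over the mirror position. But a stroke lesion
reroutes current, and the field actually delivered to the hand-motor
target varies widely between patients. This package asks the montage
question computationally: given a labeled head volume conductor, where
should a 5×5 cm electrode pair sit to maximize the electric field in a
2 mm region of interest (ROI) at the hand knob, and how far does that
optimum move from the conventional placement?

It is aimed at researchers in computational neurostimulation who want a
small, fully scriptable current-flow pipeline whose every numerical claim
is testable against analytic oracles.

## Model

The induced potential solves the quasi-static continuity equation

    div( sigma grad V ) = 0        in the head domain,
    sigma dV/dn = j                on electrode pads (uniform flux, ±2 mA),
    sigma dV/dn = 0                elsewhere on the scalp,

discretized with linear tetrahedra and piecewise-constant tissue
conductivities (gray 0.265, white 0.126, CSF 1.65, skull 0.010, skin
0.465, lesion 0.8087 S/m). Element fields are E = −grad V (V/m). The
montage search scores every admissible (anode, cathode) pair of 11.11 mm
scalp candidate grids via lead fields — one solve per candidate, pair
fields by linear superposition — and iterates by re-centering the grids
on the incumbent best. The objective is the volume-weighted mean |E|
over gray elements of the ROI sphere.

Because clinical MRIs are not available, head models are synthetic
five-shell spheres (skin/skull/CSF/gray/white, outer radii
92/86/80/78/70 mm) with spherical lesions of three location classes
(cortical / subcortical / brainstem, 8/11/2 in the default 21-subject
cohort) and FMA-UE scores negatively associated with lesion size. An
N-layer concentric-sphere Legendre-series solution serves as the
independent oracle for the solver. See `docs/methods.md` for the full
account and limitations.

## Worked example

```python
from tdcsfem import (RunConfig, build_layered_sphere_head, conventional_montage,
                     assemble_system, apply_montage_currents, solve_potential,
                     ROISpec, roi_summary)

head = build_layered_sphere_head(mesh_size=6.0, seed=1)   # ~100k tets
montage = conventional_montage(head)                      # C3 anode, C4 cathode, 2 mA
system = apply_montage_currents(assemble_system(head), montage)
solution = solve_potential(system, tol=1e-9)
summary = roi_summary(solution, head, ROISpec(head.target))
print(f"ROI mean |E| = {summary.mean_magnitude:.3f} V/m, "
      f"normal component = {summary.normal_component:.3f} V/m")
```

prints

```
ROI mean |E| = 0.418 V/m, normal component = -0.365 V/m
```

i.e. the conventional montage delivers ≈ 0.42 V/m to the hand-knob ROI of
this particular synthetic head, most of it directed inward across the
local gray surface (negative sign on the outward-normal convention). The full study pipeline is one call (or
`tdcsfem run-study` on the command line):

```python
report = run_study(RunConfig(seed=1))
print(report.summary)
```

which simulates all 21 subjects, optimizes each montage, and ends with
the group tests (Wilcoxon conventional-vs-optimized fields, Mann–Whitney
displacement by lesion class, Spearman displacement-vs-FMA). The
numbered drivers under `analysis/` run the same stages as a narrative:
`01_generate_cohort.py`, `02_run_study.py`, `03_figures.py`,
`04_fem_validation.py`.

## Layout

```
src/tdcsfem/      head_model, fem, analytic, electrodes, optimize,
                  metrics, stats, mesh_io, study, cli
analysis/         numbered study drivers
tests/            unit + property + acceptance suites
scripts/          acceptance.py
docs/methods.md   model, numerics, design choices, limitations
```
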