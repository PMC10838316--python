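# Methods

`tdcsfem` simulates transcranial direct-current stimulation (tDCS) in
labeled tetrahedral head models, optimizes bi-hemispheric electrode
placement against a hand-motor target, and compares optimized with
conventional montages on a synthetic stroke cohort. This note records the
model, its numerical choices, and what the synthetic setting can and
cannot show.

## Volume-conduction model

Under the quasi-static approximation the stimulation current obeys

    div( sigma grad V ) = 0   in the head domain,

with piecewise-constant isotropic conductivity sigma per tissue:
gray 0.265, white 0.126, CSF 1.65, skull 0.010, skin 0.465 and stroke
lesion 0.8087 S/m. Boundary conditions are natural insulation
(J·n = 0) on the scalp except under the electrodes, which are modelled as
uniform-current-density Neumann patches: the total current (default
2 mA) is spread over the covered skin facets proportionally to facet
area, +I at the anode and −I at the cathode. The complete-electrode
model (contact impedance, shunting through the sponge) is deliberately
out of scope — only pad size and total current are specified inputs, and
the uniform-flux pad is the simplest model consistent with them.

Discretization is linear (P1) tetrahedra; the element stiffness is
`sigma * vol * G G^T` with `G` the barycentric shape-function gradients.
Units are mm / S/m / mA / V throughout, which makes stiffness entries
milli-siemens and loads milli-amperes with no further conversion; the
single mm→m factor of 1000 enters only when element fields
`E = -grad V` are expressed in V/m, and is audited by a linear-potential
test (`V = x` in mm must give `E = (-1000, 0, 0)` V/m).

The pure-Neumann system is singular with a constant null space. Two
equivalent solution paths are provided:

* **CG** (contract default): Jacobi-preconditioned conjugate gradients on
  the consistent (zero-sum) right-hand side, relative residual 1e-9,
  iteration cap `40 sqrt(N) + 100`; the solution is de-meaned.
* **Direct**: one grounded node, sparse LU (SuperLU/COLAMD), de-meaned.
  Used wherever many right-hand sides share one head (lead fields, the
  cohort study), with batched back-substitution.

Both produce the same zero-mean potential; their agreement and the
equality of lead-field superposition with direct pair solves are tested
at 1e-6 relative.

## Synthetic head models

Real patient MRIs are unavailable, so the head is a five-shell sphere
(outer radii 92/86/80/78/70 mm for skin, skull, CSF, gray, white —
round adult-head-scale values, configurable). Nodes are laid on
concentric spherical shells: one shell exactly at every tissue
interface, intermediate shells at the target edge length, each a
golden-angle (Fibonacci) lattice with a small seeded radial jitter that
breaks the co-sphericity which would otherwise degenerate the Delaunay
tetrahedralization. Tissue labels are assigned from tet-centroid radius.
Coordinates are RAS millimetres with the origin at the sphere centre.

Consequences worth knowing:

* Total mesh volume tracks the analytic ball to well under 1 % even at
  8 mm edges, and every construction asserts positive volumes, a
  watertight boundary and full node coverage.
* The 2 mm CSF shell is thinner than typical edge lengths, so centroid
  labeling blurs it: its discretized volume can be off by tens of
  percent at 6–8 mm edges even though the interface surfaces themselves
  are node-aligned. Field errors this induces shrink with refinement
  (the FEM-vs-analytic check passes at 4 mm with the full contrast
  stack). A builder guard rejects edge lengths above six times the
  thinnest shell.
* Spherical anatomy has no gyri; absolute field magnitudes and optimal
  electrode positions are not claims about real heads.

Stroke lesions are spheres inserted by relabeling every tet whose
centroid falls inside — topology and total volume are conserved exactly.
Three location classes proxy the clinical categories: cortical lesions
centred at 0.9× the gray radius near the target hemisphere, subcortical
at 0.5×, brainstem near the inferior pole. If a lesion swallows the
target's element, the target re-snaps to the nearest surviving gray
centroid.

The scalp 10–20 positions come from the four fiducials: Cz at the
crossing of the 50 % nasion–inion and ear-to-ear arcs, C3/C4 at 20 % of
the ear-to-ear arc from Cz toward the pre-auricular points. On the ideal
sphere this is closed-form and the implementation matches spherical
trigonometry to < 1 %. The hand-knob target sits mid-gray beneath
C3/C4 on the affected side, snapped to a gray element centroid so the
2 mm region of interest (ROI) always contains at least one element.

## Synthetic cohort

21 subjects with the 8 cortical / 11 subcortical / 2 brainstem mix.
Lesion radii are uniform per class (cortical 8–18 mm, subcortical
6–14 mm, brainstem 4–8 mm). The initial upper-extremity Fugl-Meyer
score is generated as

    fma = clip( round( 45 − 1.0·volume^(1/3) − 12·[cortical] + N(0, 5) ), 0, 66 )

— a monotone-noise model chosen once to produce the negative
impairment–severity association the group statistics exercise (sample
Spearman rho ≈ −0.7 at n = 200), with a cohort median in the low-to-mid
20s. It claims no clinical realism beyond direction and range. Age
(N(59, 10), clipped 30–85) and sex (67 % male) are decorative
covariates. Everything is reproducible from one master seed; subject i's
mesh seed is `(seed·100003 + 7919·(i+1)) mod (2^31−1)`.

## Electrodes, grids and the optimizer

Electrodes are 50×50 mm pads (disc pads exist for validation): the pad
centre is snapped to the skin, a tangent frame is built with the first
axis toward the nasion (pad rotation is otherwise arbitrary; a fixed
convention keeps runs reproducible), and skin facets whose centroids
project inside the footprint within a curvature-absorbing normal band
are selected. Pad area lands within 10 % of nominal at working
resolutions and converges with refinement.

The conventional montage is anode over the affected M1 (C3 or C4),
cathode mirrored. Candidate grids are (2m+1)² lattices at 11.11 mm
spacing laid out in geodesic (azimuthal-equidistant) coordinates on a
sphere fitted to the scalp, then projected to the mesh surface — flat
tangent-plane lattices would foreshorten the spacing by ~20 % at the
default ±44.44 mm extent (a 9×9 grid), while the geodesic layout stays
within the 10 % band. Each grid's reference (the conventional position)
is always its first point.

The optimizer maximizes the volume-weighted mean |E| over gray elements
whose centroids lie in the 2 mm ROI sphere. It scores **every**
admissible (anode, cathode) pair of the grids — pairs closer than 70 mm
centre-to-centre are excluded to prevent pad contact — using lead
fields: one solve per candidate against a fixed far-away reference pad,
pair fields by superposition, evaluated only at ROI elements. It then
re-centres both grids on the incumbent best and repeats (refinement
windows of up to 2 lattice steps, never wider than the original grid)
until relative improvement falls below 1e-4 or 10 iterations. The
incumbent is a member of every re-centred grid, so the trace is
non-decreasing; a one-iteration search is verified to coincide exactly
with brute-force enumeration. Ties within 1e-9 relative break toward
the pair nearest the conventional montage, then lexicographically.
The signed normal component of the field (projection on the outward
gray-surface normal nearest the ROI centre) is reported alongside but
not optimized.

## Metrics and statistics

* ROI summary: volume-weighted mean |E| and signed normal component over
  qualifying gray elements (volume weighting is stable under
  refinement; an unweighted convention would differ negligibly at 2 mm).
* Improvement %: `((opt − conv)/conv)·100`.
* Montage displacement: Euclidean anode-to-anode (D_anode) and
  cathode-to-cathode (D_cathode) centre distances between conventional
  and optimized montages; D = D_anode + D_cathode holds exactly by
  construction. Within-montage anode–cathode separations are recorded
  for both montages.
* Wilcoxon signed-rank (conventional vs optimized fields): exact
  sign-flip null for n ≤ 25 via shift-convolution over signed-rank sums
  (valid with tied |differences| through average ranks), tie-corrected
  normal approximation above; zero differences dropped.
* Mann–Whitney (D by cortical vs non-cortical lesion): scipy exact
  enumeration for tie-free small groups, tie-corrected asymptotic
  otherwise.
* Spearman (D and improvement vs FMA-UE): average-rank rho; exact
  permutation p for n ≤ 9, t approximation above; 95 % CI by Fisher z
  with SE = 1/sqrt(n−3).
* Kolmogorov–Smirnov normality screen with parameters estimated from the
  sample; the report notes the Lilliefors caveat (p approximate).
* No multiple-testing correction is applied; report footers say so.
* Quartiles use linear interpolation (numpy default).

Each exact routine is tested against an independent brute-force
enumeration of its null distribution.

## Validation oracle

The analytic potential of a ± surface-electrode pair in an N-layer
concentric sphere is a Legendre series; per-layer coefficients follow
from continuity of V and sigma dV/dr at each interface (propagated
centre-outward with overflow-safe scaling) and the outer Neumann
condition. Electrodes can be point sources or uniform spherical caps —
the cap factor `f_n = (P_{n−1}(cos a) − P_{n+1}(cos a)) / ((2n+1)(1−cos a))`
regularizes the series so surface potentials converge (2e-4 between 300
and 600 terms at a 5–8° cap), which is why the FEM comparison uses
matched 20 mm disc pads rather than singular point sources. The series
reduces to the homogeneous closed form at equal conductivities to
machine precision and is antisymmetric under source swap.

At 4 mm edges (~380k tets) the scalp potential matches the oracle to
≈ 3 % relative L2 for the homogeneous sphere and ≈ 1 % for the
skin/skull/brain contrast stack, improving monotonically with
refinement.

## Problem sizes and defaults

The cohort study runs at 6 mm edges (~100k tets, ~18k nodes per head), a
resolution at which the solver validates to ≈ 3–7 % against the oracle
and one subject (factorization + ~200 batched lead-field solves +
optimization) takes on the order of ten seconds, so the 21-subject study
completes in minutes. The FEM validation uses 4 mm edges. Tests use
8–10 mm heads except where the check is about production resolution.

## Known limitations

* Spherical geometry, no gyral folding, no white-matter anisotropy.
* Uniform-flux pads rather than the complete-electrode model.
* The thin-CSF labeling blur described above.
* Cohort effect sizes (how much the optimizer moves electrodes, the
  strength of the D-vs-FMA correlation) are emergent properties of the
  synthetic geometry; only directions, not magnitudes, are meaningful.
* Field focality metrics are not computed.
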