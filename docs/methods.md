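# Methods

This note documents the models, numerical choices and known limitations
behind `aortamech`, in the order the pipeline runs.

## Scope and assumptions

The package analyses a *deforming lumen surface*: a reference triangle
mesh of the aortic lumen wall plus nodal displacements for each dilation
phase of the cardiac cycle. Image registration itself is out of scope —
the pipeline consumes displacement fields (and provides synthetic ones);
segmentation and DICOM handling are likewise upstream concerns. The
vessel is treated as a single non-branching tube; the wall/thrombus
compound is lumped into a thin elastic surrogate membrane on the imaged
lumen surface, so no wall thickness or thrombus geometry is needed.

Units are mm / N / MPa internally. Blood pressures cross the API
boundary in mmHg (1 mmHg = 1.33322·10⁻⁴ MPa), and the stiffness indices
are reported with p_s in mmHg and τ_v in N/mm. Index magnitudes are
meaningless without this convention, which is therefore stated wherever
indices are produced.

## Phase selection

The dilation run is read off the per-phase lumen volume curve (computed
by the divergence theorem on the capped surface): the peak is the volume
maximum; the beginning is found by walking cyclically backward from the
peak while the volume does not increase, so plateaus of equal minima
resolve to the earliest phase. A constant curve is rejected ("no
dilation detectable"). Typical 34-phase cardiac cycles yield dilation
runs of 6–9 phases.

## Node displacement from voxel fields

Voxel displacement fields (NIfTI or MetaImage; zero-based indices, voxel
centers at origin + index·spacing) are interpolated to mesh nodes with
trilinear blending of the eight enclosing lattice corners. Points
exactly on the upper lattice plane are accepted (closed upper bound);
anything outside raises with the offending coordinates. Registration QC
uses the Dice score of lumen masks and a symmetric mean nearest-surface
distance between boundary voxel centers. The latter is our
operationalization of a "mean distance difference" between contours,
which has no single canonical formula.

## Mesh reconstruction QC

Laplace (umbrella-operator) smoothing moves each free node toward the
mean of its one-ring by a step factor per iteration, with boundary rings
pinned. Smoothing shrinks closed shapes, so the relative volume loss
(V0−V)/V0 is always reported as a QC value; the recommended setting of
5 iterations at step 0.5 keeps the loss near 3 % on the synthetic
fusiform geometry, inside the 6 % acceptance gate. Ten iterations
already exceed the gate — smoothing here is cosmetic, not a modelling
step.

## Strain

Strain is evaluated per membrane triangle. Element-local orthonormal
frames (first axis along the first edge, second by Gram–Schmidt) make
the in-plane deformation gradient a 2×2 matrix mapping reference edge
vectors to deformed ones — exact for affine element deformation. From
F, the Green–Lagrange tensor E = (FᵀF − I)/2 and the equivalent strain
e_v (von-Mises functional) follow.

Transverse components: with a 0.01-mm membrane, through-thickness
gradients of any voxel-resolution displacement field are far below
resolution, so e33 = e13 = e23 = 0 by default. An optional
incompressible rule e33 = (J⁻² − 1)/2 (J the in-plane area ratio)
exists for sensitivity checks; both paths are tested. Phases whose
displacement is exactly zero short-circuit to an identically zero field.

## Membrane tension (inverse analysis by a stiff forward solve)

A pressurized thin membrane is statically determinate: equilibrium
fixes the tension field regardless of material law or thickness. The
solver exploits this by running a *forward* solve on the imaged
(deformed) geometry with a very stiff surrogate material — linear
isotropic or compressible neo-Hookean, E = 2·10⁵ MPa, ν = 0.45 —
so displacements are ~10⁻⁶ of the radius and the recovered stress
approximates the determinate membrane tension of the imaged shape.

Discretization and solution details:

* constant-strain membrane triangles; assembly is fully vectorized;
  sparse LU solve with deterministic ordering for reproducibility;
* pressure enters as a dead load along the imaged outward normals
  (p·A/3 per vertex). With displacements at the 10⁻⁶ level the
  follower-load correction is irrelevant;
* a diagonal regularization of 10⁻¹⁰ × mean stiffness diagonal
  suppresses rigid modes of closed surfaces and residual inextensional
  mechanisms without measurable effect on the strain-producing response;
* the neo-Hookean path runs Newton iterations whose tangent is the
  material stiffness plus the geometric (stress) stiffness; the stress
  stiffness is essential because membrane assemblies of faceted shells
  have near-zero-energy inextensional modes that tension stabilizes.
  The thickness stretch solves the plane-stress condition S33 = 0 per
  element by a scalar Newton. Convergence (relative residual < 10⁻⁹)
  takes 3–5 iterations; the residual history is reported;
* stress recovery per element in the local frame; σ_v is the von-Mises
  functional with zero transverse stress; τ_v = h·σ_v.

Boundary conditions. Open tubes are clamped (all translations) on both
end rings; the clamped-end condition with ν = 0.45 reproduces the
closed-tube axial tension p·r/2 to a fraction of a percent (ε_z ≈ 0
forces σ_z ≈ ν·σ_θ ≈ 0.45·p·r/h vs 0.5·p·r/h). Ring-adjacent elements
carry a boundary-layer artifact and should be excluded from statistics;
the 20-mm analysis segment sits mid-vessel, away from it. Closed
surfaces need no explicit constraints (regularization pins the rigid
modes under the self-equilibrated pressure). When a tube must be closed
for an oracle comparison, caps are built as triangle fans with a
*conical* apex offset: a flat membrane cap cannot carry transverse
pressure at first order (it is a mechanism), whereas a conical cap
transmits the axial load and converges cleanly to the Laplace closed
forms (cylinder mid-tube error 0.8 % → 0.05 % under refinement; sphere
0.1 % at the default icosphere resolution). For volume computation flat
caps remain the default — there they are exact.

The membrane abstraction keeps surface nodes untouched when a thickness
is attached; consequently τ_v = h·σ_v is exactly thickness-invariant in
the linear solve (σ ∝ 1/h), and the thickness-sensitivity study
measures pure numerical noise. The material study (neo-Hookean vs
linear isotropic) measures genuine nonlinear corrections at the 10⁻³
relative level — both far inside the single-percent bounds used as
acceptance gates, which is precisely the static-determinacy property
the method relies on.

## Region selection and quadrants

Cross-sections normal to the vessel axis at evenly spaced stations give
per-station centroids and area-equivalent diameters 2·√(A/π) (robust to
mesh noise; a max-pairwise-distance "caliper" diameter would track
outliers). The analysis segment is 20 mm long, centered on the
maximum-diameter plane for aneurysmal cases and at mid-vessel for
healthy ones. Within the segment, nodes and elements are assigned to
anterior/left/posterior/right quadrants by the angle of their offset
from the local centroid in the section plane, with 90° sectors centered
on the anterior frame; angles exactly on a 45° boundary go to the
counterclockwise sector (deterministic). For synthetic data the
anterior direction is a config input; for scanner data the user owns
the orientation convention (LPS vs RAS).

## Curve fitting and indices

Per quadrant, area-weighted mean e_v and τ_v per phase form the samples
of τ_v = λ1·e_v^λ2 + λ3, fitted by bounded least squares (trust-region
reflective) with λ1 > 0, λ2 > 1, λ3 ≥ 0. Initialization is
deterministic: λ2⁰ = 2, λ1⁰ from the secant through the extreme
samples, λ3⁰ = min τ_v, plus three fixed alternate starts; the best of
the starts wins. λ3 absorbs the tension carried at the diastolic
reference (absent in an ex vivo test); near-linear data pin λ2 at the
1+ε bound and are flagged rather than silently accepted.

SSI and dSSI are the mean first and second derivative of the fitted
curve over the sampling grid e_i = (i/N)·e_max, i = 1..N (zero excluded
so e^(λ2−2) stays finite), normalized by 1/(e_max·p_s). λ3 never enters
(derivatives annihilate it), and both indices are linear in λ1 and in
1/p_s. N defaults to 16.

Two caveats are worth stating. First, on the zero-anchored grid the
dSSI mean is a Riemann sum of a singular integrand whenever λ2 < 2, so
it converges in N only at rate N^(λ2−1); at λ2 = 1.3 the value still
moves by ~18 % between N = 16 and N = 64. A grid anchored at the
smallest *measured* strain (the `e_min` argument of `sample_curve`)
converges fast for every admissible exponent; the zero-anchored grid
remains the default because the index definition should not depend on
where a particular acquisition happened to start measuring. Second,
dSSI grows with λ2 at fixed λ1 only for strain amplitudes near or above
unity; below that the shrinking e^(λ2−2) factor dominates, so "larger
exponent" and "larger dSSI" must not be conflated at physiological
amplitudes.

Nodal index maps use the same machinery per node (element fields
averaged onto nodes, nodal peak strain as e_max); nodes whose fit fails
carry NaN plus a status flag, never a silent zero.

## Cohort statistics

Quadrant values are pooled as independent observations — a documented
simplification that ignores within-patient correlation and is the main
statistical caveat of the cohort layer. Pearson correlation (two-sided
t transform) relates indices to diameter. Logistic regression
(aneurysm = 1) is fitted by Newton–Raphson maximum likelihood with step
halving (the log-likelihood is non-decreasing across accepted
iterations), gradient tolerance 10⁻⁸, at most 100 iterations.
Covariates enter as log10(index) by default because the indices span
orders of magnitude (switchable to raw scale). Complete separation is
detected (the fitted direction classifies with a clean margin, or
coefficients diverge past a cap) and reported as separated +
non-converged, with the coefficient vector rescaled — not clipped
componentwise — so the decision direction survives. AUC uses the rank
(Mann–Whitney) formulation with half-credit ties, evaluated on the
linear predictor (rank-equivalent to the probability but immune to
sigmoid saturation); the "optimal threshold" maximizes Youden's J, ties
resolving to the lower threshold, reported on the probability scale.
Box–whisker summaries use linear-interpolation (type-7) quantiles and
1.5·IQR whiskers. The positive class is the aneurysm; AUC and Youden's
J are invariant to consistently swapping the class labels.

## Synthetic data

The generators define the study conditions rather than mimicking any
particular dataset:

* geometry: straight cylinders (R0 = 10 mm) and fusiform aneurysms
  R(z) = R0 + A·exp(−((z−z0)/w)²) with A = 10 mm — a 40-mm maximum
  diameter over a 20-mm neck, i.e. a clearly aneurysmal morphology;
* motion: radial scaling about the axis with a raised-cosine 0→1
  schedule over 7 phases (34-phase cycles contain 6–9 dilation phases);
  peak hoop stretch 1.05, a physiological pulsation. Pressure ramps
  linearly from DBP 80 to SBP 120 mmHg across the dilation phases (the
  true pressure-phase coupling is unknown; linear is the simplest
  monotone choice and is configurable);
* ground truth: hoop Green strain ((r/R0)²−1)/2 exactly, and
  closed-cylinder Laplace tension τ_v = (√3/2)·p·r (exact for the
  cylinder; a flagged local-radius approximation for the fusiform).
  Optionally the radius schedule is constructed by root-finding so the
  analytic (e_v, τ_v) pairs follow a prescribed power law, giving
  known-true (λ1, λ2, λ3) for end-to-end round trips;
* voxel fields: the analytic motion sampled at voxel centers
  (0.4×0.4×0.3 mm default). Because radial scaling is linear in
  position, trilinear interpolation reproduces it exactly — round-trip
  errors measure only bookkeeping. Convergence under grid refinement is
  exercised separately with a nonlinear analytic field;
* cohorts: per-quadrant SSI/dSSI drawn from log-normal distributions
  whose group medians differ by a configurable factor (default 10). The
  log-normal choice, the case/quadrant spread split (0.18/0.12 decades)
  and the diameter coupling are this package's own modelling choices —
  no distributional model of real cohorts was available — and the
  spread was chosen once to resemble quadrant box-whisker variability
  (IQR ≈ factor 2) while keeping the group gap dominant. What passing
  cohort tests show is therefore *structural*: the statistics pipeline
  discriminates groups separated by an order of magnitude at realistic
  group sizes (9 vs 17). They say nothing about whether real aortas
  separate that way.

Randomness is confined to the cohort generator; geometry generation is
fully deterministic.

## Problem sizes

Default analysis meshes are a few thousand elements (the sensitivity
studies use a ~5k-element fusiform membrane; tests use 2–4k-element
tubes), chosen so the whole chain — including two thickness solves and
a Newton neo-Hookean solve — completes in seconds while keeping the
Laplace-law oracles inside 2 %. The generators expose resolution
directly, so the 0.8-mm element-size regime (~50k elements for the same
geometry) is a config change, not a code change.

## Known limitations

* Single tube only: no branching centerlines, no remeshing.
* The membrane surrogate's τ_v is not tissue stress; only its evolution
  over the dilation is interpreted, via the indices.
* No residual stress, prestretch, anisotropy (GOH-type laws) or
  fluid–structure interaction.
* Quadrants as independent observations inflate the effective sample
  size; a mixed-effects treatment is deliberately out of scope.
* The fusiform ground-truth tension is a local-radius approximation;
  quantitative oracles use the cylinder and sphere.
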