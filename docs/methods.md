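# Methods

`scolisim` is an in-silico clinical-trial framework for the posterior
surgical correction of adolescent idiopathic scoliosis (AIS).  It couples a
parametric generator of scoliotic spine anatomy to a small beam-element
finite-element kernel, simulates the correction maneuver for every
combination of subject, sagittal target and instrumentation strategy, and
analyzes the resulting instrumentation loads statistically.  This note
records the model, its assumptions, the numerical choices, and the design
decisions taken where the design was genuinely open.

## Coordinate conventions and anatomy representation

The global patient frame is right-handed with +X anterior, +Y subject-left
and +Z cranial; the coronal plane is YZ, the sagittal plane XZ, the
transverse plane XY.  All lengths are in mm, forces in N, stresses in MPa.

A spine is an ordered list of 18 vertebral frames (T1–L5 plus the first
sacral vertebra).  Each vertebra carries a body center, a rigid-body
orientation, left/right pedicle centers, superior/inferior endplate centers,
and endplate half-width/half-depth.  Per-level dimensions come from a single
embedded morphometry table with body width and depth increasing monotonically
from T1 to L5; subjects are scaled isotropically by their total spine
length.  Patient-specific sizing and tissue properties are deliberately out
of scope: material properties are patient-independent so that curve shape
and instrumentation strategy are not confounded by stiffness variability.

## Synthetic deformity generator

Vertebral templates are stacked along a centerline defined by three
per-level angle profiles:

* **Coronal tilt** — per scoliotic curve, a sine profile over the curve
  span whose integral is a raised-cosine lateral bump vanishing at the span
  ends.  The apex is the most laterally deviated vertebra; the maximally
  tilted vertebrae (the radiographic end vertebrae) sit near the quarter
  points of the span.
* **Axial rotation** — a raised-cosine copy of the bump, peaking at the
  apex and signed into the curve convexity (vertebral bodies rotate toward
  the convex side).
* **Sagittal tilt** — smooth sinusoidally weighted per-segment increments
  realizing the requested T4–T12 kyphosis (TK) and L1–L5 lordosis (LL).

Because the radiographic measurement operators couple the three projections
nonlinearly, profile amplitudes are calibrated by a fixed-point iteration
(multiplicative updates for Cobb and apical rotation, additive updates for
TK/LL, internal tolerance 0.1°, at most 50 iterations) until the *measured*
deformity parameters match the specification.  Round-trip agreement is
within 1.5° by construction and is enforced by tests.

Cohorts emulate the reported radiographic population: coronal Cobb angles
spanning 36.8°–84.6°, TK 0.2°–72.5° (median 25.9°), LL 3.2°–77.3° (median
44.1°), mixed curve types, levo- and dextroscoliosis, apexes throughout the
thoracolumbar spine, apical rotations from 0° to above 30°.  Sampling
choices, made once:

* **Cobb** is drawn with one-stratum-per-subject stratified uniform
  sampling (shuffled) so that even a 30-subject cohort covers the full
  severity range, in particular the <40° and >75° bins used in the binned
  analyses.
* **TK and LL** are triangular with modes chosen so the distribution
  medians match the reported cohort medians (25.9° and 44.1°).
* **Apical rotation** is drawn conditionally on Cobb (0.5·Cobb − 14° ±
  7° Gaussian scatter, clipped to [0°, 40°]).  Transverse apical rotation
  and coronal severity are strongly coupled in real AIS cohorts; sampling
  them independently would destroy that clinical structure and with it any
  rotation-stratified trend.
* About half the subjects receive a compensatory secondary curve of
  opposite convexity (15°–45°), which populates the different curve types
  of the simplified classification.

What the generator does *not* emulate: vertebral shape variability beyond
isotropic scaling, measurement noise, rib cage and soft-tissue asymmetry,
coronal imbalance, and true statistical shape variation learned from data.
Passing tests therefore demonstrate the mechanics and statistics pipeline on
idealized smooth deformities, not validity on real radiographic anatomy.

## Deformity measurement

A vertebra's endplate line in a planar projection is the line perpendicular
to the projected endplate normal; since vertebrae are rigid, each vertebra
has one tilt angle per projection.  Cobb angles are the angle between the
(directed, cranially oriented) projected normals of the two end vertebrae,
so values above 90° remain well defined.  Curves are detected apex-first
(alternating-sign local extrema of lateral deviation from the T1–S1 chord),
and each apex's end vertebrae are the maximally tilted vertebrae between it
and the neighbouring apexes, ties broken toward the apex.  TK and LL are
Cobb-style sagittal angles (T4–T12, L1–L5), signed positive for kyphosis
and lordosis respectively.  Apical axial rotation is the signed transverse
rotation of the vertebra's left-right axis about the cranial axis.

The simplified curve-type classification uses three regions by apex level
(proximal thoracic T1–T5, main thoracic T6–T11, thoracolumbar/lumbar
T12–L5) and a pure magnitude structurality criterion (Cobb ≥ 25°; there are
no side-bending films in silico).  Types 1–6 follow the standard
region-structurality table; lumbar and sagittal modifiers are not computed.

## Trial design

Sixteen target configurations form the 4×4 grid of TK and LL increases
{0°, 10°, 20°, 30°}; the (0°, 0°) member is the baseline.  In every target
the coronal Cobb of all curves and all axial rotations are set to zero.
Target geometries preserve per-segment arc length and the S1 pose, and
distribute the sagittal increments over the T4–T12 / L1–L5 segments
proportionally to the baseline per-segment angles (uniformly when the
baseline region is flat).

Seven pedicle-screw patterns are enumerated, described by a small rule
grammar (documented in `planning.py`) and overridable from the trial
configuration.  The published pattern figure is not machine-readable, so the
default table is a reconstruction constrained by the text: the four
concave-complete patterns (convex minimal, convex alternate, periapical
dropout, convex periapical dropout) fully instrument the apex and both
adjacent vertebrae on the concave side; apical key vertebrae and alternate
do not; all patterns anchor UIV and LIV bilaterally; segmental is the
bilateral superset; and the relative implant densities reproduce the
reported load ordering (segmental highest screw–rod force, the
alternate/apical-key patterns lowest).  Under those joint constraints:

| pattern | rule |
|---|---|
| segmental | bilateral at every level |
| convex minimal | concave all, convex at UIV/LIV only |
| apical key vertebrae | bilateral at UIV, apex, LIV |
| alternate | one screw per level, alternating sides |
| convex alternate | concave all, convex every other level |
| periapical dropout | concave all, convex dropped across apex±3 |
| convex periapical dropout | concave all, alternating convex outside apex±3 |

Isolated convex anchors near the apex act as force concentrators in this
model (they carry the whole periapical release load over a long free rod
segment), which is why bilateral-dropout readings of the dropout patterns
were rejected: they would have produced 1.4–1.6× the segmental forces,
irreconcilable with the reported similarity of the reduced patterns.

UIV and LIV are placed 4, 5 and 6 vertebrae cranial/caudal to the major
apex, restricted to T1–S1; combinations falling outside the range are
dropped.  With an unconstrained apex this yields 63 plans and 1008
simulations per subject.  Ideal rod contours are polylines through the
target-configuration pedicle centers of each side with one midpoint node
per segment (the midpoint nodes resolve the nearest-node coupling search).

## Finite-element model

The spine model consists exclusively of beam elements.  Vertebrae and the
pelvis are rigid bodies (master node at the body center; pedicle and
endplate-center slaves condensed exactly via master–slave kinematics).
Each intervertebral disc is a single two-node Euler–Bernoulli beam between
adjacent endplate centers with an elliptical section from the mean endplate
half-axes and fixed material properties (E = 6 MPa, ν = 0.45).  Rods are
titanium (E = 110 GPa, ν = 0.3) circular beams of diameter 5.5 mm.  Facet
joints, ligaments and the rib cage are not modeled.  Screw–rod junctions
are translation-only kinematic couplings (polyaxial heads before locking):
rotations are never constrained there.

The kernel assembles the reduced stiffness with batched 12-DOF space-frame
elements, enforces couplings, prescribed displacements and general
multipoint constraints with Lagrange multipliers, and solves the KKT system
with a sparse LU factorization.  Constraint rows are scaled to the
stiffness magnitude, the KKT matrix is symmetrically equilibrated, and the
solution is polished with iterative refinement whose residual is evaluated
in extended precision — together these keep rod free-body force/moment
residuals below 10⁻⁶ N / N·mm even for the most heavily loaded constructs.
A rod whose coupling points are (near-)collinear — the two-coupling convex
rod of the convex-minimal pattern exactly, the three-coupling
apical-key-vertebrae rods to within a fraction of a millimetre — retains a
spin mode about that line which translation-only couplings either cannot
resist at all or only through a sub-millimetre lever arm, beyond what a
polyaxial screw head physically transmits.  That mode is pinned at one
coupled node; the pin couple (exactly zero for a truly collinear set) is
accounted as an external action in the rod's free-body budget.  Outer-fiber rod stress is |N|/A +
√(My²+Mz²)·r/I, with an optional von Mises variant folding in torsional
shear.

## Correction procedure

The correction is simulated in two steps, both linearized about the target
configuration (a full incremental nonlinear solution is deliberately out of
scope; the linearization about the corrected shape is the consistent
small-spring-back assumption):

1. **Imposition.**  Disc internal forces for the full pre-op → target
   motion are evaluated with a finite-rotation deformation measure
   (relative translation plus axis-angle relative rotation in the
   corotated element frame), so rigid motions produce exactly zero force.
   The screw-bearing pedicle nodes are then held at their target positions
   — one pedicle holds three translations; a bilateral pair holds the
   midpoint translations plus the two rotations perpendicular to the
   pedicle axis — while all other vertebrae equilibrate against the
   released prestress.  The pelvis is left free in this step: the maneuver
   is self-contained, and a fixed pelvis would make the results depend on
   the arbitrary global placement of the target configuration relative to
   the sacrum (a pure gauge).  Holding reactions at the instrumented
   vertebrae and the held-state disc force set are reported.
2. **Release.**  The holding constraints are replaced by couplings between
   each screw-bearing pedicle and the nearest rod node of the same side
   (distance ties resolve cranially), and the held-state internal forces
   load the coupled spine + rod system.  The sacrum is fixed as a
   statically determinate gauge; since the release loads are
   self-equilibrated its reaction vanishes.  The elastic energy imposed in
   step 1 thereby determines the strains and stresses in the
   instrumentation; the release can only lower the total elastic energy,
   which is verified per simulation.

Four outcome metrics are extracted per simulation: the maximal outer-fiber
rod stress; the maximal screw–rod coupling force magnitude (evaluated from
the rod-side internal nodal forces, i.e. the load actually transmitted by
the coupling); and the craniocaudal positions of both maxima as signed
vertebra offsets from the apex (negative = cranial; midpoint rod nodes
belong to the nearer level, ties toward the apex).

The post-operative geometry is reconstructed from the final per-disc
relative deformations (element flexibility applied to the final end
forces), composed caudocranially with exact finite rotations and anchored
at the pre-operative pelvis pose — the radiographic reference.  A fully
relaxed disc thereby reproduces its pre-operative relative pose exactly,
preventing spurious accumulation of linearization drift.  Residual Cobb is
re-measured between the pre-operative end vertebrae of the major curve;
residual apical rotation at the pre-operative apex.

### Known limitations of the correction model

* The linear spring-back can be large for sparsely anchored constructs
  (apical-key-vertebrae); reported residuals there approach the
  pre-operative deformity and carry the largest linearization error.
* Holding the apex straight while unanchored neighbours spring back can
  tilt the (unanchored) end vertebrae slightly past their pre-operative
  inclination — a junctional angulation effect of up to a couple of
  degrees at the baseline target, not an over-correction.
* Targets that add 30° of kyphosis to an already hyper-kyphotic subject
  pitch vertebrae toward the transverse plane, where the coronal
  projection of an endplate line degenerates and measured coronal angles
  can exceed the pre-operative Cobb by large amounts.  This is a
  projection property of the measurement, faithfully reported.
* Set-screw locking, specific correction maneuvers (rod derotation,
  in-situ bending), bone–screw interface failure and post-operative
  functional loading are not modeled.

## Trial engine and statistics

The trial iterates subjects × 16 targets × feasible plans, sharing the
target geometry and disc prestress across the plans of one
(subject, target) pair; failures are logged and flagged, never abort the
batch; all randomness flows from the cohort seed and the analysis seed.
Records are tab-delimited text with lossless floats.

Feature importance uses gradient-boosted regression (500 trees, depth 3,
learning rate 0.1, squared-error loss — fixed for determinism and
reportability) on twelve candidate predictors: curve type, Cobb angle,
screw pattern, instrumentation length, apex level, apical rotation,
upper/lower end vertebrae, UIV, LIV, and the lordosis/kyphosis changes.
Vertebral levels are encoded ordinally in anatomical order; curve type and
pattern as indicators, with importances summed per original feature and
normalized so the top feature equals 1.  Importances are impurity-based
(labelled as such in the report).  Group comparisons stratify numeric
factors into half-open 5° bins (bins with fewer than 3 records are
dropped), run a Kruskal–Wallis omnibus, and only on significance proceed
to pairwise Wilcoxon rank-sum tests with Bonferroni correction (factor =
number of pairs).  A normality diagnostic is reported but never gates the
nonparametric pipeline.  The simulations of one subject are treated as
independent observations, mirroring the trial design being emulated;
subject identifiers are retained in the records so clustered analyses
remain possible.

## Problem sizes

The default study conditions are a 30-subject cohort under the full
factorial (≈22,000–30,000 simulations depending on apex feasibility,
about 6 minutes on one CPU at ~13 ms per simulation), 20 seeded runs for
the planted-importance recovery rate, 1000 replicates for the
Kruskal–Wallis type-I calibration, and 100 random specifications for the
generator round-trip property.
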