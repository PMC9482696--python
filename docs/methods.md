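# Methods

This note documents the models, conventions, numerical choices and known
limitations of `jointrom`.

## Rotation conventions

Joint pose is the orientation of the distal ACS relative to the proximal
ACS, `R = R_prox^T R_dist`, a proper rotation (orthonormal within 1e-9,
det = +1). Euler decomposition is intrinsic Z-then-Y-then-X on column
vectors, `R = Rz(fe)·Ry(abad)·Rx(lar)`, in degrees — the joint-coordinate
convention used across XROMM-style studies, with Z assigned to the axis
of greatest expected motion (FE). Canonical ranges are
`fe, lar ∈ (−180, 180]` (ties at ±180 map to +180) and `abad ∈ [−90, 90]`.

**Gimbal lock.** When `|cos(abad)| < 1e-8` the decomposition is singular
(only `fe − lar` or `fe + lar` is determined); the convention here sets
`lar = 0` and folds the residual rotation into `fe`. `rom_summary`
includes locked frames under this convention and counts them in
`gimbal_locked_frames`.

**Mirroring.** Left-side joints are transformed to the right-side
convention by conjugation with `M = diag(1, −1, 1)` — reflection across
the proximal-frame X–Z plane, i.e. negation of the mediolateral (Y)
direction. This is the unique orientation-consistent reflection once
that plane is fixed, and in Euler terms maps
`(fe, abad, lar) → (−fe, abad, −lar)`. It is an involution and preserves
geodesic distances between poses.

## ACS construction

Long-bone ACSs are built from perimeter landmarks at the articular ends:

* preliminary X (LAR) = unit vector from the proximal to the distal
  perimeter mean;
* preliminary Z (FE) = total-least-squares line (first principal
  component) through the perimeter at the joint end;
* Y = X × Z, normalised.

The two preliminary axes are generally not perpendicular (they follow
bone morphology), so one axis is recomputed: `keep_long_axis` (proximal
femur, tibia/fibula) retains X exactly and sets Z := X × Y;
`keep_fe_axis` (distal femur, whose distal surface is longest along FE)
retains Z exactly and sets X := Y × Z. Axis signs: X points
proximal→distal; the Y sign is chosen so a named ventral/flexor reference
point lies on the −Y side (positive Y = abduction); without a reference
the sign is canonicalised lexicographically and flagged in the output.

The pelvis ACS uses primitives: spheres fit to both acetabula (algebraic
least squares then Levenberg–Marquardt geometric refinement) and a
cylinder to the sacral vertebral body (PCA-initialised axis, nonlinear
refinement of tilt, in-plane offset and radius). Y (mediolateral) joins
the acetabular centroids (pointing right); the sacral axis is projected
onto the plane perpendicular to Y — keeping its pitch, discarding its
yaw — to give X (anteroposterior, pointing caudally, disambiguated by a
caudal reference point); Z = X × Y points dorsally; the origin is midway
between the centroids. Projection happens before Z is recomputed.
Acetabular ACSs re-label the pelvis axes per side — hip X (LAR) points
laterally out of each socket, hip Z (FE) along the pelvis dorsoventral
axis, hip Y completes the right-handed triad — a fixed convention chosen
so that in the laterally-extended null pose the femoral axes coincide
with the acetabular axes.

Tolerances: constructed triads are orthonormal and right-handed within
1e-9 (`validate_acs` reports residuals); point clouds are treated as
degenerate when the relevant design matrix has condition number > 1e8.

## Marker processing

Rigid poses are solved per frame by the closed-form Kabsch fit: centroid
alignment, SVD of the cross-covariance, determinant-sign correction
against reflections. Frames with fewer than three visible markers are
dropped and logged, not interpolated. Calibration transforms
(markers→plate from rig geometry, plate→bone from CT) are inputs;
`compose_chain` multiplies them as homogeneous transforms.

Trial quality follows the sweep protocol's discard rules. The automatable
symptom of joint damage is a pose trace that "jumps" discontinuously:
frame *i* is flagged when the geodesic angle from frame *i−1* exceeds a
threshold, default 15° between consecutive 30 Hz frames (the protocol
describes the symptom, not a number; 15° is far above the few-degree
steps of an intact quasi-static sweep and far below a damage jump).
Qualitative discard signs (tearing noise, resistance changes) are not
modelled. A specimen is sufficiently sampled when all three planar
trials (FE, ABAD, LAR) and at least two interaction-of-DoF trials
survive.

## SFP regions

Per-axis tip clouds are projected gnomonically about their spherical
centroid; the chart sends great circles to straight lines, so the planar
convex hull (default) is exactly the spherical convex hull. An alpha
shape (Delaunay triangles with circumradius below `tan(alpha_deg)`,
default 15°) is available for non-convex clouds, since published
pose-space polygons hug the data and their construction is generally
unspecified. Regions must fit inside an open hemisphere about the
centroid (guard at 90° − 1e-6); larger clouds raise an error advising a
split. Membership uses the same chart with closed boundaries (boundary
points count as inside, tolerance 1e-9 in chart coordinates) and is
cross-checked in the tests against a brute-force spherical winding-number
oracle.

Pooling concatenates per-axis tips across specimens (with provenance),
rather than unioning per-specimen polygons; left-side traces must be
mirrored first and are rejected otherwise.

## RoM tables

Extremes are order statistics of the per-frame Euler angles; ties break
to the earliest frame. The table view rounds every cell to the nearest
whole degree, half away from zero, with the range rounded from the
*unrounded* range — required for internal consistency with published
tables, where several printed ranges differ by 1° from rounded-max minus
rounded-min. Interaction of DoF is reported exactly as those tables do
(concomitant angles at the extrema) plus the full SFP export; no
additional interaction statistic is invented.

## Synthetic data

The generators define the study conditions the pipeline is tested under.

**Joint-limit model.** The feasible set is a coupled ellipsoid in Euler
space, `{e : ‖S C (e − c)‖ ≤ 1}` with `S = diag(1/semi_axes)` and `C` a
well-conditioned shear. This is the simplest smooth set exhibiting
interaction of DoF — the attainable extreme about one axis depends on
the other two — which is the central phenomenon of the analysis. Passive
torque is zero inside the set and grows linearly with the distance (in
degrees, along the ray from the centre) beyond the boundary. Defaults:
threshold τ = 10 N·mm, stiffness 10 N·mm/deg, so sweeps stop within
1° of the feasible boundary; the stiffness was set so that the
τ-crossing overshoot stays below one sweep step, keeping the emitted
extrema faithful to the model.

**Ex vivo sweeps.** A sequence such as FAL sweeps the innermost axis
(F) through its conditional feasible interval, increments the middle
axis (A) and repeats, then the outermost (L), until the limits about
each are reached. Two details the protocol leaves open are fixed as
follows: (1) when an outer axis is incremented, the inner sweep restarts
from the midpoint of its *new* conditional interval (restarting from the
global centre would make outer-axis extrema unreachable under coupling);
(2) traversal is boustrophedon and operator repositioning between sweep
rows is interpolated at the largest step size — the feasible set is
convex, so the interpolation never leaves it — keeping trials continuous
for the jump detector. A pose is emitted iff its torque is strictly
below τ (or it is the starting centre pose, so a zero threshold emits
exactly one pose). Frames are quasi-static at 30 Hz; dynamics are
ignored. Default steps are 3° (FE) and 6° (ABAD, LAR), giving ~3 × 10⁴
frames for six sequences of the hip preset — dense enough that per-axis
extrema are recovered within one step and pooled hulls cover the tip
image, while keeping a full six-sequence simulation under a few seconds.

**Presets.** `hip_like_model` (centre (−25, 0, −75)°, semi-axes
(52, 45, 52)°) is broad about all three axes with its centre at strong
internal rotation, so the null pose is infeasible — every attainable
pose involves internal rotation, as in real salamander hips.
`knee_like_model` (centre (65, 0, 0)°, semi-axes (58, 25, 30)°) is
FE-dominant with 0° flexion infeasible. Both are synthetic stand-ins
whose RoM tables resemble real hip/knee magnitudes; they are not fits to
any specimen.

**Strides.** One cycle of per-axis sinusoids (401 frames spanning
exactly one period, so first = last pose), constrained inside the
feasible set shrunk by a radial margin (default 5%); violations raise
before any data are produced. The default hip stride uses most of the
FE range, about a third of the ABAD range and an intermediate LAR range
— the qualitative in vivo walking pattern. Optional seeded Gaussian
jitter is available; all generators are bit-reproducible under a fixed
seed.

**Landmarks and markers.** Landmark fixtures are perimeter ellipses
(major axis along the FE line) at the ends of a bone along +x, with a
ventral reference point and optional noise and rigid motion, returned
with their ground-truth ACSs; the pelvis fixture provides two acetabular
sphere caps, a pitched sacral cylinder and a caudal reference. Marker
trials transform an asymmetric 7-marker tree through a pose sequence
with additive Gaussian noise.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: real feasible sets need not be ellipsoidal or
convex; real torque rises nonlinearly and anisotropically; marker noise
is not isotropic Gaussian (soft-tissue and reconstruction artefacts are
structured); sweep coverage by a human operator is uneven; and real
strides are not sums of three sinusoids. The pipeline's correctness is
established on these controlled conditions; its conclusions on real data
inherit the usual caveats of specimen variation and sampling.

## Problem sizes

The test suite and the acceptance script use: 10⁵ Euler round trips,
10⁴ region-membership queries against the winding oracle, 200-frame
marker trials at σ = 0.1 mm, six-sequence sweeps at (3°, 6°, 6°) steps
(~3 × 10⁴ frames) and dense single sweeps at (2°, 4°, 4°) for parameter
recovery, and 401-frame strides.

## Known limitations

* Translational RoM is not analysed (rotation-only, like the analyses
  this package supports); translation channels exist only inside
  `RigidTransform`.
* Per-axis SFP regions are projections of a 3-DoF pose space: a pose can
  violate joint feasibility through a coupled multi-axis combination yet
  keep all three axis tips inside the per-axis regions. Containment
  checks are therefore necessary, not sufficient, for feasibility — an
  inherent property of the visualisation, shared with the original
  method.
* The acetabular-ACS re-labelling and the mirroring plane are documented
  conventions where the field's descriptions are under-specified.
* Alpha-shape regions depend on the `alpha_deg` scale; the convex hull
  is the reproducible default.
* No quaternion/axis-angle public API; no C3D or proprietary capture
  formats; no camera calibration or marker tracking.
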