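# jointrom

Joint range-of-motion (RoM) analysis for comparative biomechanics:
anatomical coordinate systems from bone landmarks, marker-based rigid
pose recovery, ZYX Euler decomposition of relative joint rotation,
spherical frame projections (SFPs) of pose space, RoM tables with
interaction of degrees of freedom, and in vivo vs ex vivo pose-space
comparison — plus simulators of the ex vivo sweep protocol and an in
vivo stride, so every stage runs and is tested on synthetic data.

The package is aimed at researchers quantifying how much of a joint's
passively attainable (ex vivo, ligamentous) pose space an animal actually
uses during locomotion (in vivo), e.g. in salamander hindlimbs used as
analogues for early tetrapod locomotion.

## The method

A joint pose is the rotation `R` of the distal bone's anatomical
coordinate system (ACS) expressed in the proximal bone's ACS,
`R = R_prox^T R_dist`. Axes follow the XROMM convention `Z = FE`
(flexion-extension), `Y = ABAD` (abduction-adduction), `X = LAR`
(long-axis rotation), and Euler angles use the intrinsic Z-Y-X order:

```
R = Rz(fe) · Ry(abad) · Rx(lar)      (degrees, column vectors)
```

ACSs are built from points placed on the articular perimeters of the
bones (line and plane fits), with sphere/cylinder primitives at the hip
(acetabula, sacral vertebral body). Marker-cloud poses are solved with
the closed-form Kabsch (SVD) fit; left-side joints are mirrored to the
right convention by conjugation with `M = diag(1, -1, 1)`.

An **SFP** traces the three unit axis tips of `R` (its columns) on the
unit sphere fixed in the proximal ACS — blue = FE, green = ABAD,
red = LAR. Unlike Euler-angle plots, spherical distances between tips
faithfully represent distances between poses and there is no gimbal-lock
distortion. Per-axis pose-space regions are spherical convex hulls (or
alpha shapes) built on a gnomonic chart about the tip cloud's centroid;
an in vivo trace is compared against pooled ex vivo regions by tip
membership, per-axis range ratios, and reachability of the null pose
(`R = I`, both ACSs aligned).

RoM tables report, per axis, the extreme angle, its range, and the
concomitant angles about the other two axes at the extremal pose — the
interaction of degrees of freedom. Ranges are computed on unrounded
extrema and then rounded to whole degrees, so a printed range can differ
from (rounded max − rounded min) by 1°.

The synthetic joint is a coupled ellipsoid in Euler space with a linear
torque spring beyond its boundary; the ex vivo simulator performs the
six hierarchical sweep sequences (FAL … LAF) bounded by a torque
threshold, and the in vivo simulator generates one periodic 401-frame
stride cycle inside the feasible set.

## Worked example

```
$ jointrom demo --joint knee --outdir demo_knee --seed 0
demo (knee) written to demo_knee/: rom_table.csv, sfp_exvivo.json, comparison.json
  FE: inside fraction 1.000, range ratio 0.777
  ABAD: inside fraction 1.000, range ratio 0.318
  LAR: inside fraction 1.000, range ratio 0.331
  null pose reachable: False
```

Six ex vivo sweep trials of a synthetic knee are simulated, pooled into
per-axis SFP regions, and a simulated walking stride is compared against
them. Every stride tip lies inside the ex vivo pose space (inside
fraction 1.0 — in vivo RoM is a subset of ex vivo RoM); the stride uses
77.7% of the ex vivo FE range but only about a third of the ABAD and LAR
ranges; and the straightened null pose is not attainable (the synthetic
knee, like a real one, cannot reach 0° flexion). The first rows of the
RoM table (whole degrees; `conc*` are the concomitant angles at the
extrema):

```
specimen,context,axis,max,min,range,conc1_at_max,conc2_at_max,conc1_at_min,conc2_at_min
synth00,ex_vivo,FE,123,7,116,-6,0,6,0
synth00,ex_vivo,ABAD,24,-24,48,78,-12,90,0
synth00,ex_vivo,LAR,24,-24,48,76,12,96,12
```

The same pipeline is available as library functions (`jointrom.rom_summary`,
`jointrom.project_sfp`, `jointrom.compare_invivo_exvivo`, …) and as the
other CLI subcommands (`build-acs`, `pose-from-markers`, `rom-table`,
`sfp`, `compare`, `simulate-exvivo`, `simulate-invivo`).

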