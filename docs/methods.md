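# Methods

`jointmorph` re-creates, at desk scale and on fully synthetic inputs, the
computational chain used to study how muscle-contraction-generated
biophysical stimuli pattern the embryonic chick knee: a poroelastic
finite-element model of the joint section contrasting dynamic contraction
with rigid paralysis, 3D morphometry of the distal femur and adjacent
rudiments, and mixed-model statistics on chondrocyte proliferation counts.
No experimental data ship with the package; every input is generated by the
phantom and count simulators, whose defaults play the role of the study
conditions.

## The knee phantom

The phantom is stylised, not anatomically derived: the distal femur is a
pair of ellipsoid condyle caps (separate medio-lateral radii and
dorso-ventral heights) hanging from an elliptic-cylinder shaft, separated by
a rectangular-profile intercondylar fossa; the tibiotarsus and fibula are
elliptic cylinders below a planar interzone gap.  The measurements only
require well-defined extrema, so simple quadric surfaces suffice and make
every one of the twelve lengths exactly computable at construction time
(`ShapeVolume.ground_truth`).

Two deliberate departures from the plainest geometry:

- **Intercondylar eminence.**  The tibiotarsus plateau carries a parabolic
  central ridge (default 0.32 mm tall, 0.26 mm half-width).  The femur is
  positioned so the *minimum* femur–plateau approach still equals the
  nominal interzone gap, so the gap measurement is unaffected.  Without the
  ridge the articular contact sits under the condyle centres and no
  fossa-adjacent stimulus concentration can arise; with it, trans-articular
  load funnels onto the condyle inner walls flanking the fossa, as the real
  (domed, eminence-bearing) articular geometry makes it do.
- **Grid dither.**  The voxel grid is offset from the constructed surfaces
  by 0.382 of a voxel so that surface planes never coincide with
  voxel-centre boundaries; extent errors are then strictly below one voxel
  instead of occasionally exactly one.

`shape_simplification` in [0, 1] morphs the phantom towards the
immobilisation phenotype: at 1 the fossa narrows by 42 %, condyle heights by
16 %, epiphyseal widths by 19 % and the interzone gap by 30 % — the
direction and rough ordering of the reported treatment effects, with the
fossa the strongest.  The default voxel size is 0.01 mm so the 0.08 mm
interzone spans eight voxels.  Specimen-level biological variation is a
lognormal size jitter (default CV 3 %) applied independently to each primary
length; the fibula placement keeps a guaranteed clearance from the jittered
femur because the two never overlap in vivo.

Measurements are landmark-driven scans that never read the ground truth:
the fossa is the minimum-gap locus between the two condyle runs of a
frontal section, widths are plateau-averaged run lengths (averaging rows
within one voxel of the extreme removes the quantisation-phase bias a raw
max/min carries), heights are maximal dorso-ventral column extents, and the
interzone is the minimal femur–tibiotarsus column gap.  The ventral
measurement plane sits a configured absolute 0.12 mm below the
condyle-centre plane; deriving the offset from a *measured* condyle height
would leak measurement noise into the ventral widths.  With these choices
all twelve measurements recover the constructed lengths to within one voxel
across a randomised sweep covering both morphologies (tested), and are
stable to within half a voxel under 2× resolution changes.

One labelling quirk is inherited from the field's table layout: the fossa
height shares the printed label *iv* with the lateral condyle height, so it
is carried internally as `iv-b`; the medial midline width is labelled `iix`.

## Poroelastic model

The solver implements small-strain linear Biot poroelasticity with
incompressible constituents (zero storage), isotropic permeability and
plane-strain kinematics on the frontal joint section.  Both displacement and
pressure use linear triangles; a Brezzi–Pitkäranta-type pressure-Laplacian
stabilisation (coefficient 0.5 on the scale h²/(λ+2μ)) suppresses the
spurious modes of the equal-order pair.  Time integration is backward Euler;
the system matrix is factorised once per solve.  Meshes come from the voxel
phantom by column-filling the joint space (articular gap plus fossa
interior) with interzone tissue and triangulating a square resampling grid
(two right triangles per cell, minimum angle ≥ 40° by construction;
default cell 0.02 mm, four cells across the articular gap).

Verification: the drained patch test reproduces arbitrary constant
plane-strain stress states to round-off; the one-dimensional consolidation
column matches the analytic series solution to well under 2 % of the applied
load at three times, converging monotonically under combined mesh/time
refinement; global force balance holds to ~1e-14; solutions are exactly
linear in the load and rotation-equivariant.

Units are mm–kPa–s; muscle forces are µN per mm of out-of-plane thickness.
Default tissue constants are placeholders on a physiologically soft scale —
cartilage E = 1 kPa, ν = 0.3, α = 1, k = 20 mm⁴ N⁻¹ s⁻¹; interzone ten
times softer and ten times more permeable — chosen so the cartilage
consolidation time (~10 s) is long against the 1 s contraction, i.e. the
mid-contraction response is substantially undrained.  They are configuration
values, not measured properties; only spatial and ordinal field patterns are
interpreted, never absolute magnitudes.

## Loading regimes

The muscle table is declarative (attachment node set, unit direction, peak
force, functional group).  The default fixture has two flexors (10 µN each)
gripping the tibiotarsus side walls and two extensors (8 µN each) acting
through the capsular condensation anchored at the epiphysis margin just
below the joint line.  Both groups pull proximally (towards the thigh) with
opposite medio-lateral shear components: flexion and extension each load the
joint obliquely, bending the joint column with tension on alternating sides,
while rigid paralysis — every muscle applied simultaneously, continuously,
at 75 % of its peak (paralysed muscle transmits reduced force) — cancels the
shear and leaves a nearly pure trans-articular compression.  Flexion and
extension ramp linearly to peak over 1 s and are reported at mid-contraction
(0.5 s, half peak load); paralysis is constant in time and reported at its
consolidation steady state (60 s).  Boundary conditions are shared by all
regimes: proximal femoral and distal tibiotarsus cuts fully fixed and
impermeable, all other external surfaces free-draining (p = 0),
displacement and pressure continuous across tissue interfaces.

The muscle directions, magnitudes and attachment placements are model-design
parameters (no measured values exist for them); they were chosen so that the
default configuration expresses the qualitative contrast the study reports,
and they are exposed in the configuration like every other constant.

## Probe regions and regime contrast

Eight named regions quantify the field maps.  Five femoral boxes are placed
from measured landmarks: `fossa_adjacent` covers the condyle inner walls
flanking the fossa (within 1.2 fossa-widths of the fossa midline, articular
zone up to the fossa floor) and the four condyle boxes cover the remaining
outer condyle bodies, split at the condyle-centre level into "dorsal"
(proximal half) and "ventral" (distal, articular half) — the single frontal
analysis plane folds the out-of-plane dorsal/ventral distinction onto the
proximo-distal axis.  `patella_region` is an interzone polygon at the
lateral joint margin (capsular area).  The interzone sub-layers are
geometric: `chondrogenous_layer` is interzone within 0.022 mm (about a
quarter gap) of either cartilage interface, `intermediate_layer` is the
remaining core.  Region statistics are area-weighted over exact
element–polygon intersections; femoral regions are restricted to the
connectivity-identified femoral cartilage body so the eminence cannot leak
into them.

The regime contrast reports paralysis/normal ratios per region and field
(the normal statistic is the peak of mid-flexion and mid-extension) and four
ordinal flags:

- *dynamic amplitude* |mid-flexion − mid-extension| is identically zero for
  the constant paralysis regime, by definition;
- the *fossa-adjacent Von Mises peak* is present when the fossa-adjacent
  regional mean exceeds the mean of the condyle-region means — region means,
  not single-element maxima, because the latter are mesh sensitive and
  dominated by load-application concentrations (raw maxima are logged);
- *tension loss* compares the fossa-adjacent maximum-principal-stress peak
  between regimes: under paralysis the shear-free compression closes the
  notch and the fossa tension peak drops (below zero in the default run);
- *compression dominance*: an element is compression dominated when
  σ₂ < 0 and σ₁ ≤ 0.05·|σ₂| (tension minor against local compression);
  the flag requires ≥ 70 % of the distal-femur cartilage area to qualify.
  The distal femur excludes the shaft, whose attachment and cut-face
  concentrations are artefacts of the stylised 2D load application.

On the default configuration all flags hold, and in the normal regime the
chondrogenous layer shows elevated fluid velocity (×1.5 over the interzone
background) while the intermediate layer shows elevated pore pressure
(×1.7) — the layer-patterning correspondence the model exists to express.
These are ordinal properties of the default fixture, not claims about all
parameterisations.

## Outlines and overlay

Cartilage outlines are half-level contours of the Gaussian-smoothed
(σ = 1.5 voxels) femoral section mask — sub-voxel smooth, with perimeter
accurate to ~0.1 % on a disk, at the price of ~1.5-voxel corner rounding.
Anchors are fitted total-least-squares side lines along the shaft band and
the fossa-notch midpoint.  Overlay alignment is rigid only: each outline is
mapped to a canonical frame (mean side-line direction vertical, fossa
midpoint at the origin), which makes alignment exactly idempotent and
self-alignment exact to round-off.  Sector area differences are reported for
medial-condyle / fossa / lateral-condyle bands (the in-plane sectors; the
frontal plane has no dorsal/ventral extent).

## Proliferation counts and the mixed model

Counts emulate mitosis-marker scoring in five femoral regions: per box,
proliferating cells are Binomial(n_total, p) with logit p = regional
baseline + treatment effect + individual intercept + section intercept,
n_total ~ Poisson(1000) per 1.44 mm² box.  The default design is the study
design: three specimens per arm, two sections × two independent focal planes
each.  The default planted effect is a reduction of 11.8 per 1000 cells at a
~5 % baseline (converted internally to log-odds at the baseline); default
random-intercept SDs are 0.15 (individual) and 0.10 (section) on the
log-odds scale — moderate biological heterogeneity chosen so the
individual-level variance is visible but does not swamp a realistic effect.

The fitted model is the matching binomial GLMM with nested random
intercepts, estimated by maximum likelihood with a per-individual Laplace
approximation: an inner Newton iteration (standardised random-effect
parameterisation, so the iteration stays conditioned as a variance
component approaches zero; step tolerance 1e-10) finds the joint mode, and
L-BFGS-B optimises fixed effects and log-SDs (objective tolerance 1e-12,
gradient tolerance 1e-8, log-SD bounded in [−6, 2]) from plain-logistic
starting values.  Fixed-effect covariance comes from the central-difference
observed information, falling back to the fixed-effect block when a variance
component sits on its bound.  Agreement with an independent Laplace
implementation (lme4) is at the 1e-3 level on all parameters (tested).

Two p-values are reported: the default uses a t reference with
df = n_individuals − 2, the small-sample convention that gives df = 4 for
the 3 + 3 design; a Wald normal reference is also returned and is the one
whose type-I error is calibrated in the acceptance suite (≈3.5 % at the
reduced null design; the t reference is slightly conservative there).  The
treatment effect is converted to cells-per-1000 at the control-arm fitted
baseline, with a delta-method standard error.

The ANOVA stage is a two-group one-way F (equal to the squared pooled t)
per measurement with df (1, n₁+n₂−2); degenerate identical groups return
F = 0 rather than NaN.  Percent reductions are recomputed from the supplied
means — tabulations computed on unrounded raw data can differ in the last
digits, so equality with any printed table is never asserted.

## Problem sizes and reproducibility

Default sizes keep every stage at desk scale: the FE section has ~7000
elements and solves all three regimes in a few seconds; the morphometric
acceptance sweep uses 50 random phantoms; GLMM calibration uses 100 recovery
replicates (50 individuals per arm) and 200 null replicates at a reduced
design (8 per arm).  All randomness flows from explicit seeds; identical
config + seed reproduces every output file byte for byte (tested).  The
acceptance script (`scripts/acceptance.py`) recomputes the headline
quantities from scratch at any seed.

## Known limitations

- The phantom's quadric geometry supports the defined measurements and load
  paths, not realistic anatomy; passing tests certify the pipeline's
  numerics and logic on such shapes, not fidelity to real embryos.
- All FE analysis is a single 2D plane-strain frontal section; out-of-plane
  load paths (patellar mechanics, fibular articulation) are folded into
  in-plane stylisations or omitted.  The fibula is generated and measured
  but excluded from the mesh (no in-plane load path).
- Tissue constants are placeholders; absolute stimulus magnitudes are not
  meaningful, only patterns, orderings and ratios.
- The Laplace GLMM shows the usual mild small-sample attenuation at very few
  clusters; at the calibration sizes it is unbiased within Monte-Carlo
  error.
- No muscle activation dynamics, joint articulation/contact, large
  deformation, growth or remodelling; loads are point forces on boundary
  patches.
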