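# Methods

This note records the model, its assumptions, the parameter choices, and
the numerical decisions behind `pelvifem`, in the order the pipeline runs.

## The phantom and what it stands for

The study object is a parametric, fully synthetic pelvis: a mirror-symmetric
ring of axis-aligned blocks in an anatomical frame (x lateral–medial from
left to right, y posterior→anterior, z inferior→superior; all lengths mm).
The sacrum (50 × 30 × 60 mm, split into S1/S2 × left/right quadrants) is
joined to two innominate blocks (30 × 70 × 90 mm) through 3 mm sacroiliac
cartilage layers, and the ring closes anteriorly through pubic bodies,
square-section superior and inferior pubic rami (12 mm), and a midline
symphysis disc.  The blocks are voxelized at the target element size and
each voxel is split into six tetrahedra (Kuhn decomposition, which is
conforming between neighbours); voxels at x < 0 use the mirrored split, so
the noiseless phantom is *exactly* its own mirror image — a property the
tests exploit.

What the phantom emulates: the two load paths of the pelvic ring (posterior
through the sacroiliac joints, anterior through the rami and symphysis),
distinct S1/S2 measurement regions, compliant joints, ligament suspension,
and a heterogeneous osteoporotic bone field.  What it does not emulate:
real pelvic surface geometry, the wedge (keystone) shape of the sacrum,
joint curvature and contact, muscle forces, and cortical-shell thickness
maps.  Consequently, passing the qualitative construct comparisons here
shows that the *method* ranks fixation constructs for the right mechanical
reasons on a ring with the correct topology — it does not validate
patient-specific magnitudes.

Bone quality is a synthetic Hounsfield field: surface voxels (one-voxel
cortical shell) at 1800 HU, interior trabecular bone at 300 HU, element-wise
Gaussian noise (σ = 100 HU) clamped to the 220–2000 HU segmentation window.
The single RNG seed controls only this noise; geometry is deterministic.

Element size defaults to 5 mm, the coarse end of the converged 1–5 mm
range; the full comparison (9 solves) then runs in about half a minute.
With `snap_reference` set, block boundaries snap to a fixed coarse grid so
that finer meshes discretize the *same* geometry — without it, a 3 mm mesh
would, e.g., thicken the cartilage differently than a 5 mm mesh and a
refinement sweep would compare different models.

## Material mapping

Per element, HU (clamped to the window) maps to apparent density through
the linear calibration ρ_app = 0.00032362·HU + 1 (g/cm³, capped at
1.8 g/cm³ — the cap interprets the source convention that the maximum HU
corresponds to ρ_app = 1.8) and to Young's modulus through the Dalstra
power law E = 1958.6·ρ_app^2.33 MPa, clamped to the elderly-bone range
200–6530 MPa.  With HU restricted to [220, 2000] the mapping alone spans
about 2300–6270 MPa, so the lower clamp is inactive for in-window HU; it
exists to honour the stated range for arbitrary imported HU tables.

Moduli are snapped to the centers of uniform bins so the solver sees a
finite material catalog.  The bin width defaults to 5 MPa because
(6530 − 200)/5 = 1266 distinct materials; a 50 MPa increment would give
~127.  Both conventions circulate for this pipeline class and they are
mutually inconsistent; the 1266-material reading is the default and both
numbers are configurable.

Poisson's ratio for bone is ν = 0.3 (configurable).  Cartilage and the
symphysis use a linear-elastic surrogate (E = 50 MPa, ν = 0.45) valid at
the small strains of these load cases; a hyperelastic disc model is out of
scope.  Implants are titanium alloy (E = 110 GPa, ν = 0.3).

## Ligaments

Eight groups: anterior sacroiliac (ASL), short and long posterior
sacroiliac (SPSL, LPSL), interosseous (ISL), sacrospinous (SS),
sacrotuberous (ST) — bilateral — plus midline superior and inferior pubic
ligaments (SP, IP).  Each group is a bundle of 3 parallel node-to-node
springs (2 for SP/IP) between geometric attachment patches, with the group
stiffness split evenly over the bundle to avoid point singularities; rest
lengths are the undeformed attachment distances.  Bundle node selection
sorts by (z, y, |x|), which keeps left and right bundles exact mirror
images — with raw x the intact phantom showed a spurious ~1 % left/right
stress asymmetry.

Three stiffness catalogs: constant values after Shi et al. (e.g. ISL
2800 N/mm), constant values after Yao et al. (e.g. SS 12.6 N/mm), and
elongation-dependent ranges after Eichenseer et al. (e.g. ASL 39–103 N/mm).
The default combines the Eichenseer laws with the constant 500 N/mm pubic
ligaments from Shi.  The elongation-dependent law is implemented as a
secant stiffness interpolated linearly from the low value at 0 % strain to
the high value at a breakpoint strain (default 10 %, configurable), constant
beyond — a smooth, monotone reading of a range "defined by percentage
elongation" whose strain axis is not otherwise specified.  At the small
operating strains of these load cases the springs sit near their low
stiffness.

All springs are tension-only: force = k(ε)·max(ΔL, 0).

## Solver

Constant-strain (linear) tetrahedra; engineering-strain Voigt ordering
(xx, yy, zz, xy, yz, zx).  The global stiffness is assembled sparse;
bonded ("tie") constraints are eliminated master–slave (exact, well
conditioned — not penalty); Dirichlet patches clamp all three components,
and nonhomogeneous prescribed displacements are supported (used by the
patch test).  The factorization is SuperLU; the relative residual must be
below 1e-8 (it is ~1e-13 in practice).  Geometric nonlinearity is
neglected: springs act along undeformed directions and activation uses the
linearized elongation, matching a linear static analysis with spring
elements.

Tension-only behaviour is resolved by a fixed-point active-set iteration:
solve, deactivate links whose linearized elongation is negative, reactivate
links whose gap re-opens, update secant stiffnesses of elongation-dependent
laws, repeat until the active set and stiffnesses are stable (cap 50
iterations; cycling raises an error naming the oscillating springs).  A
converged solution carries no compressive force in any tension-only link.
The same machinery implements optional compression-only penalty contacts
across fracture faces (off by default: the source model class permits
fragment interpenetration, and the reported negative "gap" values are
exactly such sliding).

Stress is recovered element-wise (exact for linear tets) in the global
anatomical frame, and normal components along anatomical axes are the
headline outputs; von Mises is deliberately not reported, since bone is
brittle and direction-resolved normal stress is the fracture-relevant
quantity.

## Fracture and fixation

The FFP IIc is cut into the intact mesh by duplicating the nodes on three
grid-aligned planes: a vertical trans-alar plane at 0.6 × sacrum half-width
(Denis zone II: lateral to the S1 body, medial to the SI joint) through the
injured-side sacrum, and one plane through each ipsilateral ramus at
mid-span.  The faces are free and untied; element count is unchanged, node
count grows by exactly the number of interface nodes, and each cut is
registered as a face pair with a node-by-node bijection and a
lateral–medial measurement axis.  The injured side defaults to the right,
matching the asymmetry of the reference results (large gaps under
right-sided stance; peak uninjured-side stress under left-sided stance).

Screws are threadless cylinders (7.3 mm diameter; 14 × 2 mm washer at the
entry cortex; titanium) placed by relabeling elements whose centroid lies
within max(radius, 0.8·element size) of the axis — the floor keeps the
construct at least one element wide at coarse resolution.  USI: one screw
from the injured-side ilium to mid-sacrum at S1 level.  BSI: the same
injured-side screw plus a contralateral screw tilted ~8 mm anteriorly over
its length so the two axes are non-collinear.  TSI: one screw spanning the
full transverse width through both SI joints.  Bonding to bone is implicit
(the conforming mesh shares nodes along the bore).  Where a screw crosses
the fracture, the crack-node duplicates are merged back *for implant
elements only*: the shaft becomes continuous elastic titanium through the
crack while the bone faces stay free.  This matters: welding the faces
rigidly at the screw makes all three constructs nearly identical at the
crossing, whereas the elastic shaft lets anchorage length and contralateral
support express themselves mechanically.  Bridged face-node pairs are
flagged and excluded from gap measurement (they are occupied by implant,
not free fracture surface).

## Load cases

Validation: 294 N distributed over the S1 endplate, separately along the
anterior, posterior, superior and inferior directions, with both acetabula
fixed; the reported sacral motion is the mean S1-endplate displacement.

Stance: the 2048 N peak walking force enters as an upward hip reaction at
the stance-side acetabulum — 2048 N at one acetabulum for single-legged
stance, 1024 N at each for bipedal — with the ring held at the upper level
of the sacrum (S1 endplate).  This reading follows the source protocol for
walking loads and its convergence setup; the alternative (force on S1,
stance-side acetabulum fixed) was implemented first and discriminates the
constructs only at the ~1 % level with sign-unstable gap fields, because
the injured hemipelvis is then never loaded *through* the fixation.  With
hip-reaction loading the gaps open (positive), the posterior gap ordering
TSI < BSI < USI emerges robustly, and the uninjured-side stress shielding
by BSI/TSI appears — the mechanics the comparison is about.

## Outcome measures

**Fracture gap** — mean over free face-node pairs of the displacement
difference projected on the lateral–medial axis; positive = opening,
negative = fragments sliding past one another.  The headline value averages
the whole free face.  The fragments rotate about a near-horizontal axis, so
any single horizontal band straddles the sign crossover of the gap field
and its mean is an unstable small difference of large numbers; the
superior- and inferior-band values are therefore reported as detail, not
headline.

**Regional stress** — per sacral quadrant (S1/S2 × left/right), the signed
largest-magnitude element normal stress along the lateral–medial axis,
probing only elements at least 7.5 mm from any fixed/loaded patch node,
tie constraint, or implant node.  The margin is a Saint-Venant exclusion:
constraint corners and bimaterial implant interfaces carry singular fields
that grow under refinement and are not bone stress.  The extraction rule is
recorded in the report manifest.

**Convergence protocol** — uniform bone at E = 6000 MPa, ring fixed at the
upper sacrum, bipedal hip reactions; track peak principal tension and
compression across a descending element-size sequence (default 5 → 2.5 mm
on snap-referenced geometry) and accept when the last refinement changes
both by < 5 %.  "Peak" is the 99.5 % volume-weighted quantile of the
element principal stresses over the probe region: on a faceted phantom the
pointwise maximum rides re-entrant-corner singularities and cannot converge
(observed 20–30 % jumps), while the quantile peak converges (≈1.0 % tension,
≈0.4 % compression between 5 and 2.5 mm).  The default run therefore passes
the gate; the protocol itself — the < 5 % criterion on peak tension and
compression — is unchanged.

## Determinism and sizes

All randomness is the HU noise under one integer seed; meshing, assembly,
factorization and reports are deterministic, and two runs with the same
configuration produce byte-identical CSV reports (hashed into the run
manifest).  Default problem sizes: the 5 mm phantom has ~24k tets / ~16k
free dofs (about 3 s per stance solve including the active-set iterations);
the 2.5 mm convergence mesh has ~192k tets.  The full construct comparison
is 9 tension-only solves.

## Known limitations

Blocky geometry (no anatomical surfaces, no sacral wedge); linear
kinematics and materials; SI joints bonded through a cartilage layer rather
than articulating; single static load cases (no cyclic loading, screw
loosening or fatigue); screw threads and insertion torque not modeled;
absolute gap/stress magnitudes are phantom-specific and smaller than in
anatomical models — only orderings and ratios between constructs are
interpreted.
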