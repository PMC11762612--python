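# pelvifem

Finite-element comparison of percutaneous screw constructs for fragility
fractures of the pelvis (FFP), on a fully synthetic, parametric pelvis
phantom.

Fragility fractures of the pelvic ring (FFP type IIc: a unilateral,
non-displaced vertical fracture of the sacral ala in Denis zone II combined
with ipsilateral superior and inferior pubic ramus fractures) are commonly
fixed percutaneously with sacroiliac screws.  Three constructs compete: a
**unilateral sacroiliac screw (USI)**, **bilateral sacroiliac screws (BSI)**
and a **transsacral screw (TSI)** spanning both sacroiliac joints.
`pelvifem` builds a linear-elastic tetrahedral FE model of the instrumented
pelvic ring and quantifies, for each construct and stance, the fracture-gap
dislocation and the normal-stress distribution in the sacrum — the
quantities that decide whether a construct stabilizes the fracture and
whether it shields the *uninjured* side of the sacrum from an adjacent
fracture.

It is written for biomechanics researchers and FE-methods developers who
want a desk-scale, download-free, fully reproducible version of this class
of study: every input, from geometry to bone quality, is generated by code.

## Model

* **Phantom** — a mirror-symmetric pelvic ring of axis-aligned blocks
  (sacrum with S1/S2 left/right quadrants, sacroiliac cartilage layers,
  innominate blocks, pubic bodies, superior/inferior rami, symphysis),
  voxelized and split into linear tetrahedra (Kuhn decomposition).  A
  synthetic Hounsfield-unit field (cortical shell over osteoporotic
  trabecular interior, Gaussian noise, clamped to 220–2000 HU) rides on the
  elements.
* **Material mapping** — apparent density `ρ_app = 0.00032362·HU + 1`
  (g/cm³, capped at 1.8) and the Dalstra power law `E = 1958.6·ρ_app^2.33`
  (MPa), clamped to the elderly-bone range 200–6530 MPa and binned into a
  1266-material catalog (5 MPa bins).  Cartilage/symphysis: E = 50 MPa,
  ν = 0.45 surrogate.  Screws/washers: titanium (E = 110 GPa).
* **Ligaments** — the eight pelvic ligament groups (ASL, SPSL, LPSL, ISL,
  SS, ST, SP, IP) as tension-only spring bundles; stiffness catalogs after
  Shi, Yao, or elongation-dependent laws after Eichenseer (default:
  Eichenseer for all, constant 500 N/mm pubic ligaments from Shi).
* **Solver** — constant-strain tetrahedra, sparse direct factorization,
  master–slave tie constraints, and a fixed-point active-set iteration that
  deactivates shortened tension springs (and re-activates reopened ones)
  until the admissible set is stable.
* **Fracture & fixation** — the FFP IIc is cut by duplicating interface
  nodes (free, untied crack faces); screws are threadless cylinders bonded
  to bone, made continuous through the crack so that the elastic shaft —
  not a rigid weld — couples the fragments.
* **Loads** — validation: 294 N on the S1 endplate in each anatomical
  direction with both acetabula fixed; stance: the 2048 N peak walking
  force as an upward hip reaction at the stance acetabulum (1024 N per side
  for bipedal) with the upper sacrum held.

## Worked example

```python
import pelvifem as pf

inputs = pf.prepare_inputs()          # phantom + FFP IIc + ligaments
result = pf.compare_constructs(inputs)
print(result.gap_report.round(4))
```

prints the lateral–medial fracture-gap table (mm, positive = the fragments
separate):

```
                                 USI     BSI     TSI
load_case     site
bipedal       posterior_ring  0.1987  0.1798  0.1777
              anterior_ring   0.2822  0.2640  0.2555
right_one_leg posterior_ring  0.3589  0.3312  0.3266
              anterior_ring   0.4931  0.4618  0.4470
left_one_leg  posterior_ring  0.0386  0.0285  0.0288
              anterior_ring   0.0713  0.0662  0.0640
```

Read it as a clinical comparison: the posterior gap shrinks from USI to BSI
to TSI under both bipedal and injured-side (right) stance — the transsacral
screw, anchored in both ilia, clamps the sacral fracture hardest.  The
companion stress table (`result.stress_report`) shows the uninjured-side S1
stress under uninjured-side stance at −10.95 MPa for USI versus −7.3/−7.5
MPa for BSI/TSI: bilateral and transsacral fixation shield the uninjured
ala, i.e. they lower the load that drives adjacent fractures and fracture
progression.

The `examples/` directory walks through each capability (phantom anatomy,
material mapping, validation loads, construct comparison, mesh
convergence); each script prints the numbers it computes and a line on what
they mean.  A thin CLI mirrors the pipeline stages:

```bash
pelvifem phantom --out phantom.msh
pelvifem materials --out materials.csv
pelvifem validate-loads
pelvifem compare --out-dir results/
pelvifem convergence --sizes 5.0,2.5
```

## Limitations

The phantom preserves the load-path topology of the pelvic ring, not its
anatomy; absolute displacements and stresses are phantom-specific and the
comparison between constructs is meaningful qualitatively (orderings,
ratios), not as patient-level predictions.  See `docs/methods.md` for the
model assumptions, parameter choices and numerical decisions.
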