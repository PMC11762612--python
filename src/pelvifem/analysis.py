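"""Load cases, outcome measures and the construct-comparison study.

Two load protocols are implemented.  Validation: a 294 N probe force applied
to the first sacral endplate along each anatomical direction with both
acetabula fixed.  Stance: the peak walking force of 2048 N enters the ring
as an upward hip reaction at the stance-side acetabulum (half of it at each
acetabulum for bipedal stance) with the ring held at the upper level of the
sacrum (S1 endplate), so the injured hemipelvis loads the fixation construct
the way single-legged weight bearing does.

Outcome measures mirror the clinical tables: signed fracture-gap distance in
the lateral-medial direction at the posterior ring (superior and inferior
probe bands) and at the superior pubic ramus (positive = opening, negative =
fragments sliding past one another), and the signed extremum of the
lateral-medial normal stress in the four sacral quadrants S1/S2 left/right.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fem
from .ligaments import make_springs
from .materials import MaterialField, assign_materials, uniform_materials
from .mesh import TetMesh
from .phantom import (PhantomParams, build_phantom, cut_ffp2c, make_construct,
                      place_screws)

VALIDATION_FORCE = 294.0        # N
WALKING_FORCE = 2048.0          # N, single-legged stance peak
STANCE_CASES = ("bipedal", "right_one_leg", "left_one_leg")
VALIDATION_CASES = ("validation_anterior", "validation_posterior",
                    "validation_superior", "validation_inferior")

_DIRECTIONS = {
    "validation_anterior": np.array([0.0, 1.0, 0.0]),
    "validation_posterior": np.array([0.0, -1.0, 0.0]),
    "validation_superior": np.array([0.0, 0.0, 1.0]),
    "validation_inferior": np.array([0.0, 0.0, -1.0]),
}


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class LoadCase:
    """Named scenario: patch forces plus the fixed patches."""

    name: str
    loads: tuple                   # ((patch_name, total force vector N), ...)
    fixed_patches: tuple

    @property
    def magnitude(self) -> float:
        """Total applied force magnitude, N."""
        return float(sum(np.linalg.norm(f) for _, f in self.loads))


_UP = np.array([0.0, 0.0, 1.0])


def make_load_case(name: str) -> LoadCase:
    """Build one of the named validation or stance load cases."""
    if name in _DIRECTIONS:
        return LoadCase(
            name=name,
            loads=(("s1_endplate", VALIDATION_FORCE * _DIRECTIONS[name]),),
            fixed_patches=("acetabulum_left", "acetabulum_right"))
    if name == "bipedal":
        half = WALKING_FORCE / 2.0
        return LoadCase(name, (("acetabulum_left", half * _UP),
                               ("acetabulum_right", half * _UP)),
                        ("s1_endplate",))
    if name == "right_one_leg":
        return LoadCase(name, (("acetabulum_right", WALKING_FORCE * _UP),),
                        ("s1_endplate",))
    if name == "left_one_leg":
        return LoadCase(name, (("acetabulum_left", WALKING_FORCE * _UP),),
                        ("s1_endplate",))
    raise AnalysisError(f"unknown load case '{name}'")


# ---------------------------------------------------------------------------
# outcome measures
# ---------------------------------------------------------------------------

@dataclass
class GapMeasurement:
    headline: float                # mm, mean over the whole free face
    superior_band: float | None = None
    inferior_band: float | None = None


def fracture_gap(solution: fem.Solution, mesh: TetMesh, pair_name: str,
                 direction=None, band_split: float | None = None) -> GapMeasurement:
    """Signed fracture-gap distance for one face pair.

    Mean over free (unbridged) node pairs of the displacement difference
    projected on the measurement axis.  Positive = the lateral fragment
    separates from the medial one; negative = overlap (fragments sliding
    past each other).  The headline value averages the whole free face (the
    fragments rotate, so a single band straddles the sign crossover of the
    gap field and its mean is a small difference of large numbers); if
    ``band_split`` (a z coordinate) is given, superior and inferior probe
    bands are additionally reported.
    """
    try:
        pair = mesh.fracture_face_pairs[pair_name]
    except KeyError:
        raise AnalysisError(f"mesh has no fracture face pair '{pair_name}'") from None
    axis = np.asarray(direction, dtype=float) if direction is not None else pair.axis
    axis = axis / np.linalg.norm(axis)
    free = ~pair.bridged
    if not free.any():
        raise AnalysisError(f"face pair '{pair_name}' has no free node pairs")
    rel = solution.u[pair.lateral[free]] - solution.u[pair.medial[free]]
    proj = rel @ axis
    z = mesh.nodes[pair.medial[free], 2]
    g = float(proj.mean())
    if band_split is None:
        return GapMeasurement(headline=g)
    sup = proj[z >= band_split]
    inf = proj[z < band_split]
    sup_g = float(sup.mean()) if sup.size else float("nan")
    inf_g = float(inf.mean()) if inf.size else float("nan")
    return GapMeasurement(headline=g, superior_band=sup_g, inferior_band=inf_g)


REGION_QUADRANTS = {
    "S1_right": "sacrum_S1_right", "S1_left": "sacrum_S1_left",
    "S2_right": "sacrum_S2_right", "S2_left": "sacrum_S2_left",
}


#: Saint-Venant exclusion margin around constraint/load/implant nodes (mm).
#: Stress probes ignore material closer than this to boundary-condition
#: machinery, whose corner singularities do not converge under refinement.
EXCLUSION_MARGIN_MM = 7.5


def _excluded_nodes(mesh: TetMesh, system: fem.AssembledSystem) -> np.ndarray:
    """Nodes belonging to constraint or load machinery (stress risers)."""
    excluded = [system.fixed_nodes]
    for patch in system.loaded_patches:
        excluded.append(mesh.patch(patch))
    if mesh.tie_pairs.size:
        excluded.append(mesh.tie_pairs.ravel())
    implant = np.array([r.startswith(("screw", "washer"))
                        for r in mesh.element_region])
    if implant.any():
        excluded.append(np.unique(mesh.tets[implant]))
    return np.unique(np.concatenate(excluded))


def _probe_mask(mesh: TetMesh, system: fem.AssembledSystem,
                margin: float = EXCLUSION_MARGIN_MM) -> np.ndarray:
    """Elements whose centroid is at least ``margin`` from every excluded
    node (a fixed physical distance, so the probe region does not depend on
    mesh resolution)."""
    from scipy.spatial import cKDTree
    bad = _excluded_nodes(mesh, system)
    if bad.size == 0:
        return np.ones(mesh.n_elements, dtype=bool)
    tree = cKDTree(mesh.nodes[bad])
    d, _ = tree.query(mesh.element_centroids(), k=1)
    return d >= margin


def regional_stress(solution: fem.Solution, mesh: TetMesh,
                    system: fem.AssembledSystem, region: str,
                    direction=(1.0, 0.0, 0.0)) -> float:
    """Signed extremum of the normal stress along ``direction`` in a region.

    The largest-magnitude value with its sign preserved (negative =
    compression), over region elements at least ``EXCLUSION_MARGIN_MM`` away
    from tie constraints, implant interfaces and load/BC patches, which
    carry constraint singularities rather than bone stress.
    """
    label = REGION_QUADRANTS.get(region, region)
    mask = mesh.element_region == label
    if not mask.any():
        raise AnalysisError(f"region '{region}' is empty")
    mask = mask & _probe_mask(mesh, system)
    if not mask.any():
        raise AnalysisError(f"region '{region}' empty after constraint exclusions")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    T = fem.element_stress(solution, system)[mask]
    normal = np.einsum("i,mij,j->m", d, T, d)
    return float(normal[np.argmax(np.abs(normal))])


# ---------------------------------------------------------------------------
# pipeline building blocks
# ---------------------------------------------------------------------------

@dataclass
class PipelineInputs:
    """Everything shared across constructs: fractured phantom + materials +
    springs (constructs differ only in screws)."""

    params: PhantomParams
    intact: TetMesh
    fractured: TetMesh
    hu: np.ndarray
    materials_intact: MaterialField
    springs: list
    injured_side: str


def prepare_inputs(params: PhantomParams | None = None,
                   injured_side: str = "right",
                   ligament_source: str = "eichenseer+shi",
                   breakpoint_strain: float = 0.10) -> PipelineInputs:
    from .ligaments import StiffnessCatalog
    params = params or PhantomParams()
    intact, hu = build_phantom(params)
    catalog = StiffnessCatalog.from_source(ligament_source, breakpoint_strain)
    springs = make_springs(intact, catalog)
    fractured = cut_ffp2c(intact, injured_side=injured_side)
    materials = assign_materials(intact, hu)
    return PipelineInputs(params=params, intact=intact, fractured=fractured,
                          hu=hu, materials_intact=materials, springs=springs,
                          injured_side=injured_side)


def solve_case(mesh: TetMesh, materials, springs, case: LoadCase,
               fracture_contact: bool = False, contact_k: float = 1e4):
    """Assemble and solve one load case; returns (system, solution)."""
    contacts = fem.make_contacts(mesh, contact_k) if fracture_contact else ()
    system = fem.assemble(mesh, materials, springs=springs,
                          fixed_patches=case.fixed_patches,
                          patch_loads=list(case.loads),
                          contacts=contacts)
    solution = fem.solve_tension_only(system)
    return system, solution


# ---------------------------------------------------------------------------
# construct comparison
# ---------------------------------------------------------------------------

GAP_SITES = ("posterior_ring", "anterior_ring")
STRESS_REGIONS = ("S1_right", "S1_left", "S2_right", "S2_left")


@dataclass
class ComparisonResult:
    """Gap and stress tables (load case rows x construct columns)."""

    gap_report: pd.DataFrame
    stress_report: pd.DataFrame
    details: dict
    manifest: dict

    def gap_csv(self) -> str:
        return self.gap_report.to_csv(float_format="%.6f")

    def stress_csv(self) -> str:
        return self.stress_report.to_csv(float_format="%.6f")


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def compare_constructs(inputs: PipelineInputs,
                       variants=("USI", "BSI", "TSI"),
                       load_cases=STANCE_CASES,
                       fracture_contact: bool = False) -> ComparisonResult:
    """Run every construct under every stance case on the shared phantom.

    Returns gap and stress reports laid out like the clinical comparison
    tables, plus per-run details (band-resolved gaps, spring forces) and a
    deterministic run manifest.
    """
    band_split = inputs.intact.metadata["geometry"]["s1_mid_mm"]
    gap_rows, stress_rows, details = {}, {}, {}
    for variant in variants:
        construct = make_construct(variant, inputs.fractured,
                                   injured_side=inputs.injured_side)
        mesh = place_screws(inputs.fractured, construct)
        materials = assign_materials(mesh, inputs.hu)
        for case_name in load_cases:
            case = make_load_case(case_name)
            system, sol = solve_case(mesh, materials, inputs.springs, case,
                                     fracture_contact=fracture_contact)
            post = fracture_gap(sol, mesh, "posterior_ring", band_split=band_split)
            ant = fracture_gap(sol, mesh, "anterior_superior_ramus")
            gap_rows[(case_name, "posterior_ring", variant)] = post.headline
            gap_rows[(case_name, "anterior_ring", variant)] = ant.headline
            for region in STRESS_REGIONS:
                stress_rows[(case_name, region, variant)] = regional_stress(
                    sol, mesh, system, region)
            details[(case_name, variant)] = {
                "posterior_superior_band": post.superior_band,
                "posterior_inferior_band": post.inferior_band,
                "anterior_superior_ramus": ant.headline,
                "anterior_inferior_ramus": fracture_gap(
                    sol, mesh, "anterior_inferior_ramus").headline,
                "spring_forces": sol.spring_forces,
                "iterations": sol.n_iterations,
            }

    gap_index = pd.MultiIndex.from_product(
        [list(load_cases), list(GAP_SITES)], names=["load_case", "site"])
    gap = pd.DataFrame(index=gap_index, columns=list(variants), dtype=float)
    for (case_name, site, variant), val in gap_rows.items():
        gap.loc[(case_name, site), variant] = val
    stress_index = pd.MultiIndex.from_product(
        [list(load_cases), list(STRESS_REGIONS)], names=["load_case", "region"])
    stress = pd.DataFrame(index=stress_index, columns=list(variants), dtype=float)
    for (case_name, region, variant), val in stress_rows.items():
        stress.loc[(case_name, region), variant] = val

    manifest = {
        "seed": inputs.params.rng_seed,
        "injured_side": inputs.injured_side,
        "variants": list(variants),
        "load_cases": list(load_cases),
        "n_nodes": inputs.fractured.n_nodes,
        "n_elements": inputs.fractured.n_elements,
        "edge_length": inputs.params.target_edge_length,
        "config_hash": _config_hash({
            "params": {k: getattr(inputs.params, k) for k in vars(inputs.params)},
            "variants": list(variants), "cases": list(load_cases),
            "fracture_contact": fracture_contact,
        }),
        "stress_extraction": ("signed max-|.| of lateral-medial normal stress per "
                              "region, excluding elements touching ties, implant "
                              "interfaces and load/BC patches"),
    }
    return ComparisonResult(gap_report=gap, stress_report=stress,
                            details=details, manifest=manifest)


# ---------------------------------------------------------------------------
# validation-load protocol
# ---------------------------------------------------------------------------

def run_validation_loads(inputs: PipelineInputs) -> pd.DataFrame:
    """294 N probe loads on the intact phantom; reports sacral motion.

    Mean displacement of the S1 endplate (mm) along the load direction and
    in magnitude, per direction, with both acetabula fixed.
    """
    rows = []
    ids = inputs.intact.patch("s1_endplate")
    for name in VALIDATION_CASES:
        case = make_load_case(name)
        _, sol = solve_case(inputs.intact, inputs.materials_intact,
                            inputs.springs, case)
        u = sol.u[ids]
        d = _DIRECTIONS[name]
        rows.append({"case": name,
                     "along_load_mm": float((u @ d).mean()),
                     "magnitude_mm": float(np.linalg.norm(u, axis=1).mean())})
    return pd.DataFrame(rows).set_index("case")


# ---------------------------------------------------------------------------
# mesh convergence
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceResult:
    """Refinement sweep of the peak principal stresses.

    ``rows``: per edge length the max principal tension, max compression
    (most negative principal stress) and relative change vs the previous
    size; ``accepted`` when the last change in both is below ``threshold``.
    """

    rows: pd.DataFrame
    accepted: bool
    threshold: float = 0.05


#: Volume quantile defining the robust peak stress: on a faceted phantom the
#: pointwise maximum rides corner singularities and cannot converge under
#: refinement, so "maximum tension/compression" is evaluated as the 99.5%
#: volume-weighted quantile of the element principal stresses.
PEAK_STRESS_QUANTILE = 0.995


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w) / w.sum()
    return float(v[min(np.searchsorted(cw, q), v.size - 1)])


def _principal_extrema(solution: fem.Solution, mesh: TetMesh,
                       system: fem.AssembledSystem):
    """Robust peak principal tension and compression over the probe region."""
    bone = np.array([not r.startswith(("cartilage", "symphysis", "screw", "washer"))
                     for r in mesh.element_region])
    mask = bone & _probe_mask(mesh, system)
    T = fem.element_stress(solution, system)[mask]
    eig = np.linalg.eigvalsh(T)
    vol = mesh.volumes()[mask]
    t_peak = _weighted_quantile(eig[:, 2], vol, PEAK_STRESS_QUANTILE)
    c_peak = _weighted_quantile(eig[:, 0], vol, 1.0 - PEAK_STRESS_QUANTILE)
    return t_peak, c_peak


def convergence_study(params: PhantomParams | None = None,
                      edge_lengths=(5.0, 2.5),
                      E_bone: float = 6000.0,
                      threshold: float = 0.05) -> ConvergenceResult:
    """Mesh-refinement protocol at uniform bone modulus.

    The ring is fixed at the upper level of the sacrum (S1 endplate) and a
    bipedal stance is applied as upward hip reactions of half the walking
    force at each acetabulum.  Block boundaries are snapped to the coarsest
    grid so every size discretizes the same geometry (each finer size must
    divide the coarsest).  Accepted when the last refinement changes the
    peak tension and compression by less than 5%.
    """
    params = params or PhantomParams()
    edge_lengths = list(edge_lengths)
    if len(edge_lengths) < 2:
        raise AnalysisError("convergence needs at least two edge lengths")
    if any(b >= a for a, b in zip(edge_lengths, edge_lengths[1:])):
        raise AnalysisError("edge lengths must be strictly descending")

    import dataclasses
    snap_ref = params.snap_reference or edge_lengths[0]
    records = []
    prev = None
    for h in edge_lengths:
        p = dataclasses.replace(params, target_edge_length=h,
                                snap_reference=snap_ref)
        try:
            mesh, _ = build_phantom(p)
        except Exception as exc:   # meshing failure: record, skip
            import warnings
            warnings.warn(f"meshing failed at {h} mm ({exc}); size skipped",
                          stacklevel=2)
            continue
        materials = uniform_materials(mesh, E_bone=E_bone)
        half_up = np.array([0.0, 0.0, WALKING_FORCE / 2.0])
        system = fem.assemble(
            mesh, materials, fixed_patches=("s1_endplate",),
            patch_loads=[("acetabulum_left", half_up),
                         ("acetabulum_right", half_up)])
        sol = fem.solve_tension_only(system)
        t_max, c_min = _principal_extrema(sol, mesh, system)
        rec = {"edge_length_mm": h, "max_tension_MPa": t_max,
               "max_compression_MPa": c_min,
               "n_elements": mesh.n_elements}
        if prev is not None:
            rec["tension_change"] = abs(t_max - prev[0]) / abs(prev[0])
            rec["compression_change"] = abs(c_min - prev[1]) / abs(prev[1])
        else:
            rec["tension_change"] = np.nan
            rec["compression_change"] = np.nan
        records.append(rec)
        prev = (t_max, c_min)

    rows = pd.DataFrame(records)
    if len(rows) < 2:
        raise AnalysisError("convergence needs at least two successful sizes")
    last = rows.iloc[-1]
    accepted = bool(last["tension_change"] < threshold
                    and last["compression_change"] < threshold)
    return ConvergenceResult(rows=rows, accepted=accepted, threshold=threshold)
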