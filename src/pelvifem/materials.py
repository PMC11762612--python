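"""Hounsfield-unit to bone-material mapping.

CT attenuation (HU) is converted to apparent density with a linear
calibration and to Young's modulus with the Dalstra power law for pelvic
trabecular bone:

    rho_app = a * HU + b          (g/cm^3, capped at rho_cap)
    E       = c * rho_app ** p    (MPa, clamped to [E_min, E_max])

The clamped modulus range [200, 6530] MPa represents elderly (osteoporotic)
bone.  Moduli are snapped to the centers of uniform bins so the solver sees a
finite material catalog, mirroring how CT-based FE pipelines assign binned
materials per element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TetMesh
from .phantom import BONE_REGIONS


class MaterialError(ValueError):
    pass


@dataclass(frozen=True)
class MappingConstants:
    """Calibration and binning constants of the HU -> E mapping."""

    a: float = 0.00032362      # g/cm^3 per HU
    b: float = 1.0             # g/cm^3 intercept
    c: float = 1958.6          # MPa
    p: float = 2.33            # Dalstra exponent
    hu_min: float = 220.0
    hu_max: float = 2000.0
    E_min: float = 200.0       # MPa
    E_max: float = 6530.0      # MPa
    bin_width: float = 5.0     # MPa; 5 MPa over [200, 6530] gives 1266 materials
    rho_cap: float = 1.8       # g/cm^3

    def __post_init__(self):
        if not (self.a > 0 and self.c > 0 and self.p > 0):
            raise MaterialError("mapping constants a, c, p must be positive")
        if not self.E_min < self.E_max:
            raise MaterialError("E_min must be below E_max")
        if not self.bin_width > 0:
            raise MaterialError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return int(np.ceil((self.E_max - self.E_min) / self.bin_width))


@dataclass
class MaterialField:
    """Per-element material data covering every element of a mesh.

    Bone elements carry the binned Dalstra modulus; cartilage/symphysis and
    implant elements carry their configured constants and ``bin_id = -1``.
    """

    hu: np.ndarray
    rho_app: np.ndarray
    E: np.ndarray
    nu: np.ndarray
    bin_id: np.ndarray
    n_bins_used: int = 0

    def validate(self, constants: MappingConstants) -> None:
        bone = self.bin_id >= 0
        if bone.any():
            E = self.E[bone]
            if E.min() < constants.E_min - 1e-9 or E.max() > constants.E_max + 1e-9:
                raise MaterialError("bone modulus outside the clamped range")
        if np.any((self.nu <= 0) | (self.nu >= 0.5)):
            raise MaterialError("Poisson ratio must lie in (0, 0.5)")


def hu_to_density(hu, constants: MappingConstants = MappingConstants()):
    """Apparent density from HU (linear law, capped at ``rho_cap``)."""
    hu = np.asarray(hu, dtype=float)
    rho = np.minimum(constants.a * hu + constants.b, constants.rho_cap)
    return rho if rho.ndim else float(rho)


def density_to_modulus(rho_app, constants: MappingConstants = MappingConstants()):
    """Young's modulus from apparent density (power law, clamped)."""
    rho = np.asarray(rho_app, dtype=float)
    if np.any(rho <= 0):
        raise MaterialError("apparent density must be positive")
    E = np.clip(constants.c * rho ** constants.p, constants.E_min, constants.E_max)
    return E if E.ndim else float(E)


def modulus_bins(constants: MappingConstants):
    """Bin centers of the discrete material catalog."""
    n = constants.n_bins
    edges = constants.E_min + constants.bin_width * np.arange(n + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def assign_materials(mesh: TetMesh, hu_table: np.ndarray,
                     constants: MappingConstants = MappingConstants(),
                     nu_bone: float = 0.3,
                     soft_E: float = 50.0, soft_nu: float = 0.45,
                     implant_E: float | None = None,
                     implant_nu: float | None = None) -> MaterialField:
    """Per-element material field for a (possibly instrumented) phantom mesh.

    Bone regions get the binned Dalstra modulus from their HU; cartilage and
    symphysis get the linear-elastic soft-tissue surrogate ``(soft_E,
    soft_nu)``; screw/washer regions get the implant material (default from
    mesh metadata, titanium alloy).  Deterministic and order-independent.
    """
    hu = np.asarray(hu_table, dtype=float)
    if hu.shape[0] != mesh.n_elements:
        raise MaterialError(
            f"HU table covers {hu.shape[0]} elements, mesh has {mesh.n_elements}")
    bone = mesh.region_mask(*BONE_REGIONS)
    missing = bone & ~np.isfinite(hu)
    if missing.any():
        ids = np.flatnonzero(missing)
        raise MaterialError(
            f"{ids.size} bone elements lack HU values, first ids {ids[:10].tolist()}")

    if implant_E is None:
        implant_E = mesh.metadata.get("implant_material", {}).get("E", 110_000.0)
    if implant_nu is None:
        implant_nu = mesh.metadata.get("implant_material", {}).get("nu", 0.3)

    hu_c = np.clip(hu, constants.hu_min, constants.hu_max)
    rho = hu_to_density(hu_c, constants)
    E_exact = np.where(bone, density_to_modulus(np.maximum(rho, 1e-12), constants), 0.0)

    centers = modulus_bins(constants)
    idx = np.clip(((E_exact - constants.E_min) / constants.bin_width).astype(int),
                  0, constants.n_bins - 1)
    E = np.where(bone, centers[idx], 0.0)
    bin_id = np.where(bone, idx, -1)
    nu = np.where(bone, nu_bone, 0.0)

    implant = np.array([r.startswith(("screw", "washer"))
                        for r in mesh.element_region])
    soft = ~bone & ~implant
    E[soft], nu[soft] = soft_E, soft_nu
    E[implant], nu[implant] = implant_E, implant_nu

    field = MaterialField(hu=hu, rho_app=rho, E=E, nu=nu, bin_id=bin_id,
                          n_bins_used=int(len(np.unique(bin_id[bone])))
                          if bone.any() else 0)
    field.validate(constants)
    return field


def uniform_materials(mesh: TetMesh, E_bone: float = 6000.0, nu_bone: float = 0.3,
                      soft_E: float = 50.0, soft_nu: float = 0.45) -> MaterialField:
    """Homogeneous bone material (used by the mesh-convergence protocol)."""
    bone = mesh.region_mask(*BONE_REGIONS)
    E = np.where(bone, E_bone, soft_E)
    nu = np.where(bone, nu_bone, soft_nu)
    zeros = np.zeros(mesh.n_elements)
    return MaterialField(hu=zeros, rho_app=zeros, E=E, nu=nu,
                         bin_id=np.where(bone, 0, -1), n_bins_used=1)
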