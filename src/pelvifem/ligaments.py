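"""Pelvic ligaments as tension-only spring bundles.

Eight ligament groups close the pelvic ring around the bone/cartilage path:
anterior sacroiliac (ASL), short and long posterior sacroiliac (SPSL, LPSL),
interosseous (ISL), sacrospinous (SS), sacrotuberous (ST) — all bilateral —
and the midline superior and inferior pubic ligaments (SP, IP).  Each group
is a small bundle of parallel axial springs between attachment patches, with
the group stiffness split evenly over the bundle, carrying force only in
elongation.

Three stiffness catalogs are provided (constant stiffnesses after Shi et al.
and Yao et al., and elongation-dependent ranges after Eichenseer et al.); the
default combines the Eichenseer laws with constant pubic-ligament values from
Shi.  Elongation-dependent laws interpolate the secant stiffness linearly
from the low value at 0% strain to the high value at a configurable
breakpoint strain (default 10%), constant beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TetMesh

LIGAMENT_NAMES = ("ASL", "SPSL", "LPSL", "ISL", "SS", "ST", "SP", "IP")
BILATERAL = ("ASL", "SPSL", "LPSL", "ISL", "SS", "ST")
MIDLINE = ("SP", "IP")


class LigamentError(ValueError):
    pass


@dataclass(frozen=True)
class ConstantStiffness:
    k: float                       # N/mm

    def stiffness(self, strain: float) -> float:
        return self.k


@dataclass(frozen=True)
class ElongationStiffness:
    """Secant stiffness interpolated over percentage elongation."""

    k_low: float                   # N/mm at 0% strain
    k_high: float                  # N/mm at/beyond the breakpoint
    breakpoint: float = 0.10       # strain at which k_high is reached

    def stiffness(self, strain: float) -> float:
        s = max(float(strain), 0.0)
        if s >= self.breakpoint:
            return self.k_high
        return self.k_low + (self.k_high - self.k_low) * s / self.breakpoint


_SHI = {"ASL": 700.0, "SPSL": 400.0, "LPSL": 1000.0, "ISL": 2800.0,
        "SS": 1400.0, "ST": 1500.0, "SP": 500.0, "IP": 500.0}
_YAO = {"ASL": 18.9, "SPSL": 21.0, "LPSL": 21.0, "ISL": 22.4,
        "SS": 12.6, "ST": 22.5, "SP": 12.0, "IP": 12.0}
_EICHENSEER = {"ASL": (39.0, 103.0), "SPSL": (200.0, 525.0), "LPSL": (29.0, 75.0),
               "ISL": (13.0, 34.0), "SS": (26.0, 68.0), "ST": (17.0, 45.0)}


@dataclass(frozen=True)
class StiffnessCatalog:
    """Named stiffness laws for all eight ligament groups."""

    source: str
    table: dict

    @staticmethod
    def from_source(source: str = "eichenseer+shi",
                    breakpoint: float = 0.10) -> "StiffnessCatalog":
        if source == "shi":
            table = {n: ConstantStiffness(_SHI[n]) for n in LIGAMENT_NAMES}
        elif source == "yao":
            table = {n: ConstantStiffness(_YAO[n]) for n in LIGAMENT_NAMES}
        elif source == "eichenseer+shi":
            table = {n: ElongationStiffness(*_EICHENSEER[n], breakpoint=breakpoint)
                     for n in _EICHENSEER}
            table["SP"] = ConstantStiffness(_SHI["SP"])
            table["IP"] = ConstantStiffness(_SHI["IP"])
        else:
            raise LigamentError(f"unknown stiffness source '{source}'")
        missing = set(LIGAMENT_NAMES) - set(table)
        if missing:
            raise LigamentError(f"catalog misses ligaments {sorted(missing)}")
        return StiffnessCatalog(source=source, table=table)


DEFAULT_CATALOG = StiffnessCatalog.from_source()


@dataclass
class LigamentSpring:
    """A ligament group: parallel sub-springs sharing one stiffness law.

    ``node_pairs[i]`` connects two mesh nodes; the law's stiffness is the
    stiffness of the whole group and is split evenly across the bundle.
    """

    name: str                          # e.g. "ISL_left" or "SP"
    node_pairs: np.ndarray             # (n, 2) int
    rest_lengths: np.ndarray           # (n,) mm
    law: object
    tension_only: bool = True
    mode: str = "tension"              # tension | compression | both

    def __post_init__(self):
        self.node_pairs = np.asarray(self.node_pairs, dtype=np.int64).reshape(-1, 2)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float)
        if np.any(self.rest_lengths <= 0):
            raise LigamentError(f"spring '{self.name}' has a zero rest length")
        if not self.tension_only:
            self.mode = "both"

    @property
    def n_sub(self) -> int:
        return int(self.node_pairs.shape[0])

    def sub_stiffness(self, strain: float = 0.0) -> float:
        return self.law.stiffness(strain) / self.n_sub


def spring_force(spring: LigamentSpring, current_length: float) -> float:
    """Total axial force of a group at a uniform current length (N, tension+).

    Elongation-dependent laws use the secant stiffness at the current strain;
    tension-only springs carry no force at or below the rest length.
    """
    if current_length <= 0:
        raise LigamentError("current_length must be positive")
    rest = float(np.mean(spring.rest_lengths))
    delta = current_length - rest
    if spring.mode == "tension" and delta <= 0:
        return 0.0
    if spring.mode == "compression" and delta >= 0:
        return 0.0
    strain = max(delta, 0.0) / rest
    return spring.law.stiffness(strain) * delta


_PATCH_MAP = {
    "ASL": ("asl_sacrum", "asl_ilium"),
    "SPSL": ("spsl_sacrum", "spsl_ilium"),
    "LPSL": ("lpsl_sacrum", "lpsl_ilium"),
    "ISL": ("isl_sacrum", "isl_ilium"),
    "SS": ("ss_sacrum", "ss_ilium"),
    "ST": ("st_sacrum", "st_ilium"),
}


def _bundle_pairs(mesh: TetMesh, patch_a: str, patch_b: str, n: int):
    """Deterministic bundle: n spread-out nodes of A paired with their
    nearest nodes in B."""
    a = mesh.patch(patch_a)
    b = mesh.patch(patch_b)
    # |x| keeps the selection mirror-symmetric between left and right sides
    order = np.lexsort((np.abs(mesh.nodes[a, 0]), mesh.nodes[a, 1],
                        mesh.nodes[a, 2]))
    a = a[order]
    pick = a[np.unique(np.linspace(0, a.size - 1, min(n, a.size)).round().astype(int))]
    pairs, rests = [], []
    for na in pick:
        d = np.linalg.norm(mesh.nodes[b] - mesh.nodes[na], axis=1)
        nb = b[int(np.argmin(d))]
        rest = float(np.linalg.norm(mesh.nodes[nb] - mesh.nodes[na]))
        if rest <= 0:
            raise LigamentError(
                f"zero-length ligament between patches {patch_a}/{patch_b}")
        pairs.append((na, nb))
        rests.append(rest)
    return np.asarray(pairs, dtype=np.int64), np.asarray(rests)


def make_springs(mesh: TetMesh, catalog: StiffnessCatalog = DEFAULT_CATALOG,
                 bundle_size: int = 3) -> list:
    """Create the full ligament set for a phantom mesh.

    One bundle per side for the six bilateral groups and single midline
    bundles for SP and IP.  Rest lengths are the undeformed attachment
    distances.  Raises naming the ligament if an attachment patch is missing.
    """
    springs = []
    for lig in BILATERAL:
        pa, pb = _PATCH_MAP[lig]
        for side in ("left", "right"):
            names = (f"{pa}_{side}", f"{pb}_{side}")
            for patch in names:
                if patch not in mesh.surface_patches:
                    raise LigamentError(
                        f"ligament {lig}_{side}: attachment patch '{patch}' missing")
            pairs, rests = _bundle_pairs(mesh, *names, n=bundle_size)
            springs.append(LigamentSpring(
                name=f"{lig}_{side}", node_pairs=pairs, rest_lengths=rests,
                law=catalog.table[lig]))
    for lig in MIDLINE:
        names = (f"{lig.lower()}_pubis_left", f"{lig.lower()}_pubis_right")
        for patch in names:
            if patch not in mesh.surface_patches:
                raise LigamentError(
                    f"ligament {lig}: attachment patch '{patch}' missing")
        pairs, rests = _bundle_pairs(mesh, *names, n=max(2, bundle_size - 1))
        springs.append(LigamentSpring(
            name=lig, node_pairs=pairs, rest_lengths=rests,
            law=catalog.table[lig]))
    return springs
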