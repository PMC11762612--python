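"""Parametric synthetic pelvis phantom.

A simplified, mirror-symmetric two-ring pelvis built from axis-aligned blocks:
a sacrum flanked by sacroiliac cartilage layers and two innominate (ilium)
blocks posteriorly, and superior/inferior pubic rami joined through pubic
bodies and a midline symphysis anteriorly.  The phantom preserves the
mechanically relevant topology of the pelvic ring — two load paths from the
first sacral body to the acetabula — without claiming anatomical surface
accuracy.

The module also cuts the FFP IIc fracture pattern (a vertical trans-alar
fracture of the sacrum in Denis zone II plus ipsilateral superior and
inferior pubic ramus fractures) and places the three screw constructs
compared by the analysis: unilateral sacroiliac (USI), bilateral sacroiliac
(BSI) and transsacral (TSI) screws, each with an entry washer.  Screws are
modeled without threads as relabeled element volumes bonded to the bone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh import FacePair, TetMesh, nodes_in_box, tets_from_voxels

HU_MIN = 220.0
HU_MAX = 2000.0

#: Region labels present in every intact phantom.
INTACT_REGIONS = (
    "sacrum_S1_left", "sacrum_S1_right", "sacrum_S2_left", "sacrum_S2_right",
    "ilium_left", "ilium_right",
    "ramus_sup_left", "ramus_sup_right", "ramus_inf_left", "ramus_inf_right",
    "pubic_body_left", "pubic_body_right",
    "cartilage_si_left", "cartilage_si_right", "symphysis",
)

#: Regions treated as bone for material mapping.
BONE_REGIONS = tuple(r for r in INTACT_REGIONS
                     if not r.startswith("cartilage") and r != "symphysis")

SOFT_REGIONS = ("cartilage_si_left", "cartilage_si_right", "symphysis")


class PhantomError(ValueError):
    """Raised when phantom construction cannot satisfy its contract."""


class FixationError(ValueError):
    """Raised when a screw construct fails its placement contract."""


@dataclass
class PhantomParams:
    """Geometry, bone-quality and meshing parameters of the phantom (mm / HU).

    Defaults are sized to an adult female pelvis at desk scale and an
    osteoporotic HU distribution: a low trabecular plateau with a denser
    cortical shell, clamped to the segmentation window [220, 2000] HU.
    """

    sacrum_width: float = 50.0        # full transverse width
    sacrum_height: float = 60.0       # inferosuperior (S2 bottom .. S1 endplate)
    sacrum_depth: float = 30.0        # anteroposterior
    ilium_width: float = 30.0         # lateral extent of each innominate block
    ilium_depth: float = 70.0
    ilium_height: float = 90.0
    ilium_posterior_overhang: float = 10.0   # how far the ilium reaches behind y=0
    ilium_inferior_drop: float = 20.0        # how far it reaches below z=0
    cartilage_thickness: float = 3.0  # SI joint layers; also symphysis half-width
    pubic_body_width: float = 7.0
    ramus_section: float = 12.0       # square cross-section of each pubic ramus
    ramus_y_offset: float = 14.0      # anterior gap between sacrum and ramus band
    hu_cortical: float = 1800.0
    hu_trabecular: float = 300.0
    hu_noise_sd: float = 100.0
    rng_seed: int = 0
    target_edge_length: float = 5.0   # tet size, converged range [1, 5] mm
    #: Block boundaries snap to this grid instead of the element grid, so a
    #: refinement sweep (e.g. 5 -> 2.5 mm) discretizes the *same* geometry.
    #: Each target_edge_length must then divide snap_reference.
    snap_reference: float | None = None

    def validate(self) -> None:
        dims = {
            "sacrum_width": self.sacrum_width,
            "sacrum_height": self.sacrum_height,
            "sacrum_depth": self.sacrum_depth,
            "ilium_width": self.ilium_width,
            "ilium_depth": self.ilium_depth,
            "ilium_height": self.ilium_height,
            "cartilage_thickness": self.cartilage_thickness,
            "pubic_body_width": self.pubic_body_width,
            "ramus_section": self.ramus_section,
            "ramus_y_offset": self.ramus_y_offset,
        }
        for name, val in dims.items():
            if not val > 0:
                raise PhantomError(f"dimension {name} must be > 0, got {val}")
        if not (1.0 <= self.target_edge_length <= 5.0):
            raise PhantomError(
                f"target_edge_length {self.target_edge_length} mm outside the "
                "converged range [1, 5] mm")
        for name, hu in (("hu_cortical", self.hu_cortical),
                         ("hu_trabecular", self.hu_trabecular)):
            if not (HU_MIN <= hu <= HU_MAX):
                raise PhantomError(
                    f"{name}={hu} outside segmentation window [{HU_MIN}, {HU_MAX}] HU")
        if self.hu_noise_sd < 0:
            raise PhantomError("hu_noise_sd must be >= 0")

    @property
    def overall_width(self) -> float:
        return self.sacrum_width + 2 * (self.cartilage_thickness + self.ilium_width)


@dataclass
class FracturePlaneSet:
    """FFP IIc cut planes (all normal to the lateral-medial axis).

    ``posterior_x`` is the |x| coordinate of the vertical trans-alar plane in
    Denis zone II; ``ramus_x`` cuts the ipsilateral superior and inferior
    pubic rami.  Values are snapped to mesh grid planes by ``cut_ffp2c``.
    """

    injured_side: str = "right"
    posterior_x: float | None = None   # default: 0.6 x sacrum half-width
    ramus_x: float | None = None       # default: ramus mid-span


@dataclass
class Screw:
    entry_point: np.ndarray           # (3,) mm, on the lateral cortex
    axis: np.ndarray                  # unit vector pointing medially
    diameter: float = 7.3
    length: float = 60.0

    def __post_init__(self):
        self.entry_point = np.asarray(self.entry_point, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)


@dataclass
class FixationConstruct:
    """One of the three screw constructs (with entry washers)."""

    variant: str                      # USI | BSI | TSI
    screws: list
    screw_names: list
    washer_outer_diameter: float = 14.0
    washer_thickness: float = 2.0
    E: float = 110_000.0              # titanium alloy, MPa
    nu: float = 0.3

    def validate(self) -> None:
        if self.variant not in ("USI", "BSI", "TSI"):
            raise FixationError(f"unknown construct variant '{self.variant}'")
        n_expected = {"USI": 1, "BSI": 2, "TSI": 1}[self.variant]
        if len(self.screws) != n_expected:
            raise FixationError(
                f"{self.variant} requires {n_expected} screw(s), got {len(self.screws)}")
        if self.variant == "BSI":
            a, b = (s.axis for s in self.screws)
            if abs(abs(float(np.dot(a, b))) - 1.0) < 1e-9:
                raise FixationError("BSI screws must have distinct (non-collinear) axes")


# ---------------------------------------------------------------------------
# geometry snapping
# ---------------------------------------------------------------------------

def _snap(v: float, h: float) -> int:
    """Nearest grid plane index (round half away from grid origin ambiguity)."""
    return math.floor(v / h + 0.5)


def _geometry(params: PhantomParams) -> dict:
    """Snap the parametric blocks to the voxel grid; all values in mm or index.

    With ``snap_reference`` set, block boundaries live on the reference grid
    and are converted to (exact) element-grid indices, keeping the geometry
    identical across a refinement sweep.
    """
    p, h = params, params.target_edge_length
    grid = p.snap_reference if p.snap_reference is not None else h
    if p.snap_reference is not None:
        ratio = grid / h
        if abs(ratio - round(ratio)) > 1e-9:
            raise PhantomError(
                f"target_edge_length {h} must divide snap_reference {grid}")
        ratio = int(round(ratio))
    else:
        ratio = 1

    def _slab(lo: float, hi: float, _h=None):
        i_lo = _snap(lo, grid)
        i_hi = max(_snap(hi, grid), i_lo + 1)
        return i_lo * ratio, i_hi * ratio

    def _snap_idx(v: float, _h=None) -> int:
        return _snap(v, grid) * ratio

    g: dict = {"h": h}
    g["xs"] = _slab(0, p.sacrum_width / 2, h)          # sacrum half (x >= 0)
    g["xc"] = _slab(g["xs"][1] * h, g["xs"][1] * h + p.cartilage_thickness, h)
    g["xi"] = _slab(g["xc"][1] * h, g["xc"][1] * h + p.ilium_width, h)
    g["sac_y"] = _slab(0, p.sacrum_depth, h)
    g["sac_z"] = _slab(0, p.sacrum_height, h)
    g["il_y"] = _slab(-p.ilium_posterior_overhang,
                      -p.ilium_posterior_overhang + p.ilium_depth, h)
    g["il_z"] = _slab(-p.ilium_inferior_drop,
                      -p.ilium_inferior_drop + p.ilium_height, h)
    g["sym_x"] = _slab(0, p.cartilage_thickness, h)    # midline half
    g["pb_x"] = _slab(g["sym_x"][1] * h, g["sym_x"][1] * h + p.pubic_body_width, h)
    g["ram_x"] = (g["pb_x"][1], g["xc"][1])            # pubic body .. ilium face
    ry0 = p.sacrum_depth + p.ramus_y_offset
    g["ram_y"] = _slab(ry0, ry0 + p.ramus_section, h)
    z_sup_hi = p.sacrum_height / 2
    g["sup_z"] = _slab(z_sup_hi - p.ramus_section, z_sup_hi, h)
    g["inf_z"] = _slab(-p.ramus_section / 2, p.ramus_section / 2, h)
    g["ant_z"] = (g["inf_z"][0], g["sup_z"][1])        # pubic body / symphysis span
    g["s1_split"] = _snap_idx(p.sacrum_height / 2)     # S1/S2 boundary index

    # derived mm coordinates used downstream
    g["sacrum_half_mm"] = g["xs"][1] * h
    g["cart_outer_mm"] = g["xc"][1] * h
    g["ilium_outer_mm"] = g["xi"][1] * h
    g["sacrum_top_mm"] = g["sac_z"][1] * h
    g["sacrum_depth_mm"] = g["sac_y"][1] * h
    g["il_y_mm"] = (g["il_y"][0] * h, g["il_y"][1] * h)
    g["il_z_mm"] = (g["il_z"][0] * h, g["il_z"][1] * h)
    g["ram_y_mm"] = (g["ram_y"][0] * h, g["ram_y"][1] * h)
    g["sup_z_mm"] = (g["sup_z"][0] * h, g["sup_z"][1] * h)
    g["inf_z_mm"] = (g["inf_z"][0] * h, g["inf_z"][1] * h)
    g["ram_x_mm"] = (g["ram_x"][0] * h, g["ram_x"][1] * h)
    g["pb_x_mm"] = (g["pb_x"][0] * h, g["pb_x"][1] * h)
    g["s1_mid_mm"] = g["s1_split"] * h
    if g["ram_x"][0] >= g["ram_x"][1]:
        raise PhantomError("degenerate geometry: pubic ramus has no span "
                           "(pubic_body too wide for the ring)")
    if g["ram_y"][1] * h > g["il_y"][1] * h:
        raise PhantomError("degenerate geometry: ramus band anterior to the ilium")
    return g


def _right_half_voxels(g: dict):
    """(region, index slab triple) list for the x >= 0 half of the phantom."""
    blocks = []
    xs, xc, xi = g["xs"], g["xc"], g["xi"]
    blocks.append(("sacrum_S2_right", xs, g["sac_y"], (g["sac_z"][0], g["s1_split"])))
    blocks.append(("sacrum_S1_right", xs, g["sac_y"], (g["s1_split"], g["sac_z"][1])))
    blocks.append(("cartilage_si_right", xc, g["sac_y"], g["sac_z"]))
    blocks.append(("ilium_right", xi, g["il_y"], g["il_z"]))
    blocks.append(("symphysis", g["sym_x"], g["ram_y"], g["ant_z"]))
    blocks.append(("pubic_body_right", g["pb_x"], g["ram_y"], g["ant_z"]))
    blocks.append(("ramus_sup_right", g["ram_x"], g["ram_y"], g["sup_z"]))
    blocks.append(("ramus_inf_right", g["ram_x"], g["ram_y"], g["inf_z"]))
    return blocks


def _mirror_label(label: str) -> str:
    if label.endswith("_right"):
        return label[:-6] + "_left"
    if label.endswith("_left"):
        return label[:-5] + "_right"
    return label


def build_phantom(params: PhantomParams | None = None):
    """Build the intact phantom mesh and its per-element HU table.

    Returns ``(mesh, hu)``.  The mesh is mirror-symmetric about x = 0 by
    construction; ``hu`` is symmetric too when ``hu_noise_sd == 0``.  HU noise
    is the only randomness and is governed entirely by ``rng_seed``.
    """
    params = params or PhantomParams()
    params.validate()
    g = _geometry(params)
    h = g["h"]

    voxels, labels = [], []
    for label, (i0, i1), (j0, j1), (k0, k1) in _right_half_voxels(g):
        if i1 <= i0 or j1 <= j0 or k1 <= k0:
            raise PhantomError(f"degenerate geometry: region '{label}' is empty")
        ii, jj, kk = np.meshgrid(np.arange(i0, i1), np.arange(j0, j1),
                                 np.arange(k0, k1), indexing="ij")
        v = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        voxels.append(v)
        labels.extend([label] * v.shape[0])
        # mirror (voxel i -> -1-i); midline blocks start at i=0 and mirror cleanly
        vm = v.copy()
        vm[:, 0] = -1 - vm[:, 0]
        voxels.append(vm)
        labels.extend([_mirror_label(label)] * vm.shape[0])

    voxels = np.concatenate(voxels, axis=0)
    labels = np.asarray(labels, dtype="<U40")
    # de-duplicate (midline blocks produce their own mirrors only for i<0;
    # right slab [0, n) and mirrored [-n, 0) never overlap)
    if len(np.unique(voxels, axis=0)) != voxels.shape[0]:
        raise PhantomError("internal error: overlapping phantom blocks")

    nodes, tets, elem_voxel = tets_from_voxels(voxels, h)
    element_region = labels[elem_voxel]

    mesh = TetMesh(nodes=nodes, tets=tets, element_region=element_region)
    mesh.metadata.update({
        "edge_length": h,
        "geometry": {k: v for k, v in g.items() if k.endswith("_mm") or k == "h"},
        "params": {k: getattr(params, k) for k in vars(params)},
    })

    _attach_patches(mesh, g)
    mesh.validate()
    for region in INTACT_REGIONS:
        if not np.any(element_region == region):
            raise PhantomError(f"region '{region}' came out empty")

    hu = _hu_field(params, voxels, labels, elem_voxel)
    return mesh, hu


def _hu_field(params, voxels, labels, elem_voxel):
    """Synthetic HU: cortical shell on surface voxels, trabecular interior,
    Gaussian noise per element, clamped to the segmentation window."""
    occupied = set(map(tuple, voxels.tolist()))
    shifts = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    surface = np.array([
        any(tuple(v + s) not in occupied for s in np.asarray(shifts))
        for v in voxels
    ])
    hu_vox = np.where(surface, params.hu_cortical, params.hu_trabecular)
    rng = np.random.default_rng(params.rng_seed)
    hu = hu_vox[elem_voxel].astype(float)
    if params.hu_noise_sd > 0:
        hu = hu + rng.normal(0.0, params.hu_noise_sd, size=hu.shape)
    return np.clip(hu, HU_MIN, HU_MAX)


def _attach_patches(mesh: TetMesh, g: dict) -> None:
    """Create all named surface patches (load/BC + ligament attachments)."""
    h = g["h"]
    xs = g["sacrum_half_mm"]
    xc = g["cart_outer_mm"]
    xi = g["ilium_outer_mm"]
    sd = g["sacrum_depth_mm"]
    sh = g["sacrum_top_mm"]
    il_ylo, il_yhi = g["il_y_mm"]
    il_zlo, il_zhi = g["il_z_mm"]
    ry0, ry1 = g["ram_y_mm"]
    zs1 = g["sup_z_mm"][1]
    zi0 = g["inf_z_mm"][0]
    pb1 = g["pb_x_mm"][1]
    big = 1e9

    # lateral offset keeping ligament attachments clear of the default
    # fracture plane at 0.6 * half-width
    x_lig = 0.72 * xs

    def box(name, lo, hi):
        ids = nodes_in_box(mesh, lo, hi)
        if ids.size == 0:
            raise PhantomError(f"surface patch '{name}' is empty")
        mesh.surface_patches[name] = ids

    # load / boundary-condition patches
    box("s1_endplate", (-0.45 * xs, 0, sh), (0.45 * xs, sd, sh))
    box("acetabulum_right", (xc, il_ylo, il_zlo), (xi, il_yhi, il_zlo))
    box("acetabulum_left", (-xi, il_ylo, il_zlo), (-xc, il_yhi, il_zlo))

    for side, sgn in (("right", 1.0), ("left", -1.0)):
        def sbox(name, lo, hi, sgn=sgn, side=side):
            lo = np.asarray(lo, float)
            hi = np.asarray(hi, float)
            if sgn < 0:
                lo[0], hi[0] = -hi[0], -lo[0]
            box(f"{name}_{side}", lo, hi)

        # anterior sacroiliac: sacrum anterior face <-> ilium medial face
        sbox("asl_sacrum", (x_lig, sd, 0.5 * sh), (xs, sd, 0.92 * sh))
        sbox("asl_ilium", (xc, sd + 1e-6, 0.5 * sh), (xc, ry0 - 1e-6, 0.92 * sh))
        # short / long posterior sacroiliac: posterior faces
        sbox("spsl_sacrum", (x_lig, 0, 0.58 * sh), (xs, 0, 0.92 * sh))
        sbox("spsl_ilium", (xc, il_ylo, 0.58 * sh), (xc + 0.35 * (xi - xc), il_ylo, 0.92 * sh))
        sbox("lpsl_sacrum", (x_lig, 0, 0.08 * sh), (xs, 0, 0.5 * sh))
        sbox("lpsl_ilium", (xc, il_ylo, 0.08 * sh), (xc + 0.35 * (xi - xc), il_ylo, 0.5 * sh))
        # interosseous: sacrum top lateral <-> ilium medial face above the joint
        sbox("isl_sacrum", (x_lig, 0, sh), (xs, 0.4 * sd, sh))
        sbox("isl_ilium", (xc, 0, sh + 1e-6), (xc, 0.4 * sd, il_zhi))
        # sacrospinous: sacrum bottom lateral <-> ilium medial face below the joint
        sbox("ss_sacrum", (x_lig, 0, 0), (xs, sd, 0))
        sbox("ss_ilium", (xc, 0, il_zlo), (xc, sd, -1e-6))
        # sacrotuberous: sacrum posterior-bottom <-> ilium bottom
        sbox("st_sacrum", (x_lig, 0, 0), (xs, 0, 0.2 * sh))
        sbox("st_ilium", (xc, 0, il_zlo), (xc + 0.5 * (xi - xc), sd, il_zlo))
        # pubic ligaments: on top / bottom of the pubic bodies near the symphysis
        sbox("sp_pubis", (g["pb_x_mm"][0], ry0, zs1), (pb1, ry1, zs1))
        sbox("ip_pubis", (g["pb_x_mm"][0], ry0, zi0), (pb1, ry1, zi0))

    _ = h, big


# ---------------------------------------------------------------------------
# FFP IIc fracture
# ---------------------------------------------------------------------------

PROTECTED_PATCHES = ("s1_endplate", "acetabulum_left", "acetabulum_right")


def _cut_plane(mesh: TetMesh, name: str, x_plane: float, target_regions,
               lateral_sign: float, h: float) -> None:
    """Cut the mesh along x = x_plane inside ``target_regions``.

    Nodes on the plane attached to target elements on both sides are
    duplicated; elements on the lateral side (sign(x) matching
    ``lateral_sign`` beyond the plane) receive the duplicates, producing two
    free, untied faces registered as a :class:`FacePair`.
    """
    centroids = mesh.element_centroids()
    target = mesh.region_mask(*target_regions)
    if not target.any():
        raise PhantomError(f"fracture '{name}': no elements in target regions")
    lat = target & (lateral_sign * (centroids[:, 0] - x_plane) > 0)
    med = target & (lateral_sign * (centroids[:, 0] - x_plane) < 0)
    if not lat.any() or not med.any():
        raise PhantomError(
            f"fracture '{name}': plane x={x_plane} does not split its target region")

    on_plane = np.abs(mesh.nodes[:, 0] - x_plane) < 1e-6 * max(h, 1.0)
    lat_nodes = np.unique(mesh.tets[lat])
    med_nodes = np.unique(mesh.tets[med])
    cut_ids = np.flatnonzero(on_plane)
    cut_ids = cut_ids[np.isin(cut_ids, lat_nodes) & np.isin(cut_ids, med_nodes)]
    if cut_ids.size == 0:
        raise PhantomError(f"fracture '{name}': no shared interface nodes on the plane")

    # the crack must not sever any element outside the target regions
    touching = np.isin(mesh.tets, cut_ids).any(axis=1)
    foreign = touching & ~target
    if foreign.any():
        bad = sorted(set(mesh.element_region[foreign].tolist()))
        raise PhantomError(
            f"fracture '{name}': plane intersects non-target regions {bad}")
    for patch in PROTECTED_PATCHES:
        if patch in mesh.surface_patches and np.isin(
                mesh.surface_patches[patch], cut_ids).any():
            raise PhantomError(
                f"fracture '{name}': cut would disconnect BC patch '{patch}'")

    n0 = mesh.n_nodes
    new_ids = np.arange(n0, n0 + cut_ids.size, dtype=np.int64)
    mesh.nodes = np.vstack([mesh.nodes, mesh.nodes[cut_ids]])
    remap = np.arange(mesh.n_nodes, dtype=np.int64)
    remap[cut_ids] = new_ids
    lat_elem_ids = np.flatnonzero(lat)
    mesh.tets[lat_elem_ids] = remap[mesh.tets[lat_elem_ids]]

    axis = np.array([lateral_sign, 0.0, 0.0])
    mesh.fracture_face_pairs[name] = FacePair(
        name=name, medial=cut_ids, lateral=new_ids, axis=axis)


def cut_ffp2c(mesh: TetMesh, injured_side: str = "right",
              planes: FracturePlaneSet | None = None) -> TetMesh:
    """Cut the FFP IIc pattern into an intact phantom (returns a new mesh).

    Three cuts, each registered as a fracture face pair with a lateral-medial
    measurement axis: ``posterior_ring`` (vertical trans-alar sacral fracture,
    Denis zone II), ``anterior_superior_ramus`` and ``anterior_inferior_ramus``
    (ipsilateral pubic ramus fractures).  Duplicated faces are free and
    untied; element count is unchanged, node count grows by the number of
    interface nodes.
    """
    if injured_side not in ("left", "right"):
        raise PhantomError(f"injured_side must be 'left' or 'right', got {injured_side!r}")
    if mesh.fracture_face_pairs:
        raise PhantomError("mesh already contains fracture face pairs")
    planes = planes or FracturePlaneSet(injured_side=injured_side)
    geom = mesh.metadata.get("geometry")
    if geom is None:
        raise PhantomError("mesh lacks phantom geometry metadata")
    h = geom["h"]
    xs = geom["sacrum_half_mm"]
    rx0, rx1 = geom["ram_x_mm"]
    sgn = 1.0 if injured_side == "right" else -1.0

    post_x = planes.posterior_x if planes.posterior_x is not None else 0.6 * xs
    ram_x = planes.ramus_x if planes.ramus_x is not None else 0.5 * (rx0 + rx1)
    post_x = _snap(post_x, h) * h
    ram_x = _snap(ram_x, h) * h
    if not (0 < post_x < xs):
        raise PhantomError(f"posterior fracture plane x={post_x} outside the sacral ala")
    if not (rx0 < ram_x < rx1):
        raise PhantomError(f"ramus fracture plane x={ram_x} outside the rami")

    out = mesh.copy()
    side = injured_side
    _cut_plane(out, "posterior_ring", sgn * post_x,
               (f"sacrum_S1_{side}", f"sacrum_S2_{side}"), sgn, h)
    _cut_plane(out, "anterior_superior_ramus", sgn * ram_x,
               (f"ramus_sup_{side}",), sgn, h)
    _cut_plane(out, "anterior_inferior_ramus", sgn * ram_x,
               (f"ramus_inf_{side}",), sgn, h)
    out.metadata["injured_side"] = side
    out.metadata["fracture_planes"] = {"posterior_x": sgn * post_x,
                                       "ramus_x": sgn * ram_x}
    out.validate()
    return out


# ---------------------------------------------------------------------------
# screw constructs
# ---------------------------------------------------------------------------

def make_construct(variant: str, mesh: TetMesh, injured_side: str | None = None,
                   diameter: float = 7.3, washer_outer_diameter: float = 14.0,
                   washer_thickness: float = 2.0, E: float = 110_000.0,
                   nu: float = 0.3, bsi_tilt_mm: float = 8.0) -> FixationConstruct:
    """Default screw geometry for a variant, derived from the phantom geometry.

    All screws run laterally->medially at the level of the first sacral body.
    USI/BSI screws reach the mid-sacrum; the TSI spans the full transverse
    width.  The contralateral BSI screw is tilted anteriorly by
    ``bsi_tilt_mm`` over its length so the two axes are non-collinear
    (rotational stability of the paired construct).
    """
    injured_side = injured_side or mesh.metadata.get("injured_side", "right")
    geom = mesh.metadata["geometry"]
    xi = geom["ilium_outer_mm"]
    sh = geom["sacrum_top_mm"]
    sd = geom["sacrum_depth_mm"]
    z_s1 = 0.75 * sh
    y_mid = 0.5 * sd
    sgn = 1.0 if injured_side == "right" else -1.0

    def straight(from_sign, length):
        entry = np.array([from_sign * xi, y_mid, z_s1])
        return Screw(entry, np.array([-from_sign, 0.0, 0.0]),
                     diameter=diameter, length=length)

    if variant == "USI":
        screws = [straight(sgn, xi)]
        names = ["screw_usi"]
    elif variant == "TSI":
        screws = [straight(sgn, 2 * xi)]
        names = ["screw_tsi"]
    elif variant == "BSI":
        injured = straight(sgn, xi)
        entry = np.array([-sgn * xi, y_mid - bsi_tilt_mm / 2, z_s1])
        tip = np.array([0.0, y_mid + bsi_tilt_mm / 2, z_s1])
        axis = tip - entry
        contra = Screw(entry, axis, diameter=diameter,
                       length=float(np.linalg.norm(axis)))
        screws = [injured, contra]
        names = ["screw_bsi_injured", "screw_bsi_contra"]
    else:
        raise FixationError(f"unknown construct variant '{variant}'")
    construct = FixationConstruct(
        variant=variant, screws=screws, screw_names=names,
        washer_outer_diameter=washer_outer_diameter,
        washer_thickness=washer_thickness, E=E, nu=nu)
    construct.validate()
    return construct


def _cylinder_mask(centroids: np.ndarray, screw: Screw, radius: float,
                   s_range) -> np.ndarray:
    rel = centroids - screw.entry_point
    s = rel @ screw.axis
    radial = rel - s[:, None] * screw.axis[None, :]
    r = np.linalg.norm(radial, axis=1)
    return (r <= radius) & (s >= s_range[0]) & (s <= s_range[1])


def place_screws(mesh: TetMesh, construct: FixationConstruct) -> TetMesh:
    """Relabel elements inside the screw/washer cylinders; bond across cracks.

    Capture radius is ``max(diameter/2, 0.8 * edge_length)`` so the construct
    stays at least one element wide at coarse resolutions.  Where a screw
    crosses a fracture, the shaft is made continuous through the crack (the
    crack-plane node duplicates are merged back for screw elements only), so
    the fragments are coupled by the elastic screw rather than by a rigid
    weld; the bone faces themselves remain free.  Those face-node pairs are
    flagged as bridged.
    """
    construct.validate()
    out = mesh.copy()
    h = out.metadata.get("edge_length", 1.0)
    centroids = out.element_centroids()
    plane = out.metadata.get("fracture_planes", {}).get("posterior_x")

    screw_elem_nodes = []
    relabelable = out.region_mask(*BONE_REGIONS) | out.region_mask(*SOFT_REGIONS)
    for screw, name in zip(construct.screws, construct.screw_names):
        r_eff = max(screw.diameter / 2.0, 0.8 * h)
        mask = _cylinder_mask(centroids, screw, r_eff, (0.0, screw.length))
        mask &= relabelable
        if not mask.any():
            raise FixationError(f"screw '{name}' captures no elements")
        wmask = _cylinder_mask(centroids, screw, construct.washer_outer_diameter / 2.0,
                               (0.0, max(construct.washer_thickness, h))) & relabelable
        out.element_region[mask] = name
        out.element_region[wmask & ~mask] = name.replace("screw", "washer")
        screw_elem_nodes.append(np.unique(out.tets[mask | wmask]))

        # contract: does this screw cross the posterior fracture plane?
        if plane is not None:
            x0 = screw.entry_point[0]
            x1 = screw.entry_point[0] + screw.length * screw.axis[0]
            crossing = (x0 - plane) * (x1 - plane) < 0
            required = construct.variant in ("USI", "TSI") or name.endswith("injured")
            if required and not crossing:
                raise FixationError(
                    f"construct does not stabilize fracture: screw '{name}' "
                    f"does not cross the posterior fracture plane x={plane}")
        # protrusion warning: tip beyond the contralateral cortex
        tip = screw.entry_point + screw.length * screw.axis
        xi = out.metadata["geometry"]["ilium_outer_mm"]
        if construct.variant != "TSI" and abs(tip[0]) > xi + 1e-9:
            warnings.warn(f"screw '{name}' protrudes through a non-entry surface",
                          stacklevel=2)

    # make each screw shaft continuous through any fracture it crosses:
    # lateral-side implant elements swap the crack-node duplicate for the
    # original node, so the two fragments are coupled by the elastic shaft
    implant_mask = np.array([r.startswith(("screw", "washer"))
                             for r in out.element_region])
    implant_elems = np.flatnonzero(implant_mask)
    implant_nodes = np.unique(out.tets[implant_elems]) if implant_elems.size else \
        np.array([], dtype=np.int64)
    for pair in out.fracture_face_pairs.values():
        dup_in_implant = np.isin(pair.lateral, implant_nodes)
        if dup_in_implant.any():
            remap = np.arange(out.n_nodes, dtype=np.int64)
            remap[pair.lateral[dup_in_implant]] = pair.medial[dup_in_implant]
            out.tets[implant_elems] = remap[out.tets[implant_elems]]
        # implant-occupied pairs are not free fracture surface
        pair.bridged |= dup_in_implant | np.isin(pair.medial, implant_nodes)
    out.metadata["construct"] = construct.variant
    out.metadata["implant_regions"] = [n for n in construct.screw_names] + [
        n.replace("screw", "washer") for n in construct.screw_names]
    out.metadata["implant_material"] = {"E": construct.E, "nu": construct.nu}
    return out
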