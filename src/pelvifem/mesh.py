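"""Labeled tetrahedral meshes and structured voxel tetrahedralization.

The mesh container used throughout the package: node coordinates live in an
anatomical frame (x: left->right lateral-medial, y: posterior->anterior,
z: inferior->superior, all in mm), every element carries exactly one region
label, and named surface patches / fracture face pairs / tie constraints ride
along with the connectivity.

Meshes are generated from axis-aligned voxel sets via the Kuhn 6-tetrahedron
split, which is conforming across neighbouring voxels without parity
alternation.  Voxels at negative x are built as exact mirror images of their
positive-x counterparts so that a symmetric voxel set yields a mesh that maps
onto itself under reflection about the mid-sagittal plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class MeshError(ValueError):
    """Raised for invalid or inconsistent mesh data."""


@dataclass
class FacePair:
    """Matched pair of fracture faces with a node-by-node bijection.

    ``medial[i]`` and ``lateral[i]`` started as the same node before the cut;
    ``axis`` is the unit measurement direction (pointing from the medial to
    the lateral fragment).  ``bridged[i]`` marks pairs re-bonded by an
    implant (excluded from free-gap measurement).
    """

    name: str
    medial: np.ndarray
    lateral: np.ndarray
    axis: np.ndarray
    bridged: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.medial = np.asarray(self.medial, dtype=np.int64)
        self.lateral = np.asarray(self.lateral, dtype=np.int64)
        self.axis = np.asarray(self.axis, dtype=float)
        self.axis = self.axis / np.linalg.norm(self.axis)
        if self.medial.shape != self.lateral.shape:
            raise MeshError(
                f"face pair '{self.name}': unequal node counts "
                f"({self.medial.size} vs {self.lateral.size})"
            )
        if self.bridged is None:
            self.bridged = np.zeros(self.medial.size, dtype=bool)
        else:
            self.bridged = np.asarray(self.bridged, dtype=bool)

    @property
    def n_pairs(self) -> int:
        return int(self.medial.size)

    def copy(self) -> "FacePair":
        return FacePair(self.name, self.medial.copy(), self.lateral.copy(),
                        self.axis.copy(), self.bridged.copy())


@dataclass
class TetMesh:
    """Linear tetrahedral mesh with region labels and named node patches."""

    nodes: np.ndarray                      # (N, 3) float64, mm
    tets: np.ndarray                       # (M, 4) int64
    element_region: np.ndarray             # (M,) unicode labels
    surface_patches: dict = field(default_factory=dict)   # name -> node ids
    fracture_face_pairs: dict = field(default_factory=dict)  # name -> FacePair
    tie_pairs: np.ndarray = None           # (T, 2) int64 (master, slave)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.float64)
        self.tets = np.asarray(self.tets, dtype=np.int64)
        self.element_region = np.asarray(self.element_region)
        if self.tie_pairs is None:
            self.tie_pairs = np.zeros((0, 2), dtype=np.int64)
        else:
            self.tie_pairs = np.asarray(self.tie_pairs, dtype=np.int64).reshape(-1, 2)

    # -- basic queries ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.tets.shape[0])

    def regions(self) -> list:
        return sorted(set(self.element_region.tolist()))

    def region_mask(self, *names: str) -> np.ndarray:
        mask = np.zeros(self.n_elements, dtype=bool)
        for name in names:
            mask |= self.element_region == name
        return mask

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.nodes, self.tets)

    def patch(self, name: str) -> np.ndarray:
        try:
            return self.surface_patches[name]
        except KeyError:
            raise MeshError(f"mesh has no surface patch named '{name}'") from None

    def copy(self) -> "TetMesh":
        return TetMesh(
            nodes=self.nodes.copy(),
            tets=self.tets.copy(),
            element_region=self.element_region.copy(),
            surface_patches={k: np.array(v, dtype=np.int64)
                             for k, v in self.surface_patches.items()},
            fracture_face_pairs={k: p.copy()
                                 for k, p in self.fracture_face_pairs.items()},
            tie_pairs=self.tie_pairs.copy(),
            metadata=dict(self.metadata),
        )

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Check connectivity, orientation and label invariants."""
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= self.n_nodes:
            raise MeshError("connectivity references nonexistent nodes")
        if self.element_region.shape[0] != self.n_elements:
            raise MeshError("element_region length does not match element count")
        vols = self.volumes()
        bad = np.flatnonzero(vols <= 0)
        if bad.size:
            raise MeshError(f"{bad.size} non-positive-volume tets, first ids {bad[:5].tolist()}")
        for name, ids in self.surface_patches.items():
            ids = np.asarray(ids)
            if ids.size and (ids.min() < 0 or ids.max() >= self.n_nodes):
                raise MeshError(f"patch '{name}' references nonexistent nodes")
        for pair in self.fracture_face_pairs.values():
            for arr in (pair.medial, pair.lateral):
                if arr.size and (arr.min() < 0 or arr.max() >= self.n_nodes):
                    raise MeshError(f"face pair '{pair.name}' references nonexistent nodes")


def tet_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for consistent orientation)."""
    x = nodes[tets]
    e = x[:, 1:, :] - x[:, :1, :]
    return np.linalg.det(e) / 6.0


# Kuhn split of the unit hex. Corner id bit layout: bit0 = x, bit1 = y, bit2 = z.
# Six tets (0, a, b, 7) along the six monotone lattice paths 0 -> 7.
_KUHN = np.array([
    [0, 1, 3, 7],
    [0, 1, 5, 7],
    [0, 2, 3, 7],
    [0, 2, 6, 7],
    [0, 4, 5, 7],
    [0, 4, 6, 7],
], dtype=np.int64)
# Mirror image about x: flip the x bit of every corner id.
_KUHN_MIRROR = _KUHN ^ 1

_CORNER_OFFSETS = np.array(
    [[(c >> 0) & 1, (c >> 1) & 1, (c >> 2) & 1] for c in range(8)], dtype=np.int64
)


def tets_from_voxels(voxels: np.ndarray, h: float):
    """Tetrahedralize an axis-aligned voxel set with edge length ``h``.

    ``voxels`` is an integer (K, 3) array of lattice indices; voxel (i, j, k)
    occupies [i*h, (i+1)*h] x [j*h, (j+1)*h] x [k*h, (k+1)*h].  Voxels with
    i < 0 receive the mirrored Kuhn split so a reflection-symmetric voxel set
    produces a reflection-symmetric tet mesh.

    Returns ``(nodes, tets, elem_voxel)`` where ``elem_voxel`` maps each of
    the 6*K tets back to its source voxel row.
    """
    voxels = np.asarray(voxels, dtype=np.int64).reshape(-1, 3)
    if voxels.shape[0] == 0:
        raise MeshError("empty voxel set")
    if len(np.unique(voxels, axis=0)) != voxels.shape[0]:
        raise MeshError("duplicate voxels in set")

    corners = voxels[:, None, :] + _CORNER_OFFSETS[None, :, :]      # (K, 8, 3)
    flat = corners.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    corner_ids = inverse.reshape(-1, 8)                             # (K, 8)

    mirrored = voxels[:, 0] < 0
    patterns = np.where(mirrored[:, None, None], _KUHN_MIRROR[None], _KUHN[None])
    tets = np.take_along_axis(
        corner_ids[:, None, :].repeat(6, axis=1), patterns, axis=2
    ).reshape(-1, 4)
    elem_voxel = np.repeat(np.arange(voxels.shape[0]), 6)

    nodes = uniq.astype(np.float64) * float(h)
    # enforce positive orientation (mirrored tets come out inverted)
    vols = tet_volumes(nodes, tets)
    flip = vols < 0
    tets[flip, 2], tets[flip, 3] = tets[flip, 3].copy(), tets[flip, 2].copy()
    return nodes, tets, elem_voxel


def box_mesh(lengths, h: float, origin=(0.0, 0.0, 0.0), region: str = "box") -> TetMesh:
    """Structured tet mesh of a rectangular box (testing / benchmark helper)."""
    lengths = np.asarray(lengths, dtype=float)
    n = np.maximum(np.round(lengths / h).astype(int), 1)
    ii, jj, kk = np.meshgrid(*[np.arange(c) for c in n], indexing="ij")
    voxels = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    nodes, tets, _ = tets_from_voxels(voxels, h)
    nodes = nodes + np.asarray(origin, dtype=float)
    mesh = TetMesh(
        nodes=nodes,
        tets=tets,
        element_region=np.full(tets.shape[0], region, dtype="<U40"),
    )
    mesh.metadata["edge_length"] = float(h)
    return mesh


def nodes_in_box(mesh: TetMesh, lo, hi, tol: float = 1e-9) -> np.ndarray:
    """Node ids inside the closed axis-aligned box [lo, hi]."""
    lo = np.asarray(lo, dtype=float) - tol
    hi = np.asarray(hi, dtype=float) + tol
    inside = np.all((mesh.nodes >= lo) & (mesh.nodes <= hi), axis=1)
    return np.flatnonzero(inside)


def reflect_x(mesh: TetMesh) -> TetMesh:
    """Mirror a mesh about the mid-sagittal plane x = 0."""
    out = mesh.copy()
    out.nodes[:, 0] *= -1.0
    out.tets[:, [2, 3]] = out.tets[:, [3, 2]]   # restore orientation
    return out


def canonical_tet_set(mesh: TetMesh):
    """Orientation-independent set representation {sorted node coords per tet}.

    Used to check that two meshes describe the same geometry (e.g. a phantom
    and its mirror image) irrespective of node numbering.
    """
    coords = mesh.nodes[mesh.tets]          # (M, 4, 3)
    rounded = np.round(coords, 6)
    keys = set()
    for tet in rounded:
        keys.add(tuple(sorted(map(tuple, tet.tolist()))))
    return keys
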