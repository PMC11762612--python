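"""Linear-elastic tetrahedral finite elements with axial links and ties.

Small-displacement constant-strain tetrahedra (CST), assembled into a sparse
symmetric stiffness operator over 3N nodal degrees of freedom.  Bonded (tie)
constraints are eliminated master-slave; Dirichlet patches clamp all three
components.  Ligaments and optional fracture-face contacts enter as axial
two-node links whose activity (tension-only / compression-only) is resolved
by a fixed-point active-set iteration around a direct sparse factorization.

Stress is recovered element-wise (exact for CST) in the global anatomical
frame; normal components along anatomical axes are the headline output of
the downstream analysis, von Mises deliberately is not (bone is brittle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import TetMesh

class FEMError(RuntimeError):
    pass


class InsufficientConstraintsError(FEMError):
    """Rigid-body modes remain after boundary conditions."""


class ActiveSetError(FEMError):
    """Tension-only iteration failed to settle."""


# ---------------------------------------------------------------------------
# element matrices
# ---------------------------------------------------------------------------

def _element_operators(nodes: np.ndarray, tets: np.ndarray,
                       E: np.ndarray, nu: np.ndarray):
    """Vectorized CST operators: volumes V, strain matrices B (M,6,12),
    elasticity D (M,6,6) and stiffness Ke (M,12,12)."""
    X = nodes[tets]                             # (M,4,3)
    edges = X[:, 1:, :] - X[:, :1, :]           # rows e_i = x_i - x_0
    detJ = np.linalg.det(edges)
    V = detJ / 6.0
    bad = np.flatnonzero(V <= 0)
    if bad.size:
        raise FEMError(f"{bad.size} degenerate tets (non-positive volume), "
                       f"first element ids {bad[:5].tolist()}")
    Jinv = np.linalg.inv(edges)
    # grad(lambda_i), i=1..3: columns of edges^-1; lambda_0 closes the partition
    g123 = np.transpose(Jinv, (0, 2, 1))        # (M,3,3): row i -> grad lambda_{i+1}
    g0 = -g123.sum(axis=1, keepdims=True)
    G = np.concatenate([g0, g123], axis=1)      # (M,4,3)

    M = tets.shape[0]
    B = np.zeros((M, 6, 12))
    for a in range(4):
        gx, gy, gz = G[:, a, 0], G[:, a, 1], G[:, a, 2]
        c = 3 * a
        B[:, 0, c + 0] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c + 0] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c + 0] = gz
        B[:, 5, c + 2] = gx

    E = np.broadcast_to(np.asarray(E, dtype=float), (M,))
    nu = np.broadcast_to(np.asarray(nu, dtype=float), (M,))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((M, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] += 2 * mu
        D[:, 3 + i, 3 + i] = mu

    Ke = V[:, None, None] * np.einsum("mia,mij,mjb->mab", B, D, B, optimize=True)
    return V, B, D, Ke


def element_stiffness(tet_nodes: np.ndarray, E: float, nu: float) -> np.ndarray:
    """12x12 stiffness of one linear tetrahedron (nodes (4,3) in mm, E MPa)."""
    tet_nodes = np.asarray(tet_nodes, dtype=float)
    _, _, _, Ke = _element_operators(tet_nodes, np.arange(4)[None, :],
                                     np.array([E]), np.array([nu]))
    return Ke[0]


# ---------------------------------------------------------------------------
# axial links (ligament sub-springs and optional face contacts)
# ---------------------------------------------------------------------------

@dataclass
class _Links:
    """Flattened axial two-node links."""

    a: np.ndarray          # (L,) node ids
    b: np.ndarray
    direction: np.ndarray  # (L,3) unit, undeformed, a -> b
    k: np.ndarray          # (L,) current (secant) stiffness N/mm
    rest: np.ndarray       # (L,) mm (0 for coincident-face contacts)
    mode: np.ndarray       # (L,) 'tension' | 'compression' | 'both'
    spring_idx: np.ndarray  # (L,) index into the springs list, -1 for contacts
    laws: list             # per-link law object or None

    @property
    def n(self) -> int:
        return int(self.a.size)


def _flatten_links(mesh: TetMesh, springs, contacts):
    a, b, dirs, k, rest, mode, sidx, laws = [], [], [], [], [], [], [], []
    for si, s in enumerate(springs):
        for (na, nb), r in zip(s.node_pairs, s.rest_lengths):
            d = mesh.nodes[nb] - mesh.nodes[na]
            a.append(na)
            b.append(nb)
            dirs.append(d / np.linalg.norm(d))
            k.append(s.sub_stiffness(0.0))
            rest.append(r)
            mode.append(s.mode)
            sidx.append(si)
            laws.append(s.law)
    for (na, nb, axis, kc) in contacts:
        a.append(na)
        b.append(nb)
        dirs.append(np.asarray(axis, dtype=float))
        k.append(kc)
        rest.append(0.0)
        mode.append("compression")
        sidx.append(-1)
        laws.append(None)
    if not a:
        return _Links(*(np.zeros(0, dtype=np.int64),) * 2,
                      direction=np.zeros((0, 3)), k=np.zeros(0),
                      rest=np.zeros(0), mode=np.zeros(0, dtype="<U11"),
                      spring_idx=np.zeros(0, dtype=np.int64), laws=[])
    return _Links(np.asarray(a, np.int64), np.asarray(b, np.int64),
                  np.asarray(dirs, float), np.asarray(k, float),
                  np.asarray(rest, float), np.asarray(mode, dtype="<U11"),
                  np.asarray(sidx, np.int64), laws)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _union_find(n: int, pairs: np.ndarray) -> np.ndarray:
    parent = np.arange(n, dtype=np.int64)

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for m, s in pairs:
        rm, rs = find(int(m)), find(int(s))
        if rm != rs:
            parent[max(rm, rs)] = min(rm, rs)
    return np.array([find(i) for i in range(n)], dtype=np.int64)


@dataclass
class AssembledSystem:
    """Reduced linear system plus everything needed for post-processing."""

    mesh: TetMesh
    E: np.ndarray
    nu: np.ndarray
    K_vol: sp.csr_matrix          # volume stiffness on free reduced dofs
    f_free: np.ndarray
    f_ext: np.ndarray             # (N,3) applied nodal loads (full mesh)
    dofmap: np.ndarray            # (N,3) -> free dof id or -1
    rep: np.ndarray               # (N,) representative node after ties
    fixed_nodes: np.ndarray
    links: _Links
    springs: list
    Ke: np.ndarray                # (M,12,12)
    B: np.ndarray                 # (M,6,12)
    D: np.ndarray                 # (M,6,6)
    loaded_patches: list = field(default_factory=list)
    u_fixed: np.ndarray = None    # (N,3) prescribed values on fixed nodes

    @property
    def n_free(self) -> int:
        return int(self.f_free.size)


def assemble(mesh: TetMesh, materials, springs=(), fixed_patches=(),
             patch_loads=(), contacts=(), extra_ties=None,
             prescribed=()) -> AssembledSystem:
    """Assemble the constrained system.

    ``materials`` provides per-element ``E``/``nu`` (a MaterialField or any
    object with those arrays).  ``patch_loads`` is a sequence of
    ``(patch_name, total_force_vector)``; the force is distributed uniformly
    over the patch nodes.  ``fixed_patches`` clamp all three components to
    zero; ``prescribed`` is a sequence of ``(node_ids, values (n,3))`` pairs
    imposing nonzero displacements (used e.g. by the patch test).
    ``contacts`` are compression-only links ``(node_a, node_b, axis, k)``.
    """
    E = np.asarray(materials.E, dtype=float)
    nu = np.asarray(materials.nu, dtype=float)
    if E.shape[0] != mesh.n_elements:
        raise FEMError("material field does not match element count")

    ties = mesh.tie_pairs
    if extra_ties is not None and len(extra_ties):
        ties = np.concatenate([ties, np.asarray(extra_ties, np.int64).reshape(-1, 2)])
    rep = _union_find(mesh.n_nodes, ties)

    fixed = set()
    for patch in fixed_patches:
        fixed.update(mesh.patch(patch).tolist())
    u_fixed = np.zeros((mesh.n_nodes, 3))
    for ids, values in prescribed:
        ids = np.asarray(ids, dtype=np.int64)
        u_fixed[ids] = np.asarray(values, dtype=float)
        fixed.update(ids.tolist())
    # a tie group containing a fixed node is entirely fixed
    fixed_reps = {int(rep[n]) for n in fixed}
    fixed_mask = np.isin(rep, np.fromiter(fixed_reps, dtype=np.int64)
                         if fixed_reps else np.array([], dtype=np.int64))
    if not fixed_mask.any():
        raise InsufficientConstraintsError(
            "insufficient constraints: no fixed patches, rigid-body modes remain")

    # nodes no longer referenced by any element (e.g. crack-node duplicates
    # absorbed into a screw shaft) carry no stiffness: exclude their dofs
    referenced = np.zeros(mesh.n_nodes, dtype=bool)
    referenced[np.unique(mesh.tets)] = True
    fixed_mask |= ~referenced

    free_rep = np.unique(rep[~fixed_mask])
    red_index = -np.ones(mesh.n_nodes, dtype=np.int64)
    red_index[free_rep] = np.arange(free_rep.size)
    node_red = red_index[rep]                  # (N,) reduced node or -1
    dofmap = np.where(node_red[:, None] >= 0,
                      3 * node_red[:, None] + np.arange(3)[None, :], -1)
    n_free = 3 * free_rep.size

    V, B, D, Ke = _element_operators(mesh.nodes, mesh.tets, E, nu)

    edof = dofmap[mesh.tets].reshape(-1, 12)   # (M,12)
    rows = np.repeat(edof, 12, axis=1).ravel()
    cols = np.tile(edof, (1, 12)).ravel()
    vals = Ke.reshape(-1, 144).ravel()
    keep = (rows >= 0) & (cols >= 0)
    K_vol = sp.coo_matrix((vals[keep], (rows[keep], cols[keep])),
                          shape=(n_free, n_free)).tocsr()

    f_ext = np.zeros((mesh.n_nodes, 3))
    loaded = []
    for patch, force in patch_loads:
        ids = mesh.patch(patch)
        f_ext[ids] += np.asarray(force, dtype=float) / ids.size
        loaded.append(patch)
    f_free = np.zeros(n_free)
    valid = dofmap >= 0
    np.add.at(f_free, dofmap[valid], f_ext[valid])

    # nonzero prescribed displacements move to the right-hand side
    if np.any(u_fixed):
        # value of each element dof if it is fixed (via its representative)
        u_fix_rep = u_fixed.copy()
        u_fix_rep[~fixed_mask] = 0.0
        uvals = u_fix_rep[mesh.tets].reshape(-1, 12)
        ucols = np.tile(uvals, (1, 12)).ravel()
        bc = (rows >= 0) & (cols < 0)
        np.add.at(f_free, rows[bc], -vals[bc] * ucols[bc])

    links = _flatten_links(mesh, list(springs), list(contacts))
    return AssembledSystem(mesh=mesh, E=E, nu=nu, K_vol=K_vol, f_free=f_free,
                           f_ext=f_ext, dofmap=dofmap, rep=rep,
                           fixed_nodes=np.flatnonzero(fixed_mask), links=links,
                           springs=list(springs), Ke=Ke, B=B, D=D,
                           loaded_patches=loaded, u_fixed=u_fixed)


def _link_matrix(system: AssembledSystem, active: np.ndarray,
                 k: np.ndarray) -> sp.csr_matrix:
    n = system.n_free
    if not active.any():
        return sp.csr_matrix((n, n))
    rows, cols, vals = [], [], []
    L = system.links
    for i in np.flatnonzero(active):
        d = L.direction[i]
        block = k[i] * np.outer(d, d)
        da = system.dofmap[L.a[i]]
        db = system.dofmap[L.b[i]]
        for (dofs_i, dofs_j, sign) in ((da, da, 1.0), (db, db, 1.0),
                                       (da, db, -1.0), (db, da, -1.0)):
            for p in range(3):
                if dofs_i[p] < 0:
                    continue
                for q in range(3):
                    if dofs_j[q] < 0:
                        continue
                    rows.append(dofs_i[p])
                    cols.append(dofs_j[q])
                    vals.append(sign * block[p, q])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

@dataclass
class Solution:
    """Converged displacements, element fields and link forces."""

    u: np.ndarray                # (N,3) mm
    strain: np.ndarray           # (M,6) engineering, (xx,yy,zz,xy,yz,zx)
    stress: np.ndarray           # (M,6) MPa, anatomical frame
    spring_forces: dict          # spring name -> total axial force N (tension+)
    link_delta: np.ndarray
    link_force: np.ndarray
    active_links: np.ndarray
    residual: float
    n_iterations: int
    f_int: np.ndarray            # (N,3) internal nodal forces
    f_ext: np.ndarray

    def reactions(self, fixed_nodes: np.ndarray) -> np.ndarray:
        return (self.f_int - self.f_ext)[fixed_nodes]


def _linear_solve(system: AssembledSystem, K: sp.csr_matrix) -> np.ndarray:
    try:
        lu = spla.splu(K.tocsc())
    except RuntimeError as exc:  # singular factorization
        raise InsufficientConstraintsError(
            f"stiffness factorization failed ({exc}); check constraints") from exc
    u = lu.solve(system.f_free)
    if not np.all(np.isfinite(u)):
        raise FEMError("solver produced non-finite displacements")
    return u


def _expand(system: AssembledSystem, u_free: np.ndarray) -> np.ndarray:
    u = (system.u_fixed.copy() if system.u_fixed is not None
         else np.zeros((system.mesh.n_nodes, 3)))
    valid = system.dofmap >= 0
    u[valid] = u_free[system.dofmap[valid]]
    return u


def _link_deltas(system: AssembledSystem, u: np.ndarray) -> np.ndarray:
    L = system.links
    if L.n == 0:
        return np.zeros(0)
    rel = u[L.b] - u[L.a]
    return np.einsum("ij,ij->i", rel, L.direction)


def _finish(system: AssembledSystem, u_free: np.ndarray, active: np.ndarray,
            k: np.ndarray, n_iter: int) -> Solution:
    K = system.K_vol + _link_matrix(system, active, k)
    r = K @ u_free - system.f_free
    fnorm = np.linalg.norm(system.f_free)
    residual = float(np.linalg.norm(r) / (fnorm if fnorm > 0 else 1.0))
    if residual > 1e-8:
        raise FEMError(f"solver residual {residual:.2e} above tolerance 1e-8")

    u = _expand(system, u_free)
    mesh = system.mesh
    ue = u[mesh.tets].reshape(-1, 12)
    strain = np.einsum("mij,mj->mi", system.B, ue)
    stress = np.einsum("mij,mj->mi", system.D, strain)

    fe = np.einsum("mij,mj->mi", system.Ke, ue).reshape(-1, 4, 3)
    f_int = np.zeros_like(u)
    np.add.at(f_int, mesh.tets, fe)

    delta = _link_deltas(system, u)
    force = np.where(active, k * delta, 0.0)
    # marginally-active tension links may carry O(eps) negative force: clamp
    force[(system.links.mode == "tension") & (force < 0)] = 0.0
    L = system.links
    for i in range(L.n):
        if force[i] == 0.0:
            continue
        f_int[L.b[i]] += force[i] * L.direction[i]
        f_int[L.a[i]] -= force[i] * L.direction[i]

    spring_forces = {}
    for si, s in enumerate(system.springs):
        idx = np.flatnonzero(L.spring_idx == si)
        spring_forces[s.name] = float(force[idx].sum())
    return Solution(u=u, strain=strain, stress=stress,
                    spring_forces=spring_forces, link_delta=delta,
                    link_force=force, active_links=active, residual=residual,
                    n_iterations=n_iter, f_int=f_int, f_ext=system.f_ext)


def solve(system: AssembledSystem) -> Solution:
    """Single linear solve (tension links taken active at zero-strain
    stiffness, contacts inactive).  Use :func:`solve_tension_only` for the
    physically admissible ligament state."""
    L = system.links
    active = L.mode != "compression"
    u_free = _linear_solve(system, system.K_vol + _link_matrix(system, active, L.k))
    return _finish(system, u_free, active, L.k.copy(), 1)


def solve_tension_only(system: AssembledSystem, max_iterations: int = 50,
                       k_rtol: float = 1e-9) -> Solution:
    """Fixed-point active-set iteration for sign-constrained links.

    Tension-only links are deactivated when the trial solution shortens them
    and reactivated when their gap re-opens; compression-only contacts are
    the mirror image.  Elongation-dependent laws update their secant
    stiffness in the same loop.  Converged solutions carry no compressive
    force in any tension-only link.
    """
    L = system.links
    if L.n == 0:
        u_free = _linear_solve(system, system.K_vol)
        return _finish(system, u_free, np.zeros(0, dtype=bool), L.k.copy(), 1)

    active = L.mode != "compression"
    k = L.k.copy()
    seen_patterns = set()
    history = []
    for it in range(1, max_iterations + 1):
        u_free = _linear_solve(system, system.K_vol + _link_matrix(system, active, k))
        delta = _link_deltas(system, _expand(system, u_free))
        new_active = np.where(L.mode == "tension", delta > -1e-12,
                              np.where(L.mode == "compression", delta < 1e-12, True))
        k_new = k.copy()
        for i in range(L.n):
            law = L.laws[i]
            if law is not None and L.rest[i] > 0:
                strain = max(delta[i], 0.0) / L.rest[i]
                n_sub = np.count_nonzero(L.spring_idx == L.spring_idx[i])
                k_new[i] = law.stiffness(strain) / n_sub
        k_change = np.max(np.abs(k_new - k) / np.maximum(np.abs(k), 1e-30))
        if np.array_equal(new_active, active) and k_change < k_rtol:
            return _finish(system, u_free, active, k, it)
        pattern = new_active.tobytes()
        history.append(new_active)
        if pattern in seen_patterns and k_change < k_rtol:
            osc = np.flatnonzero(history[-1] != history[-2]) if len(history) > 1 else []
            names = sorted({system.springs[L.spring_idx[i]].name
                            for i in osc if L.spring_idx[i] >= 0})
            raise ActiveSetError(f"active set cycles without settling; "
                                 f"oscillating springs: {names or 'contacts'}")
        seen_patterns.add(pattern)
        active, k = new_active, k_new
    raise ActiveSetError(
        f"active set did not converge within {max_iterations} iterations")


def element_stress(solution: Solution, system: AssembledSystem) -> np.ndarray:
    """Per-element stress tensors as (M,3,3) arrays in the anatomical frame."""
    s = solution.stress
    T = np.zeros((s.shape[0], 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = s[:, 0], s[:, 1], s[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = s[:, 3]
    T[:, 1, 2] = T[:, 2, 1] = s[:, 4]
    T[:, 0, 2] = T[:, 2, 0] = s[:, 5]
    return T


def make_contacts(mesh: TetMesh, penalty_k: float = 1e4):
    """Compression-only penalty contacts for all unbridged fracture face
    pairs (off by default in the pipeline; interpenetration is permitted in
    the source model)."""
    contacts = []
    for pair in mesh.fracture_face_pairs.values():
        free = ~pair.bridged
        for na, nb in zip(pair.medial[free], pair.lateral[free]):
            contacts.append((int(na), int(nb), pair.axis, penalty_k))
    return contacts
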