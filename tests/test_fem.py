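"""Solver verification: element matrices, patch test, equilibrium, energy,
dense-vs-sparse oracle, cantilever benchmark and tension-only iteration."""

import itertools

import numpy as np
import pytest
import scipy.sparse as sp

import pelvifem as pf
from pelvifem import fem
from pelvifem.ligaments import ConstantStiffness, LigamentSpring

RNG = np.random.default_rng(42)

REF_TET = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def _affine_strain_energy(X, u, E, nu):
    """Independent oracle: fit the (unique) affine displacement field through
    the four nodal values, evaluate Hooke's law energy density analytically
    and multiply by the tet volume."""
    A = np.hstack([X, np.ones((4, 1))])
    coef = np.linalg.solve(A, u)          # rows: d(u)/dx, /dy, /dz, const
    G = coef[:3].T                        # displacement gradient
    eps = 0.5 * (G + G.T)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    W = 0.5 * lam * np.trace(eps) ** 2 + mu * np.sum(eps * eps)
    V = abs(np.linalg.det(X[1:] - X[0])) / 6.0
    return V * W


class TestElementStiffness:
    def test_rigid_modes_produce_zero_force(self):
        X = REF_TET + RNG.normal(0, 0.1, (4, 3))
        K = pf.element_stiffness(X, E=1000.0, nu=0.3)
        # 3 translations + 3 infinitesimal rotations
        modes = []
        for d in np.eye(3):
            modes.append(np.tile(d, 4))
        for axis in np.eye(3):
            modes.append(np.cross(np.broadcast_to(axis, (4, 3)), X).ravel())
        for m in modes:
            assert np.linalg.norm(K @ m) <= 1e-9 * np.linalg.norm(K)

    def test_energy_matches_independent_affine_oracle(self):
        for E, nu in [(1.0, 0.0), (1000.0, 0.3), (50.0, 0.45)]:
            X = REF_TET + RNG.normal(0, 0.05, (4, 3))
            K = pf.element_stiffness(X, E, nu)
            for _ in range(5):
                u = RNG.normal(0, 1, 12)
                fem_energy = 0.5 * u @ K @ u
                oracle = _affine_strain_energy(X, u.reshape(4, 3), E, nu)
                assert fem_energy == pytest.approx(oracle, rel=1e-10)

    def test_symmetric_positive_semidefinite_with_six_zero_modes(self):
        K = pf.element_stiffness(REF_TET, 1.0, 0.0)
        assert np.allclose(K, K.T)
        w = np.linalg.eigvalsh(K)
        assert np.sum(np.abs(w) < 1e-12) == 6
        assert np.all(w > -1e-12)

    def test_coordinate_scaling_scales_stiffness_linearly(self):
        K1 = pf.element_stiffness(REF_TET, 1000.0, 0.3)
        K2 = pf.element_stiffness(2.0 * REF_TET, 1000.0, 0.3)
        assert np.allclose(K2, 2.0 * K1, rtol=1e-12)

    def test_degenerate_tet_rejected(self):
        flat = REF_TET.copy()
        flat[3] = [0.5, 0.5, 0.0]
        with pytest.raises(fem.FEMError, match="degenerate"):
            pf.element_stiffness(flat, 1000.0, 0.3)


class TestAssembleAndSolve:
    def test_patch_test_reproduces_constant_strain(self, small_block,
                                                   uniform_material):
        mesh = small_block
        A = np.array([[1e-3, 2e-4, 0.0], [2e-4, -5e-4, 1e-4],
                      [0.0, 1e-4, 3e-4]])
        ids = mesh.patch("boundary")
        system = fem.assemble(mesh, uniform_material(mesh, 1000.0, 0.3),
                              prescribed=[(ids, mesh.nodes[ids] @ A.T)])
        sol = fem.solve(system)
        expected = np.array([A[0, 0], A[1, 1], A[2, 2],
                             2 * A[0, 1], 2 * A[1, 2], 2 * A[0, 2]])
        err = np.abs(sol.strain - expected[None, :]).max()
        assert err <= 1e-8 * np.abs(expected).max()

    def test_rigid_motion_produces_zero_stress(self, small_block,
                                               uniform_material):
        mesh = small_block
        W = np.array([[0.0, 1e-3, -2e-4], [-1e-3, 0.0, 5e-4],
                      [2e-4, -5e-4, 0.0]])  # skew: infinitesimal rotation
        ids = mesh.patch("boundary")
        u_bc = mesh.nodes[ids] @ W.T + np.array([0.1, -0.2, 0.05])
        system = fem.assemble(mesh, uniform_material(mesh, 1000.0, 0.3),
                              prescribed=[(ids, u_bc)])
        sol = fem.solve(system)
        assert np.abs(sol.stress).max() <= 1e-8

    def test_reactions_balance_applied_load(self, small_block,
                                            uniform_material):
        mesh = small_block
        system = fem.assemble(mesh, uniform_material(mesh),
                              fixed_patches=("left",),
                              patch_loads=[("right", [7.0, -3.0, 11.0])])
        sol = fem.solve(system)
        reactions = sol.reactions(system.fixed_nodes).sum(axis=0)
        applied = np.array([7.0, -3.0, 11.0])
        assert np.linalg.norm(reactions + applied) <= 1e-6 * np.linalg.norm(applied)

    def test_energy_identity(self, small_block, uniform_material):
        mesh = small_block
        system = fem.assemble(mesh, uniform_material(mesh),
                              fixed_patches=("left",),
                              patch_loads=[("right", [0.0, 0.0, -5.0])])
        sol = fem.solve(system)
        u_free = sol.u[system.dofmap >= 0]
        strain_energy = float(np.einsum("mi,mi->", sol.strain, sol.stress)
                              * 0) + 0.0
        # strain energy via element fields: 1/2 sum V sigma:eps
        V = mesh.volumes()
        strain_energy = 0.5 * float(np.einsum("m,mi,mi->", V, sol.stress,
                                              sol.strain))
        external_work = 0.5 * float(np.einsum("ni,ni->", sol.f_ext, sol.u))
        assert strain_energy == pytest.approx(external_work, rel=1e-8)
        del u_free

    def test_sparse_matches_dense_oracle(self, small_block, uniform_material):
        mesh = small_block
        system = fem.assemble(mesh, uniform_material(mesh),
                              fixed_patches=("left",),
                              patch_loads=[("right", [1.0, 2.0, 3.0])])
        assert system.n_free <= 500 * 3
        sol = fem.solve(system)
        K = system.K_vol.toarray()
        u_dense = np.linalg.solve(K, system.f_free)
        u_sparse = sol.u[system.dofmap >= 0]
        assert np.linalg.norm(u_sparse - u_dense) <= 1e-9 * np.linalg.norm(u_dense)

    def test_stiffness_operator_is_symmetric(self, small_block,
                                             uniform_material):
        system = fem.assemble(small_block, uniform_material(small_block),
                              fixed_patches=("left",))
        diff = (system.K_vol - system.K_vol.T)
        assert abs(diff).max() <= 1e-12 * abs(system.K_vol).max()

    def test_no_constraints_raises(self, small_block, uniform_material):
        with pytest.raises(fem.InsufficientConstraintsError):
            fem.assemble(small_block, uniform_material(small_block))

    def test_zero_load_gives_zero_solution(self, small_block,
                                           uniform_material):
        system = fem.assemble(small_block, uniform_material(small_block),
                              fixed_patches=("left",))
        sol = fem.solve(system)
        assert np.abs(sol.u).max() == 0.0
        assert np.abs(sol.stress).max() == 0.0

    def test_tie_constraints_weld_nodes(self, uniform_material):
        # two disjoint blocks tied along matching faces act as one block
        import pelvifem.mesh as pm
        a = pf.box_mesh((2.0, 1.0, 1.0), h=1.0)
        b = pf.box_mesh((2.0, 1.0, 1.0), h=1.0, origin=(2.0, 0.0, 0.0))
        nodes = np.vstack([a.nodes, b.nodes])
        tets = np.vstack([a.tets, b.tets + a.n_nodes])
        mesh = pm.TetMesh(nodes=nodes, tets=tets,
                          element_region=np.full(tets.shape[0], "box"))
        face_a = np.flatnonzero(np.abs(a.nodes[:, 0] - 2.0) < 1e-9)
        face_b_local = np.flatnonzero(np.abs(b.nodes[:, 0] - 2.0) < 1e-9)
        face_b = a.n_nodes + face_b_local
        # pair by coordinates
        order_a = np.lexsort(a.nodes[face_a].T)
        order_b = np.lexsort(b.nodes[face_b_local].T)
        mesh.tie_pairs = np.stack([face_a[order_a], face_b[order_b]], axis=1)
        mesh.surface_patches["root"] = np.flatnonzero(nodes[:, 0] < 1e-9)
        mesh.surface_patches["tip"] = np.flatnonzero(nodes[:, 0] > 4.0 - 1e-9)
        system = fem.assemble(mesh, uniform_material(mesh),
                              fixed_patches=("root",),
                              patch_loads=[("tip", [10.0, 0.0, 0.0])])
        sol = fem.solve(system)
        # tied pairs move identically
        assert np.allclose(sol.u[mesh.tie_pairs[:, 0]],
                           sol.u[mesh.tie_pairs[:, 1]])
        # and the welded bar stretches like a monolithic one
        mono = pf.box_mesh((4.0, 1.0, 1.0), h=1.0)
        mono.surface_patches["root"] = np.flatnonzero(mono.nodes[:, 0] < 1e-9)
        mono.surface_patches["tip"] = np.flatnonzero(mono.nodes[:, 0] > 4 - 1e-9)
        sysm = fem.assemble(mono, uniform_material(mono),
                            fixed_patches=("root",),
                            patch_loads=[("tip", [10.0, 0.0, 0.0])])
        solm = fem.solve(sysm)
        assert (sol.u[mesh.patch("tip"), 0].mean()
                == pytest.approx(solm.u[mono.patch("tip"), 0].mean(), rel=1e-9))


class TestStress:
    def test_uniaxial_bar_stress(self, uniform_material):
        mesh = pf.box_mesh((4.0, 2.0, 2.0), h=1.0)
        n = mesh.nodes
        mesh.surface_patches["left"] = np.flatnonzero(n[:, 0] < 1e-9)
        ids = np.arange(mesh.n_nodes)
        # prescribe uniform uniaxial strain, nu = 0: sigma = diag(E eps, 0, 0)
        eps = 1e-3
        system = fem.assemble(mesh, uniform_material(mesh, 1000.0, 0.0),
                              prescribed=[(ids, np.column_stack(
                                  [eps * n[:, 0], np.zeros(len(n)),
                                   np.zeros(len(n))]))])
        sol = fem.solve(system)
        assert np.allclose(sol.stress[:, 0], 1000.0 * eps, atol=1e-8)
        assert np.abs(sol.stress[:, 1:]).max() <= 1e-8

    def test_pure_shear_single_tet_matches_hand_value(self):
        # displacement u_x = gamma * y on one tet: sigma_xy = mu * gamma
        gamma, E_mod, nu_val = 1e-3, 1000.0, 0.25
        mu = E_mod / (2 * (1 + nu_val))
        X = REF_TET
        import pelvifem.mesh as pm
        mesh = pm.TetMesh(nodes=X, tets=np.arange(4)[None, :],
                          element_region=np.array(["t"]))
        mesh.surface_patches["all"] = np.arange(4)
        u = np.zeros((4, 3))
        u[:, 0] = gamma * X[:, 1]

        class M:
            E = np.array([1000.0])
            nu = np.array([0.25])
        system = fem.assemble(mesh, M, prescribed=[(np.arange(4), u)])
        sol = fem.solve(system)
        assert sol.stress[0, 3] == pytest.approx(mu * gamma, rel=1e-10)

    def test_element_stress_tensor_layout(self, small_block, uniform_material):
        system = fem.assemble(small_block, uniform_material(small_block),
                              fixed_patches=("left",),
                              patch_loads=[("right", [5.0, 0.0, 0.0])])
        sol = fem.solve(system)
        T = fem.element_stress(sol, system)
        assert T.shape == (small_block.n_elements, 3, 3)
        assert np.allclose(T, np.transpose(T, (0, 2, 1)))


class TestCantileverBenchmark:
    def test_tip_deflection_converges_to_beam_theory(self, uniform_material):
        L, t, P, E = 40.0, 4.0, 10.0, 1000.0
        I = t * t ** 3 / 12.0
        euler = P * L ** 3 / (3 * E * I)
        tips = []
        for h in (2.0, 1.0, 0.5):
            mesh = pf.box_mesh((L, t, t), h=h)
            n = mesh.nodes
            mesh.surface_patches["root"] = np.flatnonzero(n[:, 0] < 1e-9)
            mesh.surface_patches["tip"] = np.flatnonzero(n[:, 0] > L - 1e-9)
            system = fem.assemble(mesh, uniform_material(mesh, E, 0.0),
                                  fixed_patches=("root",),
                                  patch_loads=[("tip", [0.0, 0.0, -P])])
            sol = fem.solve(system)
            tips.append(-sol.u[mesh.patch("tip"), 2].mean())
        # monotone release of the overly stiff coarse model
        assert tips[0] < tips[1] < tips[2]
        assert abs(tips[-1] - euler) / euler <= 0.10


class TestTensionOnly:
    @staticmethod
    def _plate_with_springs(uniform_material, spring_defs, load):
        """A soft plate held by springs: spring behaviour dominates."""
        mesh = pf.box_mesh((2.0, 2.0, 1.0), h=1.0)
        n = mesh.nodes
        mesh.surface_patches["base"] = np.flatnonzero(n[:, 2] < 1e-9)
        springs = []
        for name, (a, b, k, mode) in spring_defs.items():
            rest = float(np.linalg.norm(mesh.nodes[b] - mesh.nodes[a]))
            springs.append(LigamentSpring(
                name=name, node_pairs=[(a, b)], rest_lengths=[rest],
                law=ConstantStiffness(k), tension_only=(mode == "tension")))
        system = fem.assemble(mesh, uniform_material(mesh, 1e4, 0.3),
                              springs=springs, fixed_patches=("base",),
                              patch_loads=load)
        return mesh, system

    def test_all_tension_equals_plain_solve(self, uniform_material):
        mesh = pf.box_mesh((2.0, 2.0, 2.0), h=1.0)
        n = mesh.nodes
        mesh.surface_patches["base"] = np.flatnonzero(n[:, 2] < 1e-9)
        mesh.surface_patches["top"] = np.flatnonzero(n[:, 2] > 2 - 1e-9)
        top = int(mesh.patch("top")[0])
        base = int(mesh.patch("base")[0])
        spring = LigamentSpring(
            name="s", node_pairs=[(base, top)],
            rest_lengths=[float(np.linalg.norm(n[top] - n[base]))],
            law=ConstantStiffness(100.0))
        system = fem.assemble(mesh, uniform_material(mesh), springs=[spring],
                              fixed_patches=("base",),
                              patch_loads=[("top", [0.0, 0.0, 10.0])])
        sol_iter = fem.solve_tension_only(system)
        sol_plain = fem.solve(system)
        assert sol_iter.n_iterations == 1
        assert np.allclose(sol_iter.u, sol_plain.u)
        assert sol_iter.spring_forces["s"] > 0

    def test_compressed_spring_carries_zero_force(self, uniform_material):
        mesh = pf.box_mesh((2.0, 2.0, 2.0), h=1.0)
        n = mesh.nodes
        mesh.surface_patches["base"] = np.flatnonzero(n[:, 2] < 1e-9)
        mesh.surface_patches["top"] = np.flatnonzero(n[:, 2] > 2 - 1e-9)
        top = int(mesh.patch("top")[0])
        base = int(mesh.patch("base")[0])
        spring = LigamentSpring(
            name="s", node_pairs=[(base, top)],
            rest_lengths=[float(np.linalg.norm(n[top] - n[base]))],
            law=ConstantStiffness(100.0))
        system = fem.assemble(mesh, uniform_material(mesh), springs=[spring],
                              fixed_patches=("base",),
                              patch_loads=[("top", [0.0, 0.0, -10.0])])
        sol = fem.solve_tension_only(system)
        assert sol.spring_forces["s"] == 0.0

    def test_seesaw_active_set_matches_brute_force(self, uniform_material):
        """Two opposing springs on a tilting plate: the converged active set
        must equal the unique admissible pattern found by enumerating all
        2^2 activation patterns (KKT check: active springs elongated,
        inactive springs shortened)."""
        mesh = pf.box_mesh((2.0, 2.0, 1.0), h=1.0)
        n = mesh.nodes
        mesh.surface_patches["base"] = np.flatnonzero(n[:, 2] < 1e-9)
        # corner columns at x=0 and x=2 on the top face
        top_a = int(np.flatnonzero((np.abs(n[:, 0]) < 1e-9)
                                   & (np.abs(n[:, 1] - 1) < 1e-9)
                                   & (n[:, 2] > 1 - 1e-9))[0])
        top_b = int(np.flatnonzero((np.abs(n[:, 0] - 2) < 1e-9)
                                   & (np.abs(n[:, 1] - 1) < 1e-9)
                                   & (n[:, 2] > 1 - 1e-9))[0])
        base_a = int(np.flatnonzero((np.abs(n[:, 0]) < 1e-9)
                                    & (np.abs(n[:, 1] - 1) < 1e-9)
                                    & (n[:, 2] < 1e-9))[0])
        base_b = int(np.flatnonzero((np.abs(n[:, 0] - 2) < 1e-9)
                                    & (np.abs(n[:, 1] - 1) < 1e-9)
                                    & (n[:, 2] < 1e-9))[0])
        mesh.surface_patches["edge_b"] = np.flatnonzero(
            (n[:, 0] > 2 - 1e-9) & (n[:, 2] > 1 - 1e-9))

        def build(active_pattern=None):
            springs = []
            for nm, (a, b) in [("sa", (base_a, top_a)), ("sb", (base_b, top_b))]:
                springs.append(LigamentSpring(
                    name=nm, node_pairs=[(a, b)],
                    rest_lengths=[float(np.linalg.norm(n[b] - n[a]))],
                    law=ConstantStiffness(500.0)))
            return fem.assemble(
                mesh, uniform_material(mesh, 1e3, 0.3), springs=springs,
                fixed_patches=("base",),
                # pull the b-edge up: sb stretches, sa goes slack as the
                # plate tilts
                patch_loads=[("edge_b", [0.0, 0.0, 50.0])])

        system = build()
        sol = fem.solve_tension_only(system)
        converged = tuple(bool(x) for x in sol.active_links)

        # brute force: enumerate activation patterns, keep admissible ones
        admissible = []
        for pattern in itertools.product([False, True], repeat=2):
            K = system.K_vol + fem._link_matrix(
                system, np.array(pattern), system.links.k)
            u_free = sp.linalg.spsolve(K.tocsc(), system.f_free)
            delta = fem._link_deltas(system, fem._expand(system, u_free))
            ok = all((d >= -1e-10 if act else d <= 1e-10)
                     for act, d in zip(pattern, delta))
            if ok:
                admissible.append(pattern)
        assert admissible == [converged]
        assert min(sol.spring_forces.values()) >= 0.0
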