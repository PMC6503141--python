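"""Tetrahedral FE assembly, solvers and stress recovery."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla
import sympy

from bonedyn import fem
from bonedyn.fixtures import make_beam_fixture
from bonedyn.materials import MaterialField, MaterialLaw
from bonedyn.mesh import MeshQualityError, TetMesh


def _unit_tet_mesh():
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
    mesh = TetMesh(nodes, np.array([[0, 1, 2, 3]]))
    return mesh


def _uniform(mesh, E, nu=0.0, rho=1940.0):
    law = MaterialLaw(poisson=nu, mass_density=rho, e_floor=min(1e6, E))
    return MaterialField.uniform(mesh.n_nodes, E, law)


def _sympy_unit_tet_stiffness(E_val=1.0, nu_val=0.0):
    """Exact symbolic element stiffness of the unit tetrahedron.

    Independent oracle: symbolic shape functions, exact integration of
    B^T C B over the element volume.
    """
    x, y, z = sympy.symbols("x y z")
    shapes = [1 - x - y - z, x, y, z]
    grads = [[sympy.diff(N, v) for v in (x, y, z)] for N in shapes]
    B = sympy.zeros(6, 12)
    for a in range(4):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c], B[3, c + 1] = gy, gx
        B[4, c + 1], B[4, c + 2] = gz, gy
        B[5, c], B[5, c + 2] = gz, gx
    E, nu = sympy.Rational(E_val), sympy.Rational(nu_val)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = sympy.zeros(6, 6)
    for i in range(3):
        for j in range(3):
            C[i, j] = lam
        C[i, i] += 2 * mu
        C[3 + i, 3 + i] = mu
    V = sympy.Rational(1, 6)
    return np.array((V * B.T * C * B).evalf(), dtype=float)


class TestAssembly:
    def test_unit_tet_stiffness_matches_symbolic_oracle(self):
        mesh = _unit_tet_mesh()
        asm = fem.assemble(mesh, _uniform(mesh, 1.0, nu=0.0))
        K_exact = _sympy_unit_tet_stiffness(1.0, 0.0)
        assert np.allclose(asm.K.toarray(), K_exact, atol=1e-14)

    def test_unconstrained_stiffness_has_six_rigid_modes(self, beam_small):
        _, _, asm = beam_small
        w = np.sort(np.abs(spla.eigsh(asm.K.tocsc(), k=8, sigma=-100.0,
                                      which="LM",
                                      return_eigenvectors=False)))
        scale = np.abs(asm.K.diagonal()).max()
        assert np.all(w[:6] < 1e-8 * scale)
        assert w[6] > 1e-4 * scale

    def test_consistent_mass_conserves_total_mass(self, beam_small):
        mesh, field, asm = beam_small
        total = mesh.volumes.sum() * field.law.mass_density
        for comp in range(3):
            t = np.zeros(asm.n_dofs)
            t[comp::3] = 1.0
            assert t @ (asm.M @ t) == pytest.approx(total, rel=1e-12)

    def test_inverted_element_rejected_with_element_id(self):
        mesh = _unit_tet_mesh()
        mesh.nodes[3, 2] = 0.0  # flatten -> zero volume
        with pytest.raises(MeshQualityError, match="element 0"):
            fem.assemble(mesh, _uniform(mesh, 1.0))

    def test_symmetry(self, beam_small):
        _, _, asm = beam_small
        assert (asm.K - asm.K.T).toarray() == pytest.approx(0.0, abs=1e-18)
        assert (asm.M - asm.M.T).toarray() == pytest.approx(0.0, abs=1e-24)


class TestCouplings:
    def test_radius_selection_matches_brute_force(self, femur_coarse):
        _, mesh, _ = femur_coarse
        point = mesh.landmarks["head_center"]
        c = fem.make_coupling(mesh, point, radius=0.012)
        brute = np.where(np.linalg.norm(mesh.nodes - point, axis=1)
                         <= 0.012)[0]
        assert np.array_equal(np.sort(c.nodes), brute)

    def test_single_node_and_whole_mesh_selection(self, beam_small):
        mesh, _, _ = beam_small
        c1 = fem.make_coupling(mesh, mesh.nodes[0], radius=1e-6)
        assert np.array_equal(c1.nodes, [0])
        call = fem.make_coupling(mesh, mesh.nodes.mean(0), radius=10.0)
        assert len(call.nodes) == mesh.n_nodes
        assert np.allclose(call.weights, 1.0 / mesh.n_nodes)

    def test_empty_selection_suggests_radius(self, beam_small):
        mesh, _, _ = beam_small
        with pytest.raises(ValueError, match="radius"):
            fem.make_coupling(mesh, [10.0, 0, 0], radius=1e-4)

    def test_distributing_spread_is_statically_equivalent(self, beam_small):
        mesh, _, _ = beam_small
        c = fem.Coupling("tip", mesh.landmarks["tip_center"],
                         mesh.node_sets["tip"], mode="distributing")
        F = np.array([3.0, -2.0, 5.0])
        M = np.array([0.4, 0.1, -0.2])
        f = fem.spread_wrench(c, mesh, F, M)
        assert np.allclose(f.sum(axis=0), F, atol=1e-12)
        r = mesh.nodes[c.nodes] - c.reference_point
        assert np.allclose(np.cross(r, f).sum(axis=0), M, atol=1e-12)


class TestStatics:
    def test_zero_load_and_linearity(self, beam_system):
        f0 = beam_system.force_vector()
        q, u = beam_system.solve_static(f0)
        assert np.allclose(u, 0.0)
        f1 = beam_system.force_vector(
            wrenches={"tip": ([0, 0, -10.0], [0, 0, 0])})
        _, u1 = beam_system.solve_static(f1)
        _, u2 = beam_system.solve_static(2 * f1)
        assert np.allclose(u2, 2 * u1, rtol=1e-12, atol=1e-18)

    def test_patch_test_exact_on_perturbed_mesh(self):
        mesh, field = make_beam_fixture(3, 3, 3, dims=(0.03, 0.03, 0.03),
                                        E=5e9, nu=0.3)
        n = mesh.nodes
        boundary = np.where(
            np.isclose(n[:, 0], 0) | np.isclose(n[:, 0], 0.03)
            | np.isclose(np.abs(n[:, 1]), 0.015)
            | np.isclose(np.abs(n[:, 2]), 0.015))[0]
        interior = np.setdiff1d(np.arange(mesh.n_nodes), boundary)
        rng = np.random.default_rng(0)
        mesh.nodes[interior] += rng.uniform(-1e-3, 1e-3, (len(interior), 3))
        asm = fem.assemble(mesh, field)
        A = np.array([[1e-3, 2e-4, 0], [2e-4, -5e-4, 1e-4], [0, 1e-4, 3e-4]])
        u_exact = mesh.nodes @ A.T
        bdofs = fem.node_dofs(boundary)
        system = fem.SystemModel(asm, fixed_dofs=bdofs,
                                 prescribed_values=u_exact.ravel()[bdofs])
        _, u = system.solve_static(np.zeros(system.n_q))
        assert np.abs(u - u_exact.ravel()).max() < 1e-15
        res = fem.recover_stress(asm, u)
        assert np.abs(res.strain - res.strain[0]).max() < 1e-12

    def test_betti_reciprocity(self, beam_small):
        mesh, _, asm = beam_small
        clamp = fem.node_dofs(mesh.node_sets["clamp"])
        system = fem.SystemModel(asm, fixed_dofs=clamp)
        free = np.setdiff1d(np.arange(mesh.n_nodes), mesh.node_sets["clamp"])
        na, nb = int(free[5]), int(free[-3])
        _, ua = system.solve_static(
            system.force_vector(nodal_forces={na: [0, 0, 1.0]}))
        _, ub = system.solve_static(
            system.force_vector(nodal_forces={nb: [0, 1.0, 0]}))
        work_ab = ua[3 * nb + 1]  # u_y at B due to unit F_z at A
        work_ba = ub[3 * na + 2]  # u_z at A due to unit F_y at B
        assert work_ab == pytest.approx(work_ba, rel=1e-8, abs=1e-20)

    def test_cantilever_matches_beam_theory_within_5_percent(self):
        E, dims = 10e9, (0.10, 0.01, 0.01)
        mesh, field = make_beam_fixture(100, 4, 16, dims=dims, E=E, nu=0.0)
        asm = fem.assemble(mesh, field)
        system = fem.SystemModel(
            asm,
            couplings=[fem.Coupling("tip", mesh.landmarks["tip_center"],
                                    mesh.node_sets["tip"])],
            fixed_dofs=fem.node_dofs(mesh.node_sets["clamp"]))
        P = 10.0
        _, u = system.solve_static(system.force_vector(
            wrenches={"tip": ([0, 0, -P], [0, 0, 0])}))
        tip = system.coupling_displacement("tip", u)[2]
        L, b, h = dims
        I = b * h ** 3 / 12
        G = E / 2  # nu = 0
        delta = P * L ** 3 / (3 * E * I) + P * L / (5 / 6 * G * b * h)
        assert -tip == pytest.approx(delta, rel=0.05)

    def test_mesh_convergence_toward_beam_theory(self):
        """Refinement loop mirrors the 5%-change convergence procedure."""
        E, dims = 10e9, (0.10, 0.01, 0.01)
        P = 10.0
        tips = []
        for (nx, ny, nz) in [(25, 2, 4), (50, 3, 8), (100, 4, 16)]:
            mesh, field = make_beam_fixture(nx, ny, nz, dims=dims, E=E, nu=0.0)
            asm = fem.assemble(mesh, field)
            system = fem.SystemModel(
                asm,
                couplings=[fem.Coupling("tip", mesh.landmarks["tip_center"],
                                        mesh.node_sets["tip"])],
                fixed_dofs=fem.node_dofs(mesh.node_sets["clamp"]))
            _, u = system.solve_static(system.force_vector(
                wrenches={"tip": ([0, 0, -P], [0, 0, 0])}))
            tips.append(-system.coupling_displacement("tip", u)[2])
        L, b, h = dims
        I = b * h ** 3 / 12
        delta = P * L ** 3 / (3 * E * I) + P * L / (5 / 6 * (E / 2) * b * h)
        errs = [abs(t - delta) / delta for t in tips]
        assert errs[0] > errs[1] > errs[2]  # monotone convergence
        changes = [abs(tips[i + 1] - tips[i]) / tips[i + 1] for i in range(2)]
        assert changes[1] < changes[0]  # refinement change shrinks


class TestStressRecovery:
    def test_rigid_motion_gives_zero_stress(self, beam_small):
        mesh, _, asm = beam_small
        t = np.array([1e-3, -2e-3, 5e-4])
        w = np.array([2e-3, 1e-3, -3e-3])  # small rotation vector
        u = (t[None, :] + np.cross(np.broadcast_to(w, mesh.nodes.shape),
                                   mesh.nodes)).ravel()
        res = fem.recover_stress(asm, u)
        assert np.abs(res.strain).max() < 1e-12
        assert np.abs(res.von_mises).max() < 1e-3  # Pa round-off at E=10 GPa

    def test_uniaxial_strain_constitutive_identity(self):
        mesh, field = make_beam_fixture(3, 2, 2, E=7e9, nu=0.0)
        asm = fem.assemble(mesh, field)
        eps0 = 1e-4
        u = np.zeros((mesh.n_nodes, 3))
        u[:, 0] = eps0 * mesh.nodes[:, 0]
        res = fem.recover_stress(asm, u.ravel())
        assert np.allclose(res.stress[:, 0], 7e9 * eps0, rtol=1e-12)
        assert np.abs(res.stress[:, 1:]).max() < 1e-6

    def test_pure_shear_von_mises(self):
        mesh, field = make_beam_fixture(2, 2, 2, E=7e9, nu=0.3)
        asm = fem.assemble(mesh, field)
        gamma = 2e-4
        u = np.zeros((mesh.n_nodes, 3))
        u[:, 0] = gamma * mesh.nodes[:, 1]
        res = fem.recover_stress(asm, u.ravel())
        mu = 7e9 / (2 * 1.3)
        tau = mu * gamma
        assert np.allclose(res.von_mises, np.sqrt(3) * tau, rtol=1e-12)

    def test_von_mises_closed_form(self):
        sig = np.array([[0, 0, 0, 5.0, 0, 0]])
        assert fem.von_mises(sig)[0] == pytest.approx(np.sqrt(3) * 5.0)
        hydro = np.array([[4.0, 4.0, 4.0, 0, 0, 0]])
        assert fem.von_mises(hydro)[0] == pytest.approx(0.0, abs=1e-12)


class TestNewmark:
    def test_sdof_sinusoid_matches_analytic_solution(self):
        m, k = 2.0, 800.0
        om_f = 5.0  # forcing rad/s, well below resonance (20 rad/s)
        F0 = 3.0
        amp = F0 / (k - m * om_f ** 2)
        T = 2 * np.pi / om_f
        dt = T / 100
        M = np.array([[m]])
        K = np.array([[k]])
        q0, v0 = np.array([0.0]), np.array([amp * om_f])  # particular ICs
        Q, _, _ = fem.newmark(M, None, K, lambda t: np.array(
            [F0 * np.sin(om_f * t)]), dt, 300, q0=q0, v0=v0)
        t = dt * np.arange(301)
        exact = amp * np.sin(om_f * t)
        assert np.abs(Q[:, 0] - exact).max() < 0.01 * abs(amp)

    def test_undamped_energy_conservation(self, beam_system):
        K, M = beam_system.K, beam_system.M
        f1 = fem.natural_frequencies(K, M, k=1)[0]
        T1 = 1.0 / f1
        rng = np.random.default_rng(1)
        q0 = np.zeros(beam_system.n_q)
        # static deflection as initial displacement
        fq = beam_system.force_vector(
            wrenches={"tip": ([0, 0, -5.0], [0, 0, 0])})
        q0 = spla.spsolve(K.tocsc(), fq)
        n = 500
        dt = 10 * T1 / n
        Q, V, _ = fem.newmark(M, None, K, lambda t: np.zeros_like(q0), dt, n,
                              q0=q0)
        E = 0.5 * np.einsum("ti,ti->t", V, (M @ V.T).T) \
            + 0.5 * np.einsum("ti,ti->t", Q, (K @ Q.T).T)
        assert np.abs(E - E[0]).max() / E[0] < 1e-6

    def test_quasi_static_ramp_matches_static_limit(self, beam_system):
        wr = ([0, 0, -10.0], [0, 0, 0])
        f_static = beam_system.force_vector(wrenches={"tip": wr})
        _, u_static = beam_system.solve_static(f_static)
        f1 = fem.natural_frequencies(beam_system.K, beam_system.M, k=1)[0]
        t_ramp = 200.0 / f1  # very slow vs first period
        t = np.linspace(0, t_ramp, 81)
        w = np.zeros((len(t), 6))
        w[:, 2] = -10.0 * np.minimum(t / (0.8 * t_ramp), 1.0)
        hist = fem.LoadHistory(t, {"tip": w})
        times, U = fem.solve_dynamic(beam_system, hist, dt=t_ramp / 400,
                                     zeta=0.025, initial="rest")
        err = np.linalg.norm(U[-1] - u_static) / np.linalg.norm(u_static)
        assert err < 1e-3

    def test_invalid_inputs(self, beam_system):
        with pytest.raises(ValueError, match="dt"):
            fem.newmark(beam_system.M, None, beam_system.K,
                        lambda t: np.zeros(beam_system.n_q), -0.1, 2)
        with pytest.raises(ValueError, match="increasing"):
            fem.LoadHistory(np.array([0.0, 0.5, 0.4]),
                            {"tip": np.zeros((3, 6))})
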