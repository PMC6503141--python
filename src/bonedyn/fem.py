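"""Inhomogeneous isotropic linear-elastic tetrahedral finite elements.

Assembly uses 4-node constant-strain tetrahedra with a per-element Young's
modulus (arithmetic mean of the element's nodal moduli) and a consistent mass
matrix. Reference-point couplings connect 6-DoF masters to node patches:

* ``kinematic`` -- the patch moves rigidly with the master (master-slave
  elimination); these are the interfaces promoted to superelement boundary
  coordinates.
* ``distributing`` -- the master only spreads an applied wrench over the
  patch as the minimum-weighted-norm nodal force system that is statically
  equivalent to it; no kinematic constraint is imposed.

All quantities are SI (m, kg, s, Pa, N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import MaterialField
from .mesh import TetMesh


# ---------------------------------------------------------------------------
# element matrices


def elasticity_matrix(E, nu):
    """Isotropic 6x6 elasticity matrix (engineering shear strains)."""
    E = np.atleast_1d(np.asarray(E, dtype=float))
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros(E.shape + (6, 6))
    for i in range(3):
        for j in range(3):
            C[..., i, j] = lam
        C[..., i, i] += 2 * mu
        C[..., 3 + i, 3 + i] = mu
    return C


def shape_gradients(mesh: TetMesh):
    """Constant shape-function gradients per element: (E, 3, 4), and volumes."""
    X = mesh.nodes[mesh.elements]  # (E, 4, 3)
    A = np.concatenate([np.ones(X.shape[:2] + (1,)), X], axis=2)  # (E, 4, 4)
    G = np.linalg.inv(A)  # columns: shape-function coefficients
    grads = G[:, 1:4, :]  # (E, 3, 4): d N_a / d x_i
    vols = np.abs(np.linalg.det(A)) / 6.0
    return grads, vols


def strain_displacement_matrices(mesh: TetMesh):
    """B matrices (E, 6, 12) mapping element DoFs to strain 6-vectors."""
    grads, vols = shape_gradients(mesh)
    E = mesh.n_elements
    B = np.zeros((E, 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, 0, a], grads[:, 1, a], grads[:, 2, a]
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
    return B, vols


@dataclass
class FEAssembly:
    """Sparse stiffness/mass operators plus the per-element recovery data."""

    mesh: TetMesh
    material: MaterialField
    K: sp.csr_matrix
    M: sp.csr_matrix
    B: np.ndarray  # (E, 6, 12)
    C: np.ndarray  # (E, 6, 6) elasticity matrices
    volumes: np.ndarray

    @property
    def n_dofs(self) -> int:
        return 3 * self.mesh.n_nodes

    def element_dofs(self) -> np.ndarray:
        e = self.mesh.elements
        return (3 * e[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)


def assemble(mesh: TetMesh, material: MaterialField) -> FEAssembly:
    """Assemble sparse stiffness and consistent mass for the whole mesh."""
    if len(material.node_modulus) != mesh.n_nodes:
        raise ValueError("material field node count does not match mesh")
    mesh.orient().validate()
    B, vols = strain_displacement_matrices(mesh)
    elem_E = material.element_modulus(mesh)
    C = elasticity_matrix(elem_E, material.law.poisson)
    Ke = np.einsum("e,eki,ekl,elj->eij", vols, B, C, B, optimize=True)

    rho = material.law.mass_density
    mpat = (np.ones((4, 4)) + np.eye(4)) / 20.0
    Me_n = rho * vols[:, None, None] * mpat  # (E, 4, 4) per-coordinate
    Me = np.zeros((mesh.n_elements, 12, 12))
    for c in range(3):
        Me[:, c::3, c::3] = Me_n

    edofs = (3 * mesh.elements[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(edofs, 12, axis=1).ravel()
    cols = np.tile(edofs, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    M = sp.coo_matrix((Me.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    K = (K + K.T) * 0.5  # symmetrize round-off
    M = (M + M.T) * 0.5
    return FEAssembly(mesh, material, K, M, B, C, vols)


# ---------------------------------------------------------------------------
# couplings


@dataclass
class Coupling:
    """A 6-DoF reference point tied to a patch of mesh nodes."""

    name: str
    reference_point: np.ndarray
    nodes: np.ndarray
    mode: str = "kinematic"  # or "distributing"
    weights: np.ndarray = None

    def __post_init__(self):
        self.reference_point = np.asarray(self.reference_point, dtype=float)
        self.nodes = np.asarray(self.nodes, dtype=np.intp)
        if self.nodes.size == 0:
            raise ValueError(f"coupling {self.name!r} has an empty node patch")
        if self.mode not in ("kinematic", "distributing"):
            raise ValueError("mode must be 'kinematic' or 'distributing'")
        if self.weights is None:
            self.weights = np.full(len(self.nodes), 1.0 / len(self.nodes))
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights < 0):
                raise ValueError("distributing weights must be nonnegative")
            self.weights = self.weights / self.weights.sum()


def make_coupling(
    mesh: TetMesh, point, radius: float = 0.005, mode: str = "kinematic",
    name: str = None,
) -> Coupling:
    """Couple all nodes within ``radius`` of ``point`` to a reference point.

    The 0.005 m default mirrors attachment-site patches of roughly half a
    centimetre radius.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    nodes = mesh.nodes_within(point, radius)
    if nodes.size == 0:
        raise ValueError(
            f"no nodes within {radius} m of {np.asarray(point)}; increase the radius"
        )
    return Coupling(name or "coupling", point, nodes, mode)


def _skew(v):
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])


def spread_wrench(coupling: Coupling, mesh: TetMesh, force, moment):
    """Statically equivalent nodal forces for a wrench at the reference point.

    Minimum weighted-norm solution ``f_i = w_i (lam + mu x r_i)`` with the
    6 equivalence conditions sum(f) = F and sum(r x f) = M.
    """
    r = mesh.nodes[coupling.nodes] - coupling.reference_point
    w = coupling.weights
    S = np.zeros((6, 6))
    W = w.sum()
    swr = np.einsum("i,ij->j", w, r)
    S[:3, :3] = W * np.eye(3)
    S[:3, 3:] = -_skew(swr)
    S[3:, :3] = _skew(swr)
    # sum_i w_i S(r_i) S(r_i)^T  (moment from mu x r_i term)
    rr = np.einsum("i,ij,ik->jk", w, r, r)
    S[3:, 3:] = np.trace(rr) * np.eye(3) - rr
    rhs = np.concatenate([np.asarray(force, dtype=float),
                          np.asarray(moment, dtype=float)])
    lam_mu = np.linalg.lstsq(S, rhs, rcond=None)[0]
    lam, mu = lam_mu[:3], lam_mu[3:]
    f = w[:, None] * (lam[None, :] + np.cross(mu[None, :], r))
    return f  # (len(nodes), 3)


# ---------------------------------------------------------------------------
# generalized-coordinate system


def node_dofs(nodes) -> np.ndarray:
    nodes = np.asarray(nodes, dtype=np.intp)
    return (3 * nodes[:, None] + np.arange(3)[None, :]).ravel()


class SystemModel:
    """FE model in generalized coordinates q = [retained node DoFs, masters].

    Kinematic-coupling patches are eliminated (slave DoFs follow their 6-DoF
    master rigidly); fixed DoFs may carry prescribed displacement values
    (inhomogeneous Dirichlet). Distributing couplings do not constrain.
    """

    def __init__(self, assembly: FEAssembly, couplings=(), fixed_dofs=None,
                 prescribed_values=None):
        self.assembly = assembly
        self.couplings = {c.name: c for c in couplings}
        n = assembly.n_dofs
        fixed_dofs = (np.asarray(fixed_dofs, dtype=np.intp)
                      if fixed_dofs is not None else np.empty(0, dtype=np.intp))
        self.u_prescribed = np.zeros(n)
        if prescribed_values is not None:
            self.u_prescribed[fixed_dofs] = prescribed_values

        kin = [c for c in couplings if c.mode == "kinematic"]
        slave_nodes = (np.concatenate([c.nodes for c in kin])
                       if kin else np.empty(0, dtype=np.intp))
        if len(np.unique(slave_nodes)) != len(slave_nodes):
            raise ValueError("kinematic coupling patches overlap")
        slave_dofs = node_dofs(slave_nodes) if slave_nodes.size else slave_nodes
        if np.intersect1d(slave_dofs, fixed_dofs).size:
            raise ValueError("a fixed DoF cannot also be a kinematic slave")

        eliminated = np.union1d(slave_dofs, fixed_dofs)
        self.free_dofs = np.setdiff1d(np.arange(n), eliminated)
        nq = len(self.free_dofs) + 6 * len(kin)

        rows = [self.free_dofs]
        cols = [np.arange(len(self.free_dofs))]
        vals = [np.ones(len(self.free_dofs))]
        self.master_index = {}
        off = len(self.free_dofs)
        for c in kin:
            qi = np.arange(off, off + 6)
            self.master_index[c.name] = qi
            r = assembly.mesh.nodes[c.nodes] - c.reference_point  # (m, 3)
            m = len(c.nodes)
            # u_node = u_m + theta x r  =>  d u / d theta = -skew(r)
            dofs = node_dofs(c.nodes).reshape(m, 3)
            for k in range(3):
                rows.append(dofs[:, k])
                cols.append(np.full(m, qi[k]))
                vals.append(np.ones(m))
            sk = np.stack([-_skew(ri) for ri in r])  # (m, 3, 3)
            for k in range(3):  # rotation components
                rows.append(dofs.ravel())
                cols.append(np.full(3 * m, qi[3 + k]))
                vals.append(sk[:, :, k].ravel())
            off += 6
        self.T = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, nq),
        ).tocsr()
        self.K = (self.T.T @ assembly.K @ self.T).tocsr()
        self.M = (self.T.T @ assembly.M @ self.T).tocsr()
        self.n_q = nq

    # -- loads -------------------------------------------------------------

    def force_vector(self, wrenches=None, nodal_forces=None) -> np.ndarray:
        """Generalized force vector from master wrenches and nodal loads.

        ``wrenches`` maps coupling name -> (force 3-vec, moment 3-vec);
        ``nodal_forces`` maps node index -> force 3-vec.
        """
        f_full = np.zeros(self.assembly.n_dofs)
        f_q = np.zeros(self.n_q)
        if wrenches:
            for name, (F, Mm) in wrenches.items():
                c = self.couplings[name]
                if c.mode == "kinematic":
                    f_q[self.master_index[name][:3]] += np.asarray(F, dtype=float)
                    f_q[self.master_index[name][3:]] += np.asarray(Mm, dtype=float)
                else:
                    fn = spread_wrench(c, self.assembly.mesh, F, Mm)
                    np.add.at(f_full, node_dofs(c.nodes).reshape(-1, 3), fn)
        if nodal_forces:
            for node, F in nodal_forces.items():
                f_full[3 * node: 3 * node + 3] += np.asarray(F, dtype=float)
        return f_q + self.T.T @ f_full

    def _dirichlet_force(self) -> np.ndarray:
        if np.any(self.u_prescribed):
            return -(self.T.T @ (self.assembly.K @ self.u_prescribed))
        return np.zeros(self.n_q)

    # -- solves ------------------------------------------------------------

    def solve_static(self, f_q: np.ndarray, constraint=None):
        """Solve K q = f; returns (q, u_full). ``constraint`` is a
        :class:`MasterConstraint` restricting master DoFs."""
        f = f_q + self._dirichlet_force()
        if constraint is not None:
            P = constraint.basis(self)
            Kc = (P.T @ self.K @ P).tocsc()
            qc = _spsolve_sym(Kc, P.T @ f)
            q = P @ qc
        else:
            q = _spsolve_sym(self.K.tocsc(), f)
        return q, self.expand(q)

    def expand(self, q: np.ndarray) -> np.ndarray:
        """Full nodal displacement vector from generalized coordinates."""
        return self.T @ q + self.u_prescribed

    def coupling_displacement(self, name: str, u_full: np.ndarray) -> np.ndarray:
        """Translation of a coupling's reference point (weighted patch mean
        for distributing couplings)."""
        c = self.couplings[name]
        if c.mode == "kinematic":
            # rigid patch: best-fit rigid motion recovers the master translation
            return _fit_rigid_translation(
                self.assembly.mesh.nodes[c.nodes], c.reference_point,
                u_full[node_dofs(c.nodes).reshape(-1, 3)])
        disp = u_full[node_dofs(c.nodes)].reshape(-1, 3)
        return np.einsum("i,ij->j", c.weights, disp)


def _fit_rigid_translation(pts, ref, disp):
    """Reference-point translation of the best-fit rigid motion of a patch."""
    n = len(pts)
    A = np.zeros((3 * n, 6))
    A[:, :3] = np.tile(np.eye(3), (n, 1))
    for i, p in enumerate(pts):
        A[3 * i: 3 * i + 3, 3:] = -_skew(p - ref)
    sol = np.linalg.lstsq(A, disp.ravel(), rcond=None)[0]
    return sol[:3]


def _spsolve_sym(K, f):
    # sparse LU with one round of iterative refinement: the nodal moduli can
    # span 4+ orders of magnitude, and refinement recovers the last digits
    try:
        lu = spla.splu(K.tocsc())
    except RuntimeError as err:  # pragma: no cover - singular factorization
        raise np.linalg.LinAlgError(
            f"singular system (constraint deficiency?): {err}")
    x = lu.solve(f)
    x += lu.solve(f - K @ x)
    return x


class MasterConstraint:
    """Restriction of master DoFs: fix components and/or lock a translation
    direction (the 'load line' support used in the sideways-fall test).

    Parameters
    ----------
    fixed : dict name -> iterable of local DoF ids (0-5) or "all"
    direction_locks : dict name -> 3-vector d; removes the translation
        component along d (the master may slide transverse to d only when
        combined with ``fixed``; on its own it locks motion along d).
    """

    def __init__(self, fixed=None, direction_locks=None):
        self.fixed = fixed or {}
        self.direction_locks = direction_locks or {}

    def basis(self, system_or_map, n_q=None) -> sp.csr_matrix:
        """Sparse basis P with q = P q_c spanning the admissible subspace."""
        if n_q is None:
            master_index = system_or_map.master_index
            n_q = system_or_map.n_q
        else:
            master_index = system_or_map
        drop = set()
        rot_blocks = {}  # first translation q-dof -> 3x(<3) basis
        for name, comps in self.fixed.items():
            ids = range(6) if comps == "all" else comps
            for k in ids:
                drop.add(int(master_index[name][k]))
        for name, d in self.direction_locks.items():
            d = np.asarray(d, dtype=float)
            d = d / np.linalg.norm(d)
            # orthonormal complement of d
            Q = sla.null_space(d[None, :])
            tdofs = master_index[name][:3]
            if any(int(t) in drop for t in tdofs):
                raise ValueError("direction lock overlaps fixed translation DoFs")
            rot_blocks[int(tdofs[0])] = (tdofs.astype(int), Q)

        cols = []
        data_rows, data_cols, data_vals = [], [], []
        c = 0
        skip = set(drop)
        for blk_dofs, _ in rot_blocks.values():
            skip.update(int(t) for t in blk_dofs)
        for i in range(n_q):
            if i in skip:
                continue
            data_rows.append(i)
            data_cols.append(c)
            data_vals.append(1.0)
            c += 1
        for blk_dofs, Q in rot_blocks.values():
            for j in range(Q.shape[1]):
                for k in range(3):
                    data_rows.append(int(blk_dofs[k]))
                    data_cols.append(c)
                    data_vals.append(Q[k, j])
                c += 1
        return sp.coo_matrix((data_vals, (data_rows, data_cols)),
                             shape=(n_q, c)).tocsr()


# ---------------------------------------------------------------------------
# load cases


@dataclass
class StaticLoadCase:
    """Wrenches on couplings plus optional raw nodal forces."""

    wrenches: dict = field(default_factory=dict)  # name -> (F, M)
    nodal_forces: dict = field(default_factory=dict)
    constraint: MasterConstraint = None


@dataclass
class LoadHistory:
    """Sampled wrench histories per coupling, linearly interpolated in time."""

    times: np.ndarray
    wrenches: dict  # name -> (nt, 6) array [Fx Fy Fz Mx My Mz]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, w in self.wrenches.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (len(self.times), 6):
                raise ValueError(f"wrench history {name!r} has wrong shape")
            self.wrenches[name] = w

    def force_matrix(self, system) -> np.ndarray:
        """(n_q, nt) generalized force samples."""
        F = np.zeros((system.n_q, len(self.times)))
        for k in range(len(self.times)):
            F[:, k] = system.force_vector(
                wrenches={n: (w[k, :3], w[k, 3:]) for n, w in self.wrenches.items()}
            )
        return F

    def interpolator(self, F: np.ndarray):
        t = self.times

        def f(tq):
            tq = np.clip(tq, t[0], t[-1])
            i = np.searchsorted(t, tq, side="right") - 1
            i = min(max(i, 0), len(t) - 2)
            a = (tq - t[i]) / (t[i + 1] - t[i])
            return (1 - a) * F[:, i] + a * F[:, i + 1]

        return f


# ---------------------------------------------------------------------------
# Newmark time integration


def newmark(M, C, K, f, dt, n_steps, q0=None, v0=None, beta=0.25, gamma=0.5):
    """Implicit Newmark integration (constant average acceleration default).

    ``f`` is a callable t -> load vector. Returns displacement, velocity and
    acceleration arrays of shape (n_steps + 1, n).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = M.shape[0]
    q = np.zeros(n) if q0 is None else np.array(q0, dtype=float)
    v = np.zeros(n) if v0 is None else np.array(v0, dtype=float)
    if C is None:
        C = sp.csr_matrix((n, n)) if sp.issparse(K) else np.zeros((n, n))

    solve_M = _factorize(M)
    a = solve_M(np.asarray(f(0.0)) - C @ v - K @ q)

    c0 = 1.0 / (beta * dt * dt)
    c1 = gamma / (beta * dt)
    c2 = 1.0 / (beta * dt)
    c3 = 1.0 / (2 * beta) - 1.0
    c4 = gamma / beta - 1.0
    c5 = dt * (gamma / (2 * beta) - 1.0)

    Keff = K + c0 * M + c1 * C
    solve = _factorize(Keff)

    Q = np.empty((n_steps + 1, n))
    V = np.empty_like(Q)
    A = np.empty_like(Q)
    Q[0], V[0], A[0] = q, v, a
    for k in range(1, n_steps + 1):
        t = k * dt
        rhs = (np.asarray(f(t))
               + M @ (c0 * q + c2 * v + c3 * a)
               + C @ (c1 * q + c4 * v + c5 * a))
        q1 = solve(rhs)
        a1 = c0 * (q1 - q) - c2 * v - c3 * a
        v1 = v + dt * ((1 - gamma) * a + gamma * a1)
        q, v, a = q1, v1, a1
        Q[k], V[k], A[k] = q, v, a
    return Q, V, A


def _factorize(A):
    if sp.issparse(A):
        lu = spla.splu(A.tocsc())
        return lu.solve
    lu, piv = sla.lu_factor(np.asarray(A))
    return lambda b: sla.lu_solve((lu, piv), b)


def rayleigh_stiffness_coefficient(K, M, zeta: float) -> float:
    """Stiffness-proportional Rayleigh coefficient matched to ``zeta`` at the
    first flexible natural frequency of (K, M)."""
    w2 = spla.eigsh(K.tocsc(), k=1, M=M.tocsc(), sigma=0, which="LM",
                    v0=np.ones(K.shape[0]), return_eigenvectors=False)
    w1 = float(np.sqrt(np.abs(w2[0])))
    return 2.0 * zeta / w1


def solve_dynamic(system: SystemModel, history: LoadHistory, dt: float,
                  t_end: float = None, zeta: float = 0.025,
                  constraint: MasterConstraint = None,
                  initial: str = "static"):
    """Direct transient solve of the (constrained) full model.

    Damping is stiffness-proportional Rayleigh matched to ``zeta`` at the
    first flexible frequency. ``initial`` is ``"static"`` (equilibrium with
    the t=0 load) or ``"rest"``. Returns (times, U_full) with U_full rows
    being full nodal displacement vectors.
    """
    t_end = history.times[-1] if t_end is None else t_end
    n_steps = int(round(t_end / dt))
    F = history.force_matrix(system)
    fq = history.interpolator(F)
    K, M = system.K, system.M
    if constraint is not None:
        P = constraint.basis(system)
        K = (P.T @ K @ P).tocsr()
        M = (P.T @ M @ P).tocsr()
        fc = lambda t: P.T @ fq(t)
    else:
        P = None
        fc = fq
    aK = rayleigh_stiffness_coefficient(K, M, zeta) if zeta > 0 else 0.0
    C = aK * K
    q0 = _spsolve_sym(K.tocsc(), fc(0.0)) if initial == "static" else None
    Q, _, _ = newmark(M, C, K, fc, dt, n_steps, q0=q0)
    times = dt * np.arange(n_steps + 1)
    if P is not None:
        Q = (P @ Q.T).T
    U = (system.T @ Q.T).T + system.u_prescribed  # (nt, 3N), desk scale
    return times, U


# ---------------------------------------------------------------------------
# stress recovery


@dataclass
class FEResult:
    """Displacements with recovered per-element strain/stress fields."""

    u: np.ndarray
    strain: np.ndarray  # (E, 6) engineering strains
    stress: np.ndarray  # (E, 6) Pa
    von_mises: np.ndarray  # (E,) Pa


def recover_stress(assembly: FEAssembly, u_full: np.ndarray) -> FEResult:
    """Constant-strain-per-element strain/stress/von Mises recovery."""
    if u_full.shape[-1] != assembly.n_dofs:
        raise ValueError("displacement vector length does not match DoF count")
    ue = u_full[assembly.element_dofs()]  # (E, 12)
    eps = np.einsum("eij,ej->ei", assembly.B, ue)
    sig = np.einsum("eij,ej->ei", assembly.C, eps)
    return FEResult(u_full, eps, sig, von_mises(sig))


def von_mises(sig: np.ndarray) -> np.ndarray:
    """Equivalent stress from the second deviatoric invariant.

    ``sig`` columns are (sxx, syy, szz, sxy, syz, szx)."""
    s = np.asarray(sig)
    return np.sqrt(
        0.5 * ((s[..., 0] - s[..., 1]) ** 2
               + (s[..., 1] - s[..., 2]) ** 2
               + (s[..., 2] - s[..., 0]) ** 2)
        + 3.0 * (s[..., 3] ** 2 + s[..., 4] ** 2 + s[..., 5] ** 2)
    )


def principal_strain_magnitude(eps: np.ndarray) -> np.ndarray:
    """Largest-magnitude principal strain per element (tensor shears)."""
    e = np.asarray(eps)
    T = np.zeros(e.shape[:-1] + (3, 3))
    T[..., 0, 0] = e[..., 0]
    T[..., 1, 1] = e[..., 1]
    T[..., 2, 2] = e[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = e[..., 3] / 2
    T[..., 1, 2] = T[..., 2, 1] = e[..., 4] / 2
    T[..., 0, 2] = T[..., 2, 0] = e[..., 5] / 2
    w = np.linalg.eigvalsh(T)
    return np.abs(w).max(axis=-1)


def patch_average(values: np.ndarray, element_ids, volumes: np.ndarray) -> float:
    """Volume-weighted mean of a per-element quantity over a patch."""
    element_ids = np.asarray(element_ids, dtype=np.intp)
    if element_ids.size == 0:
        raise ValueError("empty element patch")
    v = volumes[element_ids]
    return float(np.einsum("e,e->", values[element_ids], v) / v.sum())


def natural_frequencies(K, M, k: int = 6) -> np.ndarray:
    """Lowest ``k`` natural frequencies (Hz) of the generalized problem."""
    if sp.issparse(K) and K.shape[0] > 4 * k + 20:
        w2 = spla.eigsh(K.tocsc(), k=k, M=M.tocsc(), sigma=0, which="LM",
                        v0=np.ones(K.shape[0]), return_eigenvectors=False)
        w2 = np.sort(w2)
    else:
        Kd = K.toarray() if sp.issparse(K) else np.asarray(K)
        Md = M.toarray() if sp.issparse(M) else np.asarray(M)
        w2 = sla.eigh(Kd, Md, eigvals_only=True)[:k]
    return np.sqrt(np.clip(w2, 0, None)) / (2 * np.pi)
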