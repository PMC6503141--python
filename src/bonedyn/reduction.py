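"""Craig-Bampton reduction of an FE model to a flexible superelement.

The boundary set consists of the 6-DoF interface masters (kinematically
condensed node patches) of a :class:`~bonedyn.fem.SystemModel`; the interior
is every remaining free DoF. The reduction basis combines

* static constraint modes  Psi = -K_ii^-1 K_ib  (exact static response to
  any interface load -- the module's headline invariant), and
* the lowest ``n_modes`` fixed-interface normal modes of (K_ii, M_ii),
  mass-orthonormalized.

Stress-recovery operators S_e = C_e B_e Phi_CB are precomputed per element
at reduction time so that stresses follow from the reduced coordinates by a
single matrix-vector product per element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import (
    FEResult,
    LoadHistory,
    MasterConstraint,
    SystemModel,
    newmark,
    von_mises,
)


@dataclass
class SuperElement:
    """Reduced mass/stiffness over (boundary masters + retained modes)."""

    M_red: np.ndarray
    K_red: np.ndarray
    boundary_map: dict  # master name -> 6 reduced-coordinate indices
    n_modes: int
    zeta: float
    mode_frequencies: np.ndarray  # Hz, retained fixed-interface modes
    phi_full: np.ndarray  # (3N, n_red) full-DoF mode matrix (incl. coupling map)
    stress_ops: np.ndarray  # (E, 6, n_red) Pa per unit reduced coordinate
    strain_ops: np.ndarray  # (E, 6, n_red)
    element_volumes: np.ndarray
    element_sets: dict
    landmarks: dict
    metadata: dict

    @property
    def n_boundary(self) -> int:
        return self.M_red.shape[0] - self.n_modes

    @property
    def n_red(self) -> int:
        return self.M_red.shape[0]

    def damping_matrix(self) -> np.ndarray:
        """Modal damping on the retained-mode block only; boundary undamped."""
        C = np.zeros_like(self.M_red)
        nb = self.n_boundary
        w = 2 * np.pi * self.mode_frequencies
        C[nb:, nb:] = np.diag(2.0 * self.zeta * w)
        return C

    def force_vector(self, wrenches: dict) -> np.ndarray:
        """Reduced force vector from wrenches on interface masters."""
        f = np.zeros(self.n_red)
        for name, (F, M) in wrenches.items():
            idx = self.boundary_map[name]
            f[idx[:3]] += np.asarray(F, dtype=float)
            f[idx[3:]] += np.asarray(M, dtype=float)
        return f

    def master_translation(self, q_red: np.ndarray, name: str) -> np.ndarray:
        return np.asarray(q_red)[..., self.boundary_map[name][:3]]

    def displacement(self, q_red: np.ndarray) -> np.ndarray:
        """Full nodal displacement(s) recovered from reduced coordinates."""
        return np.asarray(q_red) @ self.phi_full.T


def craig_bampton(system: SystemModel, n_modes: int = 30,
                  zeta: float = 0.025) -> SuperElement:
    """Reduce a SystemModel with kinematic interface masters to a superelement.

    The defaults (30 retained modes, 2.5% modal damping on every retained
    mode) follow standard practice for bone segments in flexible multibody
    models.
    """
    if not system.master_index:
        raise ValueError("system has no kinematic interface masters")
    nb_start = len(system.free_dofs)
    i_idx = np.arange(nb_start)
    b_idx = np.arange(nb_start, system.n_q)
    n_i, n_b = len(i_idx), len(b_idx)
    if n_modes < 0 or n_modes > n_i:
        raise ValueError(f"n_modes must lie in [0, {n_i}] (interior DoF count)")

    K = system.K.tocsc()
    M = system.M.tocsc()
    K_ii = K[i_idx][:, i_idx]
    K_ib = K[i_idx][:, b_idx]
    M_ii = M[i_idx][:, i_idx]

    try:
        lu = spla.splu(K_ii)
    except RuntimeError as err:
        raise np.linalg.LinAlgError(f"singular interior stiffness block: {err}")
    Psi = -lu.solve(K_ib.toarray())  # (n_i, n_b) constraint modes

    if n_modes > 0:
        if n_i <= max(200, 4 * n_modes):
            w2, Phi = sla.eigh(K_ii.toarray(), M_ii.toarray())
            w2, Phi = w2[:n_modes], Phi[:, :n_modes]
        else:
            w2, Phi = spla.eigsh(K_ii, k=n_modes, M=M_ii, sigma=0, which="LM",
                                  v0=np.ones(n_i))
            order = np.argsort(w2)
            w2, Phi = w2[order], Phi[:, order]
        # eigh/eigsh mass-normalize already; enforce exactly
        norms = np.sqrt(np.einsum("ij,ij->j", Phi, M_ii @ Phi))
        Phi = Phi / norms
        freqs = np.sqrt(np.clip(w2, 0, None)) / (2 * np.pi)
    else:
        Phi = np.zeros((n_i, 0))
        freqs = np.zeros(0)

    n_red = n_b + n_modes
    Phi_q = np.zeros((system.n_q, n_red))
    Phi_q[b_idx, :n_b] = np.eye(n_b)
    Phi_q[i_idx, :n_b] = Psi
    Phi_q[i_idx, n_b:] = Phi

    M_red = Phi_q.T @ (M @ Phi_q)
    K_red = Phi_q.T @ (K @ Phi_q)
    M_red = 0.5 * (M_red + M_red.T)
    K_red = 0.5 * (K_red + K_red.T)

    phi_full = system.T @ Phi_q  # (3N, n_red)
    asm = system.assembly
    edofs = asm.element_dofs()
    phi_e = phi_full[edofs]  # (E, 12, n_red)
    strain_ops = np.einsum("eij,ejr->eir", asm.B, phi_e, optimize=True)
    stress_ops = np.einsum("eij,ejr->eir", asm.C, strain_ops, optimize=True)

    boundary_map = {name: (idx - nb_start).astype(int)
                    for name, idx in system.master_index.items()}
    mesh = asm.mesh
    return SuperElement(
        M_red=M_red,
        K_red=K_red,
        boundary_map=boundary_map,
        n_modes=n_modes,
        zeta=zeta,
        mode_frequencies=freqs,
        phi_full=phi_full,
        stress_ops=stress_ops,
        strain_ops=strain_ops,
        element_volumes=asm.volumes,
        element_sets=dict(mesh.element_sets),
        landmarks=dict(mesh.landmarks),
        metadata=dict(mesh.metadata),
    )


def sem_static(sem: SuperElement, wrenches: dict,
               constraint: MasterConstraint = None) -> np.ndarray:
    """Static reduced solve; returns the reduced coordinate vector."""
    f = sem.force_vector(wrenches)
    if constraint is not None:
        P = constraint.basis(sem.boundary_map, n_q=sem.n_red).toarray()
        Kc = P.T @ sem.K_red @ P
        qc = _solve_refined(Kc, P.T @ f)
        return P @ qc
    return _solve_refined(sem.K_red, f)


def _solve_refined(K, f):
    try:
        x = sla.solve(K, f, assume_a="sym")
    except sla.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular reduced system: {err}")
    x += sla.solve(K, f - K @ x, assume_a="sym")
    return x


def sem_transient(sem: SuperElement, history: LoadHistory, dt: float,
                  t_end: float = None, constraint: MasterConstraint = None,
                  initial: str = "static"):
    """Newmark transient of the reduced system with modal damping.

    ``initial`` is ``"static"`` (start in static equilibrium with the t=0
    load -- the physical choice for sustained loads such as gravity) or
    ``"rest"`` (zero initial state). Returns (times, Q_red) with Q_red of
    shape (n_steps + 1, n_red).
    """
    t_end = history.times[-1] if t_end is None else t_end
    n_steps = int(round(t_end / dt))
    nt = len(history.times)
    F = np.zeros((sem.n_red, nt))
    for k in range(nt):
        F[:, k] = sem.force_vector(
            {n: (w[k, :3], w[k, 3:]) for n, w in history.wrenches.items()})
    fq = history.interpolator(F)
    M, K, C = sem.M_red, sem.K_red, sem.damping_matrix()
    if constraint is not None:
        P = constraint.basis(sem.boundary_map, n_q=sem.n_red).toarray()
        Mc, Kc, Cc = P.T @ M @ P, P.T @ K @ P, P.T @ C @ P
        fc = lambda t: P.T @ fq(t)
        q0 = (sla.solve(Kc, fc(0.0), assume_a="sym")
              if initial == "static" else None)
        Qc, _, _ = newmark(Mc, Cc, Kc, fc, dt, n_steps, q0=q0)
        Q = Qc @ P.T
    else:
        q0 = (sla.solve(K, fq(0.0), assume_a="sym")
              if initial == "static" else None)
        Q, _, _ = newmark(M, C, K, fq, dt, n_steps, q0=q0)
    return dt * np.arange(n_steps + 1), Q


def recover(sem: SuperElement, q_red: np.ndarray, elements=None) -> FEResult:
    """Strain/stress/von Mises recovery from reduced coordinates.

    ``q_red`` may be a single vector or a (nt, n_red) time series;
    ``elements`` restricts recovery to an element subset.
    """
    S = sem.stress_ops
    Bop = sem.strain_ops
    if elements is not None:
        elements = np.asarray(elements, dtype=np.intp)
        if elements.size and elements.max() >= S.shape[0]:
            raise IndexError("unknown element id in recovery subset")
        S, Bop = S[elements], Bop[elements]
    q = np.asarray(q_red, dtype=float)
    eps = np.einsum("eir,...r->...ei", Bop, q, optimize=True)
    sig = np.einsum("eir,...r->...ei", S, q, optimize=True)
    return FEResult(None, eps, sig, von_mises(sig))
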