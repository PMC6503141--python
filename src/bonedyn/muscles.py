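"""Hill-type muscle paths, moment arms and static optimization.

Muscles are massless line actuators routed through segment-fixed points
(origin, optional via-points, insertion). The force magnitude is
``f = f_lv * C * a`` with ``C = PCSA * sigma_max`` and the force-length-
velocity factor fixed to 1 (activation and contraction dynamics are out of
scope; the hook :func:`force_length_velocity` exists for extension).

Moment arms come from the tendon-excursion relation ``r_j = -ds/dbeta_j``
(central differences), so the generalized-force map is ``D = -C ds/dbeta``
column by column -- equivalent to summing the attachment-point Jacobians
transposed against the muscle line-of-action forces.

The muscle redundancy problem is the volume-weighted quadratic program

    min  a^T V a   s.t.  D a (+ reserves) = tau,  0 <= a <= 1,

solved exactly with a primal active-set method (diagonal Hessian), with
optional heavily penalized reserve actuators guaranteeing feasibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chain import JointChain, forward_kinematics, landmark_position


@dataclass
class MusclePath:
    """Line actuator through an ordered list of (segment, local point)."""

    name: str
    points: list  # [(segment_name or "ground", (2,) local point), ...]
    area: float  # PCSA, m^2
    sigma_max: float  # Pa
    volume: float  # m^3 (optimization weight)

    def __post_init__(self):
        if len(self.points) < 2:
            raise ValueError(f"muscle {self.name}: needs >= 2 path points")
        segs = {s for s, _ in self.points}
        if len(segs) < 2:
            raise ValueError(f"muscle {self.name}: must span >= 2 segments")
        if min(self.area, self.sigma_max, self.volume) <= 0:
            raise ValueError(f"muscle {self.name}: A, sigma, V must be positive")

    @property
    def max_force(self) -> float:
        return self.area * self.sigma_max


def force_length_velocity(s, s_dot):
    """Force-length-velocity scaling; fixed to 1 in this model."""
    return 1.0


def path_points_world(chain: JointChain, state, muscle: MusclePath) -> np.ndarray:
    return np.array([landmark_position(chain, state, seg, loc)
                     for seg, loc in muscle.points])


def muscle_length(chain: JointChain, beta, muscle: MusclePath) -> float:
    return float(all_muscle_lengths(chain, beta, [muscle])[0])


def all_muscle_lengths(chain: JointChain, beta, muscles) -> np.ndarray:
    """All muscle lengths from a single forward-kinematics evaluation."""
    state = forward_kinematics(chain, beta)
    out = np.empty(len(muscles))
    for i, m in enumerate(muscles):
        pts = path_points_world(chain, state, m)
        lens = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(lens < 1e-12):
            raise ValueError(
                f"muscle {m.name}: coincident consecutive path points")
        out[i] = lens.sum()
    return out


def muscle_geometry(chain: JointChain, beta, muscles, h: float = 1e-6):
    """Lengths, attachment unit vectors and the generalized-force map D.

    Returns (s, units, D) where ``s`` is the (n,) length vector, ``units``
    maps muscle name -> per-path-point pulling directions (unit vectors of
    the adjacent path legs), and ``D`` is the (f, n) map from activations to
    generalized torques, D[:, i] = -C_i ds_i/dbeta.
    """
    beta = np.asarray(beta, dtype=float)
    f = chain.f
    s = all_muscle_lengths(chain, beta, muscles)
    D = np.zeros((f, len(muscles)))
    for j in range(f):
        db = np.zeros(f)
        db[j] = h
        sp = all_muscle_lengths(chain, beta + db, muscles)
        sm = all_muscle_lengths(chain, beta - db, muscles)
        D[j, :] = -(sp - sm) / (2 * h)
    D *= np.array([m.max_force for m in muscles])[None, :]

    state = forward_kinematics(chain, beta)
    units = {}
    for m in muscles:
        pts = path_points_world(chain, state, m)
        legs = np.diff(pts, axis=0)
        units[m.name] = legs / np.linalg.norm(legs, axis=1, keepdims=True)
    return s, units, D


def moment_arms(chain: JointChain, beta, muscles, h: float = 1e-6) -> np.ndarray:
    """Tendon-excursion moment arms r[j, i] = -ds_i/dbeta_j (f, n)."""
    _, _, D = muscle_geometry(chain, beta, muscles, h=h)
    C = np.array([m.max_force for m in muscles])
    return D / C[None, :]


def muscle_point_forces(chain: JointChain, state, muscle: MusclePath,
                        tension: float):
    """External (point_world, force) pairs the tensioned muscle applies.

    Each straight path leg pulls its two endpoints toward each other; via
    points feel both adjacent legs.
    """
    pts = path_points_world(chain, state, muscle)
    legs = np.diff(pts, axis=0)
    u = legs / np.linalg.norm(legs, axis=1, keepdims=True)
    out = []
    for i, (seg, _) in enumerate(muscle.points):
        Fv = np.zeros(2)
        if i < len(u):
            Fv += tension * u[i]  # pulled toward next point
        if i > 0:
            Fv -= tension * u[i - 1]  # pulled toward previous point
        out.append((seg, pts[i], Fv))
    return out


# ---------------------------------------------------------------------------
# static optimization


@dataclass
class ActivationStep:
    """Solution of one static-optimization instant."""

    activations: np.ndarray
    reserves: np.ndarray
    objective: float
    kkt_residual: float
    residual: float  # equality-constraint residual norm
    reserve_flagged: bool


def static_optimization(D: np.ndarray, tau: np.ndarray, V: np.ndarray,
                        use_reserves: bool = True,
                        reserve_weight: float = None,
                        reserve_flag_level: float = 1.0) -> ActivationStep:
    """Solve the volume-weighted activation QP for one instant.

    Reserve actuators (one ideal torque per DoF, quadratic weight
    ``reserve_weight``, default 1e3 x max(V)) keep the equality constraint
    feasible when the muscles cannot produce ``tau``; reserves above
    ``reserve_flag_level`` N m are flagged.
    """
    D = np.asarray(D, dtype=float)
    tau = np.asarray(tau, dtype=float)
    V = np.asarray(V, dtype=float)
    f, n = D.shape
    if np.any(V <= 0):
        raise ValueError("muscle volumes must be positive")
    if use_reserves:
        rw = 1e3 * V.max() if reserve_weight is None else reserve_weight
        A = np.hstack([D, np.eye(f)])
        w = np.concatenate([V, np.full(f, rw)])
        lo = np.concatenate([np.zeros(n), np.full(f, -np.inf)])
        hi = np.concatenate([np.ones(n), np.full(f, np.inf)])
        x0 = np.concatenate([np.zeros(n), tau])  # trivially feasible
    else:
        A = D
        w = V.copy()
        lo = np.zeros(n)
        hi = np.ones(n)
        x0 = _feasible_point(D, tau)
    x, lam = _active_set_qp(2 * w, A, tau, lo, hi, x0)
    if use_reserves:
        # polish: absorb the residual equality defect into the free reserves
        x[n:] += tau - A @ x
    a = x[:n]
    r = x[n:] if use_reserves else np.zeros(f)
    obj = float(a @ (V * a))
    resid = float(np.linalg.norm(A @ x - tau))
    kkt = _kkt_residual(2 * w, A, tau, lo, hi, x, lam)
    return ActivationStep(a, r, obj, kkt, resid,
                          bool(np.any(np.abs(r) > reserve_flag_level)))


def _feasible_point(D, tau):
    """Phase-1 feasible activation (linear program) for the reserve-free QP."""
    from scipy.optimize import linprog

    n = D.shape[1]
    res = linprog(np.zeros(n), A_eq=D, b_eq=tau, bounds=[(0, 1)] * n,
                  method="highs")
    if not res.success:
        raise RuntimeError(
            "required torque is unreachable by the muscle set and reserve "
            "actuators are disabled")
    return res.x


def _active_set_qp(h, A, b, lo, hi, x0, tol=1e-11, max_iter=500):
    """min 1/2 x^T diag(h) x s.t. A x = b, lo <= x <= hi.

    Textbook primal active-set method with feasible iterates. With a
    diagonal Hessian the equality-constrained subproblem reduces to a small
    (f x f) solve for the constraint multipliers. Returns (x, lam).
    """
    h = np.asarray(h, dtype=float)
    x = np.array(x0, dtype=float)
    nvar = len(h)
    scale = max(1.0, np.abs(b).max())
    at_lo = np.isfinite(lo) & (x <= lo + tol * scale)
    at_hi = np.isfinite(hi) & (x >= hi - tol * scale)
    lam = np.zeros(A.shape[0])
    for _ in range(max_iter):
        free = ~(at_lo | at_hi)
        x_fix = np.where(at_hi, hi, np.where(at_lo, lo, 0.0))
        x_fix[free] = 0.0
        rhs = b - A @ x_fix
        # solve the augmented KKT system directly (small), with one round of
        # iterative refinement for tight stationarity/feasibility residuals
        Af = A[:, free]
        nf = int(free.sum())
        m = A.shape[0]
        Kmat = np.zeros((nf + m, nf + m))
        Kmat[:nf, :nf] = np.diag(h[free])
        Kmat[:nf, nf:] = Af.T
        Kmat[nf:, :nf] = Af
        rhsv = np.concatenate([np.zeros(nf), rhs])
        sol = np.linalg.lstsq(Kmat, rhsv, rcond=None)[0]
        sol += np.linalg.lstsq(Kmat, rhsv - Kmat @ sol, rcond=None)[0]
        lam = sol[nf:]
        x_eqp = x_fix.copy()
        x_eqp[free] = sol[:nf]
        p = x_eqp - x
        if np.abs(p).max() <= tol * max(1.0, np.abs(x).max()):
            # optimal on the working set; check bound multipliers
            grad = h * x + A.T @ lam
            mu = np.where(at_lo, grad, np.where(at_hi, -grad, np.inf))
            worst = int(np.argmin(mu))
            if mu[worst] >= -tol * max(1.0, np.abs(grad).max()):
                return x, lam
            at_lo[worst] = False
            at_hi[worst] = False
            continue
        # longest feasible step along p
        alpha = 1.0
        blocking = -1
        block_hi = False
        for i in np.where(free)[0]:
            if p[i] < -tol and np.isfinite(lo[i]):
                a_i = (lo[i] - x[i]) / p[i]
                if a_i < alpha:
                    alpha, blocking, block_hi = a_i, i, False
            elif p[i] > tol and np.isfinite(hi[i]):
                a_i = (hi[i] - x[i]) / p[i]
                if a_i < alpha:
                    alpha, blocking, block_hi = a_i, i, True
        x = x + max(alpha, 0.0) * p
        if blocking >= 0:
            if block_hi:
                at_hi[blocking] = True
                x[blocking] = hi[blocking]
            else:
                at_lo[blocking] = True
                x[blocking] = lo[blocking]
    raise RuntimeError("active-set QP did not converge")


def _kkt_residual(h, A, b, lo, hi, x, lam):
    """Max-norm KKT residual (stationarity, feasibility, complementarity)."""
    grad = h * x + A.T @ lam
    mu_lo = np.maximum(grad, 0.0)
    mu_hi = np.maximum(-grad, 0.0)
    finite_lo = np.isfinite(lo)
    finite_hi = np.isfinite(hi)
    comp_lo = np.zeros_like(grad)
    comp_lo[finite_lo] = mu_lo[finite_lo] * np.abs(x - lo)[finite_lo]
    comp_lo[~finite_lo] = np.abs(grad)[~finite_lo]
    comp_hi = np.zeros_like(grad)
    comp_hi[finite_hi] = mu_hi[finite_hi] * np.abs(hi - x)[finite_hi]
    prim = np.linalg.norm(A @ x - b, np.inf) if len(b) else 0.0
    bound_lo = np.where(finite_lo, lo - x, -np.inf).max()
    bound_hi = np.where(finite_hi, x - hi, -np.inf).max()
    return float(max(comp_lo.max(), comp_hi.max(), prim,
                     max(bound_lo, 0.0), max(bound_hi, 0.0)))
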