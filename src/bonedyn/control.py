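"""Computed muscle control and femur interface-load extraction.

The controller tracks reference joint trajectories by feedback-linearizing
the rigid chain: a desired acceleration with critically damped error
dynamics (k_D = 2 sqrt(k_P) per DoF) is converted to net joint torques by
inverse dynamics, the torques are distributed over the muscles by static
optimization, and the chain is integrated forward (fixed-step RK4) under the
resulting muscle and gravity generalized forces with zero-order-hold
activations between control updates.

After the simulation, the femur's interface load history (hip/knee joint
reactions from Newton-Euler subsystem balances, plus every femur-attached
muscle force along its current line of action) is extracted in the femur
body frame for one-way transfer onto the flexible superelement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chain import (
    GRAVITY,
    JointChain,
    TrajectorySet,
    _kinematic_pass,
    cross2,
    forward_dynamics,
    forward_kinematics,
    equations_of_motion,
    inverse_dynamics,
)
from .muscles import muscle_geometry, muscle_point_forces, static_optimization


class DivergenceError(RuntimeError):
    def __init__(self, t):
        super().__init__(f"simulation diverged; last stable time {t:.4f} s")
        self.last_stable_time = t


@dataclass
class ControlGains:
    """Per-DoF proportional gains; derivative gains default to critical."""

    k_p: np.ndarray  # s^-2
    k_d: np.ndarray = None  # s^-1

    def __post_init__(self):
        self.k_p = np.atleast_1d(np.asarray(self.k_p, dtype=float))
        if np.any(self.k_p <= 0):
            raise ValueError("k_p must be positive")
        if self.k_d is None:
            self.k_d = 2.0 * np.sqrt(self.k_p)
        else:
            self.k_d = np.atleast_1d(np.asarray(self.k_d, dtype=float))

    @classmethod
    def critically_damped(cls, f: int, k_p: float = 400.0) -> "ControlGains":
        return cls(np.full(f, k_p))


@dataclass
class SimulationRecord:
    """Controller/plant states sampled at the control rate."""

    times: np.ndarray
    beta: np.ndarray
    beta_dot: np.ndarray
    beta_ddot: np.ndarray
    activations: np.ndarray  # (nt, n_muscles)
    reserves: np.ndarray  # (nt, f)
    tau: np.ndarray  # (nt, f) net torques commanded
    kkt_residuals: np.ndarray
    reserve_flagged: np.ndarray
    beta_ref: np.ndarray

    def tracking_rms_deg(self) -> np.ndarray:
        """Per-joint RMS tracking error in degrees."""
        err = self.beta - self.beta_ref
        return np.degrees(np.sqrt((err ** 2).mean(axis=0)))


def cmc_track(
    chain: JointChain,
    muscles,
    traj: TrajectorySet,
    gains: ControlGains = None,
    dt_control: float = 0.01,
    dt_integrate: float = 0.001,
    use_reserves: bool = True,
    gravity: float = GRAVITY,
    speed_limit: float = 100.0,
) -> SimulationRecord:
    """Track a joint trajectory with computed muscle control.

    ``dt_control`` is the rate at which torques are recomputed and the QP is
    solved; ``dt_integrate`` the RK4 step (must divide the control step).
    """
    if gains is None:
        gains = ControlGains.critically_damped(chain.f)
    if dt_control < dt_integrate:
        raise ValueError("dt_control must be >= dt_integrate")
    n_sub = int(round(dt_control / dt_integrate))
    n_ctrl = int(round((traj.times[-1] - traj.times[0]) / dt_control))
    t0 = traj.times[0]
    beta, beta_dot, _ = traj.at(t0)
    beta = beta.copy()
    beta_dot = beta_dot.copy()

    V = np.array([m.volume for m in muscles])
    f = chain.f
    nt = n_ctrl + 1
    rec = SimulationRecord(
        times=t0 + dt_control * np.arange(nt),
        beta=np.zeros((nt, f)), beta_dot=np.zeros((nt, f)),
        beta_ddot=np.zeros((nt, f)),
        activations=np.zeros((nt, len(muscles))), reserves=np.zeros((nt, f)),
        tau=np.zeros((nt, f)), kkt_residuals=np.zeros(nt),
        reserve_flagged=np.zeros(nt, dtype=bool), beta_ref=np.zeros((nt, f)),
    )

    for k in range(nt):
        t = rec.times[k]
        b_e, bd_e, bdd_e = traj.at(t)
        # critically damped tracking law (negative feedback on the error)
        bdd_des = bdd_e - gains.k_d * (beta_dot - bd_e) - gains.k_p * (beta - b_e)
        tau = inverse_dynamics(chain, beta, beta_dot, bdd_des, gravity=gravity)
        _, _, D = muscle_geometry(chain, beta, muscles)
        step = static_optimization(D, tau, V, use_reserves=use_reserves)
        a = step.activations

        rec.beta[k], rec.beta_dot[k] = beta, beta_dot
        rec.beta_ref[k] = b_e
        rec.activations[k] = a
        rec.reserves[k] = step.reserves
        rec.tau[k] = tau
        rec.kkt_residuals[k] = step.kkt_residual
        rec.reserve_flagged[k] = step.reserve_flagged

        def applied_torque(b):
            _, _, Dn = muscle_geometry(chain, b, muscles)
            return Dn @ a + step.reserves

        rec.beta_ddot[k] = forward_dynamics(chain, beta, beta_dot,
                                            applied_torque(beta), gravity=gravity)
        if k == nt - 1:
            break
        for _ in range(n_sub):
            beta, beta_dot = _rk4_step(chain, beta, beta_dot, applied_torque,
                                       dt_integrate, gravity)
            if np.max(np.abs(beta_dot)) > speed_limit:
                raise DivergenceError(t)
    return rec


def _rk4_step(chain, beta, beta_dot, applied_torque, dt, gravity):
    M = equations_of_motion(chain, beta, beta_dot, gravity)[0]
    tau = applied_torque(beta)

    def deriv(b, bd):
        # M and the muscle generalized torque are held over the (1 ms) step;
        # the gravity/Coriolis bias is recomputed per stage
        return bd, forward_dynamics(chain, b, bd, tau, gravity=gravity, M=M)

    k1 = deriv(beta, beta_dot)
    k2 = deriv(beta + 0.5 * dt * k1[0], beta_dot + 0.5 * dt * k1[1])
    k3 = deriv(beta + 0.5 * dt * k2[0], beta_dot + 0.5 * dt * k2[1])
    k4 = deriv(beta + dt * k3[0], beta_dot + dt * k3[1])
    beta = beta + dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    beta_dot = beta_dot + dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    return beta, beta_dot


def passive_simulation(chain, traj_or_state, t_end, dt=0.001, gravity=GRAVITY):
    """Forward integration with zero actuation (controller bypass)."""
    beta, beta_dot = traj_or_state
    beta = np.array(beta, dtype=float)
    beta_dot = np.array(beta_dot, dtype=float)
    n = int(round(t_end / dt))
    out_b = np.zeros((n + 1, chain.f))
    out_bd = np.zeros((n + 1, chain.f))
    out_b[0], out_bd[0] = beta, beta_dot
    zero = np.zeros(chain.f)
    for k in range(n):
        beta, beta_dot = _rk4_step(chain, beta, beta_dot, lambda b: zero, dt,
                                   gravity)
        out_b[k + 1], out_bd[k + 1] = beta, beta_dot
    return dt * np.arange(n + 1), out_b, out_bd


# ---------------------------------------------------------------------------
# femur interface loads


@dataclass
class FemurLoadHistory:
    """Interface wrench histories on the femur, in the femur body frame.

    ``wrenches`` maps interface name -> (nt, 6) array (Fx Fy Fz Mx My Mz)
    in 3D femur-frame components; the planar simulation populates Fx, Fz
    and My. ``residuals`` holds the per-frame Newton-Euler force-balance
    residual of the femur free body, normalized by the peak interface force.
    """

    times: np.ndarray
    wrenches: dict
    residuals: np.ndarray = None


def extract_femur_loads(record: SimulationRecord, chain: JointChain, muscles,
                        femur_segment: str = "thigh",
                        gravity: float = GRAVITY) -> FemurLoadHistory:
    """Hip/knee joint reactions and femur-attached muscle forces per frame.

    Joint reactions come from Newton-Euler balances of the subsystems distal
    (in the chain sense: further from ground) of each joint; every muscle
    attachment or via-point on the femur becomes a named interface with the
    muscle force along its current line of action. All loads are expressed
    in the femur body frame.
    """
    fi = chain.segment_index(femur_segment)
    f = chain.f
    nt = len(record.times)
    seg = chain.segments[fi]

    femur_ifaces = ["knee", "hip"]
    muscle_points = []  # (iface_name, muscle_idx, point_idx)
    for mi, m in enumerate(muscles):
        for pi, (sname, _) in enumerate(m.points):
            if sname == femur_segment:
                muscle_points.append((f"{m.name}_p{pi}", mi, pi))
                femur_ifaces.append(f"{m.name}_p{pi}")
    W = {name: np.zeros((nt, 6)) for name in femur_ifaces}
    residuals = np.zeros(nt)
    peak = 0.0

    for k in range(nt):
        beta = record.beta[k]
        kin = _kinematic_pass(chain, beta, record.beta_dot[k],
                              record.beta_ddot[k])
        state = forward_kinematics(chain, beta)
        g = np.array([0.0, -gravity])

        seg_forces = {i: [] for i in range(f)}  # external muscle loads
        for mi, m in enumerate(muscles):
            tension = m.max_force * record.activations[k, mi]
            if tension <= 0:
                continue
            for sname, p, Fv in muscle_point_forces(chain, state, m, tension):
                if sname != "ground":
                    seg_forces[chain.segment_index(sname)].append((p, Fv))

        def subsystem_wrench(j):
            """Force/moment transmitted to segment j from its parent."""
            o = kin[j]["o"]
            F = np.zeros(2)
            N = 0.0
            for s in range(j, f):
                kk = kin[s]
                body = chain.segments[s]
                dyn = body.mass * (kk["ac"] - g)
                F += dyn
                N += body.inertia * kk["alpha"] + cross2(kk["xc"] - o, dyn)
                for (p, Fv) in seg_forces[s]:
                    F -= Fv
                    N -= cross2(p - o, Fv)
            return F, N

        f_knee, n_knee = subsystem_wrench(fi)
        if fi + 1 < f:
            f_hip_on_up, n_hip_on_up = subsystem_wrench(fi + 1)
        else:
            f_hip_on_up, n_hip_on_up = np.zeros(2), 0.0
        # moment of the hip subsystem was taken about the hip point already
        Rf = kin[fi]["R"]

        def to_femur(Fv, Nv):
            # plane angles rotate +x toward +z, i.e. about the -y axis of the
            # right-handed 3D femur frame, hence the sign on the moment
            loc = Rf.T @ Fv
            return np.array([loc[0], 0.0, loc[1], 0.0, -Nv, 0.0])

        W["knee"][k] = to_femur(f_knee, n_knee)
        W["hip"][k] = to_femur(-f_hip_on_up, -n_hip_on_up)

        balance = f_knee - f_hip_on_up
        for name, mi, pi in muscle_points:
            m = muscles[mi]
            tension = m.max_force * record.activations[k, mi]
            pf = muscle_point_forces(chain, state, m, tension)
            _, p, Fv = pf[pi]
            W[name][k] = to_femur(Fv, 0.0)
            balance += Fv
        # Newton-Euler residual of the femur free body
        balance += seg.mass * g - seg.mass * kin[fi]["ac"]
        residuals[k] = np.linalg.norm(balance)
        peak = max(peak, np.linalg.norm(f_knee), np.linalg.norm(f_hip_on_up))

    residuals /= max(peak, 1e-12)
    return FemurLoadHistory(record.times.copy(), W, residuals)


def symmetry_condition(offset, velocity, stiffness: float, damping: float):
    """Spring-damper wrench restraining out-of-plane pelvis motion.

    In the planar default the out-of-plane coordinates are identically zero
    and so is the returned wrench.
    """
    offset = np.atleast_1d(np.asarray(offset, dtype=float))
    velocity = np.atleast_1d(np.asarray(velocity, dtype=float))
    return -stiffness * offset - damping * velocity
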