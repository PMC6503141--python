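"""Planar rigid musculoskeletal chain: kinematics and dynamics.

The default squat model is a sagittal-plane serial chain rooted at the
ground-fixed foot: four hinge joints (ankle, knee, hip, torso) connect the
shank, thigh, pelvis and torso segments. Plane coordinates are (x, z) with x
pointing anteriorly and z up; hinge rotations are positive counter-clockwise
about the out-of-plane (+y) axis, and gravity acts along -z.

Dynamics use a recursive Newton-Euler inverse-dynamics pass; the joint-space
mass matrix is built column-wise from unit accelerations, and Coriolis /
gravity torques fall out of the same recursion, so the equations of motion

    M(beta) beta'' = tau_applied + tau_cc + tau_g

are available without symbolic derivation. Sign convention: the muscle /
actuator torque needed to realize a target acceleration is
``tau = M beta'' - (tau_cc + tau_g)``; in statics this is plain gravity
compensation, tau = -tau_g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

GRAVITY = 9.81  # m/s^2, along -z


def rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def perp(v):
    """90-degree CCW rotation of a plane vector (the 'omega cross' operator)."""
    return np.array([-v[1], v[0]])


def cross2(a, b):
    """Scalar (out-of-plane) cross product of two plane vectors."""
    return a[0] * b[1] - a[1] * b[0]


@dataclass
class Segment:
    """Rigid body of the planar chain.

    The segment frame has its origin at the proximal joint; at the reference
    pose (all joint angles zero) every segment points straight up, so local
    coordinates are (anterior offset, proximal-to-distal distance).
    """

    name: str
    mass: float
    com: np.ndarray  # (2,) centre of mass, segment frame
    inertia: float  # about CoM, out-of-plane axis (kg m^2)
    distal_joint: np.ndarray = None  # (2,) next joint in segment frame
    landmarks: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(f"segment {self.name}: mass must be positive")
        if self.inertia <= 0:
            raise ValueError(f"segment {self.name}: inertia must be positive")
        self.com = np.asarray(self.com, dtype=float)
        if self.distal_joint is not None:
            self.distal_joint = np.asarray(self.distal_joint, dtype=float)
        self.landmarks = {k: np.asarray(v, dtype=float)
                          for k, v in self.landmarks.items()}


@dataclass
class JointChain:
    """Serial planar hinge chain rooted at a ground-fixed base point."""

    segments: list
    joint_names: list
    base_point: np.ndarray = None
    ground_landmarks: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.segments) != len(self.joint_names):
            raise ValueError("one joint per segment required")
        self.base_point = (np.zeros(2) if self.base_point is None
                           else np.asarray(self.base_point, dtype=float))
        self.ground_landmarks = {k: np.asarray(v, dtype=float)
                                 for k, v in self.ground_landmarks.items()}

    @property
    def f(self) -> int:
        return len(self.segments)

    def segment_index(self, name: str) -> int:
        for i, s in enumerate(self.segments):
            if s.name == name:
                return i
        raise KeyError(name)


@dataclass
class ChainState:
    """Absolute pose quantities derived from joint coordinates."""

    beta: np.ndarray
    theta: np.ndarray  # absolute segment angles
    joint_origins: np.ndarray  # (f, 2) proximal joint positions
    com_positions: np.ndarray  # (f, 2)
    rotations: np.ndarray  # (f, 2, 2)


def forward_kinematics(chain: JointChain, beta) -> ChainState:
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (chain.f,):
        raise ValueError(f"beta must have length {chain.f}")
    theta = np.cumsum(beta)
    origins = np.zeros((chain.f, 2))
    coms = np.zeros((chain.f, 2))
    R = np.zeros((chain.f, 2, 2))
    o = chain.base_point.copy()
    for k, seg in enumerate(chain.segments):
        R[k] = rot(theta[k])
        origins[k] = o
        coms[k] = o + R[k] @ seg.com
        if seg.distal_joint is not None:
            o = o + R[k] @ seg.distal_joint
    return ChainState(beta, theta, origins, coms, R)


def landmark_position(chain: JointChain, state: ChainState, segment: str,
                      local_point=None) -> np.ndarray:
    """World position of a segment-fixed point (or named ground point)."""
    if segment == "ground":
        return np.asarray(local_point, dtype=float) if local_point is not None \
            else chain.base_point
    k = chain.segment_index(segment)
    p = np.asarray(local_point, dtype=float)
    return state.joint_origins[k] + state.rotations[k] @ p


# ---------------------------------------------------------------------------
# dynamics (recursive Newton-Euler)


def _kinematic_pass(chain, beta, beta_dot, beta_ddot):
    """Positions/velocities/accelerations of joints and CoMs."""
    f = chain.f
    theta = np.cumsum(beta)
    omega = np.cumsum(beta_dot)
    alpha = np.cumsum(beta_ddot)
    o = chain.base_point.copy()
    od = np.zeros(2)
    odd = np.zeros(2)
    out = []
    for k, seg in enumerate(chain.segments):
        R = rot(theta[k])
        rc = R @ seg.com
        xc = o + rc
        vc = od + omega[k] * perp(rc)
        ac = odd + alpha[k] * perp(rc) - omega[k] ** 2 * rc
        out.append(dict(R=R, o=o.copy(), odot=od.copy(), oddot=odd.copy(),
                        xc=xc, vc=vc, ac=ac, omega=omega[k], alpha=alpha[k],
                        theta=theta[k]))
        if seg.distal_joint is not None:
            rl = R @ seg.distal_joint
            o = o + rl
            od = od + omega[k] * perp(rl)
            odd = odd + alpha[k] * perp(rl) - omega[k] ** 2 * rl
    return out


def inverse_dynamics_full(chain: JointChain, beta, beta_dot, beta_ddot,
                          external=None, gravity=GRAVITY):
    """Joint torques (and reactions) that realize the given motion.

    ``external`` maps segment index -> list of (point_world, force_2vec)
    applied externally (e.g. muscle forces). Returns (tau, reactions) where
    reactions[k] = (force_on_child_from_parent, torque scalar) at joint k.
    """
    beta = np.asarray(beta, dtype=float)
    beta_dot = np.asarray(beta_dot, dtype=float)
    beta_ddot = np.asarray(beta_ddot, dtype=float)
    kin = _kinematic_pass(chain, beta, beta_dot, beta_ddot)
    f = chain.f
    g = np.array([0.0, -gravity])
    external = external or {}

    tau = np.zeros(f)
    forces = [None] * f
    torques = [None] * f
    f_child = np.zeros(2)
    n_child = 0.0
    child_joint = None
    for k in range(f - 1, -1, -1):
        seg = chain.segments[k]
        kk = kin[k]
        F_ext = np.zeros(2)
        N_ext = 0.0  # about the proximal joint
        for (p, Fv) in external.get(k, ()):
            F_ext += Fv
            N_ext += cross2(p - kk["o"], Fv)
        Fk = seg.mass * (kk["ac"] - g) + f_child - F_ext
        Nk = (seg.inertia * kk["alpha"]
              + cross2(kk["xc"] - kk["o"], seg.mass * (kk["ac"] - g)))
        if child_joint is not None:
            Nk += n_child + cross2(child_joint - kk["o"], f_child)
        Nk -= N_ext
        # in 2D the hinge-axis moment IS the actuation torque
        forces[k] = Fk
        torques[k] = Nk
        tau[k] = Nk
        f_child = Fk
        n_child = Nk
        child_joint = kk["o"]
    return tau, list(zip(forces, torques))


def gravity_torques(chain, beta, gravity=GRAVITY):
    tau, _ = inverse_dynamics_full(chain, beta, np.zeros(chain.f),
                                   np.zeros(chain.f), gravity=gravity)
    return -tau  # tau_g: torque *due to* gravity


def equations_of_motion(chain: JointChain, beta, beta_dot, gravity=GRAVITY):
    """Mass matrix M(beta), bias torque tau_cc(beta, beta') and tau_g(beta).

    Defined so that ``M beta'' = tau_applied + tau_cc + tau_g``.
    """
    f = chain.f
    zero = np.zeros(f)
    id_g = inverse_dynamics_full(chain, beta, zero, zero, gravity=gravity)[0]
    tau_g = -id_g
    id_v = inverse_dynamics_full(chain, beta, beta_dot, zero, gravity=gravity)[0]
    tau_cc = -(id_v - id_g)
    M = np.zeros((f, f))
    for j in range(f):
        e = np.zeros(f)
        e[j] = 1.0
        M[:, j] = inverse_dynamics_full(chain, beta, zero, e, gravity=0.0)[0]
    M = 0.5 * (M + M.T)
    return M, tau_cc, tau_g


def inverse_dynamics(chain: JointChain, beta, beta_dot, beta_ddot_target,
                     gravity=GRAVITY) -> np.ndarray:
    """Generalized actuator torque for a target acceleration:
    tau = M beta'' - (tau_cc + tau_g)."""
    tau, _ = inverse_dynamics_full(chain, beta, beta_dot, beta_ddot_target,
                                   gravity=gravity)
    return tau


def forward_dynamics(chain: JointChain, beta, beta_dot, tau_applied,
                     gravity=GRAVITY, M=None) -> np.ndarray:
    """Joint accelerations under applied generalized torques."""
    bias = inverse_dynamics_full(chain, beta, beta_dot, np.zeros(chain.f),
                                 gravity=gravity)[0]
    if M is None:
        M = equations_of_motion(chain, beta, beta_dot, gravity)[0]
    return np.linalg.solve(M, np.asarray(tau_applied, dtype=float) - bias)


def total_energy(chain: JointChain, beta, beta_dot, gravity=GRAVITY) -> float:
    """Kinetic plus gravitational potential energy of the chain."""
    M = equations_of_motion(chain, beta, beta_dot, gravity)[0]
    ke = 0.5 * float(np.asarray(beta_dot) @ M @ np.asarray(beta_dot))
    state = forward_kinematics(chain, beta)
    pe = sum(s.mass * gravity * state.com_positions[k][1]
             for k, s in enumerate(chain.segments))
    return ke + pe


# ---------------------------------------------------------------------------
# trajectories and inverse kinematics


@dataclass
class TrajectorySet:
    """Uniformly sampled joint-space trajectories beta(t) with derivatives."""

    times: np.ndarray
    beta: np.ndarray  # (nt, f)
    beta_dot: np.ndarray
    beta_ddot: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        dt = np.diff(self.times)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("trajectory sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def at(self, t: float):
        """Linear interpolation of (beta, beta_dot, beta_ddot) at time t."""
        t = np.clip(t, self.times[0], self.times[-1])
        i = min(int((t - self.times[0]) / self.dt), len(self.times) - 2)
        a = (t - self.times[i]) / self.dt
        return tuple((1 - a) * arr[i] + a * arr[i + 1]
                     for arr in (self.beta, self.beta_dot, self.beta_ddot))


def _marker_residual(chain, beta, marker_defs, observed):
    state = forward_kinematics(chain, beta)
    pred = np.array([landmark_position(chain, state, seg, loc)
                     for seg, loc in marker_defs])
    return (pred - observed).ravel()


def inverse_kinematics(marker_times, marker_positions, marker_defs,
                       chain: JointChain, beta0=None, cutoff_hz: float = 6.0,
                       max_iter: int = 50, tol: float = 1e-10) -> TrajectorySet:
    """Per-frame Gauss-Newton fit of joint angles to labeled plane markers.

    Parameters
    ----------
    marker_times : (nt,) uniform sample times.
    marker_positions : (nt, n_markers, 2) observed positions.
    marker_defs : list of (segment_name, local_point) defining each marker.
    cutoff_hz : zero-phase 2nd-order Butterworth low-pass cutoff applied to
        the fitted angles before differentiating (pass None to disable).

    Derivatives are taken by central differences of the filtered angles.
    """
    times = np.asarray(marker_times, dtype=float)
    obs = np.asarray(marker_positions, dtype=float)
    nt = len(times)
    f = chain.f
    betas = np.zeros((nt, f))
    beta = np.zeros(f) if beta0 is None else np.asarray(beta0, dtype=float)
    h = 1e-7
    for frame in range(nt):
        target = obs[frame]
        converged = False
        for _ in range(max_iter):
            r = _marker_residual(chain, beta, marker_defs, target)
            J = np.zeros((len(r), f))
            for j in range(f):
                db = np.zeros(f)
                db[j] = h
                J[:, j] = (_marker_residual(chain, beta + db, marker_defs, target)
                           - r) / h
            step, *_ = np.linalg.lstsq(J, -r, rcond=None)
            beta = beta + step
            if np.linalg.norm(step) < tol:
                converged = True
                break
        if not converged and frame > 0:
            beta = betas[frame - 1].copy()  # previous-frame fallback
        betas[frame] = beta
    dt = times[1] - times[0]
    if cutoff_hz is not None and nt > 12:
        b, a = butter(2, cutoff_hz * 2 * dt)
        betas = filtfilt(b, a, betas, axis=0)
    bdot = np.gradient(betas, dt, axis=0)
    bddot = np.gradient(bdot, dt, axis=0)
    return TrajectorySet(times, betas, bdot, bddot)
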