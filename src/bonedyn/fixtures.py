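"""Deterministic synthetic-data generators for every pipeline stage.

These stand in for the clinical inputs (a QCT scan with a density phantom,
a femur geometry, gait-lab squat data, a muscle dataset) so that the whole
workflow is testable without downloads. All generators are pure functions of
their parameters and seed.

The toy femur is a swept solid: a vertical shaft whose axis bends smoothly
into an angled neck capped by a spherical head, plus a lateral greater-
trochanter bump, meshed by mapping a structured box grid (square cross
sections mapped onto discs) onto the solid and splitting each hexahedral
cell into 6 tetrahedra. Geometric fidelity is deliberately traded for
determinism and zero external meshing dependencies. The same analytic
radius/axis description used by the mesher defines the solid for volume
cross-checks and for voxelization into the synthetic attenuation volume.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import sympy
from scipy.spatial import cKDTree

from .chain import JointChain, Segment, TrajectorySet, forward_kinematics
from .materials import (
    DEFAULT_HU_PER_UNIT_DENSITY,
    HUVolume,
    MaterialField,
    MaterialLaw,
    PhantomSpec,
)
from .mesh import TetMesh
from .muscles import MusclePath

# ---------------------------------------------------------------------------
# toy femur geometry


@dataclass
class ToyFemurParams:
    """Parameters of the parametric femur solid (metres / radians)."""

    shaft_length: float = 0.30
    shaft_radius: float = 0.016
    neck_length: float = 0.05
    neck_shaft_angle: float = np.radians(125.0)
    head_radius: float = 0.024
    trochanter_offset: float = 0.012
    cortical_thickness: float = 0.004
    resolution: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("shaft_length", "shaft_radius", "neck_length",
                     "head_radius", "trochanter_offset", "cortical_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cortical_thickness >= self.shaft_radius:
            raise ValueError("cortical shell must be thinner than the shaft radius")
        if not 0 < self.neck_shaft_angle < np.pi:
            raise ValueError("neck-shaft angle must lie in (0, pi)")


class FemurGeometry:
    """Analytic axis/radius description of the toy femur solid.

    The axis lies in the x-z plane: straight shaft along +z, then a smooth
    bend (half-cosine tilt transition of half-width ``delta``) into the neck
    direction; arc length ``s`` parametrizes it. Cross sections are discs of
    radius ``radius(s, theta)`` in the local frame (e1 in-plane, e2 = +y),
    with the trochanter as a lateral (theta = pi) Gaussian bump near the
    neck base.
    """

    N_AXIS = 1500

    def __init__(self, params: ToyFemurParams):
        p = params
        self.params = p
        self.tilt = np.pi - p.neck_shaft_angle  # tilt of neck vs shaft axis
        self.delta = 0.03  # half-width of the bend transition (m)
        self.neck_radius = 0.8 * p.shaft_radius
        rmin = 0.35 * p.head_radius  # truncation radius of the head cap
        s1 = p.shaft_length + p.neck_length  # neck end / head start
        self.s_head_center = s1 + np.sqrt(p.head_radius ** 2
                                          - self.neck_radius ** 2)
        self.total_length = self.s_head_center + np.sqrt(
            p.head_radius ** 2 - rmin ** 2)
        self.s_trochanter = p.shaft_length
        self.troch_width = 0.025

        s = np.linspace(0.0, self.total_length, self.N_AXIS)
        phi = self._tilt_angle(s)
        t = np.stack([np.sin(phi), np.zeros_like(phi), np.cos(phi)], axis=1)
        pts = np.zeros((len(s), 3))
        ds = s[1] - s[0]
        pts[1:] = np.cumsum(0.5 * (t[1:] + t[:-1]) * ds, axis=0)
        self.s_grid = s
        self.axis_points = pts
        self.tangents = t
        self.e1 = np.stack([np.cos(phi), np.zeros_like(phi), -np.sin(phi)],
                           axis=1)
        self.kappa = np.gradient(phi, s)

    def _tilt_angle(self, s):
        s = np.asarray(s, dtype=float)
        x = np.clip((s - (self.s_trochanter - self.delta)) / (2 * self.delta),
                    0.0, 1.0)
        smooth = x * x * (3 - 2 * x)
        return self.tilt * smooth

    def base_radius(self, s):
        """Axisymmetric radius profile r0(s)."""
        p = self.params
        s = np.asarray(s, dtype=float)
        r = np.full(s.shape, p.shaft_radius)
        s1 = p.shaft_length + p.neck_length
        in_neck = (s > p.shaft_length) & (s <= s1)
        frac = (s[in_neck] - p.shaft_length) / p.neck_length
        r[in_neck] = p.shaft_radius + (self.neck_radius - p.shaft_radius) * frac
        in_head = s > s1
        r[in_head] = np.sqrt(np.clip(
            p.head_radius ** 2 - (s[in_head] - self.s_head_center) ** 2, 0, None))
        return np.maximum(r, 0.3 * self.neck_radius)

    def radius(self, s, theta):
        """Full radius r(s, theta) including the trochanter bump."""
        p = self.params
        s = np.asarray(s, dtype=float)
        theta = np.asarray(theta, dtype=float)
        bump = (p.trochanter_offset
                * np.exp(-(((s - self.s_trochanter) / self.troch_width) ** 2))
                * np.maximum(0.0, np.cos(theta - np.pi)) ** 3)
        return self.base_radius(s) + bump

    def frame_at(self, s):
        """Interpolated (point, tangent, e1, kappa) at arc length(s) s."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = []
        for arr in (self.axis_points, self.tangents, self.e1):
            out.append(np.stack([np.interp(s, self.s_grid, arr[:, c])
                                 for c in range(3)], axis=-1))
        kap = np.interp(s, self.s_grid, self.kappa)
        return out[0], out[1], out[2], kap

    def surface_point(self, s, theta):
        pt, _, e1, _ = self.frame_at(s)
        e2 = np.array([0.0, 1.0, 0.0])
        r = self.radius(s, theta)
        return (pt + r[..., None] * (np.cos(theta)[..., None] * e1
                                     + np.sin(theta)[..., None] * e2)).squeeze()

    def analytic_volume(self, n_s: int = 4000, n_theta: int = 720) -> float:
        """Dense quadrature of the swept-solid volume (curvature-corrected):

        V = int ds int dtheta [ r^2/2 - kappa cos(theta) r^3/3 ].
        """
        s = np.linspace(0, self.total_length, n_s)
        th = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
        S, TH = np.meshgrid(s, th, indexing="ij")
        R = self.radius(S.ravel(), TH.ravel()).reshape(S.shape)
        kap = np.interp(s, self.s_grid, self.kappa)[:, None]
        integrand = R ** 2 / 2 - kap * np.cos(TH) * R ** 3 / 3
        dth = 2 * np.pi / n_theta
        return float(np.trapezoid(integrand.sum(axis=1) * dth, s))

    def locate(self, points):
        """Arc length, radial fraction and angle of arbitrary 3D points.

        Returns (s, rho_frac, theta) with rho_frac = distance from axis
        normalized by the local surface radius (<= 1 inside the solid).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        tree = cKDTree(self.axis_points)
        _, idx = tree.query(points)
        s = self.s_grid[idx]
        d = points - self.axis_points[idx]
        x1 = np.einsum("ij,ij->i", d, self.e1[idx])
        x2 = d[:, 1]
        theta = np.arctan2(x2, x1)
        rho = np.hypot(x1, x2)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = rho / self.radius(s, theta)
        return s, frac, theta


def _square_to_disc(u, v):
    return u * np.sqrt(1 - v ** 2 / 2), v * np.sqrt(1 - u ** 2 / 2)


def _hexes_to_tets(hexes: np.ndarray) -> np.ndarray:
    """Kuhn 6-tet split along the main diagonal (conforming globally).

    ``hexes`` is (H, 8) with vertex order (i,j,k) binary counting:
    0:(0,0,0) 1:(1,0,0) 2:(0,1,0) 3:(1,1,0) 4:(0,0,1) 5:(1,0,1)
    6:(0,1,1) 7:(1,1,1).
    """
    paths = [
        (0, 1, 3, 7), (0, 3, 2, 7), (0, 2, 6, 7),
        (0, 6, 4, 7), (0, 4, 5, 7), (0, 5, 1, 7),
    ]
    return np.concatenate([hexes[:, p] for p in paths], axis=0)


def _structured_box_tets(nx, ny, nz):
    """Node lattice index grid and tet connectivity for an nx*ny*nz cell box."""
    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    corners = []
    for dk in (0, 1):
        for dj in (0, 1):
            for di in (0, 1):
                corners.append(nid(I + di, J + dj, K + dk).ravel())
    # order built as binary (di fastest) -> matches _hexes_to_tets convention
    hexes = np.stack(corners, axis=1)
    return _hexes_to_tets(hexes)


def make_toy_femur_mesh(params: ToyFemurParams = None):
    """Parametric toy femur: mesh + named sets + landmarks.

    Returns (mesh, geometry). Element count scales with
    ``params.resolution``; the default (2) gives a few thousand elements.
    """
    params = params or ToyFemurParams()
    geo = FemurGeometry(params)
    lvl = params.resolution
    if lvl < 1:
        raise ValueError("resolution must be >= 1")
    nu = 2 * lvl + 3  # nodes per cross-section edge
    ns = 13 + 8 * lvl  # cross sections

    u = np.linspace(-1, 1, nu)
    U, V = np.meshgrid(u, u, indexing="ij")
    xd, yd = _square_to_disc(U, V)
    rho = np.hypot(xd, yd)
    theta = np.arctan2(yd, xd)

    # area-preserving radial scale: the boundary ring is a polygon inscribed
    # in the unit circle; inflate radii so each section's polygon area
    # matches the disc area
    bu = np.concatenate([U[:, 0], U[-1, 1:], U[-2::-1, -1], U[0, -2::-1]])
    bv = np.concatenate([V[:, 0], V[-1, 1:], V[-2::-1, -1], V[0, -2::-1]])
    bx, by = _square_to_disc(bu, bv)
    poly_area = 0.5 * np.abs(np.dot(bx, np.roll(by, -1))
                             - np.dot(by, np.roll(bx, -1)))
    rho = rho * np.sqrt(np.pi / poly_area)

    # adaptive axial spacing: cluster sections where the radius profile
    # changes fast (neck taper, head cap)
    s_f = np.linspace(0, geo.total_length, 3000)
    dr = np.abs(np.gradient(geo.base_radius(s_f), s_f))
    w = 1.0 + 0.35 * dr
    W = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1])
                                         * np.diff(s_f))])
    s_vals = np.interp(np.linspace(0, W[-1], ns), W, s_f)
    s_vals[0], s_vals[-1] = 0.0, geo.total_length
    pts = np.zeros((ns, nu, nu, 3))
    for i, s in enumerate(s_vals):
        p0, _, e1, _ = geo.frame_at(s)
        e2 = np.array([0.0, 1.0, 0.0])
        r = geo.radius(np.full(theta.shape, s), theta)
        rad = rho * r
        pts[i] = (p0[0]
                  + rad[..., None] * np.cos(theta)[..., None] * e1[0]
                  + rad[..., None] * np.sin(theta)[..., None] * e2)

    # node ids: (section, iu, iv) -> flatten with section slowest
    nodes = pts.reshape(-1, 3)

    def nid(sec, iu, iv):
        return (sec * nu + iu) * nu + iv

    I, J, K = np.meshgrid(np.arange(ns - 1), np.arange(nu - 1),
                          np.arange(nu - 1), indexing="ij")
    corners = []
    for dk in (0, 1):  # iv
        for dj in (0, 1):  # iu
            for di in (0, 1):  # section
                corners.append(nid(I + di, J + dj, K + dk).ravel())
    hexes = np.stack(corners, axis=1)
    elements = _hexes_to_tets(hexes)

    mesh = TetMesh(nodes, elements)
    mesh.orient()
    # drop zero-volume tets from collapsed cells (none expected, but safety
    # for extreme parameter combinations is a geometry error, not silent)
    if np.any(mesh.signed_volumes() <= 0):
        raise ValueError("self-intersecting femur parameters produce a "
                         "degenerate mesh; reduce neck tilt or radii")

    # --- named node sets -------------------------------------------------
    sec_idx = np.repeat(np.arange(ns), nu * nu)
    on_surface = np.tile((rho > 1 - 1e-9).ravel(), ns)
    s_of_node = s_vals[sec_idx]
    theta_of_node = np.tile(theta.ravel(), ns)

    distal = np.where(sec_idx <= 1)[0]
    head = np.where(on_surface & (s_of_node >= geo.s_head_center))[0]
    troch = np.where(
        on_surface
        & (np.abs(s_of_node - geo.s_trochanter) <= geo.troch_width)
        & (np.cos(theta_of_node - np.pi) > 0.4))[0]
    mesh.node_sets = {
        "distal_clamp": distal,
        "head_patch": head,
        "trochanter_patch": troch,
    }

    # --- neck element quadrant sets --------------------------------------
    cent = mesh.element_centroids()
    s_c, frac_c, th_c = geo.locate(cent)
    p = params
    neck_lo = p.shaft_length + 0.25 * p.neck_length
    neck_hi = p.shaft_length + 0.85 * p.neck_length
    in_neck = (s_c >= neck_lo) & (s_c <= neck_hi) & (frac_c > 0.45)
    quads = {
        "neck_inferior": np.cos(th_c) > np.cos(np.pi / 4),
        "neck_superior": np.cos(th_c - np.pi) > np.cos(np.pi / 4),
        "neck_anterior": np.cos(th_c - np.pi / 2) > np.cos(np.pi / 4),
        "neck_posterior": np.cos(th_c + np.pi / 2) > np.cos(np.pi / 4),
    }
    mesh.element_sets = {k: np.where(in_neck & m)[0] for k, m in quads.items()}

    # --- landmarks --------------------------------------------------------
    head_center = geo.frame_at(geo.s_head_center)[0][0]
    troch_tip = geo.surface_point(geo.s_trochanter, np.pi)
    attach3, _ = _femur_landmarks_2d(params)
    mesh.landmarks = {
        "knee_center": np.zeros(3),
        "head_center": head_center,
        "head_top": geo.surface_point(geo.total_length, 0.0),
        "trochanter_tip": troch_tip,
        **attach3,
    }
    mesh.metadata = {
        "generator": "toy-femur",
        "frame": "right-handed, z along shaft axis, bend plane x-z",
        "resolution": lvl,
    }
    mesh.validate()
    return mesh, geo


# ---------------------------------------------------------------------------
# synthetic attenuation volume


def make_synthetic_hu_volume(
    params: ToyFemurParams = None,
    phantom_densities=(0.1, 0.4, 0.8, 1.2),
    noise_sigma: float = 0.0,
    seed: int = 0,
    spacing_mm: float = 2.5,
    shell_hu: float = 1500.0,
    core_hu_range=(250.0, 500.0),
    background_hu: float = -1000.0,
):
    """Voxelized femur + calibration-phantom attenuation volume.

    The cortical shell gets high attenuation, the trabecular core a radial
    gradient, the background air-like values; phantom cylinders carry the HU
    value that inverts exactly to their nominal density through the default
    calibration line. Returns (volume, phantom_spec).
    """
    params = params or ToyFemurParams()
    geo = FemurGeometry(params)
    pad = 15.0  # mm
    xr = (-60.0 - pad, 80.0 + pad)
    yr = (-40.0 - pad, 40.0 + pad)
    zr = (-60.0, geo.total_length * 1e3 + pad + 30.0)
    axes = [np.arange(lo, hi + spacing_mm, spacing_mm) for lo, hi in (xr, yr, zr)]
    shape = tuple(len(a) for a in axes)
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)  # mm
    pts_m = grid.reshape(-1, 3) / 1e3

    s, frac, theta = geo.locate(pts_m)
    hu = np.full(len(pts_m), background_hu)
    inside = frac <= 1.0
    r_surf = geo.radius(s, theta)
    shell = inside & (frac * r_surf >= r_surf - params.cortical_thickness)
    core = inside & ~shell
    hu[shell] = shell_hu
    lo, hi = core_hu_range
    core_frac = np.clip(frac[core], 0, 1)
    hu[core] = hi - (hi - lo) * core_frac  # densest trabeculae near the axis

    # phantom cylinders along y below the bone
    inserts = []
    z0 = -35.0  # mm
    x_positions = np.linspace(-40.0, 40.0, len(phantom_densities))
    radius_mm = 9.0
    for rho_i, xc in zip(phantom_densities, x_positions):
        d2 = (grid[..., 0] - xc) ** 2 + (grid[..., 2] - z0) ** 2
        mask = d2 <= radius_mm ** 2
        hu.reshape(shape)[mask] = rho_i * DEFAULT_HU_PER_UNIT_DENSITY
        inserts.append((float(rho_i),
                        (np.array([xc, 0.0, z0]), radius_mm * 0.8)))

    hu = hu.reshape(shape)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        hu = hu + rng.normal(0.0, noise_sigma, size=shape)
    origin = np.array([axes[0][0], axes[1][0], axes[2][0]])
    vol = HUVolume(hu, np.full(3, spacing_mm), origin)
    return vol, PhantomSpec(inserts)


# ---------------------------------------------------------------------------
# chain, muscles, trajectory


def make_default_chain(params: ToyFemurParams = None) -> JointChain:
    """Sagittal squat chain with both legs lumped into one (synthetic
    anthropometry, ~67 kg total); the thigh geometry comes from the toy
    femur landmarks so chain and superelement share attachment sites."""
    params = params or ToyFemurParams()
    geo = FemurGeometry(params)
    head_center = geo.frame_at(geo.s_head_center)[0][0]
    hip_local = np.array([head_center[0], head_center[2]])  # (x, z)

    def lm2d(p3):
        return np.array([p3[0], p3[2]])

    _, femur_mesh_landmarks = _femur_landmarks_2d(params)

    shank_len = 0.43
    segments = [
        Segment("shank", mass=9.0, com=(0.0, 0.24), inertia=9.0 * 0.43 ** 2 / 12,
                distal_joint=(0.0, shank_len),
                landmarks={"post_distal": (-0.035, 0.12),
                           "ant_distal": (0.035, 0.10),
                           "ant_prox": (0.040, 0.395),
                           "post_prox": (-0.028, 0.40)}),
        Segment("thigh", mass=20.0, com=(0.0, 0.20),
                inertia=20.0 * 0.42 ** 2 / 12,
                distal_joint=hip_local,
                landmarks=femur_mesh_landmarks),
        Segment("pelvis", mass=12.0, com=(0.0, 0.08), inertia=0.15,
                distal_joint=(0.0, 0.15),
                landmarks={"post_low": (-0.10, 0.02), "ant_low": (0.06, 0.05),
                           "post_up": (-0.08, 0.13), "ant_up": (0.07, 0.13)}),
        Segment("torso", mass=29.0, com=(0.0, 0.30),
                inertia=29.0 * 0.65 ** 2 / 12,
                landmarks={"post": (-0.08, 0.14), "ant": (0.09, 0.14)}),
    ]
    return JointChain(
        segments,
        joint_names=["ankle", "knee", "hip", "torso"],
        ground_landmarks={"heel": np.array([-0.08, 0.0]),
                          "toe": np.array([0.14, 0.02])},
    )


def _femur_landmarks_2d(params: ToyFemurParams) -> tuple:
    mesh_landmarks = {}
    geo = FemurGeometry(params)
    Ls = params.shaft_length
    pts3 = {
        "attach_quad": geo.surface_point(0.55 * Ls, 0.0),
        "attach_ham": geo.surface_point(0.50 * Ls, np.pi),
        "attach_glut": geo.surface_point(geo.s_trochanter, np.pi),
        "attach_iliopsoas": geo.surface_point(0.85 * Ls, 0.0),
        # two-point patellar channel: keeps the knee-extension moment arm
        # near the anterior condyle offset over the whole flexion range
        "patella_via": np.array([params.shaft_radius + 0.029, 0.0, 0.05]),
        "patella_channel": np.array([params.shaft_radius + 0.034, 0.0, 0.01]),
    }
    for k, v in pts3.items():
        mesh_landmarks[k] = np.array([v[0], v[2]])
    return pts3, mesh_landmarks


def make_default_muscle_set(chain: JointChain) -> list:
    """Eight line actuators, one antagonist pair per hinge (synthetic
    PCSA / max-stress / volume values, not anatomical data)."""
    sig = 5e5  # Pa maximal isometric stress

    def mk(name, points, C, length):
        area = C / sig
        return MusclePath(name, points, area=area, sigma_max=sig,
                          volume=area * length)

    g = chain.ground_landmarks
    sh = chain.segments[chain.segment_index("shank")].landmarks
    th = chain.segments[chain.segment_index("thigh")].landmarks
    pe = chain.segments[chain.segment_index("pelvis")].landmarks
    to = chain.segments[chain.segment_index("torso")].landmarks
    return [
        mk("ankle_plantarflexor",
           [("ground", g["heel"]), ("shank", sh["post_distal"])], 7000, 0.30),
        mk("ankle_dorsiflexor",
           [("ground", g["toe"]), ("shank", sh["ant_distal"])], 2500, 0.25),
        mk("knee_extensor",
           [("shank", sh["ant_prox"]), ("thigh", th["patella_channel"]),
            ("thigh", th["patella_via"]), ("thigh", th["attach_quad"])],
           12000, 0.30),
        mk("knee_flexor",
           [("shank", sh["post_prox"]), ("thigh", th["attach_ham"])], 6000, 0.30),
        mk("hip_extensor",
           [("thigh", th["attach_glut"]), ("pelvis", pe["post_low"])], 10000, 0.25),
        mk("hip_flexor",
           [("thigh", th["attach_iliopsoas"]), ("pelvis", pe["ant_low"])],
           6000, 0.22),
        mk("torso_extensor",
           [("pelvis", pe["post_up"]), ("torso", to["post"])], 9000, 0.35),
        mk("torso_flexor",
           [("pelvis", pe["ant_up"]), ("torso", to["ant"])], 5000, 0.30),
    ]


def make_squat_trajectory(chain: JointChain, duration: float = 4.5,
                          depth: float = None, dt: float = 0.01,
                          stand_fraction: float = 0.97) -> TrajectorySet:
    """Closed-chain squat: hip descends vertically above the fixed ankle.

    The pelvis-height profile is a raised cosine (C^2, cyclic); ankle and
    knee angles follow from the two-link closed-chain geometry with the
    trunk kept vertical, and the time derivatives are evaluated from
    symbolically differentiated closed-form expressions.
    """
    shank = chain.segments[chain.segment_index("shank")]
    thigh = chain.segments[chain.segment_index("thigh")]
    L1 = float(np.linalg.norm(shank.distal_joint))
    dvec = thigh.distal_joint
    d = float(np.linalg.norm(dvec))
    chi = float(np.arctan2(-dvec[0], dvec[1]))
    h0 = stand_fraction * (L1 + d)
    if depth is None:
        depth = 0.15 * (L1 + d)  # moderate squat, knee flexion ~80 deg
    h_min = h0 - depth
    if h_min <= abs(L1 - d) * 1.05:
        raise ValueError(
            f"squat depth {depth:.3f} m unreachable: minimum hip height "
            f"{h_min:.3f} m collapses the two-link chain")

    hs = sympy.Symbol("h", positive=True)
    alpha = sympy.acos((L1 ** 2 + hs ** 2 - d ** 2) / (2 * L1 * hs))
    gamma = sympy.acos((L1 ** 2 + d ** 2 - hs ** 2) / (2 * L1 * d))
    theta1 = -alpha
    psi = theta1 + sympy.pi - gamma
    beta_exprs = [theta1, psi - chi - theta1, -(psi - chi), sympy.Integer(0)]
    fs, d1s, d2s = [], [], []
    for ex in beta_exprs:
        fs.append(sympy.lambdify(hs, ex, "numpy"))
        d1 = sympy.diff(ex, hs)
        d1s.append(sympy.lambdify(hs, d1, "numpy"))
        d2s.append(sympy.lambdify(hs, sympy.diff(d1, hs), "numpy"))

    t = np.arange(0.0, duration + dt / 2, dt)
    w = 2 * np.pi / duration
    h = h0 - depth / 2 * (1 - np.cos(w * t))
    hd = -depth / 2 * w * np.sin(w * t)
    hdd = -depth / 2 * w ** 2 * np.cos(w * t)

    f = chain.f
    beta = np.zeros((len(t), f))
    bdot = np.zeros_like(beta)
    bddot = np.zeros_like(beta)
    for j in range(f):
        bj = np.broadcast_to(np.asarray(fs[j](h), dtype=float), t.shape)
        d1j = np.broadcast_to(np.asarray(d1s[j](h), dtype=float), t.shape)
        d2j = np.broadcast_to(np.asarray(d2s[j](h), dtype=float), t.shape)
        beta[:, j] = bj
        bdot[:, j] = d1j * hd
        bddot[:, j] = d2j * hd ** 2 + d1j * hdd
    return TrajectorySet(t, beta, bdot, bddot)


def synthesize_markers(chain: JointChain, traj: TrajectorySet,
                       noise_sigma: float = 0.0, seed: int = 0):
    """Labeled plane markers generated from a joint trajectory.

    Returns (marker_defs, positions) suitable for
    :func:`bonedyn.chain.inverse_kinematics`.
    """
    defs = []
    for k, seg in enumerate(chain.segments):
        if seg.distal_joint is not None:
            defs.append((seg.name, tuple(seg.distal_joint)))
        defs.append((seg.name, tuple(seg.com)))
        if seg.distal_joint is None:
            defs.append((seg.name, (0.10, 0.25)))  # break torso symmetry
    nt = len(traj.times)
    pos = np.zeros((nt, len(defs), 2))
    from .chain import landmark_position

    for i in range(nt):
        state = forward_kinematics(chain, traj.beta[i])
        for m, (seg, loc) in enumerate(defs):
            pos[i, m] = landmark_position(chain, state, seg, np.asarray(loc))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        pos = pos + rng.normal(0.0, noise_sigma, size=pos.shape)
    return defs, pos


# ---------------------------------------------------------------------------
# verification beam


def make_beam_fixture(nx: int, ny: int, nz: int, dims=(0.10, 0.01, 0.01),
                      E: float = 10e9, nu: float = 0.0, rho: float = 1940.0):
    """Structured cantilever box (clamp at x=0, tip at x=Lx) with uniform
    material; 6 tetrahedra per hexahedral cell."""
    if min(nx, ny, nz) < 1 or min(dims) <= 0:
        raise ValueError("cell counts and dimensions must be positive")
    xs = np.linspace(0, dims[0], nx + 1)
    ys = np.linspace(-dims[1] / 2, dims[1] / 2, ny + 1)
    zs = np.linspace(-dims[2] / 2, dims[2] / 2, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    elements = _structured_box_tets(nx, ny, nz)
    mesh = TetMesh(nodes, elements)
    mesh.orient()
    mesh.node_sets = {
        "clamp": np.where(np.isclose(nodes[:, 0], 0.0))[0],
        "tip": np.where(np.isclose(nodes[:, 0], dims[0]))[0],
    }
    mesh.landmarks = {"tip_center": np.array([dims[0], 0.0, 0.0])}
    mesh.metadata = {"generator": "beam", "dims": dims}
    mesh.validate()
    law = MaterialLaw(poisson=nu, mass_density=rho,
                      e_floor=min(1e6, E))
    field = MaterialField.uniform(mesh.n_nodes, E, law)
    return mesh, field
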