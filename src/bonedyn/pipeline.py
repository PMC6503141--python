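"""End-to-end workflow driver.

Chains the stages: synthetic fixtures -> phantom calibration and material
mapping -> FE assembly -> Craig-Bampton reduction -> squat simulation with
computed muscle control -> femur load transfer -> reduced transient with
stress recovery -> strength / risk readouts for the native and
mineral-loss-weakened bones. Everything runs in one process from a single
seed; the deterministic run report excludes wall-clock timings, which go to
a separate profile structure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import fem, io, materials, reduction, strength
from .chain import JointChain
from .config import dump_config, resolve_config
from .control import cmc_track, extract_femur_loads
from .fixtures import (
    ToyFemurParams,
    make_default_chain,
    make_default_muscle_set,
    make_squat_trajectory,
    make_synthetic_hu_volume,
    make_toy_femur_mesh,
)

log = logging.getLogger("bonedyn")

#: attachment landmark name -> interface master name on the femur mesh
LANDMARK_TO_MASTER = {
    "attach_quad": "attach_quad",
    "attach_ham": "attach_ham",
    "attach_glut": "trochanter",
    "attach_iliopsoas": "attach_iliopsoas",
    "patella_via": "patella_via",
    # the patellar channel sits on the condyles; its (mostly compressive)
    # contact force routes through the distal interface
    "patella_channel": "distal",
}

#: interface master name -> mesh landmark holding its reference point
MASTER_REFERENCE = {
    "head": "head_center",
    "distal": "knee_center",
    "trochanter": "trochanter_tip",
    "attach_quad": "attach_quad",
    "attach_ham": "attach_ham",
    "attach_iliopsoas": "attach_iliopsoas",
    "patella_via": "patella_via",
}


def femur_params_from_config(cfg: dict) -> ToyFemurParams:
    fc = dict(cfg["fixtures"]["femur"])
    fc["neck_shaft_angle"] = np.radians(fc.pop("neck_shaft_angle_deg"))
    return ToyFemurParams(**fc, seed=cfg["run"]["seed"])


def build_interfaces(mesh) -> list:
    """Kinematic interface masters for joints, strength test and muscles."""
    lm = mesh.landmarks
    couplings = [
        fem.Coupling("head", lm["head_center"], mesh.node_sets["head_patch"]),
        fem.Coupling("distal", lm["knee_center"], mesh.node_sets["distal_clamp"]),
        fem.Coupling("trochanter", lm["trochanter_tip"],
                     mesh.node_sets["trochanter_patch"]),
        fem.make_coupling(mesh, lm["attach_quad"], radius=0.012,
                          name="attach_quad"),
        fem.make_coupling(mesh, lm["attach_ham"], radius=0.012,
                          name="attach_ham"),
        fem.make_coupling(mesh, lm["attach_iliopsoas"], radius=0.012,
                          name="attach_iliopsoas"),
        fem.make_coupling(mesh, lm["patella_via"], radius=0.045,
                          name="patella_via"),
    ]
    return couplings


def map_femur_loads_to_masters(history, chain: JointChain, muscles,
                               mesh) -> fem.LoadHistory:
    """Convert the extracted femur load history (joint reactions + per-
    muscle attachment forces) into wrench histories on the superelement's
    interface masters, transporting each force's moment to the master's
    reference point."""
    thigh = chain.segments[chain.segment_index("thigh")]
    lm_by_name = {k: np.asarray(v) for k, v in thigh.landmarks.items()}
    refs = {m: np.asarray(mesh.landmarks[lmk], dtype=float)
            for m, lmk in MASTER_REFERENCE.items()}
    out = {}

    def add(master, w, point3=None):
        w = np.asarray(w, dtype=float).copy()
        if point3 is not None:
            r = point3 - refs[master]
            w[:, 3:] += np.cross(np.broadcast_to(r, w[:, :3].shape), w[:, :3])
        out[master] = out.get(master, 0.0) + w

    for iface, w in history.wrenches.items():
        if iface == "hip":
            add("head", w)
        elif iface == "knee":
            add("distal", w)
        else:
            mname, pi = iface.rsplit("_p", 1)
            muscle = next(m for m in muscles if m.name == mname)
            _, local = muscle.points[int(pi)]
            local = np.asarray(local, dtype=float)
            lmk = next(k for k, v in lm_by_name.items()
                       if np.allclose(v, local, atol=1e-9))
            point3 = np.array([local[0], 0.0, local[1]])
            add(LANDMARK_TO_MASTER[lmk], w, point3)
    return fem.LoadHistory(history.times,
                           {k: np.asarray(v) for k, v in out.items()})


def _sha(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr, dtype=float).tobytes()
                          ).hexdigest()[:16]


def run_pipeline(config=None, out_dir=None, write_outputs: bool = False):
    """Run the full toy workflow; returns (report, profile, artifacts).

    ``report`` is deterministic for a given configuration and seed.
    """
    cfg = resolve_config(config)
    seed = int(cfg["run"]["seed"])
    timings = {}
    warnings_list = []
    artifacts = {}

    def stage(name):
        log.info("=== stage: %s ===", name)
        timings[name] = -time.perf_counter()

    def done(name):
        timings[name] += time.perf_counter()

    # -- fixtures ----------------------------------------------------------
    stage("fixtures")
    params = femur_params_from_config(cfg)
    mesh, geo = make_toy_femur_mesh(params)
    vol, phantom = make_synthetic_hu_volume(
        params, noise_sigma=cfg["fixtures"]["hu_volume"]["noise_sigma"],
        seed=seed, spacing_mm=cfg["fixtures"]["hu_volume"]["spacing_mm"])
    chain = make_default_chain(params)
    muscles = make_default_muscle_set(chain)
    traj = make_squat_trajectory(
        chain, duration=cfg["fixtures"]["squat"]["duration"],
        depth=cfg["fixtures"]["squat"]["depth"],
        dt=cfg["fixtures"]["squat"]["dt"])
    done("fixtures")

    # -- material mapping --------------------------------------------------
    stage("material")
    cal = materials.calibrate_phantom(vol, phantom)
    law = materials.MaterialLaw(**cfg["material"]["law"])
    base_field = materials.sample_field_to_nodes(vol, cal, law, mesh,
                                                 out_of_bounds="nearest")
    classification = materials.classify_tissue(
        base_field, mesh, threshold=cfg["material"]["tissue_threshold"])
    fields = {}
    for sc in cfg["pipeline"]["scenarios"]:
        cf, tf = materials.BMD_LOSS_SCENARIOS[sc]
        fields[sc] = materials.apply_bmd_loss(base_field, mesh, classification,
                                              cf, tf)
    done("material")

    # -- squat simulation (rigid chain + CMC) ------------------------------
    stage("squat")
    from .control import ControlGains

    gains = ControlGains.critically_damped(chain.f, cfg["msk"]["k_p"])
    record = cmc_track(chain, muscles, traj, gains,
                       dt_control=cfg["msk"]["dt_control"],
                       dt_integrate=cfg["msk"]["dt_integrate"],
                       use_reserves=cfg["msk"]["use_reserves"])
    max_reserve = float(np.abs(record.reserves).max())
    if record.reserve_flagged.any():
        warnings_list.append(
            f"reserve actuators active above 1 N m in "
            f"{int(record.reserve_flagged.sum())} control steps "
            f"(max {max_reserve:.2f} N m)")
    femur_history = extract_femur_loads(record, chain, muscles)
    master_history = map_femur_loads_to_masters(femur_history, chain, muscles,
                                                mesh)
    done("squat")

    # -- per-scenario reduction, strength and transient readouts -----------
    couplings = build_interfaces(mesh)
    protocol = strength.OrwollProtocol(
        threshold=cfg["strength"]["threshold"],
        max_load=cfg["strength"]["max_load"],
        n_steps=cfg["strength"]["n_steps"])
    neck_sites = {k: v for k, v in mesh.element_sets.items()
                  if k.startswith("neck_")}

    strengths = {}
    zscores = {}
    labels = {}
    readouts = {}
    sems = {}
    constraint = fem.MasterConstraint(fixed={"distal": "all"})
    dt_tr = cfg["pipeline"]["transient_dt"]
    for sc in cfg["pipeline"]["scenarios"]:
        stage(f"reduce[{sc}]")
        asm = fem.assemble(mesh, fields[sc])
        system = fem.SystemModel(asm, couplings)
        sem = reduction.craig_bampton(system, n_modes=cfg["reduction"]["n_modes"],
                                      zeta=cfg["reduction"]["zeta"])
        sems[sc] = sem
        done(f"reduce[{sc}]")

        stage(f"strength[{sc}]")
        res = strength.orwoll_strength(sem, protocol, neck_sites=neck_sites)
        strengths[f"{sc}_sem"] = res.strength
        zscores[sc] = {"non_fracture": res.z_nonfracture,
                       "fracture": res.z_fracture}
        labels[sc] = res.label
        if res.extrapolated:
            warnings_list.append(
                f"{sc}: strength obtained by extrapolation beyond the "
                f"{protocol.max_load:.0f} N ramp")
        if sc == "native":
            fem_res = strength.orwoll_strength(system, protocol)
            strengths["native_fem"] = fem_res.strength
        done(f"strength[{sc}]")

        if sc in ("native", "C84T67"):
            stage(f"transient[{sc}]")
            times_tr, q_red = reduction.sem_transient(
                sem, master_history, dt=dt_tr, constraint=constraint)
            baseline = readouts.get("native")
            readouts[sc] = strength.squat_risk_readout(
                sem, times_tr, q_red, protocol, neck_sites=neck_sites,
                baseline=baseline)
            done(f"transient[{sc}]")

    # -- report ------------------------------------------------------------
    native_ro = readouts["native"]
    weak_ro = readouts.get("C84T67")
    report = {
        "seed": seed,
        "mesh": {"nodes": mesh.n_nodes, "elements": mesh.n_elements,
                 "hash": _sha(mesh.nodes)},
        "hu_volume": {"shape": list(vol.values.shape), "hash": _sha(vol.values)},
        "calibration": {"slope_g_cm3_per_HU": cal.slope,
                        "intercept_g_cm3": cal.intercept,
                        "source": cal.source},
        "strength_N": {k: float(v) for k, v in strengths.items()},
        "z_scores": zscores,
        "classification": labels,
        "squat": {
            "tracking_rms_deg": [float(v) for v in record.tracking_rms_deg()],
            "max_reserve_Nm": max_reserve,
            "max_kkt_residual": float(record.kkt_residuals.max()),
            "peak_strain_native": float(native_ro.peak_strain),
            "peak_strain_C84T67": (float(weak_ro.peak_strain)
                                   if weak_ro else None),
            "strain_increase_percent": (
                float(weak_ro.percent_change_vs_baseline) if weak_ro else None),
            "within_safe_zone": bool(native_ro.within_safe_zone
                                     and (weak_ro is None
                                          or weak_ro.within_safe_zone)),
        },
        "warnings": sorted(warnings_list),
    }

    if write_outputs:
        out = Path(out_dir or cfg["run"]["out_dir"])
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, sort_keys=True, indent=2)
        with open(out / "profile.json", "w") as fh:
            json.dump({"timings_s": timings}, fh, sort_keys=True, indent=2)
        dump_config(cfg, out / "resolved_config.yaml")
        io.save_superelement(sems["native"], out / "superelement_native.h5")
        io.write_abaqus(mesh, out / "toy_femur.inp")
        io.write_trajectory_csv(traj, out / "squat_trajectory.csv",
                                joint_names=chain.joint_names)
        io.save_load_history(master_history, out / "femur_loads.h5")
        io.write_material_csv(fields["native"], out / "material_native.csv")
        artifacts["out_dir"] = out

    artifacts.update(dict(mesh=mesh, geometry=geo, volume=vol, phantom=phantom,
                          calibration=cal, fields=fields, chain=chain,
                          muscles=muscles, trajectory=traj, record=record,
                          femur_history=femur_history,
                          master_history=master_history, sems=sems,
                          readouts=readouts, couplings=couplings,
                          classification=classification, protocol=protocol))
    return report, {"timings_s": timings}, artifacts
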