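"""Bone-quality evaluation: computational strength test and risk readouts.

The strength test loads the bone in a sideways-fall configuration: the
distal shaft interface is fully fixed, the femoral-head interface is
supported along the load line, and a compressive load is ramped at the
greater-trochanter interface directed toward the head centre. The
*deformation measure* is the relative head-to-trochanter displacement

    m(F) = |u_head - u_troch| / |x_head - x_troch|_0,

and the bone strength F_crit is the load at which the measure reaches the
failure threshold (default 4% deformation). For the linear-elastic model
the load-deformation curve is a line through the origin, so F_crit follows
from the unit-load compliance; the ramp is still evaluated to expose the
full curve.

Computed strengths are placed against published cohort statistics of
sideways-fall femoral strength (non-fracture mean 5939 N, SD 1919 N;
fracture mean 3782 N, SD 1563 N) via z-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fem import (
    MasterConstraint,
    SystemModel,
    patch_average,
    principal_strain_magnitude,
    recover_stress,
)
from .reduction import SuperElement, recover, sem_static

#: Cohort reference distributions for sideways-fall femoral strength (N).
NONFRACTURE_MEAN, NONFRACTURE_SD = 5939.0, 1919.0
FRACTURE_MEAN, FRACTURE_SD = 3782.0, 1563.0


@dataclass
class OrwollProtocol:
    """Sideways-fall strength-test definition on interface masters."""

    load_interface: str = "trochanter"
    support_interface: str = "distal"
    head_interface: str = "head"
    threshold: float = 0.04  # relative deformation at failure
    max_load: float = 10000.0  # N, ramp end
    n_steps: int = 20
    head_point: np.ndarray = None  # filled from model landmarks if None
    trochanter_point: np.ndarray = None

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("deformation threshold must be positive")

    def resolve_points(self, landmarks: dict):
        head = (np.asarray(self.head_point, dtype=float)
                if self.head_point is not None
                else np.asarray(landmarks["head_center"], dtype=float))
        troch = (np.asarray(self.trochanter_point, dtype=float)
                 if self.trochanter_point is not None
                 else np.asarray(landmarks["trochanter_tip"], dtype=float))
        if np.allclose(head, troch):
            raise ValueError("head and trochanter reference points coincide")
        return head, troch


@dataclass
class StrengthResult:
    """Load-deformation curve, strength and cohort z-scores."""

    loads: np.ndarray
    deformation: np.ndarray
    strength: float  # N at the failure threshold
    threshold: float
    extrapolated: bool
    z_nonfracture: float
    z_fracture: float
    label: str
    neck_curves: dict = field(default_factory=dict)  # site -> (stress, strain)


def _model_parts(model):
    """(landmarks, element_sets, solve(wrenches, constraint) -> context)."""
    if isinstance(model, SuperElement):
        return model.landmarks, model.element_sets
    if isinstance(model, SystemModel):
        mesh = model.assembly.mesh
        return mesh.landmarks, mesh.element_sets
    raise TypeError("model must be a SystemModel or SuperElement")


def _unit_solution(model, protocol: OrwollProtocol):
    """Response to a unit trochanter load: relative deformation per N plus a
    stress/strain recovery closure."""
    landmarks, _ = _model_parts(model)
    head, troch = protocol.resolve_points(landmarks)
    d = head - troch
    L0 = np.linalg.norm(d)
    d = d / L0
    constraint = MasterConstraint(
        fixed={protocol.support_interface: "all"},
        direction_locks={protocol.head_interface: d},
    )
    wrenches = {protocol.load_interface: (d * 1.0, np.zeros(3))}
    if isinstance(model, SuperElement):
        q = sem_static(model, wrenches, constraint=constraint)
        u_head = model.master_translation(q, protocol.head_interface)
        u_troch = model.master_translation(q, protocol.load_interface)

        def recover_fn(scale, elements):
            return recover(model, q * scale, elements=elements)

        volumes = model.element_volumes
    else:
        f_q = model.force_vector(wrenches=wrenches)
        q, u_full = model.solve_static(f_q, constraint=constraint)
        u_head = model.coupling_displacement(protocol.head_interface, u_full)
        u_troch = model.coupling_displacement(protocol.load_interface, u_full)

        def recover_fn(scale, elements):
            res = recover_stress(model.assembly, u_full * scale)
            if elements is None:
                return res
            from .fem import FEResult
            return FEResult(res.u, res.strain[elements], res.stress[elements],
                            res.von_mises[elements])

        volumes = model.assembly.volumes
    measure_per_N = np.linalg.norm(u_head - u_troch) / L0
    return measure_per_N, recover_fn, volumes


def orwoll_strength(model, protocol: OrwollProtocol = None,
                    neck_sites: dict = None) -> StrengthResult:
    """Run the sideways-fall strength test on a full or reduced model.

    ``neck_sites`` maps site name -> element index array; when given, the
    patch-averaged von Mises stress vs principal-strain-magnitude curves are
    evaluated along the ramp.
    """
    protocol = protocol or OrwollProtocol()
    slope, recover_fn, volumes = _unit_solution(model, protocol)
    loads = np.linspace(0.0, protocol.max_load, protocol.n_steps + 1)
    deformation = slope * loads
    if deformation[-1] >= protocol.threshold:
        strength = protocol.threshold / slope
        extrapolated = False
    else:
        strength = protocol.threshold / slope
        extrapolated = True
        warnings.warn(
            f"deformation measure reaches only {deformation[-1]:.4g} at the "
            f"ramp end; strength {strength:.4g} N obtained by linear "
            "extrapolation", RuntimeWarning, stacklevel=2)
    zs = classify_strength(strength)
    curves = {}
    if neck_sites:
        for site, elems in neck_sites.items():
            elems = np.asarray(elems, dtype=np.intp)
            res = recover_fn(1.0, elems)
            vm = patch_average(res.von_mises, np.arange(len(elems)),
                               volumes[elems])
            strain = patch_average(principal_strain_magnitude(res.strain),
                                   np.arange(len(elems)), volumes[elems])
            curves[site] = (vm * loads, strain * loads)
    return StrengthResult(loads, deformation, float(strength),
                          protocol.threshold, extrapolated,
                          zs["z_nonfracture"], zs["z_fracture"], zs["label"],
                          curves)


def neck_site_curves(model, protocol: OrwollProtocol, sites: dict) -> dict:
    """Stress-strain ramp curves for named neck element patches."""
    for name, elems in sites.items():
        if np.asarray(elems).size == 0:
            raise ValueError(f"neck site {name!r} has an empty element patch")
    return orwoll_strength(model, protocol, neck_sites=sites).neck_curves


def classify_strength(strength: float) -> dict:
    """Z-scores against the fracture / non-fracture cohort distributions."""
    if strength <= 0:
        raise ValueError("strength must be positive")
    z_nf = (strength - NONFRACTURE_MEAN) / NONFRACTURE_SD
    z_f = (strength - FRACTURE_MEAN) / FRACTURE_SD
    d_nf = abs(strength - NONFRACTURE_MEAN)
    d_f = abs(strength - FRACTURE_MEAN)
    if np.isclose(d_nf, d_f, rtol=0, atol=1e-9):
        label = "indeterminate"
    elif d_nf < d_f:
        label = "non-fracture"
    else:
        label = "fracture"
    return {"z_nonfracture": float(z_nf), "z_fracture": float(z_f),
            "label": label}


def export_strength_result(result: StrengthResult, basepath,
                           plot: bool = False):
    """Write a StrengthResult as JSON report + CSV curves (+ optional PNG).

    Files are ``<basepath>.json``, ``<basepath>_curve.csv`` and, with
    ``plot=True``, ``<basepath>.png``.
    """
    import json
    from pathlib import Path

    import pandas as pd

    base = Path(basepath)
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump({
            "strength_N": result.strength,
            "threshold": result.threshold,
            "extrapolated": result.extrapolated,
            "z_nonfracture": result.z_nonfracture,
            "z_fracture": result.z_fracture,
            "label": result.label,
        }, fh, indent=2, sort_keys=True)
    cols = {"load_N": result.loads, "deformation": result.deformation}
    for site, (vm, eps) in result.neck_curves.items():
        cols[f"{site}_von_mises_Pa"] = vm
        cols[f"{site}_principal_strain"] = eps
    pd.DataFrame(cols).to_csv(base.parent / f"{base.stem}_curve.csv",
                              index=False)
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(result.deformation, result.loads, "-o", ms=3)
        ax.axvline(result.threshold, ls="--", color="r",
                   label=f"failure threshold ({result.threshold:g})")
        ax.axhline(result.strength, ls=":", color="k",
                   label=f"strength {result.strength:.0f} N")
        ax.set_xlabel("head-trochanter deformation measure")
        ax.set_ylabel("applied load (N)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(base.with_suffix(".png"), dpi=120)
        plt.close(fig)


# ---------------------------------------------------------------------------
# squat-cycle monitoring


@dataclass
class SquatRiskReadout:
    """Deformation-measure and neck-stress time series over a motion cycle."""

    times: np.ndarray
    strain_measure: np.ndarray
    peak_strain: float
    within_safe_zone: bool
    neck_von_mises: dict  # site -> (nt,) patch-averaged series
    percent_change_vs_baseline: float = None


def squat_risk_readout(sem: SuperElement, times: np.ndarray,
                       q_red: np.ndarray, protocol: OrwollProtocol = None,
                       neck_sites: dict = None,
                       baseline: "SquatRiskReadout" = None) -> SquatRiskReadout:
    """Evaluate the failure-associated strain measure over a simulated cycle.

    ``q_red`` is the (nt, n_red) reduced-coordinate history of the femur
    superelement under the squat load transfer. The strain measure is the
    same head-to-trochanter relative deformation used by the strength test;
    the safe-zone flag records whether it stays below the failure threshold
    throughout the cycle.
    """
    protocol = protocol or OrwollProtocol()
    head, troch = protocol.resolve_points(sem.landmarks)
    L0 = np.linalg.norm(head - troch)
    u_head = sem.master_translation(q_red, protocol.head_interface)
    u_troch = sem.master_translation(q_red, protocol.load_interface)
    measure = np.linalg.norm(u_head - u_troch, axis=-1) / L0
    peak = float(measure.max())
    vm_series = {}
    if neck_sites:
        for site, elems in neck_sites.items():
            elems = np.asarray(elems, dtype=np.intp)
            res = recover(sem, q_red, elements=elems)
            vols = sem.element_volumes[elems]
            vm_series[site] = np.einsum("te,e->t", res.von_mises, vols) / vols.sum()
    pct = None
    if baseline is not None:
        if len(baseline.times) != len(times) or not np.allclose(
                baseline.times, times):
            warnings.warn("baseline time base differs; comparing by resampling",
                          RuntimeWarning, stacklevel=2)
            base_peak = baseline.peak_strain
        else:
            base_peak = baseline.peak_strain
        pct = 100.0 * (peak - base_peak) / base_peak
    return SquatRiskReadout(np.asarray(times), measure, peak,
                            bool(peak < protocol.threshold), vm_series, pct)
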