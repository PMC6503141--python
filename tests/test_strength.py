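"""Sideways-fall strength test, risk classification, squat readout."""

import numpy as np
import pytest

from bonedyn import fem, reduction, strength
from bonedyn.fixtures import make_beam_fixture
from bonedyn.materials import MaterialField, MaterialLaw


@pytest.fixture(scope="module")
def strength_model():
    """Beam stand-in with head/trochanter/distal interface masters."""
    mesh, field = make_beam_fixture(12, 3, 3, dims=(0.12, 0.012, 0.012),
                                    E=10e9, nu=0.3)
    mesh.landmarks["head_center"] = np.array([0.12, 0.0, 0.0])
    mesh.landmarks["trochanter_tip"] = np.array([0.08, 0.0, 0.006])
    couplings = [
        fem.make_coupling(mesh, mesh.landmarks["head_center"], radius=0.008,
                          name="head"),
        fem.make_coupling(mesh, mesh.landmarks["trochanter_tip"],
                          radius=0.008, name="trochanter"),
        fem.make_coupling(mesh, [0.0, 0, 0], radius=0.008, name="distal"),
    ]
    asm = fem.assemble(mesh, field)
    return mesh, field, fem.SystemModel(asm, couplings), couplings


def _scaled_system(mesh, field, couplings, c):
    law = field.law
    scaled = MaterialField(field.node_ash_density,
                           np.maximum(field.node_modulus * c, law.e_floor),
                           law)
    return fem.SystemModel(fem.assemble(mesh, scaled), couplings)


class TestOrwollStrength:
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_uniform_stiffness_scaling_scales_strength_exactly(
            self, strength_model):
        mesh, field, system, couplings = strength_model
        res1 = strength.orwoll_strength(system)
        res2 = strength.orwoll_strength(
            _scaled_system(mesh, field, couplings, 0.5))
        assert res2.strength == pytest.approx(0.5 * res1.strength,
                                              rel=1e-10)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_doubling_threshold_doubles_strength(self, strength_model):
        *_, system, _ = strength_model
        p1 = strength.OrwollProtocol(threshold=0.04)
        p2 = strength.OrwollProtocol(threshold=0.08)
        r1 = strength.orwoll_strength(system, p1)
        r2 = strength.orwoll_strength(system, p2)
        assert r2.strength == pytest.approx(2 * r1.strength, rel=1e-12)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_fem_and_sem_paths_agree(self, strength_model):
        *_, system, _ = strength_model
        sem = reduction.craig_bampton(system, n_modes=12)
        r_fem = strength.orwoll_strength(system)
        r_sem = strength.orwoll_strength(sem)
        assert abs(r_sem.strength - r_fem.strength) / r_fem.strength < 0.035

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_load_deformation_curve_linear_through_origin(
            self, strength_model):
        *_, system, _ = strength_model
        res = strength.orwoll_strength(system)
        assert res.deformation[0] == 0.0
        slopes = res.deformation[1:] / res.loads[1:]
        assert np.allclose(slopes, slopes[0], rtol=1e-12)

    def test_extrapolation_warns(self, strength_model):
        *_, system, _ = strength_model
        proto = strength.OrwollProtocol(max_load=10.0)
        with pytest.warns(RuntimeWarning, match="extrapolation"):
            res = strength.orwoll_strength(system, proto)
        assert res.extrapolated


class TestNeckCurves:
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_curves_linear_and_patch_average_matches_brute_force(
            self, strength_model):
        mesh, _, system, _ = strength_model
        sites = {"mid": np.arange(40, 60)}
        proto = strength.OrwollProtocol()
        curves = strength.neck_site_curves(system, proto, sites)
        vm, eps = curves["mid"]
        assert vm[0] == 0.0 and eps[0] == 0.0
        # slope invariant under load-ramp rescaling
        proto2 = strength.OrwollProtocol(max_load=2 * proto.max_load)
        vm2, eps2 = strength.neck_site_curves(system, proto2, sites)["mid"]
        s1 = vm[-1] / eps[-1]
        s2 = vm2[-1] / eps2[-1]
        assert s1 == pytest.approx(s2, rel=1e-10)
        # brute-force patch average at the final ramp load
        f = system.force_vector(wrenches={
            "trochanter": (proto.max_load * _load_dir(mesh), np.zeros(3))})
        con = fem.MasterConstraint(
            fixed={"distal": "all"},
            direction_locks={"head": _load_dir(mesh)})
        _, u = system.solve_static(f, constraint=con)
        res = fem.recover_stress(system.assembly, u)
        vols = system.assembly.volumes
        brute = sum(res.von_mises[e] * vols[e] for e in sites["mid"]) \
            / sum(vols[e] for e in sites["mid"])
        assert vm[-1] == pytest.approx(brute, rel=1e-9)

    def test_empty_patch_rejected(self, strength_model):
        *_, system, _ = strength_model
        with pytest.raises(ValueError, match="empty"):
            strength.neck_site_curves(system, strength.OrwollProtocol(),
                                      {"void": np.array([], dtype=int)})


def _load_dir(mesh):
    d = mesh.landmarks["head_center"] - mesh.landmarks["trochanter_tip"]
    return d / np.linalg.norm(d)


class TestExport:
    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_json_csv_and_plot_files_written(self, tmp_path, strength_model):
        *_, system, _ = strength_model
        res = strength.orwoll_strength(system,
                                       neck_sites={"mid": np.arange(30, 40)})
        strength.export_strength_result(res, tmp_path / "native", plot=True)
        import json as _json

        data = _json.loads((tmp_path / "native.json").read_text())
        assert data["strength_N"] == pytest.approx(res.strength)
        import pandas as pd

        df = pd.read_csv(tmp_path / "native_curve.csv")
        assert np.allclose(df["load_N"], res.loads)
        assert "mid_von_mises_Pa" in df.columns
        assert (tmp_path / "native.png").stat().st_size > 0


class TestClassification:
    @pytest.mark.parametrize("force, z_nf, z_f, label", [
        (5939.0, 0.0, (5939 - 3782) / 1563, "non-fracture"),
        (3782.0, (3782 - 5939) / 1919, 0.0, "fracture"),
    ])
    def test_cohort_means(self, force, z_nf, z_f, label):
        out = strength.classify_strength(force)
        assert out["z_nonfracture"] == pytest.approx(z_nf, abs=1e-12)
        assert out["z_fracture"] == pytest.approx(z_f, abs=1e-12)
        assert out["label"] == label

    def test_midpoint_is_indeterminate(self):
        mid = (strength.NONFRACTURE_MEAN + strength.FRACTURE_MEAN) / 2
        assert strength.classify_strength(mid)["label"] == "indeterminate"

    def test_positive_force_required(self):
        with pytest.raises(ValueError):
            strength.classify_strength(-1.0)


@pytest.fixture(scope="module")
def sem_and_history(strength_model):
    *_, system, _ = strength_model
    sem = reduction.craig_bampton(system, n_modes=8, zeta=0.025)
    t = np.linspace(0, 1.0, 51)
    w = np.zeros((len(t), 6))
    w[:, 2] = -40.0 * np.sin(np.pi * t) ** 2
    hist = fem.LoadHistory(t, {"trochanter": w})
    con = fem.MasterConstraint(fixed={"distal": "all"})
    times, q = reduction.sem_transient(sem, hist, dt=0.01, constraint=con)
    return sem, times, q


class TestSquatReadout:

    def test_identical_baseline_gives_zero_change(self, sem_and_history):
        sem, times, q = sem_and_history
        ro = strength.squat_risk_readout(sem, times, q)
        again = strength.squat_risk_readout(sem, times, q, baseline=ro)
        assert again.percent_change_vs_baseline == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_rigid_body_motion_reads_zero_strain(self, sem_and_history):
        sem, times, _ = sem_and_history
        # uniform translation of every master, no modal content
        q = np.zeros((len(times), sem.n_red))
        for name, idx in sem.boundary_map.items():
            q[:, idx[0]] = 1e-3
        ro = strength.squat_risk_readout(sem, times, q)
        assert ro.peak_strain < 1e-15
        assert ro.within_safe_zone

    def test_softer_model_reads_larger_peak(self, strength_model):
        mesh, field, system, couplings = strength_model
        soft = _scaled_system(mesh, field, couplings, 0.5)
        out = []
        for sys_ in (system, soft):
            sem = reduction.craig_bampton(sys_, n_modes=8, zeta=0.025)
            t = np.linspace(0, 1.0, 51)
            w = np.zeros((len(t), 6))
            w[:, 2] = -40.0 * np.sin(np.pi * t) ** 2
            hist = fem.LoadHistory(t, {"trochanter": w})
            con = fem.MasterConstraint(fixed={"distal": "all"})
            times, q = reduction.sem_transient(sem, hist, dt=0.01,
                                               constraint=con)
            out.append(strength.squat_risk_readout(sem, times, q))
        native, weak = out
        assert weak.peak_strain > native.peak_strain
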