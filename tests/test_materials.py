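"""Attenuation calibration and density-to-modulus mapping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bonedyn import materials as mat
from bonedyn.fixtures import make_beam_fixture
from bonedyn.mesh import TetMesh

# frozen high-precision evaluations of the double-exponential law (sympy)
E1_OVER_E0 = 0.59431642530505755304
E0_OVER_E0 = 0.0055720068149199949594
EHALF_OVER_E0 = 0.19333229533573562411


def _volume_from_line(slope, intercept, shape=(8, 8, 8), base=200.0):
    rng = np.random.default_rng(3)
    hu = base + 50 * rng.standard_normal(shape)
    return mat.HUVolume(hu, spacing=np.ones(3))


class TestCalibration:
    def test_two_noiseless_inserts_give_exact_line(self):
        vol = mat.HUVolume(np.zeros((6, 6, 12)), np.ones(3))
        vol.values[:, :, :6] = 0.0
        vol.values[:, :, 6:] = 895.93
        phantom = mat.PhantomSpec([
            (0.0, (np.array([2.5, 2.5, 2.0]), 2.0)),
            (1.0, (np.array([2.5, 2.5, 9.0]), 2.0)),
        ])
        cal = mat.calibrate_phantom(vol, phantom)
        assert cal.source == "phantom-regression"
        assert cal.slope == pytest.approx(1 / 895.93, rel=1e-14)
        assert cal.intercept == pytest.approx(0.0, abs=1e-14)

    def test_known_line_recovered_to_machine_precision(self):
        s, c = 1.7e-3, 0.042
        vol = mat.HUVolume(np.zeros((4, 4, 20)), np.ones(3))
        centers, dens = [], []
        for i, hu in enumerate([100.0, 300.0, 600.0, 900.0]):
            vol.values[:, :, 5 * i: 5 * i + 5] = hu
            centers.append((np.array([1.5, 1.5, 5 * i + 2.0]), 1.4))
            dens.append(s * hu + c)
        phantom = mat.PhantomSpec(list(zip(dens, centers)))
        cal = mat.calibrate_phantom(vol, phantom)
        assert cal.slope == pytest.approx(s, rel=1e-12)
        assert cal.intercept == pytest.approx(c, rel=1e-12)

    def test_noisy_inserts_match_normal_equations_oracle(self):
        # independent closed-form OLS via the normal equations
        rng = np.random.default_rng(42)
        vol = mat.HUVolume(np.zeros((4, 4, 20)), np.ones(3))
        hu_nominal = [100.0, 300.0, 600.0, 900.0]
        centers, dens = [], []
        for i, hu in enumerate(hu_nominal):
            vol.values[:, :, 5 * i: 5 * i + 5] = hu + rng.normal(
                0, 5.0, (4, 4, 5))
            centers.append((np.array([1.5, 1.5, 5 * i + 2.0]), 1.4))
            dens.append(hu / 895.93)
        phantom = mat.PhantomSpec(list(zip(dens, centers)))
        cal = mat.calibrate_phantom(vol, phantom)

        masks = phantom.region_masks(vol)
        x = np.array([vol.values[m].mean() for m in masks])
        y = np.array(dens)
        X = np.stack([x, np.ones_like(x)], axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert cal.slope == pytest.approx(beta[0], rel=1e-10)
        assert cal.intercept == pytest.approx(beta[1], rel=1e-10)

    def test_degenerate_and_underdetermined_phantoms_rejected(self):
        with pytest.raises(mat.CalibrationError):
            mat.PhantomSpec([(0.5, (np.zeros(3), 1.0))])
        vol = mat.HUVolume(np.full((5, 5, 5), 100.0), np.ones(3))
        phantom = mat.PhantomSpec([
            (0.2, (np.array([2, 2, 1.0]), 1.0)),
            (0.8, (np.array([2, 2, 3.0]), 1.0)),
        ])
        with pytest.raises(mat.CalibrationError, match="degenerate"):
            mat.calibrate_phantom(vol, phantom)


class TestDensityModulusLaw:
    @pytest.mark.parametrize("hu, rho", [
        (0.0, 0.0),
        (895.93, 1.0),
        (447.965, 0.5),
    ])
    def test_default_calibration_values(self, hu, rho):
        assert mat.hu_to_ash_density(hu) == pytest.approx(rho, abs=1e-12)

    @pytest.mark.parametrize("rho, ratio", [
        (1.0, E1_OVER_E0),
        (0.0, E0_OVER_E0),
        (0.5, EHALF_OVER_E0),
    ])
    def test_modulus_matches_hand_evaluation(self, rho, ratio):
        law = mat.MaterialLaw()
        assert mat.ash_density_to_modulus(rho, law) == pytest.approx(
            ratio * law.e0, rel=1e-12)

    def test_negative_density_clamps_to_floor(self):
        law = mat.MaterialLaw()
        assert mat.ash_density_to_modulus(-0.5, law) == law.e_floor == 1e6

    @given(st.floats(-1.0, 3.0), st.floats(1e-6, 1.0))
    def test_monotone_above_floor(self, rho, drho):
        law = mat.MaterialLaw()
        e1 = mat.ash_density_to_modulus(rho, law)
        e2 = mat.ash_density_to_modulus(rho + drho, law)
        if e1 > law.e_floor * (1 + 1e-9):
            assert e2 > e1
        assert min(e1, e2) >= law.e_floor


class TestFieldSampling:
    def _mesh_in_unit_box(self):
        mesh, _ = make_beam_fixture(2, 2, 2, dims=(0.004, 0.004, 0.004))
        mesh.nodes += np.array([0.002, 0.004, 0.004])  # inside 8mm volume
        return mesh

    def test_constant_volume_gives_constant_moduli(self):
        vol = mat.HUVolume(np.full((9, 9, 9), 500.0), np.ones(3))
        mesh = self._mesh_in_unit_box()
        field = mat.sample_field_to_nodes(vol, mat.CalibrationModel.default(),
                                          mat.MaterialLaw(), mesh)
        expected = mat.ash_density_to_modulus(mat.hu_to_ash_density(500.0))
        assert np.allclose(field.node_modulus, expected, rtol=1e-12)

    def test_voxel_center_and_midpoint_interpolation(self):
        vals = np.zeros((4, 4, 4))
        vals[1, 1, 1] = 200.0
        vals[2, 1, 1] = 400.0
        vol = mat.HUVolume(vals, np.ones(3))
        nodes = np.array([[1.0, 1, 1], [1.5, 1, 1]]) / 1e3  # m
        mesh = TetMesh(np.vstack([nodes, [[1, 1, 2.0], [1, 2, 1.0]]]) / 1,
                       np.array([[0, 1, 2, 3]]))
        mesh.nodes[2:] /= 1e3
        cal = mat.CalibrationModel.default()
        field = mat.sample_field_to_nodes(vol, cal, mat.MaterialLaw(), mesh)
        rho = field.node_ash_density
        assert rho[0] == pytest.approx(mat.hu_to_ash_density(200.0), rel=1e-12)
        assert rho[1] == pytest.approx(mat.hu_to_ash_density(300.0), rel=1e-12)

    def test_out_of_bounds_policy(self):
        vol = mat.HUVolume(np.full((4, 4, 4), 100.0), np.ones(3))
        mesh = self._mesh_in_unit_box()
        mesh.nodes[0] = [0.02, 0.0, 0.0]  # 20 mm: outside
        with pytest.raises(ValueError, match="outside"):
            mat.sample_field_to_nodes(vol, mat.CalibrationModel.default(),
                                      mat.MaterialLaw(), mesh)
        field = mat.sample_field_to_nodes(vol, mat.CalibrationModel.default(),
                                          mat.MaterialLaw(), mesh,
                                          out_of_bounds="nearest")
        assert np.isfinite(field.node_modulus).all()


class TestTissueAndBMDLoss:
    def _uniform_field(self, mesh, rho):
        law = mat.MaterialLaw()
        dens = np.full(mesh.n_nodes, rho)
        return mat.MaterialField(dens, mat.ash_density_to_modulus(dens, law),
                                 law)

    def test_threshold_classification(self):
        mesh, _ = make_beam_fixture(2, 2, 2)
        assert mat.classify_tissue(self._uniform_field(mesh, 1.2), mesh,
                                   0.6).element_label.all()
        assert not mat.classify_tissue(self._uniform_field(mesh, 0.2), mesh,
                                       0.6).element_label.any()

    def test_identity_and_uniform_scaling(self):
        mesh, _ = make_beam_fixture(3, 2, 2)
        field = self._uniform_field(mesh, 1.0)
        cls = mat.classify_tissue(field, mesh, 0.6)
        same = mat.apply_bmd_loss(field, mesh, cls, 1.0, 1.0)
        assert np.array_equal(same.node_modulus, field.node_modulus)
        assert same is not field
        scaled = mat.apply_bmd_loss(field, mesh, cls, 0.7, 0.7)
        assert np.allclose(scaled.node_modulus, 0.7 * field.node_modulus)
        # input unchanged
        assert np.allclose(field.node_modulus,
                           mat.ash_density_to_modulus(1.0))

    def test_class_specific_factors(self):
        # two-element mesh: one dense, one light element
        nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                          [1, 1, 1.0]])
        mesh = TetMesh(nodes, np.array([[0, 1, 2, 3], [1, 2, 3, 4]]))
        mesh.orient()
        law = mat.MaterialLaw()
        rho = np.array([1.2, 1.2, 1.2, 1.2, -2.0])
        field = mat.MaterialField(rho, mat.ash_density_to_modulus(rho, law),
                                  law)
        cls = mat.classify_tissue(field, mesh, 0.6)
        assert cls.element_label[0] and not cls.element_label[1]
        out = mat.apply_bmd_loss(field, mesh, cls, 0.84, 0.67)
        # nodes 0-3 touch both elements -> tie/majority rules apply;
        # node 4 only the trabecular element
        labels = mat.node_tissue_labels(mesh, cls)
        assert not labels[4]
        expected = np.where(labels, 0.84, 0.67) * field.node_modulus
        assert np.allclose(out.node_modulus,
                           np.maximum(expected, law.e_floor))

    def test_floor_reapplied_after_loss(self):
        mesh, _ = make_beam_fixture(2, 2, 2)
        field = self._uniform_field(mesh, -1.0)  # clamped at floor already
        cls = mat.classify_tissue(field, mesh, 0.6)
        out = mat.apply_bmd_loss(field, mesh, cls, 0.68, 0.34)
        assert np.all(out.node_modulus >= field.law.e_floor)
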