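import numpy as np
import pytest
from hypothesis import given, strategies as st

import aortaflow as af

from conftest import constant_waveform


def _rot_z(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0],
                     [0, 0, 1.0]])


REF4 = np.array([[0.01, 0, 0], [0, 0.01, 0], [-0.01, 0, 0], [0, 0.005, 0.002]])


class TestTransformFit:
    def test_coincident_points_give_identity(self):
        tf = af.fit_plane_to_inlet_transform(REF4, REF4)
        assert np.abs(tf.rotation - np.eye(3)).max() < 1e-12
        assert np.abs(tf.translation).max() < 1e-12
        assert tf.rms_fit_error < 1e-14

    def test_known_rigid_transform_recovered(self):
        R = _rot_z(30)
        t = np.array([0.01, -0.02, 0.005])
        q = REF4 @ R.T + t
        tf = af.fit_plane_to_inlet_transform(REF4, q)
        assert np.abs(tf.rotation - R).max() < 1e-10
        assert np.abs(tf.translation - t).max() < 1e-12
        assert np.abs(tf.apply(REF4) - q).max() < 1e-12

    def test_rotation_is_proper_orthonormal(self):
        tf = af.fit_plane_to_inlet_transform(REF4, REF4 @ _rot_z(117).T)
        R = tf.rotation
        assert np.abs(R.T @ R - np.eye(3)).max() < 1e-10
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)

    def test_similarity_mode_recovers_uniform_scale(self):
        q = 1.7 * (REF4 @ _rot_z(45).T) + np.array([0, 0.01, 0])
        tf = af.fit_plane_to_inlet_transform(REF4, q, allow_scale=True)
        assert tf.scale == pytest.approx(1.7, rel=1e-10)
        assert tf.rms_fit_error < 1e-12

    def test_three_points_rejected(self):
        with pytest.raises(ValueError, match="4 reference"):
            af.fit_plane_to_inlet_transform(REF4[:3], REF4[:3])

    def test_collinear_points_rejected(self):
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3.0, 0, 0]]) * 1e-2
        with pytest.raises(ValueError, match="collinear"):
            af.fit_plane_to_inlet_transform(line, line)


@pytest.fixture(scope="module")
def jet_setup():
    """Study-default geometry with a calibrated-strength eccentric jet."""
    mesh = af.make_straight_tube_mesh(0.015, 0.18)
    wf = af.aortic_waveform(n_samples=40)
    fld = af.valve_jet_field(mesh, wf, swirl_strength=1.0, seed=0)
    plane = af.PlaneSpec(origin=[0, 0, 0.0], axis_u=[1, 0, 0], axis_v=[0, 1, 0])
    pts = plane.origin + np.array([[0.015, 0, 0], [0, 0.015, 0],
                                   [-0.015, 0, 0], [0, -0.015, 0]])
    tf = af.fit_plane_to_inlet_transform(pts, pts)
    pmap = af.acquire_plane(fld, plane, pixel_size=1.4e-3, slab_thickness=0.0,
                            noise_sd=0.0)
    return mesh, wf, fld, tf, pmap


class TestInletBCVariants:
    def test_flat_profile_is_flow_over_area(self, tube):
        wf = constant_waveform(1e-4)
        plane = af.PlaneSpec(origin=[0, 0, 0], axis_u=[1, 0, 0], axis_v=[0, 1, 0])
        fld = af.plug_field(tube, wf)
        pmap = af.acquire_plane(fld, plane, pixel_size=1e-3, slab_thickness=0.0,
                                noise_sd=0.0)
        tfm = af.fit_plane_to_inlet_transform(REF4, REF4)
        bc = af.build_inlet_bc(pmap, tfm, tube, "FLAT", waveform=wf)
        # Q/A = 1e-4 / 3.1416e-4 = 0.3183 m/s at every node and time
        speed = bc.velocity @ tube.inlet_normal
        assert np.abs(speed - 1e-4 / (np.pi * 1e-4)).max() < 1e-12
        assert np.abs(bc.velocity[:, :, :2]).max() == 0.0

    def test_uniform_normal_map_makes_all_variants_identical(self, tube):
        wf = constant_waveform(1e-4)
        plane = af.PlaneSpec(origin=[0, 0, 0], axis_u=[1, 0, 0], axis_v=[0, 1, 0])
        pmap = af.acquire_plane(af.plug_field(tube, wf), plane, pixel_size=1e-3,
                                slab_thickness=0.0, noise_sd=0.0)
        tfm = af.fit_plane_to_inlet_transform(REF4, REF4)
        bcs = [af.build_inlet_bc(pmap, tfm, tube, v, waveform=wf)
               for v in ("FLAT", "TP", "3D")]
        for bc in bcs[1:]:
            assert np.abs(bc.velocity - bcs[0].velocity).max() < 1e-12

    def test_3d_variant_conserves_flux_exactly(self, jet_setup):
        mesh, wf, fld, tfm, pmap = jet_setup
        for v in ("FLAT", "TP", "3D"):
            bc = af.build_inlet_bc(pmap, tfm, mesh, v, waveform=wf)
            assert np.abs(bc.flux(mesh) / wf.q_at(bc.times) - 1).max() < 1e-6

    def test_tp_is_normal_projection_of_3d_before_rescaling(self, jet_setup):
        mesh, wf, fld, tfm, pmap = jet_setup
        bc3 = af.build_inlet_bc(pmap, tfm, mesh, "3D", waveform=wf)
        bctp = af.build_inlet_bc(pmap, tfm, mesh, "TP", waveform=wf)
        n = mesh.inlet_normal
        proj = (bc3.raw_velocity @ n)[..., None] * n
        assert np.abs(bctp.raw_velocity - proj).max() < 1e-12
        assert np.abs(bctp.velocity[:, :, :2]).max() < 1e-12

    def test_roundtrip_reproduces_inlet_velocities(self, jet_setup):
        # noise-free acquisition -> 3D reconstruction within 2% relative L2
        mesh, wf, fld, tfm, pmap = jet_setup
        bc = af.build_inlet_bc(pmap, tfm, mesh, "3D", waveform=wf)
        truth = fld.velocity[:, mesh.inlet_patch, :]
        err = np.linalg.norm(bc.velocity - truth) / np.linalg.norm(truth)
        assert err < 0.02

    def test_target_time_outside_cycle_rejected(self, jet_setup):
        mesh, wf, fld, tfm, pmap = jet_setup
        with pytest.raises(ValueError, match="cycle"):
            af.build_inlet_bc(pmap, tfm, mesh, "3D", target_times=[0.1, 1.2],
                              waveform=wf)

    def test_unknown_variant_rejected(self, jet_setup):
        mesh, wf, fld, tfm, pmap = jet_setup
        with pytest.raises(ValueError, match="variant"):
            af.build_inlet_bc(pmap, tfm, mesh, "2D")


class TestDecompositionStats:
    def test_three_four_five_triangle(self, uniform_field):
        plane = af.PlaneSpec(origin=[0, 0, 0], axis_u=[1, 0, 0], axis_v=[0, 1, 0])
        pmap = af.acquire_plane(uniform_field, plane, pixel_size=1e-3,
                                slab_thickness=0.0, noise_sd=0.0)
        s = af.decomposition_stats(pmap)
        assert np.allclose(s.mean_total, 0.5, atol=1e-12)
        assert np.allclose(s.mean_normal, 0.4, atol=1e-12)
        assert np.allclose(s.inplane_fraction, 60.0, atol=1e-9)
        assert s.cycle_mean_total == pytest.approx(0.5)

    def test_pure_axial_flow_has_zero_inplane_fraction(self, tube):
        plane = af.PlaneSpec(origin=[0, 0, 0], axis_u=[1, 0, 0], axis_v=[0, 1, 0])
        pmap = af.acquire_plane(af.poiseuille_field(tube, 1e-4), plane,
                                pixel_size=1e-3, slab_thickness=0.0, noise_sd=0.0)
        s = af.decomposition_stats(pmap)
        assert np.abs(s.inplane_fraction).max() < 1e-9
        assert np.allclose(s.mean_normal, s.mean_total)

    def test_inplane_fraction_invariant_under_axis_rotation(self, uniform_field):
        a = np.deg2rad(35.0)
        p1 = af.PlaneSpec(origin=[0, 0, 0], axis_u=[1, 0, 0], axis_v=[0, 1, 0])
        p2 = af.PlaneSpec(origin=[0, 0, 0],
                          axis_u=[np.cos(a), np.sin(a), 0],
                          axis_v=[-np.sin(a), np.cos(a), 0])
        s1 = af.decomposition_stats(af.acquire_plane(
            uniform_field, p1, pixel_size=1e-3, slab_thickness=0.0, noise_sd=0.0))
        s2 = af.decomposition_stats(af.acquire_plane(
            uniform_field, p2, pixel_size=1e-3, slab_thickness=0.0, noise_sd=0.0))
        assert s1.cycle_inplane_fraction == pytest.approx(
            s2.cycle_inplane_fraction, abs=1e-9)

    def test_normal_never_exceeds_total(self, jet_setup):
        *_, pmap = jet_setup
        s = af.decomposition_stats(pmap)
        assert np.all(s.mean_normal <= s.mean_total + 1e-12)
        assert np.all((s.inplane_fraction >= 0) & (s.inplane_fraction <= 100))


class TestUnderestimationPercent:
    @pytest.mark.parametrize("normal,total,expected", [
        (0.16, 0.27, 41),   # stenotic-valve subject, mean velocity
        (0.14, 0.21, 33),   # mechanical-valve subject, mean velocity
        (0.25, 0.25, 0),
    ])
    def test_worked_examples(self, normal, total, expected):
        assert af.underestimation_percent(normal, total) == expected

    def test_normal_above_total_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            af.underestimation_percent(0.3, 0.2)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            af.underestimation_percent(0.0, 0.0)

    @given(normal=st.floats(0.0, 1.0), total=st.floats(0.01, 1.0))
    def test_result_bounded_in_0_100(self, normal, total):
        if normal > total:
            return
        assert 0 <= af.underestimation_percent(normal, total) <= 100
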