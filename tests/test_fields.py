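import numpy as np
import pytest
from hypothesis import given, strategies as st

import aortaflow as af
from aortaflow.fields import _periodic_trapezoid_weights

from conftest import constant_waveform


class TestPoiseuille:
    def test_centerline_speed_closed_form(self, tube):
        fld = af.poiseuille_field(tube, 1e-4)
        assert fld.velocity[0, 0, 2] == pytest.approx(2e-4 / (np.pi * 1e-4), rel=1e-12)
        assert np.all(fld.velocity[0, :, :2] == 0.0)

    def test_inlet_flux_within_quadrature_tolerance(self, tube):
        fld = af.poiseuille_field(tube, 1e-4)
        # trapezoid-in-r quadrature of the cubic integrand: O(1/n_radial^2)
        assert tube.patch_flux(fld.velocity[0]) == pytest.approx(1e-4, rel=0.03)

    def test_zero_flow_gives_zero_field(self, tube):
        assert np.all(af.poiseuille_field(tube, 0.0).velocity == 0.0)

    def test_analytic_form_matches_nodal_values(self, tube):
        fld = af.poiseuille_field(tube, 1e-4)
        v = fld.analytic_fn(tube.node_positions, 0.0)
        assert np.abs(v - fld.velocity[0]).max() < 1e-12


class TestSwirlingPoiseuille:
    def test_zero_swirl_reduces_to_poiseuille(self, tube):
        w0 = 0.5
        sw = af.swirling_poiseuille_field(tube, w0, 0.0)
        po = af.poiseuille_field(tube, w0 * np.pi * 0.01**2 / 2.0)
        assert np.abs(sw.velocity - po.velocity).max() < 1e-14

    def test_finite_decay_kills_swirl_downstream(self, tube):
        lam = 0.01
        fld = af.swirling_poiseuille_field(tube, 0.5, 10.0, decay_length=lam)
        outlet = fld.velocity[0, tube.outlet_patch, :2]
        inlet = fld.velocity[0, tube.inlet_patch, :2]
        ratio = np.abs(outlet).max() / np.abs(inlet).max()
        assert ratio == pytest.approx(np.exp(-0.1 / lam), rel=1e-9)

    def test_advertised_analytic_helicity(self, tube):
        fld = af.swirling_poiseuille_field(tube, 0.5, 10.0)
        assert fld.metadata["hk_analytic"] == pytest.approx(10.0)


class TestWomersley:
    def test_zero_amplitude_is_steady_poiseuille(self, tube, fluid):
        fld = af.womersley_field(tube, 1e-4, 0.0, 1.0, fluid, n_phases=8)
        po = af.poiseuille_field(tube, 1e-4)
        assert np.abs(fld.velocity - po.velocity[0]).max() < 1e-14

    def test_flux_tracks_sinusoidal_waveform(self, tube, fluid):
        fld = af.womersley_field(tube, 1e-4, 5e-5, 1.0, fluid, n_phases=16)
        for i in (0, 4, 9, 13):
            target = 1e-4 + 5e-5 * np.sin(2 * np.pi * fld.times[i])
            assert tube.patch_flux(fld.velocity[i]) == pytest.approx(target, rel=0.03)

    def test_low_womersley_limit_is_quasi_steady(self, tube, fluid):
        # long period -> alpha << 1 -> instantaneous parabolic profile
        T = 1e5
        fld = af.womersley_field(tube, 1e-4, 5e-5, T, fluid, n_phases=8)
        assert fld.metadata["alpha"] < 0.05
        r2 = np.sum(tube.node_positions[:, :2] ** 2, axis=1)
        for i in range(8):
            q_t = 1e-4 + 5e-5 * np.sin(2 * np.pi * fld.times[i] / T)
            quasi = 2 * q_t / (np.pi * 0.01**2) * (1 - r2 / 0.01**2)
            scale = np.abs(quasi).max()
            assert np.abs(fld.velocity[i, :, 2] - quasi).max() < 0.01 * scale

    def test_profile_equals_bessel_closed_form(self, tube, fluid):
        fld = af.womersley_field(tube, 1e-4, 5e-5, 1.0, fluid, n_phases=4)
        r = np.hypot(*tube.node_positions[:, :2].T)
        for i in range(4):
            w = af.womersley_axial_profile(r, fld.times[i], 0.01, 1e-4, 5e-5,
                                           1.0, fluid)
            assert np.abs(fld.velocity[i, :, 2] - w).max() < 1e-10

    def test_invalid_period_rejected(self, tube, fluid):
        with pytest.raises(ValueError):
            af.womersley_field(tube, 1e-4, 1e-5, -1.0, fluid)


class TestValveJet:
    def test_flux_matches_waveform_at_every_phase_and_slice(self, tube, waveform):
        fld = af.valve_jet_field(tube, waveform, swirl_strength=0.8, seed=1)
        for i in range(0, fld.n_times, 7):
            assert tube.patch_flux(fld.velocity[i]) == pytest.approx(
                waveform.q[i], rel=1e-9)
            assert tube.patch_flux(fld.velocity[i], "outlet") == pytest.approx(
                waveform.q[i], rel=1e-9)

    def test_axisymmetric_when_centred_and_swirl_free(self, tube, waveform):
        fld = af.valve_jet_field(tube, waveform, eccentricity=0.0,
                                 jet_width=0.35, swirl_strength=0.0,
                                 perturbation=0.0)
        assert np.all(fld.velocity[:, :, :2] == 0.0)
        assert fld.metadata["inlet_inplane_fraction"] == 0.0

    def test_identical_seeds_are_bit_identical(self, tube, waveform):
        a = af.valve_jet_field(tube, waveform, swirl_strength=0.5, seed=7)
        b = af.valve_jet_field(tube, waveform, swirl_strength=0.5, seed=7)
        assert np.array_equal(a.velocity, b.velocity)
        c = af.valve_jet_field(tube, waveform, swirl_strength=0.5, seed=8)
        assert not np.array_equal(a.velocity, c.velocity)

    def test_invalid_geometry_parameters_rejected(self, tube, waveform):
        with pytest.raises(ValueError):
            af.valve_jet_field(tube, waveform, eccentricity=1.0)
        with pytest.raises(ValueError):
            af.valve_jet_field(tube, waveform, jet_width=0.0)

    def test_swirl_calibration_hits_target_inplane_fraction(self, tube, waveform):
        # severe-stenosis condition: secondary flow ~51% of total at the inlet
        s, achieved = af.calibrate_swirl_strength(tube, waveform, 0.51, seed=0)
        assert s > 0
        assert abs(achieved - 0.51) < 0.02
        fld = af.valve_jet_field(tube, waveform, swirl_strength=s, seed=0)
        assert fld.metadata["inlet_inplane_fraction"] == pytest.approx(achieved)

    def test_analytic_form_matches_nodal_values(self, tube, waveform):
        fld = af.valve_jet_field(tube, waveform, swirl_strength=0.8, seed=3)
        for i in (0, 11):
            v = fld.analytic_fn(tube.node_positions, waveform.times[i])
            assert np.abs(v - fld.velocity[i]).max() < 1e-12


class TestWaveform:
    def test_mean_flow_is_physiological(self, waveform):
        # defaults target a cardiac output near 5 l/min
        assert waveform.mean == pytest.approx(5.0 / 60 * 1e-3, rel=0.25)

    def test_q_at_is_periodic(self, waveform):
        t = np.array([0.1, 0.4, 0.73])
        assert np.allclose(waveform.q_at(t), waveform.q_at(t + waveform.period))

    def test_systolic_markers_inside_systole(self, waveform):
        ts = 0.35 * waveform.period
        m = waveform.systolic_markers
        assert np.all((m > 0) & (m < ts))
        assert np.allclose(np.diff(m), m[1] - m[0])

    def test_nonmonotonic_times_rejected(self):
        with pytest.raises(ValueError):
            af.FlowWaveform(times=[0.0, 0.2, 0.1], q=[1, 1, 1], period=1.0,
                            systolic_markers=[])

    @given(n=st.integers(4, 40))
    def test_periodic_trapezoid_weights_integrate_constants(self, n):
        rng = np.random.default_rng(n)
        t = np.sort(rng.uniform(0, 0.99, n))
        w = _periodic_trapezoid_weights(t, 1.0)
        assert w.sum() == pytest.approx(1.0, rel=1e-12)

    def test_constant_waveform_mean(self):
        wf = constant_waveform(2e-4)
        assert wf.mean == pytest.approx(2e-4, rel=1e-12)


class TestFieldInterpolation:
    def test_uniform_field_sampled_exactly_anywhere(self, uniform_field):
        pts = np.array([[0.003, -0.002, 0.05], [0.0, 0.0, 0.01],
                        [0.0099, 0.0, 0.099]])
        v = uniform_field.velocity_at(pts, 0.13)
        assert np.abs(v - np.array([0.3, 0.0, 0.4])).max() < 1e-14

    def test_time_interpolation_is_periodic(self, tube):
        times = np.arange(4) * 0.25
        vel = np.zeros((4, tube.n_nodes, 3))
        vel[:, :, 2] = np.array([1.0, 2.0, 3.0, 2.0])[:, None]
        fld = af.TimeVaryingField(mesh=tube, times=times, velocity=vel, period=1.0)
        p = np.array([[0.0, 0.0, 0.05]])
        # between last stored phase (t=0.75) and wrapped first (t=1.0)
        assert fld.velocity_at(p, 0.875)[0, 2] == pytest.approx(1.5, rel=1e-12)
        # shifting by a whole period lands on the same samples
        assert fld.velocity_at(p, 1.25)[0, 2] == pytest.approx(2.0, rel=1e-12)
        assert fld.velocity_at(p, 1.125)[0, 2] == pytest.approx(1.5, rel=1e-12)

    def test_inside_predicate(self, uniform_field):
        pts = np.array([[0.0, 0.0, 0.05], [0.0109, 0.0, 0.05],
                        [0.0, 0.0, 0.11], [0.0, 0.0, -0.01]])
        assert list(uniform_field.inside(pts)) == [True, False, False, False]
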