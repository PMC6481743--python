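import numpy as np
import pytest

import aortaflow as af
from aortaflow.helicity import ParticleTrace

R, L = 0.01, 0.1


def _interior_mask(mesh, margin=0.1):
    p = mesh.node_positions
    r = np.hypot(p[:, 0], p[:, 1])
    st = mesh.structure
    return ((r < st.radius * (1 - margin)) & (p[:, 2] > st.length * margin)
            & (p[:, 2] < st.length * (1 - margin)))


class TestComputeHelicity:
    def test_poiseuille_is_helicity_free(self, tube):
        # v axial, vorticity azimuthal: orthogonal everywhere
        hel = af.compute_helicity(af.poiseuille_field(tube, 1e-4))
        scale = (np.linalg.norm(tube.node_positions, axis=1).max() * 100) ** 2
        assert np.abs(hel.hk).max() < 1e-8 * scale + 1e-10

    def test_swirling_poiseuille_matches_closed_form(self, tube):
        # Hk = 2 Omega W0 = 10 m/s^2 at every interior point
        hel = af.compute_helicity(af.swirling_poiseuille_field(tube, 0.5, 10.0))
        interior = _interior_mask(tube)
        assert np.abs(hel.hk[0, interior] / 10.0 - 1).max() < 0.05

    def test_converges_under_refinement(self):
        errs = []
        for n in (6, 12, 24):
            mesh = af.make_straight_tube_mesh(R, L, n, 2 * n, 20)
            hel = af.compute_helicity(af.swirling_poiseuille_field(mesh, 0.5, 10.0))
            w = mesh.node_volume_weights
            errs.append(float(w @ np.abs(hel.hk[0] - 10.0) / w.sum()))
        assert np.log2(errs[0] / errs[1]) >= 1.0
        assert np.log2(errs[1] / errs[2]) >= 1.0

    def test_helicity_is_a_pseudoscalar(self, tube):
        # mirror reflection = reversing the swirl handedness flips Hk's sign
        a = af.compute_helicity(af.swirling_poiseuille_field(tube, 0.5, 10.0))
        b = af.compute_helicity(af.swirling_poiseuille_field(tube, 0.5, -10.0))
        assert np.allclose(a.hk, -b.hk, rtol=1e-10, atol=1e-12)

    def test_curl_free_field_has_no_helicity(self, tube):
        p = tube.node_positions
        vel = np.zeros((1, tube.n_nodes, 3))
        vel[0, :, 0] = 2 * p[:, 0] + p[:, 2]
        vel[0, :, 1] = -2 * p[:, 1]
        vel[0, :, 2] = p[:, 0]
        fld = af.TimeVaryingField(mesh=tube, times=np.array([0.0]),
                                  velocity=vel, period=1.0)
        hel = af.compute_helicity(fld)
        assert np.abs(hel.hk).max() < 1e-10

    def test_lnh_bounded_and_zero_at_degenerate_points(self, tube, waveform):
        fld = af.valve_jet_field(tube, waveform, swirl_strength=0.8, seed=4)
        hel = af.compute_helicity(fld)
        assert np.all((hel.lnh >= -1.0) & (hel.lnh <= 1.0))
        zero = np.linalg.norm(fld.velocity, axis=2) == 0.0
        assert np.all(hel.lnh[zero] == 0.0)


class TestThresholdVolumes:
    def _uniform(self, tube, hk_value):
        T = 1
        return af.HelicityField(
            mesh=tube, times=np.array([0.0]), period=1.0,
            vorticity=np.zeros((T, tube.n_nodes, 3)),
            hk=np.full((T, tube.n_nodes), hk_value),
            lnh=np.zeros((T, tube.n_nodes)))

    def test_below_threshold_gives_zero_fractions(self, tube):
        df = af.threshold_volumes(self._uniform(tube, 10.0), theta=200.0)
        assert (df.frac_pos == 0).all() and (df.frac_neg == 0).all()

    def test_above_threshold_fills_positive_volume(self, tube):
        df = af.threshold_volumes(self._uniform(tube, 250.0), theta=200.0)
        assert (df.frac_pos == 1.0).all() and (df.frac_neg == 0).all()

    def test_half_and_half_split(self, tube):
        hel = self._uniform(tube, 0.0)
        hel.hk[0] = np.where(tube.node_positions[:, 2] < L / 2, 300.0, -300.0)
        df = af.threshold_volumes(hel, theta=200.0)
        whole = df[df.region == "whole"]
        assert whole.frac_pos.iloc[0] == pytest.approx(0.5, abs=0.05)
        assert whole.frac_neg.iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_nonpositive_threshold_rejected(self, tube):
        with pytest.raises(ValueError):
            af.threshold_volumes(self._uniform(tube, 0.0), theta=0.0)


class TestTracer:
    def test_uniform_field_gives_straight_lines(self):
        v = np.array([0.1, -0.05, 0.3])
        samp = af.AnalyticVelocity(lambda p, t: np.tile(v, (len(p), 1)),
                                   period=1.0)
        tr = af.trace_particles(samp, np.array([[0.0, 0.0, 0.0]]), 0.0, 0.01,
                                t_end=0.5)[0]
        assert np.abs(tr.positions[-1] - 0.5 * v).max() < 1e-12
        assert tr.termination == "cycle_cap"

    def test_rk4_self_convergence_order(self):
        om = 5.0
        samp = af.AnalyticVelocity(
            lambda p, t: np.stack([-om * p[:, 1], om * p[:, 0],
                                   np.zeros(len(p))], axis=1),
            period=2 * np.pi / om)
        seed = np.array([[0.005, 0.0, 0.0]])
        ends = [af.trace_particles(samp, seed, 0.0, dt, t_end=1.0)[0].positions[-1]
                for dt in (0.05, 0.025, 0.0125)]
        e1 = np.linalg.norm(ends[0] - ends[1])
        e2 = np.linalg.norm(ends[1] - ends[2])
        assert np.log2(e1 / e2) >= 3.8

    def test_orbit_radius_preserved_on_solid_body_rotation(self):
        om = 5.0
        samp = af.AnalyticVelocity(
            lambda p, t: np.stack([-om * p[:, 1], om * p[:, 0],
                                   np.zeros(len(p))], axis=1),
            period=2 * np.pi / om)
        tr = af.trace_particles(samp, np.array([[0.005, 0.0, 0.0]]), 0.0,
                                0.005, t_end=2 * np.pi / om)[0]
        radii = np.hypot(tr.positions[:, 0], tr.positions[:, 1])
        assert np.abs(radii / 0.005 - 1).max() < 1e-6

    def test_poiseuille_traces_carry_zero_lnh(self, tube):
        fld = af.poiseuille_field(tube, 1e-4)
        seeds = af.inlet_disc_seeds(tube, 20, radius_fraction=0.6)
        traces = af.trace_particles(fld, seeds, 0.0, 0.005, t_end=0.1)
        hfi = af.compute_hfi({0.0: traces})
        assert hfi.hfi[0] < 1e-8

    def test_outside_seed_skipped_with_warning(self, tube):
        fld = af.poiseuille_field(tube, 1e-4)
        seeds = np.array([[0.0, 0.0, 0.01], [0.05, 0.0, 0.01]])
        with pytest.warns(UserWarning, match="outside"):
            traces = af.trace_particles(fld, seeds, 0.0, 0.01, t_end=0.05)
        assert len(traces) == 1

    def test_exiting_particle_keeps_partial_trace(self, tube):
        fld = af.poiseuille_field(tube, 1e-3)  # fast: centre speed 6.4 m/s
        tr = af.trace_particles(fld, np.array([[0.0, 0.0, 0.09]]), 0.0, 0.005,
                                t_end=1.0)[0]
        assert tr.termination == "exited"
        assert len(tr.times) < 50
        assert np.all(np.isfinite(tr.positions))


class TestHFI:
    def _const_trace(self, lnh_value, n=30, t0=0.0):
        return ParticleTrace(release_time=t0, times=np.arange(n + 1) * 0.01,
                             positions=np.zeros((n + 1, 3)),
                             lnh=np.full(n + 1, lnh_value),
                             termination="cycle_cap")

    def test_zero_lnh_gives_zero_hfi(self):
        res = af.compute_hfi({0.0: [self._const_trace(0.0)]})
        assert res.hfi[0] == 0.0

    def test_magnitude_of_negative_lnh(self):
        res = af.compute_hfi({0.0: [self._const_trace(-0.8)]})
        assert res.hfi[0] == pytest.approx(0.8)
        signed = af.compute_hfi({0.0: [self._const_trace(-0.8)]}, signed=True)
        assert signed.hfi[0] == pytest.approx(-0.8)

    def test_short_traces_do_not_count(self):
        traces = [self._const_trace(0.9, n=3), self._const_trace(0.1, n=30)]
        res = af.compute_hfi({0.0: traces})
        assert res.hfi[0] == pytest.approx(0.1)
        assert res.particle_counts[0] == 1

    def test_release_without_survivors_raises(self):
        with pytest.raises(ValueError, match="surviving"):
            af.compute_hfi({0.0: [self._const_trace(0.5, n=2)]})

    def test_average_is_mean_over_release_times(self):
        grouped = {t: [self._const_trace(v, t0=t)]
                   for t, v in [(0.1, 0.2), (0.2, 0.4), (0.3, 0.6), (0.4, 0.8)]}
        res = af.compute_hfi(grouped)
        assert res.average == pytest.approx(0.5)
        assert np.all((res.hfi >= 0) & (res.hfi <= 1))

    def test_interpolated_lnh_agrees_with_dense_analytic_tracing(self):
        # swirling Poiseuille: package path (nodal LNH, trilinear sampling)
        # vs an independent dense-RK4 reference with closed-form LNH
        mesh = af.make_straight_tube_mesh(R, L, 20, 40, 24)
        fld = af.swirling_poiseuille_field(mesh, 0.5, 10.0)
        seeds = af.inlet_disc_seeds(mesh, 40, radius_fraction=0.7)
        ours = af.compute_hfi(
            {0.0: af.trace_particles(fld, seeds, 0.0, 0.001, t_end=0.15)})

        def lnh_exact(p, t):
            r2 = p[:, 0] ** 2 + p[:, 1] ** 2
            v = np.stack([-10 * p[:, 1], 10 * p[:, 0],
                          0.5 * (1 - r2 / R**2)], axis=1)
            om = np.stack([-p[:, 1] / R**2, p[:, 0] / R**2,
                           np.full(len(p), 20.0)], axis=1)
            return 10.0 / np.maximum(
                np.linalg.norm(v, axis=1) * np.linalg.norm(om, axis=1), 1e-30)

        samp = af.AnalyticVelocity(
            lambda p, t: np.stack([-10 * p[:, 1], 10 * p[:, 0],
                                   0.5 * (1 - (p[:, 0]**2 + p[:, 1]**2) / R**2)],
                                  axis=1),
            period=1.0,
            inside_fn=lambda p: (np.hypot(p[:, 0], p[:, 1]) <= R)
                                 & (p[:, 2] >= 0) & (p[:, 2] <= L),
            lnh_fn=lnh_exact)
        ref = af.compute_hfi(
            {0.0: af.trace_particles(samp, seeds, 0.0, 0.0005, t_end=0.15)})
        assert abs(ours.hfi[0] / ref.hfi[0] - 1) < 0.01


class TestHFIPercentDiff:
    def _result(self, values):
        return af.HFIResult(release_times=np.array([0.1, 0.2, 0.3, 0.4]),
                            hfi=np.asarray(values, float),
                            particle_counts=np.full(4, 10))

    def test_identical_results_give_zero(self):
        a = self._result([0.2, 0.3, 0.4, 0.5])
        d = af.hfi_percent_diff(a, a)
        assert all(v == 0.0 for v in d.values())

    def test_scaled_result_gives_signed_percent(self):
        a = self._result([0.2, 0.3, 0.4, 0.5])
        b = self._result([0.3, 0.45, 0.6, 0.75])
        d = af.hfi_percent_diff(a, b)
        assert d["T1"] == pytest.approx(50.0)
        assert d["Avg"] == pytest.approx(50.0)

    def test_zero_reference_flagged_not_dropped(self):
        a = self._result([0.0, 0.3, 0.4, 0.5])
        b = self._result([0.1, 0.3, 0.4, 0.5])
        d = af.hfi_percent_diff(a, b)
        assert np.isnan(d["T1"])
        assert d["T2"] == 0.0

    def test_mismatched_schedules_rejected(self):
        a = self._result([0.2, 0.3, 0.4, 0.5])
        b = af.HFIResult(release_times=np.array([0.1, 0.2, 0.3, 0.5]),
                         hfi=np.zeros(4), particle_counts=np.full(4, 10))
        with pytest.raises(ValueError, match="schedule"):
            af.hfi_percent_diff(a, b)
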