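"""Equation-of-motion integration: closed-form oracles, stability, events."""

import math
import warnings

import numpy as np
import pytest

import depsep as ds
from depsep.dynamics import (
    CentralDifferenceStepper,
    ParticleState,
    Status,
    detect_event,
    net_force,
)
from depsep.flow import FlowSpec, axial_velocity

RHO_P, RHO_M, MU = 1050.0, 1000.0, 1e-3
Q200 = ds.ul_per_h_to_m3_per_s(200)


def stokes_terminal(r):
    """Closed-form settling speed 2 (rho_e - rho_m) g r^2 / (9 mu)."""
    return 2 * (RHO_P - RHO_M) * 9.81 * r**2 / (9 * MU)


def quiescent(geo):
    return FlowSpec(0.0, geo)


@pytest.fixture(scope="module")
def geo_plain():
    return ds.DeviceGeometry(100e-6, 100e-6, 120e-6, 30e-6, 30)


class TestNetForce:
    def test_neutrally_buoyant_at_rest_zero(self, geo_plain, medium):
        p = ds.Particle(2.5e-6, ds.POLYSTYRENE, density=medium.density)
        s = ParticleState(np.array([0.0, 50e-6, 50e-6]), np.zeros(3))
        f = net_force(s, p, medium, quiescent(geo_plain), None, geo_plain, 0.0)
        np.testing.assert_allclose(f, 0.0, atol=1e-25)

    def test_zero_re_fcm_kills_dep_term(self, geo_plain, medium, field_ref, geo_ref, p_small):
        s = ParticleState(np.array([10e-6, 20e-6, 50e-6]), np.zeros(3))
        f_no = net_force(s, p_small, medium, quiescent(geo_ref), None, geo_ref, 0.0)
        f_fld = net_force(s, p_small, medium, quiescent(geo_ref), field_ref, geo_ref, 0.0)
        np.testing.assert_allclose(f_no, f_fld, atol=0.0)

    def test_force_balance_at_terminal_velocity(self, geo_plain, medium, p_big):
        vt = stokes_terminal(p_big.radius)
        s = ParticleState(np.array([0.0, 50e-6, 50e-6]), np.array([0.0, 0.0, -vt]))
        f = net_force(s, p_big, medium, quiescent(geo_plain), None, geo_plain, 0.0)
        # drag cancels net weight; residual far below the weight scale
        weight = p_big.volume * (RHO_P - RHO_M) * 9.81
        assert np.abs(f).max() < 1e-10 * weight

    def test_terminal_velocity_magnitude_printed(self, p_big):
        assert stokes_terminal(p_big.radius) == pytest.approx(2.7e-6, rel=0.02)


class TestSettling:
    @pytest.mark.parametrize("r", [1e-6, 2.5e-6, 5e-6])
    def test_terminal_velocity_recovered(self, r, geo_plain, medium):
        """Settling velocity matches the Stokes closed form within 1%."""
        p = ds.Particle(r, ds.POLYSTYRENE)
        cfg = ds.SimulationConfig(time_step=1e-5)
        st = CentralDifferenceStepper(p, medium, quiescent(geo_plain), None, geo_plain, cfg, 0.0)
        s = ParticleState(np.array([0.0, 50e-6, 50e-6]), np.zeros(3))
        st.start(s)
        for _ in range(100):
            s = st.step(s)
            s.status = Status.IN_TRANSIT  # keep stepping through the channel
        assert s.velocity[2] == pytest.approx(-stokes_terminal(r), rel=0.01)

    def test_relaxation_within_ten_tau(self, geo_plain, medium, p_big):
        """From rest, the scheme reaches 99% of terminal velocity within
        10 momentum-relaxation times."""
        cdrag = 6 * math.pi * MU * p_big.radius
        tau = p_big.mass / cdrag
        cfg = ds.SimulationConfig(time_step=1e-5)
        st = CentralDifferenceStepper(p_big, medium, quiescent(geo_plain), None, geo_plain, cfg, 0.0)
        s = ParticleState(np.array([0.0, 50e-6, 50e-6]), np.zeros(3))
        st.start(s)
        n = math.ceil(10 * tau / cfg.time_step)
        for _ in range(max(n, 2)):
            s = st.step(s)
            s.status = Status.IN_TRANSIT
        assert s.velocity[2] == pytest.approx(-stokes_terminal(p_big.radius), rel=0.01)

    def test_semi_implicit_stable_explicit_diverges(self, geo_plain, medium, p_small):
        """At dt = 1e-5 s >> tau ~ 1.5e-6 s the semi-implicit drag stays
        bounded and monotone while a fully explicit drag treatment blows up."""
        dt = 1e-5
        cfg = ds.SimulationConfig(time_step=dt)
        st = CentralDifferenceStepper(p_small, medium, quiescent(geo_plain), None, geo_plain, cfg, 0.0)
        s = ParticleState(np.array([0.0, 50e-6, 50e-6]), np.zeros(3))
        st.start(s)
        speeds, zs = [], []
        for _ in range(50):
            s = st.step(s)
            s.status = Status.IN_TRANSIT
            speeds.append(-s.velocity[2])
            zs.append(s.position[2])
        vt = stokes_terminal(p_small.radius)
        assert np.all(np.isfinite(speeds))
        # bounded (the discrete drag mode |lambda| < 1 damps any overshoot)
        assert np.max(speeds) <= vt * 2.0
        assert speeds[-1] == pytest.approx(vt, rel=0.01)
        assert np.all(np.diff(zs) < 0)  # position descends monotonically

        # explicit drag: backward-difference velocity in the drag term
        m = p_small.mass
        c = 6 * math.pi * MU * p_small.radius
        fz = -p_small.volume * (RHO_P - RHO_M) * 9.81
        z_prev, z_cur = 50e-6, 50e-6
        for _ in range(50):
            drag = -c * (z_cur - z_prev) / dt
            z_next = 2 * z_cur - z_prev + dt**2 / m * (drag + fz)
            z_prev, z_cur = z_cur, z_next
        assert not np.isfinite(z_cur) or abs(z_cur - 50e-6) > 1.0  # diverged


class TestFreeMotion:
    def test_uniform_translation_with_fluid(self, geo_plain, medium):
        """A neutrally buoyant particle starting at the local fluid velocity
        feels zero net force and advances u dt per step exactly."""
        p = ds.Particle(2.5e-6, ds.POLYSTYRENE, density=medium.density)
        flow = FlowSpec(Q200, geo_plain)
        u = axial_velocity(30e-6, 60e-6, flow)
        cfg = ds.SimulationConfig(time_step=1e-5)
        st = CentralDifferenceStepper(p, medium, flow, None, geo_plain, cfg, 0.0)
        s = ParticleState(np.array([0.0, 30e-6, 60e-6]), np.array([u, 0.0, 0.0]))
        st.start(s)
        for n in range(1, 101):
            s = st.step(s)
            assert s.position[0] == pytest.approx(n * u * cfg.time_step, rel=1e-12)
            assert s.position[1] == 30e-6 and s.position[2] == 60e-6

    def test_zero_voltage_neutral_particle_exits_straight(self, geo_plain, medium):
        p = ds.Particle(2.5e-6, ds.POLYSTYRENE, density=medium.density)
        flow = FlowSpec(Q200, geo_plain)
        cfg = ds.SimulationConfig(time_step=1e-5, max_time=5.0, operating_frequency=1e5)
        traj, out = ds.simulate_trajectory((30e-6, 60e-6), p, medium, flow, None,
                                           geo_plain, cfg, re_fcm=0.0)
        assert out.status is Status.EXITED
        assert np.abs(traj[:, 2] - 30e-6).max() < 1e-12
        assert np.abs(traj[:, 3] - 60e-6).max() < 1e-12


class TestDetectEvent:
    def test_sidewall_contact_inside_array_captures(self, geo_ref, p_small):
        s = ParticleState(np.array([1e-3, p_small.radius / 2, 50e-6]), np.zeros(3))
        assert detect_event(s, geo_ref, p_small) is Status.CAPTURED_ELECTRODE

    def test_bottom_contact_settles(self, geo_ref, p_small):
        s = ParticleState(np.array([1e-3, 50e-6, p_small.radius]), np.zeros(3))
        assert detect_event(s, geo_ref, p_small) is Status.SETTLED_BOTTOM

    def test_array_end_exits(self, geo_ref, p_small):
        s = ParticleState(np.array([geo_ref.array_length, 50e-6, 50e-6]), np.zeros(3))
        assert detect_event(s, geo_ref, p_small) is Status.EXITED

    def test_interior_in_transit(self, geo_ref, p_small):
        s = ParticleState(np.array([1e-3, 50e-6, 50e-6]), np.zeros(3))
        assert detect_event(s, geo_ref, p_small) is Status.IN_TRANSIT


class TestTrajectories:
    def test_kernel_matches_python_reference(self, geo_ref, medium, field_ref, p_small, n_cr_big):
        """Compiled integrator and the pure-Python stepper agree: the only
        drift allowed is the flow-table interpolation error in x."""
        fcm = ds.re_cm_factor(p_small, medium, n_cr_big)
        flow = FlowSpec(Q200, geo_ref)
        cfg = ds.SimulationConfig(time_step=1e-5, max_time=0.015,
                                  operating_frequency=n_cr_big, record_stride=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj, out = ds.simulate_trajectory((30e-6, 40e-6), p_small, medium, flow,
                                               field_ref, geo_ref, cfg, re_fcm=fcm)
        st = CentralDifferenceStepper(p_small, medium, flow, field_ref, geo_ref, cfg, fcm)
        s = ParticleState(np.array([0.0, 30e-6, 40e-6]),
                          np.array([axial_velocity(30e-6, 40e-6, flow), 0.0, 0.0]))
        st.start(s)
        for _ in range(len(traj) - 1):
            s = st.step(s)
            if s.status is not Status.IN_TRANSIT:
                break
        assert abs(traj[-1][1] - s.position[0]) < 1e-3 * max(s.position[0], 1e-12)
        assert abs(traj[-1][2] - s.position[1]) < 1e-8
        assert abs(traj[-1][3] - s.position[2]) < 1e-8

    def test_time_step_halving_moves_capture_point_below_1um(
        self, geo_ref, medium, field_ref, p_small, n_cr_big
    ):
        fcm = ds.re_cm_factor(p_small, medium, n_cr_big)
        flow = FlowSpec(Q200, geo_ref)
        finals = []
        for dt in (1e-5, 5e-6):
            cfg = ds.SimulationConfig(time_step=dt, max_time=10.0,
                                      operating_frequency=n_cr_big)
            _, out = ds.simulate_trajectory((20e-6, 40e-6), p_small, medium, flow,
                                            field_ref, geo_ref, cfg, re_fcm=fcm)
            assert out.status is Status.CAPTURED_ELECTRODE
            finals.append(out.position)
        assert np.abs(finals[0] - finals[1]).max() < 1e-6

    def test_equal_voltage_midplane_retained(self, medium, p_small, n_cr_big):
        """With both walls driven identically a center-plane particle feels
        zero net lateral DEP and keeps y = W/2 to machine-level precision."""
        geo = ds.DeviceGeometry(100e-6, 100e-6, 120e-6, 30e-6, 30, 20.0, 20.0)
        grid = ds.build_repeating_unit(geo, 5e-6)
        ds.solve_potential(grid)
        fld = ds.dep_force_field(grid)
        fcm = ds.re_cm_factor(p_small, medium, n_cr_big)
        flow = FlowSpec(Q200, geo)
        cfg = ds.SimulationConfig(time_step=1e-5, max_time=10.0,
                                  operating_frequency=n_cr_big)
        traj, out = ds.simulate_trajectory((50e-6, 50e-6), p_small, medium, flow,
                                           fld, geo, cfg, re_fcm=fcm)
        assert out.status is Status.EXITED
        assert np.abs(traj[:, 2] - 50e-6).max() < grid.spacing / 100

    def test_exponential_drag_mode_agrees_on_settling(self, geo_plain, medium, p_big):
        cfgs = [
            ds.SimulationConfig(time_step=1e-5, max_time=5.0, integrator_mode=mode,
                                operating_frequency=1e5)
            for mode in ("central_difference", "exponential_drag")
        ]
        flow = FlowSpec(Q200, geo_plain)
        outs = []
        for cfg in cfgs:
            _, out = ds.simulate_trajectory((50e-6, 20e-6), p_big, medium, flow, None,
                                            geo_plain, cfg, re_fcm=0.0)
            outs.append(out)
        assert outs[0].status == outs[1].status
        np.testing.assert_allclose(outs[0].position, outs[1].position, atol=2e-7)
        assert outs[0].time == pytest.approx(outs[1].time, rel=1e-2)

    def test_release_outside_inflated_section_rejected(self, geo_ref, medium, p_small):
        flow = FlowSpec(Q200, geo_ref)
        cfg = ds.SimulationConfig(time_step=1e-5, max_time=5.0, operating_frequency=1e5)
        with pytest.raises(ds.OutOfDomainError):
            ds.simulate_trajectory((1e-6, 50e-6), p_small, medium, flow, None,
                                   geo_ref, cfg, re_fcm=0.0)

    def test_timeout_is_reported_not_dropped(self, geo_ref, medium, p_small):
        flow = FlowSpec(Q200, geo_ref)
        cfg = ds.SimulationConfig(time_step=1e-5, max_time=1e-3, operating_frequency=1e5)
        with pytest.warns(UserWarning, match="timeout"):
            _, out = ds.simulate_trajectory((50e-6, 50e-6), p_small, medium, flow, None,
                                            geo_ref, cfg, re_fcm=0.0)
        assert out.status is Status.TIMEOUT
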