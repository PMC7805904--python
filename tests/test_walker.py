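import numpy as np
import pytest

from gaitbench.metrics import detect_gait_events
from gaitbench.multibody import ContactSet, State, com_state
from gaitbench.walker import (GaitPlan, default_walker_markers, planar_leg_ik,
                              simulate_walker, synthesize_markers)


def test_zero_torque_flight_follows_ballistic_parabola(walker_model):
    """COM of a passive airborne walker is a projectile."""
    model = walker_model
    q0 = np.zeros(model.n_dof)
    q0[1] = 2.0
    v0 = np.zeros(model.n_dof)
    v0[0], v0[1] = 1.0, 0.5
    fx = simulate_walker(model, lambda t, s, c: np.zeros(model.n_dof),
                         State(q0, v0), 0.3, dt=1e-3, fall_height=-10.0)
    com0, comdot0 = com_state(model, State(fx.Q[0], fx.V[0]))
    for i in (100, 200, 300):
        t = fx.times[i]
        com, _ = com_state(model, State(fx.Q[i], fx.V[i]))
        expect = com0 + comdot0 * t + 0.5 * np.array([0, 0, -9.81]) * t ** 2
        assert np.abs(com - expect).max() < 1e-8


def test_static_double_support_holds_posture(walker_model):
    """A posture-holding controller on two flat feet stays put."""
    from gaitbench.walker import GaitTrackingController

    model = walker_model
    plan = GaitPlan(model, stride_time=1e6)  # effectively frozen references
    ctrl = GaitTrackingController(plan)
    # stand at the plan's own base reference with both feet flat below it
    q0 = np.zeros(model.n_dof)
    b_pos, _, _ = plan.base_ref(0.0)
    dof = {name: i for i, name in enumerate(model.dof_names)}
    q0[dof["base_tx"]], q0[dof["base_tz"]] = b_pos
    for side in ("left", "right"):
        h, k, a = planar_leg_ik(tuple(b_pos), (b_pos[0], plan.ankle_h),
                                plan.thigh_len, plan.shank_len, 0.0, 0.0)
        q0[dof[f"hip_{side}"]], q0[dof[f"knee_{side}"]] = h, k
        q0[dof[f"ankle_{side}"]] = a
    fx = simulate_walker(model, ctrl.torques, State(q0, np.zeros(model.n_dof)),
                         0.3,
                         initial_contacts=[("left", "heel"), ("left", "hallux"),
                                           ("right", "heel"), ("right", "hallux")],
                         dt=1e-3)
    assert not fx.fell
    assert np.abs(fx.Q[-1][:3] - fx.Q[0][:3]).max() < 0.02


def test_stride_follows_eight_phase_grammar(stride):
    """One simulated stride shows the full 8-phase / 4-transition schedule."""
    sets = [cs for _, cs in stride.schedule]
    assert len(sets) == 9  # initial configuration + 8 boundaries
    assert len(stride.events.heel_strikes["left"]) == 1
    assert len(stride.events.heel_strikes["right"]) == 1
    assert len(stride.events.toe_strikes["left"]) == 1
    assert len(stride.events.toe_strikes["right"]) == 1


def test_stride_contact_forces_unilateral(stride):
    for key, fz in stride.point_forces.items():
        assert fz.min() > -1e-6, key


def test_force_based_heel_strike_detection_matches_schedule(stride):
    """Heel strikes carry an impact force spike: the force detector finds
    them within a sample or two of the hybrid schedule."""
    dt = stride.times[1] - stride.times[0]
    detected = detect_gait_events(stride.times,
                                  point_forces=stride.point_forces,
                                  body_weight=stride.model.total_mass)
    for side in ("left", "right"):
        truth = stride.events.heel_strikes[side]
        got = detected.heel_strikes[side]
        assert len(got) == len(truth), (side, got, truth)
        for a, b in zip(got, truth):
            assert abs(a - b) <= 2 * dt + 1e-12


def test_kinematic_event_detection_matches_schedule(stride):
    """Contact-point height thresholds recover all four event types close
    to the hybrid schedule (bias bounded by threshold / approach speed)."""
    model = stride.model
    heights = {}
    vels = {}
    for side in ("left", "right"):
        for pt in ("heel", "hallux"):
            body, off = model.contact_point(side, pt)
            z = np.empty(len(stride.times))
            vz = np.empty(len(stride.times))
            for i in range(len(stride.times)):
                kin = model.kinematics(stride.Q[i], stride.V[i])
                z[i] = kin.point_position(body, off)[2]
                vz[i] = kin.point_velocity(body, off)[2]
            heights[(side, pt)] = z
            vels[(side, pt)] = vz
    detected = detect_gait_events(stride.times, point_heights=heights,
                                  point_velocities=vels,
                                  height_threshold=2e-3)
    t_end = stride.times[-1]
    for kind in ("heel_strikes", "toe_strikes", "toe_offs"):
        for side in ("left", "right"):
            # a lift-off at the very last sample is kinematically invisible
            # (the foot has not risen yet); compare interior events only
            truth = [t for t in getattr(stride.events, kind)[side]
                     if t < t_end - 0.015]
            got = getattr(detected, kind)[side]
            assert len(got) == len(truth), (kind, side, got, truth)
            for a, b in zip(got, truth):
                assert abs(a - b) <= 0.02


def test_synthesize_markers_deterministic(walker_model):
    q = np.zeros((3, walker_model.n_dof))
    q[:, 1] = 1.0
    t = np.array([0.0, 0.01, 0.02])
    f1 = synthesize_markers(walker_model, t, q, default_walker_markers(),
                            noise_sigma=2e-3, seed=7)
    f2 = synthesize_markers(walker_model, t, q, default_walker_markers(),
                            noise_sigma=2e-3, seed=7)
    for a, b in zip(f1, f2):
        for n in a.markers:
            assert np.array_equal(a.markers[n], b.markers[n])


def test_synthesize_markers_noise_scale(walker_model):
    sigma = 5e-3
    n = 1000
    q = np.zeros((n, walker_model.n_dof))
    q[:, 1] = 1.0
    t = np.arange(n) * 0.01
    frames = synthesize_markers(walker_model, t, q, default_walker_markers(),
                                noise_sigma=sigma, seed=3)
    dev = np.array([f.markers["TRXT"] for f in frames])
    sd = dev.std(axis=0)
    assert np.all(np.abs(sd - sigma) < 0.1 * sigma)


def test_noise_free_markers_on_virtual_positions(walker_model, rng):
    q = rng.normal(0, 0.2, (1, walker_model.n_dof))
    frames = synthesize_markers(walker_model, [0.0], q, default_walker_markers(),
                                noise_sigma=0.0, seed=0)
    kin = walker_model.kinematics(q[0])
    for name, (seg, off) in default_walker_markers().items():
        x = kin.point_position(walker_model.body_index[seg], np.asarray(off))
        assert np.array_equal(frames[0].markers[name], x)


def test_planar_leg_ik_round_trip():
    thigh, shank = 0.42, 0.44
    hip = (0.0, 0.9)
    ankle = (0.15, 0.1)
    h, k, a = planar_leg_ik(hip, ankle, thigh, shank, base_pitch=0.05,
                            foot_pitch=-0.1)
    assert k >= 0
    # forward kinematics of the returned angles reproduces the ankle target
    alpha = 0.05 + h
    beta = alpha + k
    knee = np.array(hip) + thigh * np.array([-np.sin(alpha), -np.cos(alpha)])
    ank = knee + shank * np.array([-np.sin(beta), -np.cos(beta)])
    assert np.abs(ank - np.array(ankle)).max() < 1e-10
    assert (0.05 + h + k + a) == pytest.approx(-0.1, abs=1e-12)
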