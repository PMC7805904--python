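import numpy as np
import pytest

from gaitbench.errors import ValidationError
from gaitbench.metrics import (
    GaitEvents, GroundReferenceTrajectory, angular_eigenfrequency,
    decompose_angular_momentum, detect_gait_events, foot_placement_summary,
    instantaneous_capture_point, normalized_orbital_energy,
    residual_orbital_energy, stride_average,
)


class TestAngularEigenfrequency:
    def test_unit_case(self):
        assert angular_eigenfrequency(9.81) == pytest.approx(1.0)

    def test_subject_leg_length(self):
        # direct evaluation of sqrt(9.81 / 0.792)
        assert angular_eigenfrequency(0.792) == pytest.approx(
            np.sqrt(9.81 / 0.792), rel=1e-12)
        assert angular_eigenfrequency(0.792) == pytest.approx(3.5194, abs=1e-4)

    def test_square_root_scaling(self):
        assert angular_eigenfrequency(0.25 * 0.9) == pytest.approx(
            2.0 * angular_eigenfrequency(0.9), rel=1e-12)

    def test_rejects_nonpositive_length(self):
        with pytest.raises(ValidationError):
            angular_eigenfrequency(0.0)


class TestInstantaneousCapturePoint:
    def test_static_case(self):
        icap = instantaneous_capture_point((0.3, -0.1), (0.0, 0.0), 3.5)
        assert np.allclose(icap, (0.3, -0.1))

    def test_direct_evaluation(self):
        icap = instantaneous_capture_point((0.0, 0.0), (1.2, 0.0), 3.5)
        assert icap[0] == pytest.approx(1.2 / 3.5, rel=1e-12)  # 0.342857...
        assert icap[1] == 0.0

    def test_cop_at_icap_zeroes_orbital_energy(self):
        """Placing the CoP on the COM-based ICaP cancels Eq-16 exactly."""
        v = np.array([0.4, 0.1])
        om = 3.5
        com = np.array([0.2, 0.05])
        cop = instantaneous_capture_point(com, v, om)
        assert normalized_orbital_energy(com, cop, v, om) == pytest.approx(0.0,
                                                                           abs=1e-15)


class TestNormalizedOrbitalEnergy:
    def test_at_rest_over_cop(self):
        assert normalized_orbital_energy((0, 0), (0, 0), (0, 0), 3.3) == 0.0

    def test_direct_evaluation(self):
        # 1/2 (0.4)^2 - 1/2 (0.1)^2 (3.5)^2 = 0.08 - 0.061250
        val = normalized_orbital_energy((0.1, 0.0), (0.0, 0.0), (0.4, 0.0), 3.5)
        assert val == pytest.approx(0.018750, abs=1e-12)

    def test_normalization_order_identity(self, rng):
        """Normalizing inputs first equals normalizing the energy afterwards."""
        from gaitbench.lipm import orbital_energy_dimensional

        l = 0.83
        for _ in range(10):
            com, cop = rng.normal(0, 0.3, 2), rng.normal(0, 0.3, 2)
            v = rng.normal(0, 1.0, 2)
            om = float(rng.uniform(2.5, 4.0))
            a = normalized_orbital_energy(com / l, cop / l, v / l, om)
            b = orbital_energy_dimensional(com, cop, v, om) / l ** 2
            assert a == pytest.approx(b, abs=1e-12)


def test_stride_average_is_mean_of_sides():
    assert stride_average(0.0664, 0.0660) == pytest.approx(0.0662, abs=1e-12)


def _flat_trajectory(times, com, v, cop, height=0.9):
    n = len(times)
    om = angular_eigenfrequency(height)
    r_com = np.column_stack([com, np.full(n, height)])
    rdot = np.column_stack([v, np.zeros(n)])
    icap = com + v / om
    return GroundReferenceTrajectory(times=times, r_com=r_com, rdot_com=rdot,
                                     r_cop=cop, r_icap=icap,
                                     com_height=np.full(n, height))


def test_residual_energy_uses_post_event_sample():
    times = np.linspace(0.0, 1.0, 101)
    com = np.column_stack([np.linspace(0, 1, 101), np.zeros(101)])
    v = np.tile([1.0, 0.0], (101, 1))
    cop = np.column_stack([np.where(times < 0.5, 0.2, 0.8), np.zeros(101)])
    traj = _flat_trajectory(times, com, v, cop)
    events = GaitEvents()
    events.heel_strikes["left"] = [0.5]
    rec = residual_orbital_energy(traj, events, leg_length=0.9, with_series=False)
    assert len(rec.events) == 1
    e = rec.events[0]
    # at t = 0.5 the new CoP (0.8) must be in effect
    i = traj.sample_at_or_after(0.5)
    expect = normalized_orbital_energy(com[i] / 0.9, [0.8 / 0.9, 0.0],
                                       v[i] / 0.9, e.omega0)
    assert e.value == pytest.approx(expect, rel=1e-12)


def test_residual_energy_skips_out_of_span_events():
    times = np.linspace(0.0, 1.0, 11)
    com = np.zeros((11, 2))
    v = np.zeros((11, 2))
    cop = np.zeros((11, 2))
    traj = _flat_trajectory(times, com, v, cop)
    events = GaitEvents()
    events.heel_strikes["left"] = [0.5, 2.0]
    with pytest.warns(UserWarning):
        rec = residual_orbital_energy(traj, events, 0.9, with_series=False)
    assert len(rec.events) == 1


class TestAngularMomentumDecomposition:
    def test_static_pose_is_zero(self, walker_model):
        times = np.array([0.0, 0.1])
        Q = np.zeros((2, walker_model.n_dof))
        V = np.zeros((2, walker_model.n_dof))
        upper = ["hat"]
        lower = [s for s in walker_model.segments if s != "hat"]
        dec = decompose_angular_momentum(walker_model, times, Q, V, upper, lower)
        assert np.abs(dec.full).max() == 0.0

    def test_additivity(self, walker_model, rng):
        times = np.array([0.0])
        Q = rng.normal(0, 0.3, (1, walker_model.n_dof))
        V = rng.normal(0, 1.0, (1, walker_model.n_dof))
        upper = ["hat"]
        lower = [s for s in walker_model.segments if s != "hat"]
        dec = decompose_angular_momentum(walker_model, times, Q, V, upper, lower)
        assert np.abs(dec.upper + dec.lower - dec.full).max() <= \
            1e-9 * max(1.0, np.abs(dec.full).max())

    def test_non_partition_raises(self, walker_model):
        with pytest.raises(ValidationError):
            decompose_angular_momentum(walker_model, np.array([0.0]),
                                       np.zeros((1, 9)), np.zeros((1, 9)),
                                       ["hat"], ["hat"])

    def test_reference_point_transport_term(self, walker_model, rng):
        """Shifting the reference changes AM by m (delta x rdot_com)."""
        from gaitbench.multibody import State, angular_momentum, com_state

        st = State(rng.normal(0, 0.3, 9), rng.normal(0, 1.0, 9))
        com, comdot = com_state(walker_model, st)
        delta = np.array([0.3, -0.2, 0.1])
        L0 = angular_momentum(walker_model, st, about=com)
        L1 = angular_momentum(walker_model, st, about=com - delta)
        M = walker_model.total_mass
        assert np.abs(L1 - (L0 + M * np.cross(delta, comdot))).max() < 1e-9


def test_ground_reference_from_states_static_pose(walker_model):
    """At rest the ICaP coincides with the COM ground projection."""
    from gaitbench.metrics import ground_reference_from_states
    from gaitbench.multibody import State, com_state

    q = np.zeros(walker_model.n_dof)
    q[1] = 1.0
    times = np.array([0.0, 0.1])
    Q = np.tile(q, (2, 1))
    V = np.zeros_like(Q)
    traj = ground_reference_from_states(walker_model, times, Q, V)
    com, _ = com_state(walker_model, State(q, np.zeros_like(q)))
    assert np.allclose(traj.r_icap[0], com[:2], atol=1e-12)
    assert traj.com_height[0] > 0
    assert traj.icap_mode == "com"


class TestGaitEventDetection:
    def test_monotone_ramp_crosses_threshold_once(self):
        times = np.linspace(0, 1, 101)
        fz = np.linspace(0, 100, 101)
        ev = detect_gait_events(times, point_forces={("left", "heel"): fz},
                                body_weight=75.0)
        assert len(ev.heel_strikes["left"]) == 1
        assert ev.heel_strikes["right"] == []

    def test_no_contact_gives_empty_events(self):
        times = np.linspace(0, 1, 50)
        ev = detect_gait_events(times,
                                point_forces={("left", "heel"): np.zeros(50)},
                                body_weight=75.0)
        assert ev.heel_strikes == {"left": [], "right": []}
        assert ev.toe_offs == {"left": [], "right": []}

    def test_kinematic_mode_height_threshold(self):
        times = np.linspace(0, 1, 101)
        z = np.abs(times - 0.5) * 0.1  # touches below 5 mm around t = 0.5
        ev = detect_gait_events(times, point_heights={("right", "heel"): z})
        assert len(ev.heel_strikes["right"]) == 1
        assert abs(ev.heel_strikes["right"][0] - 0.45) < 0.02


class TestFootPlacement:
    def _traj_with_icap(self, icap):
        times = np.array([0.0, 1.0])
        tr = _flat_trajectory(times, np.zeros((2, 2)), np.zeros((2, 2)),
                              np.zeros((2, 2)))
        tr.r_icap = np.tile(icap, (2, 1))
        return tr

    def test_icap_at_heel_gives_zero_offsets(self):
        traj = self._traj_with_icap(np.array([0.3, 0.1]))
        events = GaitEvents()
        events.heel_strikes["left"] = [0.0]
        fp = {(0.0, "left"): {"heel": [0.3, 0.1], "hallux": [0.55, 0.1],
                              "meta5": [0.5, 0.02]}}
        out = foot_placement_summary(traj, events, fp)
        assert out.steps[0].anterior_offset == pytest.approx(0.0, abs=1e-12)
        assert out.steps[0].medial_offset == pytest.approx(0.0, abs=1e-12)

    def test_medial_offsets_mirror_between_sides(self):
        traj = self._traj_with_icap(np.array([0.1, 0.02]))
        events = GaitEvents()
        events.heel_strikes["left"] = [0.0]
        events.heel_strikes["right"] = [1.0]
        fp = {
            (0.0, "left"): {"heel": [0.0, 0.1], "hallux": [0.25, 0.1]},
            (1.0, "right"): {"heel": [0.0, -0.06], "hallux": [0.25, -0.06]},
        }
        out = foot_placement_summary(traj, events, fp)
        left, right = out.steps
        # the ICaP sits 0.08 m towards the midline of either foot lane; in
        # the side-aware (medial-positive) convention both offsets agree,
        # while the raw lateral offsets mirror in sign
        assert left.anterior_offset == pytest.approx(right.anterior_offset)
        assert left.medial_offset == pytest.approx(0.08, abs=1e-12)
        assert right.medial_offset == pytest.approx(0.08, abs=1e-12)
        raw_left = left.r_icap[1] - fp[(0.0, "left")]["heel"][1]
        raw_right = right.r_icap[1] - fp[(1.0, "right")]["heel"][1]
        assert raw_left == pytest.approx(-raw_right, abs=1e-12)

    def test_missing_footprint_warns_and_skips(self):
        traj = self._traj_with_icap(np.array([0.1, 0.0]))
        events = GaitEvents()
        events.heel_strikes["left"] = [0.0]
        with pytest.warns(UserWarning):
            out = foot_placement_summary(traj, events, {})
        assert out.steps == []
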