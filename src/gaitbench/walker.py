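"""Forward-simulated planar walker fixtures with ground-truth dynamics.

Generates a full stride of the planar 7-segment walker by hybrid forward
simulation: a whole-body task-space tracking controller (computed torque
with an equality-constrained least-squares torque allocation) drives the
actuated joints along a designed gait pattern while the floating base
evolves passively; touch-downs are detected geometrically and resolved with
the perfectly inelastic impact map, lift-offs follow the gait plan.  The
stride follows the canonical eight-phase grammar starting at left toe off:

  R flat > R toe > R toe + L heel > R toe + L flat > L flat > L toe
  > L toe + R heel > L toe + R flat > (next L toe off)

with four touch-down transitions (two heel strikes, two toe strikes).

The resulting fixture carries dynamically consistent ground truth —
``q(t)``, ``v(t)``, actuated torques ``u(t)``, contact forces and the exact
contact schedule — and can synthesize noisy marker trajectories, so every
pipeline stage (IK, phase scheduling, optimal-control reconstruction,
stability metrics) is testable without laboratory data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import scipy.linalg

from .errors import ValidationError
from .markerik import MarkerFrame
from .metrics import GaitEvents, detect_gait_events
from .multibody import (
    ContactPoint, ContactSet, MultibodyModel, State,
    com_state, constrained_forward_dynamics, project_to_constraints,
)

__all__ = [
    "WalkerFixture", "GaitPlan", "GaitTrackingController", "SampledController",
    "simulate_walker", "simulate_stride", "sampled_control_grid",
    "synthesize_markers", "default_walker_markers", "planar_leg_ik",
]

_PLANAR_DIRS = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])  # x and z rows


def _rot_y(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


# ---------------------------------------------------------------------------
# fixture container
# ---------------------------------------------------------------------------


@dataclass
class WalkerFixture:
    """Ground-truth planar walking trial."""

    model: MultibodyModel
    times: np.ndarray  # (n,)
    Q: np.ndarray  # (n, n_dof)
    V: np.ndarray
    U: np.ndarray  # (n, n_act) actuated torques
    point_forces: dict  # (side, point) -> (n,) vertical contact force, N
    schedule: list  # [(t, frozenset of (side, point))] contact-set changes
    events: GaitEvents
    fell: bool = False
    control_log: Optional[list] = None  # (t, tau) samples of a ZOH controller

    def contacts_at(self, t: float) -> frozenset:
        active = frozenset()
        for ts, cs in self.schedule:
            if ts <= t + 1e-12:
                active = cs
        return active


# ---------------------------------------------------------------------------
# analytic planar leg IK (for pose construction)
# ---------------------------------------------------------------------------


def planar_leg_ik(hip_xz, ankle_xz, thigh_len, shank_len, base_pitch, foot_pitch):
    """Joint angles (hip, knee, ankle) of a planar leg.

    Absolute segment pitches are rotations about +y (positive pitches the
    distal end backwards); the knee branch keeps knee flexion non-negative.
    """
    dx, dz = ankle_xz[0] - hip_xz[0], ankle_xz[1] - hip_xz[1]
    D = np.hypot(dx, dz)
    D = min(D, 0.9999 * (thigh_len + shank_len))
    gamma = np.arctan2(-dx, -dz)
    ca = np.clip((thigh_len ** 2 + D ** 2 - shank_len ** 2) / (2 * thigh_len * D), -1, 1)
    cb = np.clip((shank_len ** 2 + D ** 2 - thigh_len ** 2) / (2 * shank_len * D), -1, 1)
    alpha = gamma - np.arccos(ca)  # thigh absolute pitch
    beta = gamma + np.arccos(cb)  # shank absolute pitch
    return alpha - base_pitch, beta - alpha, foot_pitch - beta


# ---------------------------------------------------------------------------
# gait plan: reference task trajectories over one stride
# ---------------------------------------------------------------------------


def _minjerk(u):
    u = np.clip(u, 0.0, 1.0)
    return 10 * u ** 3 - 15 * u ** 4 + 6 * u ** 5


@dataclass
class GaitPlan:
    """Designed task references for one stride of the planar walker.

    Defaults give a moderate, robustly trackable gait (~1 m/s).  Phase
    fractions follow the eight-phase grammar; lift-offs happen at the
    planned times, touch-downs when the swing foot actually reaches the
    ground.
    """

    model: MultibodyModel
    stride_time: float = 1.0  # s
    step_length: float = 0.40  # m, ankle-to-ankle
    hip_height_factor: float = 0.88  # of leg length, base height during gait
    clearance: float = 0.05  # m, swing apex extra ankle lift
    toe_off_pitch: float = 0.50  # rad, foot pitch (toe down) at lift-off
    landing_pitch: float = -0.12  # rad, toe-up pitch at heel strike
    landing_depth: float = 0.012  # m, commanded heel overshoot below ground
    base_lead: float = 0.84  # base x offset at t=0, in step lengths
    frac_flat: float = 0.34  # single-support flat fraction of each half stride
    frac_toe: float = 0.08
    frac_ds_heel: float = 0.06
    frac_ds_flat: float = 0.02

    def __post_init__(self):
        m = self.model
        self.thigh_len = abs(m.bodies[m.body_index["shank_left"]].joint_offset[2])
        self.shank_len = abs(m.bodies[m.body_index["foot_left"]].joint_offset[2])
        heel_body, heel_off = m.contact_point("left", "heel")
        hal_body, hal_off = m.contact_point("left", "hallux")
        self.heel_local, self.hallux_local = heel_off, hal_off
        self.ankle_h = abs(heel_off[2])
        self.hip_z = self.hip_height_factor * (self.thigh_len + self.shank_len) + self.ankle_h
        self.speed = 2.0 * self.step_length / self.stride_time
        half = self.frac_flat + self.frac_toe + self.frac_ds_heel + self.frac_ds_flat
        if abs(half - 0.5) > 1e-9:
            raise ValidationError("phase fractions must sum to 0.5 per half stride")

    # nominal ankle x of the stance foot during the first half (right stance)
    def stance_ankle_x(self, half: int) -> float:
        return (half + 1) * self.step_length  # left lands one step ahead, etc.

    def half_and_local(self, t: float):
        T = self.stride_time
        s = (t % T) / T
        half = 0 if s < 0.5 else 1
        return half, (s - 0.5 * half) * 2.0  # u in [0,1) within the half

    def base_ref(self, t: float):
        """Base (x, z) and trunk pitch reference with velocities."""
        x = self.speed * t + self.step_length * self.base_lead
        return np.array([x, self.hip_z]), np.array([self.speed, 0.0]), 0.0

    def swing_ankle_ref(self, t: float):
        """Swing ankle (x, z), foot pitch and their velocities within a half.

        The swing starts at the half's beginning (toe off) and lands at the
        end of the toe phase (frac_flat + frac_toe into the half).
        """
        half, u = self.half_and_local(t)
        T_half = 0.5 * self.stride_time
        u_land = self.frac_flat + self.frac_toe  # fraction of the half
        w = np.clip(u / (2 * u_land), 0.0, 1.0)  # swing progress in [0, 1]
        # ankle positions at toe off and at (commanded) landing
        x_stance = self.stance_ankle_x(half)
        ank0, th0 = self._liftoff_ankle(x_stance - self.step_length)
        ank1, th1 = self._landing_ankle(x_stance + self.step_length)
        s = _minjerk(w)
        ds_dw = 30 * w ** 2 - 60 * w ** 3 + 30 * w ** 4
        dw_dt = 1.0 / (2 * u_land * T_half)
        pos = ank0 + s * (ank1 - ank0)
        vel = ds_dw * dw_dt * (ank1 - ank0)
        bump = self.clearance * np.sin(np.pi * w)
        dbump = self.clearance * np.pi * np.cos(np.pi * w) * dw_dt
        pos = pos + np.array([0.0, bump])
        vel = vel + np.array([0.0, dbump])
        pitch = th0 + s * (th1 - th0)
        dpitch = ds_dw * dw_dt * (th1 - th0)
        return pos, vel, pitch, dpitch

    def _liftoff_ankle(self, ankle_x: float):
        """Ankle pose with the hallux on the ground at the toe-off pitch."""
        th = self.toe_off_pitch
        hal = _rot_y(th) @ self.hallux_local
        return np.array([ankle_x + 0.3 * self.ankle_h, -hal[2]]), th

    def _landing_ankle(self, ankle_x: float):
        """Ankle pose with the heel ``landing_depth`` below ground, toe up."""
        th = self.landing_pitch
        heel = _rot_y(th) @ self.heel_local
        return np.array([ankle_x, -heel[2] - self.landing_depth]), th

    def landed_pitch_ref(self, t: float):
        """Foot-pitch reference of the just-landed foot: rotate flat."""
        half, u = self.half_and_local(t)
        u0 = 2.0 * (self.frac_flat + self.frac_toe)
        span = self.frac_ds_heel
        w = np.clip((u - u0) / (2.0 * span), 0.0, 1.0)
        th = self.landing_pitch * (1.0 - _minjerk(w)) - 0.02 * _minjerk(w)
        dth = (-self.landing_pitch - 0.02) * (30 * w ** 2 - 60 * w ** 3 + 30 * w ** 4) / (
            2.0 * span * self.stride_time * 0.5
        )
        return th, dth

    # -- schedule ----------------------------------------------------------
    def liftoff_times(self, n_strides: int = 1):
        """Planned lift-off events: (t, side, what) with what in heel/all."""
        out = []
        T = self.stride_time
        for k in range(n_strides):
            for half in (0, 1):
                stance = "right" if half == 0 else "left"
                swing = "left" if half == 0 else "right"
                t0 = k * T + half * 0.5 * T
                if k == 0 and half == 0:
                    pass  # left foot starts in the air (stride begins at L toe off)
                out.append((t0 + self.frac_flat * T, stance, "heel"))
                out.append((t0 + 0.5 * T, stance, "all"))
        return sorted(out)


# ---------------------------------------------------------------------------
# whole-body tracking controller
# ---------------------------------------------------------------------------


class GaitTrackingController:
    """Task-space computed-torque controller for the planar walker.

    At every evaluation it solves an equality-constrained least-squares
    problem for (accelerations, actuated torques, contact forces): the
    equations of motion and the contact acceleration constraints are hard,
    task accelerations (swing ankle, foot pitches, base translation, trunk
    pitch, servoed with PD gains) are soft, with a small torque/force
    regularization.  The floating base is never actuated.
    """

    def __init__(self, plan: GaitPlan, kp: float = 100.0, kd: float = 20.0,
                 kp_posture: float = 100.0, kd_posture: float = 20.0,
                 reg: float = 1e-5, torque_limit: float = 400.0):
        self.plan = plan
        self.kp, self.kd, self.reg = kp, kd, reg
        self.kp_posture, self.kd_posture = kp_posture, kd_posture
        self.torque_limit = torque_limit
        m = plan.model
        self.dof = {name: i for i, name in enumerate(m.dof_names)}
        self.pitch_chain = {
            side: [self.dof["base_pitch"], self.dof[f"hip_{side}"],
                   self.dof[f"knee_{side}"], self.dof[f"ankle_{side}"]]
            for side in ("left", "right")
        }

    def foot_pitch(self, q, side):
        return float(sum(q[i] for i in self.pitch_chain[side]))

    def _tasks(self, t, state, active):
        """(J, bias, ydd_des) rows of the current task stack."""
        plan, m = self.plan, self.plan.model
        q, v = state.q, state.v
        kin = m.kinematics(q, v)
        half, u = plan.half_and_local(t)
        stance = "right" if half == 0 else "left"
        swing = "left" if half == 0 else "right"
        rows_J, rows_b, rows_y = [], [], []

        def add_point_task(body, offset, target, target_v, kp, kd, weight=1.0, sel=(0, 2)):
            Jp = kin.point_jacobian(body, offset)
            bp = kin.point_bias_acceleration(body, offset)
            x = kin.point_position(body, offset)
            xd = kin.point_velocity(body, offset)
            for k, axis in enumerate(sel):
                rows_J.append(weight * Jp[axis])
                rows_b.append(weight * bp[axis])
                rows_y.append(weight * (kp * (target[k] - x[axis])
                                        + kd * (target_v[k] - xd[axis])))

        def add_angle_task(dofs, coeffs, target, target_v, kp, kd, weight=1.0):
            row = np.zeros(m.n_dof)
            for d, c in zip(dofs, coeffs):
                row[d] = c
            y = float(row @ q)
            yd = float(row @ v)
            rows_J.append(weight * row)
            rows_b.append(0.0)
            rows_y.append(weight * (kp * (target - y) + kd * (target_v - yd)))

        # base translation + trunk pitch
        b_pos, b_vel, _ = plan.base_ref(t)
        add_point_task(m.body_index["hat"], np.zeros(3), b_pos, b_vel,
                       self.kp_posture, self.kd_posture)
        add_angle_task([self.dof["base_pitch"]], [1.0], 0.0, 0.0,
                       self.kp_posture, self.kd_posture)

        swing_on_ground = any(s == swing for (s, _p) in active)
        stance_heel_on = (stance, "heel") in active
        if not swing_on_ground:
            pos, vel, pitch, dpitch = plan.swing_ankle_ref(t)
            # ramp the swing gains in over the first tenth of the swing to
            # absorb the reference discontinuity at lift-off
            u_land = 2.0 * (plan.frac_flat + plan.frac_toe)
            w = np.clip(u / u_land, 0.0, 1.0)
            ramp = 0.3 + 0.7 * _minjerk(np.clip(w / 0.1, 0.0, 1.0))
            ankle_body = m.body_index[f"foot_{swing}"]
            add_point_task(ankle_body, np.zeros(3), pos, vel,
                           ramp * self.kp, ramp * self.kd)
            add_angle_task(self.pitch_chain[swing], np.ones(4), pitch, dpitch,
                           ramp * self.kp, ramp * self.kd)
        elif (swing, "heel") in active and (swing, "hallux") not in active:
            th, dth = plan.landed_pitch_ref(t)
            add_angle_task(self.pitch_chain[swing], np.ones(4), th, dth,
                           self.kp_posture, self.kd_posture)
        if not stance_heel_on and any(s == stance for (s, _p) in active):
            # toe-pinned stance: drive the heel to keep rising so the foot
            # vaults forward over the toe instead of rocking back
            u_ho = 2.0 * plan.frac_flat
            wtoe = np.clip((u - u_ho) / (1.0 - u_ho), 0.0, 1.0)
            th_target = 0.10 + (plan.toe_off_pitch - 0.10) * _minjerk(wtoe)
            add_angle_task(self.pitch_chain[stance], np.ones(4), th_target, 0.0,
                           self.kp_posture, self.kd_posture, weight=0.5)
        # one-sided knee barriers keep airborne legs on the physiological
        # (knee-forward) branch; the weight fades in smoothly as the knee
        # nears hyperextension so the closed-loop torque stays smooth in time
        for s in ("left", "right"):
            if any(s == cs for (cs, _p) in active):
                continue
            qk = q[self.dof[f"knee_{s}"]]
            w_barrier = 0.6 / (1.0 + np.exp((qk - 0.20) / 0.02))
            if w_barrier > 1e-4:
                add_angle_task([self.dof[f"knee_{s}"]], [1.0], 0.35, 0.0,
                               self.kp, self.kd, weight=w_barrier)
        return np.array(rows_J), np.array(rows_b), np.array(rows_y)

    def torques(self, t, state, contacts: ContactSet):
        """Full-length generalized force vector (base rows zero)."""
        m = self.plan.model
        n, na = m.n_dof, m.n_act
        kin = m.kinematics(state.q, state.v)
        from .multibody import mass_matrix_bias

        H, C = mass_matrix_bias(m, kin)
        rows = contacts.independent_rows(kin)
        G = contacts.jacobian(kin)[rows] if len(rows) else np.zeros((0, n))
        gamma = contacts.bias(kin)[rows] if len(rows) else np.zeros(0)
        nc = G.shape[0]
        active = {tuple(p.label.split(":")) for p in contacts}
        Jt, bt, ydd = self._tasks(t, state, active)
        # unknowns z = [a (n), u (na), lam (nc)]
        nz = n + na + nc
        S = np.zeros((na, n))
        S[:, m.base_dof:] = np.eye(na)
        A_eq = np.zeros((n + nc, nz))
        A_eq[:n, :n] = H
        A_eq[:n, n:n + na] = -S.T
        A_eq[:n, n + na:] = -G.T
        A_eq[n:, :n] = G
        b_eq = np.concatenate([-C, gamma])
        M = np.zeros((len(ydd) + na + nc, nz))
        M[:len(ydd), :n] = Jt
        M[len(ydd):len(ydd) + na, n:n + na] = np.sqrt(self.reg) * np.eye(na)
        M[len(ydd) + na:, n + na:] = np.sqrt(self.reg) * np.eye(nc)
        d = np.concatenate([ydd - bt, np.zeros(na + nc)])
        # KKT of min |Mz-d|^2 s.t. A_eq z = b_eq
        Q = M.T @ M + 1e-12 * np.eye(nz)
        K = np.zeros((nz + len(b_eq), nz + len(b_eq)))
        K[:nz, :nz] = Q
        K[:nz, nz:] = A_eq.T
        K[nz:, :nz] = A_eq
        rhs = np.concatenate([M.T @ d, b_eq])
        sol = scipy.linalg.lstsq(K, rhs, lapack_driver="gelsd")[0]
        # smooth (tanh) saturation keeps the applied torque bounded without
        # introducing kinks into the closed-loop torque trajectory
        L = self.torque_limit
        u = L * np.tanh(sol[n:n + na] / L)
        tau = np.zeros(n)
        tau[m.base_dof:] = u
        return tau


# ---------------------------------------------------------------------------
# hybrid simulation
# ---------------------------------------------------------------------------


def _make_contact(model, side, point, x_anchor, planar=True):
    body, off = model.contact_point(side, point)
    dirs = _PLANAR_DIRS if planar else np.eye(3)
    return ContactPoint(f"{side}:{point}", body, off, dirs, x_anchor)


def simulate_walker(
    model: MultibodyModel,
    controller: Callable[[float, State, ContactSet], np.ndarray],
    initial_state: State,
    duration: float,
    initial_contacts: Optional[list] = None,
    liftoffs: Optional[list] = None,
    dt: float = 1e-3,
    contact_points: tuple = ("heel", "hallux"),
    fall_height: float = 0.4,
    hold_per_step: bool = False,
    project: bool = True,
) -> WalkerFixture:
    """Hybrid forward simulation with event-triggered impacts.

    With ``hold_per_step`` the controller is evaluated once at each step
    start and its torque held constant through the RK4 stages (required for
    zero-order-hold controllers to be exact).

    ``controller(t, state, contacts)`` returns the full generalized-force
    vector (use ``lambda t, s, c: np.zeros(n)`` for passive flight).
    ``initial_contacts`` lists (side, point) pairs active at t = 0 (anchored
    at their current positions); ``liftoffs`` lists planned deactivation
    events ``(t, side, "heel"|"all")``.  Touch-downs trigger when an armed
    contact point crosses the ground moving downward and are resolved with
    the impact map; the COM dropping below ``fall_height`` truncates the
    trial with ``fell=True``.
    """
    n_steps = int(round(duration / dt))
    liftoffs = sorted(liftoffs or [])
    state = State(initial_state.q.copy(), initial_state.v.copy())
    kin = model.kinematics(state.q, state.v)
    contacts = ContactSet([])
    for side, point in initial_contacts or []:
        body, off = model.contact_point(side, point)
        x = kin.point_position(body, off).copy()
        x[2] = 0.0
        contacts.points.append(_make_contact(model, side, point, x))
    state = project_to_constraints(model, state, contacts)

    sides = ("left", "right")
    armed = {(s, p): ((s, p) not in {(c[0], c[1]) for c in (initial_contacts or [])})
             for s in sides for p in contact_points}

    times = np.empty(n_steps + 1)
    Q = np.empty((n_steps + 1, model.n_dof))
    V = np.empty((n_steps + 1, model.n_dof))
    U = np.empty((n_steps + 1, model.n_act))
    forces = {(s, p): np.zeros(n_steps + 1) for s in sides for p in contact_points}
    schedule = [(0.0, frozenset(tuple(c.label.split(":")) for c in contacts.points))]
    fell = False

    def record(i, t, st, cset):
        times[i] = t
        Q[i] = st.q
        V[i] = st.v
        tau = controller(t, st, cset)
        U[i] = tau[model.base_dof:]
        ev = constrained_forward_dynamics(model, st, tau, cset)
        info = cset.row_info()
        for ridx, lam in zip(ev.rows, ev.lam):
            p_i, d_i = info[ridx]
            label = tuple(cset.points[p_i].label.split(":"))
            if cset.points[p_i].directions[d_i][2] > 0.5:  # vertical row
                forces[label][i] = lam
        return tau

    t = 0.0
    for i in range(n_steps):
        tau = record(i, t, state, contacts)
        # integrate one RK4 step with frozen contact set / torque field
        from .multibody import integrate_phase

        if hold_per_step:
            torque_fn = lambda tt, ss, tau=tau: tau  # noqa: E731
        else:
            torque_fn = lambda tt, ss: controller(tt, ss, contacts)  # noqa: E731
        state_new = integrate_phase(
            model, state, torque_fn, contacts, t, t + dt, dt=dt, project=project,
        )
        t += dt
        # planned lift-offs
        while liftoffs and liftoffs[0][0] <= t + 1e-12:
            _, side, what = liftoffs.pop(0)
            drop = {(side, p) for p in (contact_points if what == "all" else (what,))}
            contacts.points = [c for c in contacts.points
                               if tuple(c.label.split(":")) not in drop]
            schedule.append((t, frozenset(tuple(c.label.split(":"))
                                          for c in contacts.points)))
        # touch-downs: armed points crossing the ground moving down
        kin = model.kinematics(state_new.q, state_new.v)
        active_labels = {tuple(c.label.split(":")) for c in contacts.points}
        touched = []
        for s in sides:
            for p in contact_points:
                if (s, p) in active_labels:
                    continue
                body, off = model.contact_point(s, p)
                z = kin.point_position(body, off)[2]
                vz = kin.point_velocity(body, off)[2]
                if not armed[(s, p)]:
                    if z > 5e-3:
                        armed[(s, p)] = True
                    continue
                if z <= 0.0 and vz < 0.0:
                    touched.append((s, p))
        if touched:
            for s, p in touched:
                body, off = model.contact_point(s, p)
                x = kin.point_position(body, off).copy()
                x[2] = 0.0
                contacts.points.append(_make_contact(model, s, p, x))
                armed[(s, p)] = False
            from .multibody import impact_map

            res = impact_map(model, state_new.q, state_new.v, contacts)
            state_new = State(state_new.q, res.v_plus)
            if project:
                state_new = project_to_constraints(model, state_new, contacts)
            schedule.append((t, frozenset(tuple(c.label.split(":"))
                                          for c in contacts.points)))
        state = state_new
        com, _ = com_state(model, state)
        if com[2] < fall_height:
            fell = True
            n_steps = i + 1
            times, Q, V, U = times[:n_steps + 1], Q[:n_steps + 1], V[:n_steps + 1], U[:n_steps + 1]
            forces = {k: f[:n_steps + 1] for k, f in forces.items()}
            warnings.warn(f"walker fell at t={t:.3f}s; fixture truncated")
            break
    record(min(n_steps, len(times) - 1), t, state, contacts)

    events = _events_from_schedule(schedule)
    return WalkerFixture(model=model, times=times, Q=Q, V=V, U=U,
                         point_forces=forces, schedule=schedule, events=events,
                         fell=fell,
                         control_log=getattr(controller, "log", None))


def _events_from_schedule(schedule) -> GaitEvents:
    events = GaitEvents()
    prev = schedule[0][1]
    for t, cur in schedule[1:]:
        for side in ("left", "right"):
            heel_was, heel_is = (side, "heel") in prev, (side, "heel") in cur
            fore_was = any((side, p) in prev for p in ("hallux", "meta5"))
            fore_is = any((side, p) in cur for p in ("hallux", "meta5"))
            foot_was, foot_is = heel_was or fore_was, heel_is or fore_is
            if heel_is and not heel_was:
                events.heel_strikes[side].append(t)
            if fore_is and not fore_was:
                events.toe_strikes[side].append(t)
            if foot_was and not foot_is:
                events.toe_offs[side].append(t)
            elif heel_was and not heel_is and foot_is:
                events.heel_offs[side].append(t)
        prev = cur
    return events


def simulate_stride(plan: GaitPlan, dt: float = 1e-3,
                    control_sampling: Optional[float] = 0.02,
                    project: bool = True) -> WalkerFixture:
    """Simulate one full stride beginning at left toe off.

    By default the tracking controller runs through a zero-order-hold
    sampler (``control_sampling`` seconds, node clock restarting at contact
    events), so the fixture's torques are exactly piecewise constant on a
    per-phase node grid (see :func:`sampled_control_grid`); pass
    ``control_sampling=None`` for the continuous controller.  With
    ``project=False`` the contact ODE is integrated without constraint
    projection, making the trajectory the exact composition of RK4 steps of
    the same ODE the reconstruction discretizes.
    """
    model = plan.model
    ctrl = GaitTrackingController(plan)
    q0, v0 = _initial_stride_state(plan)
    controller = ctrl.torques
    hold = False
    if control_sampling is not None:
        controller = SampledController(ctrl.torques, spacing=control_sampling)
        hold = True
    fixture = simulate_walker(
        model, controller, State(q0, v0), plan.stride_time,
        initial_contacts=[("right", "heel"), ("right", "hallux")],
        liftoffs=plan.liftoff_times(1), dt=dt, hold_per_step=hold,
        project=project,
    )
    return fixture


def _initial_stride_state(plan: GaitPlan):
    """Stride-start state (left toe off) built from the plan references."""
    model = plan.model
    dof = {name: i for i, name in enumerate(model.dof_names)}

    def pose_at(t):
        q = np.zeros(model.n_dof)
        b_pos, _, pitch = plan.base_ref(t)
        q[dof["base_tx"]], q[dof["base_tz"]], q[dof["base_pitch"]] = b_pos[0], b_pos[1], pitch
        # stance (right) leg: flat foot at its nominal ankle position
        x_st = plan.stance_ankle_x(0)
        hip, knee, ank = planar_leg_ik((b_pos[0], b_pos[1]), (x_st, plan.ankle_h),
                                       plan.thigh_len, plan.shank_len, pitch, 0.0)
        q[dof["hip_right"]], q[dof["knee_right"]], q[dof["ankle_right"]] = hip, knee, ank
        pos, _, fpitch, _ = plan.swing_ankle_ref(t)
        hip, knee, ank = planar_leg_ik((b_pos[0], b_pos[1]), tuple(pos),
                                       plan.thigh_len, plan.shank_len, pitch, fpitch)
        q[dof["hip_left"]], q[dof["knee_left"]], q[dof["ankle_left"]] = hip, knee, ank
        return q

    eps = 1e-4
    q0 = pose_at(0.0)
    v0 = (pose_at(eps) - q0) / eps
    return q0, v0


# ---------------------------------------------------------------------------
# sampled (zero-order-hold) control
# ---------------------------------------------------------------------------


class SampledController:
    """Zero-order-hold wrapper around a continuous controller.

    The inner controller is re-evaluated only on a node clock (every
    ``spacing`` seconds) that restarts whenever the contact set changes; the
    returned generalized-force vector is held constant in between.  The
    resulting applied torque is exactly piecewise constant on a per-phase
    node grid — the model class of the reconstruction's "hold" control
    parameterization — while the walk remains closed loop and stable.
    ``log`` records every (time, torque) sample for ground-truth export.
    """

    def __init__(self, inner, spacing: float = 0.02):
        self.inner = inner
        self.spacing = spacing
        self._key = None
        self._t_next = -np.inf
        self._tau = None
        self.log = []

    def __call__(self, t, state, contacts: ContactSet):
        key = frozenset(p.label for p in contacts.points)
        if key != self._key or t >= self._t_next - 1e-9:
            self._key = key
            self._tau = np.asarray(self.inner(t, state, contacts), float)
            self.log.append((t, self._tau.copy()))
            self._t_next = t + self.spacing
        return self._tau


def sampled_control_grid(fixture: WalkerFixture, schedule_phases):
    """Per-phase node grids and held torques of a sampled-control trial.

    Returns ``(node_times, U_intervals)``: for each phase of
    ``schedule_phases`` the node times (resample instants plus the phase
    end) and the actuated torque held on each interval — the exact ground
    truth for a "hold"-mode reconstruction.
    """
    if fixture.control_log is None:
        raise ValidationError("fixture was not simulated with a SampledController")
    nb = fixture.model.base_dof
    node_times, U_nodes = [], []
    for ph in schedule_phases.phases:
        ts, us = [], []
        for t, tau in fixture.control_log:
            if ph.start - 1e-9 <= t < ph.end - 1e-9:
                ts.append(t)
                us.append(tau[nb:])
        node_times.append(np.array(ts + [ph.end]))
        U_nodes.append(np.array(us))
    return node_times, U_nodes


# ---------------------------------------------------------------------------
# marker synthesis
# ---------------------------------------------------------------------------


def default_walker_markers() -> dict:
    """Marker-set definition for the planar walker: name -> (segment, offset)."""
    d = {
        "TRXT": ("hat", (0.03, 0.00, 0.55)),
        "TRXF": ("hat", (0.08, 0.10, 0.35)),
        "TRXB": ("hat", (-0.08, -0.10, 0.15)),
    }
    for side, sgn in (("L", 1.0), ("R", -1.0)):
        sd = "left" if side == "L" else "right"
        d[f"{side}THF"] = (f"thigh_{sd}", (0.05, sgn * 0.05, -0.15))
        d[f"{side}THB"] = (f"thigh_{sd}", (-0.03, sgn * 0.02, -0.32))
        d[f"{side}SHF"] = (f"shank_{sd}", (0.04, sgn * 0.04, -0.12))
        d[f"{side}SHB"] = (f"shank_{sd}", (-0.03, sgn * 0.02, -0.30))
        d[f"{side}HEE"] = (f"foot_{sd}", (-0.05, 0.0, -0.02))
        d[f"{side}TOE"] = (f"foot_{sd}", (0.16, 0.0, -0.04))
        d[f"{side}MT5"] = (f"foot_{sd}", (0.10, sgn * 0.04, -0.04))
    return d


def synthesize_markers(
    model: MultibodyModel,
    times: np.ndarray,
    Q: np.ndarray,
    marker_set: dict,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list:
    """Forward-kinematics marker trajectories with seeded isotropic noise."""
    rng = np.random.default_rng(seed)
    frames = []
    defs = {name: (model.body_index[seg], np.asarray(off, float))
            for name, (seg, off) in marker_set.items()}
    for t, q in zip(times, Q):
        kin = model.kinematics(q)
        markers = {}
        for name, (body, off) in defs.items():
            x = kin.point_position(body, off)
            if noise_sigma > 0:
                x = x + rng.normal(0.0, noise_sigma, 3)
            markers[name] = x
        frames.append(MarkerFrame(time=float(t), markers=markers))
    return frames
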