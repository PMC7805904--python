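"""Floating-base rigid multibody kinematics and dynamics.

The engine represents a kinematic tree of rigid bodies connected by
*elementary* one-DoF joints (revolute or prismatic); multi-DoF anatomical
joints and the 6-DoF floating base are chains of elementary joints through
massless intermediate bodies.  All body frames coincide with their joint
anchor and are axis-aligned with the world frame in the neutral pose
(q = 0); world axes are x anterior, y left, z up, gravity along -z.

Dynamics are evaluated in world coordinates through body Jacobians:

    H(q) qdd + C(q, v) = tau + G(q)^T lambda,

with the mass matrix assembled as ``sum_i Jv_i^T m_i Jv_i + Jw_i^T I_i Jw_i``
over the (real) bodies and the bias vector from the Newton-Euler equations
evaluated at zero generalized acceleration.  Ground contacts are modelled as
point constraints along declared world directions; redundant constraint rows
are removed by a deterministic Gram-Schmidt sweep in declaration order so
that the contact Jacobian passed to the KKT solves has full row rank.

Touch-downs are perfectly inelastic: the impact map solves the same KKT
structure for the post-impact velocity and contact impulse, conserving the
momentum component orthogonal to the constraint directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.linalg

from .anthropometry import SegmentParameters
from .errors import ConfigurationError, DegenerateContactError, ValidationError

GRAVITY = 9.81  #: m/s^2, along -z

_AXES = {"x": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]), "z": np.array([0, 0, 1.0])}


def _cross(a, b):
    """Cross product of two 3-vectors (faster than np.cross for scalars)."""
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues; coordinate axes fast-pathed)."""
    c, s = np.cos(angle), np.sin(angle)
    if axis[0] == 1.0 and axis[1] == 0.0 and axis[2] == 0.0:
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    if axis[1] == 1.0 and axis[0] == 0.0 and axis[2] == 0.0:
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    if axis[2] == 1.0 and axis[0] == 0.0 and axis[1] == 0.0:
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


@dataclass
class BodyNode:
    """One node of the kinematic tree (possibly a massless joint link)."""

    name: str
    parent: int  # index into the model's body list, -1 = world
    joint_kind: str  # 'revolute' | 'prismatic' | 'fixed'
    joint_axis: np.ndarray  # unit axis in the parent frame (ignored for fixed)
    joint_offset: np.ndarray  # anchor in the parent frame, m
    mass: float = 0.0
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))  # in body frame
    inertia: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))  # about COM
    dof_index: int = -1  # filled by the model; -1 for fixed joints
    dof_name: str = ""


class MultibodyModel:
    """Kinematic tree with inertial parameters and foot contact geometry.

    Parameters
    ----------
    bodies:
        Topologically ordered nodes (parents before children).
    base_dof:
        Number of unactuated floating-base coordinates (6 spatial, 3 planar).
    segments:
        Names of the *real* (massive) segment bodies, for bookkeeping.
    foot_geometry:
        ``{"left"/"right": {"heel"/"hallux"/"meta5": (body_name, offset)}}``.
    """

    def __init__(
        self,
        bodies: Sequence[BodyNode],
        base_dof: int,
        segments: Optional[Sequence[str]] = None,
        foot_geometry: Optional[dict] = None,
        name: str = "model",
    ):
        self.name = name
        self.bodies = list(bodies)
        self.base_dof = base_dof
        self.body_index = {b.name: i for i, b in enumerate(self.bodies)}
        if len(self.body_index) != len(self.bodies):
            raise ConfigurationError("duplicate body names")
        ndof = 0
        for i, b in enumerate(self.bodies):
            if b.parent >= i:
                raise ConfigurationError("bodies must be topologically ordered")
            if b.joint_kind not in ("revolute", "prismatic", "fixed"):
                raise ConfigurationError(f"unknown joint kind {b.joint_kind!r}")
            b.joint_axis = np.asarray(b.joint_axis, dtype=float)
            b.joint_offset = np.asarray(b.joint_offset, dtype=float)
            b.com = np.asarray(b.com, dtype=float)
            b.inertia = np.asarray(b.inertia, dtype=float)
            if b.joint_kind != "fixed":
                b.dof_index = ndof
                if not b.dof_name:
                    b.dof_name = b.name
                ndof += 1
        self.n_dof = ndof
        self.n_act = ndof - base_dof
        self.segments = list(segments) if segments is not None else [
            b.name for b in self.bodies if b.mass > 0
        ]
        self.foot_geometry = foot_geometry or {}
        # ancestor DoF chains (root..self) per body, for Jacobians
        self._dof_path: list[list[int]] = []
        for i, b in enumerate(self.bodies):
            path = list(self._dof_path[b.parent]) if b.parent >= 0 else []
            if b.dof_index >= 0:
                path.append(i)
            self._dof_path.append(path)
        self._massive = [i for i, b in enumerate(self.bodies) if b.mass > 0]
        self.dof_names = [b.dof_name for b in self.bodies if b.dof_index >= 0]

    # -- convenience -------------------------------------------------------
    @property
    def total_mass(self) -> float:
        return float(sum(self.bodies[i].mass for i in self._massive))

    def segment_bodies(self, names: Sequence[str]) -> list[int]:
        try:
            return [self.body_index[n] for n in names]
        except KeyError as exc:
            raise ConfigurationError(f"unknown segment {exc.args[0]!r}") from exc

    def kinematics(self, q: np.ndarray, v: Optional[np.ndarray] = None) -> "Kinematics":
        return Kinematics(self, q, v)

    def contact_point(self, side: str, point: str) -> tuple[int, np.ndarray]:
        """Body index and local offset of a named foot contact point."""
        body_name, offset = self.foot_geometry[side][point]
        return self.body_index[body_name], np.asarray(offset, float)


@dataclass(frozen=True)
class State:
    """Generalized positions and velocities."""

    q: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "q", np.asarray(self.q, dtype=float))
        object.__setattr__(self, "v", np.asarray(self.v, dtype=float))
        if self.q.shape != self.v.shape:
            raise ValidationError("q and v must have the same length")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.v))):
            raise ValidationError("state entries must be finite")


class Kinematics:
    """Forward kinematics cache: world pose, velocity and bias acceleration.

    Bias accelerations are the classical accelerations obtained with zero
    generalized acceleration (the ``Jdot v`` terms), gravity excluded.
    """

    def __init__(self, model: MultibodyModel, q: np.ndarray, v: Optional[np.ndarray] = None):
        self.model = model
        q = np.asarray(q, dtype=float)
        v = np.zeros(model.n_dof) if v is None else np.asarray(v, dtype=float)
        if q.shape != (model.n_dof,) or v.shape != (model.n_dof,):
            raise ValidationError(
                f"expected q, v of length {model.n_dof}, got {q.shape}, {v.shape}"
            )
        self.q, self.v = q, v
        n = len(model.bodies)
        self.R = np.empty((n, 3, 3))
        self.p = np.empty((n, 3))
        self.w = np.empty((n, 3))  # angular velocity, world
        self.vo = np.empty((n, 3))  # velocity of the body-frame origin, world
        self.alpha0 = np.empty((n, 3))  # bias angular acceleration
        self.a0 = np.empty((n, 3))  # bias linear acceleration of the origin point
        self.s_world = np.zeros((n, 3))  # world joint axis per body (dof joints)
        for i, b in enumerate(model.bodies):
            if b.parent < 0:
                Rp, pp = np.eye(3), np.zeros(3)
                wp = vop = alp = a0p = np.zeros(3)
            else:
                j = b.parent
                Rp, pp, wp, vop = self.R[j], self.p[j], self.w[j], self.vo[j]
                alp, a0p = self.alpha0[j], self.a0[j]
            anchor = pp + Rp @ b.joint_offset
            rel = anchor - pp
            v_anchor = vop + _cross(wp, rel)
            a_anchor = a0p + _cross(alp, rel) + _cross(wp, _cross(wp, rel))
            if b.joint_kind == "fixed":
                self.R[i], self.p[i] = Rp, anchor
                self.w[i], self.vo[i] = wp, v_anchor
                self.alpha0[i], self.a0[i] = alp, a_anchor
                continue
            qi, vi = q[b.dof_index], v[b.dof_index]
            s = Rp @ b.joint_axis
            self.s_world[i] = s
            if b.joint_kind == "revolute":
                self.R[i] = Rp @ _rot(b.joint_axis, qi)
                self.p[i] = anchor
                self.w[i] = wp + s * vi
                self.vo[i] = v_anchor
                self.alpha0[i] = alp + _cross(wp, s * vi)
                self.a0[i] = a_anchor
            else:  # prismatic
                self.R[i] = Rp
                self.p[i] = anchor + s * qi
                rel2 = self.p[i] - pp
                self.w[i] = wp
                self.vo[i] = vop + _cross(wp, rel2) + s * vi
                self.alpha0[i] = alp
                self.a0[i] = (
                    a0p
                    + _cross(alp, rel2)
                    + _cross(wp, _cross(wp, rel2))
                    + 2.0 * _cross(wp, s * vi)
                )

    # -- points ------------------------------------------------------------
    def point_position(self, body: int, offset: np.ndarray) -> np.ndarray:
        return self.p[body] + self.R[body] @ offset

    def point_velocity(self, body: int, offset: np.ndarray) -> np.ndarray:
        x = self.point_position(body, offset)
        return self.vo[body] + _cross(self.w[body], x - self.p[body])

    def point_bias_acceleration(self, body: int, offset: np.ndarray) -> np.ndarray:
        """Classical acceleration of a body-fixed point at zero qdd (no gravity)."""
        x = self.point_position(body, offset)
        rel = x - self.p[body]
        return (
            self.a0[body]
            + _cross(self.alpha0[body], rel)
            + _cross(self.w[body], _cross(self.w[body], rel))
        )

    def point_jacobian(self, body: int, offset: np.ndarray) -> np.ndarray:
        """3 x n_dof world-frame translational Jacobian of a body-fixed point."""
        model = self.model
        J = np.zeros((3, model.n_dof))
        x = self.point_position(body, offset)
        for jb in model._dof_path[body]:
            node = model.bodies[jb]
            k = node.dof_index
            if node.joint_kind == "revolute":
                J[:, k] = _cross(self.s_world[jb], x - self.p[jb])
            else:
                J[:, k] = self.s_world[jb]
        return J

    def body_jacobians(self, body: int, offset: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Translational (at ``offset``) and rotational world Jacobians."""
        model = self.model
        Jv = np.zeros((3, model.n_dof))
        Jw = np.zeros((3, model.n_dof))
        x = self.point_position(body, offset)
        for jb in model._dof_path[body]:
            node = model.bodies[jb]
            k = node.dof_index
            if node.joint_kind == "revolute":
                Jv[:, k] = _cross(self.s_world[jb], x - self.p[jb])
                Jw[:, k] = self.s_world[jb]
            else:
                Jv[:, k] = self.s_world[jb]
        return Jv, Jw


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


@dataclass
class ContactPoint:
    """One active point constraint.

    ``directions`` are world-frame unit vectors (rows); the constraint pins
    the point's coordinates along those directions to ``anchor``.
    """

    label: str  # e.g. "left:heel"
    body: int
    offset: np.ndarray
    directions: np.ndarray  # (k, 3)
    anchor: np.ndarray  # (3,) world position the point is pinned to

    def __post_init__(self):
        self.offset = np.asarray(self.offset, float)
        self.directions = np.atleast_2d(np.asarray(self.directions, float))
        self.anchor = np.asarray(self.anchor, float)


class ContactSet:
    """Ordered collection of active contact points with redundancy reduction."""

    def __init__(self, points: Sequence[ContactPoint] = ()):  # order matters
        self.points = list(points)

    def __len__(self):
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.points]

    def row_info(self) -> list[tuple[int, int]]:
        """(point index, direction index) per raw constraint row."""
        return [(i, j) for i, p in enumerate(self.points) for j in range(len(p.directions))]

    def jacobian(self, kin: Kinematics) -> np.ndarray:
        rows = []
        for p in self.points:
            Jp = kin.point_jacobian(p.body, p.offset)
            rows.append(p.directions @ Jp)
        return np.vstack(rows) if rows else np.zeros((0, kin.model.n_dof))

    def position_error(self, kin: Kinematics) -> np.ndarray:
        rows = []
        for p in self.points:
            x = kin.point_position(p.body, p.offset)
            rows.append(p.directions @ (x - p.anchor))
        return np.concatenate(rows) if rows else np.zeros(0)

    def bias(self, kin: Kinematics) -> np.ndarray:
        """Contact Hessian term gamma = -Gdot v, per raw row."""
        rows = []
        for p in self.points:
            acc = kin.point_bias_acceleration(p.body, p.offset)
            rows.append(-(p.directions @ acc))
        return np.concatenate(rows) if rows else np.zeros(0)

    def independent_rows(self, kin: Kinematics, tol: float = 0.02) -> np.ndarray:
        """Indices of a well-conditioned independent subset of constraint rows.

        Deterministic: rows are swept in declaration order and kept when
        their component orthogonal to the rows already kept exceeds ``tol``
        relative to the row norm (modified Gram-Schmidt).  The default
        tolerance also discards *nearly* dependent rows (e.g. the fourth
        planar row of an almost-flat foot), whose retention would make the
        KKT systems ill-conditioned and the contact-force split physically
        meaningless.
        """
        G = self.jacobian(kin)
        kept: list[int] = []
        basis: list[np.ndarray] = []
        for i, row in enumerate(G):
            r = row.copy()
            for b in basis:
                r -= (r @ b) * b
            nr, n0 = np.linalg.norm(r), np.linalg.norm(row)
            if n0 > 0 and nr > tol * max(n0, 1.0):
                kept.append(i)
                basis.append(r / nr)
        return np.asarray(kept, dtype=int)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------


@dataclass
class DynamicsEval:
    """Constrained forward-dynamics solution (reduced constraint rows)."""

    H: np.ndarray
    C: np.ndarray
    G: np.ndarray
    gamma: np.ndarray
    a: np.ndarray
    lam: np.ndarray  # contact forces per retained row, N
    rows: np.ndarray  # retained raw-row indices


def mass_matrix_bias(model: MultibodyModel, kin: Kinematics) -> tuple[np.ndarray, np.ndarray]:
    """Joint-space mass matrix H(q) and bias vector C(q, v) incl. gravity."""
    n = model.n_dof
    H = np.zeros((n, n))
    C = np.zeros(n)
    gvec = np.array([0.0, 0.0, -GRAVITY])
    for i in model._massive:
        b = model.bodies[i]
        Jv, Jw = kin.body_jacobians(i, b.com)
        Iw = kin.R[i] @ b.inertia @ kin.R[i].T
        H += b.mass * Jv.T @ Jv + Jw.T @ Iw @ Jw
        ac = kin.point_bias_acceleration(i, b.com)
        wi = kin.w[i]
        C += Jv.T @ (b.mass * (ac - gvec)) + Jw.T @ (Iw @ kin.alpha0[i] + _cross(wi, Iw @ wi))
    return H, C


def _kkt_solve(H, G, rhs_top, rhs_bot):
    n, m = H.shape[0], G.shape[0]
    K = np.zeros((n + m, n + m))
    K[:n, :n] = H
    K[:n, n:] = G.T
    K[n:, :n] = G
    rhs = np.concatenate([rhs_top, rhs_bot])
    try:
        sol = scipy.linalg.solve(K, rhs)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - guarded by reduction
        raise DegenerateContactError(str(exc)) from exc
    return sol[:n], -sol[n:]


def constrained_forward_dynamics(
    model: MultibodyModel,
    state: State,
    tau: np.ndarray,
    contacts: ContactSet,
    kin: Optional[Kinematics] = None,
    gravity: bool = True,
    rows: Optional[np.ndarray] = None,
) -> DynamicsEval:
    """Solve the contact-constrained equations of motion.

    Returns accelerations ``a`` and contact forces ``lam`` satisfying

        [H  G^T] [ a      ]   [tau - C]
        [G   0 ] [ -lambda] = [gamma  ]

    with redundant constraint rows removed deterministically beforehand.
    """
    tau = np.asarray(tau, float)
    if not np.all(np.isfinite(tau)):
        raise ValidationError("non-finite torques")
    kin = kin or model.kinematics(state.q, state.v)
    H, C = mass_matrix_bias(model, kin)
    if not gravity:
        kin0 = model.kinematics(state.q, np.zeros_like(state.v))
        _, Cg = mass_matrix_bias(model, kin0)
        # remove the pure-gravity part of the bias
        C = C - Cg
    if rows is None:
        rows = contacts.independent_rows(kin)
    G = contacts.jacobian(kin)[rows] if len(rows) else np.zeros((0, model.n_dof))
    gamma = contacts.bias(kin)[rows] if len(rows) else np.zeros(0)
    if len(contacts) and len(rows) == 0:
        raise DegenerateContactError("all contact rows degenerate")
    a, lam = _kkt_solve(H, G, tau - C, gamma)
    return DynamicsEval(H=H, C=C, G=G, gamma=gamma, a=a, lam=lam, rows=rows)


def contact_hessian(
    model: MultibodyModel, q: np.ndarray, v: np.ndarray, contacts: ContactSet
) -> np.ndarray:
    """gamma(q, v) = -Gdot(q) v, one entry per raw constraint row."""
    kin = model.kinematics(q, v)
    return contacts.bias(kin)


@dataclass
class ImpactResult:
    v_plus: np.ndarray
    impulse: np.ndarray  # N s, per retained constraint row
    rows: np.ndarray
    energy_loss: float  # J, kinetic energy dissipated (>= 0)


def impact_map(
    model: MultibodyModel, q: np.ndarray, v_minus: np.ndarray,
    new_contacts: ContactSet, rows: Optional[np.ndarray] = None,
) -> ImpactResult:
    """Perfectly inelastic velocity reset at contact gain.

    Solves ``[H G^T; G 0] (v+; -Lambda) = (H v-; 0)``: the post-impact
    velocity zeroes the constrained point velocities while conserving the
    momentum projection orthogonal to the constraint directions.
    """
    kin = model.kinematics(q, v_minus)
    H, _ = mass_matrix_bias(model, kin)
    if rows is None:
        rows = new_contacts.independent_rows(kin)
    if len(new_contacts) and len(rows) == 0:
        raise DegenerateContactError("all impact rows degenerate")
    G = new_contacts.jacobian(kin)[rows] if len(rows) else np.zeros((0, model.n_dof))
    v_plus, impulse = _kkt_solve(H, G, H @ v_minus, np.zeros(len(rows)))
    de = 0.5 * float(v_minus @ H @ v_minus - v_plus @ H @ v_plus)
    return ImpactResult(v_plus=v_plus, impulse=impulse, rows=rows, energy_loss=de)


# ---------------------------------------------------------------------------
# aggregate quantities
# ---------------------------------------------------------------------------


def com_state(model: MultibodyModel, state: State, kin: Optional[Kinematics] = None):
    """Whole-body COM position and velocity (world frame)."""
    kin = kin or model.kinematics(state.q, state.v)
    M = 0.0
    r = np.zeros(3)
    rd = np.zeros(3)
    for i in model._massive:
        b = model.bodies[i]
        c = kin.point_position(i, b.com)
        cv = kin.point_velocity(i, b.com)
        M += b.mass
        r += b.mass * c
        rd += b.mass * cv
    return r / M, rd / M


def angular_momentum(
    model: MultibodyModel,
    state: State,
    segment_subset: Optional[Sequence[str]] = None,
    about: Optional[np.ndarray] = None,
    kin: Optional[Kinematics] = None,
) -> np.ndarray:
    """Angular momentum of a segment subset about a world point (kg m^2/s).

    ``about`` defaults to the whole-body COM.  An empty subset yields zero.
    """
    kin = kin or model.kinematics(state.q, state.v)
    if about is None:
        about, _ = com_state(model, state, kin)
    if segment_subset is None:
        indices = model._massive
    else:
        indices = [i for i in model.segment_bodies(segment_subset) if model.bodies[i].mass > 0]
    L = np.zeros(3)
    for i in indices:
        b = model.bodies[i]
        c = kin.point_position(i, b.com)
        cv = kin.point_velocity(i, b.com)
        Iw = kin.R[i] @ b.inertia @ kin.R[i].T
        L += Iw @ kin.w[i] + b.mass * _cross(c - np.asarray(about, float), cv)
    return L


def kinetic_energy(model: MultibodyModel, state: State, kin: Optional[Kinematics] = None) -> float:
    kin = kin or model.kinematics(state.q, state.v)
    T = 0.0
    for i in model._massive:
        b = model.bodies[i]
        cv = kin.point_velocity(i, b.com)
        Iw = kin.R[i] @ b.inertia @ kin.R[i].T
        T += 0.5 * b.mass * cv @ cv + 0.5 * kin.w[i] @ Iw @ kin.w[i]
    return float(T)


def potential_energy(model: MultibodyModel, state: State, kin: Optional[Kinematics] = None) -> float:
    kin = kin or model.kinematics(state.q, state.v)
    U = 0.0
    for i in model._massive:
        b = model.bodies[i]
        U += b.mass * GRAVITY * kin.point_position(i, b.com)[2]
    return float(U)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------


def project_to_constraints(
    model: MultibodyModel, state: State, contacts: ContactSet, tol: float = 1e-8, max_iter: int = 10
) -> State:
    """Project (q, v) back onto the active constraint manifold.

    Gauss-Newton on the position error followed by a velocity null-space
    projection; the drift-control tolerance defaults to 1e-8.
    """
    if len(contacts) == 0:
        return state
    q = state.q.copy()
    for _ in range(max_iter):
        kin = model.kinematics(q)
        rows = contacts.independent_rows(kin)
        err = contacts.position_error(kin)[rows]
        if np.linalg.norm(err, ord=np.inf) < tol:
            break
        G = contacts.jacobian(kin)[rows]
        q -= G.T @ np.linalg.solve(G @ G.T, err)
    kin = model.kinematics(q)
    rows = contacts.independent_rows(kin)
    G = contacts.jacobian(kin)[rows]
    v = state.v - G.T @ np.linalg.solve(G @ G.T, G @ state.v)
    return State(q=q, v=v)


def integrate_phase(
    model: MultibodyModel,
    state: State,
    torque_fn: Callable[[float, State], np.ndarray],
    contacts: ContactSet,
    t0: float,
    t1: float,
    dt: float = 1e-3,
    project: bool = True,
    record: bool = False,
):
    """Fixed-step RK4 integration of one contact phase.

    ``torque_fn(t, state)`` returns the full-length generalized force vector.
    Returns the final state; with ``record`` also (times, Q, V, LAM) arrays
    (LAM holds the reduced-row contact forces of the first KKT evaluation per
    step).
    """
    n_steps = max(1, int(round((t1 - t0) / dt)))
    h = (t1 - t0) / n_steps
    times, Q, V, LAM = [], [], [], []

    def deriv(t, q, v):
        st = State(q=q, v=v)
        ev = constrained_forward_dynamics(model, st, torque_fn(t, st), contacts)
        return v, ev.a, ev

    q, v = state.q.copy(), state.v.copy()
    t = t0
    for _ in range(n_steps):
        k1q, k1v, ev = deriv(t, q, v)
        if record:
            times.append(t)
            Q.append(q.copy())
            V.append(v.copy())
            LAM.append(ev.lam.copy())
        k2q, k2v, _ = deriv(t + h / 2, q + h / 2 * k1q, v + h / 2 * k1v)
        k3q, k3v, _ = deriv(t + h / 2, q + h / 2 * k2q, v + h / 2 * k2v)
        k4q, k4v, _ = deriv(t + h, q + h * k3q, v + h * k3v)
        q = q + h / 6 * (k1q + 2 * k2q + 2 * k3q + k4q)
        v = v + h / 6 * (k1v + 2 * k2v + 2 * k3v + k4v)
        t += h
        if project and len(contacts):
            st = project_to_constraints(model, State(q=q, v=v), contacts)
            q, v = st.q, st.v
    final = State(q=q, v=v)
    if record:
        times.append(t)
        Q.append(q.copy())
        V.append(v.copy())
        ev = constrained_forward_dynamics(model, final, torque_fn(t, final), contacts)
        LAM.append(ev.lam.copy())
        return final, (np.array(times), np.array(Q), np.array(V), LAM)
    return final
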