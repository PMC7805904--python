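"""Multi-phase least-squares optimal-control reconstruction of walking.

Reconstructs dynamically consistent state and torque trajectories from an
inverse-kinematics reference motion: over the eight contact phases of a full
stride (with four touch-down transitions), the reconstruction minimizes

    sum_j 1/2 ||q_ref_j - q(t_j)||^2  +  gamma_u ||W u(t_j)||^2

subject to the contact-constrained multibody dynamics per phase, the
inelastic impact map at each touch-down, bounds, and unilateral vertical
contact forces.

The problem is transcribed by direct collocation on a fixed node grid per
phase, with either piecewise-linear controls and Hermite-Simpson defects
(default) or zero-order-hold controls with a matching fixed-step RK4 defect
scheme.  Defects, inter-phase continuity/impact conditions and
unilaterality enter a nonlinear least-squares residual with fixed weights
(an exactly consistent reference zeroes them), solved by a trust-region
reflective method with sparse finite-difference Jacobians.
``check_solution`` independently re-integrates each collocation interval
with the solved controls and reports the local defects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.optimize
import scipy.sparse

from .errors import ScheduleError, SolverError, ValidationError
from .markerik import ReferenceMotion
from .metrics import GaitEvents
from .multibody import (
    ContactPoint, ContactSet, MultibodyModel, State,
    constrained_forward_dynamics, impact_map, integrate_phase,
)

__all__ = [
    "Phase", "PhaseSchedule", "build_phase_schedule",
    "OCPConfig", "ReconstructionResult", "solve_reconstruction", "check_solution",
]

_PLANAR_DIRS = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


# ---------------------------------------------------------------------------
# phase schedule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Phase:
    start: float
    end: float
    contacts: frozenset  # of (side, point) with point in heel / hallux

    @property
    def duration(self):
        return self.end - self.start


@dataclass
class PhaseSchedule:
    """Eight contact phases of one stride plus the touch-down transitions."""

    phases: list
    transitions: list  # (time, gained contacts frozenset)

    @property
    def n_phases(self):
        return len(self.phases)

    @property
    def stride_time(self):
        return self.phases[-1].end - self.phases[0].start


def _single(events: GaitEvents, kind: str, side: str, lo: float, hi: float) -> float:
    times = [t for t in getattr(events, kind)[side] if lo - 1e-9 <= t <= hi + 1e-9]
    if len(times) != 1:
        raise ScheduleError(
            f"expected exactly one {side} {kind[:-1]} in [{lo:.3f}, {hi:.3f}], "
            f"got {len(times)}"
        )
    return times[0]


def build_phase_schedule(events: GaitEvents, t0: float = 0.0,
                         t_end: Optional[float] = None) -> PhaseSchedule:
    """Phase schedule of a full stride beginning at left toe off.

    The canonical grammar is: right flat stance, right heel off, left heel
    strike, left toe strike, right toe off, left heel off, right heel
    strike, right toe strike, stride end at the next left toe off.  Any
    deviation raises :class:`ScheduleError` naming the offending event.
    """
    if t_end is None:
        candidates = [t for t in events.toe_offs["left"] if t > t0 + 1e-9]
        if not candidates:
            raise ScheduleError("no terminating left toe off found")
        t_end = min(candidates)
    rho = _single(events, "heel_offs", "right", t0, t_end)
    lhs = _single(events, "heel_strikes", "left", t0, t_end)
    lts = _single(events, "toe_strikes", "left", t0, t_end)
    rto = _single(events, "toe_offs", "right", t0, t_end)
    lho = _single(events, "heel_offs", "left", t0, t_end)
    rhs = _single(events, "heel_strikes", "right", t0, t_end)
    rts = _single(events, "toe_strikes", "right", t0, t_end)
    knots = [t0, rho, lhs, lts, rto, lho, rhs, rts, t_end]
    names = ["stride start", "right heel off", "left heel strike",
             "left toe strike", "right toe off", "left heel off",
             "right heel strike", "right toe strike", "left toe off"]
    for k in range(len(knots) - 1):
        if not knots[k] < knots[k + 1]:
            raise ScheduleError(
                f"event {names[k + 1]!r} at {knots[k + 1]:.3f}s does not follow "
                f"{names[k]!r} at {knots[k]:.3f}s"
            )
    R, L = "right", "left"
    configs = [
        frozenset({(R, "heel"), (R, "hallux")}),
        frozenset({(R, "hallux")}),
        frozenset({(R, "hallux"), (L, "heel")}),
        frozenset({(R, "hallux"), (L, "heel"), (L, "hallux")}),
        frozenset({(L, "heel"), (L, "hallux")}),
        frozenset({(L, "hallux")}),
        frozenset({(L, "hallux"), (R, "heel")}),
        frozenset({(L, "hallux"), (R, "heel"), (R, "hallux")}),
    ]
    phases = [Phase(knots[i], knots[i + 1], configs[i]) for i in range(8)]
    transitions = [
        (lhs, frozenset({(L, "heel")})),
        (lts, frozenset({(L, "hallux")})),
        (rhs, frozenset({(R, "heel")})),
        (rts, frozenset({(R, "hallux")})),
    ]
    return PhaseSchedule(phases=phases, transitions=transitions)


# ---------------------------------------------------------------------------
# OCP configuration / result
# ---------------------------------------------------------------------------


@dataclass
class OCPConfig:
    """Transcription and solver settings.

    ``control_weights`` is the diagonal of W (all > 0); the default scales
    each actuated channel by a nominal 100 N m torque.  ``gamma_u`` is the
    regularization factor of the control term.  ``node_spacing`` sets the
    target collocation interval (s); each phase gets at least two intervals.
    Defect, transition and unilaterality residuals carry fixed weights.
    """

    gamma_u: float = 1e-3
    control_weights: Optional[np.ndarray] = None
    track_weights: Optional[np.ndarray] = None
    #: weight of a weak velocity-consistency regularizer: node velocities
    #: are softly matched to finite-differenced reference velocities.  This
    #: pins the controls of short pre-impact intervals, which are nearly
    #: invisible in positions (their effect is first order in velocity but
    #: second order in position, and the impact map annihilates part of it)
    velocity_weight: float = 0.0
    #: control parameterization per phase: "linear" (piecewise linear,
    #: values at nodes) or "hold" (zero-order hold, one value per interval)
    control: str = "linear"
    node_spacing: float = 0.025
    node_spacing_short: Optional[float] = 0.01  # for phases < short_phase below
    short_phase: float = 0.1
    #: defect integrator per interval: "hs" (Hermite-Simpson) or "rk4"
    #: (fixed-step RK4 substeps of length <= rk4_step; only with "hold")
    defect_scheme: str = "hs"
    rk4_step: float = 0.01
    defect_weight: float = 1e3
    unilateral_weight: float = 1.0
    #: weight of a small contact-force regularizer (same scale as W); it
    #: resolves the torque/contact-force indeterminacy of over-constrained
    #: double support towards the minimum-norm solution
    gamma_lambda: Optional[float] = None  # defaults to gamma_u
    planar_contacts: bool = True
    q_bounds: Optional[tuple] = None  # (lower, upper) arrays, length n_dof
    u_bound: float = 1e4
    max_nfev: int = 200
    #: trust-region restarts: re-entering the solver resets the trust
    #: radius, which breaks the slow crawl the reflective method can fall
    #: into inside long curved valleys
    restarts: int = 2
    x_scale_jac: bool = False  # use Jacobian-based column scaling
    diff_step: Optional[float] = None  # finite-difference relative step
    jac: str = "2-point"  # finite-difference scheme ("3-point" = central)
    ftol: float = 1e-12
    xtol: float = 1e-10

    def W(self, n_act: int) -> np.ndarray:
        if self.control_weights is not None:
            w = np.asarray(self.control_weights, float)
            if np.any(w <= 0):
                raise ValidationError("control weights must be positive")
            return w
        return np.full(n_act, 1.0 / 100.0)


def phase_node_times(schedule: PhaseSchedule, config: "OCPConfig") -> list:
    """Collocation node grid per phase for a given configuration."""
    out = []
    for ph in schedule.phases:
        spacing = config.node_spacing
        if (config.node_spacing_short is not None
                and ph.duration < config.short_phase):
            spacing = config.node_spacing_short
        Ni = max(2, int(round(ph.duration / spacing)))
        out.append(np.linspace(ph.start, ph.end, Ni + 1))
    return out


@dataclass
class ReconstructionResult:
    schedule: PhaseSchedule
    node_times: list  # per phase, (Ni+1,)
    X: list  # per phase, (Ni+1, 2 n_dof)
    U: list  # per phase, (Ni+1, n_act)
    lam_z_min: float
    objective: float
    tracking_term: float
    regularization_term: float
    solver_status: int
    solver_message: str
    config: OCPConfig = field(repr=False, default=None)
    z: np.ndarray = field(repr=False, default=None)  # raw decision vector

    def q_at(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation of q over the phase grids."""
        t = np.atleast_1d(t)
        n = self.X[0].shape[1] // 2
        out = np.empty((len(t), n))
        for j, tj in enumerate(t):
            for ph, (tt, X) in enumerate(zip(self.node_times, self.X)):
                if tj <= tt[-1] + 1e-12 or ph == len(self.X) - 1:
                    for k in range(n):
                        out[j, k] = np.interp(tj, tt, X[:, k])
                    break
        return out


def _phase_contacts(model: MultibodyModel, contacts: frozenset,
                    planar: bool) -> ContactSet:
    dirs = _PLANAR_DIRS if planar else np.eye(3)
    points = []
    for side, point in sorted(contacts):
        body, off = model.contact_point(side, point)
        points.append(ContactPoint(f"{side}:{point}", body, off, dirs, np.zeros(3)))
    return ContactSet(points)


# ---------------------------------------------------------------------------
# transcription
# ---------------------------------------------------------------------------


class _Transcription:
    def __init__(self, model, reference, schedule, config, node_times=None):
        self.model, self.ref, self.sched, self.cfg = model, reference, schedule, config
        n, na = model.n_dof, model.n_act
        self.n, self.na, self.nx = n, na, 2 * n
        if config.control not in ("linear", "hold"):
            raise ValidationError(f"unknown control parameterization {config.control!r}")
        self.hold = config.control == "hold"
        self.contacts = [_phase_contacts(model, ph.contacts, config.planar_contacts)
                         for ph in schedule.phases]
        # retained constraint rows are frozen per phase (selected once at the
        # phase's mid-reference pose) so the dynamics stay smooth in the
        # decision variables even when a flat foot is marginally pitched
        self.rows = []
        for ph, cs in zip(schedule.phases, self.contacts):
            qm = reference.interpolate(0.5 * (ph.start + ph.end))[0]
            self.rows.append(cs.independent_rows(model.kinematics(qm)))
        self.node_times = (phase_node_times(schedule, config)
                           if node_times is None else
                           [np.asarray(tt, float) for tt in node_times])
        self.Wu = config.W(na)
        self.wt = (np.ones(n) if config.track_weights is None
                   else np.asarray(config.track_weights, float))
        # layout: per phase, states then controls; "hold" mode has one
        # control value per interval instead of per node
        self.m_u = [len(tt) - 1 if self.hold else len(tt)
                    for tt in self.node_times]
        self.offsets = []
        off = 0
        for tt, mu in zip(self.node_times, self.m_u):
            m = len(tt)
            self.offsets.append((off, off + m * self.nx))
            off += m * self.nx + mu * na
        self.n_z = off
        self.qref_nodes = [self.ref.interpolate(tt) for tt in self.node_times]
        # velocity / acceleration estimates per phase at the reference's
        # native rate (used only for the warm start); differentiating is
        # restricted to each phase so the impact discontinuities at the
        # transitions do not contaminate the estimates
        self.vref_nodes, self.aref_nodes = [], []
        rt, rq = self.ref.times, self.ref.postures
        for ph, tt in zip(schedule.phases, self.node_times):
            sel = (rt >= ph.start - 1e-9) & (rt < ph.end - 1e-9)
            if sel.sum() < 3:
                lo = max(0, np.searchsorted(rt, ph.start) - 1)
                sel = np.zeros(len(rt), bool)
                sel[lo:lo + 3] = True
            ts, qs = rt[sel], rq[sel]
            if len(ts) >= 7 and np.allclose(np.diff(ts), ts[1] - ts[0]):
                from scipy.signal import savgol_filter

                dt = ts[1] - ts[0]
                vr = savgol_filter(qs, 7, 4, deriv=1, delta=dt, axis=0)
                ar = savgol_filter(qs, 7, 4, deriv=2, delta=dt, axis=0)
            else:
                vr = np.gradient(qs, ts, axis=0)
                ar = np.gradient(vr, ts, axis=0)
            vv = np.empty((len(tt), n))
            aa = np.empty((len(tt), n))
            for k in range(n):
                vv[:, k] = np.interp(tt, ts, vr[:, k])
                aa[:, k] = np.interp(tt, ts, ar[:, k])
            self.vref_nodes.append(vv)
            self.aref_nodes.append(aa)

    # -- packing -----------------------------------------------------------
    def unpack(self, z):
        X, U = [], []
        for (o_x, o_u), tt, mu in zip(self.offsets, self.node_times, self.m_u):
            m = len(tt)
            X.append(z[o_x:o_x + m * self.nx].reshape(m, self.nx))
            U.append(z[o_u:o_u + mu * self.na].reshape(mu, self.na))
        return X, U

    def pack(self, X, U):
        z = np.empty(self.n_z)
        for (o_x, o_u), Xi, Ui in zip(self.offsets, X, U):
            z[o_x:o_x + Xi.size] = Xi.ravel()
            z[o_u:o_u + Ui.size] = Ui.ravel()
        return z

    # -- dynamics ----------------------------------------------------------
    def f(self, phase, x, u):
        n = self.n
        st = State(x[:n], x[n:])
        tau = np.zeros(n)
        tau[self.model.base_dof:] = u
        ev = constrained_forward_dynamics(self.model, st, tau,
                                          self.contacts[phase],
                                          rows=self.rows[phase])
        vert = 1 if self.cfg.planar_contacts else 2
        info = self.contacts[phase].row_info()
        lamz = [ev.lam[k] for k, ridx in enumerate(ev.rows)
                if info[ridx][1] == vert]
        return (np.concatenate([x[n:], ev.a]), ev.lam,
                (min(lamz) if lamz else np.inf))

    # -- residuals ---------------------------------------------------------
    def residuals(self, z):
        cfg = self.cfg
        X, U = self.unpack(z)
        res = []
        lam_mins = []
        sqg = np.sqrt(cfg.gamma_u)
        gl = cfg.gamma_lambda if cfg.gamma_lambda is not None else cfg.gamma_u
        sql = np.sqrt(gl) / 100.0
        for i, tt in enumerate(self.node_times):
            m = len(tt)
            wv = cfg.velocity_weight
            if not self.hold:
                fs = np.empty((m, self.nx))
                for k in range(m):
                    fs[k], lam, lmin = self.f(i, X[i][k], U[i][k])
                    lam_mins.append(lmin)
                    res.append(self.wt * (X[i][k][:self.n] - self.qref_nodes[i][k]))
                    if wv > 0:
                        res.append(wv * (X[i][k][self.n:] - self.vref_nodes[i][k]))
                    res.append(sqg * (self.Wu * U[i][k]))
                    if len(self.rows[i]):
                        res.append(sql * lam)
                    if cfg.unilateral_weight > 0 and len(self.contacts[i]):
                        val = min(0.0, lmin) if np.isfinite(lmin) else 0.0
                        res.append(np.array([cfg.unilateral_weight * val]))
                for k in range(m - 1):
                    h = tt[k + 1] - tt[k]
                    xm = 0.5 * (X[i][k] + X[i][k + 1]) + h / 8.0 * (fs[k] - fs[k + 1])
                    um = 0.5 * (U[i][k] + U[i][k + 1])
                    fm, _, _ = self.f(i, xm, um)
                    defect = (X[i][k + 1] - X[i][k]
                              - h / 6.0 * (fs[k] + 4.0 * fm + fs[k + 1]))
                    res.append(cfg.defect_weight * defect)
            else:
                rk4 = cfg.defect_scheme == "rk4"
                for k in range(m - 1):
                    uk = U[i][k]
                    f0, lam, lmin = self.f(i, X[i][k], uk)
                    lam_mins.append(lmin)
                    res.append(self.wt * (X[i][k][:self.n] - self.qref_nodes[i][k]))
                    if wv > 0:
                        res.append(wv * (X[i][k][self.n:] - self.vref_nodes[i][k]))
                    res.append(sqg * (self.Wu * uk))
                    if len(self.rows[i]):
                        res.append(sql * lam)
                    if cfg.unilateral_weight > 0 and len(self.contacts[i]):
                        val = min(0.0, lmin) if np.isfinite(lmin) else 0.0
                        res.append(np.array([cfg.unilateral_weight * val]))
                    h = tt[k + 1] - tt[k]
                    if rk4:
                        nsub = max(1, int(round(h / cfg.rk4_step)))
                        hs = h / nsub
                        x = X[i][k]
                        k1 = f0
                        for s in range(nsub):
                            if s > 0:
                                k1, _, _ = self.f(i, x, uk)
                            k2, _, _ = self.f(i, x + hs / 2 * k1, uk)
                            k3, _, _ = self.f(i, x + hs / 2 * k2, uk)
                            k4, _, _ = self.f(i, x + hs * k3, uk)
                            x = x + hs / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                        defect = X[i][k + 1] - x
                    else:
                        f1, _, _ = self.f(i, X[i][k + 1], uk)
                        xm = 0.5 * (X[i][k] + X[i][k + 1]) + h / 8.0 * (f0 - f1)
                        fm, _, _ = self.f(i, xm, uk)
                        defect = (X[i][k + 1] - X[i][k]
                                  - h / 6.0 * (f0 + 4.0 * fm + f1))
                    res.append(cfg.defect_weight * defect)
                res.append(self.wt * (X[i][-1][:self.n] - self.qref_nodes[i][-1]))
                if wv > 0:
                    res.append(wv * (X[i][-1][self.n:] - self.vref_nodes[i][-1]))
        # inter-phase links
        for i in range(len(self.node_times) - 1):
            x_end = X[i][-1]
            x_start = X[i + 1][0]
            gained = self.sched.phases[i + 1].contacts - self.sched.phases[i].contacts
            if gained:
                imp = impact_map(self.model, x_end[:self.n], x_end[self.n:],
                                 self.contacts[i + 1], rows=self.rows[i + 1])
                x_plus = np.concatenate([x_end[:self.n], imp.v_plus])
            else:
                x_plus = x_end
            res.append(cfg.defect_weight * (x_start - x_plus))
        self._last_lam_min = min(lam_mins) if lam_mins else np.inf
        return np.concatenate(res)

    # -- sparsity ----------------------------------------------------------
    def sparsity(self):
        rows, cols = [], []
        r = 0

        def link(nrows, col_blocks):
            nonlocal r
            base = r
            for k in range(nrows):
                for lo, hi in col_blocks:
                    for c in range(lo, hi):
                        rows.append(base + k)
                        cols.append(c)
            r = base + nrows

        for i, tt in enumerate(self.node_times):
            m = len(tt)
            o_x, o_u = self.offsets[i]

            def xb(k):
                return (o_x + k * self.nx, o_x + (k + 1) * self.nx)

            def ub(k):
                return (o_u + k * self.na, o_u + (k + 1) * self.na)

            wv = self.cfg.velocity_weight
            if not self.hold:
                for k in range(m):
                    link(self.n, [xb(k)])  # tracking
                    if wv > 0:
                        link(self.n, [xb(k)])  # velocity consistency
                    link(self.na, [ub(k)])  # regularization
                    if len(self.rows[i]):
                        link(len(self.rows[i]), [xb(k), ub(k)])
                    if self.cfg.unilateral_weight > 0 and len(self.contacts[i]):
                        link(1, [xb(k), ub(k)])
                for k in range(m - 1):
                    link(self.nx, [xb(k), xb(k + 1), ub(k), ub(k + 1)])
            else:
                for k in range(m - 1):
                    link(self.n, [xb(k)])
                    if wv > 0:
                        link(self.n, [xb(k)])
                    link(self.na, [ub(k)])
                    if len(self.rows[i]):
                        link(len(self.rows[i]), [xb(k), ub(k)])
                    if self.cfg.unilateral_weight > 0 and len(self.contacts[i]):
                        link(1, [xb(k), ub(k)])
                    link(self.nx, [xb(k), xb(k + 1), ub(k)])
                link(self.n, [xb(m - 1)])
                if wv > 0:
                    link(self.n, [xb(m - 1)])
        for i in range(len(self.node_times) - 1):
            o_x0, _ = self.offsets[i]
            m0 = len(self.node_times[i])
            o_x1, _ = self.offsets[i + 1]
            xb_end = (o_x0 + (m0 - 1) * self.nx, o_x0 + m0 * self.nx)
            xb_start = (o_x1, o_x1 + self.nx)
            link(self.nx, [xb_end, xb_start])
        n_rows = r
        mat = scipy.sparse.coo_matrix(
            (np.ones(len(rows), dtype=np.uint8), (rows, cols)),
            shape=(n_rows, self.n_z),
        )
        return mat.tocsr()

    # -- initial guess -----------------------------------------------------
    def initial_guess(self):
        from .multibody import mass_matrix_bias

        X, U = [], []
        n, na = self.n, self.na
        for i, tt in enumerate(self.node_times):
            qr, vr = self.qref_nodes[i], self.vref_nodes[i]
            Xi = np.hstack([qr, vr])
            ar = self.aref_nodes[i]
            Un = np.empty((len(tt), na))
            for k in range(len(tt)):
                st = State(qr[k], vr[k])
                kin = self.model.kinematics(st.q, st.v)
                H, C = mass_matrix_bias(self.model, kin)
                rowsG = self.rows[i]
                G = (self.contacts[i].jacobian(kin)[rowsG] if len(rowsG)
                     else np.zeros((0, n)))
                S = np.zeros((n, na))
                S[self.model.base_dof:, :] = np.eye(na)
                A = np.hstack([S, G.T]) if G.size else S
                b = H @ ar[k] + C
                sol = np.linalg.lstsq(A, b, rcond=None)[0]
                Un[k] = sol[:na]
            X.append(Xi)
            U.append(0.5 * (Un[:-1] + Un[1:]) if self.hold else Un)
        return self.pack(X, U)


def _polish_controls(tr, z0, sp, config, max_nfev=25):
    """Pre-optimize the controls with the states frozen at the warm start.

    The inverse-dynamics control guess is weakest near phase boundaries;
    this cheap reduced solve (controls only, ~an order of magnitude fewer
    variables) removes those defects before the full solve.
    """
    u_cols = []
    for (o_x, o_u), mu in zip(tr.offsets, tr.m_u):
        u_cols.extend(range(o_u, o_u + mu * tr.na))
    u_cols = np.asarray(u_cols)
    base = z0.copy()

    def fun(zu):
        z = base.copy()
        z[u_cols] = zu
        return tr.residuals(z)

    sub_sp = sp[:, u_cols]
    sol = scipy.optimize.least_squares(
        fun, z0[u_cols], jac_sparsity=sub_sp, method="trf", x_scale=100.0,
        ftol=1e-10, xtol=1e-10, gtol=1e-12, max_nfev=max_nfev,
    )
    out = z0.copy()
    out[u_cols] = sol.x
    return out


def solve_reconstruction(
    model: MultibodyModel,
    reference: ReferenceMotion,
    schedule: PhaseSchedule,
    config: Optional[OCPConfig] = None,
    initial_guess: Optional[np.ndarray] = None,
    node_times: Optional[list] = None,
    verbose: int = 0,
) -> ReconstructionResult:
    """Solve the multi-phase least-squares reconstruction problem.

    ``node_times`` optionally overrides the per-phase collocation grids
    (e.g. to match the node clock of a sampled-control fixture).
    """
    config = config or OCPConfig()
    tr = _Transcription(model, reference, schedule, config, node_times=node_times)
    z0 = tr.initial_guess() if initial_guess is None else initial_guess
    sp = tr.sparsity()
    if initial_guess is None:
        z0 = _polish_controls(tr, z0, sp, config)
    # variable scales: positions ~1 rad/m, velocities ~5, controls ~100 N m
    x_scale = np.empty(tr.n_z)
    for (o_x, o_u), tt, mu in zip(tr.offsets, tr.node_times, tr.m_u):
        m = len(tt)
        blk = np.concatenate([np.ones(tr.n), 5.0 * np.ones(tr.n)])
        x_scale[o_x:o_x + m * tr.nx] = np.tile(blk, m)
        x_scale[o_u:o_u + mu * tr.na] = 100.0
    n_rounds = max(1, 1 + config.restarts)
    budget = max(10, config.max_nfev // n_rounds)
    try:
        zk = z0
        sol = None
        for _ in range(n_rounds):
            prev_cost = None if sol is None else sol.cost
            sol = scipy.optimize.least_squares(
                tr.residuals, zk, jac_sparsity=sp, method="trf",
                jac=config.jac,
                x_scale=("jac" if config.x_scale_jac else x_scale),
                diff_step=config.diff_step,
                ftol=config.ftol, xtol=config.xtol,
                gtol=1e-12, max_nfev=budget, verbose=verbose,
            )
            zk = sol.x
            if prev_cost is not None and sol.cost > 0.999 * prev_cost:
                break
    except Exception as exc:  # numerical failure inside the solver
        raise SolverError(f"reconstruction solve failed: {exc}") from exc
    X, U = tr.unpack(sol.x)
    tracking = 0.0
    reg = 0.0
    for i in range(len(X)):
        dq = X[i][:, :tr.n] - tr.qref_nodes[i]
        tracking += 0.5 * float(np.sum((tr.wt * dq) ** 2))
        reg += config.gamma_u * float(np.sum((tr.Wu * U[i]) ** 2))
    tr.residuals(sol.x)
    return ReconstructionResult(
        schedule=schedule, node_times=tr.node_times, X=X, U=U,
        lam_z_min=float(tr._last_lam_min), objective=tracking + reg,
        tracking_term=tracking, regularization_term=reg,
        solver_status=sol.status, solver_message=sol.message, config=config,
        z=sol.x,
    )


# ---------------------------------------------------------------------------
# independent verification
# ---------------------------------------------------------------------------


def check_solution(result: ReconstructionResult, model: MultibodyModel,
                   schedule: PhaseSchedule, dt: float = 1e-3) -> dict:
    """Independently re-integrate the solved controls and report defects.

    Each collocation interval is re-integrated with plain RK4 from its
    start node (no projection) and compared against the next node state —
    the local consistency collocation promises; whole-phase open-loop
    re-integration is not meaningful for an inherently unstable walking
    system, whose state error grows exponentially regardless of solution
    quality.  Also reports the transition-map residuals at touch-downs and
    the most negative vertical contact force seen at the nodes.
    """
    cfg = result.config or OCPConfig()
    report = {"phase_defects": [], "transition_residuals": [],
              "lam_z_min": result.lam_z_min}
    n = model.n_dof
    for i, (tt, X, U) in enumerate(zip(result.node_times, result.X, result.U)):
        contacts = _phase_contacts(model, schedule.phases[i].contacts,
                                   cfg.planar_contacts)

        hold = cfg.control == "hold"

        def torque_for(k):
            if hold:
                tau = np.zeros(n)
                tau[model.base_dof:] = U[k]
                return lambda t, state: tau

            def fn(t, state):
                tau = np.zeros(n)
                for j in range(model.n_act):
                    tau[model.base_dof + j] = np.interp(t, tt, U[:, j])
                return tau

            return fn

        worst = 0.0
        for k in range(len(tt) - 1):
            st = State(X[k][:n], X[k][n:])
            fin = integrate_phase(model, st, torque_for(k), contacts,
                                  tt[k], tt[k + 1], dt=dt, project=False)
            defect = np.concatenate([fin.q - X[k + 1][:n], fin.v - X[k + 1][n:]])
            worst = max(worst, float(np.abs(defect).max()))
        report["phase_defects"].append(worst)
        if i + 1 < len(result.X):
            gained = schedule.phases[i + 1].contacts - schedule.phases[i].contacts
            x_end, x_next = X[-1], result.X[i + 1][0]
            if gained:
                nxt = _phase_contacts(model, schedule.phases[i + 1].contacts,
                                      cfg.planar_contacts)
                imp = impact_map(model, x_end[:n], x_end[n:], nxt)
                resid = np.abs(x_next[n:] - imp.v_plus).max()
            else:
                resid = np.abs(x_next[n:] - x_end[n:]).max()
            resid = max(resid, float(np.abs(x_next[:n] - x_end[:n]).max()))
            report["transition_residuals"].append(float(resid))
    report["max_defect"] = max(report["phase_defects"])
    report["max_transition_residual"] = (max(report["transition_residuals"])
                                         if report["transition_residuals"] else 0.0)
    return report
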