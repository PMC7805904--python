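"""Dynamics-engine checks against independent oracles.

The oracles are deliberately different code paths: dense null-space solves,
finite differences, closed-form rigid-body mechanics and conservation laws.
"""

import numpy as np
import pytest

from gaitbench.bodymodels import build_planar_walker
from gaitbench.errors import DegenerateContactError
from gaitbench.multibody import (
    BodyNode, ContactPoint, ContactSet, MultibodyModel, State,
    angular_momentum, com_state, constrained_forward_dynamics, contact_hessian,
    impact_map, integrate_phase, kinetic_energy, mass_matrix_bias,
    potential_energy,
)


def _random_state(model, rng, spread=0.3):
    q = rng.normal(0.0, spread, model.n_dof)
    q[:3] = rng.normal(0.0, 0.1, 3)
    v = rng.normal(0.0, 1.0, model.n_dof)
    return State(q, v)


def _planar_point(model, side, point, anchor=np.zeros(3)):
    body, off = model.contact_point(side, point)
    dirs = np.array([[1.0, 0, 0], [0, 0, 1.0]])
    return ContactPoint(f"{side}:{point}", body, off, dirs, anchor)


def test_mass_matrix_spd_on_random_poses(reduced_model, rng):
    for _ in range(3):
        st = _random_state(reduced_model, rng)
        kin = reduced_model.kinematics(st.q, st.v)
        H, _ = mass_matrix_bias(reduced_model, kin)
        assert np.allclose(H, H.T, atol=1e-10)
        assert np.linalg.eigvalsh(H).min() > 0


def test_kkt_matches_dense_nullspace_solution(reduced_model, rng):
    """Accelerations agree with an independent null-space projection solve."""
    model = reduced_model
    st = _random_state(model, rng)
    tau = rng.normal(0, 20, model.n_dof)
    tau[:6] = 0.0
    kin = model.kinematics(st.q, st.v)
    # constrain both heels fully (6 independent rows)
    cps = []
    for side in ("left", "right"):
        body, off = model.contact_point(side, "heel")
        cps.append(ContactPoint(f"{side}:heel", body, off, np.eye(3),
                                kin.point_position(body, off)))
    contacts = ContactSet(cps)
    ev = constrained_forward_dynamics(model, st, tau, contacts)
    # oracle: eliminate lambda with a null-space basis of G
    H, C = mass_matrix_bias(model, kin)
    G = contacts.jacobian(kin)
    gamma = contacts.bias(kin)
    from scipy.linalg import null_space

    Z = null_space(G)
    a_part = np.linalg.lstsq(G, gamma, rcond=None)[0]
    y = np.linalg.solve(Z.T @ H @ Z, Z.T @ (tau - C - H @ a_part))
    a_oracle = a_part + Z @ y
    assert np.abs(ev.a - a_oracle).max() < 1e-8
    assert np.abs(ev.G @ ev.a - ev.gamma).max() < 1e-8


def test_contact_hessian_matches_finite_differences(walker_model, rng):
    """gamma = -Gdot v against a central difference of G(q(t)) v."""
    model = walker_model
    q = rng.normal(0, 0.2, model.n_dof)
    q[1] += 1.0
    v = rng.normal(0, 0.5, model.n_dof)
    cs = ContactSet([_planar_point(model, "left", "heel"),
                     _planar_point(model, "right", "hallux")])
    gamma = contact_hessian(model, q, v, cs)
    eps = 1e-6
    Gp = cs.jacobian(model.kinematics(q + eps * v))
    Gm = cs.jacobian(model.kinematics(q - eps * v))
    gamma_fd = -((Gp - Gm) / (2 * eps)) @ v
    assert np.abs(gamma - gamma_fd).max() < 1e-5 * max(1.0, np.abs(gamma_fd).max())


def test_contact_hessian_quadratic_in_velocity(walker_model, rng):
    model = walker_model
    q = rng.normal(0, 0.2, model.n_dof)
    v = rng.normal(0, 0.5, model.n_dof)
    cs = ContactSet([_planar_point(model, "left", "heel")])
    assert np.allclose(contact_hessian(model, q, np.zeros_like(v), cs), 0.0)
    g1 = contact_hessian(model, q, v, cs)
    g2 = contact_hessian(model, q, 2.0 * v, cs)
    assert np.allclose(g2, 4.0 * g1, rtol=1e-10)


def _planar_rod():
    b1 = BodyNode("px", -1, "prismatic", [1, 0, 0], [0, 0, 0])
    b2 = BodyNode("pz", 0, "prismatic", [0, 0, 1], [0, 0, 0])
    b3 = BodyNode("rod", 1, "revolute", [0, 1, 0], [0, 0, 0], mass=2.0,
                  com=[0, 0, 0], inertia=np.diag([2 / 12, 2 / 12, 0.0]))
    return MultibodyModel([b1, b2, b3], base_dof=3, segments=["rod"])


def test_impact_matches_closed_form_falling_rod():
    """Inelastic endpoint impact of a planar rod: angular momentum about the
    contact point is conserved, omega+ = L / (I_com + m r^2)."""
    rod = _planar_rod()
    q = np.array([0.0, 1.0, 0.4])
    v = np.array([0.1, -3.0, 0.2])
    end = np.array([0, 0, -0.5])
    cp = ContactPoint("end", 2, end, np.array([[1.0, 0, 0], [0, 0, 1.0]]),
                      np.zeros(3))
    res = impact_map(rod, q, v, ContactSet([cp]))
    kin = rod.kinematics(q, v)
    pc = kin.point_position(2, end)
    L = angular_momentum(rod, State(q, v), about=pc)[1]
    m, I = 2.0, 2.0 / 12.0
    r = np.linalg.norm(kin.point_position(2, np.zeros(3)) - pc)
    omega_plus = L / (I + m * r ** 2)
    assert res.v_plus[2] == pytest.approx(omega_plus, abs=1e-8)
    # constrained point velocity zeroed, energy dissipated
    kin_p = rod.kinematics(q, res.v_plus)
    assert np.abs(kin_p.point_velocity(2, end)[[0, 2]]).max() < 1e-10
    assert res.energy_loss >= -1e-12


def test_impact_noop_when_already_consistent(walker_model, rng):
    model = walker_model
    q = rng.normal(0, 0.1, model.n_dof)
    q[1] += 1.0
    cs = ContactSet([_planar_point(model, "left", "heel")])
    kin = model.kinematics(q)
    rows = cs.independent_rows(kin)
    G = cs.jacobian(kin)[rows]
    v = rng.normal(0, 1, model.n_dof)
    v -= G.T @ np.linalg.solve(G @ G.T, G @ v)  # project onto G v = 0
    res = impact_map(model, q, v, cs)
    assert np.abs(res.v_plus - v).max() < 1e-10
    assert np.abs(res.impulse).max() < 1e-8


def test_impact_idempotent_and_dissipative(walker_model, rng):
    model = walker_model
    st = _random_state(model, rng)
    cs = ContactSet([_planar_point(model, "left", "heel"),
                     _planar_point(model, "left", "hallux")])
    r1 = impact_map(model, st.q, st.v, cs)
    r2 = impact_map(model, st.q, r1.v_plus, cs)
    assert np.abs(r2.v_plus - r1.v_plus).max() < 1e-10
    assert kinetic_energy(model, State(st.q, r1.v_plus)) <= \
        kinetic_energy(model, st) + 1e-12


def test_flight_conserves_energy_and_angular_momentum(reduced_model, rng):
    """Ballistic 0.2 s: total energy and AM about the COM conserved."""
    model = reduced_model
    st = _random_state(model, rng, spread=0.2)
    E0 = kinetic_energy(model, st) + potential_energy(model, st)
    L0 = angular_momentum(model, st)
    fin = integrate_phase(model, st, lambda t, s: np.zeros(model.n_dof),
                          ContactSet(), 0.0, 0.2, dt=5e-4)
    E1 = kinetic_energy(model, fin) + potential_energy(model, fin)
    L1 = angular_momentum(model, fin)
    assert abs(E1 - E0) / abs(E0) < 1e-6
    assert np.abs(L1 - L0).max() / max(np.linalg.norm(L0), 1.0) < 1e-6


def test_com_matches_per_segment_summation(reduced_model, rng):
    model = reduced_model
    st = _random_state(model, rng)
    r, rd = com_state(model, st)
    kin = model.kinematics(st.q, st.v)
    num = np.zeros(3)
    numd = np.zeros(3)
    M = 0.0
    for name in model.segments:
        i = model.body_index[name]
        b = model.bodies[i]
        num += b.mass * kin.point_position(i, b.com)
        numd += b.mass * kin.point_velocity(i, b.com)
        M += b.mass
    assert np.abs(r - num / M).max() < 1e-10
    assert np.abs(rd - numd / M).max() < 1e-10


def test_angular_momentum_closed_form_spinning_body():
    """A single rigid body spinning about its COM carries exactly I omega."""
    I = np.diag([0.2, 0.3, 0.4])
    chain = []
    prev = -1
    for k, ax in enumerate((np.eye(3))):
        node = BodyNode(f"w{k}", prev, "revolute", ax, np.zeros(3))
        chain.append(node)
        prev = k
    chain[-1].mass, chain[-1].com, chain[-1].inertia = 1.5, np.zeros(3), I
    model = MultibodyModel(chain, base_dof=3, segments=["w2"])
    q = np.array([0.3, -0.2, 0.5])
    v = np.array([1.0, -2.0, 0.7])
    kin = model.kinematics(q, v)
    L = angular_momentum(model, State(q, v), about=np.zeros(3))
    Iw = kin.R[2] @ I @ kin.R[2].T
    assert np.abs(L - Iw @ kin.w[2]).max() < 1e-12


def test_angular_momentum_additive_over_partition(reduced_model, rng):
    model = reduced_model
    st = _random_state(model, rng)
    upper = [s for s in model.segments
             if s in ("trunk", "head") or "arm" in s or "forearm" in s]
    lower = [s for s in model.segments if s not in upper]
    com, _ = com_state(model, st)
    Lu = angular_momentum(model, st, upper, about=com)
    Ll = angular_momentum(model, st, lower, about=com)
    Lf = angular_momentum(model, st, None, about=com)
    assert np.abs(Lu + Ll - Lf).max() < 1e-9 * max(1.0, np.abs(Lf).max())


def test_static_double_support_force_balance(walker_model):
    """Holding the standing pose: vertical contact forces sum to body weight."""
    model = walker_model
    q = np.zeros(model.n_dof)
    # place the base so both feet rest flat on the ground
    body, off = model.contact_point("left", "heel")
    drop = model.kinematics(q).point_position(body, off)[2]
    q[1] -= drop
    kin = model.kinematics(q)
    cps = [_planar_point(model, s, p, kin.point_position(
        *model.contact_point(s, p)))
        for s in ("left", "right") for p in ("heel", "hallux")]
    contacts = ContactSet(cps)
    st = State(q, np.zeros(model.n_dof))
    # torques that hold the posture: least-squares inverse dynamics at a = 0
    H, C = mass_matrix_bias(model, kin)
    rows = contacts.independent_rows(kin)
    G = contacts.jacobian(kin)[rows]
    S = np.zeros((model.n_dof, model.n_act))
    S[model.base_dof:, :] = np.eye(model.n_act)
    sol = np.linalg.lstsq(np.hstack([S, G.T]), C, rcond=None)[0]
    tau = S @ sol[:model.n_act]
    ev = constrained_forward_dynamics(model, st, tau, contacts)
    assert np.abs(ev.a).max() < 1e-6
    info = contacts.row_info()
    fz = sum(lam for ridx, lam in zip(ev.rows, ev.lam)
             if info[ridx][1] == 1)  # vertical planar row
    assert fz == pytest.approx(model.total_mass * 9.81, abs=1e-6)


def test_degenerate_contact_raises(walker_model):
    model = walker_model
    q = np.zeros(model.n_dof)
    body, off = model.contact_point("left", "heel")
    # duplicate the same constraint row twice -> no independent rows beyond
    # the first set; a fully duplicated set still reduces fine, so force an
    # all-zero direction instead
    cp = ContactPoint("bad", body, off, np.zeros((2, 3)), np.zeros(3))
    with pytest.raises(DegenerateContactError):
        constrained_forward_dynamics(model, State(q, np.zeros_like(q)),
                                     np.zeros(model.n_dof), ContactSet([cp]))


def test_redundant_flat_foot_rows_are_reduced(walker_model):
    model = walker_model
    q = np.zeros(model.n_dof)
    body, off = model.contact_point("left", "heel")
    q[1] -= model.kinematics(q).point_position(body, off)[2]
    kin = model.kinematics(q)
    cs = ContactSet([
        _planar_point(model, "left", "heel"),
        _planar_point(model, "left", "hallux"),
    ])
    rows = cs.independent_rows(kin)
    # 4 planar rows on one rigid flat foot span rank 3
    assert len(rows) == 3
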