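"""Gait-stability benchmarks.

Implements the quantities used to benchmark walking stability:

* the **Instantaneous Capture Point** (ICaP), the ground point offset from a
  reference point by the horizontal COM velocity divided by the linear
  inverted pendulum (LIPM) eigenfrequency ``omega0 = sqrt(g / l)`` —
  stepping onto it brings the LIPM to rest;
* the **normalized orbital energy** ``E'_lip = 1/2 rdot'^2 - 1/2 (r'_com -
  r'_cop)^2 omega0^2`` of the LIPM, with all position-like quantities divided
  by the subject's leg length;
* the **residual orbital energy** ``E'_res``: the normalized orbital energy
  right after each heel strike, summarised per side and stride-averaged;
* the **whole-body angular-momentum decomposition** about the COM into
  upper-body and lower-body contributions per anatomical plane;
* **gait-event detection** (heel strike, toe strike, heel off, toe off) from
  contact forces or contact-point kinematics, and the per-step **foot
  placement** geometry of the ICaP relative to the landing foot.

Two conventions are configurable and echoed in every record: the ICaP
reference point (the COM ground projection by default, the CoP in
``"cop"`` mode) and the pendulum length behind ``omega0`` (the instantaneous
COM height by default, the constant leg length in ``"leg_length"`` mode).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .multibody import GRAVITY, MultibodyModel, State, angular_momentum, com_state

__all__ = [
    "GroundReferenceTrajectory",
    "GaitEvents",
    "OrbitalEnergyRecord",
    "HeelStrikeEnergy",
    "AngularMomentumDecomposition",
    "FootPlacementSummary",
    "StepPlacement",
    "angular_eigenfrequency",
    "instantaneous_capture_point",
    "normalized_orbital_energy",
    "residual_orbital_energy",
    "stride_average",
    "decompose_angular_momentum",
    "detect_gait_events",
    "foot_placement_summary",
    "ground_reference_from_states",
]

PLANES = ("frontal", "sagittal", "horizontal")  # x, y, z axis components


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class GroundReferenceTrajectory:
    """COM / CoP / ICaP time series in the ground (xy) plane."""

    times: np.ndarray  # (n,)
    r_com: np.ndarray  # (n, 3)
    rdot_com: np.ndarray  # (n, 3)
    r_cop: np.ndarray  # (n, 2); NaN outside contact
    r_icap: np.ndarray  # (n, 2)
    com_height: np.ndarray  # (n,)
    icap_mode: str = "com"  # reference point used for the ICaP
    omega0_mode: str = "com_height"

    def __post_init__(self):
        for name in ("times", "r_com", "rdot_com", "r_cop", "r_icap", "com_height"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        if np.any(self.com_height <= 0):
            raise ValidationError("com_height must be positive")

    def sample_at_or_after(self, t: float) -> int:
        """Index of the first sample at or after ``t`` (the v+ side of an event)."""
        i = int(np.searchsorted(self.times, t - 1e-12))
        if i >= len(self.times):
            raise ValidationError(f"time {t} outside trajectory span")
        return i


@dataclass
class GaitEvents:
    """Per-side ordered gait event times (s)."""

    heel_strikes: dict = field(default_factory=lambda: {"left": [], "right": []})
    toe_strikes: dict = field(default_factory=lambda: {"left": [], "right": []})
    toe_offs: dict = field(default_factory=lambda: {"left": [], "right": []})
    heel_offs: dict = field(default_factory=lambda: {"left": [], "right": []})

    def validate(self):
        """Check per-side ordering heel strike < toe strike < next toe off."""
        for side in ("left", "right"):
            hs, ts, to = (sorted(self.heel_strikes[side]), sorted(self.toe_strikes[side]),
                          sorted(self.toe_offs[side]))
            for h, t in zip(hs, ts):
                if not h < t:
                    raise ValidationError(f"{side}: heel strike {h} not before toe strike {t}")
            for t, o in zip(ts, [x for x in to if x > (ts[0] if ts else -np.inf)]):
                if not t < o:
                    raise ValidationError(f"{side}: toe strike {t} not before toe off {o}")
        return self

    def all_heel_strikes(self) -> list[tuple[float, str]]:
        ev = [(t, "left") for t in self.heel_strikes["left"]]
        ev += [(t, "right") for t in self.heel_strikes["right"]]
        return sorted(ev)


@dataclass
class HeelStrikeEnergy:
    time: float
    side: str
    value: float  # E'_res, 1/s^2
    omega0: float


@dataclass
class OrbitalEnergyRecord:
    """Normalized orbital energy along a trajectory and at heel strikes."""

    norm_length: float  # m, leg length used for normalization
    g: float
    omega0_mode: str
    events: list  # of HeelStrikeEnergy
    times: Optional[np.ndarray] = None
    E_lip_prime: Optional[np.ndarray] = None  # 1/s^2 time series

    def side_mean(self, side: str) -> float:
        vals = [e.value for e in self.events if e.side == side]
        if not vals:
            raise ValidationError(f"no heel strikes on side {side!r}")
        return float(np.mean(vals))

    @property
    def stride_average(self) -> float:
        return stride_average(self.side_mean("left"), self.side_mean("right"))


@dataclass
class AngularMomentumDecomposition:
    """Upper/lower/full-body angular momentum about the COM per plane."""

    times: np.ndarray
    upper: np.ndarray  # (n, 3): x=frontal, y=sagittal, z=horizontal components
    lower: np.ndarray
    full: np.ndarray

    def plane(self, name: str, part: str = "full") -> np.ndarray:
        return getattr(self, part)[:, PLANES.index(name)]


@dataclass
class StepPlacement:
    time: float
    side: str
    footprint: dict  # point name -> (2,) ground position
    r_icap: np.ndarray  # (2,)
    r_com_ground: np.ndarray  # (2,)
    anterior_offset: float  # m, ICaP along the foot's anterior axis from the heel
    medial_offset: float  # m, ICaP along the foot's medial axis (towards midline)


@dataclass
class FootPlacementSummary:
    steps: list  # of StepPlacement


# ---------------------------------------------------------------------------
# scalar operations
# ---------------------------------------------------------------------------


def angular_eigenfrequency(length: float) -> float:
    """LIPM eigenfrequency ``omega0 = sqrt(g / l)`` for pendulum length l (m)."""
    if not np.isfinite(length) or length <= 0:
        raise ValidationError(f"pendulum length must be positive, got {length}")
    return float(np.sqrt(GRAVITY / length))


def instantaneous_capture_point(reference_point, rdot_com, omega0: float) -> np.ndarray:
    """Ground-plane ICaP: ``reference_point + rdot_com / omega0``.

    ``reference_point`` is the COM ground projection in the default mode or
    the CoP in the as-printed mode; both are 2-vectors in the ground plane.
    """
    if omega0 <= 0:
        raise ValidationError("omega0 must be positive")
    return np.asarray(reference_point, float) + np.asarray(rdot_com, float) / omega0


def normalized_orbital_energy(r_com_n, r_cop_n, rdot_com_n, omega0: float) -> float:
    """Normalized LIPM orbital energy (1/s^2) from pre-normalized inputs.

    Inputs are horizontal (ground-plane) components already divided by the
    normalization length: positions dimensionless, velocities in 1/s.  The
    COM velocity is assumed horizontal.
    """
    d = np.asarray(r_com_n, float) - np.asarray(r_cop_n, float)
    v = np.asarray(rdot_com_n, float)
    return float(0.5 * v @ v - 0.5 * (d @ d) * omega0 ** 2)


def stride_average(left: float, right: float) -> float:
    """Stride-level aggregate: mean of the left-HS and right-HS values."""
    return 0.5 * (left + right)


# ---------------------------------------------------------------------------
# trajectory-level operations
# ---------------------------------------------------------------------------


def _omega0_at(traj: GroundReferenceTrajectory, i: int, leg_length: float, mode: str) -> float:
    if mode == "com_height":
        return angular_eigenfrequency(float(traj.com_height[i]))
    if mode == "leg_length":
        return angular_eigenfrequency(leg_length)
    raise ValidationError(f"unknown omega0 mode {mode!r}")


def residual_orbital_energy(
    traj: GroundReferenceTrajectory,
    events: GaitEvents,
    leg_length: float,
    omega0_mode: str = "com_height",
    with_series: bool = True,
) -> OrbitalEnergyRecord:
    """Normalized orbital energy right after each heel strike (``E'_res``).

    Each heel strike is evaluated at the first trajectory sample at or after
    the event time, i.e. on the post-impact side of the transition.  Heel
    strikes outside the trajectory span are skipped with a warning entry.
    All quantities related to positions are divided by ``leg_length``;
    ``omega0`` uses the instantaneous COM height unless ``omega0_mode`` is
    ``"leg_length"``.
    """
    if leg_length <= 0:
        raise ValidationError("leg_length must be positive")
    l = leg_length
    out = []
    for t_hs, side in events.all_heel_strikes():
        try:
            i = traj.sample_at_or_after(t_hs)
        except ValidationError:
            import warnings

            warnings.warn(f"heel strike at {t_hs:.3f}s outside trajectory; skipped")
            continue
        om = _omega0_at(traj, i, l, omega0_mode)
        val = normalized_orbital_energy(
            traj.r_com[i, :2] / l, traj.r_cop[i] / l, traj.rdot_com[i, :2] / l, om
        )
        out.append(HeelStrikeEnergy(time=float(traj.times[i]), side=side, value=val, omega0=om))
    series = times = None
    if with_series:
        vals = np.empty(len(traj.times))
        for i in range(len(traj.times)):
            om = _omega0_at(traj, i, l, omega0_mode)
            if np.any(np.isnan(traj.r_cop[i])):
                vals[i] = np.nan
                continue
            vals[i] = normalized_orbital_energy(
                traj.r_com[i, :2] / l, traj.r_cop[i] / l, traj.rdot_com[i, :2] / l, om
            )
        series, times = vals, traj.times
    return OrbitalEnergyRecord(
        norm_length=l, g=GRAVITY, omega0_mode=omega0_mode, events=out,
        times=times, E_lip_prime=series,
    )


def decompose_angular_momentum(
    model: MultibodyModel,
    times: np.ndarray,
    Q: np.ndarray,
    V: np.ndarray,
    upper: Sequence[str],
    lower: Sequence[str],
) -> AngularMomentumDecomposition:
    """Upper/lower/full-body angular momentum about the whole-body COM.

    ``upper`` and ``lower`` must partition the model's segments.  Plane
    mapping (documented convention): the frontal-plane momentum is the x-axis
    component, sagittal the y-axis, horizontal the z-axis.
    """
    if sorted(list(upper) + list(lower)) != sorted(model.segments):
        raise ValidationError("upper + lower must partition the model segments")
    n = len(times)
    Lu, Ll = np.empty((n, 3)), np.empty((n, 3))
    for i in range(n):
        st = State(Q[i], V[i])
        kin = model.kinematics(st.q, st.v)
        com, _ = com_state(model, st, kin)
        Lu[i] = angular_momentum(model, st, upper, about=com, kin=kin)
        Ll[i] = angular_momentum(model, st, lower, about=com, kin=kin)
    return AngularMomentumDecomposition(
        times=np.asarray(times, float), upper=Lu, lower=Ll, full=Lu + Ll
    )


# ---------------------------------------------------------------------------
# gait events
# ---------------------------------------------------------------------------


def _debounce(times, active, min_gap):
    """Close inactive gaps shorter than ``min_gap`` (force flicker)."""
    act = active.copy()
    n = len(act)
    i = 0
    while i < n:
        if not act[i]:
            j = i
            while j < n and not act[j]:
                j += 1
            if 0 < i and j < n and times[j] - times[i] < min_gap:
                act[i:j] = True
            i = j
        else:
            i += 1
    return act


def _onsets_offsets(times, active):
    on = list(times[1:][(~active[:-1]) & active[1:]])
    off = list(times[1:][active[:-1] & (~active[1:])])
    return on, off


def detect_gait_events(
    times: np.ndarray,
    point_forces: Optional[dict] = None,
    body_weight: Optional[float] = None,
    point_heights: Optional[dict] = None,
    point_velocities: Optional[dict] = None,
    force_threshold: float = 0.02,
    height_threshold: float = 5e-3,
    debounce: float = 0.05,
) -> GaitEvents:
    """Detect heel strike, toe strike, heel off and toe off per side.

    Force mode (preferred, used when ``point_forces`` is given): a contact
    point is active while its vertical force exceeds ``force_threshold``
    (fraction of body weight, default 2%).  Kinematic mode: a point is
    active while its height is below ``height_threshold`` (default 5 mm)
    with non-positive vertical velocity.

    ``point_forces`` / ``point_heights`` map ``(side, point)`` keys — with
    point in heel / hallux / meta5 — to arrays over ``times``.  Forefoot
    contact is the union of hallux and meta5.
    """
    times = np.asarray(times, float)
    active = {}
    if point_forces is not None:
        if body_weight is None:
            raise ValidationError("body_weight required for force-based detection")
        thr = force_threshold * body_weight * GRAVITY
        for key, fz in point_forces.items():
            active[key] = _debounce(times, np.asarray(fz, float) > thr, debounce)
    elif point_heights is not None:
        for key, z in point_heights.items():
            act = np.asarray(z, float) < height_threshold
            if point_velocities is not None and key in point_velocities:
                act &= np.asarray(point_velocities[key], float) <= 1e-3
            active[key] = _debounce(times, act, debounce)
    else:
        raise ValidationError("provide point_forces or point_heights")

    events = GaitEvents()
    for side in ("left", "right"):
        heel = active.get((side, "heel"), np.zeros(len(times), bool))
        fore = np.zeros(len(times), bool)
        for pt in ("hallux", "meta5"):
            fore |= active.get((side, pt), np.zeros(len(times), bool))
        foot = heel | fore
        hs, _ = _onsets_offsets(times, heel)
        ts, _ = _onsets_offsets(times, fore)
        _, to = _onsets_offsets(times, foot)
        _, ho = _onsets_offsets(times, heel)
        events.heel_strikes[side] = hs
        events.toe_strikes[side] = ts
        events.toe_offs[side] = to
        events.heel_offs[side] = [t for t in ho if t not in to]
    return events


# ---------------------------------------------------------------------------
# foot placement
# ---------------------------------------------------------------------------


def foot_placement_summary(
    traj: GroundReferenceTrajectory,
    events: GaitEvents,
    footprints: dict,
) -> FootPlacementSummary:
    """ICaP offsets in the landing foot frame at each heel strike.

    ``footprints`` maps heel-strike times (rounded to 1e-9) or
    ``(time, side)`` tuples to ``{point: (2,) ground position}`` dictionaries
    of the landing foot.  The foot frame has its origin at the heel, the
    anterior axis towards the hallux, and the medial axis towards the body
    midline (so left and right feet mirror in sign).
    """
    steps = []
    for t_hs, side in events.all_heel_strikes():
        fp = (footprints.get((t_hs, side))
              or footprints.get((round(t_hs, 9), side)))
        if fp is None:
            import warnings

            warnings.warn(f"no footprint for heel strike at {t_hs:.3f}s; step skipped")
            continue
        i = traj.sample_at_or_after(t_hs)
        heel = np.asarray(fp["heel"], float)
        hallux = np.asarray(fp["hallux"], float)
        anterior = hallux - heel
        anterior = anterior / np.linalg.norm(anterior)
        # medial: rotate anterior by +90 deg (ccw) for the right foot
        # (midline is to its left), -90 deg for the left foot
        sgn = 1.0 if side == "right" else -1.0
        medial = sgn * np.array([-anterior[1], anterior[0]])
        rel = traj.r_icap[i] - heel
        steps.append(
            StepPlacement(
                time=float(traj.times[i]), side=side, footprint=dict(fp),
                r_icap=traj.r_icap[i].copy(), r_com_ground=traj.r_com[i, :2].copy(),
                anterior_offset=float(rel @ anterior), medial_offset=float(rel @ medial),
            )
        )
    return FootPlacementSummary(steps=steps)


# ---------------------------------------------------------------------------
# from reconstructed states
# ---------------------------------------------------------------------------


def ground_reference_from_states(
    model: MultibodyModel,
    times: np.ndarray,
    Q: np.ndarray,
    V: np.ndarray,
    cop: Optional[np.ndarray] = None,
    icap_mode: str = "com",
    omega0_mode: str = "com_height",
    leg_length: Optional[float] = None,
) -> GroundReferenceTrajectory:
    """Build the ground-plane reference trajectory from generalized states.

    ``cop`` is an (n, 2) CoP series (e.g. from force plates or reconstructed
    contact forces, NaN outside contact).  In the default ``icap_mode="com"``
    the ICaP extrapolates from the COM ground projection; in ``"cop"`` mode
    from the CoP (the as-printed variant).
    """
    n = len(times)
    r_com = np.empty((n, 3))
    rdot = np.empty((n, 3))
    for i in range(n):
        st = State(Q[i], V[i])
        r_com[i], rdot[i] = com_state(model, st)
    height = r_com[:, 2].copy()
    cop = np.full((n, 2), np.nan) if cop is None else np.asarray(cop, float)
    icap = np.empty((n, 2))
    for i in range(n):
        if omega0_mode == "com_height":
            om = angular_eigenfrequency(height[i])
        else:
            om = angular_eigenfrequency(leg_length)
        ref = r_com[i, :2] if icap_mode == "com" else cop[i]
        icap[i] = instantaneous_capture_point(ref, rdot[i, :2], om)
    return GroundReferenceTrajectory(
        times=times, r_com=r_com, rdot_com=rdot, r_cop=cop, r_icap=icap,
        com_height=height, icap_mode=icap_mode, omega0_mode=omega0_mode,
    )
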