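"""Closed-form linear-inverted-pendulum (LIPM) walking fixtures.

The LIPM keeps the COM at a constant height ``z0``; with the CoP fixed at
``r_cop`` each horizontal coordinate follows

    x(t) = x_cop + (x0 - x_cop) cosh(omega0 t) + (xdot0 / omega0) sinh(omega0 t)

with ``omega0 = sqrt(g / z0)``.  The generator produces a periodic stepping
gait fully determined by (COM height, step length L, step width W, step time
Ts): the sagittal orbit enters each support phase half a step length behind
the stance foot and exits half a step length ahead of it, the lateral orbit
is the mirror-symmetric cosh arc between the two foot lanes at ``±W/2``.
Support exchange is instantaneous (optional finite double support linearly
transfers the CoP) and each exchange is a heel strike of the landing side
with a simultaneous toe off of the other.

In ``on_icap`` mode the final step is placed exactly on the COM-referenced
Instantaneous Capture Point, after which the COM decays to rest over the
stance foot — the defining property of the capture point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .metrics import GaitEvents, GroundReferenceTrajectory, angular_eigenfrequency
from .multibody import GRAVITY

__all__ = ["LipmGaitSpec", "simulate_lipm_gait", "orbital_energy_dimensional"]


@dataclass(frozen=True)
class LipmGaitSpec:
    """Parameters of a synthetic LIPM gait."""

    com_height: float = 0.9  # m
    step_length: float = 0.6  # m
    step_width: float = 0.2  # m
    step_time: float = 0.55  # s
    n_steps: int = 10
    foot_placement_mode: str = "fixed_offsets"  # or "on_icap"
    double_support_fraction: float = 0.0  # of step_time; linear CoP transfer
    first_side: str = "left"
    dt: float = 2e-3  # s, sampling interval
    seed: int = 0  # reserved for optional noise; the closed form is exact

    def __post_init__(self):
        for nm in ("com_height", "step_length", "step_width", "step_time", "dt"):
            if getattr(self, nm) <= 0:
                raise ValidationError(f"{nm} must be positive")
        if self.n_steps < 2:
            raise ValidationError("n_steps must be >= 2")
        if self.foot_placement_mode not in ("fixed_offsets", "on_icap"):
            raise ValidationError(f"unknown foot_placement_mode {self.foot_placement_mode!r}")
        if not 0 <= self.double_support_fraction < 0.5:
            raise ValidationError("double_support_fraction must be in [0, 0.5)")


def _lipm_segment(t, cop, r0, v0, omega0):
    """Closed-form fixed-CoP LIPM propagation; t may be an array.

    Uses the growing/decaying mode split ``A e^{w t} + B e^{-w t}`` instead
    of cosh/sinh so that a capture step (growing amplitude exactly zero)
    decays to rest without catastrophic cancellation.
    """
    A = 0.5 * ((r0 - cop) + v0 / omega0)
    B = 0.5 * ((r0 - cop) - v0 / omega0)
    # amplitudes below the float resolution of their inputs are numerical
    # zero; clamping keeps a capture step from re-exciting the growing mode
    scale = np.abs(r0 - cop) + np.abs(v0) / omega0 + np.abs(cop)
    A = np.where(np.abs(A) < 1e-13 * scale, 0.0, A)
    ep = np.exp(omega0 * t)[..., None]
    em = np.exp(-omega0 * t)[..., None]
    r = cop + A * ep + B * em
    v = omega0 * (A * ep - B * em)
    return r, v


def orbital_energy_dimensional(r_com, r_cop, rdot_com, omega0):
    """Un-normalized LIPM orbital energy (m^2/s^2), horizontal components."""
    d = np.asarray(r_com, float) - np.asarray(r_cop, float)
    v = np.asarray(rdot_com, float)
    return 0.5 * v @ v - 0.5 * (d @ d) * omega0 ** 2


def periodic_initial_conditions(spec: LipmGaitSpec):
    """Entry state of a periodic step, relative to the stance foot.

    Returns (d_x, v_x0, c_y, vy_entry): the COM enters at ``-d_x`` behind the
    foot with forward speed ``v_x0``; the lateral arc has half-amplitude
    ``c_y`` around the foot lane with entry velocity ``vy_entry`` towards the
    body midline of the next step.
    """
    om = angular_eigenfrequency(spec.com_height)
    sig = om * spec.step_time / 2.0
    d_x = spec.step_length / 2.0
    v_x0 = om * d_x / np.tanh(sig)
    c_y = spec.step_width / (2.0 * np.cosh(sig))
    vy_entry = c_y * om * np.sinh(sig)
    if not np.isfinite(v_x0) or v_x0 <= 0:
        raise ValidationError("no periodic LIPM solution for these parameters")
    return d_x, v_x0, c_y, vy_entry


def simulate_lipm_gait(spec: LipmGaitSpec):
    """Generate the closed-form LIPM gait.

    Returns ``(GroundReferenceTrajectory, GaitEvents, footprints)`` where
    ``footprints`` maps ``(time, side)`` of each heel strike to the landing
    foot's contact-point ground positions (heel at the CoP, a nominal
    hallux one foot-length ahead), as consumed by
    :func:`gaitbench.metrics.foot_placement_summary`.
    """
    om = angular_eigenfrequency(spec.com_height)
    d_x, v_x0, c_y, vy_entry = periodic_initial_conditions(spec)
    Ts, dt = spec.step_time, spec.dt
    sides = {"left": 1.0, "right": -1.0}
    side = spec.first_side
    # stance foot positions: step k at x = k L, alternating y lanes
    feet = []
    for k in range(spec.n_steps):
        feet.append((k * spec.step_length, sides[side] * spec.step_width / 2.0, side))
        side = "right" if side == "left" else "left"

    times_all, r_all, v_all, cop_all = [], [], [], []
    events = GaitEvents()
    footprints = {}
    foot_len = 0.25  # m, nominal footprint for placement geometry
    t0 = 0.0
    # entry state relative to the first stance foot
    fx, fy, s0 = feet[0]
    lat = sides[s0]
    r = np.array([fx - d_x, fy - lat * c_y * np.cosh(om * Ts / 2.0)])
    v = np.array([v_x0, lat * vy_entry])
    capture_done = False
    for k, (fx, fy, s) in enumerate(feet):
        cop = np.array([fx, fy])
        last_step = k == len(feet) - 1
        if spec.foot_placement_mode == "on_icap" and last_step:
            # place the final foot exactly on the COM-referenced ICaP
            cop = r + v / om
            capture_done = True
        if k > 0:
            t_hs = t0
            events.heel_strikes[s].append(t_hs)
            other = "right" if s == "left" else "left"
            events.toe_offs[other].append(t_hs)
            heel = cop.copy()
            footprints[(round(t_hs, 9), s)] = {
                "heel": heel,
                "hallux": heel + np.array([foot_len, 0.0]),
                "meta5": heel + np.array([0.8 * foot_len, sides[s] * 0.08]),
            }
        duration = Ts if not capture_done else max(Ts, 22.0 / om)
        n = max(2, int(round(duration / dt)) + 1)
        tloc = np.linspace(0.0, duration, n)
        ds_T = spec.double_support_fraction * Ts
        if ds_T > 0 and k > 0:
            # linear CoP transfer from the previous foot over the first ds_T
            prev = np.array(feet[k - 1][:2])
            seg_r, seg_v = [], []
            ri, vi = r.copy(), v.copy()
            cops = []
            t_prev = 0.0
            for tl in tloc:
                # integrate piecewise: within double support the CoP ramps
                nsub = max(1, int(np.ceil((tl - t_prev) / 1e-3)))
                for _ in range(nsub):
                    h = (tl - t_prev) / nsub
                    frac = min(1.0, (t_prev + h / 2) / ds_T) if ds_T > 0 else 1.0
                    c = prev + frac * (cop - prev)
                    ri, vi = _lipm_segment(np.array([h]), c, ri, vi, om)
                    ri, vi = ri[0], vi[0]
                    t_prev += h
                seg_r.append(ri.copy())
                seg_v.append(vi.copy())
                frac = min(1.0, tl / ds_T) if ds_T > 0 else 1.0
                cops.append(prev + frac * (cop - prev))
            seg_r, seg_v = np.array(seg_r), np.array(seg_v)
            cops = np.array(cops)
            r, v = seg_r[-1], seg_v[-1]
        else:
            seg_r, seg_v = _lipm_segment(tloc, cop, r, v, om)
            cops = np.tile(cop, (n, 1))
            r, v = seg_r[-1], seg_v[-1]
        # drop the duplicate sample at phase end (next phase re-adds it)
        keep = slice(0, n - 1) if not last_step else slice(0, n)
        times_all.append(t0 + tloc[keep])
        r_all.append(seg_r[keep])
        v_all.append(seg_v[keep])
        cop_all.append(cops[keep])
        t0 += duration

    times = np.concatenate(times_all)
    r2 = np.vstack(r_all)
    v2 = np.vstack(v_all)
    cop2 = np.vstack(cop_all)
    n = len(times)
    r_com = np.column_stack([r2, np.full(n, spec.com_height)])
    rdot = np.column_stack([v2, np.zeros(n)])
    icap = r2 + v2 / om
    traj = GroundReferenceTrajectory(
        times=times, r_com=r_com, rdot_com=rdot, r_cop=cop2, r_icap=icap,
        com_height=np.full(n, spec.com_height), icap_mode="com",
        omega0_mode="com_height",
    )
    return traj, events, footprints
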