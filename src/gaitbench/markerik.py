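"""Whole-body inverse kinematics from marker trajectories.

Each frame solves a nonlinear least-squares fit over the entire kinematic
chain: virtual markers rigidly attached to model segments are matched to
measured marker positions by a damped Gauss-Newton iteration on the chain
Jacobian.  Markers are weighted uniformly by default; frames with fewer than
three valid markers are skipped, and each frame warm-starts from the
previous solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, EmptyMotionError, ValidationError
from .multibody import Kinematics, MultibodyModel

__all__ = ["MarkerFrame", "ReferenceMotion", "VirtualMarkerSet", "fit_frame", "fit_trajectory"]


@dataclass
class MarkerFrame:
    """Measured marker positions at one time instant."""

    time: float
    markers: dict  # name -> (3,) position, m
    valid: dict = field(default_factory=dict)  # name -> bool; missing = True

    def valid_markers(self) -> list[str]:
        return [m for m in self.markers if self.valid.get(m, True)]


class VirtualMarkerSet:
    """Maps marker names to (segment body, local offset) on a model."""

    def __init__(self, model: MultibodyModel, definition: dict, weights: Optional[dict] = None):
        self.model = model
        self.definition = {}
        for name, (segment, offset) in definition.items():
            if segment not in model.body_index:
                raise ConfigurationError(f"marker {name!r}: unknown segment {segment!r}")
            self.definition[name] = (model.body_index[segment], np.asarray(offset, float))
        self.weights = weights or {}

    def names(self):
        return list(self.definition)

    def positions(self, kin: Kinematics, names: Sequence[str]) -> np.ndarray:
        return np.array(
            [kin.point_position(*self.definition[n]) for n in names]
        )

    def jacobian(self, kin: Kinematics, names: Sequence[str]) -> np.ndarray:
        return np.vstack([kin.point_jacobian(*self.definition[n]) for n in names])


@dataclass
class ReferenceMotion:
    """Discrete postures q_j at strictly increasing times, with fit residuals."""

    times: np.ndarray  # (m+1,)
    postures: np.ndarray  # (m+1, n_dof)
    residuals: np.ndarray  # (m+1,) RMS marker distance per frame, m
    flags: list = field(default_factory=list)  # per-frame notes ('' if clean)

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.postures = np.asarray(self.postures, float)
        self.residuals = np.asarray(self.residuals, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("reference motion times must be strictly increasing")
        if np.any(self.residuals < 0):
            raise ValidationError("residuals must be non-negative")

    @property
    def residual_mean(self) -> float:
        return float(np.mean(self.residuals))

    @property
    def residual_sd(self) -> float:
        return float(np.std(self.residuals, ddof=1)) if len(self.residuals) > 1 else 0.0

    def interpolate(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the postures at times ``t``."""
        t = np.atleast_1d(np.asarray(t, float))
        out = np.empty((len(t), self.postures.shape[1]))
        for k in range(self.postures.shape[1]):
            out[:, k] = np.interp(t, self.times, self.postures[:, k])
        return out


def fit_frame(
    model: MultibodyModel,
    virtual_markers: VirtualMarkerSet,
    frame: MarkerFrame,
    q_init: np.ndarray,
    damping: float = 1e-6,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, bool]:
    """Least-squares pose fit of one marker frame.

    Minimizes the weighted sum of squared distances between the model's
    virtual markers and the measured positions by damped Gauss-Newton
    (Levenberg-style constant damping) with convergence at ``|dq| < tol``.
    Returns ``(q, rms_residual, converged)``; invalid markers are excluded.
    """
    names = [n for n in frame.valid_markers() if n in virtual_markers.definition]
    if len(names) < 3:
        raise ValidationError(f"frame at t={frame.time}: fewer than 3 valid markers")
    target = np.array([frame.markers[n] for n in names], float)
    w = np.array([virtual_markers.weights.get(n, 1.0) for n in names], float)
    wr = np.repeat(np.sqrt(w), 3)
    q = np.asarray(q_init, float).copy()
    n = model.n_dof
    converged = False
    for _ in range(max_iter):
        kin = model.kinematics(q)
        res = (virtual_markers.positions(kin, names) - target).ravel()
        J = virtual_markers.jacobian(kin, names)
        A = (J * wr[:, None]).T @ (J * wr[:, None]) + damping * np.eye(n)
        b = (J * wr[:, None]).T @ (wr * res)
        dq = np.linalg.solve(A, b)
        q -= dq
        if np.linalg.norm(dq) < tol:
            converged = True
            break
    kin = model.kinematics(q)
    res = virtual_markers.positions(kin, names) - target
    rms = float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))
    if not np.all(np.isfinite(q)):
        # diverged: fall back to the initial guess, flag via converged=False
        q = np.asarray(q_init, float).copy()
        kin = model.kinematics(q)
        res = virtual_markers.positions(kin, names) - target
        rms = float(np.sqrt(np.mean(np.sum(res ** 2, axis=1))))
        converged = False
    return q, rms, converged


def fit_trajectory(
    model: MultibodyModel,
    virtual_markers: VirtualMarkerSet,
    frames: Sequence[MarkerFrame],
    q_init: Optional[np.ndarray] = None,
    **fit_kwargs,
) -> ReferenceMotion:
    """Fit a time-ordered marker sequence; frame j+1 warm-starts from frame j."""
    times = [f.time for f in frames]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise ValidationError("marker frames must be strictly time-ordered")
    q = np.zeros(model.n_dof) if q_init is None else np.asarray(q_init, float).copy()
    T, Qs, Rs, flags = [], [], [], []
    for frame in frames:
        try:
            q, rms, ok = fit_frame(model, virtual_markers, frame, q, **fit_kwargs)
        except ValidationError as exc:
            warnings.warn(str(exc))
            continue
        T.append(frame.time)
        Qs.append(q.copy())
        Rs.append(rms)
        flags.append("" if ok else "not-converged")
    if not T:
        raise EmptyMotionError("no frames could be fitted")
    return ReferenceMotion(times=np.array(T), postures=np.array(Qs),
                           residuals=np.array(Rs), flags=flags)
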