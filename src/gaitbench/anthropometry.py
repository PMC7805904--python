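"""Subject-specific body-segment inertial parameters.

Segment masses, COM offsets and inertia tensors are produced from sex-specific
regression tables (:mod:`gaitbench._deleva_data`) given a subject's stature and
total body mass, with an optional prosthesis adjustment that rescales one leg's
segments to a measured mass ratio of the contralateral leg.

Conventions
-----------
Each segment has a local frame with its origin at the proximal joint centre,
x anterior, y to the subject's left and z up in the neutral standing pose.
Limb segments hang along -z, trunk segments and the head stack along +z.  The
COM offset is placed on the longitudinal axis at the regression's COM fraction
of segment length; the inertia tensor is diagonal in the local frame, built
from the three radii of gyration about the COM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

from . import _deleva_data
from .errors import ConfigurationError, ValidationError

__all__ = [
    "SubjectAnthropometry",
    "ProsthesisSpec",
    "SegmentParameters",
    "de_leva_parameters",
    "apply_prosthesis",
    "total_mass",
    "LEG_SEGMENT_BASENAMES",
]

#: segment base names that make up one leg (suffix "_left" / "_right")
LEG_SEGMENT_BASENAMES = ("thigh", "shank", "foot")

#: segments whose longitudinal axis points up (+z) in the neutral pose
_UPWARD_SEGMENTS = {"head", "upper_trunk", "mid_trunk", "pelvis"}


@dataclass(frozen=True)
class ProsthesisSpec:
    """Mass model of a unilateral leg prosthesis.

    ``mass_ratio`` is the total prosthetic-leg mass divided by the total
    contralateral-leg mass (e.g. 0.35 for a leg weighing 35% of the sound
    leg).  ``overrides`` may carry measured per-segment parameters
    (``{"shank_right": {"mass": 1.9, "com_offset": [...], "inertia": [...]}}``)
    that replace the uniform scaling for those segments.
    """

    side: Literal["left", "right"]
    mass_ratio: float
    scale_inertia: bool = True
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ValidationError(f"prosthesis side must be left/right, got {self.side!r}")
        if not (0.0 < self.mass_ratio <= 1.0):
            raise ValidationError(f"prosthesis mass_ratio must be in (0, 1], got {self.mass_ratio}")


@dataclass(frozen=True)
class SubjectAnthropometry:
    """Minimal anthropometric description of a subject.

    leg_length is the hip-to-ankle distance in metres; it sizes the thigh and
    shank segments and is the normalisation length of the stability metrics.
    """

    sex: Literal["female", "male"]
    total_mass: float
    total_height: float
    leg_length: float
    prosthesis: Optional[ProsthesisSpec] = None

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be 'female' or 'male', got {self.sex!r}")
        for name in ("total_mass", "total_height", "leg_length"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be a positive finite number")
        if self.leg_length >= self.total_height:
            raise ValidationError("leg_length must be smaller than total_height")


@dataclass(frozen=True)
class SegmentParameters:
    """Inertial parameters of one rigid body segment (SI units)."""

    name: str
    mass: float  # kg
    com_offset: np.ndarray  # (3,) m, in the segment's local frame
    inertia: np.ndarray  # (3, 3) kg m^2, about the segment COM, local frame
    length: float  # m

    def __post_init__(self):
        object.__setattr__(self, "com_offset", np.asarray(self.com_offset, dtype=float))
        object.__setattr__(self, "inertia", np.asarray(self.inertia, dtype=float))
        if self.mass < 0:
            raise ValidationError(f"segment {self.name}: negative mass")
        if self.com_offset.shape != (3,) or self.inertia.shape != (3, 3):
            raise ValidationError(f"segment {self.name}: bad parameter shapes")
        if not np.allclose(self.inertia, self.inertia.T, atol=1e-12):
            raise ValidationError(f"segment {self.name}: inertia must be symmetric")
        if np.linalg.eigvalsh(self.inertia).min() < -1e-12:
            raise ValidationError(f"segment {self.name}: inertia must be PSD")


def _table(sex: str) -> dict:
    return _deleva_data.FEMALE if sex == "female" else _deleva_data.MALE


def de_leva_parameters(anthro: SubjectAnthropometry) -> list[SegmentParameters]:
    """Regress the 16 base segments' inertial parameters for one subject.

    Mass fractions are renormalised to sum to one, so the segment masses sum
    to ``anthro.total_mass`` exactly.  Thigh and shank lengths are rescaled
    (keeping their table proportion) so that thigh + shank = ``leg_length``.
    """
    table = _table(anthro.sex)
    frac_sum = sum(row[0] for row in table.values())
    segments = []
    # keep thigh+shank consistent with the measured hip-to-ankle distance
    reg_leg = (table["thigh_left"][1] + table["shank_left"][1]) * anthro.total_height
    leg_scale = anthro.leg_length / reg_leg
    for name, (mass_pct, len_frac, com_pct, rg_s, rg_t, rg_l) in table.items():
        mass = anthro.total_mass * mass_pct / frac_sum
        length = len_frac * anthro.total_height
        if name.startswith(("thigh", "shank")):
            length *= leg_scale
        direction = 1.0 if name in _UPWARD_SEGMENTS else -1.0
        com = np.array([0.0, 0.0, direction * com_pct / 100.0 * length])
        radii = np.array([rg_s, rg_t, rg_l]) / 100.0 * length
        # rg_sagittal is about the x (sagittal-plane-normal is y)... by the
        # table's convention: sagittal rg -> about the frontal axis (y),
        # transverse rg -> about the sagittal axis (x), longitudinal -> z.
        inertia = np.diag(mass * np.array([radii[1] ** 2, radii[0] ** 2, radii[2] ** 2]))
        segments.append(SegmentParameters(name, mass, com, inertia, length))
    return segments


def total_mass(segments: list[SegmentParameters]) -> float:
    """Sum of segment masses."""
    return float(sum(s.mass for s in segments))


def _leg_segment_names(side: str) -> tuple[str, ...]:
    return tuple(f"{base}_{side}" for base in LEG_SEGMENT_BASENAMES)


def apply_prosthesis(
    segments: list[SegmentParameters], prosthesis: ProsthesisSpec
) -> list[SegmentParameters]:
    """Rescale one leg's segments to emulate a prosthetic limb.

    The three prosthesis-side leg segments (thigh, shank, foot) are scaled by
    a single factor so their total mass equals ``mass_ratio`` times the total
    mass of the contralateral three.  Inertia tensors scale with the same
    factor when ``scale_inertia`` is set; explicit per-segment ``overrides``
    win over the uniform scaling.  All other segments are untouched.
    """
    by_name = {s.name: s for s in segments}
    side, other = prosthesis.side, ("right" if prosthesis.side == "left" else "left")
    for name in _leg_segment_names(side):
        if name not in by_name:
            raise ConfigurationError(f"prosthesis side segment {name!r} missing")
    contralateral_mass = sum(by_name[n].mass for n in _leg_segment_names(other))
    current_mass = sum(by_name[n].mass for n in _leg_segment_names(side))
    scale = prosthesis.mass_ratio * contralateral_mass / current_mass
    out = []
    for seg in segments:
        if seg.name in _leg_segment_names(side):
            override = prosthesis.overrides.get(seg.name)
            if override:
                seg = replace(
                    seg,
                    mass=float(override.get("mass", seg.mass * scale)),
                    com_offset=np.asarray(override.get("com_offset", seg.com_offset), float),
                    inertia=np.asarray(
                        override.get(
                            "inertia",
                            seg.inertia * (scale if prosthesis.scale_inertia else 1.0),
                        ),
                        float,
                    ),
                )
            else:
                seg = replace(
                    seg,
                    mass=seg.mass * scale,
                    inertia=seg.inertia * (scale if prosthesis.scale_inertia else 1.0),
                )
        out.append(seg)
    return out
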