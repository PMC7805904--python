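"""Whole-body model builders.

Builds the 16-segment / 43-DoF full human model, the 13-segment / 34-DoF
reduced model (trunk and wrist joints locked) and a planar 7-segment walker
used as the desk-scale fixture, all on top of :mod:`gaitbench.multibody`.

Skeleton template
-----------------
Joint-centre locations are a documented convention scaled from stature ``H``
(the source regressions only provide segment lengths):

* half inter-hip distance ``0.052 H``; half biacromial distance ``0.115 H``;
* ankle height ``0.04 H``; the ankle sits one quarter of the foot length
  behind the heel-to-toe midline, i.e. the heel lies ``0.25 L_f`` behind and
  the hallux ``0.75 L_f`` in front of the ankle; meta5 sits at ``0.55 L_f``
  with a lateral offset of ``0.125 L_f``;
* 3-DoF joints decompose intrinsically as Y (flexion/extension),
  X (ab/adduction), Z (internal rotation); 1-DoF knees and elbows flex about
  Y; the floating base is x-y-z translation followed by intrinsic
  Z (yaw) - Y (pitch) - X (roll).

These are conventions of this package, not measured facts; override the foot
geometry via the ``foot_template`` argument where lab measurements exist.
"""

from __future__ import annotations

import numpy as np
import yaml

from .anthropometry import SegmentParameters
from .errors import ConfigurationError
from .multibody import BodyNode, MultibodyModel

__all__ = [
    "build_full_model",
    "build_reduced_model",
    "build_planar_walker",
    "merge_segments",
    "model_to_yaml",
    "model_from_yaml",
    "UPPER_BODY_SEGMENTS",
    "LOWER_BODY_SEGMENTS",
]

_AX = {"x": np.array([1.0, 0.0, 0.0]), "y": np.array([0.0, 1.0, 0.0]), "z": np.array([0.0, 0.0, 1.0])}

#: default upper/lower split for angular-momentum decomposition
#: (pelvis counts as lower body; configurable in the metrics call)
LOWER_BODY_SEGMENTS = (
    "pelvis",
    "thigh_left", "thigh_right",
    "shank_left", "shank_right",
    "foot_left", "foot_right",
)
UPPER_BODY_SEGMENTS_FULL = (
    "mid_trunk", "upper_trunk", "head",
    "upper_arm_left", "upper_arm_right",
    "forearm_left", "forearm_right",
    "hand_left", "hand_right",
)
UPPER_BODY_SEGMENTS = (
    "trunk", "head",
    "upper_arm_left", "upper_arm_right",
    "forearm_left", "forearm_right",
)

_DEFAULT_FOOT = {"heel": (-0.25, 0.0), "hallux": (0.75, 0.0), "meta5": (0.55, 0.125)}


def _foot_points(length: float, ankle_height: float, side: str, template=None):
    """Contact-point offsets in the foot (ankle) frame."""
    template = template or _DEFAULT_FOOT
    lat = 1.0 if side == "left" else -1.0
    return {
        name: np.array([fx * length, lat * fy * length, -ankle_height])
        for name, (fx, fy) in template.items()
    }


def _seg_map(segments) -> dict[str, SegmentParameters]:
    return {s.name: s for s in segments}


def _spherical(bodies, joint_name, parent_name, offset, child: BodyNode):
    """Append a Y-X-Z intrinsic 3-DoF joint chain ending in ``child``."""
    parent = child.parent  # placeholder; resolved by name below
    del parent
    by = BodyNode(f"{joint_name}__y", -1, "revolute", _AX["y"], offset)
    bx = BodyNode(f"{joint_name}__x", -1, "revolute", _AX["x"], np.zeros(3))
    by.dof_name, bx.dof_name, child.dof_name = (
        f"{joint_name}_flex", f"{joint_name}_abd", f"{joint_name}_rot",
    )
    by._parent_name = parent_name
    bx._parent_name = by.name
    child._parent_name = bx.name
    child.joint_kind, child.joint_axis, child.joint_offset = "revolute", _AX["z"], np.zeros(3)
    bodies += [by, bx, child]


def _resolve_parents(bodies):
    index = {b.name: i for i, b in enumerate(bodies)}
    for b in bodies:
        pname = getattr(b, "_parent_name", None)
        if pname is not None:
            b.parent = index[pname] if pname != "<world>" else -1
    return bodies


def _base_chain(root_name: str) -> list[BodyNode]:
    """Floating base: x, y, z translation then yaw-pitch-roll."""
    chain = []
    prev = "<world>"
    for nm, kind, ax in [
        ("base_tx", "prismatic", "x"), ("base_ty", "prismatic", "y"),
        ("base_tz", "prismatic", "z"), ("base_yaw", "revolute", "z"),
        ("base_pitch", "revolute", "y"),
    ]:
        node = BodyNode(f"{root_name}:{nm}", -1, kind, _AX[ax], np.zeros(3))
        node.dof_name = nm
        node._parent_name = prev
        chain.append(node)
        prev = node.name
    return chain


def build_full_model(segments, leg_length=None, total_height=None, foot_template=None,
                     name="human43") -> MultibodyModel:
    """16-segment, 43-DoF whole-body model.

    ``segments`` is the output of :func:`gaitbench.anthropometry.de_leva_parameters`
    (optionally prosthesis-adjusted).  ``total_height`` defaults to the head
    segment length divided by its stature fraction implied by the shipped
    tables, but passing the subject's height is more direct.
    """
    return _build_human(segments, reduced=False, total_height=total_height,
                        foot_template=foot_template, name=name)


def build_reduced_model(segments, leg_length=None, total_height=None, foot_template=None,
                        name="human34") -> MultibodyModel:
    """13-segment, 34-DoF model: Xiphoid and both wrists locked.

    The upper trunk is rigidly merged into the mid trunk (segment ``trunk``)
    and each hand into its forearm, with composite COM and parallel-axis
    inertia; total mass is unchanged.
    """
    return _build_human(segments, reduced=True, total_height=total_height,
                        foot_template=foot_template, name=name)


def merge_segments(a: SegmentParameters, b: SegmentParameters, offset_b: np.ndarray,
                   name: str) -> SegmentParameters:
    """Rigidly merge segment ``b`` (frame at ``offset_b`` in ``a``'s frame,
    axis-aligned) into ``a``: composite mass, COM and parallel-axis inertia."""
    m = a.mass + b.mass
    com_b = offset_b + b.com_offset
    com = (a.mass * a.com_offset + b.mass * com_b) / m
    inertia = np.zeros((3, 3))
    for mass, I, c in ((a.mass, a.inertia, a.com_offset), (b.mass, b.inertia, com_b)):
        d = c - com
        inertia += I + mass * ((d @ d) * np.eye(3) - np.outer(d, d))
    return SegmentParameters(name, m, com, inertia, a.length + b.length)


def _build_human(segments, reduced, total_height, foot_template, name):
    seg = _seg_map(segments)
    required = {
        "pelvis", "mid_trunk", "upper_trunk", "head",
        "upper_arm_left", "upper_arm_right", "forearm_left", "forearm_right",
        "hand_left", "hand_right", "thigh_left", "thigh_right",
        "shank_left", "shank_right", "foot_left", "foot_right",
    }
    missing = required - set(seg)
    if missing:
        raise ConfigurationError(f"missing segments: {sorted(missing)}")
    if total_height is None:
        # stature implied by the shipped table's head length fraction
        total_height = seg["head"].length / 0.14
    H = total_height
    hip_hw, sh_hw, ankle_h = 0.052 * H, 0.115 * H, 0.04 * H

    def inertial(node: BodyNode, s: SegmentParameters, com, inertia=None):
        node.mass, node.com = s.mass, np.asarray(com, float)
        node.inertia = s.inertia if inertia is None else np.asarray(inertia, float)
        return node

    bodies = list(_base_chain(name))

    # pelvis carries the last base DoF (roll); frame origin at mid-hip
    pelv = seg["pelvis"]
    pelvis = BodyNode("pelvis", -1, "revolute", _AX["x"], np.zeros(3))
    pelvis.dof_name = "base_roll"
    pelvis._parent_name = f"{name}:base_pitch"
    inertial(pelvis, pelv, [0, 0, pelv.length + pelv.com_offset[2]])  # com_offset is -frac*L
    bodies.append(pelvis)

    mt, ut = seg["mid_trunk"], seg["upper_trunk"]
    if reduced:
        trunk_seg = merge_segments(
            SegmentParameters("mid_trunk", mt.mass, [0, 0, mt.length + mt.com_offset[2]],
                              mt.inertia, mt.length),
            SegmentParameters("upper_trunk", ut.mass, [0, 0, ut.length + ut.com_offset[2]],
                              ut.inertia, ut.length),
            offset_b=np.array([0, 0, mt.length]), name="trunk",
        )
        trunk = BodyNode("trunk", -1, "fixed", _AX["z"], np.zeros(3))
        trunk.mass, trunk.com, trunk.inertia = trunk_seg.mass, trunk_seg.com_offset, trunk_seg.inertia
        _spherical(bodies, "lumbosacral", "pelvis", np.array([0, 0, pelv.length]), trunk)
        shoulder_parent, shoulder_z = "trunk", mt.length + ut.length
        cerv_z = mt.length + ut.length
    else:
        mid = BodyNode("mid_trunk", -1, "fixed", _AX["z"], np.zeros(3))
        inertial(mid, mt, [0, 0, mt.length + mt.com_offset[2]])
        _spherical(bodies, "lumbosacral", "pelvis", np.array([0, 0, pelv.length]), mid)
        upper = BodyNode("upper_trunk", -1, "fixed", _AX["z"], np.zeros(3))
        inertial(upper, ut, [0, 0, ut.length + ut.com_offset[2]])
        _spherical(bodies, "xiphoid", "mid_trunk", np.array([0, 0, mt.length]), upper)
        shoulder_parent, shoulder_z = "upper_trunk", ut.length
        cerv_z = ut.length

    hd = seg["head"]
    head = BodyNode("head", -1, "fixed", _AX["z"], np.zeros(3))
    inertial(head, hd, [0, 0, hd.length + hd.com_offset[2]])
    _spherical(bodies, "cervicale", shoulder_parent, np.array([0, 0, cerv_z]), head)

    for side, sgn in (("left", 1.0), ("right", -1.0)):
        ua, fa, ha = seg[f"upper_arm_{side}"], seg[f"forearm_{side}"], seg[f"hand_{side}"]
        arm = BodyNode(f"upper_arm_{side}", -1, "fixed", _AX["z"], np.zeros(3))
        inertial(arm, ua, ua.com_offset)
        _spherical(bodies, f"shoulder_{side}", shoulder_parent,
                   np.array([0, sgn * sh_hw, shoulder_z]), arm)
        if reduced:
            fa_seg = merge_segments(fa, ha, offset_b=np.array([0, 0, -fa.length]),
                                    name=f"forearm_{side}")
            fore = BodyNode(f"forearm_{side}", -1, "revolute", _AX["y"],
                            np.array([0, 0, -ua.length]))
            fore.dof_name = f"elbow_{side}"
            fore._parent_name = f"upper_arm_{side}"
            fore.mass, fore.com, fore.inertia = fa_seg.mass, fa_seg.com_offset, fa_seg.inertia
            bodies.append(fore)
        else:
            fore = BodyNode(f"forearm_{side}", -1, "revolute", _AX["y"],
                            np.array([0, 0, -ua.length]))
            fore.dof_name = f"elbow_{side}"
            fore._parent_name = f"upper_arm_{side}"
            inertial(fore, fa, fa.com_offset)
            bodies.append(fore)
            hand = BodyNode(f"hand_{side}", -1, "fixed", _AX["z"], np.zeros(3))
            inertial(hand, ha, ha.com_offset)
            _spherical(bodies, f"wrist_{side}", f"forearm_{side}",
                       np.array([0, 0, -fa.length]), hand)

        th, sh, ft = seg[f"thigh_{side}"], seg[f"shank_{side}"], seg[f"foot_{side}"]
        thigh = BodyNode(f"thigh_{side}", -1, "fixed", _AX["z"], np.zeros(3))
        inertial(thigh, th, th.com_offset)
        _spherical(bodies, f"hip_{side}", "pelvis", np.array([0, sgn * hip_hw, 0]), thigh)
        shank = BodyNode(f"shank_{side}", -1, "revolute", _AX["y"],
                         np.array([0, 0, -th.length]))
        shank.dof_name = f"knee_{side}"
        shank._parent_name = f"thigh_{side}"
        inertial(shank, sh, sh.com_offset)
        bodies.append(shank)
        foot = BodyNode(f"foot_{side}", -1, "fixed", _AX["z"], np.zeros(3))
        # foot longitudinal axis is anterior (x); COM from the table's
        # COM fraction measured from the heel, ankle 0.25 L_f ahead of it
        rg = np.sqrt(np.diag(ft.inertia) / max(ft.mass, 1e-12))  # [trans, sag, long] radii
        foot_inertia = ft.mass * np.diag([rg[2] ** 2, rg[1] ** 2, rg[0] ** 2])
        com_x = (abs(ft.com_offset[2]) / max(ft.length, 1e-12) - 0.25) * ft.length
        foot.mass = ft.mass
        foot.com = np.array([com_x, 0.0, -0.5 * ankle_h])
        foot.inertia = foot_inertia
        _spherical(bodies, f"ankle_{side}", f"shank_{side}",
                   np.array([0, 0, -sh.length]), foot)

    _resolve_parents(bodies)
    foot_geometry = {
        side: {
            pt: (f"foot_{side}", off)
            for pt, off in _foot_points(seg[f"foot_{side}"].length, ankle_h, side,
                                        foot_template).items()
        }
        for side in ("left", "right")
    }
    segment_names = [b.name for b in bodies if b.mass > 0]
    return MultibodyModel(bodies, base_dof=6, segments=segment_names,
                          foot_geometry=foot_geometry, name=name)


# ---------------------------------------------------------------------------
# planar walker fixture model
# ---------------------------------------------------------------------------

def build_planar_walker(total_mass: float = 75.0, total_height: float = 1.75,
                        name: str = "walker9") -> MultibodyModel:
    """Planar 7-segment walker: HAT + two (thigh, shank, foot) chains, 9 DoF.

    The base is sagittal only (x, z translation and pitch); hips, knees and
    ankles are pitch revolutes, so motion started in the sagittal plane stays
    there while the model remains a 3-D rigid-body system.  Inertial
    parameters lump head, arms and trunk into a single HAT segment using the
    male regression fractions.
    """
    H, M = total_height, total_mass
    hat_m = 0.678 * M  # head + trunk + both arms
    thigh_m, shank_m, foot_m = 0.1416 * M, 0.0433 * M, 0.0137 * M
    thigh_l, shank_l, foot_l = 0.2425 * H, 0.2493 * H, 0.1482 * H
    ankle_h, hip_hw = 0.04 * H, 0.052 * H

    bodies = []
    prev = "<world>"
    for nm, kind, ax in [("base_tx", "prismatic", "x"), ("base_tz", "prismatic", "z")]:
        node = BodyNode(f"{name}:{nm}", -1, kind, _AX[ax], np.zeros(3))
        node.dof_name = nm
        node._parent_name = prev
        bodies.append(node)
        prev = node.name
    hat = BodyNode("hat", -1, "revolute", _AX["y"], np.zeros(3))
    hat.dof_name = "base_pitch"
    hat._parent_name = prev
    hat.mass = hat_m
    hat.com = np.array([0.0, 0.0, 0.30 * H])
    rg = 0.25 * H
    hat.inertia = hat_m * np.diag([rg ** 2, rg ** 2, (0.12 * H) ** 2])
    bodies.append(hat)

    for side, sgn in (("left", 1.0), ("right", -1.0)):
        thigh = BodyNode(f"thigh_{side}", -1, "revolute", _AX["y"],
                         np.array([0, sgn * hip_hw, 0]))
        thigh.dof_name = f"hip_{side}"
        thigh._parent_name = "hat"
        thigh.mass = thigh_m
        thigh.com = np.array([0, 0, -0.41 * thigh_l])
        thigh.inertia = thigh_m * np.diag([(0.329 * thigh_l) ** 2, (0.329 * thigh_l) ** 2,
                                           (0.149 * thigh_l) ** 2])
        shank = BodyNode(f"shank_{side}", -1, "revolute", _AX["y"],
                         np.array([0, 0, -thigh_l]))
        shank.dof_name = f"knee_{side}"
        shank._parent_name = f"thigh_{side}"
        shank.mass = shank_m
        shank.com = np.array([0, 0, -0.446 * shank_l])
        shank.inertia = shank_m * np.diag([(0.255 * shank_l) ** 2, (0.249 * shank_l) ** 2,
                                           (0.103 * shank_l) ** 2])
        foot = BodyNode(f"foot_{side}", -1, "revolute", _AX["y"],
                        np.array([0, 0, -shank_l]))
        foot.dof_name = f"ankle_{side}"
        foot._parent_name = f"shank_{side}"
        foot.mass = foot_m
        foot.com = np.array([0.19 * foot_l, 0, -0.5 * ankle_h])
        foot.inertia = foot_m * np.diag([(0.124 * foot_l) ** 2, (0.257 * foot_l) ** 2,
                                         (0.245 * foot_l) ** 2])
        bodies += [thigh, shank, foot]

    _resolve_parents(bodies)
    foot_geometry = {
        side: {pt: (f"foot_{side}", off)
               for pt, off in _foot_points(foot_l, ankle_h, side).items()}
        for side in ("left", "right")
    }
    return MultibodyModel(bodies, base_dof=3,
                          segments=["hat"] + [f"{s}_{side}" for side in ("left", "right")
                                              for s in ("thigh", "shank", "foot")],
                          foot_geometry=foot_geometry, name=name)


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------

def model_to_yaml(model: MultibodyModel) -> str:
    """Serialise a model description (segments, joints, contact points)."""
    doc = {
        "name": model.name,
        "base_dof": model.base_dof,
        "segments": model.segments,
        "bodies": [
            {
                "name": b.name,
                "parent": model.bodies[b.parent].name if b.parent >= 0 else None,
                "joint": {"kind": b.joint_kind, "axis": b.joint_axis.tolist(),
                          "offset": b.joint_offset.tolist(), "dof_name": b.dof_name},
                "mass": float(b.mass),
                "com": b.com.tolist(),
                "inertia": b.inertia.tolist(),
            }
            for b in model.bodies
        ],
        "foot_geometry": {
            side: {pt: {"body": body, "offset": np.asarray(off).tolist()}
                   for pt, (body, off) in pts.items()}
            for side, pts in model.foot_geometry.items()
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def model_from_yaml(text: str) -> MultibodyModel:
    doc = yaml.safe_load(text)
    bodies = []
    index = {}
    for i, bd in enumerate(doc["bodies"]):
        node = BodyNode(
            bd["name"],
            index[bd["parent"]] if bd["parent"] is not None else -1,
            bd["joint"]["kind"], np.array(bd["joint"]["axis"]),
            np.array(bd["joint"]["offset"]),
            mass=bd["mass"], com=np.array(bd["com"]), inertia=np.array(bd["inertia"]),
        )
        node.dof_name = bd["joint"].get("dof_name", "")
        bodies.append(node)
        index[bd["name"]] = i
    foot_geometry = {
        side: {pt: (spec["body"], np.array(spec["offset"]))
               for pt, spec in pts.items()}
        for side, pts in doc.get("foot_geometry", {}).items()
    }
    return MultibodyModel(bodies, base_dof=doc["base_dof"], segments=doc.get("segments"),
                          foot_geometry=foot_geometry, name=doc.get("name", "model"))
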