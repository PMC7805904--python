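"""Sex-specific body-segment inertial-parameter regression table.

Values follow de Leva's adjusted Zatsiorsky-Seluyanov regressions: per segment,
the mass as a fraction of total body mass, the segment length as a fraction of
stature, the longitudinal COM position as a fraction of segment length measured
from the proximal end, and the three radii of gyration (sagittal, transverse,
longitudinal) as fractions of segment length.

The table is versioned with the package: tests pin these exact numbers, and any
revision must bump ``TABLE_VERSION``.  Mass fractions are normalised at load
time so that they sum to one exactly (the raw published fractions round to
99.99-100.00%).

Longitudinal reference landmarks (our convention, documented here once):
segment frames sit at the proximal joint centre with the longitudinal axis
pointing towards the distal end; COM offsets and radii of gyration are applied
along/about that axis.
"""

TABLE_VERSION = "deleva-1996-adjusted-zs-v1"

#: segment -> (mass fraction %, length fraction of stature,
#:             com % from proximal, rg_sagittal %, rg_transverse %, rg_longitudinal %)
FEMALE = {
    "head": (6.68, 0.1405, 48.41, 27.1, 29.5, 26.1),
    "upper_trunk": (15.45, 0.0821, 20.77, 74.6, 50.2, 71.8),
    "mid_trunk": (14.65, 0.1183, 45.12, 43.3, 35.4, 41.5),
    "pelvis": (12.47, 0.1046, 49.20, 43.3, 40.2, 44.4),
    "upper_arm_left": (2.55, 0.1586, 57.54, 27.8, 26.0, 14.8),
    "upper_arm_right": (2.55, 0.1586, 57.54, 27.8, 26.0, 14.8),
    "forearm_left": (1.38, 0.1523, 45.59, 26.1, 25.7, 9.4),
    "forearm_right": (1.38, 0.1523, 45.59, 26.1, 25.7, 9.4),
    "hand_left": (0.56, 0.0450, 74.74, 53.1, 45.4, 33.5),
    "hand_right": (0.56, 0.0450, 74.74, 53.1, 45.4, 33.5),
    "thigh_left": (14.78, 0.2124, 36.12, 36.9, 36.4, 16.2),
    "thigh_right": (14.78, 0.2124, 36.12, 36.9, 36.4, 16.2),
    "shank_left": (4.81, 0.2528, 44.16, 27.1, 26.7, 9.3),
    "shank_right": (4.81, 0.2528, 44.16, 27.1, 26.7, 9.3),
    "foot_left": (1.29, 0.1316, 40.14, 29.9, 27.9, 13.9),
    "foot_right": (1.29, 0.1316, 40.14, 29.9, 27.9, 13.9),
}

MALE = {
    "head": (6.94, 0.1395, 50.02, 30.3, 31.5, 26.1),
    "upper_trunk": (15.96, 0.0981, 29.99, 71.6, 45.4, 65.9),
    "mid_trunk": (16.33, 0.1238, 45.02, 48.2, 38.3, 46.8),
    "pelvis": (11.17, 0.0837, 61.15, 61.5, 55.1, 58.7),
    "upper_arm_left": (2.71, 0.1618, 57.72, 28.5, 26.9, 15.8),
    "upper_arm_right": (2.71, 0.1618, 57.72, 28.5, 26.9, 15.8),
    "forearm_left": (1.62, 0.1545, 45.74, 27.6, 26.5, 12.1),
    "forearm_right": (1.62, 0.1545, 45.74, 27.6, 26.5, 12.1),
    "hand_left": (0.61, 0.0495, 79.00, 62.8, 51.3, 40.1),
    "hand_right": (0.61, 0.0495, 79.00, 62.8, 51.3, 40.1),
    "thigh_left": (14.16, 0.2425, 40.95, 32.9, 32.9, 14.9),
    "thigh_right": (14.16, 0.2425, 40.95, 32.9, 32.9, 14.9),
    "shank_left": (4.33, 0.2493, 44.59, 25.5, 24.9, 10.3),
    "shank_right": (4.33, 0.2493, 44.59, 25.5, 24.9, 10.3),
    "foot_left": (1.37, 0.1482, 44.15, 25.7, 24.5, 12.4),
    "foot_right": (1.37, 0.1482, 44.15, 25.7, 24.5, 12.4),
}

SEGMENT_NAMES = tuple(MALE.keys())
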