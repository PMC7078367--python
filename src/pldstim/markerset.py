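"""The 41-marker full-body marker set and its joint reduction table.

Layout follows the full-body optical capture convention of a headband
cluster plus torso, waist, arm and leg clusters with hinged-toe markers
(41 labels total).  The reduction table maps each of the 13 canonical
point-light joints to the marker cluster whose centroid stands for it.
"""

from __future__ import annotations

import numpy as np

from .clips import JOINT_NAMES

#: 41 marker labels: headband (3), torso (4), waist (4), shoulders (4),
#: upper arms (2), elbows (2), wrists (4), hands (2), thighs (2), knees (2),
#: shins (2), ankles (2), heels (2), hinged toes (6).
MARKER_LABELS_41: tuple[str, ...] = (
    "HeadTop", "HeadFront", "HeadSide",
    "Chest", "BackTop", "BackLeft", "BackRight",
    "WaistLFront", "WaistRFront", "WaistLBack", "WaistRBack",
    "LShoulderTop", "LShoulderBack", "RShoulderTop", "RShoulderBack",
    "LUArmHigh", "RUArmHigh",
    "LElbowOut", "RElbowOut",
    "LWristIn", "LWristOut", "RWristIn", "RWristOut",
    "LHandOut", "RHandOut",
    "LThigh", "RThigh",
    "LKneeOut", "RKneeOut",
    "LShin", "RShin",
    "LAnkleOut", "RAnkleOut",
    "LHeel", "RHeel",
    "LToeIn", "LToeOut", "LToeTip", "RToeIn", "RToeOut", "RToeTip",
)

assert len(MARKER_LABELS_41) == 41

#: Joint -> marker-cluster reduction table (centroid of each cluster).
DEFAULT_JOINT_MAPPING: dict[str, list[str]] = {
    "head": ["HeadTop", "HeadFront", "HeadSide"],
    "l_shoulder": ["LShoulderTop", "LShoulderBack"],
    "r_shoulder": ["RShoulderTop", "RShoulderBack"],
    "l_elbow": ["LElbowOut"],
    "r_elbow": ["RElbowOut"],
    "l_wrist": ["LWristIn", "LWristOut"],
    "r_wrist": ["RWristIn", "RWristOut"],
    "l_hip": ["WaistLFront", "WaistLBack"],
    "r_hip": ["WaistRFront", "WaistRBack"],
    "l_knee": ["LKneeOut"],
    "r_knee": ["RKneeOut"],
    "l_ankle": ["LAnkleOut"],
    "r_ankle": ["RAnkleOut"],
}

#: Markers not mapped to any joint ride along on a nearby joint (or a pair
#: of joints, interpolated) when a joint clip is expanded back to markers.
_CARRIER: dict[str, tuple[str, str, float]] = {
    # label -> (joint_a, joint_b, weight of joint_a); position is
    # w*a + (1-w)*b plus a fixed offset.
    "Chest": ("l_shoulder", "r_shoulder", 0.5),
    "BackTop": ("l_shoulder", "r_shoulder", 0.5),
    "BackLeft": ("l_shoulder", "l_hip", 0.5),
    "BackRight": ("r_shoulder", "r_hip", 0.5),
    "LUArmHigh": ("l_shoulder", "l_elbow", 0.5),
    "RUArmHigh": ("r_shoulder", "r_elbow", 0.5),
    "LHandOut": ("l_wrist", "l_wrist", 1.0),
    "RHandOut": ("r_wrist", "r_wrist", 1.0),
    "LThigh": ("l_hip", "l_knee", 0.5),
    "RThigh": ("r_hip", "r_knee", 0.5),
    "LShin": ("l_knee", "l_ankle", 0.5),
    "RShin": ("r_knee", "r_ankle", 0.5),
    "LHeel": ("l_ankle", "l_ankle", 1.0),
    "RHeel": ("r_ankle", "r_ankle", 1.0),
    "LToeIn": ("l_ankle", "l_ankle", 1.0),
    "LToeOut": ("l_ankle", "l_ankle", 1.0),
    "LToeTip": ("l_ankle", "l_ankle", 1.0),
    "RToeIn": ("r_ankle", "r_ankle", 1.0),
    "RToeOut": ("r_ankle", "r_ankle", 1.0),
    "RToeTip": ("r_ankle", "r_ankle", 1.0),
}

# Fixed, zero-mean offsets (meters) for each mapped cluster so that the
# cluster centroid recovers the joint exactly.  Cluster half-spacings are
# a few centimeters, like physical marker placements.
_CLUSTER_OFFSETS: dict[str, np.ndarray] = {
    "head": np.array([[0.0, 0.06, 0.0], [0.0, -0.03, 0.05], [0.05, -0.03, -0.05]]) - np.array(
        [[0.0, 0.06, 0.0], [0.0, -0.03, 0.05], [0.05, -0.03, -0.05]]
    ).mean(axis=0),
    "l_shoulder": np.array([[0.0, 0.03, 0.0], [0.0, -0.03, -0.04]]) / 1.0,
    "r_shoulder": np.array([[0.0, 0.03, 0.0], [0.0, -0.03, -0.04]]) / 1.0,
    "l_elbow": np.zeros((1, 3)),
    "r_elbow": np.zeros((1, 3)),
    "l_wrist": np.array([[0.025, 0.0, 0.0], [-0.025, 0.0, 0.0]]),
    "r_wrist": np.array([[0.025, 0.0, 0.0], [-0.025, 0.0, 0.0]]),
    "l_hip": np.array([[0.0, 0.0, 0.06], [0.0, 0.0, -0.06]]),
    "r_hip": np.array([[0.0, 0.0, 0.06], [0.0, 0.0, -0.06]]),
    "l_knee": np.zeros((1, 3)),
    "r_knee": np.zeros((1, 3)),
    "l_ankle": np.zeros((1, 3)),
    "r_ankle": np.zeros((1, 3)),
}
# re-center the shoulder pairs so each cluster is exactly zero-mean
for _k in ("l_shoulder", "r_shoulder"):
    _CLUSTER_OFFSETS[_k] = _CLUSTER_OFFSETS[_k] - _CLUSTER_OFFSETS[_k].mean(axis=0)

_CARRIER_OFFSETS: dict[str, np.ndarray] = {
    "Chest": np.array([0.0, -0.06, 0.08]),
    "BackTop": np.array([0.0, 0.0, -0.08]),
    "BackLeft": np.array([0.0, 0.0, -0.09]),
    "BackRight": np.array([0.0, 0.0, -0.09]),
    "LUArmHigh": np.array([0.03, 0.0, 0.0]),
    "RUArmHigh": np.array([-0.03, 0.0, 0.0]),
    "LHandOut": np.array([0.03, -0.06, 0.02]),
    "RHandOut": np.array([-0.03, -0.06, 0.02]),
    "LThigh": np.array([0.05, 0.0, 0.02]),
    "RThigh": np.array([-0.05, 0.0, 0.02]),
    "LShin": np.array([0.04, 0.0, 0.01]),
    "RShin": np.array([-0.04, 0.0, 0.01]),
    "LHeel": np.array([0.0, -0.03, -0.07]),
    "RHeel": np.array([0.0, -0.03, -0.07]),
    "LToeIn": np.array([-0.02, -0.05, 0.12]),
    "LToeOut": np.array([0.03, -0.05, 0.12]),
    "LToeTip": np.array([0.0, -0.06, 0.18]),
    "RToeIn": np.array([0.02, -0.05, 0.12]),
    "RToeOut": np.array([-0.03, -0.05, 0.12]),
    "RToeTip": np.array([0.0, -0.06, 0.18]),
}

_MAPPED_LABELS = {m for cluster in DEFAULT_JOINT_MAPPING.values() for m in cluster}
assert _MAPPED_LABELS | set(_CARRIER) == set(MARKER_LABELS_41)
assert set(DEFAULT_JOINT_MAPPING) == set(JOINT_NAMES)
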