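"""Parametric human-like motion fixtures.

Real point-light databases are built from motion capture of actors; this
module generates plausible stand-ins so the whole pipeline (reduction,
composition, display manipulation, rendering, validation studies) can be
exercised without any recorded data.  Clips follow the capture protocol
conventions: 3-second actions sampled at 120 Hz, an initiating agent
moving from T = 0 s and a responding agent starting at T = 1.5 s.

The gait model is a set of sinusoidal joint oscillators on a fixed
skeleton — not biomechanics, just periodic, phase-opposed limb motion
with the right spatial scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clips import JOINT_NAMES, N_JOINTS, ClipError, JointClip, MarkerClip
from .io import write_joint_clip
from .markerset import (
    _CARRIER,
    _CARRIER_OFFSETS,
    _CLUSTER_OFFSETS,
    DEFAULT_JOINT_MAPPING,
    MARKER_LABELS_41,
)

#: The six stimulus categories: communicative gestures (initiator/response
#: takes), emotional exchanges, synchronous activity, and object-/non-object-
#: related individual actions.
CATEGORIES = ("COM_A", "COM_B", "HAPPY", "ANGRY", "SYNC", "ORA", "NORA")

DEFAULT_DURATION = 3.0
DEFAULT_RATE = 120.0
RESPONDER_ONSET = 1.5

_J = {name: i for i, name in enumerate(JOINT_NAMES)}


def neutral_pose(stance_height: float = 0.95) -> np.ndarray:
    """Upright standing pose (13 x 3), arms slightly out, facing +z."""
    hips_y = stance_height
    shoulders_y = hips_y + 0.50
    pose = np.zeros((N_JOINTS, 3))
    pose[_J["head"]] = (0.0, shoulders_y + 0.25, 0.0)
    pose[_J["l_shoulder"]] = (-0.20, shoulders_y, 0.0)
    pose[_J["r_shoulder"]] = (0.20, shoulders_y, 0.0)
    pose[_J["l_elbow"]] = (-0.33, shoulders_y - 0.28, 0.0)
    pose[_J["r_elbow"]] = (0.33, shoulders_y - 0.28, 0.0)
    pose[_J["l_wrist"]] = (-0.38, shoulders_y - 0.55, 0.0)
    pose[_J["r_wrist"]] = (0.38, shoulders_y - 0.55, 0.0)
    pose[_J["l_hip"]] = (-0.12, hips_y, 0.0)
    pose[_J["r_hip"]] = (0.12, hips_y, 0.0)
    pose[_J["l_knee"]] = (-0.13, hips_y * 0.52, 0.0)
    pose[_J["r_knee"]] = (0.13, hips_y * 0.52, 0.0)
    pose[_J["l_ankle"]] = (-0.14, 0.08, 0.0)
    pose[_J["r_ankle"]] = (0.14, 0.08, 0.0)
    return pose


@dataclass
class GaitParams:
    """Parameters of the sinusoidal walker.

    ``cycle_freq`` is the full gait-cycle frequency (one left+right stride)
    in Hz; amplitudes are peak joint excursions in meters; ``noise_sd`` adds
    a per-joint constant placement jitter (like marker placement error), so
    clips stay periodic.
    """

    cycle_freq: float = 1.0
    ankle_amplitude: float = 0.30
    wrist_amplitude: float = 0.20
    knee_lift: float = 0.06
    vertical_bob: float = 0.03
    stance_height: float = 0.95
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_freq <= 0:
            raise ClipError("cycle_freq must be positive")
        if self.noise_sd < 0:
            raise ClipError("noise_sd must be non-negative")


@dataclass
class ActionScript:
    """Keyframed action: sparse (time, pose) pairs, linearly interpolated.

    ``keyframes`` maps times in seconds to partial poses: a dict of joint
    name -> (x, y, z).  Joints never mentioned hold the neutral pose.
    """

    role: str = "solo"  # initiator | responder | solo
    keyframes: list[tuple[float, dict[str, tuple[float, float, float]]]] = field(
        default_factory=list
    )
    onset: float = 0.0
    category: str = "NORA"

    def __post_init__(self) -> None:
        if self.role not in ("initiator", "responder", "solo"):
            raise ClipError(f"unknown role {self.role!r}")
        times = [t for t, _ in self.keyframes]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ClipError("keyframe times must be non-decreasing")
        if self.category not in CATEGORIES:
            raise ClipError(f"category {self.category!r} not one of {CATEGORIES}")


def make_walker(
    params: GaitParams | None = None,
    duration: float = DEFAULT_DURATION,
    rate: float = DEFAULT_RATE,
) -> JointClip:
    """Generate an in-place walking clip.

    Contralateral limbs are phase-opposed by pi: the left ankle leads the
    right ankle by half a gait cycle, and each wrist swings opposite its
    ipsilateral ankle.
    """
    params = params or GaitParams()
    if duration <= 0 or rate <= 0:
        raise ClipError("duration and rate must be positive")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    w = 2 * np.pi * params.cycle_freq
    base = neutral_pose(params.stance_height)
    pos = np.repeat(base[None, :, :], n, axis=0)

    la, ra = _J["l_ankle"], _J["r_ankle"]
    lk, rk = _J["l_knee"], _J["r_knee"]
    lw, rw = _J["l_wrist"], _J["r_wrist"]
    le, re_ = _J["l_elbow"], _J["r_elbow"]

    swing = np.sin(w * t)
    # legs: forward-back (z) swing, phase-opposed; feet lift on the swing phase
    pos[:, la, 2] += params.ankle_amplitude * swing
    pos[:, ra, 2] += params.ankle_amplitude * np.sin(w * t + np.pi)
    pos[:, la, 1] += params.knee_lift * np.clip(np.cos(w * t), 0, None)
    pos[:, ra, 1] += params.knee_lift * np.clip(np.cos(w * t + np.pi), 0, None)
    pos[:, lk, 2] += 0.5 * params.ankle_amplitude * swing
    pos[:, rk, 2] += 0.5 * params.ankle_amplitude * np.sin(w * t + np.pi)
    # arms: counter-swing to the ipsilateral leg
    pos[:, lw, 2] += params.wrist_amplitude * np.sin(w * t + np.pi)
    pos[:, rw, 2] += params.wrist_amplitude * swing
    pos[:, le, 2] += 0.5 * params.wrist_amplitude * np.sin(w * t + np.pi)
    pos[:, re_, 2] += 0.5 * params.wrist_amplitude * swing
    # trunk bob at twice the cycle frequency (two steps per cycle)
    upper = [_J[j] for j in ("head", "l_shoulder", "r_shoulder", "l_hip", "r_hip")]
    pos[:, upper, 1] += params.vertical_bob * np.sin(2 * w * t)[:, None]

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        pos += rng.normal(0.0, params.noise_sd, size=(1, N_JOINTS, 3))

    return JointClip(
        positions=pos,
        rate=rate,
        events={"onset": 0.0, "midpoint": duration / 2, "offset": duration},
        meta={"generator": "walker", "seed": params.seed, "category": "NORA"},
    )


def make_gesture(
    script: ActionScript,
    duration: float = DEFAULT_DURATION,
    rate: float = DEFAULT_RATE,
) -> JointClip:
    """Render a keyframed gesture as a joint clip.

    Poses are linearly interpolated between keyframes; before the first and
    after the last keyframe the pose holds.  With no keyframes the clip is a
    static neutral stance.
    """
    if duration <= 0 or rate <= 0:
        raise ClipError("duration and rate must be positive")
    for kf_t, _ in script.keyframes:
        if not (0.0 <= kf_t <= duration):
            raise ClipError(f"keyframe at {kf_t} s outside [0, {duration}] s")
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    base = neutral_pose()

    # dense keyframe poses: partial keyframes override the neutral pose
    times = [kf_t for kf_t, _ in script.keyframes]
    poses = []
    for _, partial in script.keyframes:
        pose = base.copy()
        for joint, xyz in partial.items():
            pose[_J[joint]] = xyz
        poses.append(pose)

    if not poses:
        pos = np.repeat(base[None], n, axis=0)
    else:
        knots_t = np.array([0.0] + times + [duration]) if times[0] > 0 else np.array(
            times + [duration]
        )
        knots_p = ([base] + poses + [poses[-1]]) if times[0] > 0 else (poses + [poses[-1]])
        knots = np.stack(knots_p).reshape(len(knots_p), -1)
        flat = np.empty((n, knots.shape[1]))
        for c in range(knots.shape[1]):
            flat[:, c] = np.interp(t, knots_t, knots[:, c])
        pos = flat.reshape(n, N_JOINTS, 3)

    return JointClip(
        positions=pos,
        rate=rate,
        events={"onset": script.onset, "offset": duration},
        meta={"generator": "gesture", "role": script.role, "category": script.category},
    )


def make_dyad_fixture(
    scriptA: ActionScript,
    scriptB: ActionScript,
    onsetB: float = RESPONDER_ONSET,
    duration: float = DEFAULT_DURATION,
    rate: float = DEFAULT_RATE,
) -> tuple[JointClip, JointClip]:
    """Sequential two-agent choreography.

    Agent A acts from T = 0; Agent B holds a neutral stance (exactly
    motionless) until ``onsetB`` — by default the mid-clip cue at 1.5 s —
    then performs its scripted response with keyframe times re-based to the
    onset.
    """
    if not (0.0 <= onsetB < duration):
        raise ClipError(f"onsetB {onsetB} outside [0, {duration}) s")
    clipA = make_gesture(scriptA, duration, rate)

    shifted = ActionScript(
        role="responder",
        keyframes=[(min(onsetB + kf_t, duration), pose) for kf_t, pose in scriptB.keyframes],
        onset=onsetB,
        category=scriptB.category,
    )
    if shifted.keyframes and onsetB > 0:
        # pin the neutral pose through the waiting period
        shifted.keyframes = [(onsetB, {})] + shifted.keyframes
    clipB = make_gesture(shifted, duration, rate)
    # hard guarantee: B does not move a hair before its onset
    n_pre = int(round(onsetB * rate))
    if n_pre > 0:
        clipB.positions[:n_pre] = clipB.positions[0]
    clipA.events["responder_onset"] = onsetB
    clipB.events["responder_onset"] = onsetB
    return clipA, clipB


def expand_to_markers(clip: JointClip) -> MarkerClip:
    """Expand a 13-joint clip to the 41-marker full-body layout.

    Mapped clusters are placed with fixed zero-mean offsets around their
    joint, so reducing the result with the default mapping recovers the
    joint trajectory exactly; the remaining markers ride on interpolated
    segment positions.
    """
    n = clip.n_frames
    out = np.zeros((n, len(MARKER_LABELS_41), 3))
    col = {label: i for i, label in enumerate(MARKER_LABELS_41)}
    jpos = clip.positions
    for joint, cluster in DEFAULT_JOINT_MAPPING.items():
        offsets = _CLUSTER_OFFSETS[joint]
        j = _J[joint]
        for m, off in zip(cluster, offsets):
            out[:, col[m], :] = jpos[:, j, :] + off
    for label, (ja, jb, wa) in _CARRIER.items():
        anchor = wa * jpos[:, _J[ja], :] + (1 - wa) * jpos[:, _J[jb], :]
        out[:, col[label], :] = anchor + _CARRIER_OFFSETS[label]
    return MarkerClip(
        labels=list(MARKER_LABELS_41),
        positions=out,
        rate=clip.rate,
        events=dict(clip.events),
        meta=dict(clip.meta),
    )


# --------------------------------------------------------------------------
# catalog fixture
# --------------------------------------------------------------------------


def _arm_raise_script(role: str, category: str, peak: float, side: str = "r") -> ActionScript:
    wrist = f"{side}_wrist"
    elbow = f"{side}_elbow"
    base = neutral_pose()
    up = {
        wrist: (float(base[_J[wrist], 0]), peak, 0.15),
        elbow: (float(base[_J[elbow], 0]), peak - 0.25, 0.10),
    }
    return ActionScript(
        role=role,
        keyframes=[(0.0, {}), (0.7, up), (1.2, up), (1.5, {})],
        category=category,
    )


def _crouch_script(role: str, category: str, depth: float = 0.45) -> ActionScript:
    base = neutral_pose()
    down = {}
    for j in ("head", "l_shoulder", "r_shoulder", "l_hip", "r_hip", "l_knee", "r_knee"):
        x, y, z = base[_J[j]]
        down[j] = (float(x), float(y - depth), float(z + 0.05))
    return ActionScript(role=role, keyframes=[(0.0, {}), (0.8, down), (1.4, {})], category=category)


def make_catalog_fixture(
    seed: int,
    out_dir: str | Path,
    duration: float = DEFAULT_DURATION,
    rate: float = DEFAULT_RATE,
) -> dict:
    """Generate a small action catalog with clips on disk.

    Produces at least two entries per category; communicative initiator
    takes (COM_A) carry ``congruent_partners`` links to their scripted
    responses (COM_B), and paired-situation categories (HAPPY / ANGRY /
    SYNC) share a ``situation`` tag.  Deterministic for a given seed.

    Returns the manifest dict (also written to ``catalog.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries = []

    def emit(action_id, category, clip, actor, situation=None, partners=()):
        fname = f"{action_id}.json"
        clip.meta.update({"action_id": action_id, "category": category, "actor_id": actor})
        write_joint_clip(clip, out_dir / fname)
        entries.append(
            {
                "action_id": action_id,
                "category": category,
                "actor_id": actor,
                "clip": fname,
                "situation": situation,
                "congruent_partners": list(partners),
            }
        )

    # COM: two situations, initiator + response each
    for i, (sit, maker) in enumerate(
        [("come_closer", _arm_raise_script), ("squat_down", _arm_raise_script)]
    ):
        peak = 1.55 + 0.1 * i + 0.02 * rng.standard_normal()
        a_script = maker("initiator", "COM_A", peak=peak)
        if sit == "squat_down":
            b_script = _crouch_script("responder", "COM_B")
        else:
            b_script = _arm_raise_script("responder", "COM_B", peak=peak - 0.1, side="l")
        clip_a, clip_b = make_dyad_fixture(a_script, b_script, duration=duration, rate=rate)
        emit(f"{sit}_A", "COM_A", clip_a, actor=f"M{i+1}", situation=sit,
             partners=[f"{sit}_B"])
        emit(f"{sit}_B", "COM_B", clip_b, actor=f"M{2-i}", situation=sit)

    # HAPPY / ANGRY: paired exchanges, both agents of a situation
    for category, sits in (("HAPPY", ["jumping_for_joy", "enjoying_success"]),
                           ("ANGRY", ["denying_accusations", "taking_the_blame"])):
        for k, sit in enumerate(sits):
            amp = 0.25 + 0.05 * rng.random()
            for agent in ("A", "B"):
                script = _arm_raise_script("solo", category, peak=1.5 + amp,
                                           side="l" if agent == "A" else "r")
                clip = make_gesture(script, duration, rate)
                emit(f"{sit}_{agent}", category, clip, actor=f"F{k+1}", situation=sit)

    # SYNC: synchronized whole-body activity, both agents share the clip shape
    for k, sit in enumerate(["dancing", "boxing"]):
        freq = 0.8 + 0.2 * k
        for agent in ("A", "B"):
            clip = make_walker(
                GaitParams(cycle_freq=freq, ankle_amplitude=0.22, seed=seed + 31 * k),
                duration,
                rate,
            )
            clip.meta["category"] = "SYNC"
            emit(f"{sit}_{agent}", "SYNC", clip, actor=f"M{k+1}", situation=sit)

    # ORA / NORA: individual actions
    for k, sit in enumerate(["hammering", "sweeping"]):
        script = _arm_raise_script("solo", "ORA", peak=1.3 + 0.1 * k)
        emit(f"{sit}", "ORA", make_gesture(script, duration, rate), actor=f"F{k+1}",
             situation=sit)
    for k, (sit, freq) in enumerate([("walking", 1.0), ("hip_swinging", 0.7)]):
        clip = make_walker(GaitParams(cycle_freq=freq, seed=seed + 7 * k), duration, rate)
        clip.meta["category"] = "NORA"
        emit(f"{sit}", "NORA", clip, actor=f"M{k+1}", situation=sit)

    manifest = {
        "schema": "pldstim.catalog/1",
        "seed": seed,
        "rate": rate,
        "duration": duration,
        "entries": entries,
    }
    (out_dir / "catalog.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
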