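"""Core trajectory containers and clip-level operations.

Two containers cover the pipeline: :class:`MarkerClip` holds raw labeled
motion-capture marker trajectories (e.g. a 41-marker full-body set), and
:class:`JointClip` holds the reduced 13-dot point-light representation
(head, shoulders, elbows, wrists, hips, knees, ankles).  All coordinates
are meters, y-up, with the origin on the floor midline between the two
actors' capture subspaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

#: Canonical 13-joint order of the point-light skeleton.
JOINT_NAMES: tuple[str, ...] = (
    "head",
    "l_shoulder",
    "r_shoulder",
    "l_elbow",
    "r_elbow",
    "l_wrist",
    "r_wrist",
    "l_hip",
    "r_hip",
    "l_knee",
    "r_knee",
    "l_ankle",
    "r_ankle",
)

N_JOINTS = len(JOINT_NAMES)


class ClipError(ValueError):
    """Invalid clip contents or an operation outside a clip's domain."""


@dataclass(frozen=True)
class JointTopology:
    """Stick-figure edge list over the canonical 13 joints."""

    edges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        touched = set()
        for a, b in self.edges:
            if not (0 <= a < N_JOINTS and 0 <= b < N_JOINTS):
                raise ClipError(f"edge ({a}, {b}) references a joint outside 0..{N_JOINTS - 1}")
            touched.update((a, b))
        if touched != set(range(N_JOINTS)):
            missing = sorted(set(range(N_JOINTS)) - touched)
            raise ClipError(f"joints {missing} are not touched by any edge")


def _j(name: str) -> int:
    return JOINT_NAMES.index(name)


#: Default skeleton used when ``show_skeleton`` is on: head-to-shoulder
#: midline, arms, torso sides, and legs.
DEFAULT_TOPOLOGY = JointTopology(
    edges=(
        (_j("head"), _j("l_shoulder")),
        (_j("head"), _j("r_shoulder")),
        (_j("l_shoulder"), _j("r_shoulder")),
        (_j("l_shoulder"), _j("l_elbow")),
        (_j("l_elbow"), _j("l_wrist")),
        (_j("r_shoulder"), _j("r_elbow")),
        (_j("r_elbow"), _j("r_wrist")),
        (_j("l_shoulder"), _j("l_hip")),
        (_j("r_shoulder"), _j("r_hip")),
        (_j("l_hip"), _j("r_hip")),
        (_j("l_hip"), _j("l_knee")),
        (_j("l_knee"), _j("l_ankle")),
        (_j("r_hip"), _j("r_knee")),
        (_j("r_knee"), _j("r_ankle")),
    )
)


def _validate_common(positions: np.ndarray, rate: float, events: dict[str, float]) -> None:
    if rate <= 0:
        raise ClipError(f"sampling rate must be positive, got {rate}")
    if positions.ndim != 3 or positions.shape[2] != 3:
        raise ClipError(f"positions must be frames x points x 3, got shape {positions.shape}")
    if not np.all(np.isfinite(positions)):
        bad = np.argwhere(~np.isfinite(positions))
        frame, point = int(bad[0][0]), int(bad[0][1])
        raise ClipError(f"non-finite coordinate at frame {frame}, point index {point}")
    duration = positions.shape[0] / rate
    for name, t in events.items():
        if not (0.0 <= t <= duration + 1e-9):
            raise ClipError(f"event {name!r} at {t} s lies outside [0, {duration}] s")


@dataclass
class MarkerClip:
    """Labeled 3-D marker trajectories at a fixed sampling rate.

    Attributes
    ----------
    labels : marker names, unique, one per column of ``positions``.
    positions : ``(frames, markers, 3)`` float array, meters.
    rate : sampling frequency in Hz (capture standard is 120 Hz).
    events : named time points in seconds (e.g. action onset at 0.0,
        responder onset at 1.5, offset at 3.0).
    meta : free-form provenance (actor id, action id, category ...).
    """

    labels: list[str]
    positions: np.ndarray
    rate: float
    events: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({x for x in self.labels if self.labels.count(x) > 1})
            raise ClipError(f"duplicate marker labels: {dupes}")
        if self.positions.shape[1] != len(self.labels):
            raise ClipError(
                f"{len(self.labels)} labels but positions have "
                f"{self.positions.shape[1]} marker columns"
            )
        _validate_common(self.positions, self.rate, self.events)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        """Clip length in seconds (frames / rate)."""
        return self.n_frames / self.rate


@dataclass
class JointClip:
    """Canonical 13-joint point-light clip for one agent."""

    positions: np.ndarray
    rate: float
    events: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    joints: tuple[str, ...] = JOINT_NAMES

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if tuple(self.joints) != JOINT_NAMES:
            raise ClipError("joints must be the canonical 13-joint list in canonical order")
        if self.positions.shape[1] != N_JOINTS:
            raise ClipError(f"expected {N_JOINTS} joint columns, got {self.positions.shape[1]}")
        _validate_common(self.positions, self.rate, self.events)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.rate


def trim_clip(clip, t0: float, t1: float):
    """Cut a clip to the half-open time window ``[t0, t1)``.

    The half-open convention makes a 3 s window at 120 Hz exactly 360
    frames.  Events are re-based to the new origin; events falling outside
    the window are dropped.
    """
    if not (0.0 <= t0 < t1 <= clip.duration + 1e-9):
        raise ClipError(
            f"trim window [{t0}, {t1}) outside clip range [0, {clip.duration:.6g}]"
        )
    i0 = int(round(t0 * clip.rate))
    n = int(round((t1 - t0) * clip.rate))
    positions = clip.positions[i0 : i0 + n]
    new_dur = n / clip.rate
    events = {
        name: t - t0 for name, t in clip.events.items() if -1e-9 <= t - t0 <= new_dur + 1e-9
    }
    return replace(clip, positions=positions, events=events)


def smooth_clip(clip, window: int = 11, order: int = 3):
    """Polynomial (Savitzky-Golay) smoothing of every coordinate track.

    Replaces the manual clean-up step of a capture pipeline with a
    deterministic filter.  Endpoints are mirror-padded; length and rate are
    never changed.
    """
    if window % 2 == 0:
        raise ClipError(f"window must be odd, got {window}")
    if window <= order:
        raise ClipError(f"window ({window}) must exceed polynomial order ({order})")
    if window > clip.n_frames:
        raise ClipError(f"window ({window}) exceeds clip length ({clip.n_frames} frames)")
    smoothed = savgol_filter(clip.positions, window, order, axis=0, mode="mirror")
    return replace(clip, positions=smoothed)


def resample(clip, new_rate: float):
    """Linearly resample a clip to a new sampling rate.

    Duration is preserved to within one output sample; each coordinate is
    interpolated independently.
    """
    if new_rate <= 0:
        raise ClipError(f"new_rate must be positive, got {new_rate}")
    if abs(new_rate - clip.rate) < 1e-12:
        return replace(clip)
    n_new = int(round(clip.duration * new_rate))
    n_new = max(n_new, 1)
    t_old = np.arange(clip.n_frames) / clip.rate
    t_new = np.arange(n_new) / new_rate
    flat = clip.positions.reshape(clip.n_frames, -1)
    out = np.empty((n_new, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(t_new, t_old, flat[:, c])
    return replace(
        clip, positions=out.reshape(n_new, clip.positions.shape[1], 3), rate=new_rate
    )


def reduce_to_joints(clip: MarkerClip, mapping: dict[str, list[str]]) -> JointClip:
    """Collapse a full marker set to the 13-dot skeleton.

    Each joint is the unweighted per-frame centroid of its mapped marker
    cluster; the default mapping for the 41-marker full-body set lives in
    :mod:`pldstim.markerset`.
    """
    index = {label: i for i, label in enumerate(clip.labels)}
    cols = []
    for joint in JOINT_NAMES:
        group = mapping.get(joint, [])
        missing = [m for m in group if m not in index]
        if not group or missing:
            raise ClipError(
                f"joint {joint!r} has no usable markers (mapped {group}, missing {missing})"
            )
        idx = [index[m] for m in group]
        cols.append(clip.positions[:, idx, :].mean(axis=1))
    positions = np.stack(cols, axis=1)
    return JointClip(
        positions=positions, rate=clip.rate, events=dict(clip.events), meta=dict(clip.meta)
    )
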