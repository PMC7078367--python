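"""Stimulus-degradation operators: spatial scrambling and flicker.

*Scrambling* destroys the global body form while leaving every dot's
local motion intact: each marker independently draws one of the three
axes and a sign, and its whole trajectory is relocated by a constant
offset of ``level / 100`` meters along that axis (100% scrambling moves
each marker by one meter).  Velocities are untouched.

*Flicker* limits visual availability: each marker gets an alternating
visible/invisible schedule with segment durations drawn uniformly from a
user range, under a cap on the number of simultaneously visible markers
(0-13 for a single agent).  Flicker changes visibility only, never
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .clips import JointClip

SCOPES = ("agentA", "agentB", "both")


class DisplayOpError(ValueError):
    """Invalid display-operation specification."""


class FlickerSchedulingError(RuntimeError):
    """No visibility schedule satisfying the cap was found."""


@dataclass(frozen=True)
class ScrambleSpec:
    """Spatial scrambling: ``level`` percent of a 1 m displacement."""

    level: float
    seed: int = 0
    scope: str = "both"

    def __post_init__(self) -> None:
        if self.level < 0:
            raise DisplayOpError(f"scramble level must be >= 0, got {self.level}")
        if self.scope not in SCOPES:
            raise DisplayOpError(f"scope must be one of {SCOPES}, got {self.scope!r}")


@dataclass(frozen=True)
class FlickerSpec:
    """Flicker: visibility cap plus segment-duration range in seconds."""

    max_visible: int
    duration_range: tuple[float, float]
    seed: int = 0
    scope: str = "both"

    def __post_init__(self) -> None:
        if not (0 <= self.max_visible <= 13):
            raise DisplayOpError(f"max_visible must be in [0, 13], got {self.max_visible}")
        t_min, t_max = self.duration_range
        if not (0 < t_min <= t_max):
            raise DisplayOpError(f"need 0 < t_min <= t_max, got {self.duration_range}")
        if self.scope not in SCOPES:
            raise DisplayOpError(f"scope must be one of {SCOPES}, got {self.scope!r}")


def scramble_offsets(n_markers: int, spec: ScrambleSpec) -> np.ndarray:
    """Per-marker constant offsets: one random axis, one random sign, fixed
    magnitude ``level/100`` m.  Deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    axes = rng.integers(0, 3, size=n_markers)
    signs = rng.integers(0, 2, size=n_markers) * 2 - 1
    offsets = np.zeros((n_markers, 3))
    offsets[np.arange(n_markers), axes] = signs * (spec.level / 100.0)
    return offsets


def scramble(clip: JointClip, spec: ScrambleSpec) -> JointClip:
    """Relocate each marker's whole trajectory by its drawn offset.

    Level 0 is the identity; the per-marker velocity time series (finite
    differences) is invariant at any level.
    """
    offsets = scramble_offsets(clip.positions.shape[1], spec)
    return replace(clip, positions=clip.positions + offsets[None, :, :])


# --------------------------------------------------------------------------
# flicker
# --------------------------------------------------------------------------


def _draw_schedule(
    rng: np.random.Generator, n_frames: int, rate: float, dur_range: tuple[float, float],
    start_visible: bool,
) -> list[tuple[int, int, bool]]:
    """Alternating (start, stop, visible) segments covering the clip."""
    t_min, t_max = dur_range
    segs = []
    pos = 0
    visible = start_visible
    while pos < n_frames:
        dur = rng.uniform(t_min, t_max)
        n = max(1, int(round(dur * rate)))
        segs.append((pos, min(pos + n, n_frames), visible))
        pos += n
        visible = not visible
    return segs


def _mask_from_schedule(segs, n_frames: int) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for a, b, vis in segs:
        if vis:
            mask[a:b] = True
    return mask


def flicker(
    clip: JointClip,
    spec: FlickerSpec,
    max_attempts: int = 100,
    strict: bool = False,
) -> tuple[JointClip, np.ndarray]:
    """Assign per-marker visibility schedules under the simultaneity cap.

    Each marker alternates visible/invisible segments with durations drawn
    uniformly from ``spec.duration_range`` (cyclically over the whole
    clip).  Markers are processed greedily in a seeded random order; a
    marker whose drawn schedule would break the cap is redrawn up to
    ``max_attempts`` times.  If no clean redraw fits, the schedule's
    visible segments are truncated at capacity-full frames (``strict=True``
    raises :class:`FlickerSchedulingError` instead).

    Returns the untouched clip and a (frames x markers) boolean mask.
    """
    n_frames, n_markers = clip.positions.shape[:2]
    mask = np.zeros((n_frames, n_markers), dtype=bool)
    if spec.max_visible == 0:
        return replace(clip), mask
    if spec.max_visible >= n_markers:
        # cap can never bind: draw independent schedules
        rng = np.random.default_rng(spec.seed)
        for m in range(n_markers):
            segs = _draw_schedule(rng, n_frames, clip.rate, spec.duration_range,
                                  start_visible=bool(rng.integers(0, 2)))
            mask[:, m] = _mask_from_schedule(segs, n_frames)
        return replace(clip), mask

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n_markers)
    counts = np.zeros(n_frames, dtype=int)
    for m in order:
        placed = None
        for _ in range(max_attempts):
            segs = _draw_schedule(rng, n_frames, clip.rate, spec.duration_range,
                                  start_visible=bool(rng.integers(0, 2)))
            cand = _mask_from_schedule(segs, n_frames)
            if np.all(counts + cand <= spec.max_visible):
                placed = cand
                break
        if placed is None:
            if strict:
                raise FlickerSchedulingError(
                    f"no schedule for marker {m} satisfied max_visible="
                    f"{spec.max_visible} after {max_attempts} attempts"
                )
            # capacity-aware repair: keep the drawn rhythm but black out
            # frames that are already at the cap
            cand = _mask_from_schedule(segs, n_frames)
            cand &= counts < spec.max_visible
            placed = cand
        counts += placed
        mask[:, m] = placed
    return replace(clip), mask


def visible_segment_lengths(mask: np.ndarray, rate: float) -> list[float]:
    """Durations (s) of contiguous visible runs per marker, for diagnostics.

    The final run of each marker is dropped — it is truncated by the clip
    boundary, not by a drawn duration.
    """
    out: list[float] = []
    for m in range(mask.shape[1]):
        col = mask[:, m].astype(int)
        edges = np.flatnonzero(np.diff(col))
        bounds = np.concatenate([[-1], edges, [len(col) - 1]])
        runs = [
            (bounds[i] + 1, bounds[i + 1] + 1, col[bounds[i] + 1])
            for i in range(len(bounds) - 1)
        ]
        for a, b, vis in runs[:-1]:  # last run hits the clip boundary
            if vis:
                out.append((b - a) / rate)
    return out
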