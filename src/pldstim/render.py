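"""Rasterization and export of point-light scenes.

Frames are drawn as anti-aliased discs (and optionally stick-figure
edges) on a solid background, at 4x supersampling for stable dot shapes,
then exported either as an MP4 movie (when an FFmpeg-backed encoder is
available) or as a lossless PNG sequence for bit-exact testing.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
from PIL import Image, ImageDraw

from .camera import CameraSpec, project
from .clips import DEFAULT_TOPOLOGY, N_JOINTS, JointTopology, resample
from .compose import SceneSpec
from .ops import FlickerSpec, ScrambleSpec, flicker, scramble

SUPERSAMPLE = 4


class RenderError(ValueError):
    """Invalid render request."""


class EncoderUnavailableError(RuntimeError):
    """No MP4 encoder could be loaded in this environment."""


def _scope_selects(scope: str, agent_index: int) -> bool:
    return scope == "both" or (scope == "agentA" and agent_index == 0) or (
        scope == "agentB" and agent_index == 1
    )


def scene_points_and_mask(
    scene: SceneSpec,
    fps: float,
    scramble_spec: ScrambleSpec | None = None,
    flicker_spec: FlickerSpec | None = None,
):
    """World-space point tracks at the output frame rate plus visibility.

    Display operators are applied per agent according to their scope; each
    agent draws its own sub-seed so dyads are not mirror-scrambled.
    """
    points, masks = [], []
    for k, agent in enumerate(scene.agents):
        clip = resample(agent.clip, fps)
        if scramble_spec is not None and _scope_selects(scramble_spec.scope, k):
            sub = ScrambleSpec(
                level=scramble_spec.level, seed=scramble_spec.seed + 1000 * k, scope="both"
            )
            clip = scramble(clip, sub)
        n = clip.n_frames
        if flicker_spec is not None and _scope_selects(flicker_spec.scope, k):
            sub = FlickerSpec(
                max_visible=flicker_spec.max_visible,
                duration_range=flicker_spec.duration_range,
                seed=flicker_spec.seed + 1000 * k,
                scope="both",
            )
            _, mask = flicker(clip, sub)
        else:
            mask = np.ones((n, N_JOINTS), dtype=bool)
        # re-place the transformed clip with the agent's offset/yaw
        placed = type(agent)(clip=clip, offset=agent.offset, yaw=agent.yaw)
        points.append(placed.world_positions())
        masks.append(mask)
    n = min(p.shape[0] for p in points)
    pts = np.concatenate([p[:n] for p in points], axis=1)
    mask = np.concatenate([m[:n] for m in masks], axis=1)
    return pts, mask


def render_frames(
    scene: SceneSpec,
    cam: CameraSpec,
    scramble_spec: ScrambleSpec | None = None,
    flicker_spec: FlickerSpec | None = None,
    topology: JointTopology = DEFAULT_TOPOLOGY,
) -> list[np.ndarray]:
    """Rasterize a scene through a camera into a list of RGB uint8 frames.

    The scene is resampled to ``cam.fps``; dots are drawn back-to-front as
    anti-aliased discs; ``cam.show_skeleton`` additionally draws the stick
    topology per agent.  Deterministic given the operator seeds.
    """
    if scene.duration <= 0:
        raise RenderError("zero-duration scene")
    pts, mask = scene_points_and_mask(scene, cam.fps, scramble_spec, flicker_spec)
    w, h = cam.resolution
    ss = SUPERSAMPLE
    frames: list[np.ndarray] = []
    n_agents = len(scene.agents)
    for f in range(pts.shape[0]):
        img = Image.new("RGB", (w * ss, h * ss), tuple(cam.background))
        draw = ImageDraw.Draw(img)
        xy, radii, order, visible = project(pts[f], cam)
        vis = visible & mask[f]
        if cam.show_skeleton:
            for a in range(n_agents):
                base = a * N_JOINTS
                for i, j in topology.edges:
                    if vis[base + i] and vis[base + j]:
                        draw.line(
                            [tuple(xy[base + i] * ss), tuple(xy[base + j] * ss)],
                            fill=tuple(cam.foreground),
                            width=max(1, int(round(radii[base + i] * ss / 2))),
                        )
        for idx in order:
            if not vis[idx]:
                continue
            u, v = xy[idx] * ss
            r = max(radii[idx] * ss, ss / 2)
            draw.ellipse([u - r, v - r, u + r, v + r], fill=tuple(cam.foreground))
        frames.append(np.asarray(img.resize((w, h), Image.LANCZOS)))
    return frames


def export_png_sequence(frames: list[np.ndarray], directory: str | Path) -> list[Path]:
    """Write frames as zero-padded PNGs (lossless; bit-exact round-trip)."""
    if not frames:
        raise RenderError("empty frame sequence")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = directory / f"frame_{i:05d}.png"
        imageio.imwrite(p, frame)
        paths.append(p)
    return paths


def export_video(
    frames: list[np.ndarray],
    path: str | Path,
    fps: float,
    png_fallback: bool = True,
) -> Path:
    """Export frames to an MP4 (H.264) movie.

    If no FFmpeg encoder is importable, falls back (with a warning) to a
    lossless PNG sequence in a sibling directory named after the movie;
    with ``png_fallback=False`` an :class:`EncoderUnavailableError` is
    raised instead.
    """
    if not frames:
        raise RenderError("empty frame sequence")
    path = Path(path)
    try:
        writer = imageio.get_writer(path, fps=fps, codec="libx264", format="FFMPEG")
    except Exception as exc:
        msg = (
            f"MP4 encoder unavailable ({exc.__class__.__name__}: {exc}); "
            "install imageio-ffmpeg for movie export"
        )
        if not png_fallback:
            raise EncoderUnavailableError(msg) from exc
        warnings.warn(msg + " — writing a PNG sequence instead", RuntimeWarning, stacklevel=2)
        out_dir = path.with_suffix("") if path.suffix else path
        export_png_sequence(frames, out_dir)
        return out_dir
    with writer:
        for frame in frames:
            writer.append_data(frame)
    return path
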