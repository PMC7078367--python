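"""Camera model: presets, free pose, orthographic and perspective projection.

The viewing convention mirrors the stimulus tool it models: camera
position in meters (x left/right, y up/down, z closer/further), rotation
in degrees (pitch about x, yaw about y, roll about z), and two projection
modes — perspective (pinhole; farther dots are drawn smaller) and
orthographic (parallel; every dot the same size, no depth cues).

The *front* preset sits on the midline between the agents at a height of
one meter and 15 meters from their axis; left/right/back are the same
pose rotated about the scene center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PRESETS = ("front", "left", "right", "back", "free")

FRONT_DISTANCE = 15.0  # m from the agents' axis
FRONT_HEIGHT = 1.0  # m


class CameraError(ValueError):
    """Invalid camera specification."""


@dataclass
class CameraSpec:
    """Projection model plus pose and raster settings.

    ``mode`` is ``"perspective"`` (uses ``fov``, degrees, vertical) or
    ``"orthographic"`` (uses ``size``, the world half-height in meters
    mapped to the image half-height).  ``marker_size`` is the dot diameter
    in centimeters in world units.
    """

    mode: str = "perspective"
    fov: float = 60.0
    size: float = 1.5
    preset: str = "front"
    position: tuple[float, float, float] = (0.0, FRONT_HEIGHT, -FRONT_DISTANCE)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    marker_size: float = 6.0
    show_skeleton: bool = False
    resolution: tuple[int, int] = (800, 600)
    fps: float = 60.0
    foreground: tuple[int, int, int] = (255, 255, 255)
    background: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if self.mode not in ("perspective", "orthographic"):
            raise CameraError(f"unknown projection mode {self.mode!r}")
        if not (0.0 < self.fov < 180.0):
            raise CameraError(f"fov must be in (0, 180) degrees, got {self.fov}")
        if self.size <= 0:
            raise CameraError(f"orthographic size must be positive, got {self.size}")
        if self.marker_size <= 0:
            raise CameraError(f"marker_size must be positive, got {self.marker_size}")
        w, h = self.resolution
        if w <= 0 or h <= 0:
            raise CameraError(f"resolution must be positive, got {self.resolution}")
        if self.preset not in PRESETS:
            raise CameraError(f"unknown preset {self.preset!r}")
        if self.preset != "free":
            self.position, self.rotation = resolve_preset(self.preset)

    def rotation_matrix(self) -> np.ndarray:
        """Camera-to-world rotation from Euler degrees (yaw, then pitch, roll)."""
        rx, ry, rz = np.deg2rad(self.rotation)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Ry @ Rx @ Rz


def resolve_preset(preset: str) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Standard poses: front / left / right / back around the scene center.

    Front looks along +z from (0, 1, -15); the others are the front pose
    rotated 90 / 270 / 180 degrees about the vertical axis through the
    scene center, so all four sit 15 m out at 1 m height.
    """
    if preset == "free":
        raise CameraError("the free preset requires an explicit position and rotation")
    angles = {"front": 0.0, "right": 90.0, "back": 180.0, "left": 270.0}
    if preset not in angles:
        raise CameraError(f"unknown preset {preset!r}")
    th = np.deg2rad(angles[preset])
    x = FRONT_DISTANCE * -np.sin(th)
    z = -FRONT_DISTANCE * np.cos(th)
    yaw = angles[preset]
    position = (float(round(x, 12)), FRONT_HEIGHT, float(round(z, 12)))
    rotation = (0.0, yaw, 0.0)
    return position, rotation


def look_at_rotation(position, target) -> tuple[float, float, float]:
    """Euler (pitch, yaw, 0) that points the camera's +z axis at a target."""
    d = np.asarray(target, float) - np.asarray(position, float)
    yaw = np.rad2deg(np.arctan2(d[0], d[2]))
    pitch = np.rad2deg(np.arctan2(-d[1], np.hypot(d[0], d[2])))
    return (float(pitch), float(yaw), 0.0)


def project(points: np.ndarray, cam: CameraSpec):
    """Project world points to pixel coordinates with per-dot disc radii.

    Returns ``(xy, radii, order, visible)``: pixel centers ``(n, 2)``,
    disc radii in pixels, a back-to-front draw order over the visible
    subset, and a boolean mask of points in front of the camera
    (points behind the camera are culled, never an error).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    R = cam.rotation_matrix()
    local = (pts - np.asarray(cam.position)) @ R  # world -> camera axes
    x, y, z = local[:, 0], local[:, 1], local[:, 2]
    w, h = cam.resolution
    cx, cy = w / 2.0, h / 2.0
    r_world = cam.marker_size / 100.0 / 2.0  # cm diameter -> m radius

    if cam.mode == "perspective":
        visible = z > 1e-6
        f = (h / 2.0) / np.tan(np.deg2rad(cam.fov) / 2.0)
        zs = np.where(visible, z, 1.0)
        u = cx + f * x / zs
        v = cy - f * y / zs
        radii = f * r_world / zs
    else:
        visible = z > 0.0
        scale = (h / 2.0) / cam.size
        u = cx + scale * x
        v = cy - scale * y
        radii = np.full_like(z, scale * r_world)

    xy = np.stack([u, v], axis=1)
    idx = np.flatnonzero(visible)
    order = idx[np.argsort(-z[idx])]  # farthest first (painter's algorithm)
    return xy, radii, order, visible
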