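"""Ingest a marker clip, trim it, and reduce 41 markers to 13 joints.

A motion-capture take is usually longer than the stimulus you want and uses
the full marker set of the capture system. This example writes a synthetic
41-marker take to C3D, reads it back, trims it to a 3-second window, smooths
it, and collapses the marker clusters to the canonical 13-joint point-light
skeleton.
"""

import tempfile
from pathlib import Path

import numpy as np

import pldstim as p

tmp = Path(tempfile.mkdtemp())

# A synthetic walker stands in for a real capture take.
walker = p.make_walker(p.GaitParams(seed=42, noise_sd=0.002))
take = p.expand_to_markers(walker)
print(f"synthetic take: {len(take.labels)} markers, "
      f"{take.n_frames} frames at {take.rate:.0f} Hz")

# Round-trip through C3D, the native capture format.
c3d_path = tmp / "take.c3d"
p.write_marker_clip(take, c3d_path)
loaded = p.read_marker_clip(c3d_path)
err = np.abs(loaded.positions - take.positions).max()
print(f"C3D round-trip max error: {err:.2e} m (float32 storage)")

# Trim to the stimulus window and smooth residual marker jitter.
trimmed = p.trim_clip(loaded, 0.0, 3.0)
smoothed = p.smooth_clip(trimmed, window=11, order=3)
print(f"trimmed clip: {trimmed.n_frames} frames "
      f"({trimmed.n_frames / trimmed.rate:.1f} s)")

# Reduce marker clusters to the 13-joint skeleton.
joints = p.reduce_to_joints(smoothed, p.DEFAULT_JOINT_MAPPING)
print(f"reduced to {joints.positions.shape[1]} joints: {', '.join(p.JOINT_NAMES)}")

out = tmp / "walking.json"
p.write_joint_clip(joints, out)
print(f"wrote joint clip to {out}")
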