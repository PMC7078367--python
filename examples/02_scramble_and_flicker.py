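"""Apply the two display manipulations: spatial scrambling and flicker.

Scrambling displaces each dot's whole trajectory by a constant offset along
one random axis — local motion is preserved exactly while global form is
destroyed. Flicker alternates each dot between visible and invisible so
that at most `max_visible` of the 13 dots are on screen at any moment.
"""

import numpy as np

import pldstim as p

walker = p.make_walker(p.GaitParams(seed=42))

# --- scrambling -----------------------------------------------------------
for level in (15, 30, 100):
    scrambled = p.scramble(walker, p.ScrambleSpec(level=level, seed=7))
    offsets = scrambled.positions[0] - walker.positions[0]
    dist = np.linalg.norm(offsets, axis=1)
    vel_change = np.abs(np.diff(scrambled.positions, axis=0)
                        - np.diff(walker.positions, axis=0)).max()
    print(f"{level:3d}% scrambling: every dot displaced by "
          f"{dist.min():.2f}-{dist.max():.2f} m, "
          f"max velocity change {vel_change:.1e} m/frame")

# --- flicker ---------------------------------------------------------------
spec = p.FlickerSpec(max_visible=5, duration_range=(0.1, 0.5), seed=3)
_, mask = p.flicker(walker, spec)
per_frame = mask.sum(axis=1)
print(f"flicker cap 5: visible dots per frame range "
      f"{per_frame.min()}-{per_frame.max()} (mean {per_frame.mean():.2f})")

segs = p.visible_segment_lengths(mask, walker.rate)
print(f"visible segment durations: {min(segs):.3f}-{max(segs):.3f} s "
      f"across {len(segs)} segments")
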