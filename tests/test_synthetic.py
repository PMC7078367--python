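"""Synthetic motion fixtures: walker, gestures, dyads, marker expansion."""

import json

import numpy as np
import pytest

import pldstim as p
from pldstim.clips import ClipError
from pldstim.synthetic import CATEGORIES, ActionScript, _J


class TestWalker:
    def test_three_seconds_at_120hz(self, walker):
        assert walker.n_frames == 360
        assert walker.positions.shape == (360, 13, 3)

    def test_deterministic_given_seed(self):
        a = p.make_walker(p.GaitParams(noise_sd=0.01, seed=5))
        b = p.make_walker(p.GaitParams(noise_sd=0.01, seed=5))
        np.testing.assert_array_equal(a.positions, b.positions)

    def test_contralateral_ankles_phase_opposed(self, walker):
        # cross-correlation of the generating sinusoids peaks at half a cycle
        la = walker.positions[:, _J["l_ankle"], 2] - walker.positions[:, _J["l_ankle"], 2].mean()
        ra = walker.positions[:, _J["r_ankle"], 2] - walker.positions[:, _J["r_ankle"], 2].mean()
        n = len(la)
        lags = np.arange(n)
        xc = np.array([np.dot(la, np.roll(ra, k)) for k in lags])
        best = lags[np.argmax(xc)] / walker.rate
        half_cycle = 0.5 / 1.0  # cycle_freq = 1 Hz
        assert min(abs(best - half_cycle), abs(best - (3.0 - half_cycle))) < 0.05

    def test_periodicity_invariant(self):
        params = p.GaitParams(cycle_freq=1.0, noise_sd=0.002, seed=9)
        clip = p.make_walker(params)
        period = int(round(clip.rate / params.cycle_freq))
        diff = np.abs(clip.positions[period:] - clip.positions[:-period])
        assert diff.max() <= 3 * max(params.noise_sd, 1e-9) + 1e-9

    def test_invalid_params_rejected(self):
        with pytest.raises(ClipError):
            p.GaitParams(cycle_freq=0)
        with pytest.raises(ClipError):
            p.GaitParams(noise_sd=-1)


class TestGesture:
    def test_identical_first_last_pose(self):
        # pose holds after the final keyframe, so first and last frames match
        up = {"r_wrist": (0.4, 1.6, 0.1)}
        script = ActionScript(keyframes=[(0.0, up), (1.5, {}), (2.9, up)], category="COM_A")
        clip = p.make_gesture(script)
        np.testing.assert_allclose(clip.positions[0], clip.positions[-1], atol=1e-9)

    def test_single_arm_raise_is_monotone_up_to_keyframe(self):
        script = ActionScript(keyframes=[(1.0, {"r_wrist": (0.38, 1.8, 0.0)})], category="COM_A")
        clip = p.make_gesture(script)
        n = int(1.0 * clip.rate)
        heights = clip.positions[: n + 1, _J["r_wrist"], 1]
        assert np.all(np.diff(heights) > 0)

    def test_empty_keyframes_is_static_neutral(self):
        clip = p.make_gesture(ActionScript(category="NORA"))
        assert np.abs(np.diff(clip.positions, axis=0)).max() == 0.0
        np.testing.assert_allclose(clip.positions[0], p.neutral_pose())

    def test_keyframe_outside_duration_rejected(self):
        script = ActionScript(keyframes=[(4.0, {})], category="NORA")
        with pytest.raises(ClipError, match="keyframe"):
            p.make_gesture(script, duration=3.0)

    def test_nondecreasing_keyframe_times_enforced(self):
        with pytest.raises(ClipError, match="non-decreasing"):
            ActionScript(keyframes=[(2.0, {}), (1.0, {})], category="NORA")


class TestDyad:
    @staticmethod
    def _scripts():
        a = ActionScript(role="initiator",
                         keyframes=[(0.0, {}), (1.0, {"r_wrist": (0.4, 1.7, 0.2)})],
                         category="COM_A")
        b = ActionScript(role="responder",
                         keyframes=[(0.0, {}), (1.0, {"l_wrist": (-0.4, 1.6, 0.2)})],
                         category="COM_B")
        return a, b

    def test_responder_starts_at_default_onset(self):
        a, b = self._scripts()
        clip_a, clip_b = p.make_dyad_fixture(a, b)
        speed_b = np.abs(np.diff(clip_b.positions, axis=0)).max(axis=(1, 2))
        n_onset = int(round(1.5 * clip_b.rate))
        assert np.all(speed_b[: n_onset - 1] < 1e-6)  # motionless before 1.5 s
        assert speed_b[n_onset:].max() > 1e-4  # responding after
        first_moving = int(np.argmax(speed_b > 1e-6))
        assert abs(first_moving / clip_b.rate - 1.5) < 0.02
        # initiator moves from the start
        speed_a = np.abs(np.diff(clip_a.positions, axis=0)).max(axis=(1, 2))
        assert speed_a[0] > 0

    def test_onset_zero_moves_both_from_start(self):
        a, b = self._scripts()
        _, clip_b = p.make_dyad_fixture(a, b, onsetB=0.0)
        speed_b = np.abs(np.diff(clip_b.positions, axis=0)).max(axis=(1, 2))
        assert speed_b[0] > 0

    def test_empty_responder_script_is_static(self):
        a, _ = self._scripts()
        _, clip_b = p.make_dyad_fixture(a, ActionScript(role="responder", category="COM_B"))
        assert np.abs(np.diff(clip_b.positions, axis=0)).max() < 1e-6

    def test_onset_outside_clip_rejected(self):
        a, b = self._scripts()
        with pytest.raises(ClipError):
            p.make_dyad_fixture(a, b, onsetB=3.0)


class TestExpandToMarkers:
    def test_produces_41_labels(self, walker):
        mc = p.expand_to_markers(walker)
        assert len(mc.labels) == 41
        assert mc.positions.shape == (walker.n_frames, 41, 3)

    def test_reduce_inverts_expand(self, walker):
        mc = p.expand_to_markers(walker)
        back = p.reduce_to_joints(mc, p.DEFAULT_JOINT_MAPPING)
        assert np.abs(back.positions - walker.positions).max() < 1e-9

    def test_static_pose_gives_static_markers(self, static_clip):
        mc = p.expand_to_markers(static_clip)
        assert np.abs(np.diff(mc.positions, axis=0)).max() == 0.0


class TestCatalogFixture:
    def test_every_com_gesture_has_congruent_partner(self, catalog):
        for e in catalog.entries.values():
            if e["category"] == "COM_A":
                assert e["congruent_partners"]
                for partner in e["congruent_partners"]:
                    assert catalog[partner]["category"] == "COM_B"

    def test_same_seed_gives_byte_identical_manifest(self, tmp_path):
        p.make_catalog_fixture(seed=11, out_dir=tmp_path / "a")
        p.make_catalog_fixture(seed=11, out_dir=tmp_path / "b")
        assert (tmp_path / "a" / "catalog.json").read_bytes() == (
            tmp_path / "b" / "catalog.json"
        ).read_bytes()

    def test_categories_closed_over_the_six(self, catalog):
        assert {e["category"] for e in catalog.entries.values()} <= set(CATEGORIES)

    def test_at_least_two_entries_per_category(self, catalog):
        from collections import Counter

        counts = Counter(e["category"] for e in catalog.entries.values())
        for cat in CATEGORIES:
            assert counts[cat] >= 2, cat

    def test_clips_load_and_are_3s_120hz(self, catalog):
        aid = next(iter(catalog.entries))
        clip = catalog.load_clip(aid)
        assert clip.n_frames == 360 and clip.rate == 120.0

    def test_manifest_json_round_trip(self, catalog, tmp_path):
        manifest = p.make_catalog_fixture(seed=3, out_dir=tmp_path)
        reloaded = json.loads((tmp_path / "catalog.json").read_text())
        assert reloaded["entries"] == manifest["entries"]
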