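"""Clip containers and trajectory operations."""

import numpy as np
import pytest

import pldstim as p
from pldstim.clips import ClipError, JointTopology


def _linear_marker_clip(n=600, rate=120.0, n_markers=3):
    t = np.arange(n) / rate
    pos = np.zeros((n, n_markers, 3))
    for m in range(n_markers):
        pos[:, m, 0] = 0.1 * m + 0.5 * t  # straight-line motion
        pos[:, m, 1] = 1.0 + 0.05 * m
    return p.MarkerClip(labels=[f"M{m}" for m in range(n_markers)], positions=pos, rate=rate,
                        events={"onset": 0.0, "midpoint": 2.5, "offset": 5.0})


class TestValidation:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ClipError, match="duplicate"):
            p.MarkerClip(labels=["A", "A"], positions=np.zeros((10, 2, 3)), rate=120)

    def test_nonfinite_coordinates_rejected_with_location(self):
        pos = np.zeros((10, 2, 3))
        pos[3, 1, 0] = np.nan
        with pytest.raises(ClipError, match="frame 3"):
            p.MarkerClip(labels=["A", "B"], positions=pos, rate=120)

    def test_event_outside_clip_rejected(self):
        with pytest.raises(ClipError, match="event"):
            p.JointClip(positions=np.zeros((12, 13, 3)), rate=120, events={"late": 1.0})

    def test_joint_clip_requires_13_canonical_joints(self):
        with pytest.raises(ClipError):
            p.JointClip(positions=np.zeros((10, 12, 3)), rate=120)

    def test_topology_must_touch_every_joint(self):
        with pytest.raises(ClipError, match="not touched"):
            JointTopology(edges=((0, 1),))


class TestTrim:
    def test_three_second_window_at_120hz_is_360_frames(self):
        clip = _linear_marker_clip()
        out = p.trim_clip(clip, 0.0, 3.0)
        assert out.n_frames == 360
        assert out.rate == 120.0

    def test_full_window_is_identity(self, walker):
        out = p.trim_clip(walker, 0.0, walker.duration)
        np.testing.assert_array_equal(out.positions, walker.positions)

    def test_first_retained_sample_matches_source_index(self):
        clip = _linear_marker_clip()
        out = p.trim_clip(clip, 1.5, 3.0)
        i0 = int(round(1.5 * clip.rate))
        np.testing.assert_array_equal(out.positions[0], clip.positions[i0])
        assert out.n_frames == 180

    def test_events_rebased_and_filtered(self):
        clip = _linear_marker_clip()
        out = p.trim_clip(clip, 1.5, 4.0)
        assert out.events["midpoint"] == pytest.approx(1.0)
        assert "onset" not in out.events

    def test_window_outside_clip_raises(self):
        clip = _linear_marker_clip()
        with pytest.raises(ClipError):
            p.trim_clip(clip, 0.0, 10.0)
        with pytest.raises(ClipError):
            p.trim_clip(clip, 3.0, 2.0)


class TestSmooth:
    def test_constant_clip_unchanged(self, static_clip):
        out = p.smooth_clip(static_clip, window=11, order=3)
        np.testing.assert_allclose(out.positions, static_clip.positions, atol=1e-12)

    def test_single_frame_spike_attenuated(self, walker):
        spiked = p.JointClip(positions=walker.positions.copy(), rate=walker.rate)
        spiked.positions[180, 5, 1] += 0.05  # 5 cm glitch
        out = p.smooth_clip(spiked, window=11, order=3)
        residual = np.abs(out.positions - walker.positions).max()
        assert residual < 0.05 * 0.8  # spike magnitude clearly reduced

    def test_one_hz_sine_attenuation_below_one_percent(self):
        # filter frequency response oracle: slow signals pass through
        rate, n = 120.0, 600
        t = np.arange(n) / rate
        pos = np.zeros((n, 13, 3))
        pos[:, :, 1] = 1.0 + 0.1 * np.sin(2 * np.pi * 1.0 * t)[:, None]
        clip = p.JointClip(positions=pos, rate=rate)
        out = p.smooth_clip(clip, window=11, order=3)
        amp_out = (out.positions[:, 0, 1].max() - out.positions[:, 0, 1].min()) / 2
        assert abs(amp_out - 0.1) / 0.1 < 0.01

    def test_length_and_rate_never_change(self, walker):
        out = p.smooth_clip(walker, window=21, order=2)
        assert out.n_frames == walker.n_frames and out.rate == walker.rate

    @pytest.mark.parametrize("window,order", [(10, 3), (5, 5), (5, 7), (100001, 3)])
    def test_invalid_window_order_combinations(self, walker, window, order):
        with pytest.raises(ClipError):
            p.smooth_clip(walker, window=window, order=order)


class TestResample:
    def test_half_rate_halves_frames(self, walker):
        out = p.resample(walker, 60.0)
        assert out.n_frames == 180 and out.rate == 60.0

    def test_same_rate_is_identity(self, walker):
        out = p.resample(walker, walker.rate)
        np.testing.assert_array_equal(out.positions, walker.positions)

    def test_linear_motion_interpolates_exactly(self):
        clip = _linear_marker_clip()
        out = p.resample(clip, 90.0)
        t_new = np.arange(out.n_frames) / 90.0
        expected = 0.5 * t_new  # marker 0 x-track is 0.5*t
        np.testing.assert_allclose(out.positions[:, 0, 0], expected, atol=1e-12)

    def test_duration_preserved_within_one_sample(self, walker):
        out = p.resample(walker, 47.0)
        assert abs(out.duration - walker.duration) <= 1.0 / 47.0


class TestReduce:
    def test_41_marker_fixture_reduces_to_13_joints(self, marker_walker):
        joints = p.reduce_to_joints(marker_walker, p.DEFAULT_JOINT_MAPPING)
        assert joints.positions.shape[1] == 13
        assert joints.rate == marker_walker.rate

    def test_single_marker_mapping_passes_through(self):
        pos = np.random.default_rng(0).normal(size=(20, 13, 3))
        clip = p.MarkerClip(labels=[f"J{i}" for i in range(13)], positions=pos, rate=120)
        mapping = {j: [f"J{i}"] for i, j in enumerate(p.JOINT_NAMES)}
        out = p.reduce_to_joints(clip, mapping)
        np.testing.assert_array_equal(out.positions, pos)

    def test_two_marker_head_group_is_midpoint(self):
        pos = np.zeros((5, 2, 3))
        pos[:, 0] = (0.0, 1.7, 0.0)
        pos[:, 1] = (0.0, 1.8, 0.0)
        clip = p.MarkerClip(labels=["H1", "H2"], positions=pos, rate=120)
        mapping = {j: ["H1"] for j in p.JOINT_NAMES}
        mapping["head"] = ["H1", "H2"]
        out = p.reduce_to_joints(clip, mapping)
        np.testing.assert_allclose(out.positions[:, 0], [[0.0, 1.75, 0.0]] * 5)

    def test_missing_marker_error_names_the_joint(self, marker_walker):
        mapping = dict(p.DEFAULT_JOINT_MAPPING)
        mapping["l_knee"] = ["NoSuchMarker"]
        with pytest.raises(ClipError, match="l_knee"):
            p.reduce_to_joints(marker_walker, mapping)

    def test_reduce_commutes_with_trim(self, marker_walker):
        a = p.reduce_to_joints(p.trim_clip(marker_walker, 0.5, 2.5), p.DEFAULT_JOINT_MAPPING)
        b = p.trim_clip(p.reduce_to_joints(marker_walker, p.DEFAULT_JOINT_MAPPING), 0.5, 2.5)
        np.testing.assert_allclose(a.positions, b.positions, atol=1e-12)
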