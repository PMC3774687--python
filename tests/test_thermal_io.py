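import numpy as np
import pandas as pd
import pytest

from thermotrack import thermal_io
from thermotrack.thermal_io import (
    ThermalFrame,
    read_video,
    write_video,
    write_tracks,
    read_tracks,
    MissingVideoError,
    EmptyVideoError,
    FrameDimensionError,
)
from thermotrack.synth import (
    ScenarioSpec,
    MouseSpec,
    MotionPiece,
    Segment,
    InfeasibleScriptError,
    generate_scenario,
)
from thermotrack.temporal_watershed import MousePose
from thermotrack import scenarios


def _write_pngs(path, arrays):
    import imageio.v3 as iio

    for i, arr in enumerate(arrays):
        iio.imwrite(path / f"frame_{i:04d}.png", arr.astype(np.uint16))


class TestReadVideo:
    def test_directory_of_frames_preserves_order_and_indices(self, tmp_path):
        arrays = [np.full((24, 32), 1000 + i, dtype=np.uint16) for i in range(3)]
        _write_pngs(tmp_path, arrays)
        frames = read_video(tmp_path, scale=0.01)
        assert [f.index for f in frames] == [0, 1, 2]
        assert frames[0].shape == (24, 32)
        assert frames[1].values[0, 0] == pytest.approx(10.01)

    def test_single_page_tiff_roundtrip(self, tmp_path):
        frame = ThermalFrame(np.full((10, 12), 25.0), index=0)
        path = tmp_path / "v.tif"
        write_video([frame], path, scale=0.01)
        frames = read_video(path, scale=0.01)
        assert len(frames) == 1
        np.testing.assert_allclose(frames[0].values, 25.0, atol=0.01)

    def test_missing_path_raises_named_error(self, tmp_path):
        with pytest.raises(MissingVideoError):
            read_video(tmp_path / "nope")

    def test_empty_directory_raises(self, tmp_path):
        with pytest.raises(EmptyVideoError):
            read_video(tmp_path)

    def test_mixed_dimensions_raise(self, tmp_path):
        _write_pngs(tmp_path, [np.zeros((24, 32)), np.zeros((12, 16))])
        with pytest.raises(FrameDimensionError):
            read_video(tmp_path)


class TestTracks:
    @staticmethod
    def _pose(frame, mid, x):
        return MousePose(
            mouse_id=mid,
            frame=frame,
            nose=np.array([x + 5.0, 7.0]),
            genitals=np.array([x - 5.0, 7.0]),
            centroid=np.array([x, 7.0]),
            length=10.0,
        )

    def test_row_count_and_roundtrip(self, tmp_path):
        poses = [
            [self._pose(t, m, 10.0 * m + 0.123456 * t) for m in range(2)]
            for t in range(10)
        ]
        path = tmp_path / "tracks.csv"
        write_tracks(poses, path)
        df = read_tracks(path)
        assert len(df) == 20
        # round-trip lossless to 1e-6
        for t in range(10):
            for m in range(2):
                row = df[(df.frame == t) & (df.mouse_id == m)].iloc[0]
                assert row.centroid_x == pytest.approx(10.0 * m + 0.123456 * t, abs=1e-6)

    def test_reinit_frame_retained_with_flag_and_empty_keypoints(self, tmp_path):
        poses = [[self._pose(0, 0, 5.0)], (1, "reinit"), [self._pose(2, 0, 6.0)]]
        path = tmp_path / "tracks.csv"
        write_tracks(poses, path)
        df = read_tracks(path)
        flagged = df[df.flag == "reinit"]
        assert len(flagged) == 1
        assert flagged.iloc[0].frame == 1
        assert np.isnan(flagged.iloc[0].nose_x)


class TestGenerateScenario:
    def test_single_mouse_walkalone_has_no_pair_labels(self):
        spec = ScenarioSpec(
            mice=[MouseSpec()],
            motions=[[MotionPiece(50, (40.0, 40.0), (100.0, 40.0))]],
            segments=[Segment(0, 50, {})],
            seed=0,
        )
        frames, gt = generate_scenario(spec)
        assert len(frames) == 50
        assert gt.pair_labels == {}
        assert len(gt.poses[0]) == 1

    def test_nose2nose_segment_places_noses_within_half_cm(self):
        spec = scenarios.four_class_cycle(n_cycles=1, seed=3)
        frames, gt = generate_scenario(spec)
        # the Nose2Nose segment of the first cycle spans frames [150, 240)
        for t in (160, 200, 230):
            assert gt.pair_labels[(t, 0, 1)] == "Nose2Nose"
            d = np.linalg.norm(gt.poses[t][0].nose - gt.poses[t][1].nose)
            assert d < 0.5 * spec.px_per_cm
            assert gt.pair_labels[(t, 1, 0)] == "Nose2Nose"

    def test_determinism_bit_identical(self):
        spec_a = scenarios.disjoint_scenario(n_mice=2, n_frames=12, seed=7)
        spec_b = scenarios.disjoint_scenario(n_mice=2, n_frames=12, seed=7)
        fa, _ = generate_scenario(spec_a)
        fb, _ = generate_scenario(spec_b)
        for a, b in zip(fa, fb):
            np.testing.assert_array_equal(a.values, b.values)

    def test_escaping_script_rejected_at_build_time(self):
        spec = ScenarioSpec(
            mice=[MouseSpec()],
            motions=[[MotionPiece(10, (150.0, 80.0), (200.0, 80.0))]],
            segments=[Segment(0, 10, {})],
        )
        with pytest.raises(InfeasibleScriptError):
            generate_scenario(spec)

    def test_spec_from_config_file_roundtrip(self, tmp_path):
        import yaml
        from thermotrack.synth import load_scenario

        cfg = {
            "arena": [120, 120],
            "seed": 4,
            "noise_sd": 0.4,
            "mice": [{"half_axes": [10, 4], "temp_offset": 5.0, "tail_length": 6}],
            "motions": [[{"n_frames": 20, "start": [40, 60], "end": [80, 60]}]],
            "segments": [{"start": 0, "end": 20, "labels": {}}],
        }
        path = tmp_path / "scenario.yaml"
        path.write_text(yaml.safe_dump(cfg))
        spec = load_scenario(path)
        assert spec.arena == (120, 120)
        assert spec.n_frames == 20
        frames, gt = generate_scenario(spec)
        assert len(frames) == 20
        np.testing.assert_allclose(gt.poses[0][0].centroid, [40.0, 60.0])

    def test_photometric_contract(self, disjoint_video):
        """Mean in-body temperature exceeds background by >= offset - 3 sd."""
        frames, gt = disjoint_video
        spec = gt.spec
        ok = 0
        for t in range(0, len(frames), 10):
            good = True
            for m, pose in enumerate(gt.poses[t]):
                mask = pose.mask(frames[t].shape)
                body_mean = frames[t].values[mask].mean()
                if body_mean - spec.bg_mean < spec.mice[m].temp_offset - 3 * spec.noise_sd:
                    good = False
            ok += good
        assert ok == len(range(0, len(frames), 10))
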