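"""Frame geometry, gaze mapping, cross-camera transfer, episodes, trials."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from planegaze import (
    GazeSample,
    IndividualMarker,
    MarkerDetection,
    associate_gaze_to_frames,
    build_observations,
    detect_individual_marker_episodes,
    episodes_to_trials,
    estimate_frame_geometry,
    map_gaze_to_plane,
    map_plane_gaze_to_camera,
    make_default_plane,
    project_point,
)
from planegaze.mapping import detect_markers, read_detections, write_detections
from planegaze.planes import PlaneDefinition, marker_corners_mm

from .conftest import random_pose


def _detections_for_pose(plane, pose, calib, frame_idx=0, ts=0.0, n_markers=None):
    dets = []
    for m in plane.markers[: (n_markers or len(plane.markers))]:
        px = project_point(marker_corners_mm(m), pose, calib)
        dets.append(MarkerDetection(frame_idx, ts, m.marker_id, px))
    return dets


# ------------------------------------------------------------ frame geometry

class TestFrameGeometry:
    def test_too_few_markers_gives_none(self, wide_calib):
        plane = make_default_plane()
        rng = np.random.default_rng(0)
        dets = _detections_for_pose(plane, random_pose(rng), wide_calib, n_markers=2)
        assert estimate_frame_geometry(dets, plane, wide_calib) is None

    def test_noise_free_recovery(self, wide_calib):
        plane = make_default_plane()
        rng = np.random.default_rng(1)
        pose_true = random_pose(rng)
        dets = _detections_for_pose(plane, pose_true, wide_calib, n_markers=5)
        obs = estimate_frame_geometry(dets, plane, wide_calib)
        assert obs is not None
        assert obs.n_markers_used == 5
        assert obs.reprojection_rms < 1e-6
        assert np.abs(obs.pose.t - pose_true.t).max() < 1e-6
        assert obs.homography.rms < 1e-6

    def test_single_marker_flagged_when_allowed(self, wide_calib):
        plane0 = make_default_plane()
        plane = PlaneDefinition(
            plane0.name, plane0.markers, plane0.width, plane0.height, min_markers=1
        )
        rng = np.random.default_rng(2)
        dets = _detections_for_pose(plane, random_pose(rng), wide_calib, n_markers=1)
        obs = estimate_frame_geometry(dets, plane, wide_calib)
        assert obs is not None
        assert "ambiguous pose risk" in obs.flags

    def test_no_calibration_gives_homography_only(self, wide_calib):
        plane = make_default_plane()
        rng = np.random.default_rng(3)
        dets = _detections_for_pose(plane, random_pose(rng), wide_calib, n_markers=4)
        obs = estimate_frame_geometry(dets, plane, None)
        assert obs.pose is None and obs.homography is not None

    def test_mixed_frames_rejected(self, wide_calib):
        plane = make_default_plane()
        rng = np.random.default_rng(4)
        pose = random_pose(rng)
        dets = _detections_for_pose(plane, pose, wide_calib, frame_idx=0, n_markers=3)
        dets += _detections_for_pose(plane, pose, wide_calib, frame_idx=1, n_markers=3)
        with pytest.raises(ValueError, match="single frame"):
            estimate_frame_geometry(dets, plane, wide_calib)


def test_detect_markers_requires_plugged_detector():
    with pytest.raises(NotImplementedError, match="detector"):
        detect_markers([], ["4x4_50"])


def test_detections_cache_round_trip(tmp_path, wide_calib):
    plane = make_default_plane()
    rng = np.random.default_rng(5)
    dets = _detections_for_pose(plane, random_pose(rng), wide_calib, ts=0.123)
    write_detections(dets, tmp_path / "dets.tsv")
    back = read_detections(tmp_path / "dets.tsv")
    assert len(back) == len(dets)
    for a, b in zip(dets, back):
        assert (a.frame_idx, a.marker_id) == (b.frame_idx, b.marker_id)
        assert np.allclose(a.corners, b.corners, atol=1e-5)


# ------------------------------------------------------------- association

class TestAssociation:
    def test_nearest_frame(self):
        idx = associate_gaze_to_frames([0.101], [0.10, 0.12])
        assert idx.tolist() == [0]

    def test_midpoint_tie_goes_to_earlier_frame(self):
        idx = associate_gaze_to_frames([0.11], [0.10, 0.12])
        assert idx.tolist() == [0]

    def test_far_out_of_range_unassociated(self):
        frames = np.arange(0, 5.001, 0.02)
        idx = associate_gaze_to_frames([9.99], frames)
        assert idx.tolist() == [-1]

    def test_slightly_past_last_frame_still_associated(self):
        frames = np.arange(0, 5.001, 0.02)
        idx = associate_gaze_to_frames([5.01], frames)
        assert idx.tolist() == [len(frames) - 1]


# ---------------------------------------------------------------- mapping

class TestGazeMapping:
    def test_recovers_simulator_fixations(self, small_mapping_sim):
        spec, gt = small_mapping_sim
        rt = gt.recordings["et1"]
        plane = gt.plane
        obs = build_observations(rt.detections, plane, spec.calib)
        gaze = [GazeSample(t, tuple(p)) for t, p in zip(rt.gaze_rec_times, rt.true_gaze_px)]
        pgs = map_gaze_to_plane(gaze, obs, rt.frame_rec_times, plane, spec.calib, "pose")
        valid = [(pg, tp) for pg, tp in zip(pgs, rt.true_plane_point) if pg.valid]
        assert len(valid) > 0.9 * len(pgs)
        err = max(np.abs(np.array(pg.pos_mm) - tp).max() for pg, tp in valid)
        assert err < 1e-6

    def test_homography_path_close_to_truth(self, small_mapping_sim):
        spec, gt = small_mapping_sim
        rt = gt.recordings["et1"]
        obs = build_observations(rt.detections, gt.plane, None)
        gaze = [GazeSample(t, tuple(p)) for t, p in zip(rt.gaze_rec_times, rt.true_gaze_px)]
        pgs = map_gaze_to_plane(gaze, obs, rt.frame_rec_times, gt.plane, None, "homography")
        valid = [(pg, tp) for pg, tp in zip(pgs, rt.true_plane_point) if pg.valid]
        err = max(np.abs(np.array(pg.pos_mm) - tp).max() for pg, tp in valid)
        assert err < 1e-3

    def test_auto_prefers_pose_when_calibrated(self, small_mapping_sim):
        spec, gt = small_mapping_sim
        rt = gt.recordings["et1"]
        obs = build_observations(rt.detections, gt.plane, spec.calib)
        gaze = [GazeSample(t, tuple(p)) for t, p in zip(rt.gaze_rec_times[:50], rt.true_gaze_px[:50])]
        pgs = map_gaze_to_plane(gaze, obs, rt.frame_rec_times, gt.plane, spec.calib, "auto")
        assert all(pg.method == "pose" for pg in pgs if pg.valid)

    def test_missing_observation_gives_invalid_sample(self, small_mapping_sim):
        spec, gt = small_mapping_sim
        rt = gt.recordings["et1"]
        obs = build_observations(rt.detections, gt.plane, spec.calib)
        obs.pop(0, None)  # remove the first frame's geometry
        gaze = [GazeSample(float(rt.frame_rec_times[0]), (960.0, 540.0))]
        pgs = map_gaze_to_plane(gaze, obs, rt.frame_rec_times, gt.plane, spec.calib)
        assert pgs[0].valid is False and pgs[0].pos_mm is None

    def test_pose_method_without_calibration_errors(self, small_mapping_sim):
        spec, gt = small_mapping_sim
        rt = gt.recordings["et1"]
        obs = build_observations(rt.detections, gt.plane, None)
        with pytest.raises(Exception, match="calibration"):
            map_gaze_to_plane([], obs, rt.frame_rec_times, gt.plane, None, "pose")

    def test_mapping_noise_stays_bounded(self):
        """0.5 px corner noise keeps median mapping error below 5 mm at 600 mm."""
        from planegaze.simulate import Segment, SimRecording, SimulationSpec, simulate_session

        spec = SimulationSpec(
            segments=(Segment("static", 2.0),),
            recordings=(SimRecording("et1", "eye_tracker", (0.0, 0.0, -600.0)),),
            corner_noise_px=0.5, gaze_noise_deg=0.0,
            video_fps=25.0, gaze_rate_hz=50.0, seed=21,
        )
        gt = simulate_session(spec)
        rt = gt.recordings["et1"]
        obs = build_observations(rt.detections, gt.plane, spec.calib)
        gaze = [GazeSample(t, tuple(p)) for t, p in zip(rt.gaze_rec_times, rt.true_gaze_px)]
        pgs = map_gaze_to_plane(gaze, obs, rt.frame_rec_times, gt.plane, spec.calib, "pose")
        errs = [
            np.linalg.norm(np.array(pg.pos_mm) - tp)
            for pg, tp in zip(pgs, rt.true_plane_point) if pg.valid
        ]
        assert 0 < np.median(errs) < 5.0


class TestCrossCameraTransfer:
    def test_self_transfer_is_identity(self, small_mapping_sim):
        spec, gt = small_mapping_sim
        rt = gt.recordings["et1"]
        obs = build_observations(rt.detections, gt.plane, spec.calib)
        gaze = [GazeSample(t, tuple(p)) for t, p in zip(rt.gaze_rec_times[:100], rt.true_gaze_px[:100])]
        pgs = map_gaze_to_plane(gaze, obs, rt.frame_rec_times, gt.plane, spec.calib, "pose")
        ident = lambda t: t
        out = map_plane_gaze_to_camera(
            pgs, ident, obs, rt.frame_rec_times, ident, spec.calib
        )
        for pg, (t_ref, px), g in zip(pgs, out, gaze):
            if pg.valid and px is not None:
                assert np.abs(np.array(px) - np.array(g.gaze_px)).max() < 1e-3

    def test_missing_other_observation_gives_none(self, small_mapping_sim):
        spec, gt = small_mapping_sim
        rt = gt.recordings["et1"]
        obs = build_observations(rt.detections, gt.plane, spec.calib)
        gaze = [GazeSample(float(rt.gaze_rec_times[0]), tuple(rt.true_gaze_px[0]))]
        pgs = map_gaze_to_plane(gaze, obs, rt.frame_rec_times, gt.plane, spec.calib)
        ident = lambda t: t
        out = map_plane_gaze_to_camera(pgs, ident, {}, rt.frame_rec_times, ident, spec.calib)
        assert out[0][1] is None


# ---------------------------------------------------------------- episodes

def _dets_at_frames(frames, marker_id, fps=60.0):
    return [
        MarkerDetection(f, f / fps, marker_id, np.array(
            [[0, 0], [10, 0], [10, 10], [0, 10.0]]))
        for f in frames
    ]


def brute_force_episodes(times, min_duration, max_gap):
    """Independent O(n^2) oracle: all maximal valid runs of detection times."""
    times = sorted(set(times))
    episodes = []
    n = len(times)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and times[j + 1] - times[j] <= max_gap:
            j += 1
        if times[j] - times[i] >= min_duration:
            episodes.append((times[i], times[j]))
        i = j + 1
    return episodes


class TestEpisodes:
    def test_gap_bridging(self):
        frames = [f for f in range(100, 151) if f not in (120, 121)]
        dets = _dets_at_frames(frames, 80)
        eps = detect_individual_marker_episodes(dets, 80, min_duration=0.3, max_gap=0.1)
        assert len(eps) == 1
        assert np.isclose(eps[0][0], 100 / 60) and np.isclose(eps[0][1], 150 / 60)

    def test_single_frame_too_short(self):
        dets = _dets_at_frames([42], 80)
        assert detect_individual_marker_episodes(dets, 80, 0.2, 0.1) == []

    def test_absent_marker_gives_nothing(self):
        dets = _dets_at_frames([1, 2, 3], 80)
        assert detect_individual_marker_episodes(dets, 99, 0.0, 0.1) == []

    def test_accepts_individual_marker_object(self):
        dets = _dets_at_frames(range(50), 80)
        m = IndividualMarker(80, "sync_transient")
        assert len(detect_individual_marker_episodes(dets, m, 0.3, 0.1)) == 1

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.integers(0, 300), min_size=0, max_size=80),
        st.sampled_from([0.0, 0.1, 0.2, 0.3, 0.5]),
        st.sampled_from([0.017, 0.05, 0.1, 0.2, 0.4]),
    )
    def test_matches_brute_force_oracle(self, frames, min_dur, max_gap):
        dets = _dets_at_frames(frames, 7)
        got = detect_individual_marker_episodes(dets, 7, min_dur, max_gap)
        expected = brute_force_episodes([f / 60.0 for f in frames], min_dur, max_gap)
        assert len(got) == len(expected)
        for (a0, a1), (b0, b1) in zip(got, expected):
            assert np.isclose(a0, b0) and np.isclose(a1, b1)


class TestTrials:
    def test_simple_pairing(self):
        trials, issues = episodes_to_trials([(10, 10.5), (60, 60.5)], [(50, 50.5), (100, 100.5)])
        assert issues == []
        assert [(t.number, t.start, t.end) for t in trials] == [(1, 10.5, 50), (2, 60.5, 100)]

    def test_start_without_end_reported(self):
        trials, issues = episodes_to_trials([(10, 10.5)], [])
        assert trials == [] and len(issues) == 1

    def test_end_before_any_start_skipped(self):
        trials, issues = episodes_to_trials([(60, 60.5)], [(10, 10.5), (100, 100.5)])
        assert len(trials) == 1 and trials[0].start == 60.5
        assert any("no preceding start" in i for i in issues)

    def test_double_start_drops_first(self):
        trials, issues = episodes_to_trials([(10, 10.5), (20, 20.5)], [(50, 50.5)])
        assert len(trials) == 1 and trials[0].start == 20.5
        assert any("unpaired" in i for i in issues)
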