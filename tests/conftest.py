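"""Shared fixtures: cameras, poses, and simulated sessions.

Expensive simulated sessions are session-scoped so the whole suite
reuses one generation + pipeline run.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from planegaze import (
    CameraCalibration,
    Pose,
    default_spec,
    run_pipeline,
    simulate_session,
)
from planegaze.simulate import Segment, SimRecording, SimulationSpec, _look_at, _rot


@pytest.fixture
def calib() -> CameraCalibration:
    return CameraCalibration(fx=1000.0, fy=1000.0, cx=640.0, cy=360.0, w=1280, h=720)


@pytest.fixture
def wide_calib() -> CameraCalibration:
    return CameraCalibration(fx=1000.0, fy=1000.0, cx=960.0, cy=540.0, w=1920, h=1080)


@pytest.fixture
def fronto_pose() -> Pose:
    return Pose(np.eye(3), np.array([0.0, 0.0, 500.0]))


def random_pose(rng: np.random.Generator, distance=(400.0, 900.0)) -> Pose:
    """A camera in front of the plane: bounded tilt, random distance."""
    d = rng.uniform(*distance)
    C = np.array([rng.uniform(-150, 150), rng.uniform(-150, 150), -d])
    base = _look_at(C, np.zeros(3))
    yaw = math.radians(rng.uniform(-15, 15))
    pitch = math.radians(rng.uniform(-15, 15))
    R = _rot("x", pitch) @ _rot("y", yaw) @ base.R
    return Pose(R, -R @ C)


@pytest.fixture(scope="session")
def e2e_project(tmp_path_factory):
    """Noise-free canonical session (2 eye trackers + overview), pipeline run."""
    d = tmp_path_factory.mktemp("e2e")
    spec = default_spec(seed=7, corner_noise_px=0.0, gaze_noise_deg=0.0)
    gt = simulate_session(spec, d)
    status = run_pipeline(d)
    return d, spec, gt, status


@pytest.fixture(scope="session")
def vor_sim():
    """Single eye tracker doing the VOR task, zero noise, zero latency."""
    spec = SimulationSpec(
        segments=(
            Segment("static", 1.0),
            Segment("yaw", 10.0, amplitude_deg=20.0, frequency_hz=0.5),
            Segment("pitch", 10.0, amplitude_deg=20.0, frequency_hz=0.5),
            Segment("static", 1.6),
        ),
        recordings=(SimRecording("et1", "eye_tracker", (0.0, 0.0, -600.0)),),
        corner_noise_px=0.0,
        gaze_noise_deg=0.0,
        transient_times=(),
        seed=3,
    )
    return spec, simulate_session(spec)


@pytest.fixture(scope="session")
def small_mapping_sim():
    """Short static-then-dwell session used by mapping tests (noise-free)."""
    spec = SimulationSpec(
        segments=(Segment("static", 1.0), Segment("dwell", 4.5, dwell_s=0.5)),
        recordings=(SimRecording("et1", "eye_tracker", (0.0, 0.0, -600.0)),),
        corner_noise_px=0.0,
        gaze_noise_deg=0.0,
        video_fps=25.0,
        gaze_rate_hz=50.0,
        seed=11,
    )
    return spec, simulate_session(spec)
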