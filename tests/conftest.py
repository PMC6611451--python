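"""Shared fixtures: phantoms and tracking runs reused across test modules.

The heavy end-to-end runs are session-scoped so the recovery, invariance
and statistics tests share one tracking pass each.
"""

import numpy as np
import pytest

from fasctrack.phantom import KinematicProfile, PhantomConfig, generate, make_annotation
from fasctrack.tracking import TrackerConfig, track_video


def _static_config(n_frames, seed=0):
    return PhantomConfig(
        n_frames=n_frames,
        seed=seed,
        length_profile=KinematicProfile("linear_ramp", 55.0, 55.0),
        pennation_profile=KinematicProfile("linear_ramp", 25.0, 25.0),
    )


@pytest.fixture(scope="session")
def contraction_phantom():
    """The reference contraction: L 60 -> 40 mm, theta 20 -> 35 deg over
    120 frames at 60 frames/s, default speckle, perfect annotation."""
    cfg = PhantomConfig(n_frames=120, seed=0)
    return cfg, generate(cfg)


@pytest.fixture(scope="session")
def contraction_tracking(contraction_phantom):
    cfg, pv = contraction_phantom
    result = track_video(pv.frames, pv.annotation, TrackerConfig(), cfg.frame_spec)
    return cfg, pv, result


@pytest.fixture(scope="session")
def static_video_50(static_phantom_frame):
    """50 identical frames of the static phantom."""
    cfg, frame, annotation = static_phantom_frame
    frames = np.repeat(frame[None], 50, axis=0)
    return cfg, frames, annotation


@pytest.fixture(scope="session")
def static_phantom_frame():
    """One rendered frame of a static (constant-kinematics) phantom plus
    its perfect annotation."""
    cfg = _static_config(n_frames=1)
    pv = generate(cfg)
    return cfg, pv.frames[0], pv.annotation


@pytest.fixture(scope="session")
def static_tracking_50(static_video_50):
    cfg, frames, annotation = static_video_50
    result = track_video(frames, annotation, TrackerConfig(), cfg.frame_spec)
    return cfg, frames, result


@pytest.fixture(scope="session")
def small_static_video(static_phantom_frame):
    """Short identical-frame video for fast invariance tests."""
    cfg, frame, annotation = static_phantom_frame
    frames = np.repeat(frame[None], 8, axis=0)
    return cfg, frames, annotation


@pytest.fixture(scope="session")
def jittered_replicates():
    """Nine tracked replicates of one short contraction with jittered
    first-frame annotations, mimicking 3 examiners x 3 days."""
    cfg = PhantomConfig(
        n_frames=30,
        seed=0,
        length_profile=KinematicProfile("linear_ramp", 58.0, 48.0),
        pennation_profile=KinematicProfile("linear_ramp", 21.0, 28.0),
    )
    pv = generate(cfg)
    runs = []
    for rep in range(9):
        if rep == 0:
            annotation = pv.annotation  # first examiner draws perfectly
        else:
            rng = np.random.default_rng(1000 + rep)
            annotation = make_annotation(cfg, jitter_mm=1.0, jitter_deg=2.0, rng=rng)
        result = track_video(pv.frames, annotation, TrackerConfig(), cfg.frame_spec)
        runs.append(result)
    return cfg, pv, runs
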