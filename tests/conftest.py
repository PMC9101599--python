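"""Shared fixtures: curves, profiles, and a small synthetic cohort."""

import numpy as np
import pytest

import wristkin as wk


@pytest.fixture(scope="session")
def square_curve():
    return wk.make_task_curve("square", 8, 400)


@pytest.fixture(scope="session")
def circle_curve():
    return wk.make_task_curve("circle", 8, 720)


@pytest.fixture(scope="session")
def healthy_recording(square_curve):
    return wk.simulate_trajectory(square_curve, wk.profile_from_score(28, 5), 0.0)


@pytest.fixture(scope="session")
def impaired_recording(square_curve):
    return wk.simulate_trajectory(square_curve, wk.profile_from_score(10, 5), 0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """5 patients + 1 control (63 trials), scores drawn uniformly on 0-28."""
    return wk.make_cohort(5, 1, score_sampler="uniform", seed=3)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    return wk.build_feature_table(small_cohort, wk.default_curves())


def line_recording(points, dt=1.0, **kwargs):
    """Recording helper: positions sampled at a fixed interval."""
    points = np.asarray(points, dtype=float)
    defaults = dict(subject_id="t", hand="right", shape_id="square", force_mode=0.0)
    defaults.update(kwargs)
    return wk.TrajectoryRecording(
        times=np.arange(len(points)) * dt,
        xs=points[:, 0],
        ys=points[:, 1],
        **defaults,
    )
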