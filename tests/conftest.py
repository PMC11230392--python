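import numpy as np
import pandas as pd
import pytest

import foragekit as fk
from foragekit import features as feat
from foragekit import segmentation as seg


@pytest.fixture(scope="session")
def geometry():
    return fk.ArenaGeometry()


@pytest.fixture(scope="session")
def toy_cohort():
    """Small two-archetype cohort with ground truth (seeded)."""
    cfg = fk.make_default_config("two_archetype_toy", seed=1)
    traj, meta, gross, truth = fk.simulate_cohort(cfg)
    return cfg, traj, meta, gross, truth


@pytest.fixture(scope="session")
def toy_segmented(toy_cohort, geometry):
    cfg, traj, meta, gross, truth = toy_cohort
    ann = seg.annotate_zones(traj, geometry)
    exc = seg.segment_excursions(ann, geometry)
    return ann, exc


@pytest.fixture(scope="session")
def toy_features(toy_segmented, geometry):
    ann, exc = toy_segmented
    return feat.feature_matrix(exc, ann, geometry)


def make_trajectory(samples, mouse_id="M001", phase="Exploration", dt=0.2):
    """Build a trajectory frame from a list of (x, y) positions."""
    xy = np.asarray(samples, dtype=float)
    return pd.DataFrame({
        "mouse_id": mouse_id, "phase": phase,
        "t_s": np.arange(len(xy)) * dt,
        "x_cm": xy[:, 0], "y_cm": xy[:, 1],
    })


def straight_path(start, end, speed_cm_s, dt=0.2):
    """Constant-speed straight polyline from start to end (inclusive)."""
    start, end = np.asarray(start, float), np.asarray(end, float)
    dist = np.linalg.norm(end - start)
    n = int(round(dist / (speed_cm_s * dt)))
    ts = np.linspace(0.0, 1.0, n + 1)
    return start + ts[:, None] * (end - start)
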