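import numpy as np
import pandas as pd
import pytest

from trapnet.events import AssociationMatrix
from trapnet.synthetic import SimulationConfig, simulate_community


def make_matrix(weights, roster=None) -> AssociationMatrix:
    w = np.asarray(weights, dtype=float)
    if roster is None:
        roster = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ"[: w.shape[0]])
    return AssociationMatrix(tuple(roster), w)


def random_symmetric(rng, n, scale=1.0) -> np.ndarray:
    w = rng.random((n, n)) * scale
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return w


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulated deployment shared across read-only tests."""
    return simulate_community(SimulationConfig(n_events=120, seed=42))


@pytest.fixture(scope="session")
def recovery_dataset():
    """Deployment large enough for planted-structure recovery checks."""
    return simulate_community(
        SimulationConfig(n_events=500, seed=3, p_within=0.7, p_between=0.05)
    )


def videos_frame(rows):
    """rows of (video_id, camera_id, iso_timestamp)."""
    return pd.DataFrame(rows, columns=["video_id", "camera_id", "start_timestamp"])


def detections_frame(rows):
    """rows of (video_id, camera_id, ts, channel, individual_id[, token])."""
    full = []
    for r in rows:
        vid, cam, ts, channel, ind = r[:5]
        token = r[5] if len(r) > 5 else f"{vid}:{ind or id(r)}"
        full.append((vid, cam, ts, channel, "", ind, "adult_female", 1, token))
    return pd.DataFrame(
        full,
        columns=[
            "video_id", "camera_id", "start_timestamp", "channel",
            "clip_positions", "individual_id", "age_sex_class", "weaned", "token",
        ],
    )
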