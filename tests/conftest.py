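"""Shared fixtures: small synthetic scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from ms2burst.segmentation import SegmentationConfig, segment_movie
from ms2burst.spot_quant import extract_traces
from ms2burst.synth import NoiseModel, SceneConfig, simulate_scene
from ms2burst.tracking import track_movie


@pytest.fixture(scope="session")
def small_scene() -> SceneConfig:
    return SceneConfig(
        n_nuclei=12, frame_count=40, image_shape=(3, 120, 160), seed=5
    )


@pytest.fixture(scope="session")
def small_sim(small_scene):
    return simulate_scene(small_scene)


@pytest.fixture(scope="session")
def small_frames(small_sim):
    movie, _ = small_sim
    return segment_movie(movie, SegmentationConfig())


@pytest.fixture(scope="session")
def small_tracks(small_frames):
    return track_movie(small_frames)


@pytest.fixture(scope="session")
def small_traces(small_sim, small_frames, small_tracks):
    movie, _ = small_sim
    traces, spotfits = extract_traces(movie, small_frames, small_tracks)
    return traces, spotfits


@pytest.fixture(scope="session")
def noisefree_sim():
    scene = SceneConfig(
        n_nuclei=10,
        frame_count=30,
        image_shape=(3, 120, 160),
        seed=7,
        noise_model=NoiseModel(enabled=False),
    )
    return simulate_scene(scene), scene


def match_track_to_truth(tracks, frames, truth) -> dict[int, int]:
    """Map each track id to the ground-truth nucleus index it follows,
    using the centroid at the track's first frame."""
    out = {}
    for tid in sorted(tracks.table["track_id"].unique()):
        sub = tracks.table[tracks.table["track_id"] == tid]
        row = sub.iloc[0]
        t = int(row["frame"])
        d = np.hypot(
            truth.centroids[t][:, 0] - row["centroid_row"],
            truth.centroids[t][:, 1] - row["centroid_col"],
        )
        out[int(tid)] = int(np.argmin(d))
    return out
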