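import numpy as np
import pandas as pd
import pytest

from kymotility.io_model import ExperimentManifest, KymographContext, Track, TrackVertex


def make_track(points, track_id="t1", context_id="mt1"):
    """Build a Track from (t, x) pairs."""
    return Track(
        track_id=track_id,
        vertices=tuple(TrackVertex(t=float(t), x=float(x)) for t, x in points),
        context_id=context_id,
    )


@pytest.fixture
def context():
    return KymographContext(
        context_id="mt1",
        mt_length_nm=10_000.0,
        duration_s=100.0,
        pixel_size_nm=105.0,
        frame_interval_s=0.136,
        polarity="plus_right",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_tracks(rng, n, context_id="mt1"):
    """Random valid tracks with strictly increasing times."""
    tracks = []
    for i in range(n):
        m = rng.integers(2, 12)
        t = np.cumsum(rng.uniform(0.05, 3.0, size=m)) + rng.uniform(0, 5)
        x = rng.normal(0, 2000, size=m)
        tracks.append(make_track(zip(t, x), track_id=f"trk{i}", context_id=context_id))
    return tracks


def simple_manifest(track_ids, experiment="exp1", condition="cond", context_id="mt1", movie="mov1"):
    rows = [(condition, experiment, movie, context_id, t) for t in track_ids]
    return ExperimentManifest(
        pd.DataFrame(rows, columns=["condition", "experiment_id", "movie_id", "context_id", "track_id"])
    )
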