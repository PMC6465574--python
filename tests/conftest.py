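"""Shared fixtures: small, fast synthetic designs and preprocessed features."""

import numpy as np
import pandas as pd
import pytest

from nirsemo import behavior
from nirsemo.io import RunConfig
from nirsemo.pipeline import preprocess_recording
from nirsemo.synthetic import SimDesign, gen_ratings, gen_recording


@pytest.fixture(scope="session")
def small_design() -> SimDesign:
    """Full 37-clip layout at reduced sampling rate and short clips."""
    return SimDesign(
        n_participants=3,
        fs=10.0,
        duration_range_s=(30.0, 45.0),
        rest_jitter_s=5.0,
    )


@pytest.fixture(scope="session")
def small_config() -> RunConfig:
    return RunConfig(fs=10.0, n_shuffles=20, n_participants=3)


@pytest.fixture(scope="session")
def small_recording(small_design):
    raw, truth = gen_recording(small_design, participant=0, seed=11)
    return raw, truth


@pytest.fixture(scope="session")
def small_features(small_recording, small_config):
    raw, _ = small_recording
    return preprocess_recording(raw, small_config, participant_id="sub01")


@pytest.fixture(scope="session")
def small_ratings(small_design):
    ratings, truth = gen_ratings(small_design, seed=11)
    return ratings


@pytest.fixture(scope="session")
def selected_clips(small_design, small_ratings):
    """Top-6 clips per cluster plus the negative set."""
    scores = behavior.cluster_scores(
        small_ratings.clip_means("positive"), small_design.clusters
    )
    sel = {
        name: behavior.select_top_clips(scores[name])
        for name in small_design.clusters.names
    }
    sel["negative"] = small_ratings.clips.loc[
        small_ratings.clips["condition"] == "negative", "clip_id"
    ].tolist()
    return sel, scores
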