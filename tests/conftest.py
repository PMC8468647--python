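"""Shared fixtures: the full-protocol synthetic dataset is expensive to
extract features from, so it is built once per test session."""

import numpy as np
import pandas as pd
import pytest

from gazedyn import features, simdata

FULL_MASTER_SEED = 1


@pytest.fixture(scope="session")
def cohort_dataset():
    """Full-protocol dataset: 24 subjects x 2 sessions x 29 points."""
    recordings, manifest = simdata.simulate_dataset(
        n_subjects=24, n_sessions=2, master_seed=FULL_MASTER_SEED)
    return recordings, manifest


@pytest.fixture(scope="session")
def cohort_features(cohort_dataset):
    """Segment-level feature table of the full dataset (13920 rows)."""
    recordings, _ = cohort_dataset
    return features.features_table(recordings)


@pytest.fixture(scope="session")
def stimulus():
    return simdata.make_stimulus_layout(seed=3)


def make_segment_table(n_subjects, n_sessions, n_points=29, seed=0):
    """Structurally valid random segment-feature table (no simulation)."""
    rng = np.random.default_rng(seed)
    rows = []
    for subj in range(1, n_subjects + 1):
        for sess in range(1, n_sessions + 1):
            for point in range(1, n_points + 1):
                for seg in range(1, features.SEGMENTS_PER_POINT + 1):
                    rows.append((subj, sess, point, seg,
                                 *rng.normal(size=features.N_FEATURES), True))
    return pd.DataFrame(
        rows, columns=["subject", "session", "point", "segment",
                       *features.FEATURE_NAMES, "lle_valid"])


@pytest.fixture()
def segment_table():
    """Small random table: 3 subjects x 2 sessions x 29 points."""
    return make_segment_table(3, 2)
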