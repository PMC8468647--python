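"""Feature-vector assembly and train/test set construction.

A feature vector describes one stimulus point (10 segments x 23 features =
230 values) or three consecutive points (690 values), labelled with the
subject it came from.  Two split schemes are supported:

* mixed-session stratified — 75% of vectors drawn at random for training
  with identical per-subject proportions and disjoint train/test sets;
* session-disjoint — train on one full session, test on the other,
  exposing session-to-session changes in the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .exceptions import ConfigurationError, SchemaError, StratificationError
from .features import FEATURE_NAMES, N_FEATURES, SEGMENTS_PER_POINT

SCHEME_STRATIFIED = "mixed-session-stratified"
SCHEME_SESSION = "session-disjoint"


@dataclass(frozen=True, eq=False)
class FeatureVector:
    """Labelled concatenation of segment descriptors for 1 or 3 points."""

    subject_id: int
    session_id: int
    point_ids: tuple[int, ...]
    values: np.ndarray
    check_dim: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "point_ids", tuple(self.point_ids))
        expected = N_FEATURES * SEGMENTS_PER_POINT * len(self.point_ids)
        if self.check_dim and len(vals) != expected:
            raise SchemaError(
                f"vector for points {self.point_ids} has {len(vals)} values, "
                f"expected {expected}")


@dataclass
class DatasetSplit:
    """Disjoint train/test vector lists plus the scheme that produced them."""

    train: list[FeatureVector]
    test: list[FeatureVector]
    scheme: str
    seed: int | None = None


def _point_block(table, subject: int, session: int, point: int) -> np.ndarray:
    """230 values for one (subject, session, point): 10 segments x 23 features."""
    sel = table[(table["subject"] == subject) & (table["session"] == session)
                & (table["point"] == point)].sort_values("segment")
    if len(sel) != SEGMENTS_PER_POINT:
        raise SchemaError(
            f"subject {subject} session {session} point {point}: expected "
            f"{SEGMENTS_PER_POINT} segments, found {len(sel)}")
    return sel[list(FEATURE_NAMES)].to_numpy(dtype=float).ravel()


def build_point_vectors(table) -> list[FeatureVector]:
    """One 230-value vector per (subject, session, stimulus point)."""
    vectors = []
    for (subject, session), grp in table.groupby(["subject", "session"],
                                                 sort=True):
        for point in sorted(grp["point"].unique()):
            vectors.append(FeatureVector(
                subject_id=int(subject), session_id=int(session),
                point_ids=(int(point),),
                values=_point_block(table, subject, session, point)))
    return vectors


def build_window_vectors(table, window: int = 3) -> list[FeatureVector]:
    """Sliding windows of consecutive points (stride 1) within each session.

    With 29 points per session and ``window=3`` this yields 27 overlapping
    690-value vectors per subject-session; windows never cross a session
    boundary.
    """
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    vectors = []
    for (subject, session), grp in table.groupby(["subject", "session"],
                                                 sort=True):
        points = sorted(grp["point"].unique())
        if len(points) < window:
            raise SchemaError(
                f"subject {subject} session {session}: {len(points)} points "
                f"cannot form a window of {window}")
        blocks = {p: _point_block(table, subject, session, p) for p in points}
        for i in range(len(points) - window + 1):
            span = points[i:i + window]
            vectors.append(FeatureVector(
                subject_id=int(subject), session_id=int(session),
                point_ids=tuple(int(p) for p in span),
                values=np.concatenate([blocks[p] for p in span])))
    return vectors


def stratified_split(vectors: list[FeatureVector], train_fraction: float = 0.75,
                     seed: int = 0) -> DatasetSplit:
    """Per-subject stratified random split with disjoint train/test sets.

    Stratifying on the subject label keeps the train:test ratio identical
    for every subject (to within rounding) and guarantees each subject is
    represented in both sets.
    """
    labels = [v.subject_id for v in vectors]
    counts = {s: labels.count(s) for s in set(labels)}
    thin = [s for s, c in counts.items() if c < 2]
    if thin:
        raise StratificationError(
            f"subjects {sorted(thin)} have fewer than 2 vectors")
    idx = np.arange(len(vectors))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=labels, random_state=seed)
    return DatasetSplit(
        train=[vectors[i] for i in sorted(train_idx)],
        test=[vectors[i] for i in sorted(test_idx)],
        scheme=SCHEME_STRATIFIED, seed=seed)


def session_split(vectors: list[FeatureVector],
                  train_session: int = 1) -> DatasetSplit:
    """Train on one session, test on all others (disjoint by construction)."""
    train = [v for v in vectors if v.session_id == train_session]
    test = [v for v in vectors if v.session_id != train_session]
    if not train:
        raise ConfigurationError(f"no vectors from session {train_session}")
    if not test:
        raise ConfigurationError("no vectors from any other session")
    return DatasetSplit(train=train, test=test, scheme=SCHEME_SESSION, seed=None)
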