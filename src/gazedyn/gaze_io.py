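"""On-disk formats: recordings, feature tables, manifests, splits.

One CSV dialect everywhere (comma separator, dot decimal, mandatory
header).  Recordings are one row per sample (`time_ms,x_deg,y_deg,
stimulus_index`); feature tables are one row per labelled feature vector;
manifests and splits are JSON.  All writers are deterministic and all
(writer, reader) pairs are inverse on valid data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DegenerateInputError, ParseError, SchemaError
from .simdata import GazeRecording
from .vectors import FeatureVector, DatasetSplit

RECORDING_COLUMNS = ["time_ms", "x_deg", "y_deg", "stimulus_index"]


def write_recording(recording: GazeRecording, path) -> None:
    """Write a recording as CSV, one row per sample.

    ``stimulus_index`` is 1-based and increments at each onset; time is in
    milliseconds from recording start.
    """
    n = recording.n_samples
    if n == 0:
        raise DegenerateInputError("refusing to write an empty recording")
    step = 1000.0 / recording.sampling_rate
    time_ms = np.round(np.arange(n) * step).astype(int)
    stim = np.searchsorted(recording.onsets, np.arange(n), side="right")
    df = pd.DataFrame({
        "time_ms": time_ms,
        "x_deg": recording.horizontal,
        "y_deg": recording.vertical,
        "stimulus_index": stim,
    })
    df.to_csv(path, index=False)


def read_recording(path, subject_id: int = 0, session_id: int = 0) -> GazeRecording:
    """Read a recording CSV; onsets and sampling rate are reconstructed.

    Onsets are the sample indices where ``stimulus_index`` changes
    (including the first sample); the sampling rate comes from the median
    ``time_ms`` spacing.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing} in header line 1")
    if len(df) == 0:
        raise ParseError(f"{path}: no samples")
    t = df["time_ms"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if len(bad):
        raise ParseError(
            f"{path}: time_ms not strictly increasing at data line {bad[0] + 2}")
    dt_ms = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    stim = df["stimulus_index"].to_numpy()
    onsets = np.concatenate([[0], np.flatnonzero(np.diff(stim) != 0) + 1])
    return GazeRecording(
        subject_id=subject_id,
        session_id=session_id,
        sampling_rate=1000.0 / dt_ms,
        horizontal=df["x_deg"].to_numpy(dtype=float),
        vertical=df["y_deg"].to_numpy(dtype=float),
        onsets=onsets,
    )


def write_feature_table(vectors: list[FeatureVector], path) -> None:
    """Write labelled feature vectors as CSV (subject, session, point_ids,
    f_0001..f_NNNN)."""
    if not vectors:
        raise SchemaError("no vectors to write")
    dims = {len(v.values) for v in vectors}
    if len(dims) != 1:
        raise SchemaError(f"mixed vector dimensionality: {sorted(dims)}")
    dim = dims.pop()
    cols = [f"f_{i + 1:04d}" for i in range(dim)]
    rows = [
        {"subject": v.subject_id, "session": v.session_id,
         "point_ids": "-".join(map(str, v.point_ids)),
         **dict(zip(cols, v.values))}
        for v in vectors
    ]
    pd.DataFrame(rows, columns=["subject", "session", "point_ids", *cols]
                 ).to_csv(path, index=False)


def read_feature_table(path, with_report: bool = False):
    """Read a feature-vector CSV back into FeatureVector objects.

    Rows with NaN features are kept (so the round trip is lossless) and
    flagged in the validity report available via ``with_report=True``.
    """
    try:
        df = pd.read_csv(path, dtype={"point_ids": str})
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("subject", "session", "point_ids"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    fcols = [c for c in df.columns if c.startswith("f_")]
    if not fcols:
        raise ParseError(f"{path}: no feature columns")
    vectors = []
    nan_rows = []
    for i, row in df.iterrows():
        values = row[fcols].to_numpy(dtype=float)
        if np.any(np.isnan(values)):
            nan_rows.append(int(i))
        vectors.append(FeatureVector(
            subject_id=int(row["subject"]),
            session_id=int(row["session"]),
            point_ids=tuple(int(p) for p in str(row["point_ids"]).split("-")),
            values=values,
            check_dim=False,
        ))
    if with_report:
        return vectors, {"n_rows": len(vectors), "nan_rows": nan_rows,
                         "valid": not nan_rows}
    return vectors


def save_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def load_manifest(path, check_files: bool = True) -> dict:
    """Load a dataset manifest, checking entry uniqueness and file existence."""
    try:
        manifest = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    entries = manifest.get("entries", [])
    keys = [(e["subject_id"], e["session_id"]) for e in entries]
    if len(set(keys)) != len(keys):
        raise SchemaError(f"{path}: duplicate (subject, session) entries")
    if check_files:
        base = Path(path).parent
        for e in entries:
            f = e.get("file")
            if f is not None and not (base / f).exists():
                raise ParseError(f"{path}: referenced file {f} does not exist")
    return manifest


def save_split(split: DatasetSplit, path) -> None:
    """Serialize a split as JSON (scheme, seed, and vector identities)."""
    def key(v: FeatureVector):
        return [v.subject_id, v.session_id, list(v.point_ids)]

    Path(path).write_text(json.dumps({
        "scheme": split.scheme,
        "seed": split.seed,
        "train": [key(v) for v in split.train],
        "test": [key(v) for v in split.test],
    }, sort_keys=True))


def load_split(path, vectors: list[FeatureVector]) -> DatasetSplit:
    """Rebuild a split by matching stored identities against ``vectors``."""
    try:
        blob = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    index = {(v.subject_id, v.session_id, v.point_ids): v for v in vectors}

    def pick(keys):
        out = []
        for s, sess, pts in keys:
            k = (s, sess, tuple(pts))
            if k not in index:
                raise SchemaError(f"{path}: vector {k} not present")
            out.append(index[k])
        return out

    return DatasetSplit(train=pick(blob["train"]), test=pick(blob["test"]),
                        scheme=blob["scheme"], seed=blob["seed"])
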