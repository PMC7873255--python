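"""File formats: track CSV, peak TSV, image stacks, metadata sidecars.

Units are micrometres and seconds everywhere on disk; column headers
carry units (``x_um``, ``t_s``) to prevent nm/um confusion.  Peak tables
are BED-derived TSV (0-based half-open intervals) with one or more
numeric read-count columns.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .tracks import TrackSchemaError, TrackSet, validate_track_table

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_peaks",
    "read_stack",
    "write_stack",
    "write_sidecar",
]


def write_tracks(tracks: TrackSet, path) -> None:
    """Write a TrackSet to CSV (track_id, frame, t_s, x_um, y_um, ...)."""
    tracks.df.to_csv(path, index=False)


def read_tracks(path, frame_interval: float | None = None) -> TrackSet:
    """Read a track CSV; infers the frame interval from t_s if not given.

    A write -> read round trip is the identity.  Schema violations raise
    :class:`~chromokin.tracks.TrackSchemaError` naming the offending
    column.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TrackSchemaError(f"{path}: empty file without header") from exc
    df = validate_track_table(df)
    if frame_interval is None:
        if len(df) >= 2:
            frames = df["frame"].to_numpy()
            t = df["t_s"].to_numpy()
            span = frames.max() - frames.min()
            frame_interval = (
                float((t.max() - t.min()) / span) if span > 0 else 1.0
            )
        else:
            frame_interval = 1.0
    return TrackSet(df, frame_interval, _validated=True)


PEAK_REQUIRED = ("chrom", "start", "end")


def read_peaks(path) -> pd.DataFrame:
    """Read a BED-derived TSV peak table with read-count columns.

    Validates 0-based half-open intervals (end > start), non-negative
    counts, and rejects duplicate intervals.  A table whose smallest start
    coordinate is 1 triggers an off-by-one warning (likely 1-based input).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEAK_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: peak table missing column(s): {missing}")
    for col in ("start", "end"):
        if not np.issubdtype(df[col].dtype, np.integer):
            raise ValueError(f"{path}: column {col!r} must be integer")
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise ValueError(
            f"{path}: end <= start at row(s) {bad.tolist()[:5]}"
        )
    dup = df.duplicated(subset=["chrom", "start", "end"])
    if dup.any():
        raise ValueError(
            f"{path}: duplicate interval(s) at row(s) "
            f"{df.index[dup].tolist()[:5]}"
        )
    count_cols = [
        c for c in df.columns
        if c not in PEAK_REQUIRED + ("name",) and np.issubdtype(df[c].dtype, np.number)
    ]
    for c in count_cols:
        if (df[c] < 0).any():
            raise ValueError(f"{path}: negative count in column {c!r}")
    if len(df) and int(df["start"].min()) == 1:
        warnings.warn(
            f"{path}: smallest start coordinate is 1 - input may be 1-based "
            "(expected 0-based half-open intervals)",
            stacklevel=2,
        )
    return df


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF as a 3D (z, y, x) float array."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return np.asarray(arr, dtype=float)


def write_stack(stack: np.ndarray, path) -> None:
    """Write a 3D array as a multi-page float32 TIFF."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_sidecar(
    artifact_path, config: dict, seed: int | None, inputs: list | None = None
) -> Path:
    """Write a JSON metadata sidecar next to an artifact.

    Records the package version, the full configuration echo, the seed and
    sha256 hashes of the input files, so any artifact is reproducible from
    its sidecar.
    """
    from . import __version__

    artifact_path = Path(artifact_path)
    meta = {
        "version": __version__,
        "artifact": artifact_path.name,
        "seed": seed,
        "config": config,
        "inputs": {
            str(p): _sha256(p) for p in (inputs or []) if Path(p).exists()
        },
    }
    sidecar = artifact_path.with_suffix(artifact_path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, default=str))
    return sidecar
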