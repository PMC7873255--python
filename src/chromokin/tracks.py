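"""Track container shared by the simulators, the linker and the kinetic fits.

A :class:`TrackSet` is a thin wrapper around a tidy pandas DataFrame with one
row per localization.  Required columns::

    track_id  int     molecule/track identifier
    frame     int     frame index within the movie
    t_s       float   acquisition time in seconds
    x_um      float   position, micrometres
    y_um      float   position, micrometres

Optional columns (``intensity``, ``precision_um``) are carried through
unchanged.  Frame indices are strictly increasing within a track; gaps are
allowed (blinking memory) and contribute their full frame interval to track
duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("track_id", "frame", "t_s", "x_um", "y_um")
OPTIONAL_COLUMNS = ("intensity", "precision_um")


class TrackSchemaError(ValueError):
    """Raised when a track table violates the CSV schema."""


def validate_track_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a track table; returns a sorted copy."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackSchemaError(f"track table is missing column(s): {missing}")
    unknown = [
        c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS
    ]
    if unknown:
        raise TrackSchemaError(f"track table has unknown column(s): {unknown}")
    out = df.copy()
    if len(out) == 0:
        # an empty table with a valid header is a valid (empty) TrackSet
        for col in ("t_s", "x_um", "y_um"):
            out[col] = out[col].astype(float)
    for col in ("t_s", "x_um", "y_um"):
        if not np.issubdtype(out[col].dtype, np.number):
            raise TrackSchemaError(f"column {col!r} is not numeric")
    out["track_id"] = out["track_id"].astype(np.int64)
    out["frame"] = out["frame"].astype(np.int64)
    out = out.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
    bad = out.groupby("track_id")["frame"].apply(
        lambda f: not np.all(np.diff(f.to_numpy()) > 0)
    )
    if bad.any():
        offenders = bad[bad].index.tolist()[:5]
        raise TrackSchemaError(
            f"non-increasing frame indices within track(s) {offenders}"
        )
    return out


@dataclass
class TrackSet:
    """A set of single-molecule tracks plus the acquisition frame interval."""

    df: pd.DataFrame
    frame_interval: float
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not self._validated:
            self.df = validate_track_table(self.df)
            self._validated = True

    @property
    def n_tracks(self) -> int:
        return int(self.df["track_id"].nunique())

    @property
    def n_localizations(self) -> int:
        return int(len(self.df))

    def track_ids(self) -> np.ndarray:
        return self.df["track_id"].unique()

    def iter_tracks(self) -> Iterator[tuple[int, pd.DataFrame]]:
        yield from self.df.groupby("track_id", sort=True)

    def durations(self) -> pd.Series:
        """Track durations in seconds, spanning frame gaps.

        A track observed on frames f0..f1 (inclusive, possibly with gaps)
        lasts (f1 - f0 + 1) frame intervals: each gap frame contributes its
        full interval, and the single-frame exposure itself counts.
        """
        g = self.df.groupby("track_id")["frame"]
        return (g.max() - g.min() + 1) * self.frame_interval

    @classmethod
    def empty(cls, frame_interval: float) -> "TrackSet":
        df = pd.DataFrame(
            {
                "track_id": pd.Series(dtype=np.int64),
                "frame": pd.Series(dtype=np.int64),
                "t_s": pd.Series(dtype=float),
                "x_um": pd.Series(dtype=float),
                "y_um": pd.Series(dtype=float),
            }
        )
        return cls(df, frame_interval)
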