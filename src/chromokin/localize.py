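"""Spot detection, sub-pixel Gaussian localization and track linking.

Detection finds one candidate (the brightest pixel) per connected
above-threshold region of a frame.  Candidates are refined by
least-squares fitting of an elliptical 2D Gaussian plus constant offset,
giving sub-pixel centers and per-axis widths.  Localizations are linked
frame-to-frame into tracks by greedy global nearest-neighbour assignment
(candidate links sorted by ascending distance, each endpoint used at most
once, links longer than the regime's radius forbidden), with a one-frame
memory so a molecule lost for a single frame (fluorophore blinking)
continues its track.  Gap frames contribute their full frame interval to
track duration.

Coordinates are continuous micrometres with the origin at the image
corner; the center of pixel (i, j) is at ((i + 0.5), (j + 0.5)) * pixel
size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize
from scipy import ndimage

from .constants import LINK_MEMORY_FRAMES, LOC_PRECISION_UM
from .tracks import TrackSet

__all__ = [
    "Localization",
    "LinkConfig",
    "GaussianFitError",
    "detect_spots",
    "fit_gaussian",
    "localize_frame",
    "link_tracks",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Localization:
    frame_index: int
    x_um: float
    y_um: float
    intensity: float
    fit_sd_x_um: float
    fit_sd_y_um: float
    precision_um: float = LOC_PRECISION_UM


@dataclass(frozen=True)
class LinkConfig:
    """Linking parameters; radii are regime-specific (0.768 um at 67 Hz,
    0.192 um at 2 Hz, 0.672 um at 0.03 Hz)."""

    radius: float
    frame_interval: float
    memory: int = LINK_MEMORY_FRAMES

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.frame_interval <= 0:
            raise ValueError("radius and frame_interval must be positive")
        if self.memory < 0:
            raise ValueError("memory must be >= 0")


class GaussianFitError(RuntimeError):
    """Raised when a spot cannot be fitted (flat patch, non-convergence)."""


def detect_spots(frame: np.ndarray, intensity_threshold: float) -> np.ndarray:
    """Candidate spot pixels: one local maximum per above-threshold region.

    Returns an (n, 2) integer array of (row, col) positions; empty frames
    yield an empty array.
    """
    frame = np.asarray(frame, dtype=float)
    mask = frame > intensity_threshold
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    labels, n = ndimage.label(mask)
    peaks = ndimage.maximum_position(frame, labels, np.arange(1, n + 1))
    return np.asarray(peaks, dtype=np.int64).reshape(-1, 2)


def _elliptical_gaussian(params, yy, xx):
    a = params["amplitude"].value
    x0, y0 = params["x0"].value, params["y0"].value
    sx, sy = params["sd_x"].value, params["sd_y"].value
    c = params["offset"].value
    return c + a * np.exp(
        -((xx - x0) ** 2 / (2 * sx**2) + (yy - y0) ** 2 / (2 * sy**2))
    )


def fit_gaussian(
    patch: np.ndarray,
    initial_center: tuple[float, float] | None = None,
    frame_index: int = 0,
    origin: tuple[int, int] = (0, 0),
    pixel_size_um: float = 0.1,
    min_snr: float = 2.0,
) -> Localization:
    """Fit an elliptical Gaussian plus offset to a single-spot patch.

    ``initial_center`` is (row, col) within the patch; ``origin`` is the
    patch's (row, col) offset within the full frame, so the returned
    coordinates are full-frame micrometres.  Flat patches and
    non-converging fits raise :class:`GaussianFitError` (callers log and
    drop the candidate).
    """
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) < 3:
        raise GaussianFitError("patch too small to fit")
    spread = patch.max() - patch.min()
    noise = max(float(np.std(patch)), 1e-12)
    if spread <= 0 or spread < min_snr * np.median(
        np.abs(patch - np.median(patch))
    ):
        raise GaussianFitError("flat patch: no dominant spot")
    if initial_center is None:
        initial_center = np.unravel_index(np.argmax(patch), patch.shape)
    r0, c0 = float(initial_center[0]), float(initial_center[1])
    yy, xx = np.indices(patch.shape, dtype=float)

    params = Parameters()
    params.add("amplitude", value=spread, min=1e-12)
    params.add("x0", value=c0, min=-1.0, max=patch.shape[1] + 1.0)
    params.add("y0", value=r0, min=-1.0, max=patch.shape[0] + 1.0)
    params.add("sd_x", value=1.3, min=0.3, max=patch.shape[1])
    params.add("sd_y", value=1.3, min=0.3, max=patch.shape[0])
    params.add("offset", value=float(np.min(patch)))

    def resid(p):
        return (_elliptical_gaussian(p, yy, xx) - patch).ravel()

    try:
        out = minimize(resid, params)
    except Exception as exc:
        raise GaussianFitError(f"fit did not converge: {exc}") from exc
    if not out.success:
        raise GaussianFitError(f"fit did not converge: {out.message}")
    p = out.params
    if p["amplitude"].value < min_snr * noise:
        raise GaussianFitError("fitted amplitude below noise floor")
    # pixel centers sit at (index + 0.5) * pixel_size
    x_um = (origin[1] + p["x0"].value + 0.5) * pixel_size_um
    y_um = (origin[0] + p["y0"].value + 0.5) * pixel_size_um
    return Localization(
        frame_index=frame_index,
        x_um=x_um,
        y_um=y_um,
        intensity=float(p["amplitude"].value),
        fit_sd_x_um=float(p["sd_x"].value * pixel_size_um),
        fit_sd_y_um=float(p["sd_y"].value * pixel_size_um),
    )


def localize_frame(
    frame: np.ndarray,
    frame_index: int,
    intensity_threshold: float,
    pixel_size_um: float = 0.1,
    patch_half: int = 4,
) -> list[Localization]:
    """Detect and Gaussian-fit all spots in one frame."""
    locs = []
    for r, c in detect_spots(frame, intensity_threshold):
        r0 = max(r - patch_half, 0)
        c0 = max(c - patch_half, 0)
        patch = frame[r0 : r + patch_half + 1, c0 : c + patch_half + 1]
        try:
            locs.append(
                fit_gaussian(
                    patch,
                    initial_center=(r - r0, c - c0),
                    frame_index=frame_index,
                    origin=(r0, c0),
                    pixel_size_um=pixel_size_um,
                )
            )
        except GaussianFitError as exc:
            log.info("frame %d: candidate at (%d, %d) rejected: %s",
                     frame_index, r, c, exc)
    return locs


def link_tracks(localizations: pd.DataFrame, config: LinkConfig) -> TrackSet:
    """Link localizations into tracks by greedy global nearest neighbour.

    ``localizations`` needs columns ``frame``, ``x_um``, ``y_um``
    (optional ``intensity``, ``precision_um``).  For each new frame,
    candidate links between open track ends (seen within ``memory + 1``
    frames) and new localizations closer than ``radius`` are sorted by
    distance and assigned greedily, each endpoint used once.  Unmatched
    localizations open new tracks; tracks unmatched for more than
    ``memory`` consecutive frames are closed.
    """
    needed = {"frame", "x_um", "y_um"}
    if not needed <= set(localizations.columns):
        raise ValueError(f"localizations need columns {sorted(needed)}")
    df = localizations.sort_values("frame", kind="stable").reset_index(drop=True)
    has_int = "intensity" in df.columns
    has_prec = "precision_um" in df.columns

    open_tracks: list[dict] = []  # {"id", "last_frame", "x", "y"}
    assignments = np.full(len(df), -1, dtype=np.int64)
    next_id = 0
    # localization density sanity check for the warning contract
    frames_arr = df["frame"].to_numpy()
    for frame_val in np.unique(frames_arr):
        rows = np.flatnonzero(frames_arr == frame_val)
        xs = df.loc[rows, "x_um"].to_numpy()
        ys = df.loc[rows, "y_um"].to_numpy()
        alive = [
            t for t in open_tracks
            if frame_val - t["last_frame"] <= config.memory + 1
        ]
        open_tracks = alive
        # candidate links within radius, sorted by ascending distance
        links = []
        for ti, t in enumerate(alive):
            d = np.hypot(xs - t["x"], ys - t["y"])
            for li in np.flatnonzero(d <= config.radius):
                links.append((d[li], ti, li))
        links.sort()
        used_t: set[int] = set()
        used_l: set[int] = set()
        for d, ti, li in links:
            if ti in used_t or li in used_l:
                continue
            used_t.add(ti)
            used_l.add(li)
            t = alive[ti]
            t["last_frame"] = frame_val
            t["x"], t["y"] = xs[li], ys[li]
            assignments[rows[li]] = t["id"]
        for li in range(len(rows)):
            if li in used_l:
                continue
            open_tracks.append(
                {"id": next_id, "last_frame": frame_val,
                 "x": xs[li], "y": ys[li]}
            )
            assignments[rows[li]] = next_id
            next_id += 1

    out = pd.DataFrame(
        {
            "track_id": assignments,
            "frame": df["frame"].to_numpy(np.int64),
            "t_s": df["frame"].to_numpy(float) * config.frame_interval,
            "x_um": df["x_um"].to_numpy(float),
            "y_um": df["y_um"].to_numpy(float),
        }
    )
    if has_int:
        out["intensity"] = df["intensity"].to_numpy(float)
    if has_prec:
        out["precision_um"] = df["precision_um"].to_numpy(float)
    ts = TrackSet(out, config.frame_interval)
    mean_len = len(out) / max(ts.n_tracks, 1)
    if ts.n_tracks > 20 and mean_len < 2.0:
        warnings.warn(
            "mean track length below 2 localizations: localization density "
            "may be too high for reliable linking",
            stacklevel=2,
        )
    return ts
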