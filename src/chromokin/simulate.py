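"""Synthetic-data generators standing in for the microscope.

Four generators with known ground truth:

* :func:`simulate_tracks` — fast-tracking (15 ms) photoactivation SPT of a
  2- or 3-state Brownian mixture inside a finite axial detection slab, with
  localization noise and per-frame photobleaching.
* :func:`simulate_dwell_times` — slow-tracking (2 Hz) dwell observations:
  a two-component exponential mixture of binding durations censored by
  exponential photobleaching.
* :func:`simulate_nucleus_stack` — a 3D confocal-like z-stack of a nucleus
  containing bright spherical foci (Polycomb-body-like) over a uniform
  nucleoplasm, with Poisson shot noise and Gaussian read noise.
* :func:`simulate_frap_trace` — raw bleached/unbleached/background FRAP
  intensity series with exponential recovery.

Molecules never switch diffusive state within a track: the downstream
jump-length mixture model assumes state constancy over its short (<=8 frame)
analysis window, and the generator mirrors that assumption.  Axial (z)
motion is simulated explicitly; a molecule is detected only while
|z| <= dz/2, which is exactly the loss process the defocalization
correction in the kinetic fit compensates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DZ_UM, FRAME_INTERVAL_FAST_S, LOC_ERROR_UM
from .tracks import TrackSet

__all__ = [
    "SimTrackConfig",
    "simulate_tracks",
    "simulate_dwell_times",
    "simulate_nucleus_stack",
    "simulate_frap_trace",
]


@dataclass(frozen=True)
class SimTrackConfig:
    """Ground-truth parameters for the fast-tracking simulator.

    Defaults reproduce the acquisition regime the analysis targets: 15 ms
    frames, 40 nm localization error, a 0.7 um HILO detection slab, and a
    three-state mixture (bound / slow / fast) with a 20% bound fraction and
    diffusion coefficients 0.03 / 0.5 / 3.5 um^2/s.  Photobleaching is
    per-frame geometric; the default mean of 100 frames (1.5 s) reflects
    the rapid bleaching of photoactivatable dyes under continuous
    high-power excitation.
    """

    frame_interval: float = FRAME_INTERVAL_FAST_S
    n_frames_per_movie: int = 4000
    n_molecules: int = 3000
    state_fractions: tuple[float, ...] = (0.20, 0.30, 0.50)
    diffusion_coeffs: tuple[float, ...] = (0.03, 0.5, 3.5)  # um^2/s
    loc_error_sigma: float = LOC_ERROR_UM
    slab_depth_dz: float = DZ_UM
    bleach_mean_frames: float = 100.0
    fov_size: float = 20.0  # um, square field of view
    min_track_length: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.state_fractions) not in (1, 2, 3):
            raise ValueError("state_fractions must have 1-3 entries")
        if len(self.state_fractions) != len(self.diffusion_coeffs):
            raise ValueError("state_fractions and diffusion_coeffs mismatch")
        if abs(sum(self.state_fractions) - 1.0) > 1e-9:
            raise ValueError("state_fractions must sum to 1")
        if any(f < 0 for f in self.state_fractions):
            raise ValueError("state_fractions must be non-negative")
        if any(d < 0 for d in self.diffusion_coeffs):
            raise ValueError("diffusion_coeffs must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.slab_depth_dz <= 0:
            raise ValueError("slab_depth_dz must be positive")
        if self.loc_error_sigma < 0:
            raise ValueError("loc_error_sigma must be non-negative")
        if self.bleach_mean_frames < 1:
            raise ValueError("bleach_mean_frames must be >= 1")
        if self.n_molecules < 0 or self.n_frames_per_movie < 1:
            raise ValueError("counts must be non-negative / positive")


def simulate_tracks(config: SimTrackConfig) -> tuple[TrackSet, pd.DataFrame]:
    """Simulate photoactivation SPT tracks with ground-truth state labels.

    Each molecule is photoactivated at a uniformly random frame at a
    uniformly random xy position, with z uniform inside the detection slab.
    It performs 3D Brownian motion with its state's diffusion coefficient;
    the observed 2D position is the true xy plus Gaussian localization
    noise.  The track ends at the first frame at which the molecule has
    left the slab (|z| > dz/2), photobleached (geometric lifetime with the
    configured mean), or the movie ends.

    Returns
    -------
    (TrackSet, DataFrame)
        Tracks, and a ground-truth table with one row per emitted track
        (``track_id``, ``state``, ``n_localizations``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_molecules
    if n == 0:
        truth = pd.DataFrame(
            {"track_id": pd.Series(dtype=np.int64),
             "state": pd.Series(dtype=np.int64),
             "n_localizations": pd.Series(dtype=np.int64)}
        )
        return TrackSet.empty(config.frame_interval), truth

    fracs = np.asarray(config.state_fractions, dtype=float)
    states = rng.choice(len(fracs), size=n, p=fracs)
    t0 = rng.integers(0, config.n_frames_per_movie, size=n)
    # geometric bleach lifetime in frames (>=1), discrete analogue of
    # exponential bleaching under frame-based acquisition
    bleach = rng.geometric(1.0 / config.bleach_mean_frames, size=n)

    half = config.slab_depth_dz / 2.0
    dt = config.frame_interval
    sigma = config.loc_error_sigma

    rec_id, rec_frame, rec_x, rec_y = [], [], [], []
    truth_id, truth_state, truth_n = [], [], []
    next_id = 0
    for i in range(n):
        max_steps = int(min(bleach[i], config.n_frames_per_movie - 1 - t0[i]))
        d = config.diffusion_coeffs[states[i]]
        step_sd = math.sqrt(2.0 * d * dt)
        x0 = rng.uniform(0.0, config.fov_size)
        y0 = rng.uniform(0.0, config.fov_size)
        z0 = rng.uniform(-half, half)
        if max_steps > 0 and step_sd > 0:
            steps = rng.normal(0.0, step_sd, size=(max_steps, 3))
            z = z0 + np.cumsum(steps[:, 2])
            outside = np.abs(z) > half
            exit_idx = int(np.argmax(outside)) if outside.any() else max_steps
            m = exit_idx  # number of surviving steps after the first frame
            x = x0 + np.concatenate(([0.0], np.cumsum(steps[:m, 0])))
            y = y0 + np.concatenate(([0.0], np.cumsum(steps[:m, 1])))
        else:
            m = max_steps
            x = np.full(m + 1, x0)
            y = np.full(m + 1, y0)
        n_loc = m + 1
        if n_loc < config.min_track_length:
            continue
        if sigma > 0:
            x = x + rng.normal(0.0, sigma, size=n_loc)
            y = y + rng.normal(0.0, sigma, size=n_loc)
        frames = t0[i] + np.arange(n_loc)
        rec_id.append(np.full(n_loc, next_id, dtype=np.int64))
        rec_frame.append(frames)
        rec_x.append(x)
        rec_y.append(y)
        truth_id.append(next_id)
        truth_state.append(int(states[i]))
        truth_n.append(n_loc)
        next_id += 1

    if not rec_id:
        truth = pd.DataFrame(
            {"track_id": pd.Series(dtype=np.int64),
             "state": pd.Series(dtype=np.int64),
             "n_localizations": pd.Series(dtype=np.int64)}
        )
        return TrackSet.empty(config.frame_interval), truth

    frame = np.concatenate(rec_frame)
    df = pd.DataFrame(
        {
            "track_id": np.concatenate(rec_id),
            "frame": frame,
            "t_s": frame * dt,
            "x_um": np.concatenate(rec_x),
            "y_um": np.concatenate(rec_y),
        }
    )
    truth = pd.DataFrame(
        {"track_id": truth_id, "state": truth_state, "n_localizations": truth_n}
    )
    return TrackSet(df, dt), truth


def simulate_dwell_times(
    stable_fraction: float,
    tau_short: float,
    tau_long: float,
    t_bleach: float,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate photobleach-censored binding durations.

    True dwell times follow a two-component exponential mixture: with
    probability ``stable_fraction`` the molecule is stably bound (mean
    ``tau_long``), otherwise transiently bound (mean ``tau_short``).  The
    observed dwell is the minimum of the true dwell and an exponential
    photobleaching time with mean ``t_bleach``.

    Returns the observed dwell times and a ground-truth table
    (``is_stable``, ``true_dwell_s``, ``bleach_s``, ``observed_s``).
    """
    if not 0.0 <= stable_fraction <= 1.0:
        raise ValueError("stable_fraction must lie in [0, 1]")
    if min(tau_short, tau_long, t_bleach) <= 0:
        raise ValueError("all time constants must be positive")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    is_stable = rng.random(n) < stable_fraction
    true_dwell = np.where(
        is_stable,
        rng.exponential(tau_long, size=n),
        rng.exponential(tau_short, size=n),
    )
    bleach_t = rng.exponential(t_bleach, size=n)
    observed = np.minimum(true_dwell, bleach_t)
    truth = pd.DataFrame(
        {
            "is_stable": is_stable,
            "true_dwell_s": true_dwell,
            "bleach_s": bleach_t,
            "observed_s": observed,
        }
    )
    return observed, truth


def _sphere_mask(shape, centers_vox, radius_vox):
    zz, yy, xx = np.indices(shape)
    mask = np.zeros(shape, dtype=bool)
    for cz, cy, cx in centers_vox:
        mask |= (
            ((zz - cz) / radius_vox[0]) ** 2
            + ((yy - cy) / radius_vox[1]) ** 2
            + ((xx - cx) / radius_vox[2]) ** 2
        ) <= 1.0
    return mask


def simulate_nucleus_stack(
    n_foci: int,
    focus_enrichment: float = 3.0,
    focus_radius: float = 0.31,
    voxel_size: tuple[float, float, float] = (0.15, 0.1, 0.1),
    nucleus_radii: tuple[float, float, float] = (2.6, 3.2, 3.2),
    shape: tuple[int, int, int] = (24, 80, 80),
    baseline: float = 200.0,
    background: float = 20.0,
    read_noise_sd: float = 2.0,
    min_separation_factor: float = 2.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate a 3D nuclear z-stack with bright spherical foci.

    The stack contains an ellipsoidal nucleus of uniform ``baseline``
    intensity over a ``background`` level outside the nucleus.  Each focus
    is a sphere of radius ``focus_radius`` (um) whose mean intensity is
    ``focus_enrichment`` x baseline.  Noise is Poisson on the signal plus
    Gaussian read noise (a standard EMCCD approximation).  Focus centers
    are placed with a minimum separation of ``min_separation_factor`` x
    radius; if that cannot be satisfied the placement is rejected because
    overlapping foci would make the ground truth ambiguous.

    Returns ``(stack, nucleus_mask, truth)`` where truth lists each focus
    center (um), radius and analytic sphere volume.
    """
    if any(v <= 0 for v in voxel_size):
        raise ValueError("voxel sizes must be positive")
    if n_foci < 0:
        raise ValueError("n_foci must be non-negative")
    if focus_enrichment <= 0 or focus_radius <= 0:
        raise ValueError("focus parameters must be positive")
    rng = np.random.default_rng(seed)
    vz, vy, vx = voxel_size
    center_um = (shape[0] * vz / 2, shape[1] * vy / 2, shape[2] * vx / 2)
    zz, yy, xx = np.indices(shape)
    z_um = (zz + 0.5) * vz
    y_um = (yy + 0.5) * vy
    x_um = (xx + 0.5) * vx
    nucleus_mask = (
        ((z_um - center_um[0]) / nucleus_radii[0]) ** 2
        + ((y_um - center_um[1]) / nucleus_radii[1]) ** 2
        + ((x_um - center_um[2]) / nucleus_radii[2]) ** 2
    ) <= 1.0

    # place foci fully inside the nucleus with pairwise separation
    centers: list[tuple[float, float, float]] = []
    min_sep = min_separation_factor * focus_radius
    attempts = 0
    while len(centers) < n_foci:
        attempts += 1
        if attempts > 5000 * max(n_foci, 1):
            raise ValueError(
                "could not place foci without overlap; reduce n_foci or radius"
            )
        u = rng.uniform(-1.0, 1.0, size=3)
        cand = (
            center_um[0] + u[0] * (nucleus_radii[0] - 2 * focus_radius),
            center_um[1] + u[1] * (nucleus_radii[1] - 2 * focus_radius),
            center_um[2] + u[2] * (nucleus_radii[2] - 2 * focus_radius),
        )
        inside = (
            ((cand[0] - center_um[0]) / (nucleus_radii[0] - focus_radius)) ** 2
            + ((cand[1] - center_um[1]) / (nucleus_radii[1] - focus_radius)) ** 2
            + ((cand[2] - center_um[2]) / (nucleus_radii[2] - focus_radius)) ** 2
        ) <= 1.0
        # the nucleus may extend beyond the stack in z (as in real
        # acquisitions); keep foci well inside the imaged volume
        z_margin = focus_radius + 2 * vz
        if not inside or not z_margin <= cand[0] <= shape[0] * vz - z_margin:
            continue
        if all(
            math.dist(cand, c) >= min_sep for c in centers
        ):
            centers.append(cand)

    signal = np.where(nucleus_mask, baseline, background).astype(float)
    radius_vox = (focus_radius / vz, focus_radius / vy, focus_radius / vx)
    if centers:
        centers_vox = [
            (c[0] / vz - 0.5, c[1] / vy - 0.5, c[2] / vx - 0.5) for c in centers
        ]
        focus_mask = _sphere_mask(shape, centers_vox, radius_vox)
        signal[focus_mask] = focus_enrichment * baseline
    stack = rng.poisson(signal).astype(float)
    if read_noise_sd > 0:
        stack += rng.normal(0.0, read_noise_sd, size=shape)
    truth = pd.DataFrame(
        centers, columns=["z_um", "y_um", "x_um"]
    )
    truth["radius_um"] = focus_radius
    truth["volume_um3"] = 4.0 / 3.0 * math.pi * focus_radius**3
    return stack, nucleus_mask, truth


def simulate_frap_trace(
    recovery_fraction: float,
    recovery_rate: float,
    prebleach_n: int = 10,
    seed: int = 0,
    dt: float = 1.0,
    n_post: int = 120,
    post_bleach_floor: float = 0.0,
    unbleached_level: float = 1000.0,
    background_level: float = 100.0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate a raw FRAP intensity series.

    The normalized ground-truth recovery is
    ``floor + recovery_fraction * (1 - exp(-rate * t_post))`` with the
    prebleach plateau at 1.  Raw intensities are reconstructed around a
    constant unbleached reference and constant background, with optional
    additive Gaussian noise.

    Returns a tidy DataFrame (``t_s``, ``bleached``, ``unbleached``,
    ``background``, ``is_prebleach``).
    """
    if not 0.0 <= recovery_fraction <= 1.0:
        raise ValueError("recovery_fraction must lie in [0, 1]")
    if recovery_rate < 0 or prebleach_n < 1:
        raise ValueError("invalid recovery_rate or prebleach_n")
    rng = np.random.default_rng(seed)
    t = np.arange(prebleach_n + n_post) * dt
    t_post = t[prebleach_n:] - t[prebleach_n]
    rel = np.ones_like(t)
    rel[prebleach_n:] = post_bleach_floor + recovery_fraction * (
        1.0 - np.exp(-recovery_rate * t_post)
    )
    amplitude = unbleached_level - background_level
    bleached = background_level + amplitude * rel
    unbleached = np.full_like(t, unbleached_level)
    background = np.full_like(t, background_level)
    if noise_sd > 0:
        bleached = bleached + rng.normal(0.0, noise_sd, size=t.size)
        unbleached = unbleached + rng.normal(0.0, noise_sd, size=t.size)
        background = background + rng.normal(0.0, noise_sd, size=t.size)
    return pd.DataFrame(
        {
            "t_s": t,
            "bleached": bleached,
            "unbleached": unbleached,
            "background": background,
            "is_prebleach": np.arange(t.size) < prebleach_n,
        }
    )
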