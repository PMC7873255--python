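"""Multi-state diffusion analysis of jump-length distributions.

Implements the kinetic-modelling stage of fast-tracking SPT analysis:

* per-track apparent diffusion coefficients,
  ``D* = MSD/(4 dt) - sigma^2/dt``, where MSD is the mean squared
  one-frame displacement over the whole track and sigma the localization
  uncertainty;
* empirical jump-length distributions over multiple frame lags
  (default 8 lags, at most 4 jumps per track per lag, 0.01 um bins up to
  5.05 um);
* a 2- or 3-state Brownian-mixture fit to the per-lag jump-length CDFs
  with localization error and defocalization (axial detection-slab loss)
  correction, in the style of the Spot-On kinetic model.

The 2D jump length of a Brownian state with diffusion coefficient D over
lag k*dt, observed with per-localization Gaussian error sigma on each
coordinate of both endpoints, is Rayleigh with
``E[r^2] = 4 D k dt + 4 sigma^2``, so the state's CDF is
``1 - exp(-r^2 / (4 D k dt + 4 sigma^2))``.

Defocalization: fast-diffusing molecules leave the axial detection slab
(depth dz), so long-lag jumps under-sample them.  Two survival functions
are provided.  :func:`defocalization_probability` is the classical
continuous-time absorbing-slab eigenfunction series (a molecule counts as
lost the instant it touches the boundary).  The fit's per-lag state
weights instead use a frame-sampled survival — the probability that a
molecule starting uniformly in the slab is inside at every one of k frame
observations — computed by iterating a Gaussian convolution kernel over
the slab.  The frame-sampled form matches how tracks are actually
truncated (a molecule is only checked at exposures and may re-enter
between frames) and additionally accounts for the capped per-track jump
count: the expected number of lag-k jumps a track contributes is
``sum_{j=0..cap-1} S(k+j)``, which the weight model uses so that
long-lived (bound) tracks, whose jump count saturates the cap, are not
over-weighted relative to short-lived fast tracks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import (
    D_BOUNDS,
    DZ_UM,
    FIT_RESTARTS,
    JUMP_BIN_WIDTH_UM,
    JUMP_MAX_UM,
    LOC_ERROR_UM,
    MAX_JUMPS_PER_TRACK,
    N_LAGS,
)
from .tracks import TrackSet

__all__ = [
    "DiffusionEstimate",
    "JumpConfig",
    "JumpHistogramSet",
    "KineticFit",
    "apparent_diffusion",
    "apparent_diffusion_table",
    "build_jump_histograms",
    "defocalization_probability",
    "fit_kinetic_model",
    "compare_models",
]


# ---------------------------------------------------------------------------
# apparent diffusion coefficients
# ---------------------------------------------------------------------------

MIN_TRACK_LOCALIZATIONS = 5


@dataclass(frozen=True)
class DiffusionEstimate:
    track_id: int
    msd: float       # um^2, mean squared one-frame displacement
    d_star: float    # um^2/s, may be negative for static noisy tracks
    n_localizations: int


def apparent_diffusion(
    track: pd.DataFrame, dt: float, sigma: float
) -> DiffusionEstimate:
    """Apparent diffusion coefficient of one track.

    ``D* = MSD/(4 dt) - sigma^2/dt`` with MSD the mean squared displacement
    between consecutive frames over the whole track.  Negative values
    (static tracks whose noise term exceeds the MSD term) are preserved —
    clipping them would bias the static peak of the D* distribution.
    """
    if len(track) < MIN_TRACK_LOCALIZATIONS:
        raise ValueError(
            f"track has {len(track)} localizations; "
            f">= {MIN_TRACK_LOCALIZATIONS} required"
        )
    frames = track["frame"].to_numpy()
    consecutive = np.diff(frames) == 1
    dx = np.diff(track["x_um"].to_numpy())[consecutive]
    dy = np.diff(track["y_um"].to_numpy())[consecutive]
    if dx.size == 0:
        raise ValueError("track has no consecutive-frame displacements")
    msd = float(np.mean(dx**2 + dy**2))
    d_star = msd / (4.0 * dt) - sigma**2 / dt
    tid = int(track["track_id"].iloc[0]) if "track_id" in track else -1
    return DiffusionEstimate(tid, msd, d_star, int(len(track)))


def apparent_diffusion_table(
    tracks: TrackSet, sigma: float = LOC_ERROR_UM
) -> tuple[pd.DataFrame, dict]:
    """Per-track D* for all tracks with >= 5 localizations.

    Returns the estimate table and a skip report counting excluded tracks.
    """
    rows = []
    skipped = 0
    for tid, tdf in tracks.iter_tracks():
        if len(tdf) < MIN_TRACK_LOCALIZATIONS:
            skipped += 1
            continue
        est = apparent_diffusion(tdf, tracks.frame_interval, sigma)
        rows.append(
            {"track_id": tid, "msd_um2": est.msd, "d_star_um2_s": est.d_star,
             "n_localizations": est.n_localizations}
        )
    report = {"n_used": len(rows), "n_skipped_short": skipped}
    return pd.DataFrame(rows), report


# ---------------------------------------------------------------------------
# jump-length histograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JumpConfig:
    bin_width: float = JUMP_BIN_WIDTH_UM
    max_jump: float = JUMP_MAX_UM
    n_lags: int = N_LAGS
    max_jumps_per_track: int = MAX_JUMPS_PER_TRACK

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.max_jump <= 0:
            raise ValueError("bin_width and max_jump must be positive")
        if self.n_lags < 1 or self.max_jumps_per_track < 1:
            raise ValueError("n_lags and max_jumps_per_track must be >= 1")


@dataclass
class JumpHistogramSet:
    """Empirical jump-length PDFs/CDFs per frame lag."""

    config: JumpConfig
    frame_interval: float
    jumps: dict[int, np.ndarray]          # lag -> raw jump lengths (um)
    bin_edges: np.ndarray = field(init=False)
    pdf: dict[int, np.ndarray] = field(init=False)   # normalized histogram
    cdf: dict[int, np.ndarray] = field(init=False)   # CDF at right bin edges

    def __post_init__(self) -> None:
        c = self.config
        n_bins = int(round(c.max_jump / c.bin_width))
        self.bin_edges = np.arange(n_bins + 1) * c.bin_width
        self.pdf, self.cdf = {}, {}
        for lag, r in self.jumps.items():
            counts, _ = np.histogram(r, bins=self.bin_edges)
            total = counts.sum()
            self.pdf[lag] = counts / (total * c.bin_width) if total else counts * 0.0
            r_sorted = np.sort(r)
            self.cdf[lag] = (
                np.searchsorted(r_sorted, self.bin_edges[1:], side="right")
                / max(total, 1)
            )

    @property
    def lags(self) -> list[int]:
        return sorted(self.jumps)

    @property
    def n_jumps(self) -> dict[int, int]:
        return {lag: int(v.size) for lag, v in self.jumps.items()}

    def fingerprint(self) -> tuple:
        return tuple((lag, int(v.size)) for lag, v in sorted(self.jumps.items()))


def build_jump_histograms(
    tracks: TrackSet, config: JumpConfig | None = None
) -> JumpHistogramSet:
    """Collect jump lengths for lags 1..n_lags frames.

    For each lag k, each track contributes at most ``max_jumps_per_track``
    jumps (its earliest ones), and only between localizations exactly k
    frames apart.  Jumps longer than ``max_jump`` are discarded.  Lags with
    no jumps are omitted with a warning.
    """
    config = config or JumpConfig()
    per_lag: dict[int, list[np.ndarray]] = {k: [] for k in range(1, config.n_lags + 1)}
    cap = config.max_jumps_per_track
    for _, tdf in tracks.iter_tracks():
        if len(tdf) < 2:
            continue
        frames = tdf["frame"].to_numpy()
        x = tdf["x_um"].to_numpy()
        y = tdf["y_um"].to_numpy()
        # positions indexed by frame offset; gaps (blinking) break pairs
        offset = frames - frames[0]
        for k in range(1, config.n_lags + 1):
            # match pairs (i, j) with offset[j] - offset[i] == k
            idx = {o: i for i, o in enumerate(offset)}
            taken = 0
            r_list = []
            for o in offset:
                if taken >= cap:
                    break
                j = idx.get(o + k)
                if j is None:
                    continue
                i = idx[o]
                r_list.append(math.hypot(x[j] - x[i], y[j] - y[i]))
                taken += 1
            if r_list:
                per_lag[k].append(np.asarray(r_list))
    jumps = {}
    for k, chunks in per_lag.items():
        r = np.concatenate(chunks) if chunks else np.empty(0)
        r = r[r <= config.max_jump]
        if r.size == 0:
            warnings.warn(f"no jumps at lag {k}; lag omitted", stacklevel=2)
            continue
        jumps[k] = r
    return JumpHistogramSet(config, tracks.frame_interval, jumps)


# ---------------------------------------------------------------------------
# defocalization
# ---------------------------------------------------------------------------


def defocalization_probability(
    d: float, t: float, dz: float, tol: float = 1e-10
) -> float:
    """Probability a Brownian molecule stays inside an axial slab up to t.

    Continuous-time survival for 1D Brownian motion with absorbing
    boundaries at +/- dz/2, starting from a uniform position in the slab:
    ``S(t) = sum_{n odd} 8/(n pi)^2 exp(-(n pi)^2 D t / dz^2)``, truncated
    once terms fall below ``tol``.
    """
    if d < 0 or t <= 0 or dz <= 0:
        raise ValueError("require D >= 0, t > 0, dz > 0")
    if d == 0:
        return 1.0
    alpha = (math.pi / dz) ** 2 * d * t
    s = 0.0
    n = 1
    while True:
        coeff = 8.0 / (n * math.pi) ** 2
        term = coeff * math.exp(-(n**2) * alpha)
        s += term
        if term < tol or n > 100001:
            break
        n += 2
    return min(s, 1.0)


def _frame_sampled_slab_survival(
    d: float, dt: float, n_steps: int, dz: float, n_grid: int = 81
) -> np.ndarray:
    """Survival S(m), m = 1..n_steps, with loss checked only at frame times.

    A molecule starts uniformly in the slab and diffuses freely; it counts
    as surviving m frames if it is inside the slab at each of the m
    observation times (it may leave and re-enter between frames).  Computed
    by iterating the Gaussian transition kernel on a grid over the slab.
    """
    if d <= 0:
        return np.ones(n_steps)
    z = np.linspace(-dz / 2, dz / 2, n_grid)
    h = z[1] - z[0]
    sd = math.sqrt(2.0 * d * dt)
    kernel = np.exp(-((z[:, None] - z[None, :]) ** 2) / (2 * sd**2)) / (
        math.sqrt(2 * math.pi) * sd
    )
    weights = np.full(n_grid, h)
    weights[0] = weights[-1] = h / 2  # trapezoid
    transfer = kernel * weights[None, :]
    density = np.full(n_grid, 1.0 / dz)
    out = np.empty(n_steps)
    for m in range(n_steps):
        density = transfer @ density
        out[m] = float(weights @ density)
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# kinetic-model fitting
# ---------------------------------------------------------------------------


@dataclass
class KineticFit:
    """Fitted 2-/3-state Brownian mixture.

    States are labelled by increasing diffusion coefficient: index 0 is the
    bound (immobile) state.
    """

    n_states: int
    fractions: tuple[float, ...]
    diffusion_coeffs: tuple[float, ...]
    loc_error: float
    dz: float
    residual_ss: float
    n_restarts: int
    n_residuals: int
    n_parameters: int
    sigma_mode: str
    zcorr_mode: str
    hist_fingerprint: tuple = ()

    @property
    def f_bound(self) -> float:
        return self.fractions[0]

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "fractions": list(self.fractions),
            "diffusion_coeffs_um2_s": list(self.diffusion_coeffs),
            "f_bound": self.f_bound,
            "loc_error_um": self.loc_error,
            "dz_um": self.dz,
            "residual_ss": self.residual_ss,
            "n_restarts": self.n_restarts,
            "sigma_mode": self.sigma_mode,
            "zcorr_mode": self.zcorr_mode,
        }


class KineticFitError(RuntimeError):
    """Raised when the mixture fit fails to converge on every restart."""

    def __init__(self, message: str, best_residual: float, trace: list):
        super().__init__(message)
        self.best_residual = best_residual
        self.trace = trace


def _stick_breaking(q: np.ndarray) -> np.ndarray:
    """Map n-1 unit-interval parameters to n simplex fractions."""
    fracs = []
    rem = 1.0
    for qi in q:
        fracs.append(rem * qi)
        rem *= 1.0 - qi
    fracs.append(rem)
    return np.asarray(fracs)


def _state_cdf(r: np.ndarray, d: float, k: int, dt: float, sigma: float,
               sigma_mode: str) -> np.ndarray:
    if sigma_mode == "per_jump":
        noise = 4.0 * sigma**2
    elif sigma_mode == "per_lag":
        noise = 4.0 * k * sigma**2
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    scale = 4.0 * d * k * dt + noise
    if scale <= 0:
        return (r >= 0).astype(float)
    return 1.0 - np.exp(-(r**2) / scale)


def _lag_weights(
    fracs: np.ndarray,
    ds: np.ndarray,
    lags: list[int],
    dt: float,
    dz: float,
    cap: int,
    zcorr_mode: str,
) -> dict[int, np.ndarray]:
    """Per-lag mixture weights after defocalization correction."""
    max_m = max(lags) + (cap - 1 if zcorr_mode == "track_sampling" else 0)
    surv = np.vstack(
        [_frame_sampled_slab_survival(d, dt, max_m, dz) for d in ds]
    )  # shape (n_states, max_m), surv[:, m-1] = S(m)
    weights = {}
    for k in lags:
        if zcorr_mode == "track_sampling":
            z = surv[:, k - 1 : k - 1 + cap].sum(axis=1) / cap
        elif zcorr_mode == "survival":
            z = surv[:, k - 1]
        elif zcorr_mode == "none":
            z = np.ones(len(ds))
        else:
            raise ValueError(f"unknown zcorr_mode {zcorr_mode!r}")
        w = fracs * z
        weights[k] = w / w.sum()
    return weights


def model_cdf(
    r: np.ndarray,
    k: int,
    dt: float,
    fracs: np.ndarray,
    ds: np.ndarray,
    sigma: float,
    dz: float,
    cap: int = MAX_JUMPS_PER_TRACK,
    sigma_mode: str = "per_jump",
    zcorr_mode: str = "track_sampling",
) -> np.ndarray:
    """Mixture jump-length CDF at lag k (convenience wrapper)."""
    w = _lag_weights(np.asarray(fracs, float), np.asarray(ds, float),
                     [k], dt, dz, cap, zcorr_mode)[k]
    out = np.zeros_like(r, dtype=float)
    for wi, d in zip(w, ds):
        out += wi * _state_cdf(r, d, k, dt, sigma, sigma_mode)
    return out


def fit_kinetic_model(
    hist: JumpHistogramSet,
    n_states: int = 3,
    sigma: float = LOC_ERROR_UM,
    dz: float = DZ_UM,
    n_restarts: int = FIT_RESTARTS,
    sigma_mode: str = "per_jump",
    zcorr_mode: str = "track_sampling",
    d_bounds: tuple[float, float] = D_BOUNDS,
    min_jumps_warn: int = 1000,
    restart_seed: int = 12345,
) -> KineticFit:
    """Fit an n-state Brownian mixture to per-lag jump-length CDFs.

    Parameters are the simplex of state fractions (stick-breaking
    parameterization, so fitted fractions always lie in [0, 1] and sum to
    1) and one diffusion coefficient per state, bounded to
    ``d_bounds``.  The objective is the summed squared difference between
    the empirical and model CDFs across all lags; ``n_restarts`` optimizer
    starts from jittered initial values are run and the best retained
    (ties broken by lowest residual, then lowest fast-state D).
    """
    if n_states not in (2, 3):
        raise ValueError("n_states must be 2 or 3")
    lags = hist.lags
    if not lags:
        raise ValueError("histogram set has no lags with jumps")
    total_jumps = sum(hist.n_jumps.values())
    if total_jumps < min_jumps_warn:
        warnings.warn(
            f"only {total_jumps} jumps; >= {min_jumps_warn} recommended",
            stacklevel=2,
        )
    dt = hist.frame_interval
    cap = hist.config.max_jumps_per_track
    r = hist.bin_edges[1:]
    emp = {k: hist.cdf[k] for k in lags}

    def residuals(params: np.ndarray) -> np.ndarray:
        q = params[: n_states - 1]
        ds = params[n_states - 1 :]
        fracs = _stick_breaking(q)
        w = _lag_weights(fracs, ds, lags, dt, dz, cap, zcorr_mode)
        res = []
        for k in lags:
            model = np.zeros_like(r)
            for wi, d in zip(w[k], ds):
                model += wi * _state_cdf(r, d, k, dt, sigma, sigma_mode)
            res.append(model - emp[k])
        return np.concatenate(res)

    if n_states == 2:
        base_q = [0.3]
        base_d = [0.01, 2.0]
    else:
        base_q = [0.3, 0.4]
        base_d = [0.01, 0.4, 3.0]
    lo = [0.0] * (n_states - 1) + [d_bounds[0]] * n_states
    hi = [1.0] * (n_states - 1) + [d_bounds[1]] * n_states

    rng = np.random.default_rng(restart_seed)
    best = None
    trace = []
    for attempt in range(n_restarts):
        q0 = np.asarray(base_q)
        d0 = np.asarray(base_d)
        if attempt > 0:
            q0 = np.clip(q0 + rng.uniform(-0.2, 0.2, size=q0.size), 0.02, 0.98)
            d0 = np.clip(
                d0 * rng.uniform(0.3, 3.0, size=d0.size), *d_bounds
            )
        x0 = np.clip(np.concatenate([q0, d0]), lo, hi)
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf")
        except Exception as exc:  # pragma: no cover - scipy internal failure
            trace.append({"attempt": attempt, "error": str(exc)})
            continue
        rss = float(np.sum(sol.fun**2))
        d_fast = float(np.max(sol.x[n_states - 1 :]))
        trace.append({"attempt": attempt, "rss": rss, "x": sol.x.tolist()})
        key = (rss, d_fast)
        if sol.success and (best is None or key < best[0]):
            best = (key, sol)
    if best is None:
        rsss = [t.get("rss", math.inf) for t in trace]
        raise KineticFitError(
            "kinetic fit failed on all restarts", min(rsss, default=math.inf), trace
        )
    sol = best[1]
    fracs = _stick_breaking(sol.x[: n_states - 1])
    ds = sol.x[n_states - 1 :].copy()
    order = np.argsort(ds)  # label states by increasing D: bound < slow < fast
    fracs = fracs[order]
    ds = ds[order]
    # gauge fix: when two states converge to the same D the split of their
    # weights is unidentifiable; concentrate it on one of them
    for i in range(len(ds) - 1):
        if ds[i + 1] - ds[i] < 0.01 * max(ds[i + 1], 1e-12):
            fracs[i + 1] += fracs[i]
            fracs[i] = 0.0
    return KineticFit(
        n_states=n_states,
        fractions=tuple(float(f) for f in fracs),
        diffusion_coeffs=tuple(float(d) for d in ds),
        loc_error=sigma,
        dz=dz,
        residual_ss=float(np.sum(sol.fun**2)),
        n_restarts=n_restarts,
        n_residuals=int(sol.fun.size),
        n_parameters=2 * n_states - 1,
        sigma_mode=sigma_mode,
        zcorr_mode=zcorr_mode,
        hist_fingerprint=hist.fingerprint(),
    )


def compare_models(fit2: KineticFit, fit3: KineticFit) -> dict:
    """Residual and information-criterion comparison of two fits.

    Both fits must come from the same histogram set.  Reports residual
    sums and AIC/BIC computed from the Gaussian-residual approximation
    ``n ln(RSS/n) + penalty``; no automatic selection is made.
    """
    if fit2.hist_fingerprint != fit3.hist_fingerprint:
        raise ValueError("fits were made on different histogram sets")

    def crit(fit: KineticFit) -> dict:
        n, p = fit.n_residuals, fit.n_parameters
        aic = n * math.log(max(fit.residual_ss, 1e-300) / n) + 2 * p
        bic = n * math.log(max(fit.residual_ss, 1e-300) / n) + p * math.log(n)
        return {"rss": fit.residual_ss, "aic": aic, "bic": bic,
                "n_parameters": p}

    report = {
        "two_state": crit(fit2),
        "three_state": crit(fit3),
    }
    report["delta_rss"] = fit2.residual_ss - fit3.residual_ss
    report["delta_aic"] = report["two_state"]["aic"] - report["three_state"]["aic"]
    return report
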