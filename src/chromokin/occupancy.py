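"""Absolute abundance, genome occupancy and histone-mark turnover budgets.

Links three measurement scales:

* **molecules per cell** from in-gel fluorescence against a standard curve
  of known protein quantities;
* **per-peak occupancy**: the chromatin-bound molecule count (total
  molecules x SPT bound fraction) apportioned over ChIP-seq peaks in
  proportion to read counts,
  ``molecules_in_peak = reads_in_peak * total_bound / reads_in_all_peaks``,
  with densities in molecules per kilobase and equal-count density deciles;
* **H2AK119ub1 turnover budget**: nucleosome counts from genome size and
  mean nucleosome spacing, steady-state modification numbers, first-order
  decay flux, and the implied per-complex deposition interval.

Peak coordinates follow the BED convention (0-based, half-open), so peak
length = end - start.  Molecule counts stay fractional internally and are
rounded only at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    AVOGADRO,
    FRAC_H2A_UB,
    GENOME_SIZE_2N_BP,
    H2A_PER_NUCLEOSOME,
    MAPPABLE_FRACTION,
    NUCLEOSOME_SPACING_BP,
    PLOIDY,
    UB_HALF_LIFE_S,
)

__all__ = [
    "StandardCurve",
    "UbiquitinBudget",
    "molecules_per_cell",
    "bound_molecules",
    "peak_occupancy",
    "nucleosome_budget",
    "h2aub_budget",
    "deposition_interval",
    "h2aub_at_peaks",
]


# ---------------------------------------------------------------------------
# in-gel fluorescence quantification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardCurve:
    """Known protein quantities vs measured band fluorescence.

    ``quantities`` are in mol when ``unit == "mol"`` (converted with
    Avogadro's number) or directly in molecules when ``unit ==
    "molecules"``.
    """

    quantities: np.ndarray
    intensities: np.ndarray
    unit: str = "mol"

    def __post_init__(self) -> None:
        q = np.asarray(self.quantities, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "quantities", q)
        object.__setattr__(self, "intensities", i)
        if q.size != i.size or q.size < 2:
            raise ValueError("need >= 2 matched standard points")
        if np.any(i < 0):
            raise ValueError("intensities must be non-negative")
        if self.unit not in ("mol", "molecules"):
            raise ValueError("unit must be 'mol' or 'molecules'")
        order = np.argsort(q)
        if not np.all(np.diff(i[order]) > 0):
            raise ValueError("standard intensities are not monotone in quantity")


def molecules_per_cell(
    curve: StandardCurve,
    sample_intensities,
    cells_loaded,
) -> tuple[float, tuple[float, float]]:
    """Molecules per cell from sample band intensities and a standard curve.

    Fits intensity = slope * quantity + intercept through the standards,
    inverts it for each sample lane, divides by the cells loaded in that
    lane, and averages replicate lanes.  Returns the mean and a 95%
    confidence interval across replicate lanes (equal to the point
    estimate when only one lane is provided).  Sample intensities outside
    the standard range trigger an extrapolation warning.
    """
    import warnings

    samples = np.atleast_1d(np.asarray(sample_intensities, dtype=float))
    cells = np.broadcast_to(
        np.atleast_1d(np.asarray(cells_loaded, dtype=float)), samples.shape
    )
    if np.any(cells <= 0):
        raise ValueError("cells_loaded must be positive")
    fit = stats.linregress(curve.quantities, curve.intensities)
    if samples.min() < curve.intensities.min() - 1e-12 or (
        samples.max() > curve.intensities.max() + 1e-12
    ):
        warnings.warn(
            "sample intensity outside the standard-curve range; extrapolating",
            stacklevel=2,
        )
    quantity = (samples - fit.intercept) / fit.slope
    if curve.unit == "mol":
        molecules = quantity * AVOGADRO
    else:
        molecules = quantity
    per_cell = molecules / cells
    mean = float(np.mean(per_cell))
    if per_cell.size > 1:
        sem = float(stats.sem(per_cell))
        half = stats.t.ppf(0.975, per_cell.size - 1) * sem
        ci = (mean - half, mean + half)
    else:
        ci = (mean, mean)
    return mean, ci


def bound_molecules(total_molecules: float, f_bound: float) -> int:
    """Chromatin-bound molecule count: total x SPT bound fraction."""
    if not 0.0 <= f_bound <= 1.0:
        raise ValueError("f_bound must lie in [0, 1]")
    return int(round(total_molecules * f_bound))


# ---------------------------------------------------------------------------
# per-peak occupancy
# ---------------------------------------------------------------------------


def _validate_peaks(peaks: pd.DataFrame, count_col: str) -> pd.DataFrame:
    required = {"chrom", "start", "end", count_col}
    missing = required - set(peaks.columns)
    if missing:
        raise ValueError(f"peak table missing column(s): {sorted(missing)}")
    out = peaks.copy()
    if (out["end"] <= out["start"]).any():
        raise ValueError("peaks with end <= start (zero/negative length)")
    if (out[count_col] < 0).any():
        raise ValueError("negative read counts")
    return out


def peak_occupancy(
    peaks: pd.DataFrame,
    total_bound: float,
    count_col: str = "read_count",
    n_deciles: int = 10,
    ploidy: int = PLOIDY,
) -> pd.DataFrame:
    """Apportion bound molecules over peaks in proportion to read counts.

    Adds, per peak: ``length_bp``, ``bound_molecules`` (fractional),
    ``density_per_kb`` (molecules per kilobase), ``molecules_per_allele``
    (bound / ploidy) and ``decile`` (1 = lowest density, ``n_deciles`` =
    highest; equal-count groups, ties broken by genomic coordinate).
    The apportioning conserves the total: the per-peak molecule counts sum
    to ``total_bound`` exactly (before any rounding) and are invariant to
    rescaling all read counts by a constant.
    """
    out = _validate_peaks(peaks, count_col)
    total_reads = float(out[count_col].sum())
    if total_reads <= 0:
        raise ValueError("total reads in peaks must be positive")
    out["length_bp"] = out["end"] - out["start"]
    out["bound_molecules"] = out[count_col] / total_reads * total_bound
    out["density_per_kb"] = out["bound_molecules"] / (out["length_bp"] / 1000.0)
    out["molecules_per_allele"] = out["bound_molecules"] / ploidy
    # equal-count deciles of density, ties broken by genomic order
    order = np.lexsort(
        (out["start"].to_numpy(), out["chrom"].to_numpy(),
         out["density_per_kb"].to_numpy())
    )
    decile = np.empty(len(out), dtype=np.int64)
    for i, chunk in enumerate(np.array_split(order, n_deciles)):
        decile[chunk] = i + 1
    out["decile"] = decile
    return out


def decile_summary(occupancy: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of density per decile."""
    g = occupancy.groupby("decile")["density_per_kb"]
    return pd.DataFrame(
        {
            "n_peaks": g.size(),
            "median": g.median(),
            "q25": g.quantile(0.25),
            "q75": g.quantile(0.75),
        }
    )


def mean_density_per_kb(occupancy: pd.DataFrame, per_peak_mean: bool = False) -> float:
    """Mean bound-molecule density over peaks.

    Default: conserved-total version, total molecules / total peak kb.
    ``per_peak_mean=True`` returns the unweighted mean of per-peak
    densities instead.
    """
    if per_peak_mean:
        return float(occupancy["density_per_kb"].mean())
    return float(
        occupancy["bound_molecules"].sum()
        / (occupancy["length_bp"].sum() / 1000.0)
    )


# ---------------------------------------------------------------------------
# nucleosome / H2AK119ub1 turnover budget
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UbiquitinBudget:
    """Steady-state H2AK119ub1 bookkeeping for a 2n genome."""

    genome_size_bp: float
    nucleosome_spacing_bp: float
    total_nucleosomes: float
    total_h2a: float
    frac_ub: float
    total_h2aub: float
    half_life_s: float
    decay_constant_per_s: float   # ln 2 / half-life
    flux_per_s: float             # modifications lost (and replaced) per second
    mappable_fraction: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def nucleosome_budget(
    genome_size_bp: float = GENOME_SIZE_2N_BP,
    spacing_bp: float = NUCLEOSOME_SPACING_BP,
) -> float:
    """Total nucleosomes = genome size / mean nucleosome spacing."""
    if spacing_bp <= 0:
        raise ValueError("spacing must be positive")
    return genome_size_bp / spacing_bp


def h2aub_budget(
    total_nucleosomes: float | None = None,
    frac_ub: float = FRAC_H2A_UB,
    half_life_s: float = UB_HALF_LIFE_S,
    genome_size_bp: float = GENOME_SIZE_2N_BP,
    spacing_bp: float = NUCLEOSOME_SPACING_BP,
    mappable_fraction: float = MAPPABLE_FRACTION,
) -> UbiquitinBudget:
    """Steady-state H2AK119ub1 numbers and turnover flux.

    total H2A = 2 x nucleosomes; total ub = frac_ub x total H2A;
    decay constant = ln 2 / half-life; flux = decay constant x total ub
    (replacement rate equals loss rate at steady state).
    """
    if not 0.0 <= frac_ub <= 1.0:
        raise ValueError("frac_ub must lie in [0, 1]")
    if half_life_s <= 0:
        raise ValueError("half_life_s must be positive")
    if total_nucleosomes is None:
        total_nucleosomes = nucleosome_budget(genome_size_bp, spacing_bp)
    total_h2a = H2A_PER_NUCLEOSOME * total_nucleosomes
    total_ub = frac_ub * total_h2a
    k = math.log(2.0) / half_life_s
    return UbiquitinBudget(
        genome_size_bp=genome_size_bp,
        nucleosome_spacing_bp=spacing_bp,
        total_nucleosomes=total_nucleosomes,
        total_h2a=total_h2a,
        frac_ub=frac_ub,
        total_h2aub=total_ub,
        half_life_s=half_life_s,
        decay_constant_per_s=k,
        flux_per_s=k * total_ub,
        mappable_fraction=mappable_fraction,
    )


def deposition_interval(
    flux_per_s: float, complex_share: float, n_complexes: float
) -> float:
    """Seconds between deposition events per complex.

    ``1 / (flux * complex_share / n_complexes)``: the share of the global
    replacement flux carried by a complex family, divided evenly over its
    molecules, inverted to an interval.
    """
    if min(flux_per_s, complex_share, n_complexes) <= 0:
        raise ValueError("all inputs must be positive")
    return 1.0 / (flux_per_s * complex_share / n_complexes)


def h2aub_at_peaks(
    budget: UbiquitinBudget,
    peaks: pd.DataFrame,
    total_reads: float,
    count_col: str = "read_count",
) -> tuple[pd.DataFrame, float]:
    """Apportion genome-wide H2AK119ub1 molecules over peaks by read share.

    total in peaks = total_ub x mappable_fraction x (reads in peaks /
    total reads); per peak = reads x total_ub x mappable_fraction /
    total reads; density per kb from peak length.  Requires
    total_reads >= reads in peaks.

    Returns (per-peak table, total molecules in peaks).
    """
    out = _validate_peaks(peaks, count_col)
    reads_in_peaks = float(out[count_col].sum())
    if total_reads < reads_in_peaks:
        raise ValueError("total_reads must be >= reads in peaks")
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    scale = budget.total_h2aub * budget.mappable_fraction / total_reads
    out["length_bp"] = out["end"] - out["start"]
    out["h2aub_molecules"] = out[count_col] * scale
    out["h2aub_per_kb"] = out["h2aub_molecules"] / (out["length_bp"] / 1000.0)
    total_in_peaks = reads_in_peaks * scale
    return out, float(total_in_peaks)
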