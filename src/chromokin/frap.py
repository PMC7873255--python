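"""FRAP trace normalization and across-cell aggregation.

A raw trace holds bleached-region, unbleached-region and background
intensities over time.  Normalization forms the background-corrected
ratio of bleached to unbleached signal (double normalization: the
unbleached region corrects for acquisition bleaching) and scales it so
the mean prebleach value is exactly 1.  The ratio is oriented so that a
recovery curve rises toward 1 after the bleach; the literal inverse
(unbleached / bleached, which decays toward 1 from above) is available
behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["normalize_frap", "aggregate_frap"]

RAW_COLUMNS = ("t_s", "bleached", "unbleached", "background")


def normalize_frap(
    trace: pd.DataFrame,
    n_prebleach: int | None = None,
    literal_ratio: bool = False,
) -> pd.DataFrame:
    """Normalize a raw FRAP trace.

    ``relative(t) = (bleached - background) / (unbleached - background)``
    (or its inverse with ``literal_ratio=True``), rescaled so that the
    mean over the prebleach frames is 1.  Prebleach frames are taken from
    an ``is_prebleach`` column if present, else the first ``n_prebleach``
    rows.

    Returns a DataFrame (``t_s``, ``relative``, ``is_prebleach``).
    """
    missing = [c for c in RAW_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"trace missing column(s): {missing}")
    if "is_prebleach" in trace.columns:
        pre = trace["is_prebleach"].to_numpy(dtype=bool)
    else:
        if n_prebleach is None or n_prebleach < 1:
            raise ValueError("n_prebleach (>= 1) required without is_prebleach")
        pre = np.arange(len(trace)) < n_prebleach
    if pre.sum() < 1:
        raise ValueError("at least one prebleach frame required")
    b = trace["bleached"].to_numpy(dtype=float) - trace["background"].to_numpy(
        dtype=float
    )
    u = trace["unbleached"].to_numpy(dtype=float) - trace[
        "background"
    ].to_numpy(dtype=float)
    if np.any(u <= 0):
        raise ValueError("non-positive background-corrected unbleached intensity")
    rel = u / b if literal_ratio else b / u
    rel = rel / rel[pre].mean()
    return pd.DataFrame(
        {"t_s": trace["t_s"].to_numpy(dtype=float), "relative": rel,
         "is_prebleach": pre}
    )


def aggregate_frap(traces: list[pd.DataFrame]) -> pd.DataFrame:
    """Pointwise mean and SEM of normalized traces across cells.

    All traces must share a common time base (resample upstream if not).
    Returns a DataFrame (``t_s``, ``mean``, ``sem``, ``n``).
    """
    if len(traces) < 2:
        raise ValueError("need >= 2 traces to compute a SEM")
    t0 = traces[0]["t_s"].to_numpy(dtype=float)
    values = []
    for tr in traces:
        t = tr["t_s"].to_numpy(dtype=float)
        if t.shape != t0.shape or not np.allclose(t, t0):
            raise ValueError("traces do not share a common time base")
        values.append(tr["relative"].to_numpy(dtype=float))
    arr = np.vstack(values)
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n)
    return pd.DataFrame({"t_s": t0, "mean": mean, "sem": sem, "n": n})
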