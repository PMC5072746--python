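"""Temporal aggregation, decimation, and the ITQ-vs-resolution sweep.

Aggregation (non-overlapping block means) and decimation (thinning) move a
series through the causal information planes in opposite directions:
aggregation increases serial correlation and lowers permutation entropy,
decimation destroys correlation and raises it.  Sweeping the aggregation
factor exposes oscillatory time scales — with embedding dimension D, a cycle
of period P samples is "detected" once one window spans the full cycle, i.e.
at factor P / D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .measures import itq_suite
from .ordinal import OrdinalConfig, TimeSeries

__all__ = ["aggregate", "decimate", "resolution_sweep", "ResolutionSweep"]


def aggregate(series: TimeSeries, factor: int) -> TimeSeries:
    """Non-overlapping block means with block length ``factor``.

    A block containing any missing value is missing; a trailing partial
    block is dropped.  The sampling step is multiplied by ``factor``.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    n = len(series)
    if factor > n:
        raise ValueError(f"factor {factor} exceeds series length {n}")
    if factor == 1:
        return TimeSeries(
            series.values.copy(),
            step=series.step,
            step_unit=series.step_unit,
            missing_mask=series.missing_mask.copy(),
        )
    nblocks = n // factor
    vals = series.values[: nblocks * factor].reshape(nblocks, factor)
    mask = series.missing_mask[: nblocks * factor].reshape(nblocks, factor)
    out_mask = mask.any(axis=1)
    out = np.where(out_mask, np.nan, np.nansum(np.where(mask, 0.0, vals), axis=1) / factor)
    return TimeSeries(
        out,
        step=series.step * factor,
        step_unit=series.step_unit,
        missing_mask=out_mask,
    )


def decimate(series: TimeSeries, factor: int) -> TimeSeries:
    """Keep every ``factor``-th value starting at the first."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor > len(series):
        raise ValueError(f"factor {factor} exceeds series length {len(series)}")
    return TimeSeries(
        series.values[::factor].copy(),
        step=series.step * factor,
        step_unit=series.step_unit,
        missing_mask=series.missing_mask[::factor].copy(),
    )


@dataclass
class ResolutionSweep:
    """ITQ values across a ladder of aggregation factors."""

    factors: np.ndarray
    results: pd.DataFrame  # columns: factor, step, H, C, F, n_windows

    def __iter__(self):
        return iter(self.results.itertuples(index=False))


def resolution_sweep(
    series: TimeSeries, factors, config: OrdinalConfig | None = None
) -> ResolutionSweep:
    """Run :func:`~itquant.measures.itq_suite` at each aggregation factor.

    ``factors`` must be strictly increasing positive integers; each factor
    must leave at least D! windows.  Records the effective sampling step
    (factor x native step) alongside (H, C, F).
    """
    config = config or OrdinalConfig()
    factors = np.asarray(list(factors), dtype=int)
    if factors.size == 0:
        raise ValueError("need at least one factor")
    if np.any(factors < 1) or np.any(np.diff(factors) <= 0):
        raise ValueError("factors must be strictly increasing and >= 1")
    rows = []
    for f in factors:
        agg = aggregate(series, int(f))
        res = itq_suite(agg, config)
        rows.append(
            {
                "factor": int(f),
                "step": agg.step,
                "H": res.H,
                "C": res.C,
                "F": res.F,
                "n_windows": res.n_windows,
            }
        )
    return ResolutionSweep(factors=factors, results=pd.DataFrame(rows))
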