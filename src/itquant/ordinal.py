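"""Ordinal-pattern symbolization of time series.

A scalar series is embedded in windows of ``D`` values taken ``tau`` steps
apart; each window is reduced to the permutation that sorts its values in
ascending order.  The relative frequencies of these permutations — the
ordinal-pattern (or "causal") probability distribution — are the input to
every information-theory quantifier in :mod:`itquant.measures`.  Because only
rank order enters, the symbolization is invariant under strictly increasing
transformations of the data and robust to calibration drifts.

An optional variance weighting assigns each window a weight equal to the
variance of its embedded values, so that high-amplitude (high signal-to-noise)
windows dominate the distribution.  This matters for environmental series with
strong seasonal amplitude modulation, where low-variance dormant-season
windows are mostly noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "OrdinalConfig",
    "OrdinalDistribution",
    "ValidationReport",
    "extract_patterns",
    "lehmer_rank",
    "ordinal_distribution",
    "validate_series",
]


@dataclass
class TimeSeries:
    """A regularly sampled scalar series with a missing-value mask.

    Parameters
    ----------
    values : array-like
        The samples, in arbitrary physical units.  Positions flagged missing
        may hold NaN.
    step : float
        Sampling interval (positive).
    step_unit : str
        Unit label for ``step`` (e.g. ``"hour"``, ``"month"``).
    missing_mask : array-like of bool, optional
        True where the value is missing.  Defaults to marking NaNs missing.
    """

    values: np.ndarray
    step: float = 1.0
    step_unit: str = "step"
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size < 1:
            raise ValueError("series must have length >= 1")
        if not self.step > 0:
            raise ValueError("step must be positive")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing_mask length must equal values length")
            self.missing_mask = self.missing_mask | np.isnan(self.values)
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-missing values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_valid(self) -> int:
        return int((~self.missing_mask).sum())


@dataclass(frozen=True)
class OrdinalConfig:
    """Parameters governing the symbolization.

    ``D`` is the embedding dimension (pattern length, 2..8), ``tau`` the
    embedding delay in samples.  ``weighted`` selects the variance-weighted
    pattern distribution.  ``ordering`` fixes how patterns map to indices of
    the probability vector: ``"lehmer"`` uses the Lehmer rank of the sorting
    permutation (the default and the ordering under which Fisher information
    is reported); ``"custom"`` applies the user-supplied ``custom_order``
    table, a permutation of ``range(D!)`` mapping Lehmer rank -> index.
    ``tie_rule`` either breaks ties stably by earlier time offset
    (``"stable_first_occurrence"``) or drops tied windows (``"reject"``).
    """

    D: int = 4
    tau: int = 1
    weighted: bool = True
    ordering: str = "lehmer"
    custom_order: tuple[int, ...] | None = None
    tie_rule: str = "stable_first_occurrence"

    def __post_init__(self) -> None:
        if not (2 <= self.D <= 8):
            raise ValueError("embedding dimension D must satisfy 2 <= D <= 8")
        if self.tau < 1:
            raise ValueError("delay tau must be >= 1")
        if self.ordering not in ("lehmer", "custom"):
            raise ValueError("ordering must be 'lehmer' or 'custom'")
        if self.tie_rule not in ("stable_first_occurrence", "reject"):
            raise ValueError(
                "tie_rule must be 'stable_first_occurrence' or 'reject'"
            )
        if self.ordering == "custom":
            if self.custom_order is None:
                raise ValueError("ordering='custom' requires custom_order")
            order = np.asarray(self.custom_order, dtype=int)
            if sorted(order.tolist()) != list(range(self.n_patterns)):
                raise ValueError("custom_order must be a permutation of range(D!)")
            object.__setattr__(self, "custom_order", tuple(order.tolist()))

    @property
    def n_patterns(self) -> int:
        """Number of possible patterns, D!."""
        return math.factorial(self.D)

    @property
    def window_span(self) -> int:
        """Number of series samples one window stretches over."""
        return (self.D - 1) * self.tau + 1


@dataclass
class OrdinalDistribution:
    """Probability vector over the D! ordinal patterns in a fixed ordering."""

    D: int
    tau: int
    ordering: str
    p: np.ndarray
    n_windows: int
    total_weight: float
    weighted: bool
    raw: np.ndarray = field(default=None)  # counts (unweighted) or summed weights

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.size != math.factorial(self.D):
            raise ValueError("probability vector must have length D!")
        if np.any(self.p < 0):
            raise ValueError("probabilities must be non-negative")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1 within 1e-12")
        if self.raw is None:
            self.raw = self.p * (self.total_weight if self.weighted else self.n_windows)

    @property
    def n_patterns(self) -> int:
        return self.p.size

    def compatible_with(self, other: "OrdinalDistribution") -> bool:
        return (
            self.D == other.D
            and self.tau == other.tau
            and self.ordering == other.ordering
        )


@dataclass
class ValidationReport:
    """Report-only check of a series against a symbolization config."""

    ok: bool
    errors: list[str]
    warnings: list[str]
    n_windows: int
    tied_fraction: float
    missing_fraction: float


def lehmer_rank(perm) -> int:
    """Lehmer rank of a permutation of {0..D-1}, in [0, D!-1].

    The rank is ``sum_i c_i * (D-1-i)!`` where ``c_i`` counts entries after
    position ``i`` that are smaller than ``perm[i]`` (factorial number
    system).  The map is a bijection onto ``range(D!)``; the identity
    permutation has rank 0 and the reversal rank D!-1.
    """
    perm = np.asarray(perm, dtype=int)
    d = perm.size
    if sorted(perm.tolist()) != list(range(d)):
        raise ValueError("not a permutation of 0..D-1")
    rank = 0
    for i in range(d - 1):
        c = int(np.sum(perm[i + 1 :] < perm[i]))
        rank += c * math.factorial(d - 1 - i)
    return rank


def lehmer_unrank(rank: int, d: int) -> tuple[int, ...]:
    """Inverse of :func:`lehmer_rank`: the permutation at a given rank."""
    if not 0 <= rank < math.factorial(d):
        raise ValueError("rank out of range")
    digits = []
    for i in range(d - 1, -1, -1):
        f = math.factorial(i)
        digits.append(rank // f)
        rank %= f
    pool = list(range(d))
    return tuple(pool.pop(c) for c in digits)


def _lehmer_ranks(perms: np.ndarray) -> np.ndarray:
    """Vectorized Lehmer ranks for an (n, D) array of permutations."""
    d = perms.shape[1]
    ranks = np.zeros(perms.shape[0], dtype=np.int64)
    for i in range(d - 1):
        c = (perms[:, i + 1 :] < perms[:, i : i + 1]).sum(axis=1)
        ranks += c * math.factorial(d - 1 - i)
    return ranks


def _embed(series: TimeSeries, config: OrdinalConfig):
    """Window the series and symbolize each complete window.

    Returns ``(ranks, weights, n_total, n_missing, n_tied)`` where ``ranks``
    and ``weights`` cover the retained windows only.  ``weights`` are the
    population variances of the embedded vectors (the windows the
    symbolization itself sees, also for tau > 1).
    """
    x = series.values
    D, tau = config.D, config.tau
    span = (D - 1) * tau
    n = x.size
    if n <= span:
        raise ValueError(
            f"series too short for (D={D}, tau={tau}): "
            f"need at least {span + 1} values, have {n}"
        )
    starts = np.arange(n - span)
    idx = starts[:, None] + np.arange(D)[None, :] * tau
    win = x[idx]
    complete = ~series.missing_mask[idx].any(axis=1)
    n_total = starts.size
    n_missing = int(n_total - complete.sum())

    win = win[complete]
    if win.shape[0] == 0:
        raise ValueError(
            f"series too short for (D={D}, tau={tau}): no complete window"
        )
    # stable argsort by value -> ascending-value order of time offsets,
    # ties resolved in favour of the earlier offset
    perms = np.argsort(win, axis=1, kind="stable")
    svals = np.take_along_axis(win, perms, axis=1)
    tied = (np.diff(svals, axis=1) == 0).any(axis=1)
    n_tied = int(tied.sum())

    if config.tie_rule == "reject":
        perms = perms[~tied]
        win = win[~tied]
        if perms.shape[0] == 0:
            raise ValueError("all complete windows tied; nothing to symbolize")

    ranks = _lehmer_ranks(perms)
    if config.ordering == "custom":
        table = np.asarray(config.custom_order, dtype=np.int64)
        ranks = table[ranks]
    weights = win.var(axis=1)
    return ranks, weights, n_total, n_missing, n_tied


def extract_patterns(series: TimeSeries, config: OrdinalConfig) -> np.ndarray:
    """Pattern index sequence, one per retained window.

    Window ``j`` is ``(x_j, x_{j+tau}, ..., x_{j+(D-1)tau})``; windows with
    any missing value are skipped, tied windows are skipped too under
    ``tie_rule="reject"``.  Indices are Lehmer ranks of the sorting
    permutation (or their image under a custom ordering table).
    """
    ranks, _, _, _, _ = _embed(series, config)
    return ranks


def ordinal_distribution(
    series: TimeSeries, config: OrdinalConfig
) -> OrdinalDistribution:
    """Build the (possibly variance-weighted) ordinal pattern distribution.

    Unweighted: ``p_i = count_i / n_windows``.  Weighted: each window
    contributes its variance as weight, ``p_i = sum of weights of windows
    showing pattern i / total weight``.
    """
    ranks, weights, _, _, _ = _embed(series, config)
    npat = config.n_patterns
    if config.weighted:
        total = float(weights.sum())
        if total <= 0.0:
            raise ValueError("degenerate series: zero total weight")
        raw = np.bincount(ranks, weights=weights, minlength=npat)
        p = raw / total
    else:
        raw = np.bincount(ranks, minlength=npat).astype(float)
        total = float(weights.sum())
        p = raw / ranks.size
    # guard against accumulated round-off
    p = p / p.sum()
    return OrdinalDistribution(
        D=config.D,
        tau=config.tau,
        ordering=config.ordering,
        p=p,
        n_windows=int(ranks.size),
        total_weight=total,
        weighted=config.weighted,
        raw=raw,
    )


def validate_series(series: TimeSeries, config: OrdinalConfig) -> ValidationReport:
    """Check a series for adequate length and benign tie/gap structure.

    Errors when the number of usable windows falls below ``D!`` (too few to
    populate the pattern space at all); warns below ``5 * D!``.  Reports the
    fractions of tied and of missing-skipped windows.  Weak stationarity of
    the ordinal statistics is assumed, not tested.
    """
    errors: list[str] = []
    warnings: list[str] = []
    npat = config.n_patterns
    try:
        ranks, _, n_total, n_missing, n_tied = _embed(series, config)
        n_windows = int(ranks.size)
    except ValueError as exc:
        return ValidationReport(
            ok=False,
            errors=[str(exc)],
            warnings=[],
            n_windows=0,
            tied_fraction=0.0,
            missing_fraction=0.0,
        )

    if n_windows < npat:
        errors.append(f"{n_windows} windows < {npat} patterns")
    elif n_windows < 5 * npat:
        warnings.append(
            f"{n_windows} windows < 5 x {npat} patterns; estimates will be noisy"
        )
    tied_fraction = n_tied / n_total if n_total else 0.0
    missing_fraction = n_missing / n_total if n_total else 0.0
    if n_tied:
        warnings.append(f"tied windows: fraction {tied_fraction:.3g}")
    if n_missing:
        warnings.append(f"windows skipped for missing data: fraction {missing_fraction:.3g}")
    return ValidationReport(
        ok=not errors,
        errors=errors,
        warnings=warnings,
        n_windows=n_windows,
        tied_fraction=tied_fraction,
        missing_fraction=missing_fraction,
    )
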