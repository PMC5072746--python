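"""Information-theory quantifiers on ordinal pattern distributions.

Given the causal PDF :math:`P = \\{p_i\\}` over :math:`N = D!` patterns, the
package computes

* the normalized permutation (Shannon) entropy
  :math:`H[P] = S[P] / \\ln N` with :math:`S[P] = -\\sum_i p_i \\ln p_i`,
* the statistical complexity :math:`C[P] = Q_J[P, P_e] \\cdot H[P]`, where
  :math:`Q_J` is the Jensen-Shannon disequilibrium to the uniform PDF
  :math:`P_e`, normalized so a delta distribution gives exactly 1,
* the discrete, normalized Fisher information measure
  :math:`F[P] = F_0 \\sum_i (\\sqrt{p_{i+1}} - \\sqrt{p_i})^2`, built from
  probability amplitudes and therefore dependent on the pattern ordering,
* the Rényi entropy of the pattern distribution, and
* the Jensen-Shannon divergence between two pattern distributions, the
  model-benchmark distance.

H and C depend only on global properties of P; F is local (adjacent-pattern
differences).  For a fixed H, C is confined between limit curves
:math:`C_{min}(H)` and :math:`C_{max}(H)` which :func:`complexity_bounds`
traces numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ordinal import (
    OrdinalConfig,
    OrdinalDistribution,
    TimeSeries,
    ordinal_distribution,
    validate_series,
)

__all__ = [
    "ITQResult",
    "ComplexityBounds",
    "shannon_entropy",
    "normalized_entropy",
    "disequilibrium",
    "statistical_complexity",
    "fisher_information",
    "renyi_entropy",
    "jensen_shannon_divergence",
    "complexity_bounds",
    "itq_suite",
]

_PROB_TOL = 1e-9


def _as_prob(P) -> np.ndarray:
    """Coerce an OrdinalDistribution or bare vector to a checked PDF array."""
    if isinstance(P, OrdinalDistribution):
        return P.p
    p = np.asarray(P, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("not a probability vector")
    if np.any(p < -_PROB_TOL) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("not a probability vector")
    return np.clip(p, 0.0, None)


def shannon_entropy(P) -> float:
    """Shannon entropy S[P] = -sum p_i ln p_i in nats, with 0 ln 0 := 0."""
    p = _as_prob(P)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() + 0.0)  # +0.0 avoids -0.0


def normalized_entropy(P) -> float:
    """Permutation entropy H = S[P] / ln N, in [0, 1]."""
    p = _as_prob(P)
    if p.size < 2:
        return 0.0
    return shannon_entropy(p) / math.log(p.size)


def _js_to_uniform(p: np.ndarray) -> float:
    n = p.size
    pe = 1.0 / n
    m = 0.5 * (p + pe)
    return shannon_entropy(m / m.sum()) - 0.5 * shannon_entropy(p) - 0.5 * math.log(n)


def _q0(n: int) -> float:
    """Normalization constant making the delta-PDF disequilibrium exactly 1."""
    return -2.0 / (
        (n + 1) / n * math.log(n + 1) - 2.0 * math.log(2 * n) + math.log(n)
    )


def disequilibrium(P) -> float:
    """Normalized Jensen-Shannon distance Q_J[P, Pe] to the uniform PDF.

    Q_J = Q0 * {S[(P+Pe)/2] - S[P]/2 - S[Pe]/2}; Q0 is chosen so that a
    delta distribution attains Q_J = 1 and the uniform PDF gives 0.
    """
    p = _as_prob(P)
    if p.size < 2:
        return 0.0
    return _q0(p.size) * _js_to_uniform(p)


def statistical_complexity(P) -> float:
    """Statistical complexity C = Q_J[P, Pe] * H[P], in [0, 1]."""
    p = _as_prob(P)
    return disequilibrium(p) * normalized_entropy(p)


def fisher_information(P) -> float:
    """Discrete normalized Fisher information measure.

    F = F0 * sum_{i=1}^{N-1} (sqrt(p_{i+1}) - sqrt(p_i))^2, with F0 = 1 when
    P is a delta at the first or last position and 1/2 otherwise.  The value
    depends on the pattern ordering of P (a local quantifier): F(uniform)=0,
    F(delta)=1, and F generally behaves opposite to H.
    """
    p = _as_prob(P)
    if p.size < 2:
        return 0.0
    amp = np.sqrt(p)
    raw = float(np.sum(np.diff(amp) ** 2))
    edge_delta = p[0] >= 1.0 - 1e-12 or p[-1] >= 1.0 - 1e-12
    f0 = 1.0 if edge_delta else 0.5
    return f0 * raw


def renyi_entropy(P, q: float, normalized: bool = False) -> float:
    """Rényi entropy H_q = log2(sum p_i^q)/(1-q) of the pattern PDF, in bits.

    Exponents q > 1 suppress low-frequency patterns; the q -> 1 limit is the
    Shannon entropy in bits.  ``normalized=True`` divides by log2 N.
    """
    if q <= 0:
        raise ValueError("Rényi exponent q must be positive")
    if q == 1.0:
        raise ValueError("q = 1 is the Shannon limit: use shannon_entropy")
    p = _as_prob(P)
    nz = p[p > 0]
    h = math.log2(float(np.sum(nz**q))) / (1.0 - q)
    if normalized:
        h /= math.log2(p.size)
    return h


def jensen_shannon_divergence(P, Q, normalized: bool = False) -> float:
    """Jensen-Shannon divergence J[P, Q] = S[(P+Q)/2] - S[P]/2 - S[Q]/2.

    Symmetric, non-negative, zero iff P = Q, bounded by ln 2 (nats).  This is
    the model-observation distance on ordinal pattern distributions;
    ``normalized=True`` divides by ln 2.  OrdinalDistribution inputs must
    share D, tau and ordering.
    """
    if isinstance(P, OrdinalDistribution) and isinstance(Q, OrdinalDistribution):
        if not P.compatible_with(Q):
            raise ValueError("incomparable distributions: D/tau/ordering differ")
    p, q = _as_prob(P), _as_prob(Q)
    if p.size != q.size:
        raise ValueError("incomparable distributions: lengths differ")
    if np.array_equal(p, q):
        return 0.0
    m = 0.5 * (p + q)
    j = shannon_entropy(m / m.sum()) - 0.5 * shannon_entropy(p) - 0.5 * shannon_entropy(q)
    j = max(j, 0.0)
    if normalized:
        j /= math.log(2.0)
    return float(j)


# ---------------------------------------------------------------------------
# complexity limit curves


@dataclass
class ComplexityBounds:
    """Limit curves C_min(H), C_max(H) of the entropy-complexity plane.

    Tabulated on a regular H grid for ``N`` states; evaluate at arbitrary H
    with :meth:`cmin_at` / :meth:`cmax_at` (linear interpolation).
    """

    N: int
    h_grid: np.ndarray
    c_min: np.ndarray
    c_max: np.ndarray

    def cmin_at(self, h) -> np.ndarray:
        return np.interp(h, self.h_grid, self.c_min)

    def cmax_at(self, h) -> np.ndarray:
        return np.interp(h, self.h_grid, self.c_max)

    def contains(self, h, c, tol: float = 1e-6) -> np.ndarray:
        """Elementwise check that (h, c) lies between the limit curves."""
        h = np.asarray(h, dtype=float)
        c = np.asarray(c, dtype=float)
        return (c >= self.cmin_at(h) - tol) & (c <= self.cmax_at(h) + tol)


def _family_hc(n_nonzero: int, N: int, p: np.ndarray):
    """(H, C) along the one-parameter family with one free probability.

    The family has ``n_nonzero`` positive states: one of probability ``p``
    and ``n_nonzero - 1`` sharing ``1 - p`` equally; the remaining
    ``N - n_nonzero`` states are exactly zero.
    """
    n = n_nonzero
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (1.0 - p) / (n - 1)
        s_p = -(np.where(p > 0, p * np.log(p), 0.0)
                + np.where(q > 0, (1.0 - p) * np.log(q), 0.0))
        # mixture with the uniform PDF over all N states
        a = 0.5 * (p + 1.0 / N)            # 1 state
        b = 0.5 * (q + 1.0 / N)            # n-1 states
        z = 0.5 / N                        # N-n states
        s_m = -(
            np.where(a > 0, a * np.log(a), 0.0)
            + (n - 1) * np.where(b > 0, b * np.log(b), 0.0)
            + (N - n) * (z * np.log(z))
        )
    h = s_p / math.log(N)
    js = s_m - 0.5 * s_p - 0.5 * math.log(N)
    c = _q0(N) * js * h
    return h, c


def _branch_grid(lo: float, hi: float, m: int) -> np.ndarray:
    """Parameter grid on [lo, hi] refined toward both ends."""
    t = np.linspace(0.0, 1.0, m)
    t = 0.5 - 0.5 * np.cos(np.pi * t)  # cosine clustering at the ends
    return lo + (hi - lo) * t


def complexity_bounds(N: int, grid_points: int = 512) -> ComplexityBounds:
    """Trace the limit curves of the entropy-complexity plane for N states.

    The lower curve follows the full-support family {p, (1-p)/(N-1), ...};
    the upper curve is the envelope over families with m = 0..N-2 components
    exactly zero and the remainder {p, equal shares}.  Each family is sampled
    on 2000-point parameter grids per monotone branch and the envelope is
    resampled to a regular H grid by linear interpolation.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if grid_points < 10:
        raise ValueError("grid_points must be >= 10")
    h_grid = np.linspace(0.0, 1.0, grid_points)
    m_pts = 2000

    def branch_on_grid(n_nonzero: int, lo: float, hi: float):
        p = _branch_grid(lo, hi, m_pts)
        h, c = _family_hc(n_nonzero, N, p)
        order = np.argsort(h)
        h, c = h[order], c[order]
        # restrict interpolation to the branch's H range
        out = np.full_like(h_grid, np.nan)
        inside = (h_grid >= h[0]) & (h_grid <= h[-1])
        out[inside] = np.interp(h_grid[inside], h, c)
        return out

    # lower curve: full-support family, two monotone branches split at p = 1/N
    lower_branches = [
        branch_on_grid(N, 1.0 / N, 1.0),
        branch_on_grid(N, 0.0, 1.0 / N),
    ]
    c_min = np.nanmin(np.vstack(lower_branches), axis=0)

    # upper curve: envelope over numbers of nonzero states n = 2..N
    upper = []
    for n in range(2, N + 1):
        upper.append(branch_on_grid(n, 1.0 / n, 1.0))
        upper.append(branch_on_grid(n, 0.0, 1.0 / n))
    with np.errstate(invalid="ignore"):
        c_max = np.nanmax(np.vstack(upper), axis=0)

    # endpoints are exact: delta (H=0) and uniform (H=1) both have C=0
    c_min[0] = c_max[0] = 0.0
    c_min[-1] = c_max[-1] = 0.0
    c_min = np.nan_to_num(np.clip(c_min, 0.0, None))
    c_max = np.nan_to_num(np.clip(c_max, 0.0, None))
    c_max = np.maximum(c_max, c_min)
    return ComplexityBounds(N=N, h_grid=h_grid, c_min=c_min, c_max=c_max)


# ---------------------------------------------------------------------------
# one-shot suite


@dataclass
class ITQResult:
    """The (H, C, F) triple for one series plus provenance."""

    H: float
    C: float
    F: float
    weighted: bool
    config: OrdinalConfig
    n_windows: int

    def to_dict(self) -> dict:
        return {
            "H": self.H,
            "C": self.C,
            "F": self.F,
            "D": self.config.D,
            "tau": self.config.tau,
            "weighted": self.weighted,
            "n_windows": self.n_windows,
        }


def itq_suite(series: TimeSeries, config: OrdinalConfig | None = None) -> ITQResult:
    """Compute (H, C, F) from one series: the point in the causal planes.

    Builds the (weighted) ordinal pattern distribution and evaluates the
    normalized entropy, statistical complexity and Fisher information.
    Raises when the series has fewer usable windows than patterns (D!).
    """
    config = config or OrdinalConfig()
    report = validate_series(series, config)
    if not report.ok:
        raise ValueError("; ".join(report.errors))
    dist = ordinal_distribution(series, config)
    return ITQResult(
        H=normalized_entropy(dist),
        C=statistical_complexity(dist),
        F=fisher_information(dist),
        weighted=config.weighted,
        config=config,
        n_windows=dist.n_windows,
    )
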