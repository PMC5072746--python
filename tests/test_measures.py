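"""Entropy, complexity, Fisher, Rényi, JSD, and the limit curves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itquant import (
    OrdinalConfig,
    TimeSeries,
    complexity_bounds,
    disequilibrium,
    fisher_information,
    itq_suite,
    jensen_shannon_divergence,
    logistic_map,
    normalized_entropy,
    renyi_entropy,
    shannon_entropy,
    statistical_complexity,
    white_noise,
)

UNIFORM6 = np.full(6, 1 / 6)
DELTA6 = np.eye(6)[0]


def prob_vectors(n=6):
    return (
        st.lists(st.floats(0.001, 1.0), min_size=n, max_size=n)
        .map(np.array)
        .map(lambda v: v / v.sum())
    )


class TestShannon:
    def test_uniform_is_log_n(self):
        assert shannon_entropy(UNIFORM6) == pytest.approx(math.log(6), abs=1e-12)

    def test_delta_is_zero(self):
        assert shannon_entropy(DELTA6) == 0.0

    def test_two_state(self, toy_pdf):
        assert shannon_entropy(toy_pdf) == pytest.approx(math.log(2), abs=1e-12)

    def test_normalized(self, toy_pdf):
        assert normalized_entropy(UNIFORM6) == pytest.approx(1.0, abs=1e-12)
        assert normalized_entropy(DELTA6) == 0.0
        assert normalized_entropy(toy_pdf) == pytest.approx(0.3869, abs=1e-4)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError, match="not a probability vector"):
            shannon_entropy(np.array([0.5, 0.6]))
        with pytest.raises(ValueError, match="not a probability vector"):
            shannon_entropy(np.array([1.5, -0.5]))


class TestDisequilibriumComplexity:
    def test_uniform_zero(self):
        assert disequilibrium(UNIFORM6) == pytest.approx(0.0, abs=1e-12)
        assert statistical_complexity(UNIFORM6) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 6, 24, 120])
    def test_delta_is_exactly_one(self, n):
        """The Q0 normalization makes Q_J of a delta PDF exactly 1."""
        delta = np.zeros(n)
        delta[0] = 1.0
        assert disequilibrium(delta) == pytest.approx(1.0, abs=1e-12)
        assert statistical_complexity(delta) == pytest.approx(0.0, abs=1e-12)

    def test_half_half_case(self, toy_pdf):
        assert disequilibrium(toy_pdf) == pytest.approx(0.7011, abs=1e-4)
        assert statistical_complexity(toy_pdf) == pytest.approx(0.2713, abs=1e-4)


class TestFisher:
    def test_uniform_zero(self):
        assert fisher_information(UNIFORM6) == pytest.approx(0.0, abs=1e-12)

    def test_edge_delta_one(self):
        assert fisher_information(DELTA6) == 1.0
        assert fisher_information(DELTA6[::-1]) == 1.0

    def test_interior_delta_one(self):
        delta = np.zeros(6)
        delta[3] = 1.0  # two unit amplitude jumps, F0 = 1/2
        assert fisher_information(delta) == pytest.approx(1.0, abs=1e-12)

    def test_half_half_case(self, toy_pdf):
        assert fisher_information(toy_pdf) == pytest.approx(0.25, abs=1e-4)

    def test_ordering_dependence(self, toy_pdf):
        """F is local: permuting the pattern ordering changes it."""
        spread = toy_pdf[[0, 2, 1, 3, 4, 5]]  # (0.5, 0, 0.5, 0, 0, 0)
        assert fisher_information(spread) != pytest.approx(
            fisher_information(toy_pdf), abs=1e-6
        )


class TestRenyi:
    def test_uniform_any_q(self):
        for q in (0.5, 2.0, 3.0):
            assert renyi_entropy(UNIFORM6, q) == pytest.approx(
                math.log2(6), abs=1e-12
            )

    def test_delta(self):
        assert renyi_entropy(DELTA6, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_half_half_q2(self, toy_pdf):
        assert renyi_entropy(toy_pdf, 2.0) == pytest.approx(1.0, abs=1e-12)

    def test_q1_rejected(self):
        with pytest.raises(ValueError, match="shannon_entropy"):
            renyi_entropy(UNIFORM6, 1.0)

    def test_limit_q_to_1_matches_shannon_bits(self, rng):
        """H_q -> Shannon (bits) as q -> 1: linearly one-sided, so the
        symmetric mean at q = 1 +/- eps converges at O(eps^2)."""
        p = rng.dirichlet(np.ones(24))
        shannon_bits = shannon_entropy(p) / math.log(2)
        hi = renyi_entropy(p, 1 + 1e-4)
        lo = renyi_entropy(p, 1 - 1e-4)
        assert hi == pytest.approx(shannon_bits, abs=1e-3)
        assert lo == pytest.approx(shannon_bits, abs=1e-3)
        assert 0.5 * (hi + lo) == pytest.approx(shannon_bits, abs=1e-6)

    def test_normalized_variant(self, toy_pdf):
        assert renyi_entropy(toy_pdf, 2.0, normalized=True) == pytest.approx(
            1.0 / math.log2(6), abs=1e-12
        )


class TestJensenShannon:
    def test_identity(self, toy_pdf):
        assert jensen_shannon_divergence(toy_pdf, toy_pdf) == 0.0

    def test_disjoint_deltas_ln2(self):
        d2 = np.eye(6)[3]
        assert jensen_shannon_divergence(DELTA6, d2) == pytest.approx(
            math.log(2), abs=1e-12
        )
        assert jensen_shannon_divergence(DELTA6, d2, normalized=True) == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_incomparable_configs_rejected(self, rng):
        from itquant import ordinal_distribution

        x = TimeSeries(rng.standard_normal(100))
        a = ordinal_distribution(x, OrdinalConfig(D=3))
        b = ordinal_distribution(x, OrdinalConfig(D=4))
        with pytest.raises(ValueError, match="incomparable"):
            jensen_shannon_divergence(a, b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(prob_vectors(), prob_vectors())
    def test_properties(self, p, q):
        """Symmetry, non-negativity, ln2 bound, identity of indiscernibles."""
        j = jensen_shannon_divergence(p, q)
        assert j == pytest.approx(jensen_shannon_divergence(q, p), abs=1e-12)
        assert 0.0 <= j <= math.log(2) + 1e-12
        assert jensen_shannon_divergence(p, p) <= 1e-12


class TestNormalizationFuzz:
    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(prob_vectors(24))
    def test_all_quantifiers_in_unit_interval(self, p):
        for f in (normalized_entropy, disequilibrium, statistical_complexity,
                  fisher_information):
            assert -1e-12 <= f(p) <= 1.0 + 1e-12


class TestComplexityBounds:
    def test_endpoints_zero(self):
        b = complexity_bounds(24, 200)
        assert b.c_max[0] == pytest.approx(0.0, abs=1e-6)
        assert b.c_max[-1] == pytest.approx(0.0, abs=1e-6)
        assert (b.c_min >= 0).all()

    def test_min_below_max(self):
        b = complexity_bounds(24, 300)
        assert np.all(b.c_min <= b.c_max + 1e-12)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            complexity_bounds(1)

    def test_dirichlet_containment(self, rng):
        """Random PDFs land between the limit curves (Monte-Carlo oracle)."""
        b = complexity_bounds(24, 512)
        P = rng.dirichlet(np.ones(24), size=2000)
        h = np.array([normalized_entropy(p) for p in P])
        c = np.array([statistical_complexity(p) for p in P])
        assert b.contains(h, c, tol=1e-6).all()

    def test_family_extremes_touch_curves(self):
        """The generating families themselves lie on (not outside) the bounds."""
        b = complexity_bounds(12, 2000)
        for p0 in np.linspace(0.05, 0.95, 19):
            pdf = np.r_[p0, np.full(11, (1 - p0) / 11)]
            h = normalized_entropy(pdf)
            c = statistical_complexity(pdf)
            assert c <= b.cmax_at(h) + 1e-6
            assert c >= b.cmin_at(h) - 2e-4  # resampling tolerance on the curve


class TestItqSuite:
    def test_monotone_ramp_anchor(self, ramp):
        res = itq_suite(ramp, OrdinalConfig(D=4))
        assert (res.H, res.C, res.F) == (0.0, 0.0, 1.0)

    def test_white_noise_corner(self):
        res = itq_suite(white_noise(30000, seed=5), OrdinalConfig(D=5))
        assert res.H > 0.97 and res.C < 0.05 and res.F < 0.05

    def test_logistic_near_upper_limit(self):
        res = itq_suite(logistic_map(5000, 4.0, 0.3), OrdinalConfig(D=5))
        b = complexity_bounds(120, 512)
        assert abs(res.C - b.cmax_at(res.H)) < abs(res.C - b.cmin_at(res.H))

    def test_anti_correlation_extremes(self, ramp):
        reg = itq_suite(ramp, OrdinalConfig(D=4))
        noise = itq_suite(white_noise(30000, seed=6), OrdinalConfig(D=4))
        assert reg.F > noise.F and reg.H < noise.H

    def test_surrogate_separation(self, rng):
        lm = logistic_map(8000, 4.0, 0.3)
        shuffled = TimeSeries(rng.permutation(lm.values))
        cfg = OrdinalConfig(D=5)
        a, b = itq_suite(lm, cfg), itq_suite(shuffled, cfg)
        assert b.H > a.H and b.C < a.C

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="windows"):
            itq_suite(TimeSeries(np.arange(10.0) % 3), OrdinalConfig(D=4))

    def test_result_bounds_containment(self, rng):
        b = complexity_bounds(24, 512)
        for _ in range(20):
            res = itq_suite(
                TimeSeries(rng.standard_normal(400)), OrdinalConfig(D=4)
            )
            assert 0 <= res.H <= 1 and 0 <= res.C <= 1 and 0 <= res.F <= 1
            assert b.contains(res.H, res.C, tol=1e-9)
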