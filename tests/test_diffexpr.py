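"""Audic–Claverie statistic, fold changes, BH correction and DE calls."""

from fractions import Fraction
from math import factorial

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import nbinom

from spongeworks.diffexpr import (
    DEThresholds,
    ac_log_pmf,
    ac_pmf,
    ac_test,
    bh_adjust,
    call_differential,
    log2_fold_change,
)


def exact_ac_pmf(x: int, y: int, n1: int, n2: int) -> Fraction:
    """Rational-arithmetic oracle for the count-comparison pmf."""
    r = Fraction(n2, n1)
    binom = Fraction(factorial(x + y), factorial(x) * factorial(y))
    return r**y * binom / (1 + r) ** (x + y + 1)


class TestPmf:
    @pytest.mark.parametrize(
        "x,y,n1,n2",
        [(0, 0, 10, 10), (5, 5, 7, 7), (3, 8, 100, 250), (12, 1, 9, 4)],
    )
    def test_matches_rational_oracle(self, x, y, n1, n2):
        assert ac_pmf(x, y, n1, n2) == pytest.approx(
            float(exact_ac_pmf(x, y, n1, n2)), rel=1e-12
        )

    def test_equal_libraries_zero_counts_is_half(self):
        assert ac_pmf(0, 0, 10**6, 10**6) == pytest.approx(0.5, abs=1e-12)

    def test_five_five_equal_libraries(self):
        assert ac_pmf(5, 5, 10**6, 10**6) == pytest.approx(252 / 2048, rel=1e-12)

    @pytest.mark.parametrize("x", [0, 1, 5, 20, 50, 200])
    @pytest.mark.parametrize("n1,n2", [(10**6, 10**6), (10**6, 2 * 10**6), (5 * 10**5, 10**6), (3 * 10**6, 10**6)])
    def test_normalisation(self, x, n1, n2):
        ys = np.arange(0, 5000)
        total = np.exp(ac_log_pmf(x, ys, n1, n2)).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_negative_binomial_closed_form(self):
        # independent route: NB(x+1 failures, p=N1/(N1+N2)) from scipy
        n1, n2 = 7 * 10**5, 13 * 10**5
        for x in (0, 3, 50, 200):
            ys = np.arange(0, 400)
            ours = np.exp(ac_log_pmf(x, ys, n1, n2))
            ref = nbinom.pmf(ys, x + 1, n1 / (n1 + n2))
            np.testing.assert_allclose(ours, ref, rtol=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ac_pmf(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            ac_pmf(0, 0, 0, 10)


class TestTest:
    def test_symmetric_point_caps_at_one(self):
        assert ac_test(7, 7, 10**6, 10**6) == 1.0

    def test_two_sided_matches_bruteforce_tail(self):
        # x=0, y=20, equal libraries: doubled inclusive upper tail
        direct = 2 * sum(ac_pmf(0, t, 10**6, 10**6) for t in range(20, 2000))
        assert ac_test(0, 20, 10**6, 10**6) == pytest.approx(direct, rel=1e-9)

    def test_one_sided_tails_are_inclusive(self):
        p_greater = ac_test(0, 20, 10**6, 10**6, alternative="greater")
        assert p_greater == pytest.approx(
            sum(ac_pmf(0, t, 10**6, 10**6) for t in range(20, 2000)), rel=1e-9
        )
        assert ac_test(5, 0, 10, 10, alternative="less") == pytest.approx(
            ac_pmf(5, 0, 10, 10), rel=1e-9
        )

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        x=st.integers(0, 100),
        y=st.integers(0, 100),
        n1=st.integers(1, 10**6),
        n2=st.integers(1, 10**6),
    )
    def test_exchange_symmetry(self, x, y, n1, n2):
        assert ac_test(x, y, n1, n2) == ac_test(y, x, n2, n1)

    def test_p_in_unit_interval(self):
        for x, y in [(0, 0), (0, 500), (500, 0), (250, 250)]:
            p = ac_test(x, y, 10**6, 2 * 10**6)
            assert 0 < p <= 1


class TestFoldChange:
    @pytest.mark.parametrize(
        "tum,ctr,expected",
        [(8, 2, 2.0), (5, 5, 0.0), (0, 7, -3.0), (7, 0, 3.0)],
    )
    def test_values(self, tum, ctr, expected):
        assert log2_fold_change(tum, ctr) == pytest.approx(expected)

    def test_both_zero_without_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(0, 0, pseudocount=0)


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_adjusted_at_least_raw(self):
        p = np.array([0.001, 0.5, 0.04, 0.9, 0.2])
        assert (bh_adjust(p) >= p).all()

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20), st.randoms())
    def test_permutation_invariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adjusted = bh_adjust(p)
        permuted = bh_adjust([p[i] for i in perm])
        np.testing.assert_allclose([adjusted[i] for i in perm], permuted)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDifferential:
    def test_equal_pooled_counts_not_significant(self, small_sim):
        results = call_differential(small_sim.long_counts)
        by_id = {r.feature_id: r for r in results}
        # non-implanted features overwhelmingly called ns
        null = [r for f, r in by_id.items() if f not in small_sim.truth.de_features]
        frac_ns = sum(1 for r in null if r.direction == "ns") / len(null)
        assert frac_ns > 0.95

    def test_recovers_implanted_directions(self, small_sim):
        truth = small_sim.truth.de_features
        results = call_differential(small_sim.long_counts) + call_differential(
            small_sim.small_counts
        )
        hits = 0
        for r in results:
            if r.feature_id in truth:
                want = "up" if truth[r.feature_id] > 0 else "down"
                hits += r.direction == want
        assert hits / len(truth) >= 0.9

    def test_threshold_monotonicity(self, small_sim):
        loose = call_differential(
            small_sim.long_counts, DEThresholds(min_abs_log2fc=0.5)
        )
        strict = call_differential(
            small_sim.long_counts, DEThresholds(min_abs_log2fc=1.0)
        )
        called_loose = {r.feature_id for r in loose if r.direction != "ns"}
        called_strict = {r.feature_id for r in strict if r.direction != "ns"}
        assert called_strict <= called_loose

    def test_pairwise_mode_runs_and_is_conservative(self, small_sim):
        pooled = call_differential(small_sim.small_counts)
        paired = call_differential(small_sim.small_counts, pooled=False)
        assert len(pooled) == len(paired)
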