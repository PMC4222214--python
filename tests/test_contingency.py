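"""Closed-form odds-ratio mathematics: worked example, identities, theorems."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairodds import (
    PairContingency,
    UndefinedOddsRatioError,
    apply_or_to_baseline,
    conditional_presence,
    directed_odds_ratio,
    positive_likelihood_ratio,
    symmetric_odds_ratio,
)

from conftest import small_tables


class TestWorkedExample:
    """The illustrative table: A at 50% presence, B at 20%, 15% together."""

    def test_directed_or_a_indicated_by_b(self, worked_table):
        assert directed_odds_ratio(worked_table, "A") == pytest.approx(3.0)

    def test_directed_or_b_indicated_by_a(self, worked_table):
        assert directed_odds_ratio(worked_table, "B") == pytest.approx(12.0 / 7.0)

    def test_symmetric_or(self, worked_table):
        assert symmetric_odds_ratio(worked_table) == pytest.approx(27.0 / 7.0)

    def test_conditional_presences(self, worked_table):
        # B's presence lifts A from 50% to 75%; A lifts B from 20% to 30%
        assert conditional_presence(worked_table, "A") == pytest.approx(0.75)
        assert conditional_presence(worked_table, "B") == pytest.approx(0.30)

    def test_likelihood_ratio_identity(self, worked_table):
        for target in ("A", "B"):
            assert positive_likelihood_ratio(worked_table, target) == pytest.approx(
                directed_odds_ratio(worked_table, target), rel=1e-12
            )

    def test_percent_and_count_inputs_agree(self, worked_table):
        counts = PairContingency(60, 140, 20, 180)  # same proportions, n=400
        for target in ("A", "B"):
            assert directed_odds_ratio(counts, target) == pytest.approx(
                directed_odds_ratio(worked_table, target), rel=1e-12
            )


class TestSpecialValues:
    def test_never_cooccurring_pair_is_zero_both_ways(self):
        t = PairContingency(0, 10, 10, 80)
        assert directed_odds_ratio(t, "A") == 0.0
        assert directed_odds_ratio(t, "B") == 0.0

    def test_perfect_cooccurrence_is_infinite(self):
        # A present whenever B is, but not ubiquitous
        t = PairContingency(10, 20, 0, 70)
        assert directed_odds_ratio(t, "A") == math.inf

    @pytest.mark.parametrize("cells", [(9, 21, 12, 28), (1, 1, 1, 1), (4, 2, 6, 3)])
    def test_independence_gives_one(self, cells):
        t = PairContingency(*cells)
        assert t.c * t.f == t.d * t.e  # c*f = d*e by construction
        assert directed_odds_ratio(t, "A") == pytest.approx(1.0, rel=1e-12)
        assert directed_odds_ratio(t, "B") == pytest.approx(1.0, rel=1e-12)
        assert symmetric_odds_ratio(t) == pytest.approx(1.0, rel=1e-12)
        assert positive_likelihood_ratio(t, "A") == pytest.approx(1.0, rel=1e-12)

    def test_symmetric_or_swap_invariance(self, worked_table):
        assert symmetric_odds_ratio(worked_table) == pytest.approx(
            symmetric_odds_ratio(worked_table.swapped()), rel=1e-12
        )

    def test_symmetric_indeterminate_signalled(self):
        with pytest.raises(UndefinedOddsRatioError):
            symmetric_odds_ratio(PairContingency(5, 0, 0, 5))

    def test_continuity_correction_makes_zero_or_positive(self):
        t = PairContingency(0, 10, 10, 80)
        corrected = directed_odds_ratio(t, "A", continuity_correction=True)
        assert 0.0 < corrected < 1.0


class TestErrors:
    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            PairContingency(-1, 2, 3, 4)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            PairContingency(0, 0, 0, 0)

    @pytest.mark.parametrize(
        "cells,target",
        [
            ((5, 5, 0, 0), "A"),  # target ubiquitous
            ((0, 0, 5, 5), "A"),  # target absent everywhere
            ((0, 5, 0, 5), "A"),  # predictor never present
        ],
    )
    def test_undefined_ratios_raise(self, cells, target):
        with pytest.raises(UndefinedOddsRatioError):
            directed_odds_ratio(PairContingency(*cells), target)

    def test_conditional_presence_needs_predictor(self):
        with pytest.raises(UndefinedOddsRatioError):
            conditional_presence(PairContingency(0, 5, 0, 5), "A")

    @pytest.mark.parametrize("baseline", [0.0, 1.0, -0.1, 1.5])
    def test_baseline_domain(self, baseline):
        with pytest.raises(ValueError):
            apply_or_to_baseline(3.0, baseline)


class TestOddsToPercentage:
    @pytest.mark.parametrize(
        "baseline,expected",
        [(0.10, 0.25), (0.25, 0.50), (0.50, 0.75), (0.75, 0.90)],
    )
    def test_or_three_ladder(self, baseline, expected):
        assert apply_or_to_baseline(3.0, baseline) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "baseline,expected",
        [(0.25, 0.10), (0.50, 0.25), (0.75, 0.50), (0.90, 0.75)],
    )
    def test_or_one_third_reverses(self, baseline, expected):
        assert apply_or_to_baseline(1.0 / 3.0, baseline) == pytest.approx(
            expected, rel=1e-12
        )

    @given(
        p=st.floats(min_value=0.01, max_value=0.99),
        odds_ratio=st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_roundtrip_identity(self, p, odds_ratio):
        up = apply_or_to_baseline(odds_ratio, p)
        assert apply_or_to_baseline(1.0 / odds_ratio, up) == pytest.approx(p, rel=1e-9)
        assert apply_or_to_baseline(1.0, p) == pytest.approx(p, rel=1e-12)


class TestStructuralTheorems:
    """Exhaustive checks over all small 2x2 tables (integer arithmetic)."""

    MAX_TOTAL = 30

    @staticmethod
    def _defined(c, d, e, f):
        # both directed ORs defined: neither species absent/ubiquitous
        return 0 < c + d < c + d + e + f and 0 < c + e < c + d + e + f

    def test_likelihood_ratio_form_is_the_directed_or(self):
        checked = 0
        for c, d, e, f in small_tables(self.MAX_TOTAL):
            if not self._defined(c, d, e, f):
                continue
            t = PairContingency(c, d, e, f)
            for target in ("A", "B"):
                a = directed_odds_ratio(t, target)
                b = positive_likelihood_ratio(t, target)
                if math.isinf(a) or a == 0.0:
                    assert a == b
                else:
                    assert abs(a - b) <= 1e-12 * a
            checked += 1
        assert checked > 10_000

    def test_sign_concordance(self):
        # A cannot indicate B while B contraindicates A: both directed ORs
        # sit on the same side of 1 (their sign is the sign of c*f - d*e).
        for c, d, e, f in small_tables(self.MAX_TOTAL):
            if not self._defined(c, d, e, f):
                continue
            # OR_A - 1 has the sign of c(e+f) - e(c+d); OR_B - 1 of c(d+f) - d(c+e)
            sa = c * (e + f) - e * (c + d)
            sb = c * (d + f) - d * (c + e)
            assert not (sa > 0 and sb < 0)
            assert not (sa < 0 and sb > 0)

    def test_equal_ors_iff_equal_prevalence_disjoint_or_independent(self):
        # The two directed ORs coincide exactly when the species are
        # equally common (d = e), never co-occur (c = 0, both ORs 0), or
        # are exactly independent (c*f = d*e, both ORs 1): algebraically
        # OR_A/OR_B = 1 iff (e - d)(d*e - c*f) = 0. The independence case
        # is a trivial extra equality (both values 1) on top of the
        # equal-prevalence-or-disjoint characterisation of equal
        # *non-unit* ratios.
        for c, d, e, f in small_tables(self.MAX_TOTAL):
            if not self._defined(c, d, e, f):
                continue
            # OR_A = c(e+f)/[e(c+d)], OR_B = c(d+f)/[d(c+e)]; cross-multiplied
            lhs = c * (e + f) * d * (c + e)
            rhs = c * (d + f) * e * (c + d)
            equal = lhs == rhs
            # handle infinities: d = 0 or e = 0 makes one side infinite
            if c > 0 and (d == 0) != (e == 0):
                equal = False
            elif c > 0 and d == 0 and e == 0:
                equal = True  # both infinite
            assert equal == (d == e or c == 0 or c * f == d * e), (c, d, e, f)
            if equal and not (d == e or c == 0):
                # the extra case is exactly the both-equal-one situation
                assert c * (e + f) == e * (c + d)

    def test_common_predictor_cannot_indicate_much_rarer_target(self):
        # predictor above 50% presence, target below half the predictor's:
        # the directed OR of the target given the predictor is at most 3.
        hits = 0
        for c, d, e, f in small_tables(self.MAX_TOTAL):
            if not self._defined(c, d, e, f):
                continue
            n = c + d + e + f
            pred, targ = c + d, c + e  # A predicts B
            if 2 * pred > n and 2 * targ < pred:
                # OR(B|A) = [c(d+f)] / [d(c+e)] <= 3, exact in integers
                assert c * (d + f) <= 3 * d * (c + e), (c, d, e, f)
                hits += 1
        assert hits > 1_000


def test_monotone_in_cooccurrence():
    """Adding co-occurrences (c) with the other cells held fixed strictly
    increases both directed odds ratios."""
    d, e, f = 7, 4, 9
    prev_a = prev_b = 0.0
    for c in range(1, 20):
        t = PairContingency(c, d, e, f)
        or_a = directed_odds_ratio(t, "A")
        or_b = directed_odds_ratio(t, "B")
        assert or_a > prev_a and or_b > prev_b
        prev_a, prev_b = or_a, or_b
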