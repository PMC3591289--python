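"""Interval overlap, scenario taxonomy, prevalence statistics."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hcoscan.continuation import StableInterval
from hcoscan.multistability import (BURSTING, SCENARIO_PATTERNS,
                                    classify_scenario, coexistence_ranges,
                                    multistable_at, prevalence,
                                    summarize_prevalence)
from hcoscan.scan import BurstingRange


def iv(label, lo, hi, v=None):
    if v is None:
        v = -55.0 if label.startswith("hyp") else -20.0
    return StableInterval(label=label, g_min=lo, g_max=hi, representative_v=v)


def br(lo, hi):
    return BurstingRange(g_min=lo, g_max=hi)


class TestCoexistenceRanges:
    def test_single_overlap(self):
        out = coexistence_ranges([iv("hyp1", 6.0, math.inf)], br(4.0, 8.0))
        assert len(out) == 1
        assert (out[0].g_min, out[0].g_max) == (6.0, 8.0)
        assert out[0].regimes == {BURSTING, "hyp1"}

    def test_two_disjoint_overlaps(self):
        out = coexistence_ranges([iv("dep1", 0.0, 5.0),
                                  iv("hyp1", 6.0, math.inf)], br(4.0, 8.0))
        assert [(r.g_min, r.g_max, set(r.regimes)) for r in out] == [
            (4.0, 5.0, {BURSTING, "dep1"}),
            (6.0, 8.0, {BURSTING, "hyp1"}),
        ]

    def test_tristable_decomposition(self):
        out = coexistence_ranges([iv("hyp1", 5.0, math.inf),
                                  iv("dep1", 0.0, 6.0)], br(4.0, 8.0))
        got = [(r.g_min, r.g_max, frozenset(r.regimes)) for r in out]
        assert (5.0, 6.0, frozenset({BURSTING, "hyp1", "dep1"})) in got
        assert (4.0, 5.0, frozenset({BURSTING, "dep1"})) in got
        assert (6.0, 8.0, frozenset({BURSTING, "hyp1"})) in got

    def test_stationary_stationary_overlap_included(self):
        out = coexistence_ranges([iv("dep1", 2.0, 6.0), iv("dep2", 5.0, 9.0)],
                                 None)
        assert len(out) == 1
        assert out[0].regimes == {"dep1", "dep2"}

    def test_point_overlap_dropped(self):
        out = coexistence_ranges([iv("hyp1", 8.0, math.inf)], br(4.0, 8.0))
        assert out == []

    def test_empty_input(self):
        assert coexistence_ranges([], None) == []


def ranges_for_pattern(pattern):
    """Lay a multiset of regime sets onto disjoint g sub-intervals."""
    from hcoscan.multistability import CoexistenceRange
    out = []
    for i, regime_set in enumerate(sorted(pattern.elements(),
                                          key=lambda s: sorted(s))):
        lo = 1.0 + 2.0 * i
        out.append(CoexistenceRange(lo, lo + 1.0, regime_set))
    return out


class TestScenarioTaxonomy:
    def test_ten_distinct_classes(self):
        got = {cls: classify_scenario(ranges_for_pattern(pat))
               for cls, pat in SCENARIO_PATTERNS.items()}
        assert got == {c: c for c in "ABCDEFGHIJ"}

    def test_no_coexistence_is_none(self):
        assert classify_scenario([]) == "none"

    def test_unknown_arrangement_is_unclassified(self):
        from hcoscan.multistability import CoexistenceRange
        weird = [CoexistenceRange(1.0, 2.0, frozenset({"hyp1", "hyp2"}))]
        assert classify_scenario(weird) == "unclassified"

    def test_duplicate_multiplicity_matters(self):
        # one hyp1+dep1 range plus tristability is not class J (needs two)
        from hcoscan.multistability import CoexistenceRange
        ranges = [CoexistenceRange(1.0, 2.0, frozenset({"hyp1", "dep1"})),
                  CoexistenceRange(3.0, 4.0,
                                   frozenset({BURSTING, "hyp1", "dep1"}))]
        assert classify_scenario(ranges) != "J"

    def test_burster_fixture_is_scenario_a(self, burster_intervals,
                                           scanned_range):
        ranges = coexistence_ranges(burster_intervals, scanned_range)
        assert classify_scenario(ranges) == "A"


class TestPrevalence:
    def test_quarter(self):
        ranges = coexistence_ranges([iv("hyp1", 8.0, math.inf)], br(2.0, 10.0))
        assert prevalence(br(2.0, 10.0), ranges) == pytest.approx(0.25)

    def test_full_coverage(self):
        ranges = coexistence_ranges([iv("hyp1", 0.0, math.inf)], br(2.0, 10.0))
        assert prevalence(br(2.0, 10.0), ranges) == pytest.approx(1.0)

    def test_no_bursting_coexistence(self):
        ranges = coexistence_ranges([iv("dep1", 20.0, 21.0),
                                     iv("dep2", 20.5, 22.0)], br(2.0, 10.0))
        assert prevalence(br(2.0, 10.0), ranges) == 0.0

    def test_stationary_only_excluded_from_numerator(self):
        ranges = coexistence_ranges(
            [iv("hyp1", 8.0, math.inf), iv("dep1", 3.0, 5.0),
             iv("dep2", 4.0, 6.0)], br(2.0, 10.0))
        # dep1^dep2 overlap [4,5] contains no bursting... but [4,5] is
        # inside the bursting range, making it tristable with bursting
        val = prevalence(br(2.0, 10.0), ranges)
        assert val == pytest.approx((10.0 - 8.0 + 3.0) / 8.0)

    def test_zero_width_range_rejected(self):
        with pytest.raises(ValueError):
            prevalence(br(5.0, 5.0), [])

    def test_burster_fixture_value(self, burster_intervals, scanned_range,
                                   burster_manifest):
        ranges = coexistence_ranges(burster_intervals, scanned_range)
        val = prevalence(scanned_range, ranges)
        expected = (scanned_range.g_max - burster_manifest.ah_g) / \
            scanned_range.width
        assert val == pytest.approx(expected, abs=1e-3)


class TestPrevalenceSummary:
    def test_nothing_excluded(self):
        s = summarize_prevalence([0.10, 0.20, 0.30])
        assert s.mean == pytest.approx(0.20)
        assert s.adjusted_mean == pytest.approx(0.20)
        assert s.n_excluded == 0

    def test_outlier_excluded(self):
        s = summarize_prevalence([0.10, 0.10, 1.00])
        assert s.mean == pytest.approx(0.40)
        assert s.adjusted_mean == pytest.approx(0.10)
        assert s.n_excluded == 1

    def test_single_value(self):
        s = summarize_prevalence([1.0])
        assert s.mean == s.adjusted_mean == 1.0
        assert s.n_excluded == 0
        assert s.sd == 0.0

    def test_sample_sd_convention(self):
        s = summarize_prevalence([0.1, 0.2, 0.3])
        assert s.sd == pytest.approx(np.std([0.1, 0.2, 0.3], ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_prevalence([])


class TestMultistableAt:
    def ranges(self):
        from hcoscan.multistability import CoexistenceRange
        return [CoexistenceRange(1.0, 2.0, frozenset({BURSTING, "hyp1"})),
                CoexistenceRange(2.0, 3.0, frozenset({"dep1", "dep2"}))]

    def test_inside(self):
        assert multistable_at(1.5, self.ranges()) == [
            frozenset({BURSTING, "hyp1"})]

    def test_outside(self):
        assert multistable_at(5.0, self.ranges()) == []

    def test_shared_endpoint_returns_both(self):
        got = multistable_at(2.0, self.ranges())
        assert len(got) == 2


class TestIntervalLogicProperty:
    @settings(max_examples=100, deadline=None)
    @given(data=st.data())
    def test_multistable_at_consistent_with_ranges(self, data):
        """multistable_at(g) is nonempty exactly where >= 2 of the input
        intervals overlap (brute-force check on rational endpoints)."""
        n = data.draw(st.integers(2, 4))
        intervals = []
        for k in range(n):
            lo = data.draw(st.integers(0, 20))
            w = data.draw(st.integers(1, 10))
            label = f"hyp{k + 1}" if k % 2 == 0 else f"dep{k}"
            intervals.append(iv(label, float(lo) / 2, float(lo + w) / 2))
        ranges = coexistence_ranges(intervals, None)
        for gq in [Fraction(i, 4) for i in range(0, 64)]:
            g = float(gq)
            brute_closed = sum(1 for i in intervals if i.g_min <= g <= i.g_max)
            brute_open = sum(1 for i in intervals if i.g_min < g < i.g_max)
            covered = any(r.g_min < g < r.g_max for r in ranges)
            if brute_open >= 2:
                # interior of a positive-width overlap must be captured
                assert any(r.g_min <= g <= r.g_max for r in ranges)
            if covered:
                # zero-width (touching-point) overlaps are never reported
                assert brute_closed >= 2
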