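"""Wald intervals, compliance filtering, and cohort summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.proportion import proportion_confint

from painweeks import (
    PainStatePolicy,
    ProportionEstimate,
    ci_nonoverlap,
    compliance_filter,
    missing_context_stat,
    summarize,
    wald_ci_from_proportion,
    wald_ci_percent,
)

from conftest import make_matrix


class TestWaldCi:
    @pytest.mark.parametrize(
        "num,den,expected",
        [
            (16, 80, (20.0, 11, 29)),
            (0, 80, (0.0, 0, 0)),
            (50, 100, (50.0, 40, 60)),  # 0.5 +/- 1.96*sqrt(0.25/100) = (40.2, 59.8)
            (80, 80, (100.0, 100, 100)),
        ],
    )
    def test_known_intervals(self, num, den, expected):
        est = wald_ci_percent(num, den)
        assert (est.percent, est.ci_low_pct, est.ci_high_pct) == expected

    def test_outward_rounding_widens(self):
        nearest = wald_ci_percent(52, 80, rounding="nearest")
        outward = wald_ci_percent(52, 80, rounding="outward")
        assert (nearest.ci_low_pct, nearest.ci_high_pct) == (55, 75)
        assert (outward.ci_low_pct, outward.ci_high_pct) == (54, 76)

    def test_zero_denominator_yields_undefined_marker(self):
        assert not wald_ci_percent(0, 0).defined

    @given(den=st.integers(1, 500), data=st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_statsmodels_normal_interval(self, den, data):
        """Pre-rounding bounds agree with an independent Wald implementation."""
        num = data.draw(st.integers(0, den))
        est = wald_ci_percent(num, den)
        lo, hi = proportion_confint(num, den, alpha=0.05, method="normal")
        assert est.ci_low_pct == round(max(0.0, 100 * lo))
        assert est.ci_high_pct == round(min(100.0, 100 * hi))

    @given(den=st.integers(1, 500), data=st.data())
    @settings(max_examples=200, deadline=None)
    def test_interval_invariants(self, den, data):
        num = data.draw(st.integers(0, den))
        est = wald_ci_percent(num, den)
        assert 0 <= est.ci_low_pct <= round(est.percent) <= est.ci_high_pct <= 100
        assert est.percent == pytest.approx(100 * num / den)

    def test_half_width_shrinks_with_denominator(self):
        widths = [
            est.ci_high_pct - est.ci_low_pct
            for est in (wald_ci_percent(n // 4, n) for n in (40, 160, 640))
        ]
        assert widths == sorted(widths, reverse=True)

    def test_proportion_entry_point_matches_count_entry_point(self):
        a = wald_ci_percent(16, 80)
        b = wald_ci_from_proportion(0.2, 80)
        assert (a.ci_low_pct, a.ci_high_pct) == (b.ci_low_pct, b.ci_high_pct)


class TestCiNonoverlap:
    def make(self, lo, hi):
        return ProportionEstimate(1, 10, (lo + hi) / 2, lo, hi)

    @pytest.mark.parametrize(
        "a,b,expected",
        [((11, 29), (13, 23), False), ((0, 10), (11, 29), True), ((11, 29), (11, 29), False)],
    )
    def test_disjointness(self, a, b, expected):
        assert ci_nonoverlap(self.make(*a), self.make(*b)) is expected

    def test_undefined_estimate_is_an_error(self):
        with pytest.raises(ValueError, match="undefined"):
            ci_nonoverlap(self.make(0, 10), ProportionEstimate.undefined())


class TestComplianceFilter:
    def cohort(self, n_responses_list, weeks=52):
        rows = {}
        for i, k in enumerate(n_responses_list):
            rows[f"P{i}"] = [1] * k + [None] * (weeks - k)
        return make_matrix(rows)

    def test_boundary_is_inclusive_at_half(self):
        matrix = self.cohort([26, 25])
        kept, excluded = compliance_filter(matrix, 0.5)
        assert kept.participant_ids == ["P0"]
        assert excluded == ["P1"]

    def test_empty_matrix_passes_through(self):
        kept, excluded = compliance_filter(make_matrix({}, study_weeks=52))
        assert len(kept) == 0 and excluded == []

    def test_counts_match_enrollment_minus_exclusions(self):
        # 100 entered, 20 below the 50% threshold
        matrix = self.cohort([52] * 80 + [20] * 20)
        kept, excluded = compliance_filter(matrix, 0.5)
        assert (len(kept), len(excluded)) == (80, 20)


class TestSummarize:
    def test_constant_pain_cohort(self):
        matrix = make_matrix({f"P{i}": [1 + (i % 7)] * 8 for i in range(10)})
        summary = summarize(matrix, PainStatePolicy("strict", 4))
        assert summary.max_run_table["0"].percent == 100.0
        assert summary.prev_any_non_episode.percent == 0.0
        assert summary.prev_non_episode_at_end.percent == 0.0

    def test_numerators_sum_to_n_analyzed(self, toy_matrix):
        summary = summarize(toy_matrix, PainStatePolicy("strict", 4))
        assert sum(e.numerator for e in summary.max_run_table.values()) == summary.n_analyzed
        assert sum(summary.missingness_table.values()) == summary.n_analyzed

    def test_toy_profiles_land_in_expected_bins(self, toy_matrix):
        summary = summarize(toy_matrix, PainStatePolicy("strict", 4))
        # A: run 4, B: run 5, C: run 0
        assert summary.max_run_table["4"].numerator == 1
        assert summary.max_run_table["5"].numerator == 1
        assert summary.max_run_table["0"].numerator == 1
        assert summary.prev_any_non_episode.numerator == 2
        assert summary.prev_non_episode_at_end.numerator == 1

    def test_lenient_never_reports_fewer_non_episodes(self, toy_matrix):
        strict = summarize(toy_matrix, PainStatePolicy("strict", 4))
        lenient = summarize(toy_matrix, PainStatePolicy("lenient", 4))
        assert lenient.prev_any_non_episode.numerator >= strict.prev_any_non_episode.numerator

    def test_all_excluded_yields_undefined_estimates(self):
        matrix = make_matrix({"P1": [1] + [None] * 51})
        summary = summarize(matrix, PainStatePolicy("strict", 4))
        assert summary.n_analyzed == 0
        assert not summary.prev_any_non_episode.defined
        assert all(not e.defined for e in summary.max_run_table.values())


class TestMissingContextStat:
    def test_pain_flanked_missing_cell(self):
        assert missing_context_stat(make_matrix({"P1": [3, None, 5]})) == 1.0

    def test_zero_neighbour_disqualifies(self):
        assert missing_context_stat(make_matrix({"P1": [0, None, 5]})) == 0.0

    def test_no_missing_cells_is_undefined(self):
        assert missing_context_stat(make_matrix({"P1": [0, 1, 2]})) is None

    def test_nearest_responded_neighbour_skips_missing(self):
        # neighbours of week 3 are week 1 (pain) and week 5 (pain)
        assert missing_context_stat(make_matrix({"P1": [2, None, None, None, 4]})) == 1.0
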