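"""Disproportionality metrics, exact tests, and significance rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faerspv.errors import UndefinedEstimateError
from faerspv.filters import DrugQuery, TermSet
from faerspv.stats import (
    ContingencyTable,
    SignalResult,
    build_table,
    chi_square,
    classify_significance,
    compute_signal,
    fisher_exact,
    ic_from_observed_expected,
    ic_with_ci,
    prr_with_ci,
    ror_with_ci,
)

cells = st.integers(min_value=0, max_value=500)


def fisher_enumeration(a, b, c, d):
    """Independent oracle: exact-integer hypergeometric enumeration.

    Two-sided p sums the probabilities of all tables with the observed
    margins that are no more probable than the observed table (standard
    relative tie tolerance of 1e-7, as in R and other implementations).
    """
    r1, r2, c1 = a + b, c + d, a + c
    denom = math.comb(r1 + r2, c1)
    pmf = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k) / denom
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    p_obs = pmf[a]
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-7)))


def chi2_arithmetic(a, b, c, d, yates):
    """Independent oracle: sum over the four cells of (|O-E|-h)^2/E."""
    n = a + b + c + d
    obs = [[a, b], [c, d]]
    rows, cols = [a + b, c + d], [a + c, b + d]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            e = rows[i] * cols[j] / n
            h = min(0.5, abs(obs[i][j] - e)) if yates else 0.0
            stat += (abs(obs[i][j] - e) - h) ** 2 / e
    return stat


class TestContingencyTable:
    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)

    def test_build_table_partitions_ten_reports(self, ten_report_universe):
        t = build_table(ten_report_universe, DrugQuery("EVEROLIMUS"),
                        TermSet("SAMT", ("stomatitis", "aphthous ulcer",
                                         "mouth ulceration")))
        assert t.cells() == (2, 2, 1, 5)
        assert t.n == ten_report_universe.total_count

    def test_term_matching_nothing(self, ten_report_universe):
        t = build_table(ten_report_universe, DrugQuery("EVEROLIMUS"),
                        TermSet("none", ("pancytopenia",)))
        assert t.a == 0 and t.c == 0 and t.b + t.d == 10

    def test_all_reports_have_drug_is_degenerate(self, ten_report_universe):
        keep = [r for r in ten_report_universe if r.drugs[0].raw_name == "EVEROLIMUS"]
        from faerspv.model import ReportUniverse
        t = build_table(ReportUniverse(reports=keep), DrugQuery("EVEROLIMUS"),
                        TermSet("s", ("stomatitis",)))
        assert t.c == 0 and t.d == 0 and t.degenerate

    def test_absent_drug_is_degenerate(self, ten_report_universe):
        t = build_table(ten_report_universe, DrugQuery("CAPIVASERTIB"),
                        TermSet("s", ("stomatitis",)))
        assert t.a == 0 and t.b == 0 and t.degenerate


class TestRorPrr:
    def test_ror_cross_product(self):
        est = ror_with_ci(ContingencyTable(10, 90, 100, 9900))
        assert est.point == pytest.approx(11.0)
        assert est.low < est.point < est.high

    def test_prr_proportion_ratio(self):
        est = prr_with_ci(ContingencyTable(10, 90, 100, 9900))
        assert est.point == pytest.approx(10.0)

    @pytest.mark.parametrize("k", [1, 5, 50])
    def test_symmetric_table_is_null(self, k):
        t = ContingencyTable(k, k, k, k)
        assert ror_with_ci(t).point == pytest.approx(1.0)
        assert prr_with_ci(t).point == pytest.approx(1.0)
        assert ror_with_ci(t).low < 1.0 < ror_with_ci(t).high

    def test_haldane_correction_on_zero_cell(self):
        # cells become (1.5, 0.5, 1.5, 1.5)
        est = ror_with_ci(ContingencyTable(1, 0, 1, 1), zero_policy="haldane")
        assert est.point == pytest.approx(3.0)

    def test_haldane_untouched_without_zeros(self):
        assert ror_with_ci(ContingencyTable(2, 3, 5, 7)).point == pytest.approx(
            (2 * 7) / (3 * 5))

    def test_strict_policy_names_the_zero_cell(self):
        with pytest.raises(UndefinedEstimateError, match="cell b"):
            ror_with_ci(ContingencyTable(1, 0, 1, 1), zero_policy="strict")

    def test_prr_with_zero_a_is_below_one_and_finite(self):
        est = prr_with_ci(ContingencyTable(0, 10, 50, 1000))
        assert 0 < est.point < 1 and math.isfinite(est.high)

    @settings(max_examples=100, deadline=None)
    @given(cells, cells, cells, cells)
    def test_flip_inverts_ror(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        flipped = ContingencyTable(c, d, a, b)
        assert ror_with_ci(t).point * ror_with_ci(flipped).point == pytest.approx(1.0)

    def test_ror_at_least_prr_in_rare_event_regime(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n1, n0 = rng.integers(200, 5000, 2)
            a = rng.binomial(n1, 0.008)
            c = rng.binomial(n0, 0.005)
            t = ContingencyTable(a, n1 - a, c, n0 - c)
            if 0 in t.cells():
                continue
            ror, prr = ror_with_ci(t).point, prr_with_ci(t).point
            if a / (a + n1 - a) >= c / n0:  # rare-event regime with excess reporting
                assert ror >= prr - 1e-12
            assert ror == pytest.approx(prr, rel=0.05)  # both -> equal as rates -> 0


class TestInformationComponent:
    def test_observed_equals_expected_is_zero(self):
        for a in (1, 10, 1000):
            assert ic_from_observed_expected(a, a).point == 0.0

    def test_hand_computed_value(self):
        est = ic_from_observed_expected(3, 1)
        assert est.point == pytest.approx(math.log2(3.5 / 1.5), abs=1e-12)
        assert est.point == pytest.approx(1.2224, abs=1e-4)

    def test_shrinkage_bounds_zero_count(self):
        est = ic_from_observed_expected(0, 10)
        assert est.point == pytest.approx(math.log2(0.5 / 10.5))
        assert abs(est.point) < abs(math.log2(1e-9 / 10))  # unshrunk diverges

    def test_monotone_in_observed_at_fixed_expected(self):
        vals = [ic_from_observed_expected(a, 10).point for a in range(0, 60)]
        assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_table_form_uses_margin_expectation(self):
        t = ContingencyTable(10, 90, 100, 9900)
        e = (10 + 90) * (10 + 100) / t.n
        assert ic_with_ci(t).point == pytest.approx(
            ic_from_observed_expected(10, e).point)

    def test_empty_table_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            ic_with_ci(ContingencyTable(0, 0, 0, 0))

    def test_bounds_bracket_point(self):
        est = ic_with_ci(ContingencyTable(25, 500, 80, 9000))
        assert est.low < est.point < est.high


class TestFisher:
    @pytest.mark.parametrize("k", [1, 4, 9])
    def test_symmetric_table_p_one(self, k):
        assert fisher_exact(ContingencyTable(k, k, k, k)) == pytest.approx(1.0)

    def test_extreme_table_by_full_enumeration(self):
        # margins (5,5)/(5,5): six tables; only a=0 and a=5 are as improbable
        p = fisher_exact(ContingencyTable(5, 0, 0, 5))
        assert p == pytest.approx(2 / math.comb(10, 5), abs=1e-15)
        assert p == pytest.approx(fisher_enumeration(5, 0, 0, 5), abs=1e-15)

    @settings(max_examples=150, deadline=None)
    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        assert fisher_exact(t) == pytest.approx(
            fisher_enumeration(a, b, c, d), abs=1e-12)


class TestChiSquare:
    def test_symmetric_table_zero_statistic(self):
        stat, p = chi_square(ContingencyTable(7, 7, 7, 7), yates=False)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_hand_arithmetic(self):
        stat, _ = chi_square(ContingencyTable(10, 90, 100, 9900), yates=False)
        assert stat == pytest.approx(chi2_arithmetic(10, 90, 100, 9900, False), rel=1e-12)

    @pytest.mark.parametrize("cells_", [(10, 90, 100, 9900), (3, 7, 9, 11), (50, 5, 40, 80)])
    def test_yates_never_exceeds_uncorrected(self, cells_):
        t = ContingencyTable(*cells_)
        assert chi_square(t, yates=True).statistic <= chi_square(t, yates=False).statistic

    def test_zero_expected_cell_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            chi_square(ContingencyTable(0, 0, 5, 5))


class TestSignificance:
    def _result(self, **kw):
        base = dict(table=ContingencyTable(1, 1, 1, 1),
                    ror=1, ror_low=1, ror_high=1, prr=1, prr_low=1, prr_high=1,
                    ic=0, ic_low=0, ic_high=0, fisher_p=1, chi2=0, chi2_p=1,
                    chi2_yates=0, chi2_yates_p=1)
        base.update(kw)
        return SignalResult(**base)

    def test_interval_excluding_one_is_significant(self):
        r = classify_significance(self._result(ror=30.72, ror_low=29.61, ror_high=31.88))
        assert r.significant_ror

    def test_interval_covering_one_is_not(self):
        r = classify_significance(self._result(ror_low=0.8, ror_high=1.3))
        assert not r.significant_ror

    def test_ic_lower_bound_above_zero(self):
        r = classify_significance(self._result(ic_low=0.01, ic_high=2))
        assert r.significant_ic
        assert not classify_significance(self._result(ic_low=-0.01)).significant_ic

    def test_compute_signal_invariants(self):
        s = compute_signal(ContingencyTable(10, 90, 100, 9900))
        assert s.ror_low <= s.ror <= s.ror_high
        assert s.prr_low <= s.prr <= s.prr_high
        assert s.ic_low <= s.ic <= s.ic_high
        for p in (s.fisher_p, s.chi2_p, s.chi2_yates_p):
            assert 0.0 <= p <= 1.0
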