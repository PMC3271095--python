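"""Wald statistics, Barnard's unconditional exact test, odds ratios, HWE."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import barnard_exact as scipy_barnard
from scipy.stats import binom

from mirsnpkit import (
    CohortGenotypes,
    ContingencyTable2x2,
    barnard_two_sided,
    dominant_collapse,
    hwe_chi2,
    odds_ratio,
    wald_statistic,
)

tables = st.tuples(
    st.integers(1, 12), st.integers(1, 12), st.integers(0, 12), st.integers(0, 12)
).map(lambda t: ContingencyTable2x2("a", "b", min(t[2], t[0]), t[0], min(t[3], t[1]), t[1]))


def brute_force_barnard(t: ContingencyTable2x2, n_grid: int = 100_000) -> float:
    """Independent oracle: direct binomial-product sum over a dense grid.

    Separate code path from the implementation: scipy pmf per outcome table,
    no log-space collapse by total successes.
    """
    n1, n2 = t.n1, t.n2
    y1 = np.arange(n1 + 1)
    y2 = np.arange(n2 + 1)
    p1 = y1 / n1
    p2 = y2 / n2
    pooled = (y1[:, None] + y2[None, :]) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (p1[:, None] - p2[None, :]) / np.sqrt(var)
    w = np.where(var > 0, w, 0.0)
    extreme = np.abs(w) >= abs(w[t.x1, t.x2]) - 1e-12
    grid = np.linspace(1e-8, 1 - 1e-8, n_grid)
    pmf1 = binom.pmf(y1[:, None], n1, grid[None, :])
    pmf2 = binom.pmf(y2[:, None], n2, grid[None, :])
    tail = np.einsum("ig,jg,ij->g", pmf1, pmf2, extreme.astype(float))
    return float(tail.max())


class TestDominantCollapse:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((30, 11, 3), (14, 44)),   # mild TBMN
            ((21, 12, 0), (12, 33)),   # severe CFHR5
            ((5, 0, 0), (0, 5)),
        ],
    )
    def test_carriers_and_total(self, counts, expected):
        c = CohortGenotypes("c", *counts)
        assert dominant_collapse(c) == expected

    def test_rejects_negative_or_empty(self):
        with pytest.raises(ValueError):
            CohortGenotypes("c", -1, 2, 3)
        with pytest.raises(ValueError):
            CohortGenotypes("c", 0, 0, 0)


class TestWaldStatistic:
    @pytest.mark.parametrize(
        "x1,n1,x2,n2,expected",
        [
            (6, 45, 12, 33, -2.385),   # mild vs severe CFHR5 carriers
            (14, 44, 6, 45, 2.089),    # mild TBMN vs mild CFHR5
            (3, 27, 3, 6, -2.234),     # mild vs severe CFHR5 women
        ],
    )
    def test_reported_values_to_three_decimals(self, x1, n1, x2, n2, expected):
        t = ContingencyTable2x2("g1", "g2", x1, n1, x2, n2)
        assert wald_statistic(t) == pytest.approx(expected, abs=5e-4)

    def test_equal_proportions_give_zero(self):
        assert wald_statistic(ContingencyTable2x2("a", "b", 3, 6, 4, 8)) == 0.0

    def test_degenerate_pooled_proportion_defined_as_zero(self):
        assert wald_statistic(ContingencyTable2x2("a", "b", 0, 5, 0, 7)) == 0.0
        assert wald_statistic(ContingencyTable2x2("a", "b", 5, 5, 7, 7)) == 0.0

    @given(tables)
    def test_antisymmetric_under_group_swap(self, t):
        assert wald_statistic(t.swapped()) == pytest.approx(-wald_statistic(t), abs=1e-12)


class TestBarnard:
    def test_balanced_table_has_p_one(self):
        res = barnard_two_sided(ContingencyTable2x2("a", "b", 1, 2, 1, 2))
        assert res.p_two_sided == pytest.approx(1.0, abs=1e-9)

    def test_two_of_two_versus_zero_of_two(self):
        # E = {(2,0), (0,2)}; tail(pi) = 2 pi^2 (1-pi)^2, max 0.125 at 1/2
        res = barnard_two_sided(ContingencyTable2x2("a", "b", 2, 2, 0, 2))
        assert res.p_two_sided == pytest.approx(0.125, abs=1e-6)
        assert res.pi_star == pytest.approx(0.5, abs=1e-3)

    def test_degenerate_table_gives_p_one(self):
        res = barnard_two_sided(ContingencyTable2x2("a", "b", 0, 5, 0, 7))
        assert res.W_obs == 0.0 and res.p_two_sided == pytest.approx(1.0, abs=1e-9)

    def test_invalid_grid_step_rejected(self):
        with pytest.raises(ValueError):
            barnard_two_sided(ContingencyTable2x2("a", "b", 1, 2, 1, 2), grid_step=0.01)

    def test_p_value_dominates_any_single_nuisance_value(self):
        from mirsnpkit.association import _extreme_region, _tail_at, _tail_coefficients

        t = ContingencyTable2x2("a", "b", 6, 45, 12, 33)
        res = barnard_two_sided(t)
        coeffs = _tail_coefficients(t, _extreme_region(t, "two-sided"))
        pis = np.linspace(0.01, 0.99, 57)
        tails = _tail_at(coeffs, pis, t.n1 + t.n2)
        assert np.all(res.p_two_sided >= tails - 1e-12)

    @given(tables)
    def test_symmetric_under_group_swap(self, t):
        a = barnard_two_sided(t, grid_step=1e-3)
        b = barnard_two_sided(t.swapped(), grid_step=1e-3)
        assert a.p_two_sided == pytest.approx(b.p_two_sided, abs=1e-9)
        assert a.W_obs == pytest.approx(-b.W_obs, abs=1e-12)

    def test_monotone_in_observed_wald_for_fixed_margins(self):
        n1, n2 = 7, 5
        results = [
            barnard_two_sided(ContingencyTable2x2("a", "b", x1, n1, x2, n2), grid_step=1e-3)
            for x1 in range(n1 + 1)
            for x2 in range(n2 + 1)
        ]
        results.sort(key=lambda r: abs(r.W_obs))
        for a, b in zip(results, results[1:]):
            assert a.p_two_sided >= b.p_two_sided - 1e-9

    def test_one_sided_agrees_with_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n1, n2 = (int(v) for v in rng.integers(2, 15, 2))
            x1, x2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            t = ContingencyTable2x2("a", "b", x1, n1, x2, n2)
            for alt in ("less", "greater"):
                mine = barnard_two_sided(t, alternative=alt).p_two_sided
                ref = scipy_barnard(
                    [[x1, x2], [n1 - x1, n2 - x2]], alternative=alt, pooled=True
                ).pvalue
                assert mine == pytest.approx(ref, abs=1e-5)

    def test_two_sided_agrees_with_scipy_on_study_tables(self):
        # scipy's two-sided region is also |W| >= |W_obs|; on the study
        # tables (no |W| float ties) the two agree tightly
        for x1, n1, x2, n2 in [(6, 45, 12, 33), (14, 44, 14, 59), (3, 27, 3, 6)]:
            mine = barnard_two_sided(ContingencyTable2x2("a", "b", x1, n1, x2, n2))
            ref = scipy_barnard([[x1, x2], [n1 - x1, n2 - x2]], pooled=True)
            assert mine.p_two_sided == pytest.approx(ref.pvalue, abs=1e-5)
            assert mine.W_obs == pytest.approx(ref.statistic, abs=1e-9)

    def test_matches_bruteforce_oracle_on_moderate_tables(self):
        rng = np.random.default_rng(13)
        for _ in range(6):
            n1, n2 = (int(v) for v in rng.integers(3, 10, 2))
            x1, x2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
            t = ContingencyTable2x2("a", "b", x1, n1, x2, n2)
            assert barnard_two_sided(t).p_two_sided == pytest.approx(
                brute_force_barnard(t), abs=1e-6
            )


class TestOddsRatio:
    def test_cfhr5_carrier_odds_ratio(self):
        t = ContingencyTable2x2("mild", "severe", 6, 45, 12, 33)
        assert odds_ratio(t) == pytest.approx(3.7, abs=0.05)

    def test_women_carrier_odds_ratio_is_eight(self):
        t = ContingencyTable2x2("mild_w", "severe_w", 3, 27, 3, 6)
        assert odds_ratio(t) == pytest.approx(8.0, abs=1e-12)

    def test_equal_odds_give_one(self):
        assert odds_ratio(ContingencyTable2x2("a", "b", 5, 10, 5, 10)) == pytest.approx(1.0)

    def test_zero_cell_rejected_naming_the_cell(self):
        t = ContingencyTable2x2("a", "b", 0, 10, 5, 10)
        with pytest.raises(ZeroDivisionError, match="group1 carriers"):
            odds_ratio(t)

    def test_haldane_correction_handles_zero_cells(self):
        t = ContingencyTable2x2("a", "b", 0, 10, 5, 10)
        expected = (5.5 / 5.5) / (0.5 / 10.5)
        assert odds_ratio(t, haldane=True) == pytest.approx(expected)

    def test_flip_inverts_orientation(self):
        t = ContingencyTable2x2("mild", "severe", 6, 45, 12, 33)
        assert odds_ratio(t, flip=True) == pytest.approx(1 / odds_ratio(t))


class TestHWE:
    def test_exact_proportions_give_zero_chi2(self):
        res = hwe_chi2(CohortGenotypes("c", 25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_no_heterozygotes_extreme_departure(self):
        # q = 0.5, expected 25/50/25 -> chi2 = 25 + 50 + 25 = 100
        res = hwe_chi2(CohortGenotypes("c", 50, 0, 50))
        assert res.chi2 == pytest.approx(100.0)
        assert res.p < 1e-20

    def test_expected_counts_sum_to_total(self):
        res = hwe_chi2(CohortGenotypes("c", 30, 11, 3))
        assert sum(res.expected) == pytest.approx(44.0)

    def test_monomorphic_cohort_warns_and_degenerates(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            res = hwe_chi2(CohortGenotypes("c", 40, 0, 0))
        assert res.chi2 == 0.0 and res.p == 1.0
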