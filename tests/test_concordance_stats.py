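"""Contingency collapse, binomial CIs, chi-squared, r and d contracts."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps_stats

from gaitclass import reference_data as ref
from gaitclass.concordance_stats import (
    PAIRS,
    ContingencyTable,
    TwoByTwo,
    binomial_ci,
    build_contingency,
    chi_squared_homogeneity,
    cohens_d,
    collapse_pair,
    compare_with_published,
    concordance_table,
    footwear_correlations,
    interpret_d,
    interpret_r,
    pair_concordance,
    pearson_with_ci,
    round_half_away,
)


@pytest.fixture
def table_9kmh() -> ContingencyTable:
    return ContingencyTable(counts=ref.CONTINGENCY_COUNTS[9.0], speed=9.0)


class TestContingency:
    def test_reference_marginals(self, table_9kmh):
        np.testing.assert_array_equal(table_9kmh.counts.sum(axis=1), [27, 34, 39])
        np.testing.assert_array_equal(table_9kmh.counts.sum(axis=0), [33, 33, 34])

    def test_build_from_labels_roundtrips_counts(self, table_9kmh):
        rows = []
        rid = 0
        for i, fsp in enumerate(("RFS", "MFS", "FFS")):
            for j, dfg in enumerate(("DF_high", "DF_mid", "DF_low")):
                for _ in range(table_9kmh.counts[i, j]):
                    rid += 1
                    rows.append({"runner_id": rid, "fsp": fsp, "df_group": dfg})
        rebuilt = build_contingency(pd.DataFrame(rows), speed=9.0)
        np.testing.assert_array_equal(rebuilt.counts, table_9kmh.counts)

    def test_missing_label_names_runner(self):
        labels = pd.DataFrame({"fsp": ["RFS", None], "df_group": ["DF_high", "DF_mid"]},
                              index=[1, 2])
        with pytest.raises(ValueError, match="2"):
            build_contingency(labels, speed=9.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ContingencyTable(counts=np.zeros((3, 3), dtype=int), speed=9.0)


class TestCollapsePair:
    def test_reference_rfs_pair(self, table_9kmh):
        cell = collapse_pair(table_9kmh, ("RFS", "DF_high"))
        assert (cell.tp, cell.fn, cell.fp, cell.tn) == (15, 12, 18, 55)

    def test_diagonal_table_has_no_confusions(self):
        table = ContingencyTable(counts=np.diag([10, 20, 30]), speed=9.0)
        for pair in PAIRS:
            cell = collapse_pair(table, pair)
            assert cell.fn == cell.fp == 0

    def test_uniform_table_symmetry(self):
        table = ContingencyTable(counts=np.full((3, 3), 10), speed=9.0)
        cell = collapse_pair(table, ("MFS", "DF_mid"))
        assert (cell.tp, cell.fn, cell.fp, cell.tn) == (10, 20, 20, 40)

    def test_tp_over_pairs_sums_to_trace(self, table_9kmh):
        total = sum(collapse_pair(table_9kmh, p).tp for p in PAIRS)
        assert total == np.trace(table_9kmh.counts)


class TestPairConcordance:
    def test_reference_rfs_pair_percentages(self):
        pc = pair_concordance(TwoByTwo(tp=15, fn=12, fp=18, tn=55), pair=("RFS", "DF_high"))
        row = pc.to_percent_row()
        assert row["sensitivity_pct"] == 56
        assert row["specificity_pct"] == 75
        assert row["agreement_pct"] == 70

    def test_reference_mfs_pair_percentages(self):
        pc = pair_concordance(TwoByTwo(tp=12, fn=22, fp=21, tn=45), pair=("MFS", "DF_mid"))
        row = pc.to_percent_row()
        assert row["sensitivity_pct"] == 35
        assert row["specificity_pct"] == 68
        assert row["agreement_pct"] == 57  # count-derived, differs from published 76

    def test_perfect_table_all_statistics_100(self):
        pc = pair_concordance(TwoByTwo(tp=50, fn=0, fp=0, tn=0))
        assert pc.agreement == pc.sensitivity == 1.0
        assert np.isnan(pc.specificity)  # no negatives at all
        assert pc.undefined == ("specificity",)
        pc2 = pair_concordance(TwoByTwo(tp=30, fn=0, fp=0, tn=20))
        assert pc2.agreement == pc2.sensitivity == pc2.specificity == 1.0

    @settings(deadline=None, max_examples=100)
    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        fp=st.integers(0, 50), tn=st.integers(1, 50),
    )
    def test_agreement_identity(self, tp, fn, fp, tn):
        """agreement*N == sensitivity*(tp+fn) + specificity*(tn+fp), always."""
        pc = pair_concordance(TwoByTwo(tp=tp, fn=fn, fp=fp, tn=tn))
        lhs = pc.agreement * pc.counts.n
        rhs = 0.0
        rhs += pc.sensitivity * (tp + fn) if tp + fn else 0.0
        rhs += pc.specificity * (tn + fp) if tn + fp else 0.0
        assert lhs == pytest.approx(rhs, abs=1e-9)


class TestBinomialCi:
    def test_wald_reproduces_published_interval(self):
        low, high = binomial_ci(70, 100, method="wald")
        assert (round_half_away(100 * low), round_half_away(100 * high)) == (61, 79)

    def test_wald_reproduces_published_sensitivity_interval(self):
        low, high = binomial_ci(15, 27, method="wald")
        assert (round_half_away(100 * low), round_half_away(100 * high)) == (37, 74)

    @pytest.mark.parametrize("method", ["wald", "clopper-pearson"])
    def test_zero_successes_lower_bound_zero(self, method):
        low, _ = binomial_ci(0, 20, method=method)
        assert low == 0.0

    def test_clopper_pearson_matches_tail_inversion(self):
        """Beta-quantile form vs direct binomial-tail bisection."""
        def brute(x, n, alpha=0.05):
            def solve(f, lo, hi):
                for _ in range(60):
                    mid = (lo + hi) / 2
                    lo, hi = (mid, hi) if f(mid) else (lo, mid)
                return (lo + hi) / 2
            low = 0.0 if x == 0 else solve(
                lambda p: sps_stats.binom.sf(x - 1, n, p) < alpha / 2, 0.0, 1.0)
            high = 1.0 if x == n else solve(
                lambda p: sps_stats.binom.cdf(x, n, p) >= alpha / 2, 0.0, 1.0)
            return low, high

        for x, n in [(15, 27), (70, 100), (1, 10), (26, 27)]:
            expected = brute(x, n)
            got = binomial_ci(x, n, method="clopper-pearson")
            assert got == pytest.approx(expected, abs=1e-6)

    def test_clopper_pearson_contains_point_estimate(self):
        for x, n in [(15, 27), (70, 100), (5, 6)]:
            low, high = binomial_ci(x, n, method="clopper-pearson")
            assert low <= x / n <= high

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 0)
        with pytest.raises(ValueError):
            binomial_ci(5, 10, level=1.5)
        with pytest.raises(ValueError):
            binomial_ci(5, 10, method="bayes")


class TestChiSquared:
    def test_reference_fsp_by_speed_table(self):
        counts = np.array([[27, 31, 38], [34, 33, 23], [39, 36, 39]])
        stat, dof, p = chi_squared_homogeneity(counts)
        assert stat == pytest.approx(4.6, abs=0.05)
        assert dof == 4
        assert p == pytest.approx(0.34, abs=0.01)

    def test_identical_distributions_give_zero(self):
        stat, _, p = chi_squared_homogeneity(np.array([[10, 20], [5, 10], [15, 30]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        stat, dof, p = chi_squared_homogeneity(np.array([[10, 0], [0, 10]]))
        assert stat == pytest.approx(20.0)
        assert dof == 1
        assert p < 0.001

    def test_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            counts = rng.integers(1, 40, size=(3, 3)).astype(float)
            expected_counts = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
            direct = ((counts - expected_counts) ** 2 / expected_counts).sum()
            stat, _, _ = chi_squared_homogeneity(counts)
            assert stat == pytest.approx(direct, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared_homogeneity(np.array([[0, 0], [1, 2]]))


class TestPearsonAndEffectSize:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_with_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.interpretation == "very high"

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_with_ci(np.ones(10), np.arange(10.0))

    def test_fisher_ci_width_matches_closed_form(self):
        rng = np.random.default_rng(8)
        n, rho = 2000, 0.5
        x = rng.standard_normal(n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
        res = pearson_with_ci(x, y)
        z = np.arctanh(res.r)
        half = 1.959963984540054 / np.sqrt(n - 3)
        assert res.ci_low == pytest.approx(np.tanh(z - half), abs=1e-6)
        assert res.ci_high == pytest.approx(np.tanh(z + half), abs=1e-6)

    @pytest.mark.parametrize(
        "r,band",
        [(0.1, "negligible"), (0.39, "low"), (0.52, "moderate"),
         (-0.75, "high"), (0.95, "very high")],
    )
    def test_r_interpretation_bands(self, r, band):
        assert interpret_r(r) == band

    def test_cohens_d_identical_groups_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).d == 0.0

    def test_cohens_d_unit_difference_unit_sd(self):
        es = cohens_d([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])
        assert es.d == pytest.approx(1.0)
        assert es.interpretation == "large"

    def test_cohens_d_recovers_simulated_effect(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0.8, 1.0, 1000)
        b = rng.normal(0.0, 1.0, 1000)
        assert abs(cohens_d(a, b).d - 0.8) < 0.1

    def test_cohens_d_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [2.0, 2.0])

    @pytest.mark.parametrize("d,band", [(0.05, "very small"), (0.25, "small"),
                                        (-0.5, "moderate"), (0.9, "large")])
    def test_d_interpretation_bands(self, d, band):
        assert interpret_d(d) == band


class TestFootwearCorrelations:
    def _metrics(self, n=50):
        rng = np.random.default_rng(6)
        return pd.DataFrame({
            "speed_kmh": 9.0,
            "runner_id": np.arange(n),
            "df": rng.normal(0.37, 0.02, n),
            "fsa_deg": rng.normal(3, 7, n),
            "shoe_mass_g": rng.normal(257, 49, n),
            "shoe_drop_mm": rng.normal(7, 3, n),
        })

    def test_independent_shoes_give_negligible_r(self):
        out = footwear_correlations(self._metrics(200))
        assert (out["r"].abs() < 0.3).all()

    def test_duplicated_variable_gives_unit_r(self):
        m = self._metrics()
        m["shoe_mass_g"] = m["df"]
        out = footwear_correlations(m)
        row = out[(out.x == "shoe_mass_g") & (out.y == "df")].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_constant_variable_flagged_undefined(self):
        m = self._metrics()
        m["shoe_drop_mm"] = 7.0
        out = footwear_correlations(m)
        rows = out[out.x == "shoe_drop_mm"]
        assert (rows["interpretation"] == "undefined").all()
        assert rows["r"].isna().all()


class TestPublishedComparison:
    def test_mfs_agreement_discrepancy_is_flagged(self):
        tables = {s: ContingencyTable(counts=c, speed=s)
                  for s, c in ref.CONTINGENCY_COUNTS.items()}
        computed = concordance_table(tables)
        comparison = compare_with_published(computed, ref.PUBLISHED_CONCORDANCE)
        mism = comparison[~comparison["match"]]
        # exactly the three midfoot agreement entries disagree
        assert len(mism) == 3
        assert set(mism["pair"]) == {"MFS-DF_mid"}
        assert set(mism["statistic"]) == {"agreement"}
        assert list(mism["count_derived_pct"]) == [57, 62, 66]
        assert list(mism["published_pct"]) == [76, 81, 85]
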