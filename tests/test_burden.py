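"""Carrier tables, exact burden tests, heteroplasmy summaries, Poisson-age fit."""

import math

import numpy as np
import pytest
import statsmodels.api as sm

from mitocohort.burden import (BurdenFilters, BurdenResult, SampleMeta,
                               bonferroni_threshold, burden_test, carrier_table,
                               heteroplasmy_summary, poisson_age_model,
                               proportion_pct, score_summary)
from mitocohort.exact import DegenerateTableWarning, fisher_two_sided
from mitocohort.variants import VariantCall


def make_call(sample_id, position=10410, alt="G", zygosity="homoplasmic_alt",
              rarity="rare", genes=("MT-TR",), region="tRNA", hf=95.0, score=None):
    return VariantCall(sample_id=sample_id, position=position, ref="A", alt=alt,
                       kind="SNV", hf=hf, depth=100, qs=36.0, zygosity=zygosity,
                       gene_names=genes, region=region, rarity=rarity,
                       patho_score=score)


def make_cohort(n_case, n_control, case_group="AD", ages=None):
    samples = []
    for i in range(n_case):
        samples.append(SampleMeta(f"c{i}", case_group,
                                  age_death=ages[i] if ages else 70.0))
    for i in range(n_control):
        samples.append(SampleMeta(f"k{i}", "Control", age_death=75.0))
    return samples


class TestCarrierTable:
    def test_counts_match_carrier_definition(self):
        samples = make_cohort(282, 344)
        calls = [make_call(f"c{i}") for i in range(6)]
        filters = BurdenFilters(rarity=frozenset({"rare"}))
        table = carrier_table(calls, samples, "gene", "MT-TR", "AD", "Control",
                              filters)
        assert table == (6, 276, 0, 344)

    def test_multiple_calls_count_once(self):
        samples = make_cohort(5, 5)
        calls = [make_call("c0", position=p) for p in (10410, 10420, 10430)]
        a, b, c, d = carrier_table(calls, samples, "gene", "MT-TR", "AD", "Control")
        assert (a, b) == (1, 4)

    def test_duplicate_calls_leave_table_invariant(self):
        samples = make_cohort(4, 4)
        calls = [make_call("c1")]
        base = carrier_table(calls, samples, "gene", "MT-TR", "AD", "Control")
        doubled = carrier_table(calls * 3, samples, "gene", "MT-TR", "AD", "Control")
        assert base == doubled

    def test_age_predicate_filters_denominators(self):
        ages = [55.0] * 23 + [80.0] * 66
        samples = make_cohort(89, 10, case_group="DLB-PD", ages=ages)
        filters = BurdenFilters(age_predicate=lambda s: s.age_death < 70)
        a, b, c, d = carrier_table([], samples, "gene", "MT-CO2", "DLB-PD",
                                   "Control", filters)
        assert a + b == 23  # young-onset stratum size equals the direct filter

    def test_same_group_rejected(self):
        with pytest.raises(ValueError):
            carrier_table([], make_cohort(2, 2), "gene", "MT-TR", "AD", "AD")

    def test_empty_group_warns(self):
        samples = [SampleMeta("c0", "AD", age_death=70.0)]
        with pytest.warns(DegenerateTableWarning):
            carrier_table([], samples, "gene", "MT-TR", "AD", "Control")

    def test_complex_unit_pools_member_genes(self, gene_model):
        samples = make_cohort(3, 3)
        calls = [make_call("c0", position=7600, genes=("MT-CO2",), region="protein")]
        a, *_ = carrier_table(calls, samples, "complex", "IV", "AD", "Control",
                              model=gene_model)
        assert a == 1


class TestFisherPrintedTables:
    @pytest.mark.parametrize("table, printed, digits", [
        ([[30, 252], [16, 328]], 0.005, 3),
        ([[6, 276], [0, 344]], 0.008, 3),
        ([[9, 44], [2, 63]], 0.012, 3),
        ([[5, 18], [5, 208]], 0.0010, 4),
    ])
    def test_reproduces_reported_values(self, table, printed, digits):
        assert round(fisher_two_sided(table), digits) == printed


class TestBonferroni:
    def test_gene_family_threshold(self):
        assert bonferroni_threshold(0.05, 37) == pytest.approx(0.05 / 37)
        assert float(f"{bonferroni_threshold(0.05, 37):.2g}") == 0.0014

    @pytest.mark.parametrize("alpha, m, expected", [(0.05, 1, 0.05),
                                                    (0.01, 4, 0.0025)])
    def test_examples(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_antitone_in_family_size(self):
        thresholds = [bonferroni_threshold(0.05, m) for m in range(1, 100)]
        assert all(a > b for a, b in zip(thresholds, thresholds[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestBurdenResult:
    def test_significance_flag_follows_threshold(self):
        samples = make_cohort(282, 344)
        calls = [make_call(f"c{i}") for i in range(6)]
        res = burden_test(calls, samples, "gene", "MT-TR", "AD", "Control",
                          BurdenFilters(rarity=frozenset({"rare"})))
        assert (res.a, res.c) == (6, 0)
        assert res.p == pytest.approx(0.00811, rel=1e-3)
        assert res.alpha_corrected == pytest.approx(0.05 / 37)
        assert res.significant is False  # 0.008 fails the corrected threshold

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            BurdenResult("gene", "X", "all", -1, 2, 3, 4, 0.5, 0.05)


class TestHeteroplasmySummary:
    def test_constant_counts(self):
        samples = [SampleMeta(f"s{i}", "Control", age_death=70.0) for i in range(10)]
        calls = [make_call(f"s{i}", position=100 + j, zygosity="heteroplasmic",
                           hf=40.0, region="dloop")
                 for i in range(10) for j in range(2)]
        out = heteroplasmy_summary(calls, samples)
        assert out["mean_het_count"] == pytest.approx(2.0)
        assert out["sd_het_count"] == pytest.approx(0.0)
        assert out["carrier_fraction_pct"] == pytest.approx(100.0)
        assert sum(out["region_breakdown_pct"].values()) == pytest.approx(100.0)

    def test_carrier_fraction_percentage(self):
        samples = [SampleMeta(f"s{i}", "Control", age_death=70.0)
                   for i in range(1363)]
        calls = [make_call(f"s{i}", zygosity="heteroplasmic", hf=30.0)
                 for i in range(440)]
        out = heteroplasmy_summary(calls, samples)
        assert round(out["carrier_fraction_pct"], 1) == 32.3

    def test_no_heteroplasmy(self):
        samples = [SampleMeta("s0", "Control", age_death=70.0)]
        out = heteroplasmy_summary([], samples)
        assert out["mean_het_count"] == 0.0 and out["mean_hf"] is None

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError):
            heteroplasmy_summary([], [])


def test_proportion_pct_printed_values():
    assert proportion_pct(30, 282) == 10.6
    assert proportion_pct(440, 1363) == 32.3
    with pytest.raises(ValueError):
        proportion_pct(1, 0)


class TestPoissonAgeModel:
    def test_constant_counts_give_zero_slope(self):
        fit = poisson_age_model([3] * 20, np.linspace(40, 90, 20))
        assert fit.slope == pytest.approx(0.0, abs=1e-8)
        assert fit.intercept == pytest.approx(math.log(3), abs=1e-8)

    def test_recovers_generating_slope_and_matches_grid_oracle(self):
        rng = np.random.default_rng(14)
        b0, b1, n = -3.0, 0.05, 2000
        ages = rng.uniform(40, 95, size=n)
        counts = rng.poisson(np.exp(b0 + b1 * ages))
        fit = poisson_age_model(counts, ages)
        assert abs(fit.slope - b1) < 3 * fit.slope_se

        # independent oracle: profile log-likelihood grid over the slope
        def profile_ll(slope):
            # intercept MLE given slope: log(sum y / sum exp(slope*age))
            b0_hat = np.log(counts.sum() / np.exp(slope * ages).sum())
            lam = np.exp(b0_hat + slope * ages)
            return (counts * np.log(lam) - lam).sum()

        grid = np.linspace(b1 - 0.03, b1 + 0.03, 601)
        best = grid[np.argmax([profile_ll(s) for s in grid])]
        assert fit.slope == pytest.approx(best, abs=1e-4)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            poisson_age_model([1], [50.0])
        with pytest.raises(ValueError):
            poisson_age_model([1, 2], [50.0, 50.0])
        with pytest.raises(ValueError):
            poisson_age_model([1.5, 2], [50.0, 60.0])

    def test_all_zero_counts_flagged(self):
        fit = poisson_age_model([0, 0, 0], [50.0, 60.0, 70.0])
        assert fit.all_zero and math.isnan(fit.slope)


class TestScoreSummary:
    def test_identical_groups_give_p_one(self):
        samples = make_cohort(4, 4)
        calls = ([make_call(f"c{i}", score=0.2 * (i + 1)) for i in range(4)]
                 + [make_call(f"k{i}", score=0.2 * (i + 1)) for i in range(4)])
        out = score_summary(calls, samples, "AD", "Control")
        assert out["p"] == pytest.approx(1.0)

    def test_strict_dominance_enumeration(self):
        # every case score above every control score, 4 vs 4:
        # p = 2 / C(8,4) = 0.0286 by full enumeration of rank sums
        samples = make_cohort(4, 4)
        calls = ([make_call(f"c{i}", score=0.8 + 0.01 * i) for i in range(4)]
                 + [make_call(f"k{i}", score=0.1 + 0.01 * i) for i in range(4)])
        out = score_summary(calls, samples, "AD", "Control")
        assert out["p"] == pytest.approx(2 / 70)
        assert out["mean_score"]["AD"] > out["mean_score"]["Control"]

    def test_no_scores_warns_and_skips(self):
        samples = make_cohort(2, 2)
        with pytest.warns(DegenerateTableWarning):
            assert score_summary([make_call("c0")], samples, "AD", "Control") is None


def test_sample_meta_validation():
    with pytest.raises(ValueError):
        SampleMeta("x", "NotAGroup")
    with pytest.raises(ValueError):
        SampleMeta("x", "AD", age_death=0.0)


def test_poisson_fit_matches_statsmodels_reference():
    rng = np.random.default_rng(15)
    ages = rng.uniform(40, 90, size=300)
    counts = rng.poisson(np.exp(-2 + 0.03 * ages))
    fit = poisson_age_model(counts, ages)
    ref = sm.GLM(counts, sm.add_constant(ages), family=sm.families.Poisson()).fit()
    assert fit.slope == pytest.approx(ref.params[1])
    assert fit.p_slope == pytest.approx(ref.pvalues[1])
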