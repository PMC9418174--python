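"""Normality gating, two-group tests, summaries and the longitudinal report."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mrimon.cohortstats import (
    NON_NORMAL,
    NORMAL,
    compare_groups,
    group_summary,
    longitudinal_report,
    mann_whitney,
    normality_gate,
    stars_from_p,
)
from mrimon.synth import CohortGenConfig, MeasurementEffect, generate_cohort


class TestNormalityGate:
    def test_gaussian_draw_passes(self):
        x = np.random.default_rng(123).normal(10.0, 2.0, 1000)
        assert normality_gate(x) == NORMAL

    def test_bimodal_fixture_fails(self):
        x = np.array([0.0] * 50 + [100.0] * 50)
        # direct-formula KS oracle: D for a two-point mass vs fitted normal
        mu, sd = x.mean(), x.std(ddof=1)
        d_oracle = sps.kstest(x, "norm", args=(mu, sd)).statistic
        assert d_oracle > 0.3
        assert normality_gate(x) == NON_NORMAL

    def test_constant_values_non_normal(self):
        assert normality_gate([5.0, 5.0, 5.0, 5.0]) == NON_NORMAL

    def test_n_below_three_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            normality_gate([1.0, 2.0])


class TestMannWhitney:
    def test_disjoint_groups_exact_p(self):
        # U = 0; full enumeration over C(6,3) = 20 rank splits gives p = 0.1
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 4), (5, 5), (7, 7), (6, 8)])
    def test_matches_scipy_exact_enumeration(self, n1, n2, rng):
        for _ in range(20):
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.5, 1, n2)
            _, p = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exact_under_ties_via_midranks(self, rng):
        for _ in range(10):
            a = rng.integers(0, 4, 5).astype(float)
            b = rng.integers(0, 4, 5).astype(float)
            if np.array_equal(np.sort(a), np.sort(b)) and a.std() == 0:
                continue
            _, p = mann_whitney(a, b)
            # permutation oracle: exact two-sided p over all rank splits
            pooled = np.concatenate([a, b])
            from itertools import combinations
            ranks = sps.rankdata(pooled)
            base = 5 * 6 / 2.0
            us = [ranks[list(c)].sum() - base for c in combinations(range(10), 5)]
            us = np.asarray(us)
            u_obs = ranks[:5].sum() - base
            p_ref = min(1.0, 2 * min((us <= u_obs + 1e-12).mean(),
                                     (us >= u_obs - 1e-12).mean()))
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_large_sample_normal_approximation(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 30)
        _, p = mann_whitney(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestCompareGroups:
    def test_identical_samples_t_branch_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = compare_groups(a, a, force="t")
        assert res.test == "t"
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)
        assert res.stars == "ns"

    def test_forced_mw_branch(self):
        res = compare_groups([1, 2, 3], [10, 11, 12], force="mann_whitney")
        assert res.test == "mann_whitney"
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_degenerate_zero_sd_routes_to_mw(self):
        res = compare_groups([5.0] * 5, [7.0, 7.1, 7.2, 7.3, 7.4])
        assert res.test == "mann_whitney"

    def test_overlapping_ids_rejected(self):
        with pytest.raises(ValueError, match="share animal ids"):
            compare_groups([1, 2, 3], [4, 5, 6],
                           ids_a=["a", "b", "c"], ids_b=["c", "d", "e"])

    def test_label_swap_symmetry(self, rng):
        a = rng.normal(0, 1, 7)
        b = rng.normal(1, 1, 7)
        r1 = compare_groups(a, b, force="t")
        r2 = compare_groups(b, a, force="t")
        assert r1.statistic == pytest.approx(-r2.statistic, rel=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)

    def test_power_with_three_sd_effect(self, rng):
        # n=7/group, effect 3 sd: rejection nearly certain
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            a = rng.normal(0.0, 1.0, 7)
            b = rng.normal(3.0, 1.0, 7)
            rejections += compare_groups(a, b).p_value <= 0.05
        assert rejections / n_sim > 0.99

    def test_monotone_power_in_effect_size(self, rng):
        rates = []
        for effect in (0.0, 0.5, 1.0, 2.0):
            rej = sum(
                compare_groups(rng.normal(0, 1, 7),
                               rng.normal(effect, 1, 7)).p_value <= 0.05
                for _ in range(150)
            )
            rates.append(rej / 150)
        # non-decreasing within Monte-Carlo slack
        assert all(rates[i + 1] >= rates[i] - 0.05 for i in range(3))
        assert rates[-1] > rates[0]

    def test_stars_thresholds(self):
        assert stars_from_p(0.2) == "ns"
        assert stars_from_p(0.05) == "*"
        assert stars_from_p(0.01) == "**"
        assert stars_from_p(0.001) == "***"


class TestSummariesAndReport:
    def _table(self):
        rows = []
        for i, v in enumerate((2.0, 4.0, 6.0)):
            rows.append({"animal": f"f_mut_{i}", "sex": "f", "genotype": "mutant",
                         "timepoint": 4.0, "measurement": "w", "value": v,
                         "excluded": False, "exclusion_reason": ""})
        rows.append({"animal": "f_con_0", "sex": "f", "genotype": "control",
                     "timepoint": 4.0, "measurement": "w", "value": 9.0,
                     "excluded": True, "exclusion_reason": "splenic cancer"})
        return pd.DataFrame(rows)

    def test_cell_mean_sd(self):
        summary = group_summary(self._table(), "w", 4.0)
        cell = summary[(summary.sex == "f") & (summary.genotype == "mutant")].iloc[0]
        assert cell["mean"] == pytest.approx(4.0)
        assert cell["sd"] == pytest.approx(2.0)
        assert cell["n"] == 3

    def test_excluded_records_dropped_and_logged(self):
        summary = group_summary(self._table(), "w", 4.0)
        cell = summary[(summary.sex == "f") & (summary.genotype == "control")].iloc[0]
        assert cell["n"] == 0
        assert "splenic cancer" in cell["exclusions"]

    def test_empty_measurement_rejected(self):
        with pytest.raises(ValueError, match="unknown measurement"):
            group_summary(self._table(), "nope", 4.0)

    def test_genotype_effect_recovered_in_summary(self):
        cfg = CohortGenConfig(
            n_per_group=7, timepoints=(12.0,),
            effects={"t1": MeasurementEffect(baseline=700.0, genotype_effect=-60.0,
                                             residual_sd=20.0)},
            tumor_model=None, seed=5,
        )
        table = generate_cohort(cfg)
        summary = group_summary(table, "t1", 12.0)
        mut = summary[summary.genotype == "mutant"]["mean"].mean()
        con = summary[summary.genotype == "control"]["mean"].mean()
        assert mut - con == pytest.approx(-60.0, abs=3 * 20.0 / np.sqrt(14))

    def test_longitudinal_report_structure(self):
        cfg = CohortGenConfig(
            n_per_group=4, timepoints=(4.0, 12.0),
            effects={"w": MeasurementEffect(baseline=(10.0, 12.0), residual_sd=1.0)},
            tumor_model=None, seed=2,
        )
        summary, tests = longitudinal_report(generate_cohort(cfg))
        assert set(tests["grouping"]) == {
            "genotype_within_f", "genotype_within_m",
            "sex_within_mutant", "sex_within_control",
        }
        assert len(tests) == 8  # 1 measurement x 2 timepoints x 4 comparisons
        assert (tests["n_a"] >= 2).all()

    def test_sex_effect_only_hits_sex_comparisons(self):
        cfg = CohortGenConfig(
            n_per_group=7, timepoints=(12.0,),
            effects={"w": MeasurementEffect(baseline=25.0, sex_effect=6.0,
                                            residual_sd=1.0)},
            tumor_model=None, seed=3,
        )
        _, tests = longitudinal_report(generate_cohort(cfg))
        sex_rows = tests[tests.grouping.str.startswith("sex")]
        geno_rows = tests[tests.grouping.str.startswith("genotype")]
        assert (sex_rows["p_value"] <= 0.001).all()
        assert (geno_rows["stars"] == "ns").all()

    def test_empty_table_empty_report(self):
        empty = pd.DataFrame(columns=["animal", "sex", "genotype", "timepoint",
                                      "measurement", "value", "excluded",
                                      "exclusion_reason"])
        summary, tests = longitudinal_report(empty)
        assert len(summary) == 0 and len(tests) == 0

    def test_bh_adjustment_adds_columns(self):
        cfg = CohortGenConfig(
            n_per_group=4, timepoints=(4.0,),
            effects={"w": MeasurementEffect(baseline=10.0, residual_sd=1.0)},
            tumor_model=None, seed=4,
        )
        _, tests = longitudinal_report(generate_cohort(cfg), mtc="bh")
        assert "p_adjusted" in tests.columns
        assert (tests["p_adjusted"] >= tests["p_value"] - 1e-12).all()
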