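"""Triplicate averaging, normality-gated tests, correlation matrices,
regression comparison, concordance and ddCt analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuroihc.clinstats import (
    case_average,
    choose_and_run_test,
    compare_regressions,
    ddct_analysis,
    grade_concordance,
    spearman_matrix,
    spearman_pair,
    triplicate_average,
)
from neuroihc.cohort import generate_qpcr_plate


def _per_roi(values_by_cell):
    rows = []
    for (case, stain, region, matter, adj), vals in values_by_cell.items():
        for rep, v in enumerate(vals, start=1):
            rows.append(
                {
                    "case_id": case,
                    "stain": stain,
                    "region": region,
                    "matter": matter,
                    "adjacency": adj,
                    "replicate": rep,
                    "count": v,
                }
            )
    return pd.DataFrame(rows)


class TestTriplicateAverage:
    def test_arithmetic_mean(self):
        df = _per_roi({("c1", "Iba1", "BA4", "GM", "VA"): [10, 20, 30]})
        out = triplicate_average(df, ["count"])
        assert out["count"].iloc[0] == 20
        assert bool(out["complete"].iloc[0])

    def test_single_replicate_flagged_incomplete(self):
        df = _per_roi({("c1", "Iba1", "BA4", "GM", "VA"): [7]})
        out = triplicate_average(df, ["count"])
        assert out["count"].iloc[0] == 7
        assert not bool(out["complete"].iloc[0])

    def test_excess_replicates_rejected(self):
        df = _per_roi({("c1", "Iba1", "BA4", "GM", "VA"): [1, 2, 3, 4]})
        with pytest.raises(ValueError):
            triplicate_average(df, ["count"])

    def test_case_average_equals_direct_mean_of_region_means(self):
        cells = {
            ("c1", "Iba1", "BA4", "GM", "VA"): [0, 3, 6],
            ("c1", "Iba1", "BA4", "GM", "NVA"): [9, 9, 9],
            ("c1", "Iba1", "BA39", "WM", "VA"): [12, 15, 18],
        }
        summary = triplicate_average(_per_roi(cells), ["count"])
        per_case = case_average(summary, ["count"])
        direct = np.mean([np.mean(v) for v in cells.values()])
        assert per_case["count"].iloc[0] == pytest.approx(direct)

    def test_grouping_then_averaging_associativity(self, rng):
        cells = {
            ("c1", "Iba1", r, m, a): list(rng.integers(0, 50, 3))
            for r in ("BA4", "BA39")
            for m in ("GM", "WM")
            for a in ("VA", "NVA")
        }
        df = _per_roi(cells)
        summary = triplicate_average(df, ["count"])
        by_region = summary.groupby("region")["count"].mean()
        direct = df.groupby(["region", "matter", "adjacency"])["count"].mean().groupby("region").mean()
        assert np.allclose(by_region.sort_index(), direct.sort_index())


class TestChooseAndRunTest:
    def test_identical_samples_give_p_one(self, rng):
        x = rng.normal(0, 1, 30)
        res = choose_and_run_test({"a": x, "b": x.copy()})
        assert res.tested
        assert res.p_value == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize("na,nb", [(1, 10), (2, 2), (0, 5), (2, 30)])
    def test_small_groups_refused(self, rng, na, nb):
        res = choose_and_run_test({"a": rng.normal(size=na), "b": rng.normal(size=nb)})
        assert not res.tested
        assert "a" in res.reason

    def test_gaussian_shift_takes_parametric_branch_with_power(self):
        branches, sig = [], 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = choose_and_run_test(
                {"a": rng.normal(0, 1, 50), "b": rng.normal(1, 1, 50)}
            )
            branches.append(res.branch)
            sig += res.p_value < 0.05
        assert branches.count("parametric") >= 14
        assert sig >= 18  # 1-sigma shift at n=50/50 is near-certain detection

    def test_heavy_tails_take_nonparametric_branch(self):
        branches = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = choose_and_run_test(
                {"a": rng.standard_cauchy(40), "b": rng.standard_cauchy(40)}
            )
            branches.append(res.branch)
        assert branches.count("nonparametric") >= 14

    def test_three_group_parametric_reports_tukey_pairs(self, rng):
        res = choose_and_run_test(
            {
                "impaired": rng.normal(3, 1, 20),
                "unimpaired": rng.normal(0, 1, 20),
                "control": rng.normal(0, 1, 20),
            }
        )
        if res.branch == "parametric":
            assert res.pairwise is not None and len(res.pairwise) == 3
        else:
            assert "Holm-Sidak" in res.test

    def test_three_group_nonparametric_adjusts_pairs(self, rng):
        a = np.exp(rng.standard_cauchy(15))
        res = choose_and_run_test({"a": a, "b": a * 2, "c": a * 3})
        if res.branch == "nonparametric":
            assert (res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-12).all()

    def test_type_one_error_near_nominal_both_branches(self):
        """Null two-group comparisons reject at ~5% in each branch."""
        results = {"parametric": [], "nonparametric": []}
        for seed in range(400):
            rng = np.random.default_rng(seed)
            draw = rng.normal if seed % 2 == 0 else rng.standard_cauchy
            res = choose_and_run_test({"a": draw(size=20), "b": draw(size=20)})
            results[res.branch].append(res.p_value < 0.05)
        for branch, hits in results.items():
            assert len(hits) >= 50
            rate = np.mean(hits)
            ci = 3 * np.sqrt(0.05 * 0.95 / len(hits))
            assert rate == pytest.approx(0.05, abs=max(ci, 0.03)), branch


class TestSpearman:
    def test_monotone_transform_gives_perfect_rho(self):
        x = np.linspace(-3, 3, 50)
        rho, p = spearman_pair(x, x**3)
        assert rho == pytest.approx(1.0)

    def test_constant_variable_is_na(self):
        rho, p = spearman_pair(np.ones(10), np.arange(10))
        assert np.isnan(rho)

    def test_null_distribution_of_rho(self):
        rhos = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            rho, _ = spearman_pair(rng.normal(size=100), rng.normal(size=100))
            rhos.append(rho)
        rhos = np.asarray(rhos)
        assert abs(rhos.mean()) < 0.02
        assert np.quantile(np.abs(rhos), 0.95) == pytest.approx(0.2, abs=0.05)

    def test_planted_rank_correlation_recovered(self):
        """Gaussian copula with rank correlation 0.45."""
        r = 2 * np.sin(np.pi * 0.45 / 6)
        rng = np.random.default_rng(7)
        cov = [[1, r], [r, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=500)
        rho, _ = spearman_pair(xy[:, 0], xy[:, 1])
        assert rho == pytest.approx(0.45, abs=0.1)

    def test_matrix_layout_per_group(self, rng):
        df = pd.DataFrame(
            {
                "group": ["disease"] * 20 + ["control"] * 20,
                "Iba1": rng.normal(size=40),
                "CD68": rng.normal(size=40),
                "GFAP": rng.normal(size=40),
            }
        )
        out = spearman_matrix(df, ["Iba1", "CD68", "GFAP"])
        assert len(out) == 2 * 3  # 2 groups x 3 pairs
        assert set(out["group"]) == {"disease", "control"}


class TestCompareRegressions:
    def test_same_line_both_tests_null(self, rng):
        x = rng.uniform(0, 10, 120)
        y = 1.5 * x + 2 + rng.normal(0, 0.5, 120)
        g = np.array(["control", "disease"])[rng.integers(0, 2, 120)]
        rc = compare_regressions(x, y, g, reference="control")
        assert rc.intercept_diff_p["disease"] > 0.05
        assert rc.slope_diff_p["disease"] > 0.05

    def test_per_group_fits_match_independent_least_squares(self, rng):
        x = rng.uniform(0, 10, 80)
        g = np.repeat(["control", "disease"], 40)
        y = np.where(g == "disease", 3.0, 1.0) + 2.0 * x + rng.normal(0, 1, 80)
        rc = compare_regressions(x, y, g)
        for lev in ("control", "disease"):
            m = g == lev
            slope, intercept = np.polyfit(x[m], y[m], 1)
            row = rc.per_group.set_index("group").loc[lev]
            assert row["slope"] == pytest.approx(slope, abs=1e-8)
            assert row["intercept"] == pytest.approx(intercept, abs=1e-8)

    def test_slope_only_difference_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 10, 200)
            g = np.repeat(["control", "disease"], 100)
            y = np.where(g == "disease", 1.5, 0.5) * x + rng.normal(0, 1, 200)
            rc = compare_regressions(x, y, g, reference="control")
            hits += rc.slope_diff_p["disease"] < 0.001
        assert hits >= 9

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_regressions([1, 2, 3, 4], [1, 2, 3, 4], ["a", "a", "a", "b"])


class TestGradeConcordance:
    def test_identical_binning_gives_unit_rho(self):
        # manual grades are the binned digital scores (same tie pattern)
        digital = np.array([0, 0, 3, 3, 5, 5, 8, 8])
        manual = np.array([0, 0, 1, 1, 2, 2, 3, 3])
        rho, p = grade_concordance(digital, manual)
        assert rho == pytest.approx(1.0)
        assert p < 0.01

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            grade_concordance([1, 2], [1, 2])

    def test_null_p_values_roughly_uniform(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rho, p = grade_concordance(rng.normal(size=30), rng.integers(0, 4, 30))
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestDdct:
    def test_fold_change_identities(self):
        # ddCt of 0, 1 and -2 map to fold changes 1, 0.5 and 4
        assert 2.0 ** -0.0 == 1.0
        plate = generate_qpcr_plate(3, 3, true_log2_fc=-1.0, ct_sd=0.0, seed=1)
        res = ddct_analysis(plate)
        dis = res.per_sample[res.per_sample["group"] == "disease"]
        assert np.allclose(dis["ddct"], 1.0)
        assert np.allclose(dis["fold_change"], 0.5)
        plate = generate_qpcr_plate(3, 3, true_log2_fc=2.0, ct_sd=0.0, seed=2)
        dis = ddct_analysis(plate).per_sample.query("group == 'disease'")
        assert np.allclose(dis["ddct"], -2.0)
        assert np.allclose(dis["fold_change"], 4.0)

    def test_control_fold_changes_centre_at_one(self):
        plate = generate_qpcr_plate(8, 8, 0.7, 0.2, seed=3)
        res = ddct_analysis(plate)
        ctl = res.per_sample[res.per_sample["group"] == "control"]
        assert ctl["ddct"].mean() == pytest.approx(0.0, abs=1e-12)
        assert stats.gmean(ctl["fold_change"]) == pytest.approx(1.0, abs=1e-12)

    def test_inconsistent_triplicates_excluded(self):
        plate = generate_qpcr_plate(4, 4, 0.0, 0.05, seed=4)
        noisy_sample = plate["sample_id"].iloc[0]
        m = (plate["sample_id"] == noisy_sample) & (plate["gene"] == "FUS")
        plate.loc[m, "ct"] = [10.0, 13.0, 16.0]  # sd = 3 >> cutoff
        res = ddct_analysis(plate)
        assert noisy_sample in res.excluded
        assert noisy_sample not in set(res.per_sample["sample_id"])

    def test_missing_reference_gene_rejected(self):
        plate = generate_qpcr_plate(3, 3, 0.0, 0.0, seed=5)
        with pytest.raises(ValueError, match="18S"):
            ddct_analysis(plate[plate["gene"] == "FUS"])

    def test_null_expression_test_is_calibrated(self):
        ps = []
        for seed in range(150):
            plate = generate_qpcr_plate(8, 8, 0.0, 0.3, seed=seed)
            ps.append(ddct_analysis(plate).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
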