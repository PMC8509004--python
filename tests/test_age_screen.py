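"""The slope-test screen: OLS oracles, FDR, DEGA calling and summary tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ciliascreen.age_screen import (
    NEG_LOG10_P_CAP,
    ScreenConfig,
    age_group_fold_change,
    annotate_degas,
    bh_fdr,
    call_degas,
    fit_age_regression,
    region_summary,
    screen_all,
    volcano_table,
)
from ciliascreen.data_io import ExpressionMatrix, SampleRecord
from ciliascreen.synthetic_data import SimConfig, generate_dataset


def ols_oracle(x, y):
    """Independent normal-equations + t-CDF oracle for the slope test."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    X = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    sxx = float(((x - x.mean()) ** 2).sum())
    se = np.sqrt(rss / (n - 2) / sxx)
    t = beta[1] / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return beta[0], beta[1], se, t, p


class TestFitAgeRegression:
    def test_exact_line_is_perfect_fit(self):
        r = fit_age_regression([1, 2, 3, 4], [5, 7, 9, 11])
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(3.0)
        assert r.status == "perfect_fit"
        assert r.p_value == 0.0
        assert r.r_squared == 1.0

    def test_constant_expression_has_no_signal(self):
        r = fit_age_regression([1, 2, 3, 4], [5, 5, 5, 5])
        assert r.slope == 0.0
        assert r.t_stat == 0.0
        assert r.p_value == 1.0
        assert r.r_squared == 0.0
        assert r.status == "ok"

    def test_six_point_fixture_matches_closed_form_oracle(self):
        ages = [0.33, 1, 5, 13, 21, 40]
        expr = [10.0, 12.1, 11.5, 18.0, 16.3, 30.2]
        r = fit_age_regression(ages, expr)
        b0, b1, se, t, p = ols_oracle(ages, expr)
        assert r.intercept == pytest.approx(b0, abs=1e-10)
        assert r.slope == pytest.approx(b1, abs=1e-10)
        assert r.se_slope == pytest.approx(se, abs=1e-10)
        assert r.t_stat == pytest.approx(t, abs=1e-10)
        assert r.p_value == pytest.approx(p, abs=1e-10)

    def test_matches_scipy_linregress(self, rng):
        for _ in range(50):
            n = rng.integers(4, 30)
            x = rng.uniform(0.33, 40, n)
            y = rng.normal(10 + 0.5 * x, 3.0)
            r = fit_age_regression(x, y)
            ref = stats.linregress(x, y)
            assert r.slope == pytest.approx(ref.slope, abs=1e-10)
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            assert r.se_slope == pytest.approx(ref.stderr, abs=1e-10)

    def test_slope_p_equals_correlation_test_p(self, rng):
        """Two routes to one statistic: t = r * sqrt((n-2)/(1-r^2))."""
        for _ in range(50):
            n = int(rng.integers(5, 40))
            x = rng.uniform(0.33, 40, n)
            y = rng.normal(5 + x, 8.0)
            fit = fit_age_regression(x, y)
            r = np.corrcoef(x, y)[0, 1]
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert fit.t_stat == pytest.approx(t, abs=1e-10)
            assert fit.p_value == pytest.approx(p, abs=1e-10)

    @pytest.mark.parametrize("c", [0.5, 2.0, 117.3])
    def test_response_scaling_moves_slope_but_not_t_p_r2(self, c, rng):
        x = rng.uniform(0.33, 40, 20)
        y = rng.normal(10 + 0.3 * x, 2.0)
        base, scaled = fit_age_regression(x, y), fit_age_regression(x, c * y)
        assert scaled.slope == pytest.approx(c * base.slope, rel=1e-10)
        assert scaled.t_stat == pytest.approx(base.t_stat, rel=1e-10)
        assert scaled.p_value == pytest.approx(base.p_value, rel=1e-10)
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-10)

    def test_degenerate_inputs_are_flagged_not_raised(self):
        assert fit_age_regression([1, 2], [3, 4]).status == "degenerate"
        assert fit_age_regression([5, 5, 5], [1, 2, 3]).status == "degenerate"


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.05]).tolist() == [0.05]

    def test_ties_stay_tied(self):
        assert bh_fdr([0.5, 0.5, 0.5]).tolist() == [0.5, 0.5, 0.5]

    def test_textbook_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.2])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.2])

    def test_out_of_range_p_raises(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @staticmethod
    def step_up_oracle(p):
        """Exhaustive textbook BH step-up: q_i = min_{j: p_(j) >= p_i} p_(j)*m/j."""
        p = np.asarray(p, float)
        m = p.size
        sorted_p = np.sort(p)
        q = np.empty(m)
        for i, pi in enumerate(p):
            candidates = [
                sorted_p[j] * m / (j + 1)
                for j in range(m)
                if sorted_p[j] >= pi - 1e-15
            ]
            q[i] = min(min(candidates), 1.0)
        return q

    def test_matches_step_up_oracle_on_all_small_subsets(self, rng):
        pool = rng.uniform(0, 1, 8)
        from itertools import combinations

        for size in range(1, 9):
            for subset in combinations(pool, size):
                assert np.allclose(
                    bh_fdr(list(subset)), self.step_up_oracle(subset),
                    atol=1e-12,
                )

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        q = bh_fdr(p)
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q_perm = bh_fdr([p[i] for i in perm])
        assert np.allclose(q_perm, q[perm], atol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 200)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), expected, atol=1e-12)


class TestScreenAll:
    def test_single_gene_single_region(self):
        data = pd.DataFrame([[4.0, 20.0, 40.0, 80.0]], index=["G1"],
                            columns=["S1", "S2", "S3", "S4"])
        samples = [
            SampleRecord(f"S{i+1}", f"D{i}", age, "PVC", "F")
            for i, age in enumerate([2.0, 10.0, 20.0, 40.0])
        ]
        results = screen_all(ExpressionMatrix(data), samples)
        assert len(results) == 1
        assert results.iloc[0]["status"] == "perfect_fit"

    def test_full_grid_enumerated_including_degenerates(self, small_dataset):
        matrix, samples, _, config = small_dataset
        results = screen_all(
            matrix, samples,
            gene_list=list(matrix.gene_symbols) + ["NOT_IN_MATRIX"],
        )
        assert len(results) == (config.n_genes + 1) * len(config.regions)
        missing = results[results["gene"] == "NOT_IN_MATRIX"]
        assert (missing["status"] == "degenerate").all()
        assert missing["q"].isna().all()

    def test_q_values_are_bh_of_p_values(self, small_dataset):
        matrix, samples, _, _ = small_dataset
        results = screen_all(matrix, samples)
        ok = results[results["status"].isin(["ok", "perfect_fit"])]
        assert np.allclose(ok["q"], bh_fdr(ok["p"].to_numpy()), atol=1e-12)

    def test_per_region_fdr_option(self, small_dataset):
        matrix, samples, _, config = small_dataset
        results = screen_all(
            matrix, samples, config=ScreenConfig(per_region_fdr=True)
        )
        for region in config.regions:
            ok = results[(results["region"] == region)
                         & results["status"].isin(["ok", "perfect_fit"])]
            assert np.allclose(ok["q"], bh_fdr(ok["p"].to_numpy()), atol=1e-12)

    def test_empty_gene_list_raises(self, small_dataset):
        matrix, samples, _, _ = small_dataset
        with pytest.raises(ValueError, match="empty gene list"):
            screen_all(matrix, samples, gene_list=[])


def _toy_results():
    return pd.DataFrame(
        {
            "gene": ["SNAP25", "TUBB2B", "G3", "G4"],
            "region": ["PVC", "OFC", "PVC", "PVC"],
            "n": [40] * 4,
            "intercept": [10.0] * 4,
            "slope": [22.3, -4.0, 5.0, 0.8],
            "se": [1.0] * 4,
            "t": [22.3, -4.0, 1.3, 2.4],
            "p": [1e-20, 0.001, 0.2, 0.03],
            "q": [1e-18, 0.004, 0.3, 0.06],
            "r2": [0.9, 0.5, 0.05, 0.2],
            "status": ["ok"] * 4,
        }
    )


class TestDegaCalling:
    def test_directions_follow_slope_sign_under_raw_p_cutoff(self):
        dega_sets = call_degas(_toy_results())
        assert dega_sets.by_region["PVC"]["SNAP25"] == "up"
        assert dega_sets.by_region["OFC"]["TUBB2B"] == "down"
        assert "G3" not in dega_sets.by_region["PVC"]  # p = 0.2 fails cutoff
        assert "G4" in dega_sets.by_region["PVC"]

    def test_fdr_tier_is_a_subset(self):
        dega_sets = call_degas(_toy_results())
        assert dega_sets.fdr_by_region["PVC"] == {"SNAP25"}  # G4 q > 0.05
        for region in dega_sets.regions:
            assert dega_sets.fdr_by_region[region] <= set(
                dega_sets.by_region[region]
            )

    def test_region_summary_counts(self):
        dega_sets = call_degas(_toy_results())
        summary = region_summary(dega_sets, n_screened_genes=4)
        pvc = summary[summary["region"] == "PVC"].iloc[0]
        assert (pvc["n_dega"], pvc["n_up"], pvc["n_down"]) == (2, 2, 0)
        union = summary[summary["region"] == "ALL"].iloc[0]
        assert union["n_dega"] == 3
        assert union["pct_of_panel"] == pytest.approx(75.0)

    def test_empty_results_give_zero_summary(self):
        empty = _toy_results().assign(p=1.0)
        dega_sets = call_degas(empty)
        summary = region_summary(dega_sets, 4)
        assert (summary.loc[summary["region"] != "ALL", "n_dega"] == 0).all()


class TestVolcano:
    def test_log10_mapping(self):
        results = _toy_results().assign(p=[0.01, 1.0, 0.5, 1e-310])
        table = volcano_table(results, "PVC")
        by_gene = table.set_index("gene")
        assert by_gene.loc["SNAP25", "neg_log10_p"] == pytest.approx(2.0)
        assert by_gene.loc["G4", "neg_log10_p"] == NEG_LOG10_P_CAP
        ofc = volcano_table(results, "OFC")
        assert ofc["neg_log10_p"].iloc[0] == pytest.approx(0.0)

    def test_unknown_region_raises(self):
        with pytest.raises(KeyError):
            volcano_table(_toy_results(), "Cer")

    def test_rows_match_direct_recomputation(self, small_dataset):
        matrix, samples, _, config = small_dataset
        results = screen_all(matrix, samples)
        region = config.regions[0]
        table = volcano_table(results, region).set_index("gene")
        sub = results[(results["region"] == region)
                      & (results["status"] != "degenerate")]
        for row in sub.itertuples(index=False):
            expected = min(-np.log10(row.p) if row.p > 0 else np.inf,
                           NEG_LOG10_P_CAP)
            assert table.loc[row.gene, "neg_log10_p"] == pytest.approx(expected)
            assert table.loc[row.gene, "slope"] == pytest.approx(row.slope)


class TestFoldChange:
    @staticmethod
    def _dataset(values_by_age, region="PVC"):
        ages = list(values_by_age)
        data = pd.DataFrame(
            [list(values_by_age.values())], index=["G1"],
            columns=[f"S{i}" for i in range(len(ages))],
        )
        samples = [
            SampleRecord(f"S{i}", f"D{i}", age, region, "M")
            for i, age in enumerate(ages)
        ]
        return ExpressionMatrix(data), samples

    def test_ratio_of_bin_means(self):
        matrix, samples = self._dataset({1.0: 10.0, 3.0: 10.0, 37.0: 40.0, 39.0: 40.0})
        fc = age_group_fold_change(matrix, samples, "G1", "PVC")
        assert fc == pytest.approx(4.0)

    def test_constant_gene_gives_unity(self):
        matrix, samples = self._dataset({1.0: 7.0, 38.0: 7.0})
        assert age_group_fold_change(matrix, samples, "G1", "PVC") == 1.0

    def test_linear_gene_matches_binning_oracle(self):
        b, s = 12.0, 0.8
        ages = np.linspace(0.4, 39.9, 400)
        values = b + s * ages
        data = pd.DataFrame([values], index=["G1"],
                            columns=[f"S{i}" for i in range(ages.size)])
        samples = [
            SampleRecord(f"S{i}", f"D{i}", float(a), "PVC", "F")
            for i, a in enumerate(ages)
        ]
        fc = age_group_fold_change(ExpressionMatrix(data), samples, "G1", "PVC")
        first = values[ages < 5.0].mean()
        last = values[ages >= 35.0].mean()
        assert fc == pytest.approx(last / first, abs=1e-12)
        # dense uniform ages: bin means sit near the bin mid-ages
        assert fc == pytest.approx((b + 37.5 * s) / (b + 2.5 * s), rel=0.03)

    def test_empty_extreme_bin_raises(self):
        matrix, samples = self._dataset({10.0: 5.0, 20.0: 6.0, 39.0: 8.0})
        with pytest.raises(ValueError, match="empty first or last"):
            age_group_fold_change(matrix, samples, "G1", "PVC")

    def test_zero_first_bin_mean_raises(self):
        matrix, samples = self._dataset({1.0: 0.0, 39.0: 8.0})
        with pytest.raises(ValueError, match="zero"):
            age_group_fold_change(matrix, samples, "G1", "PVC")


def test_type_one_error_calibrated_on_null_screen():
    """Rejections at alpha = 0.05 on null pairs stay in the binomial band."""
    config = SimConfig(
        n_genes=250, n_donors=25, regions=("ACC", "PVC", "Str", "Hipp"),
        frac_age_linear=0.0, intercept_range=(50.0, 80.0), noise_sd=3.0,
        missing_rate=0.0, seed=31,
    )
    matrix, samples, _ = generate_dataset(config)
    results = screen_all(matrix, samples)
    p = results.loc[results["status"] == "ok", "p"].to_numpy()
    rate = float(np.mean(p < 0.05))
    n = p.size
    lo = stats.binom.ppf(0.005, n, 0.05) / n
    hi = stats.binom.ppf(0.995, n, 0.05) / n
    assert lo <= rate <= hi
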