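import numpy as np
import pandas as pd
import pytest

from conftest import balanced_table
from oracles import anova_projection_oracle, bh_stepup_brute, icc_oneway_brute
from swaylab.stats import (
    antilog1,
    bca_ci,
    bh_adjust,
    classify_weight,
    cohens_f_from_eta,
    cohens_f_from_t,
    icc_1_1,
    icc_band,
    independent_t,
    log1_transform,
    mixed_anova_2x2x2,
    posthoc_pairwise_bh,
    reliability_gate,
)


class TestTransform:
    def test_fixed_points(self):
        assert log1_transform(np.array([0.0]))[0] == 0.0
        assert log1_transform(np.array([np.e - 1]))[0] == pytest.approx(1.0)

    def test_roundtrip(self):
        x = np.random.default_rng(0).uniform(0, 100, 50)
        np.testing.assert_allclose(antilog1(log1_transform(x)), x, atol=1e-12)

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            log1_transform(np.array([-1.5]))


class TestEffectSizes:
    def test_group_characteristic_effect_sizes(self):
        # body mass and BMI-percentile contrasts of two 19-child groups
        assert cohens_f_from_t(5.32, 36) == pytest.approx(0.89, abs=0.01)
        assert cohens_f_from_t(9.22, 36) == pytest.approx(1.54, abs=0.01)

    def test_null_and_closed_form(self):
        assert cohens_f_from_t(0.0, 36) == 0.0
        assert cohens_f_from_eta(0.5) == pytest.approx(1.0)


class TestIndependentT:
    def test_body_mass_row(self):
        t, df, p = independent_t(64.0, 10.8, 19, 46.4, 9.6, 19)
        # printed summary stats are rounded, so the t carries that rounding
        assert t == pytest.approx(5.32, abs=0.05)
        assert df == 36
        assert p < 0.001

    def test_bmi_percentile_row(self):
        t, df, p = independent_t(93.4, 3.7, 19, 45.1, 22.5, 19)
        assert t == pytest.approx(9.22, abs=0.05)

    def test_identical_groups(self):
        t, df, p = independent_t(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == 1.0


class TestMixedAnova:
    def test_matches_projection_oracle(self):
        df = balanced_table(8, seed=42, effects={"group": 0.5, "condition": 0.8, "group x condition": 0.3})
        res = mixed_anova_2x2x2(df).set_index("effect")
        wide = df.pivot_table(index=["group", "subject"], columns=["condition", "visit"], values="value")
        y = wide.to_numpy().reshape(2, 8, 2, 2)
        oracle = anova_projection_oracle(y)
        for effect, f_oracle in oracle.items():
            assert res.loc[effect, "F"] == pytest.approx(f_oracle, abs=1e-8)

    def test_between_f_equals_squared_t_on_subject_means(self):
        df = balanced_table(10, seed=3, effects={"group": 0.7})
        res = mixed_anova_2x2x2(df).set_index("effect")
        means = df.groupby(["group", "subject"])["value"].mean().unstack(0)
        from scipy.stats import ttest_ind

        t, _ = ttest_ind(means["YO"].dropna(), means["YN"].dropna())
        assert res.loc["group", "F"] == pytest.approx(t**2, rel=1e-10)

    def test_ss_decomposition_is_complete(self):
        df = balanced_table(6, seed=11)
        res = mixed_anova_2x2x2(df)
        # all seven F values are finite and non-negative on arbitrary data
        assert np.isfinite(res["F"]).all() and (res["F"] >= 0).all()
        assert (res["df2"] == 10).all()

    def test_type_i_error_calibrated(self):
        # pure subject noise: group effect should reject at ~alpha
        rejections = 0
        n_sims = 1000
        for s in range(n_sims):
            df = balanced_table(8, seed=1000 + s)
            res = mixed_anova_2x2x2(df).set_index("effect")
            rejections += res.loc["group", "p"] < 0.05
        assert rejections / n_sims == pytest.approx(0.05, abs=0.02)

    def test_missing_cell_named_in_error(self):
        df = balanced_table(4, seed=0)
        df = df[~((df["subject"] == "YO02") & (df["visit"] == 2) & (df["condition"] == "foam"))]
        with pytest.raises(ValueError, match="(?i)cell|design"):
            mixed_anova_2x2x2(df)

    def test_df_matches_full_study_design(self):
        df = balanced_table(19, seed=5)
        res = mixed_anova_2x2x2(df)
        assert (res["df1"] == 1).all() and (res["df2"] == 36).all()


class TestBH:
    def test_matches_stepup_definition(self):
        p = np.random.default_rng(1).uniform(size=10)
        reject, _ = bh_adjust(p, alpha=0.05)
        np.testing.assert_array_equal(reject, bh_stepup_brute(p, 0.05))

    def test_equal_pvalues_all_or_nothing(self):
        for p0 in (0.01, 0.2):
            reject, _ = bh_adjust(np.full(5, p0), alpha=0.05)
            assert reject.all() == (p0 <= 0.05) and reject.any() == (p0 <= 0.05)

    def test_single_comparison_is_unadjusted(self):
        reject, p_adj = bh_adjust(np.array([0.04]), alpha=0.05)
        assert reject[0] and p_adj[0] == pytest.approx(0.04)

    def test_monotone_in_pvalues(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=8)
        base, _ = bh_adjust(p, 0.05)
        for i in range(8):
            lowered = p.copy()
            lowered[i] = p[i] / 2
            new, _ = bh_adjust(lowered, 0.05)
            assert (new | ~base)[np.arange(8) != i].all() or new[np.arange(8) != i].sum() >= base[np.arange(8) != i].sum()


class TestPosthoc:
    def test_visit_pooling_when_visit_terms_negligible(self):
        df = balanced_table(10, seed=22, effects={"condition": 1.0})
        anova = mixed_anova_2x2x2(df)
        out = posthoc_pairwise_bh(df, anova)
        assert out["visits_pooled"].all()
        assert len(out) == 4  # 2 group contrasts + 2 condition contrasts
        cond_rows = out[out["comparison"].str.contains("firm vs foam")]
        assert cond_rows["significant"].all()

    def test_no_pooling_with_strong_visit_effect(self):
        df = balanced_table(10, seed=8, effects={"visit": 2.0})
        anova = mixed_anova_2x2x2(df)
        out = posthoc_pairwise_bh(df, anova)
        assert not out["visits_pooled"].any()


class TestICC:
    def test_identical_visits_give_one(self):
        v = np.random.default_rng(0).uniform(size=10)
        icc, band = icc_1_1(v, v)
        assert icc == pytest.approx(1.0)
        assert band == "excellent"

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        iccs = [icc_1_1(rng.standard_normal(20), rng.standard_normal(20))[0] for _ in range(100)]
        assert abs(np.mean(iccs)) < 0.1

    def test_matches_mean_squares_oracle(self):
        v1 = np.array([10.0, 12.0, 9.0, 14.0, 11.0, 13.0])
        v2 = np.array([11.0, 12.5, 8.0, 13.0, 10.5, 14.0])
        icc, _ = icc_1_1(v1, v2)
        assert icc == pytest.approx(icc_oneway_brute(v1, v2), abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        subj = rng.normal(0, 1, 12)
        v1 = subj + rng.normal(0, 0.5, 12)
        v2 = subj + rng.normal(0, 0.5, 12)
        icc, _ = icc_1_1(v1, v2)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile(["a", "b"], 12),
                "value": np.column_stack([v1, v2]).ravel(),
            }
        )
        ref = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="value")
        icc1 = ref.loc[ref["Type"].str.startswith("ICC(1,1")   , "ICC"]
        if icc1.empty:  # column label differs across pingouin versions
            icc1 = ref["ICC"].iloc[:1]
        assert icc == pytest.approx(float(icc1.iloc[0]), abs=1e-8)

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        v1, v2 = rng.standard_normal((2, 15))
        icc_raw, _ = icc_1_1(v1, v2)
        icc_aff, _ = icc_1_1(4.0 * v1 + 3.0, 4.0 * v2 + 3.0)
        assert icc_aff == pytest.approx(icc_raw, abs=1e-12)

    def test_bands(self):
        assert icc_band(0.40) == "poor"
        assert icc_band(0.41) == "fair"
        assert icc_band(0.75) == "good"
        assert icc_band(0.99) == "excellent"


class TestReliabilityGate:
    def grid(self, low_cell=None):
        rows = []
        for m in ("SEn", "aDFA"):
            for ax in ("ML", "AP"):
                for g in ("YO", "YN"):
                    for c in ("firm", "foam"):
                        icc = 0.7
                        if low_cell == (m, ax, g, c):
                            icc = 0.20
                        rows.append({"measure": m, "axis": ax, "group": g, "condition": c, "icc": icc})
        return pd.DataFrame(rows)

    def test_single_poor_cell_excludes_measure(self):
        excluded = reliability_gate(self.grid(low_cell=("aDFA", "AP", "YN", "foam")))
        assert excluded == [("aDFA", "AP")]

    def test_all_good_retained(self):
        assert reliability_gate(self.grid()) == []

    def test_boundary_cell_excluded(self):
        g = self.grid()
        g.loc[0, "icc"] = 0.40  # "poor" includes the boundary
        assert (g.loc[0, "measure"], g.loc[0, "axis"]) in reliability_gate(g)


class TestBca:
    def test_constant_samples_collapse_to_point(self):
        lo, hi = bca_ci(np.full(5, 3.0), np.full(6, 1.0), B=500)
        assert lo == hi == pytest.approx(2.0)

    def test_symmetric_case_close_to_percentile(self):
        # symmetric samples: zero jackknife skewness, median-unbiased stat
        s1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 4)
        s2 = np.array([0.5, 1.5, 2.5, 3.5, 4.5] * 4)
        from scipy.stats import bootstrap

        lo, hi = bca_ci(s1, s2, B=4000, seed=7)
        res = bootstrap(
            (s1, s2),
            lambda a, b, axis: np.mean(a, axis=axis) - np.mean(b, axis=axis),
            n_resamples=4000,
            method="percentile",
            rng=np.random.default_rng(7),
        )
        assert lo == pytest.approx(res.confidence_interval.low, abs=0.1)
        assert hi == pytest.approx(res.confidence_interval.high, abs=0.1)

    def test_coverage_on_gaussian_two_sample(self):
        rng = np.random.default_rng(12)
        true_diff = 1.0
        covered = 0
        n_rep = 500
        for _ in range(n_rep):
            s1 = rng.normal(true_diff, 1.0, 19)
            s2 = rng.normal(0.0, 1.0, 19)
            lo, hi = bca_ci(s1, s2, B=2000, seed=int(rng.integers(2**31)))
            covered += lo <= true_diff <= hi
        assert covered / n_rep == pytest.approx(0.95, abs=0.03)


class TestClassifyWeight:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (45.1, "normal"),
            (93.4, "overweight"),
            (85.0, "overweight"),
            (95.0, "obese"),
            (4.9, "underweight"),
            (5.0, "normal"),
            (100.0, "obese"),
            (0.0, "underweight"),
        ],
    )
    def test_thresholds(self, p, expected):
        assert classify_weight(p) == expected

    def test_partitions_without_gaps(self):
        for p in np.linspace(0, 100, 2001):
            assert classify_weight(p) in {"underweight", "normal", "overweight", "obese"}
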