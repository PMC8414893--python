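import numpy as np
import pandas as pd
import pytest

from intellipheno import stats as st
from oracles import cellmeans_anova


def _random_design(rng, n_per_group=(4, 5), d=3):
    X = rng.normal(size=(sum(n_per_group), d))
    groups = np.repeat(["A", "B"], n_per_group)
    return st.RMDesign(data=X, groups=groups)


class TestRMAnova:
    def test_identical_groups_give_zero_between_f(self):
        block = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [2.0, 2.0, 2.0]])
        design = st.RMDesign(
            data=np.vstack([block, block]),
            groups=np.repeat(["A", "B"], 3),
        )
        res = st.rm_anova(design)
        assert res["between"].statistic == pytest.approx(0.0, abs=1e-12)
        assert res["between"].p == pytest.approx(1.0)

    def test_df_structure_for_32_subjects_3_days(self):
        rng = np.random.default_rng(0)
        design = _random_design(rng, (16, 16), d=3)
        res = st.rm_anova(design)
        assert (res["within"].df1, res["within"].df2) == (2, 60)
        assert (res["interaction"].df1, res["interaction"].df2) == (2, 60)
        assert (res["between"].df1, res["between"].df2) == (1, 30)

    def test_hand_worked_six_subject_design_matches_cellmeans_oracle(self):
        X = np.array(
            [
                [3.0, 4.0, 6.0],
                [2.0, 5.0, 7.0],
                [4.0, 4.0, 5.0],
                [6.0, 7.0, 9.0],
                [5.0, 8.0, 10.0],
                [7.0, 7.0, 8.0],
            ]
        )
        groups = np.array(["ctl", "ctl", "ctl", "trt", "trt", "trt"])
        res = st.rm_anova(st.RMDesign(data=X, groups=groups))
        fb, fw, fi = cellmeans_anova(X.tolist(), groups.tolist())
        assert res["between"].statistic == pytest.approx(fb, abs=1e-9)
        assert res["within"].statistic == pytest.approx(fw, abs=1e-9)
        assert res["interaction"].statistic == pytest.approx(fi, abs=1e-9)

    def test_unbalanced_groups_match_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            design = _random_design(rng, (3, 7), d=4)
            res = st.rm_anova(design)
            fb, fw, fi = cellmeans_anova(design.data.tolist(), design.groups.tolist())
            for key, f in (("between", fb), ("within", fw), ("interaction", fi)):
                assert res[key].statistic == pytest.approx(f, abs=1e-9)

    def test_agrees_with_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        design = _random_design(rng, (6, 6), d=4)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 4),
                "group": np.repeat(design.groups, 4),
                "day": np.tile(np.arange(4), 12),
                "y": design.data.ravel(),
            }
        )
        table = pg.mixed_anova(long, dv="y", within="day", between="group",
                               subject="subject")
        res = st.rm_anova(design)
        by_source = table.set_index("Source")
        assert res["between"].statistic == pytest.approx(
            by_source.loc["group", "F"], rel=1e-6)
        assert res["within"].statistic == pytest.approx(
            by_source.loc["day", "F"], rel=1e-6)
        assert res["interaction"].statistic == pytest.approx(
            by_source.loc["Interaction", "F"], rel=1e-6)

    def test_listwise_deletion_drops_incomplete_subjects(self):
        X = np.array([[1.0, 2.0], [np.nan, 3.0], [2.0, 1.0],
                      [4.0, 4.0], [5.0, 6.0]])
        design = st.RMDesign(data=X, groups=np.array(["A", "A", "A", "B", "B"]))
        assert design.data.shape == (4, 2)

    def test_too_small_group_rejected(self):
        X = np.ones((3, 3)) + np.arange(9).reshape(3, 3)
        with pytest.raises(ValueError, match="< 2 complete subjects"):
            st.rm_anova(st.RMDesign(data=X, groups=np.array(["A", "A", "B"])))


class TestMauchly:
    def test_two_levels_are_always_spherical(self):
        rng = np.random.default_rng(1)
        design = _random_design(rng, (5, 5), d=2)
        res = st.mauchly_test(design)
        assert res["W"] == 1.0 and res["p"] == 1.0

    def test_agrees_with_pingouin_on_one_group_layout(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 4)) @ np.diag([1.0, 1.5, 0.7, 1.2])
        spher = pg.sphericity(pd.DataFrame(X), method="mauchly")
        # one group: pooled within-group covariance df reduce to n - 1
        design = st.RMDesign(data=X, groups=np.array(["A"] * 15))
        res = st.mauchly_test(design)
        assert res["W"] == pytest.approx(spher.W, rel=1e-9)
        assert res["chi2"] == pytest.approx(spher.chi2, rel=1e-9)
        # higher-order terms of the chi-square expansion differ slightly
        assert res["p"] == pytest.approx(spher.pval, abs=1e-3)

    def test_detects_strong_autocorrelation(self):
        # AR(1) rho=0.9: sphericity badly violated, test should reject mostly
        rng = np.random.default_rng(3)
        d, n = 4, 30
        rho = 0.9
        cov = rho ** np.abs(np.subtract.outer(np.arange(d), np.arange(d)))
        cov *= np.linspace(0.5, 3.0, d)[:, None] * np.linspace(0.5, 3.0, d)[None, :]
        rejections = 0
        reps = 200
        for _ in range(reps):
            X = rng.multivariate_normal(np.zeros(d), cov, size=n)
            design = st.RMDesign(data=X, groups=np.repeat(["A", "B"], n // 2))
            if st.mauchly_test(design)["p"] < 0.05:
                rejections += 1
        assert rejections / reps > 0.5

    def test_type_one_error_near_nominal_under_compound_symmetry(self):
        rng = np.random.default_rng(4)
        d, n, reps = 4, 30, 500
        rejections = 0
        for _ in range(reps):
            subj = rng.normal(scale=1.0, size=(n, 1))
            X = subj + rng.normal(size=(n, d))  # compound symmetric
            design = st.RMDesign(data=X, groups=np.repeat(["A", "B"], n // 2))
            if st.mauchly_test(design)["p"] < 0.05:
                rejections += 1
        # chi-square approximation: close to, but not exactly, 5%
        assert 0.02 <= rejections / reps <= 0.09

    def test_gg_epsilon_bounds(self):
        rng = np.random.default_rng(6)
        design = _random_design(rng, (8, 8), d=5)
        eps = st.greenhouse_geisser_epsilon(design)
        assert 1.0 / 4 <= eps <= 1.0 + 1e-12


class TestBonferroni:
    def test_requires_significant_interaction(self):
        rng = np.random.default_rng(7)
        design = _random_design(rng, (5, 5), d=3)  # pure noise
        res = st.rm_anova(design)
        if res["interaction"].p >= 0.05:
            with pytest.raises(ValueError, match="not licensed"):
                st.bonferroni_posthoc(design, res)

    def test_adjustment_multiplies_and_caps(self):
        rng = np.random.default_rng(8)
        # build a design with a real day-specific group difference
        X = rng.normal(size=(12, 3))
        X[6:, 2] += 4.0
        design = st.RMDesign(data=X, groups=np.repeat(["A", "B"], 6))
        res = st.rm_anova(design)
        posthocs = st.bonferroni_posthoc(design, res)
        assert len(posthocs) == 3
        for r in posthocs:
            assert r.adjusted_p == pytest.approx(min(1.0, r.p * 3))
            assert r.adjusted_p >= r.p


class TestPooledT:
    def test_equal_means_give_zero_t(self):
        r = st.pooled_t_from_summary(5.0, 0.5, 10, 5.0, 0.5, 10)
        assert r.statistic == 0.0 and r.p == pytest.approx(1.0)

    def test_summary_and_data_variants_agree_exactly(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            x1 = rng.normal(size=rng.integers(3, 20))
            x2 = rng.normal(size=rng.integers(3, 20))
            m1, s1 = st.mean_sem(x1)
            m2, s2 = st.mean_sem(x2)
            a = st.pooled_t_from_data(x1, x2)
            b = st.pooled_t_from_summary(m1, s1, len(x1), m2, s2, len(x2))
            assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
            assert a.p == pytest.approx(b.p, abs=1e-12)

    def test_matches_permutation_distribution(self):
        rng = np.random.default_rng(12)
        x1 = rng.normal(0.0, 1.0, 10)
        x2 = rng.normal(1.2, 1.0, 10)
        res = st.pooled_t_from_data(x1, x2)
        pooled = np.concatenate([x1, x2])
        count = 0
        reps = 4000
        for _ in range(reps):
            perm = rng.permutation(pooled)
            r = st.pooled_t_from_data(perm[:10], perm[10:])
            if abs(r.statistic) >= abs(res.statistic):
                count += 1
        p_perm = count / reps
        assert abs(p_perm - res.p) < 0.03

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            st.pooled_t_from_summary(1.0, 0.1, 1, 2.0, 0.1, 5)
        with pytest.raises(ValueError):
            st.pooled_t_from_summary(1.0, -0.1, 5, 2.0, 0.1, 5)
        with pytest.raises(ValueError):
            st.pooled_t_from_data([1.0], [2.0, 3.0])


class TestMeanSem:
    def test_hand_computed_values(self):
        mean, sem = st.mean_sem([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(0.5773502691896258)

    def test_constant_vector_has_zero_sem(self):
        assert st.mean_sem([4.0, 4.0, 4.0])[1] == 0.0

    def test_scale_equivariance(self):
        x = [1.0, 5.0, 2.0, 8.0]
        m1, s1 = st.mean_sem(x)
        m2, s2 = st.mean_sem([3.0 * v for v in x])
        assert m2 == pytest.approx(3 * m1) and s2 == pytest.approx(3 * s1)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            st.mean_sem([1.0])


class TestSignificanceMarkers:
    def test_thresholds(self):
        assert st.significance_marker(0.2) == "ns"
        assert st.significance_marker(0.04) == "*"
        assert st.significance_marker(0.009) == "**"
        assert st.significance_marker(0.0009) == "***"
        assert st.significance_marker(0.00009) == "****"


class TestAnalyzeMetrics:
    def test_identical_groups_yield_no_significant_terms(self):
        rows = []
        rng = np.random.default_rng(13)
        base = rng.normal(50, 1, size=(8, 3))
        for i in range(8):
            for day in range(3):
                rows.append(
                    ("srt", "pct_correct", f"M{i:02d}",
                     "NonTg" if i < 4 else "TG", day + 1,
                     base[i % 4, day])  # TG values copy NonTg values
                )
        df = pd.DataFrame(
            rows, columns=["phase", "metric", "animal_id", "genotype", "day", "value"]
        )
        report = st.analyze_metrics(df)
        between = report[report["term"] == "between"]
        assert (between["p"] > 0.9999).all()

    def test_single_window_metric_gets_t_test(self):
        rows = []
        rng = np.random.default_rng(14)
        for i in range(10):
            rows.append(
                ("avoidance", "airpuff_nosepoke_visits", f"M{i:02d}",
                 "NonTg" if i < 5 else "TG", 1, float(rng.poisson(8)))
            )
        df = pd.DataFrame(
            rows, columns=["phase", "metric", "animal_id", "genotype", "day", "value"]
        )
        report = st.analyze_metrics(df)
        assert len(report) == 1
        assert report.iloc[0]["term"] == "pairwise"
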