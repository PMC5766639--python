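import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spfmri import (
    CohortTable,
    bonferroni_alpha,
    correlation_matrix,
    delong_test,
    grading_report,
    icc_agreement,
    loocv_accuracy,
    make_cohort,
    mann_whitney,
    roc_analysis,
    spearman_rho,
)
from spfmri.cohort_stats import _placements
from spfmri.synthetic import GroupDistributionSpec, default_group_specs


class TestSpearman:
    def test_monotone(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [1, 4, 9, 16])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_midrank_tie_oracle(self):
        # independent oracle: rank with midranks by hand, then Pearson
        x = [1.0, 2.0, 2.0, 4.0]
        y = [2.0, 1.0, 3.0, 4.0]
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([2.0, 1.0, 3.0, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(expected)

    def test_against_scipy(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman_rho(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_signalled(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_short(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2, 3])


class TestMannWhitney:
    def test_exact_enumeration(self):
        # all 6 label permutations of ranks {1..4}: P(U <= 0) = 1/6, two-sided 1/3
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1.0 / 3.0)

    def test_identical_multisets(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_large_shift_significant(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 30)
        y = rng.normal(2, 1, 30)
        _, p = mann_whitney(x, y)
        assert p < 1e-3

    def test_normal_approximation_against_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 1, 25)
        u, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_against_scipy(self):
        x = [1.2, 3.4, 0.5, 7.7]
        y = [2.2, 5.1, 6.3, 0.9, 4.4]
        u, p = mann_whitney(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])


class TestICC:
    def test_identical_readers(self):
        r = np.column_stack([np.arange(6.0), np.arange(6.0)])
        assert icc_agreement(r) == pytest.approx(1.0)

    def test_offset_penalized_matches_anova_oracle(self):
        r1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        r2 = r1 + 10.0
        r = np.column_stack([r1, r2])
        icc = icc_agreement(r)
        assert icc < 1.0
        # closed-form two-way ANOVA decomposition computed independently
        n, k = 6, 2
        grand = r.mean()
        msr = k * ((r.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((r.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = (
            ((r - r.mean(axis=1, keepdims=True)
              - r.mean(axis=0, keepdims=True) + grand) ** 2).sum()
            / ((n - 1) * (k - 1))
        )
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc == pytest.approx(expected)

    def test_against_pingouin(self):
        rng = np.random.default_rng(3)
        subj = rng.normal(0, 2, 20)
        r = np.column_stack([subj + rng.normal(0, 1, 20),
                             subj + 0.5 + rng.normal(0, 1, 20)])
        import pingouin as pg

        df = pd.DataFrame({
            "subject": np.repeat(np.arange(20), 2),
            "rater": np.tile([0, 1], 20),
            "score": r.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        # absolute-agreement single-rater row (labelled ICC2 or ICC(A,1)
        # depending on the pingouin version)
        row = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])]
        icc2 = row["ICC"].iloc[0]
        assert icc_agreement(r) == pytest.approx(icc2, abs=1e-9)

    def test_independent_ratings_near_zero(self):
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            vals.append(icc_agreement(rng.normal(size=(100, 2))))
        assert abs(np.mean(vals)) < 0.2

    def test_validation(self):
        with pytest.raises(ValueError):
            icc_agreement(np.zeros((4, 2)))  # too few subjects
        with pytest.raises(ValueError):
            icc_agreement(np.zeros((6, 3)))  # not two readers
        bad = np.zeros((6, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_agreement(bad)


class TestROC:
    def test_perfect_separation(self):
        r = roc_analysis([1, 2, 3, 10, 11, 12],
                         np.array([False, False, False, True, True, True]))
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.youden == pytest.approx(1.0)

    def test_derived_pair_enumeration(self):
        # pos {2,4} vs neg {3,1}: 3 of 4 pairs favor positive
        r = roc_analysis([3, 1, 2, 4], np.array([False, False, True, True]))
        assert r.auc == pytest.approx(0.75)

    def test_youden_identity(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=40)
        lab = rng.random(40) > 0.5
        r = roc_analysis(v, lab)
        assert r.youden == pytest.approx(r.sensitivity + r.specificity - 1.0)

    def test_auc_u_duality(self):
        # AUC * n1 * n2 equals the Mann-Whitney U statistic, ties halved
        for seed in range(5):
            rng = np.random.default_rng(seed)
            v = np.round(rng.normal(size=30), 1)  # rounding induces ties
            lab = rng.random(30) > 0.4
            if lab.all() or not lab.any():
                continue
            r = roc_analysis(v, lab)
            u, _ = mann_whitney(v[lab], v[~lab])
            n1, n2 = lab.sum(), (~lab).sum()
            auc_raw = u / (n1 * n2)
            assert r.auc == pytest.approx(max(auc_raw, 1 - auc_raw))

    def test_direction_auto_orientation(self):
        v = np.array([10.0, 9.0, 8.0, 1.0, 2.0, 3.0])
        lab = np.array([False, False, False, True, True, True])
        r = roc_analysis(v, lab)
        assert r.direction == "less"
        assert r.auc == 1.0
        # positive predicted when value <= threshold
        assert np.all(v[lab] <= r.threshold)
        assert np.all(v[~lab] > r.threshold)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        v = rng.normal(size=30)
        lab = rng.random(30) > 0.5
        base = roc_analysis(v, lab)
        for tf in (np.exp, lambda x: 3 * x + 1):
            r = roc_analysis(tf(v), lab)
            assert r.auc == pytest.approx(base.auc)
            assert r.sensitivity == pytest.approx(base.sensitivity)
            assert r.specificity == pytest.approx(base.specificity)
            assert r.threshold == pytest.approx(tf(base.threshold))

    def test_youden_tie_favors_specificity(self):
        # cuts 2 and 3 both give Youden 0.5; the higher cut has spec 1.0
        v = np.array([1.0, 2.0, 3.0, 2.5, 4.0, 5.0, 0.5, 3.5])
        lab = np.array([False, False, False, False, True, True, True, True])
        r = roc_analysis(v, lab)
        cuts = np.unique(v)
        youd = [( (v[lab] > c).mean() + (v[~lab] <= c).mean() - 1) for c in cuts]
        best = max(youd)
        tied = [c for c, j in zip(cuts, youd) if np.isclose(j, best)]
        specs = [(v[~lab] <= c).mean() for c in tied]
        assert r.threshold == tied[int(np.argmax(specs))]

    def test_published_cutoff_classification(self):
        # at the published optimal SPF cutoff 19.26% with direction 'greater'
        threshold, direction = 19.26, "greater"
        assert (23.56 > threshold) == (direction == "greater")  # high grade
        assert not (10.47 > threshold)  # low grade

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1, 2, 3], np.array([True, True, True]))


class TestDeLong:
    def test_identical_inputs_degenerate(self):
        v = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2])
        lab = np.array([False, False, False, True, True, True])
        res = delong_test(v, v, lab)
        assert res.delta == 0.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_variance_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(2)
        lab = np.array([False] * 5 + [True] * 5)
        v1 = np.round(rng.normal(lab * 1.0, 1.0), 3)
        v2 = np.round(rng.normal(lab * 1.0, 1.0), 3)
        res = delong_test(v1, v2, lab)
        # paired bootstrap over subjects (independent oracle)
        brng = np.random.default_rng(102)
        deltas = []
        while len(deltas) < 10000:
            idx = brng.integers(0, 10, 10)
            bl = lab[idx]
            if bl.all() or not bl.any():
                continue
            deltas.append(_placements(v1[idx], bl)[2] - _placements(v2[idx], bl)[2])
        assert res.variance_of_delta == pytest.approx(np.var(deltas), rel=0.15)

    def test_strong_vs_random_predictor(self):
        rng = np.random.default_rng(8)
        lab = rng.random(100) > 0.5
        strong = lab + rng.normal(0, 0.3, 100)
        random = rng.normal(size=100)
        res = delong_test(strong, random, lab)
        assert res.p_value < 0.01
        assert res.delta == pytest.approx(res.auc_1 - res.auc_2)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            delong_test([1, 2], [1, 2, 3], np.array([True, False, True]))


class TestLOOCV:
    def test_perfect_separation(self):
        acc, preds = loocv_accuracy(
            [1, 2, 3, 10, 11, 12],
            np.array([False, False, False, True, True, True]),
        )
        assert acc == 1.0
        assert preds == [False, False, False, True, True, True]

    def test_random_labels_near_half(self):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            v = rng.normal(size=40)
            lab = np.array([False, True] * 20)
            accs.append(loocv_accuracy(v, lab)[0])
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_six_point_fixture_manual_rederivation(self):
        # independent oracle: re-derive each fold's Youden cut by brute force
        v = np.array([1.0, 4.0, 5.0, 6.0, 7.0, 9.0])
        lab = np.array([False, True, False, True, False, True])
        acc, preds = loocv_accuracy(v, lab)

        def youden_cut(vals, labs):
            # orientation so auc >= 0.5, then max Youden, spec on ties
            auc = _placements(vals, labs)[2]
            direction = "greater" if auc >= 0.5 else "less"
            best = None
            for c in np.unique(vals):
                if direction == "greater":
                    se = (vals[labs] > c).mean()
                    sp = (vals[~labs] <= c).mean()
                else:
                    se = (vals[labs] <= c).mean()
                    sp = (vals[~labs] > c).mean()
                j = se + sp - 1
                if best is None or j > best[0] + 1e-12 or (
                    abs(j - best[0]) < 1e-12 and sp > best[2]
                ):
                    best = (j, c, sp, direction)
            return best

        expected = []
        for i in range(6):
            keep = np.ones(6, bool)
            keep[i] = False
            j, c, sp, direction = youden_cut(v[keep], lab[keep])
            above = v[keep][v[keep] > c]
            boundary = (c + above.min()) / 2.0 if above.size else c
            expected.append(
                bool(v[i] > boundary if direction == "greater" else v[i] <= boundary)
            )
        assert preds == expected
        assert acc == pytest.approx(np.mean([p == t for p, t in zip(expected, lab)]))

    def test_validation(self):
        with pytest.raises(ValueError):
            loocv_accuracy([1, 2, 3], np.array([True, False, True]))
        with pytest.raises(ValueError):
            loocv_accuracy([1, 2, 3, 4], np.array([True, True, True, True]))


class TestBonferroni:
    def test_twelve_comparison_level(self):
        assert round(bonferroni_alpha(0.05, 12), 3) == 0.004

    def test_trivial(self):
        assert bonferroni_alpha(0.05, 1) == 0.05
        assert bonferroni_alpha(0.01, 5) == pytest.approx(0.002)

    def test_errors(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_alpha(1.5, 3)


def small_table(n=24, seed=0):
    rng = np.random.default_rng(seed)
    lab = np.array(["low"] * (n // 2) + ["high"] * (n // 2))
    shift = (lab == "high") * 1.5
    return CohortTable(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "grade": lab,
        "SPF": rng.normal(10 + 5 * shift, 2, n),
        "Ktrans": rng.normal(0.05 + 0.05 * shift, 0.02, n).clip(0.001),
    }))


class TestCohortTable:
    def test_duplicate_subject_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "a"], "grade": ["low", "high"],
                           "SPF": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicated"):
            CohortTable(df)

    def test_bad_label_rejected(self):
        df = pd.DataFrame({"subject_id": ["a", "b"], "grade": ["low", "mid"],
                           "SPF": [1.0, 2.0]})
        with pytest.raises(ValueError, match="grade"):
            CohortTable(df)

    def test_reader_averaging(self):
        df = pd.DataFrame({
            "subject_id": ["a", "b", "c", "d"],
            "grade": ["low", "low", "high", "high"],
            "SPF_r1": [1.0, 2.0, 3.0, 4.0],
            "SPF_r2": [3.0, 4.0, 5.0, 6.0],
        })
        t = CohortTable(df).averaged()
        np.testing.assert_allclose(t.values("SPF"), [2.0, 3.0, 4.0, 5.0])


class TestCorrelationMatrix:
    def test_duplicate_column_rho_one(self):
        t = small_table()
        t.df["SPF2"] = t.df["SPF"]
        out = correlation_matrix(t, [("SPF", "SPF2")])
        assert out["rho"].iloc[0] == pytest.approx(1.0)

    def test_twelve_pairs_adjusted_alpha(self):
        t = small_table()
        pairs = [("SPF", "Ktrans")] * 12
        out = correlation_matrix(t, pairs)
        assert out.attrs["adjusted_alpha"] == pytest.approx(0.05 / 12)
        assert round(out.attrs["adjusted_alpha"], 3) == 0.004

    def test_unknown_column_rejected(self):
        with pytest.raises(KeyError):
            correlation_matrix(small_table(), [("SPF", "nope")])

    def test_copula_rank_correlation_target(self):
        specs = [
            GroupDistributionSpec("a", g, m, m / 1.5, m * 1.5)
            for g, m in (("low", 10.0), ("high", 20.0))
        ] + [
            GroupDistributionSpec("b", g, m, m / 2, m * 2)
            for g, m in (("low", 1.0), ("high", 2.0))
        ]
        corr = np.array([[1.0, 0.7], [0.7, 1.0]])
        t = make_cohort(specs, n_low=2000, n_high=2000, seed=5,
                        rank_correlation=corr)
        lab = t.labels
        rho, _ = spearman_rho(t.values("a")[lab], t.values("b")[lab])
        assert rho == pytest.approx(0.7, abs=0.05)


class TestGradingReport:
    def test_perfect_separation_auc_one(self):
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(10)],
            "grade": ["low"] * 5 + ["high"] * 5,
            "SPF": list(range(5)) + list(range(10, 15)),
        })
        rep = grading_report(CohortTable(df))
        row = rep["per_parameter"].iloc[0]
        assert row["parameter"] == "SPF"
        assert row["auc"] == 1.0

    def test_calibrated_cohort_structure(self):
        t = make_cohort(default_group_specs(), seed=3)
        rep = grading_report(t)
        per = rep["per_parameter"].set_index("parameter")
        assert set(per.index) == {
            "ADC_0_1000", "SPF", "f", "D", "D_star", "Ktrans", "v_e", "v_p"
        }
        assert ((per["auc"] >= 0.5) & (per["auc"] <= 1.0)).all()
        assert len(rep["delong"]) == 28  # all parameter pairs

    def test_empty_column_omitted(self, caplog):
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(10)],
            "grade": ["low"] * 5 + ["high"] * 5,
            "SPF": list(range(5)) + list(range(10, 15)),
            "Ktrans": [np.nan] * 10,
        })
        with caplog.at_level("WARNING"):
            rep = grading_report(CohortTable(df))
        assert list(rep["per_parameter"]["parameter"]) == ["SPF"]

    def test_reader_columns_used_as_mean(self):
        rng = np.random.default_rng(10)
        base = rng.normal(10, 3, 12) + np.array([0.0] * 6 + [5.0] * 6)
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(12)],
            "grade": ["low"] * 6 + ["high"] * 6,
            "SPF_r1": base - 0.5,
            "SPF_r2": base + 0.5,
        })
        rep = grading_report(CohortTable(df))
        df2 = df.copy()
        df2["SPF"] = base
        df2 = df2.drop(columns=["SPF_r1", "SPF_r2"])
        rep2 = grading_report(CohortTable(df2))
        pd.testing.assert_frame_equal(rep["per_parameter"], rep2["per_parameter"])
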