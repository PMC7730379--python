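import numpy as np
import pytest

from spotsim import MetricsError, anova_icc, build_report, quantile_accuracy, r2_curve


class TestR2Curve:
    def test_proportional_concentration_gives_unit_r2(self, rng):
        aucs = rng.lognormal(0, 1, 50)
        pools = {1: 3.7 * aucs}
        assert r2_curve(aucs, pools)[1] == pytest.approx(1.0, abs=1e-12)

    def test_three_point_exact_line(self):
        aucs = np.exp([0.0, 1.0, 2.0])
        pools = {1: np.exp([0.0, 1.0, 2.0])}
        assert r2_curve(aucs, pools)[1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_variables_have_near_zero_r2(self, rng):
        # null oracle: correlation of independent log-normal draws
        aucs = rng.lognormal(0, 1, 3000)
        pools = {1: rng.permutation(rng.lognormal(0, 1, 3000))}
        assert r2_curve(aucs, pools)[1] < 0.01

    def test_r2_matches_polyfit_regression(self, rng):
        # independent oracle: residual sum of squares of the least-squares line
        aucs = rng.lognormal(0, 0.7, 200)
        conc = aucs ** 0.8 * rng.lognormal(0, 0.3, 200)
        x, y = np.log(conc), np.log(aucs)
        slope, intercept = np.polyfit(x, y, 1)
        ss_res = np.sum((y - slope * x - intercept) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert r2_curve(aucs, {1: conc})[1] == pytest.approx(1 - ss_res / ss_tot, rel=1e-10)

    def test_nonpositive_concentration_raises_actionable_error(self, rng):
        aucs = rng.lognormal(0, 1, 10)
        with pytest.raises(MetricsError, match="accumulation"):
            r2_curve(aucs, {1: np.zeros(10)})

    def test_zero_variance_reported_missing_with_warning(self, rng):
        aucs = rng.lognormal(0, 1, 10)
        with pytest.warns(UserWarning, match="zero variance"):
            out = r2_curve(aucs, {1: np.ones(10)})
        assert np.isnan(out[1])

    def test_too_few_individuals_rejected(self):
        with pytest.raises(MetricsError):
            r2_curve(np.array([1.0, 2.0]), {1: np.array([1.0, 2.0])})


class TestQuantileAccuracy:
    def test_identical_rankings_fully_correct(self, rng):
        x = rng.lognormal(0, 1, 99)
        assert quantile_accuracy(x, x, 3) == 100.0

    def test_reversed_quartiles_fully_wrong(self):
        auc = np.array([1.0, 2.0, 3.0, 4.0])
        assert quantile_accuracy(auc, auc[::-1].copy(), 4) == 0.0

    def test_random_agreement_near_one_third(self, rng):
        # permutation oracle: independent rankings agree ~1/q per group
        auc = rng.lognormal(0, 1, 6000)
        conc = rng.permutation(auc)
        assert quantile_accuracy(auc, conc, 3) == pytest.approx(100 / 3, abs=3.0)
        assert quantile_accuracy(auc, conc, 4) == pytest.approx(25.0, abs=3.0)

    def test_remainder_goes_to_lower_groups(self):
        # 5 individuals in tertiles -> group sizes 2,2,1
        vals = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        from spotsim.metrics import _equal_count_groups

        assert _equal_count_groups(vals, 3).tolist() == [0, 0, 1, 1, 2]

    def test_ties_broken_by_stable_index(self):
        from spotsim.metrics import _equal_count_groups

        vals = np.array([1.0, 1.0, 1.0, 1.0])
        assert _equal_count_groups(vals, 4).tolist() == [0, 1, 2, 3]


class TestAnovaIcc:
    def test_hand_computed_three_by_three(self):
        # one-way ANOVA by hand on log values [[1,2,3],[2,3,4],[5,5,5]]:
        # MSB = 7, MSW = 2/3, ICC = (7 - 2/3)/(7 + 2*2/3) = 19/25
        x = np.exp([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [5.0, 5.0, 5.0]])
        icc, raw = anova_icc(x)
        assert icc == pytest.approx(19.0 / 25.0, abs=1e-12)
        assert raw == icc

    def test_agrees_with_pingouin_icc1(self, rng):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        x = rng.lognormal(0, 1, size=(12, 4)) * rng.lognormal(0, 1, 12)[:, None]
        _, raw = anova_icc(x)
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 4),
                "raters": np.tile(np.arange(4), 12),
                "ratings": np.log(x).ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, targets="targets", raters="raters", ratings="ratings")
        icc1 = ref.loc[ref["Type"] == "ICC(1,1)", "ICC"].item()
        assert raw == pytest.approx(icc1, rel=1e-8)

    def test_zero_within_variance_gives_one(self):
        x = np.exp([[0.0, 0.0], [1.0, 1.0]])
        icc, _ = anova_icc(x)
        assert icc == 1.0

    def test_exchangeable_data_gives_near_zero(self, rng):
        # oracle: no between-person effect => expected MSB ~ MSW
        x = rng.lognormal(0, 1, size=(2000, 3))
        icc, raw = anova_icc(x)
        assert icc < 0.05

    def test_negative_estimate_clipped_with_warning(self):
        # anti-correlated rows force MSB < MSW
        x = np.exp([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="clipped"):
            icc, raw = anova_icc(x)
        assert icc == 0.0 and raw < 0

    def test_unbalanced_or_single_sample_rejected(self):
        with pytest.raises(MetricsError):
            anova_icc(np.ones((5, 1)))
        with pytest.raises(MetricsError):
            anova_icc(np.ones(5))


class TestBuildReport:
    def test_report_shapes_and_boundaries(self, rng):
        aucs = rng.lognormal(0, 1, 40)
        mat = aucs[:, None] * rng.lognormal(0, 0.5, size=(40, 5))
        from spotsim import pooled_means

        report = build_report(aucs, pooled_means(mat), mat)
        assert sorted(report.r2_by_n) == [1, 2, 3, 4, 5]
        assert all(0 <= v <= 1 for v in report.r2_by_n.values())
        assert all(0 <= v <= 100 for v in report.tertile_accuracy_by_n.values())
        assert report.icc is not None and 0 <= report.icc <= 1
        assert len(report.scatter_max_n) == 40

    def test_single_sample_report_has_no_icc(self, rng):
        aucs = rng.lognormal(0, 1, 40)
        mat = aucs[:, None] * rng.lognormal(0, 0.5, size=(40, 1))
        from spotsim import pooled_means

        report = build_report(aucs, pooled_means(mat), mat)
        assert list(report.r2_by_n) == [1]
        assert report.icc is None
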