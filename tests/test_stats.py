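"""Inference layer: ANOVA, Tukey HSD, regression, assumption validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cocomorph import PopulationSpec
from cocomorph.measure import SampleTable
from cocomorph.stats import (analyze_study, influential_points,
                             linear_regression, one_way_anova,
                             regress_with_validation, resolvable_difference,
                             studentized_range_cdf, tukey_hsd,
                             validate_assumptions)
from cocomorph.synth import simulate_study


class TestOneWayAnova:
    FIXTURE = [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [3.0, 4.0, 5.0]]

    def test_hand_computed_decomposition(self):
        # group means 2,3,4; grand mean 3 → SSB = 3·(1+0+1) = 6; SSW = 6
        an = one_way_anova(self.FIXTURE)
        assert an.ss_between == pytest.approx(6.0)
        assert an.ss_within == pytest.approx(6.0)
        assert (an.df_between, an.df_within) == (2, 6)
        assert an.f == pytest.approx(3.0)
        assert an.p == pytest.approx(float(sps.f.sf(3.0, 2, 6)))

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(i * 0.3, 1.0, 12) for i in range(4)]
        an = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert an.f == pytest.approx(ref.statistic, rel=1e-10)
        assert an.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_decomposition_identity(self, rng):
        groups = [rng.normal(0, 1, 10), rng.normal(0.5, 1, 15),
                  rng.normal(1, 2, 8)]
        an = one_way_anova(groups)
        allv = np.concatenate(groups)
        sst = np.sum((allv - allv.mean()) ** 2)
        assert an.ss_total == pytest.approx(sst, rel=1e-12)

    def test_identical_groups_give_f0_p1(self):
        an = one_way_anova([[1, 1, 1], [1, 1, 1]])
        assert an.f == 0.0 and an.p == 1.0

    def test_group_of_one_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0, 2.0], [3.0]])

    def test_f_invariant_under_affine_transform(self, rng):
        groups = [rng.normal(i, 1, 10) for i in range(3)]
        an1 = one_way_anova(groups)
        an2 = one_way_anova([7.3 * g - 11.0 for g in groups])
        assert an2.f == pytest.approx(an1.f, rel=1e-9)


class TestStudentizedRange:
    def test_zero_q_gives_zero(self):
        assert studentized_range_cdf(0.0, 3, 10) == 0.0

    def test_monotone_in_q(self):
        vals = [studentized_range_cdf(q, 4, 20)
                for q in (0.5, 1.5, 3.0, 5.0)]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_k2_large_df_normal_difference_limit(self):
        # for k=2, df→∞: P(q ≤ x) → 2Φ(x/√2) − 1
        for q in (1.0, 2.0, 3.5):
            limit = 2 * sps.norm.cdf(q / np.sqrt(2)) - 1
            assert studentized_range_cdf(q, 2, 10000) == pytest.approx(
                limit, abs=1e-3)

    def test_against_monte_carlo_oracle(self):
        q, k, df = 3.2, 3, 12
        rng = np.random.default_rng(123)
        reps = 40000
        z = rng.normal(size=(reps, k))
        s = np.sqrt(rng.chisquare(df, size=reps) / df)
        qs = (z.max(axis=1) - z.min(axis=1)) / s
        mc = (qs <= q).mean()
        se = np.sqrt(mc * (1 - mc) / reps)
        assert studentized_range_cdf(q, k, df) == pytest.approx(mc,
                                                                abs=3 * se)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            studentized_range_cdf(1.0, 1, 10)
        with pytest.raises(ValueError):
            studentized_range_cdf(-1.0, 3, 10)


class TestTukeyHsd:
    def test_identical_groups_all_null(self):
        res = tukey_hsd([[1.0, 1.0, 1.0]] * 3)
        assert (res.pairs["diff"] == 0).all()
        assert (res.pairs["p_adj"] == 1.0).all()

    def test_k2_reduces_to_pooled_t_test(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 15)
        res = tukey_hsd([a, b])
        t_p = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert res.pairs["p_adj"].iloc[0] == pytest.approx(t_p, rel=1e-6)

    def test_adjusted_p_at_least_pairwise_p_for_k3(self, rng):
        groups = [rng.normal(m, 1.0, 10) for m in (0.0, 0.5, 1.1)]
        res = tukey_hsd(groups)
        for _, row in res.pairs.iterrows():
            i, j = int(row["group_i"]), int(row["group_j"])
            t_p = sps.ttest_ind(groups[i], groups[j], equal_var=True).pvalue
            assert row["p_adj"] >= t_p - 1e-12

    def test_matches_scipy_tukey_hsd(self, rng):
        groups = [rng.normal(m, 1.0, 11) for m in (0.0, 0.4, 1.0)]
        res = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for _, row in res.pairs.iterrows():
            i, j = int(row["group_i"]), int(row["group_j"])
            assert row["p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-3)
            assert row["diff"] == pytest.approx(
                -ref.statistic[i, j], rel=1e-9)

    def test_confidence_limits_bracket_difference(self, rng):
        groups = [rng.normal(m, 1.0, 9) for m in (0, 1, 2)]
        res = tukey_hsd(groups)
        assert (res.pairs["lower"] <= res.pairs["diff"]).all()
        assert (res.pairs["diff"] <= res.pairs["upper"]).all()


class TestLinearRegression:
    def test_collinear_data_is_perfect_fit(self):
        x = np.arange(1.0, 6.0)
        reg = linear_regression(x, 2.0 * x + 1.0)
        assert reg.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(reg.residuals, 0.0, atol=1e-10)

    def test_constant_response_has_zero_slope(self):
        reg = linear_regression([1, 2, 3, 4], [5.0, 5.0, 5.0, 5.0])
        assert reg.slope == pytest.approx(0.0, abs=1e-12)
        assert reg.r2 == 0.0

    def test_five_point_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 2.9, 4.2, 4.8, 6.3])
        X = np.column_stack([np.ones(5), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        reg = linear_regression(x, y)
        assert reg.intercept == pytest.approx(beta[0], rel=1e-10)
        assert reg.slope == pytest.approx(beta[1], rel=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([2, 2, 2, 2], [1, 2, 3, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1, 2], [1, 2])


class TestAssumptionValidation:
    def test_global_stat_is_sum_of_components(self, rng):
        x = rng.uniform(2, 4, 30)
        y = 1 + 0.4 * x + rng.normal(0, 0.2, 30)
        rep = validate_assumptions(linear_regression(x, y))
        total = (rep.stat_skewness + rep.stat_kurtosis + rep.stat_link
                 + rep.stat_heteroscedasticity)
        assert rep.global_stat == pytest.approx(total, rel=1e-12)

    def test_level_near_nominal_on_gaussian_data(self):
        rng = np.random.default_rng(99)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.uniform(2, 4, 30)
            y = 1 + 0.5 * x + rng.normal(0, 0.3, 30)
            rep = validate_assumptions(linear_regression(x, y))
            rejections += rep.global_p < 0.05
        assert 0.02 <= rejections / reps <= 0.09

    def test_heteroscedasticity_component_has_power(self):
        rng = np.random.default_rng(7)
        hits = 0
        reps = 60
        for _ in range(reps):
            x = rng.uniform(0.5, 12, 100)
            mu = 1 + x
            y = mu + rng.normal(0, np.sqrt(0.3 * mu))  # var ∝ fitted
            rep = validate_assumptions(linear_regression(x, y))
            hits += rep.p_heteroscedasticity < 0.05
        assert hits / reps > 0.8

    def test_log_linear_data_triggers_log_transform(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 6, 120)
        y = 0.5 * x ** 2.0 * np.exp(rng.normal(0, 0.45, 120))
        reg, rep = regress_with_validation(x, y)
        assert rep.decision == "log-transform"
        assert reg.transform == "log-log"
        assert reg.slope == pytest.approx(2.0, abs=0.3)

    def test_small_sample_rejected(self):
        reg = linear_regression([1, 2, 3, 4], [1.1, 2.0, 2.8, 4.2])
        with pytest.raises(ValueError):
            validate_assumptions(reg)


class TestInfluentialPoints:
    def test_injected_outlier_is_flagged(self, rng):
        x = rng.uniform(0, 10, 40)
        y = 2 + 0.5 * x + rng.normal(0, 0.3, 40)
        y[17] += 10 * 0.3
        reg = linear_regression(x, y)
        assert 17 in influential_points(reg)

    def test_clean_gaussian_flag_rate_conservative(self):
        """On clean data the envelope is conservative: studentization pins
        the residual scale, so the mean flag rate sits well below the
        pointwise 5 % level (clean samples rarely leave the envelope) while
        genuine outliers are still caught (previous test)."""
        rng = np.random.default_rng(21)
        n, reps = 200, 100
        rates = []
        for _ in range(reps):
            x = rng.uniform(0, 10, n)
            y = 1 + x + rng.normal(0, 1, n)
            rates.append(
                len(influential_points(linear_regression(x, y))) / n)
        assert np.mean(rates) <= 0.05
        assert any(r > 0 for r in rates)

    def test_perfect_tiny_fit_flags_nothing(self):
        reg = linear_regression([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert influential_points(reg) == []


class TestResolvability:
    def test_length_thresholds(self):
        assert not resolvable_difference(0.3, 0.2)
        assert resolvable_difference(0.4, 0.2)
        assert not resolvable_difference(0.0, 0.2)

    def test_sign_irrelevant(self):
        assert resolvable_difference(-0.5, 0.2)

    def test_negative_uncertainty_rejected(self):
        with pytest.raises(ValueError):
            resolvable_difference(0.3, -0.1)


class TestAnalyzeStudy:
    @staticmethod
    def _study(coupling, seed, slope=0.037):
        design = [("S1", sal,
                   PopulationSpec(n=30, mean_length=2.7, sd_length=0.27,
                                  salinity_slope=slope,
                                  reference_salinity=34.0,
                                  coupling=coupling, coupling_c=0.025,
                                  thickness_intercept=0.067,
                                  sd_thickness=0.004))
                  for sal in (25.0, 34.0, 44.0)]
        bundle = simulate_study(design, seed=seed)
        return [SampleTable(strain=s, salinity=sal,
                            data=g.reset_index(drop=True))
                for (s, sal), g in
                bundle.tables.groupby(["strain", "salinity"])]

    def test_decoupled_study_shows_length_but_not_thickness_effect(self):
        report = analyze_study(self._study("decoupled", seed=42))
        an = report.anova.set_index("metric")
        assert an.loc["length_um", "significant"]
        assert not an.loc["mean_thickness_um", "significant"]

    def test_isometric_study_shows_both_effects_and_coupling(self):
        report = analyze_study(self._study("isometric", seed=42))
        an = report.anova.set_index("metric")
        assert an.loc["length_um", "significant"]
        assert an.loc["mean_thickness_um", "significant"]
        regs = report.regressions
        lt = regs[(regs.y == "mean_thickness_um")]
        assert lt["significant"].all()

    def test_single_salinity_strain_skipped(self, caplog):
        tables = self._study("decoupled", seed=1)[:1]
        report = analyze_study(tables)
        assert report.anova.empty

    def test_tukey_rows_carry_resolvability_flags(self):
        report = analyze_study(self._study("decoupled", seed=42,
                                           slope=0.037))
        assert not report.tukey.empty
        assert {"significant", "resolved"} <= set(report.tukey.columns)
        # resolved differences are a subset of significant ones
        assert (~report.tukey["resolved"]
                | report.tukey["significant"]).all()
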