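import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from stromaprox import (
    CohortSpec,
    classify_status_5y,
    fit_cox_single,
    fit_radial_trend,
    generate_cohort,
    rank_compare,
    relative_hazard,
    sensitivity_with_covariate,
)
from stromaprox.stats import (
    RadialTrendModel,
    SinglePredictorCox,
    _gaussian_binomial_counts,
    _signed_rank_counts,
)
from stromaprox.stats import test_proportional_hazards as schoenfeld_ph_test


class TestClassifyStatus5y:
    @pytest.mark.parametrize(
        "t, event, expected",
        [
            (24.0, True, "recurrent"),
            (72.0, False, "non-recurrent"),
            (36.0, False, "unclassifiable"),  # censored short of 5 years
            (80.0, True, "non-recurrent"),  # event after the horizon
            (60.0, True, "recurrent"),  # boundary: event at exactly 5 years
        ],
    )
    def test_rule(self, t, event, expected):
        assert classify_status_5y(t, event) == expected

    def test_partitions_every_subject(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(1, 120, 500)
        e = rng.random(500) < 0.4
        status = classify_status_5y(t, e)
        assert set(np.unique(status)) <= {"recurrent", "non-recurrent", "unclassifiable"}
        assert len(status) == 500

    def test_invalid_times_rejected(self):
        with pytest.raises(ValueError, match="inconsistent record"):
            classify_status_5y(np.array([0.0]), np.array([True]))


class TestRadialTrend:
    def test_noise_free_slope_exact(self):
        spec = CohortSpec(n_subjects=8, sd_intercept=0, sd_slope=0, sd_residual=0, seed=1)
        _, bands = generate_cohort(spec)
        fit = fit_radial_trend(bands)
        assert fit.slope_ == pytest.approx(spec.pe_slope, abs=1e-6)

    def test_single_subject_equals_ols(self):
        spec = CohortSpec(n_subjects=2, sd_residual=2.0, seed=2)
        _, bands = generate_cohort(spec)
        one = bands[bands["subject"] == "S0000"]
        fit = RadialTrendModel().fit(one)
        ols_slope = np.polyfit(one["distance_mm"], one["pe"], 1)[0]
        assert fit.fallback_
        assert fit.slope_ == pytest.approx(ols_slope, abs=1e-9)

    def test_fit_reports_uncertainty_and_random_effects(self):
        spec = CohortSpec(n_subjects=40, seed=3)
        _, bands = generate_cohort(spec)
        fit = fit_radial_trend(bands)
        lo, hi = fit.slope_ci_
        assert lo < fit.slope_ < hi
        assert fit.slope_se_ > 0
        assert all(v >= 0 for v in fit.random_effects_var_.values())
        theo, sample = fit.qq_data()
        assert len(theo) == len(sample) == len(bands)

    def test_group_factor_reports_slope_difference(self):
        rng = np.random.default_rng(4)
        rows = []
        mids = np.arange(7.5, 40, 5.0)
        for i in range(30):
            group = "rec" if i < 15 else "nonrec"
            slope = -0.45 if group == "rec" else -0.40
            b0 = rng.normal(0, 3)
            for d in mids:
                rows.append(
                    {
                        "subject": f"S{i}",
                        "group": group,
                        "distance_mm": d,
                        "pe": 25 + b0 + slope * d + rng.normal(0, 1),
                    }
                )
        fit = RadialTrendModel(group_col="group").fit(pd.DataFrame(rows))
        assert set(fit.group_slopes_) == {"rec", "nonrec"}
        diff = fit.slope_difference_
        assert diff["ci"][0] < diff["difference"] < diff["ci"][1]
        # estimated per-group slopes near their truths
        assert fit.group_slopes_["rec"] == pytest.approx(-0.40, abs=0.1)
        assert fit.group_slopes_["nonrec"] == pytest.approx(-0.45, abs=0.1)

    def test_requires_two_distances(self):
        df = pd.DataFrame({"subject": ["a", "b"], "distance_mm": [5.0, 5.0], "pe": [1.0, 2.0]})
        with pytest.raises(ValueError, match="two distinct distances"):
            fit_radial_trend(df)


class TestRankCompare:
    def test_constant_shift_unpaired(self):
        res = rank_compare(np.array([1.0, 2, 3]), np.array([11.0, 12, 13]))
        assert res.test == "rank-sum"
        assert res.hl_estimate == pytest.approx(-10.0)

    def test_identical_groups_p_one(self):
        x = np.array([5.0, 5, 5, 5])
        res = rank_compare(x, x.copy())
        assert res.p_value == 1.0 and res.all_tied and res.hl_estimate == 0.0

    def test_paired_constant_shift(self):
        x = np.arange(10.0)
        res = rank_compare(x + 2.5, x, paired=True)
        assert res.test == "signed-rank"
        assert res.hl_estimate == pytest.approx(2.5)
        assert res.ci[0] <= 2.5 <= res.ci[1]

    def test_pure_location_shift_hl_is_exact_constant(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 40)
        res = rank_compare(base + 3.0, base, paired=True)
        assert res.hl_estimate == pytest.approx(3.0, abs=1e-12)

    def test_unpaired_ci_covers_truth_and_inverts_test(self):
        rng = np.random.default_rng(6)
        x = rng.normal(3.0, 1.0, 30)
        y = rng.normal(0.0, 1.0, 25)
        res = rank_compare(x, y)
        assert res.ci[0] < 3.0 < res.ci[1]
        assert res.p_value < 0.001

    def test_small_sample_results_match_r_oracle(self):
        # frozen oracle: R wilcox.test(x, y, conf.int=TRUE) on these data
        # reports HL 0.770, CI (-0.430, 1.602), p 0.420635; the paired call
        # on d reports HL 0.800, CI (-0.100, 1.500), p 0.054688
        x = np.array([1.83, 0.50, 1.62, 2.48, 1.68])
        y = np.array([0.878, 0.647, 0.598, 2.05, 1.06])
        res = rank_compare(x, y)
        assert res.hl_estimate == pytest.approx(0.770, abs=1e-9)
        assert res.ci[0] == pytest.approx(-0.430, abs=1e-9)
        assert res.ci[1] == pytest.approx(1.602, abs=1e-9)
        assert res.p_value == pytest.approx(0.420635, abs=1e-4)

        d = np.array([1.5, -0.2, 0.8, 2.1, 0.3, 1.1, -0.5, 0.9])
        resp = rank_compare(d, np.zeros_like(d), paired=True)
        assert resp.hl_estimate == pytest.approx(0.800, abs=1e-9)
        assert resp.ci[0] == pytest.approx(-0.100, abs=1e-9)
        assert resp.ci[1] == pytest.approx(1.500, abs=1e-9)
        assert resp.p_value == pytest.approx(0.054688, abs=1e-4)

    def test_ci_coverage_near_nominal(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            d = 1.0 + rng.normal(0, 2, 25)
            res = rank_compare(d, np.zeros(25), paired=True)
            hits += res.ci[0] <= 1.0 <= res.ci[1]
        assert 0.89 <= hits / n_rep <= 0.99

    def test_minimum_sizes_enforced(self):
        with pytest.raises(ValueError):
            rank_compare(np.array([1.0, 2]), np.array([1.0, 2, 3]))
        with pytest.raises(ValueError):
            rank_compare(np.array([1.0, 2]), np.array([1.0, 2]), paired=True)


class TestNullDistributions:
    def test_signed_rank_counts_sum_and_symmetry(self):
        n = 8
        counts = _signed_rank_counts(n)
        assert counts.sum() == 2**n
        np.testing.assert_array_equal(counts, counts[::-1])
        # moments match the classical formulas via the scipy null
        w = sps.wilcoxon(np.arange(1.0, n + 1), alternative="two-sided")
        assert w.pvalue == pytest.approx(2 / 2**n)

    def test_mannwhitney_counts_match_scipy_exact_p(self):
        m, n = 4, 5
        counts = _gaussian_binomial_counts(m, n)
        from math import comb

        assert counts.sum() == comb(m + n, m)
        # P(U <= u) from enumeration equals scipy's exact distribution
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        p = sps.mannwhitneyu(x, y, alternative="less", method="exact").pvalue
        assert counts[0] / counts.sum() == pytest.approx(p)


class TestCox:
    def _cohort(self, beta, seed, n=1500, sd=1.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, sd, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(beta * x)))
        c = rng.uniform(0, 60, n)
        return np.minimum(t, c), t <= c, x

    def test_null_predictor_hr_near_one(self):
        t, e, x = self._cohort(0.0, 8)
        fit = fit_cox_single(t, e, x)
        assert fit.hazard_ratio == pytest.approx(1.0, abs=0.1)
        assert fit.wald_ci[0] < 1.0 < fit.wald_ci[1]

    def test_unit_rescaling_halves_log_hr(self):
        t, e, x = self._cohort(0.4, 9)
        fit1 = fit_cox_single(t, e, x)
        fit2 = fit_cox_single(t, e, 2 * x)
        assert fit2.log_hr == pytest.approx(fit1.log_hr / 2, rel=1e-6)

    def test_recovers_known_hrs_at_large_n(self):
        # magnitudes matching the cohort analyses: strong protective and
        # weak adverse per-unit effects
        for hr, sd in [(0.058, 0.15), (1.22, 1.0)]:
            t, e, x = self._cohort(np.log(hr), seed=abs(hash(hr)) % 2**31, n=2000, sd=sd)
            fit = fit_cox_single(t, e, x)
            se = 1.0 / np.sqrt(fit.n_events * sd**2)
            assert abs(fit.log_hr - np.log(hr)) < 3 * se

    def test_estimator_interface(self):
        t, e, x = self._cohort(0.3, 10)
        est = SinglePredictorCox().fit(t, e, x)
        assert est.hazard_ratio_ > 1.0
        assert est.wald_ci_[0] < est.hazard_ratio_ < est.wald_ci_[1]
        np.testing.assert_allclose(est.predict(np.array([0.0])), [1.0])
        params = est.get_params()
        assert "check_ph" in params

    def test_requires_events_and_variation(self):
        t = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="event"):
            fit_cox_single(t, np.zeros(3, dtype=bool), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="variation"):
            fit_cox_single(t, np.array([True, True, False]), np.ones(3))


class TestProportionalHazards:
    def test_ph_consistent_data_rarely_rejected(self):
        rejections = 0
        n_rep = 40
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x = rng.normal(0, 1, 300)
            t = rng.exponential(1.0 / (0.05 * np.exp(0.4 * x)))
            c = rng.uniform(0, 60, 300)
            est = SinglePredictorCox(check_ph=True).fit(np.minimum(t, c), t <= c, x)
            rejections += est.summary_.ph_p < 0.05
        # type-I error near alpha: allow generous binomial slack at 40 reps
        assert rejections / n_rep <= 0.2

    def test_time_varying_effect_detected(self):
        # effect reverses over follow-up: scaled Schoenfeld test should flag it
        rng = np.random.default_rng(99)
        n = 500
        x = rng.normal(0, 1, n)
        # piecewise hazard: strong positive effect early, none late
        t_early = rng.exponential(1.0 / (0.25 * np.exp(1.5 * x)))
        t = np.where(t_early < 4.0, t_early, 4.0 + rng.exponential(1.0 / 0.25, n))
        e = np.ones(n, dtype=bool)
        est = SinglePredictorCox(check_ph=True).fit(t, e, x)
        assert est.summary_.ph_p < 0.05

    def test_too_few_events_flagged(self):
        df = pd.DataFrame(
            {"time": [1.0, 2, 3, 4], "event": [1, 0, 0, 0], "x": [1.0, 2, 3, 4]}
        )
        est = SinglePredictorCox().fit(df["time"], df["event"].astype(bool), df["x"])
        with pytest.raises(ValueError, match="undefined"):
            schoenfeld_ph_test(est.fitter_, df, "x")


class TestSensitivityAnalysis:
    def test_independent_covariate_leaves_hr(self):
        rng = np.random.default_rng(11)
        n = 1500
        x = rng.normal(0, 1, n)
        cov = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.5 * x)))
        c = rng.uniform(0, 60, n)
        out = sensitivity_with_covariate(np.minimum(t, c), t <= c, x, cov)
        assert not out["collinear"]
        assert out["adjusted_hr"] == pytest.approx(out["unadjusted"].hazard_ratio, rel=0.05)

    def test_duplicate_covariate_flags_collinearity(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 200)
        t = rng.exponential(1.0, 200)
        out = sensitivity_with_covariate(t, np.ones(200, dtype=bool), x, x.copy())
        assert out["collinear"] and out["adjusted"] is None

    def test_null_covariate_p_not_small(self):
        rng = np.random.default_rng(13)
        n = 1000
        x = rng.normal(0, 1, n)
        cov = rng.normal(0, 1, n)
        t = rng.exponential(1.0 / (0.05 * np.exp(0.4 * x)))
        c = rng.uniform(0, 60, n)
        out = sensitivity_with_covariate(np.minimum(t, c), t <= c, x, cov)
        assert out["covariate_p"] > 0.01


class TestRelativeHazard:
    def test_compounding(self):
        assert relative_hazard(1.017, 10) == pytest.approx(1.017**10)

    def test_identity_and_errors(self):
        assert relative_hazard(1.0, 50) == 1.0
        with pytest.raises(ValueError):
            relative_hazard(0.0, 1)
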