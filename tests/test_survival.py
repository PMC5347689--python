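"""KM summaries, log-rank, Cox HRs and the treatment x biomarker
interaction test, checked against hand-computed and analytic oracles."""

import numpy as np
import pandas as pd
import pytest

from e2fscore import (
    CohortSpec,
    CoxConvergenceError,
    TrialDesign,
    cohort_report,
    cox_hr,
    generate_cohort,
    generate_trial,
    interaction_test,
    km_summary,
    logrank,
)
from conftest import make_clinical


class TestKMSummary:
    def test_no_censoring_equals_empirical_sf(self):
        clin = make_clinical([1, 2, 3, 4], [1, 1, 1, 1])
        km = km_summary(clin, endpoint="os")["all"]
        curve = km.curve.set_index("time")["survival"]
        # S drops by 1/4 at each event time; S(2.5) = 0.5; median = 2
        np.testing.assert_allclose(curve.loc[[1, 2, 3, 4]], [0.75, 0.5, 0.25, 0.0])
        assert km.median == 2

    def test_all_censored_median_not_reached(self):
        clin = make_clinical([10, 20, 30], [0, 0, 0])
        km = km_summary(clin, endpoint="os")["all"]
        assert km.median is None
        assert km.rate_at_horizon == 1.0
        assert km.rate_ci == (1.0, 1.0)

    def test_hand_computed_km_and_greenwood(self):
        """Six subjects, one censored at t=3: product-limit steps and the
        exponential-Greenwood (log-log) CI computed from first principles."""
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 0, 1, 1, 1]
        clin = make_clinical(times, events)
        km = km_summary(clin, endpoint="os", horizon_months=4.5)["all"]

        # hand KM: drops at 1, 2 (n=6, 5), censor at 3, drops at 4, 5, 6 (n=3, 2, 1)
        surv = {}
        s = 1.0
        var_sum = 0.0  # Greenwood accumulator sum d / (n (n - d))
        at_risk = 6
        for t, d, c in [(1, 1, 0), (2, 1, 0), (3, 0, 1), (4, 1, 0), (5, 1, 0), (6, 1, 0)]:
            if d:
                s *= (at_risk - d) / at_risk
                if at_risk > d:  # Greenwood term undefined once S hits 0
                    var_sum += d / (at_risk * (at_risk - d))
            surv[t] = (s, var_sum)
            at_risk -= d + c
        curve = km.curve.set_index("time")
        for t, (s_hand, _) in surv.items():
            assert curve.loc[t, "survival"] == pytest.approx(s_hand, abs=1e-10)

        # horizon 4.5 sits on the S(4) step: S = 4/6 * 3/4 = 0.5
        s4, v4 = surv[4]
        assert km.rate_at_horizon == pytest.approx(s4, abs=1e-10)
        # exponential Greenwood: CI = exp(-exp(log(-log S) +/- z * sqrt(v)))
        # with v = var_sum / (log S)^2
        z = 1.959963984540054
        c = np.log(-np.log(s4))
        half = z * np.sqrt(v4 / np.log(s4) ** 2)
        lo, hi = np.exp(-np.exp(c + half)), np.exp(-np.exp(c - half))
        assert km.rate_ci[0] == pytest.approx(lo, abs=1e-10)
        assert km.rate_ci[1] == pytest.approx(hi, abs=1e-10)

    def test_per_group_summaries(self):
        clin = make_clinical([1, 2, 3, 10, 20, 30], [1, 1, 1, 1, 1, 1])
        labels = pd.Series(
            ["high"] * 3 + ["low"] * 3, index=clin["sample_id"]
        )
        km = km_summary(clin, labels=labels)
        assert km["high"].n == 3 and km["low"].n == 3
        assert km["high"].median < km["low"].median


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        times = [1, 2, 3, 4, 5]
        events = [1, 1, 0, 1, 1]
        clin = pd.concat(
            [
                make_clinical(times, events, sample_prefix="A"),
                make_clinical(times, events, sample_prefix="B"),
            ],
            ignore_index=True,
        )
        labels = pd.Series(["g1"] * 5 + ["g2"] * 5, index=clin["sample_id"])
        chi2, p = logrank(clin, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_observed_minus_expected_oracle(self):
        """Definitional log-rank: sum over event times of (observed -
        expected) deaths in group 1, variance by the hypergeometric
        formula, statistic = U^2 / V."""
        times = [3.0, 5.0, 7.0, 2.0, 4.0, 6.0, 8.0]
        events = [1, 1, 0, 1, 1, 1, 1]
        group = np.array([1, 1, 1, 0, 0, 0, 0])
        clin = make_clinical(times, events)
        labels = pd.Series(np.where(group, "g1", "g0"), index=clin["sample_id"])

        t = np.asarray(times)
        e = np.asarray(events)
        u = 0.0
        v = 0.0
        for et in sorted(t[e == 1]):
            at_risk = t >= et
            n = at_risk.sum()
            n1 = (at_risk & (group == 1)).sum()
            d = ((t == et) & (e == 1)).sum()
            d1 = ((t == et) & (e == 1) & (group == 1)).sum()
            u += d1 - d * n1 / n
            if n > 1:
                v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        chi2_oracle = u**2 / v
        chi2, _ = logrank(clin, labels)
        assert chi2 == pytest.approx(chi2_oracle, abs=1e-10)

    def test_invariant_to_monotone_time_transform(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(10, 30) + 0.1
        events = rng.integers(0, 2, 30)
        events[0] = 1
        clin1 = make_clinical(times, events)
        clin2 = make_clinical(times**2, events)
        labels = pd.Series(
            np.where(np.arange(30) % 2 == 0, "a", "b"), index=clin1["sample_id"]
        )
        assert logrank(clin1, labels) == pytest.approx(logrank(clin2, labels))

    def test_null_rejection_rate_near_nominal(self):
        """Median-split classification of null data rejects at ~5%."""
        from e2fscore import ScoreSet, classify_by_percentile

        rng = np.random.default_rng(6)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            n = 100
            times = rng.exponential(50, n)
            events = (times <= 60).astype(int)
            clin = make_clinical(np.minimum(times, 60), events)
            scores = ScoreSet(scores=pd.Series(rng.normal(size=n), index=clin["sample_id"]))
            labelled = classify_by_percentile(scores, 50)
            _, p = logrank(clin, labelled.labels)
            rejections += p < 0.05
        rate = rejections / n_reps
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < 3 * se

    def test_zero_events_rejected(self):
        clin = make_clinical([1, 2], [0, 0])
        labels = pd.Series(["a", "b"], index=clin["sample_id"])
        with pytest.raises(ValueError):
            logrank(clin, labels)


class TestCoxHR:
    def test_null_labels_give_unit_hr(self):
        rng = np.random.default_rng(7)
        n = 2000
        times = rng.exponential(40, n)
        clin = make_clinical(np.minimum(times, 120), (times <= 120).astype(int))
        labels = pd.Series(
            np.where(rng.random(n) < 0.5, "high", "low"), index=clin["sample_id"]
        )
        hr, lo, hi, p = cox_hr(clin, labels)
        assert 0.9 <= hr <= 1.1
        assert lo <= 1.0 <= hi

    def test_recovers_true_hazard_ratio_two(self):
        rng = np.random.default_rng(8)
        n = 2000
        group = rng.random(n) < 0.5
        rate = np.where(group, 2.0 / 50.0, 1.0 / 50.0)
        times = rng.exponential(1 / rate)
        clin = make_clinical(np.minimum(times, 150), (times <= 150).astype(int))
        labels = pd.Series(np.where(group, "high", "low"), index=clin["sample_id"])
        hr, lo, hi, _ = cox_hr(clin, labels)
        assert 1.8 <= hr <= 2.2
        assert lo <= 2.0 <= hi

    def test_covariate_adjustment_accepts_stage(self):
        _, clin = generate_cohort(CohortSpec(n_patients=300, seed=13))
        labels = pd.Series(
            np.where(clin["latent_activity"] > clin["latent_activity"].median(), "high", "low"),
            index=clin["sample_id"],
        )
        hr_adj, *_ = cox_hr(clin, labels, covariates=["stage"])
        assert hr_adj > 1.0

    def test_event_free_group_raises(self):
        clin = make_clinical([5, 6, 7, 8], [1, 1, 0, 0])
        labels = pd.Series(["a", "a", "b", "b"], index=clin["sample_id"])
        with pytest.raises(CoxConvergenceError, match="no events"):
            cox_hr(clin, labels)


@pytest.fixture(scope="module")
def big_trial():
    """Large trial at the design point used for sample-size work:
    control-arm 5-year survival 66% (low) vs 20% (high), treated 66%/66%."""
    design = TrialDesign(n_patients=20000, surv5=(0.66, 0.20, 0.66, 0.66), seed=101)
    return design, generate_trial(design)


class TestInteractionTest:
    def test_null_design_interaction_near_zero(self):
        trial = generate_trial(
            TrialDesign(n_patients=4000, surv5=(0.5, 0.5, 0.5, 0.5), seed=9)
        )
        res = interaction_test(trial, "e2f_group", per_group=False)
        assert abs(np.log(res.hr_ratio)) < 0.15
        assert res.ci[0] <= 1.0 <= res.ci[1]

    def test_recovers_analytic_hr_ratio(self, big_trial):
        """The interaction coefficient estimates ln(0.66)/ln(0.20) under
        exponential cell survival."""
        _, trial = big_trial
        res = interaction_test(trial, "e2f_group", per_group=False)
        analytic = np.log(0.66) / np.log(0.20)
        assert res.hr_ratio == pytest.approx(analytic, abs=0.03)

    def test_consistent_with_stratified_fits(self, big_trial):
        _, trial = big_trial
        res = interaction_test(trial, "e2f_group", per_group=True)
        ratio_of_strata = (
            res.treatment_hr_by_group["high"].hr / res.treatment_hr_by_group["low"].hr
        )
        assert res.hr_ratio == pytest.approx(ratio_of_strata, rel=0.05)

    def test_wald_and_lrt_agree_on_strong_effects(self):
        """Wald p and the likelihood-ratio test agree in rejection at
        alpha = 0.05 on simulated strong-interaction trials."""
        from lifelines import CoxPHFitter

        agree = 0
        n_trials = 20
        for i in range(n_trials):
            trial = generate_trial(TrialDesign(n_patients=500, seed=200 + i))
            res = interaction_test(trial, "e2f_group", per_group=False)
            df = pd.DataFrame(
                {
                    "t": trial["os_months"],
                    "e": trial["os_event"],
                    "treated": (trial["arm"] == "ACT").astype(float),
                    "high": (trial["e2f_group"] == "high").astype(float),
                }
            )
            df["tx"] = df["treated"] * df["high"]
            full = CoxPHFitter().fit(df, "t", "e")
            reduced = CoxPHFitter().fit(df.drop(columns="tx"), "t", "e")
            from scipy import stats as sps

            lr = 2 * (full.log_likelihood_ - reduced.log_likelihood_)
            p_lrt = sps.chi2.sf(lr, 1)
            agree += (res.p < 0.05) == (p_lrt < 0.05)
        assert agree / n_trials >= 0.95

    def test_empty_cell_raises(self):
        trial = generate_trial(TrialDesign(n_patients=200, seed=10))
        broken = trial[~((trial["arm"] == "ACT") & (trial["e2f_group"] == "high"))]
        with pytest.raises(CoxConvergenceError, match="cell"):
            interaction_test(broken, "e2f_group")


@pytest.fixture(scope="module")
def prognostic_inputs():
    _, clin = generate_cohort(CohortSpec(n_patients=400, latent_hazard_coef=0.8, seed=14))
    labels = pd.Series(
        np.where(clin["latent_activity"] > clin["latent_activity"].median(), "high", "low"),
        index=clin["sample_id"],
    )
    return clin, labels


class TestCohortReport:
    def test_row_count_is_strata_plus_overall(self, prognostic_inputs):
        clin, labels = prognostic_inputs
        table = cohort_report(clin, labels, mode="prognostic")
        present = {s for s in ("I", "II", "III/IV") if (clin["stage"] == s).any()}
        assert len(table) == len(present) + 1
        assert table.loc[0, "stratum"] == "overall"

    def test_composition_matches_direct_calls(self, prognostic_inputs):
        clin, labels = prognostic_inputs
        table = cohort_report(clin, labels, mode="prognostic").set_index("stratum")
        _, p = logrank(clin, labels)
        hr, *_ = cox_hr(clin, labels)
        km = km_summary(clin, labels=labels)
        assert table.loc["overall", "logrank_p"] == pytest.approx(p)
        assert table.loc["overall", "hr_high_vs_low"] == pytest.approx(hr, abs=0.005)
        assert table.loc["overall", "n_high"] == km["high"].n

    def test_predictive_report_flags_interaction(self):
        trial = generate_trial(TrialDesign(n_patients=600, seed=15))
        table = cohort_report(trial, "e2f_group", mode="predictive", stages=())
        assert table.loc[0, "interaction_p"] < 0.05
        assert table.loc[0, "act_hr_high"] < table.loc[0, "act_hr_low"]

    def test_missing_stage_column_warns(self, prognostic_inputs):
        clin, labels = prognostic_inputs
        with pytest.warns(UserWarning, match="stage"):
            table = cohort_report(clin.drop(columns="stage"), labels, mode="prognostic")
        assert len(table) == 1
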