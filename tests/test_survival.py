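"""Left-truncated Kaplan-Meier and stratified Cox regression."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ehrgenrisk.experiments import (
    cox_partial_loglik_bruteforce,
    six_subject_cox_fixture,
    untruncated_km_oracle,
)
from ehrgenrisk.simulate import DAYS_PER_YEAR, simulate_survival_cohort
from ehrgenrisk.survival import (
    RETENTION_DAYS,
    build_survival_records,
    compare_scenarios,
    cox_fit,
    km_estimate,
)


def records_frame(entry, exit_, event, **cov):
    base = {
        "entry_age_years": np.asarray(entry, dtype=float),
        "exit_age_years": np.asarray(exit_, dtype=float),
        "event": np.asarray(event, dtype=bool),
    }
    base.update(cov)
    return pd.DataFrame(base)


class TestKaplanMeier:
    def test_no_censoring_equals_ecdf(self):
        """KM reduces to the empirical CDF without censoring or truncation."""
        rec = records_frame([0, 0, 0, 0], [50, 60, 70, 80], [True, True, True, True])
        km = km_estimate(rec)
        assert km.cuminc_at(65.0) == pytest.approx(0.5)
        times = np.array([50, 60, 70, 80.0])
        for t in times:
            ecdf = np.mean(times <= t)
            assert km.cuminc_at(t) == pytest.approx(ecdf)

    def test_delayed_entry_hand_computation(self):
        """entries (0,0,5), events at 3 and 7, censor at 10: S(7) = 1/4."""
        rec = records_frame([0, 0, 5], [3, 7, 10], [True, True, False])
        km = km_estimate(rec)
        t = km.table
        assert t["n_risk"].tolist() == [2, 2]
        assert km.survival_at(7.0) == pytest.approx(0.25)
        assert km.cuminc_at(7.0) == pytest.approx(0.75)

    def test_matches_untruncated_oracle(self):
        rng = np.random.default_rng(17)
        n = 300
        exit_ = rng.exponential(10, n) + 0.1
        event = rng.random(n) < 0.6
        km = km_estimate(records_frame(np.zeros(n), exit_, event))
        t_o, s_o = untruncated_km_oracle(exit_, event)
        got = np.array([km.survival_at(t) for t in t_o])
        np.testing.assert_allclose(got, s_o, atol=1e-12)

    def test_matches_lifelines_with_entry(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(23)
        n = 400
        entry = rng.uniform(0, 6, n)
        exit_ = entry + rng.exponential(8, n) + 0.01
        exit_ = np.round(exit_, 1)  # create ties
        event = rng.random(n) < 0.5
        ok = exit_ > entry
        rec = records_frame(entry[ok], exit_[ok], event[ok])
        km = km_estimate(rec)
        kmf = KaplanMeierFitter().fit(exit_[ok], event[ok], entry=entry[ok])
        times = km.table["time"].to_numpy()
        np.testing.assert_allclose(
            km.table["survival"].to_numpy(),
            kmf.survival_function_at_times(times).to_numpy(),
            atol=1e-10,
        )

    def test_greenwood_and_cloglog_bounds(self):
        rec = records_frame([0] * 10, list(range(1, 11)), [True] * 5 + [False] * 5)
        km = km_estimate(rec)
        t = km.table
        # Greenwood accumulator is the textbook sum d/(n(n-d))
        v_expected = np.cumsum(
            t["n_event"] / (t["n_risk"] * (t["n_risk"] - t["n_event"]))
        )
        np.testing.assert_allclose(t["greenwood_v"], v_expected)
        # cloglog bounds stay inside [0, 1] and bracket the estimate
        assert ((t["surv_lower95"] >= 0) & (t["surv_upper95"] <= 1)).all()
        assert ((t["surv_lower95"] <= t["survival"]) & (t["survival"] <= t["surv_upper95"])).all()
        assert (t["cuminc_lower95"] <= t["cuminc"]).all()
        assert (t["cuminc"] <= t["cuminc_upper95"]).all()

    def test_monotone_survival_and_risk_set_convention(self):
        rec = records_frame([0, 2, 2], [2, 5, 9], [True, True, False])
        km = km_estimate(rec)
        # half-open convention: entering exactly at an event age not at risk
        assert km.table.set_index("time").loc[2.0, "n_risk"] == 1
        s = km.table["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()

    def test_entry_shift_never_decreases_cuminc(self):
        """Monotonicity: later entries (events retained) inflate cumulative incidence."""
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            entry = rng.uniform(0, 10, n)
            exit_ = entry + rng.exponential(10, n) + 0.05
            event = rng.random(n) < 0.6
            shift = rng.uniform(0, 15, n)
            entry2 = entry + shift * (rng.random(n) < 0.7)
            # retention adjustment for events overtaken by the shift
            entry2 = np.where(
                event & (exit_ <= entry2), exit_ - RETENTION_DAYS / DAYS_PER_YEAR, entry2
            )
            # drop non-events whose shifted entry passes their exit
            keep = entry2 < exit_
            km1 = km_estimate(records_frame(entry[keep], exit_[keep], event[keep]))
            km2 = km_estimate(records_frame(entry2[keep], exit_[keep], event[keep]))
            for age in np.linspace(0.5, 40, 15):
                assert km2.cuminc_at(age) >= km1.cuminc_at(age) - 1e-12


class TestCoxFit:
    def test_separation_flagged(self):
        """Single event in the exposed of two subjects: monotone likelihood."""
        rec = records_frame([0, 0], [1.0, 1.5], [True, False], x=[1.0, 0.0],
                            site=["s", "s"])
        fit = cox_fit(rec, covariates=("x",), strata="site")
        assert not fit.converged
        assert "separation" in fit.reason or "monotone" in fit.reason

    def test_no_events_raises(self):
        rec = records_frame([0, 0], [1, 2], [False, False], x=[0.0, 1.0], site=["s", "s"])
        with pytest.raises(ValueError):
            cox_fit(rec, covariates=("x",))

    def test_six_subject_bruteforce_oracle(self):
        """Newton fit equals brute-force partial-likelihood maximization to 1e-6."""
        df = six_subject_cox_fixture()
        fit = cox_fit(df, covariates=("x",), strata="site")
        res = optimize.minimize_scalar(
            lambda b: -cox_partial_loglik_bruteforce(b, df),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.converged
        assert fit.params["x"] == pytest.approx(res.x, abs=1e-6)
        assert fit.score_norm < 1e-6

    def test_matches_lifelines_with_truncation_strata_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(41)
        n = 600
        entry = rng.uniform(0, 5, n)
        exit_ = np.round(entry + rng.exponential(8, n) + 0.05, 1)
        event = rng.random(n) < 0.6
        x1 = (rng.random(n) < 0.3).astype(float)
        x2 = rng.standard_normal(n)
        site = rng.choice(["a", "b", "c"], n)
        ok = exit_ > entry
        rec = records_frame(entry[ok], exit_[ok], event[ok], x1=x1[ok], x2=x2[ok],
                            site=site[ok])
        fit = cox_fit(rec, covariates=("x1", "x2"), strata="site")
        ldf = rec.rename(
            columns={"entry_age_years": "entry", "exit_age_years": "T", "event": "E"}
        )
        cph = CoxPHFitter().fit(
            ldf, duration_col="T", event_col="E", entry_col="entry",
            strata=["site"], formula="x1+x2",
        )
        np.testing.assert_allclose(fit.params.to_numpy(), cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.vcov)), cph.standard_errors_.to_numpy(), atol=1e-5
        )

    def test_breslow_vs_efron_differ_only_with_ties(self):
        df = six_subject_cox_fixture()  # no ties
        fe = cox_fit(df, covariates=("x",), strata="site", ties="efron")
        fb = cox_fit(df, covariates=("x",), strata="site", ties="breslow")
        assert fe.params["x"] == pytest.approx(fb.params["x"], abs=1e-9)

    def test_single_stratum_equals_unstratified(self):
        df = six_subject_cox_fixture()
        f1 = cox_fit(df, covariates=("x",), strata="site")
        f2 = cox_fit(df, covariates=("x",), strata=None)
        assert f1.params["x"] == pytest.approx(f2.params["x"], abs=1e-12)

    def test_parameter_recovery_true_hr2(self):
        """Left-truncated Gompertz PH data: HR(high PRS) = 2 inside the Wald CI."""
        surv = simulate_survival_cohort(n=20000, seed=77)
        fit = cox_fit(surv)
        hr = fit.hazard_ratios().set_index("covariate").loc["high_prs"]
        assert hr["lower95"] <= 2.0 <= hr["upper95"]
        assert fit.score_norm < 1e-6


class TestBuildSurvivalRecords:
    @staticmethod
    def _cohort():
        return pd.DataFrame(
            {
                "participant_id": ["ev", "noncase", "prevalent"],
                "first_code_age_days": [round(30 * DAYS_PER_YEAR)] * 3,
                "recent_period_start_days": [
                    round(30 * DAYS_PER_YEAR),
                    round(30 * DAYS_PER_YEAR),
                    round(50 * DAYS_PER_YEAR),
                ],
                "last_code_age_days": [round(60 * DAYS_PER_YEAR)] * 3,
                "ehr_chd": [True, False, True],
                "onset_age_days": [round(55 * DAYS_PER_YEAR), np.nan, round(45 * DAYS_PER_YEAR)],
                "monogenic": [False] * 3,
                "high_prs": [False] * 3,
                "sex": ["female", "male", "female"],
                "site": ["s"] * 3,
            }
        )

    def test_no_truncation_entries_zero(self):
        rec = build_survival_records(self._cohort(), "no_truncation")
        assert (rec["entry_age_years"] == 0).all()

    def test_event_exit_is_onset_noncase_exit_is_last_code(self):
        rec = build_survival_records(self._cohort(), "first_code").set_index("participant_id")
        assert rec.loc["ev", "exit_age_years"] == pytest.approx(55, abs=0.01)
        assert rec.loc["noncase", "exit_age_years"] == pytest.approx(60, abs=0.01)
        assert rec.loc["noncase", "entry_age_years"] == pytest.approx(30, abs=0.01)

    def test_prevalent_event_retained_by_entry_adjustment(self):
        """Onset at 45 but recent period starts at 50: entry moved just below 45."""
        rec = build_survival_records(self._cohort(), "recent_period_start").set_index(
            "participant_id"
        )
        onset = 45.0
        assert rec.loc["prevalent", "entry_age_years"] < rec.loc["prevalent", "exit_age_years"]
        assert rec.loc["prevalent", "entry_age_years"] == pytest.approx(
            rec.loc["prevalent", "exit_age_years"] - RETENTION_DAYS / DAYS_PER_YEAR
        )
        assert rec.loc["prevalent", "exit_age_years"] == pytest.approx(onset, abs=0.01)

    def test_onset_after_last_code_rejected(self):
        cohort = self._cohort()
        cohort.loc[0, "onset_age_days"] = round(70 * DAYS_PER_YEAR)
        with pytest.raises(ValueError, match="inconsistent"):
            build_survival_records(cohort, "first_code")

    def test_degenerate_records_logged(self):
        cohort = self._cohort()
        # non-case with a single-instant record: rejected with a reason
        cohort.loc[1, "first_code_age_days"] = cohort.loc[1, "last_code_age_days"]
        rec = build_survival_records(cohort, "first_code")
        rejected = rec.attrs["rejected"]
        assert rejected["participant_id"].tolist() == ["noncase"]


class TestCompareScenarios:
    def test_identical_entries_give_identical_estimates(self):
        cohort = TestBuildSurvivalRecords._cohort().assign(
            recent_period_start_days=0, first_code_age_days=0
        )
        report = compare_scenarios(cohort, ages_of_interest=(58.0,), fit_cox=False)
        vals = [
            report["scenarios"][s]["cumulative_incidence"]["58.0"]["estimate"]
            for s in report["scenarios"]
        ]
        assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])

    def test_risk_set_largest_without_truncation(self, small_analysis_cohort):
        report = compare_scenarios(small_analysis_cohort, fit_cox=False)
        at20 = {
            s: report["scenarios"][s]["risk_set_sizes"]["20"]
            for s in report["scenarios"]
        }
        assert at20["no_truncation"] >= at20["first_code"] >= at20["recent_period_start"]

    def test_truncation_ordering_on_simulated_cohort(self, small_analysis_cohort):
        report = compare_scenarios(small_analysis_cohort, ages_of_interest=(75.0,), fit_cox=False)
        ci = {
            s: report["scenarios"][s]["cumulative_incidence"]["75.0"]["estimate"]
            for s in report["scenarios"]
        }
        assert ci["recent_period_start"] >= ci["first_code"] >= ci["no_truncation"]
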