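"""Design-matrix conventions and model fits (GEE, stratified, transitions)."""

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from netimpact.cognition import classify_cohort
from netimpact.errors import DegenerateOutcomeError, EmptySubsetError, ValidationError
from netimpact.stats import (
    ModelSpec,
    covariate_design,
    fit_gee_logistic,
    fit_stratified_logistic,
    fit_transition_logistic,
)
from netimpact.synthetic import SimulationConfig, simulate_cohort_table


def make_classified(seed=0, n=400, visits=1, **cfg_kw):
    cfg = dataclasses.replace(
        SimulationConfig(seed=seed), n_patients=n, visits_fixed=visits, **cfg_kw
    )
    cohort, scores, truth = simulate_cohort_table(cfg)
    classified = classify_cohort(cohort).merge(
        scores[["patient_id", "log_score"]], on="patient_id"
    )
    return classified, truth


class TestCovariateDesign:
    def test_scalings_and_codings(self, small_cohort):
        classified = classify_cohort(small_cohort)
        classified["log_score"] = 0.5
        classified.loc[classified.index[0], "age_years"] = 67.0
        classified.loc[classified.index[0], "infarct_volume_ml"] = 3.7
        d = covariate_design(classified, ModelSpec(adjust_site=False), "psci")
        row = d.X.iloc[0]
        assert row["age_decades"] == pytest.approx(6.7)
        assert row["volume_per_10ml"] == pytest.approx(0.37)
        assert row["male"] in (0.0, 1.0)

    def test_missing_covariate_rows_dropped_and_counted(self, small_cohort):
        classified = classify_cohort(small_cohort)
        classified["log_score"] = 0.5
        classified.loc[classified["patient_id"] == "B", "prior_stroke"] = np.nan
        d = covariate_design(classified, ModelSpec(), "psci")
        assert d.n_dropped_missing == 2  # both of B's visits
        assert d.dropped_patient_ids == ("B",)

    def test_unknown_education_category_rejected(self, small_cohort):
        classified = classify_cohort(small_cohort)
        classified["log_score"] = 0.5
        classified.loc[classified.index[0], "education_category"] = "doctorate"
        with pytest.raises(ValidationError):
            covariate_design(classified, ModelSpec(), "psci")

    def test_site_exclusion_removes_exactly_those_rows(self):
        classified, _ = make_classified(seed=5, n=300)
        site = classified["site_id"].iloc[0]
        n_site = int((classified["site_id"] == site).sum())
        d_all = covariate_design(classified, ModelSpec(univariable=True), "psci")
        d_excl = covariate_design(
            classified, ModelSpec(univariable=True, exclude_sites=(site,)), "psci"
        )
        n_ind_all = int(classified["psci"].isna().sum())
        n_ind_site = int(classified.loc[classified["site_id"] == site, "psci"].isna().sum())
        assert d_all.n_obs - d_excl.n_obs == n_site - n_ind_site
        assert d_all.n_obs == len(classified) - n_ind_all


class TestGee:
    def test_single_visit_independence_equals_ordinary_logistic(self):
        """GEE with one visit per subject and independence working structure
        is the same estimating equation as ML logistic regression."""
        classified, _ = make_classified(seed=1, n=400, visits=1)
        gee = fit_gee_logistic(classified, ModelSpec(correlation="independence"))
        d = covariate_design(classified, ModelSpec(), "psci")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(d.y, d.X, family=sm.families.Binomial()).fit()
        for _, row in gee.terms.iterrows():
            ml = glm.params[row["term"]]
            assert row["coef"] == pytest.approx(ml, rel=1e-6, abs=1e-8)

    def test_recovers_generative_log_odds(self):
        classified, truth = make_classified(seed=2, n=1000, visits=3)
        result = fit_gee_logistic(classified, ModelSpec())
        term = result.term("log_score")
        assert abs(term["coef"] - truth["beta_score"]) < 3 * term["se"]
        assert result.working_corr > 0.1  # correlation was injected

    def test_translation_invariance_of_score_or(self):
        """Adding a constant to every log score moves only the intercept."""
        classified, _ = make_classified(seed=3, n=500, visits=2)
        shifted = classified.copy()
        shifted["log_score"] = shifted["log_score"] + 2.5
        r1 = fit_gee_logistic(classified, ModelSpec(univariable=True))
        r2 = fit_gee_logistic(shifted, ModelSpec(univariable=True))
        assert r2.term("log_score")["coef"] == pytest.approx(
            r1.term("log_score")["coef"], rel=1e-6
        )

    def test_all_one_outcome_rejected(self):
        classified, _ = make_classified(seed=4, n=50)
        classified["psci"] = 1.0
        with pytest.raises(DegenerateOutcomeError):
            fit_gee_logistic(classified, ModelSpec(univariable=True))

    def test_result_invariants(self):
        classified, _ = make_classified(seed=6, n=300, visits=2)
        r = fit_gee_logistic(classified, ModelSpec())
        assert r.n_obs >= r.n_subjects
        for _, row in r.terms.iterrows():
            assert row["ci_low"] <= row["or"] <= row["ci_high"]
            assert row["or"] == pytest.approx(math.exp(row["coef"]), rel=1e-12)


class TestStratified:
    def test_consistent_with_gee_on_single_visit_stratum(self):
        classified, _ = make_classified(seed=7, n=500, visits=1)
        stratum = classified[classified["interval"] == "<3 months"]
        gee = fit_gee_logistic(stratum, ModelSpec(correlation="independence"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            strat = fit_stratified_logistic(classified, ModelSpec(interval="<3 months"))
        assert strat.term("log_score")["coef"] == pytest.approx(
            gee.term("log_score")["coef"], rel=1e-6
        )

    def test_small_stratum_warns_but_fits(self):
        classified, _ = make_classified(seed=8, n=600, visits=1)
        # push nearly everyone out of the late stratum, keep a sliver in it
        late = classified.sample(n=16, random_state=0).index
        classified.loc[late, "days_post_stroke"] = 800
        classified.loc[late, "interval"] = ">24 months"
        with pytest.warns(UserWarning, match="events"):
            r = fit_stratified_logistic(
                classified, ModelSpec(interval=">24 months", univariable=True)
            )
        assert r.converged

    def test_one_subject_stratum_degenerate(self):
        classified, _ = make_classified(seed=9, n=200, visits=1)
        one = classified.iloc[[0]].copy()
        one["days_post_stroke"] = 800
        one["interval"] = ">24 months"
        rest = classified.iloc[1:].copy()
        rest = rest[rest["interval"] != ">24 months"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(DegenerateOutcomeError):
                fit_stratified_logistic(
                    pd.concat([rest, one]), ModelSpec(interval=">24 months", univariable=True)
                )

    def test_unknown_interval_rejected(self):
        classified, _ = make_classified(seed=10, n=100)
        with pytest.raises(ValidationError):
            fit_stratified_logistic(classified, ModelSpec(interval="5 years"))


class TestTransitionModels:
    def test_recovers_transition_signal(self):
        classified, _ = make_classified(seed=11, n=2000, visits=3)
        r = fit_transition_logistic(classified, "recovery", ModelSpec(univariable=True))
        assert r.converged and r.n_subjects > 50

    def test_empty_conditioning_set(self):
        classified, _ = make_classified(seed=12, n=100, visits=1)
        # single-visit patients have no follow-up: no evaluable transitions
        with pytest.raises(EmptySubsetError):
            fit_transition_logistic(classified, "decline", ModelSpec(univariable=True))

    def test_all_recover_is_degenerate(self):
        classified, _ = make_classified(seed=13, n=800, visits=2)
        from netimpact.cognition import classify_transitions

        tr = classify_transitions(classified)
        keep = tr.loc[tr["transition"] == "recovery", "patient_id"]
        subset = classified[classified["patient_id"].isin(keep)]
        with pytest.raises((DegenerateOutcomeError, EmptySubsetError)):
            fit_transition_logistic(subset, "recovery", ModelSpec(univariable=True))
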