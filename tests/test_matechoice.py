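"""Choice-table aggregation and the weighted binomial GLM."""

import numpy as np
import pandas as pd
import pytest

import mimicvis as mv
from mimicvis.errors import ConfigurationError, InsufficientDataError
from mimicvis.matechoice import TrialRecord


def _trial(male, treatment, target, approaches, courtships=0):
    return TrialRecord(male_id=male, treatment=treatment,
                       target_species=target, approaches=approaches,
                       courtships=courtships)


def _both_treatments(male, s_plus, f_plus, s_minus, f_minus):
    return [
        _trial(male, "UVplus", "melpomene_model", s_plus),
        _trial(male, "UVplus", "erato_model", f_plus),
        _trial(male, "UVminus", "melpomene_model", s_minus),
        _trial(male, "UVminus", "erato_model", f_minus),
    ]


class TestBuildChoiceTable:
    def test_successes_failures_weight_definition(self):
        trials = _both_treatments("m1", 6, 4, 3, 7)
        tab = mv.build_choice_table(trials)
        plus = tab[tab["treatment"] == "UVplus"].iloc[0]
        assert (plus["successes"], plus["failures"], plus["weight"]) == (6, 4, 10)
        assert plus["proportion"] == 0.6

    def test_all_events_to_conspecific_gives_zero_proportion(self):
        tab = mv.build_choice_table(_both_treatments("m1", 0, 5, 0, 3))
        assert (tab["proportion"] == 0).all()

    def test_zero_event_rows_kept_with_zero_weight(self):
        tab = mv.build_choice_table(_both_treatments("m1", 0, 0, 2, 1))
        zero = tab[(tab["treatment"] == "UVplus")].iloc[0]
        assert zero["weight"] == 0

    def test_male_missing_a_treatment_excluded(self):
        trials = _both_treatments("m1", 1, 1, 1, 1) + [
            _trial("m2", "UVplus", "melpomene_model", 5),
            _trial("m2", "UVplus", "erato_model", 5)]
        tab = mv.build_choice_table(trials)
        assert set(tab["male_id"]) == {"m1"}

    def test_replicates_summed_per_male(self):
        trials = _both_treatments("m1", 2, 1, 0, 0) \
            + _both_treatments("m1", 3, 2, 1, 1)
        tab = mv.build_choice_table(trials)
        plus = tab[tab["treatment"] == "UVplus"].iloc[0]
        assert (plus["successes"], plus["failures"]) == (5, 3)

    def test_courtship_counts_selected_by_behavior(self):
        trials = [_trial("m1", tr, tg, approaches=9, courtships=c)
                  for tr in ("UVplus", "UVminus")
                  for tg, c in (("melpomene_model", 2), ("erato_model", 1))]
        tab = mv.build_choice_table(trials, behavior="courtship")
        assert (tab["successes"] == 2).all() and (tab["failures"] == 1).all()


class TestWeightedBinomialGLM:
    def test_intercept_only_matches_pooled_logit(self):
        tab = pd.DataFrame({"treatment": ["UVplus", "UVminus"],
                            "successes": [18, 12], "failures": [10, 10]})
        fit = mv.fit_weighted_binomial(tab, design="intercept_only")
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(30 / 20), abs=1e-8)

    def test_two_group_coefficient_is_log_odds_ratio(self):
        tab = pd.DataFrame({"treatment": ["UVplus", "UVminus"],
                            "successes": [30, 20], "failures": [20, 30]})
        fit = mv.fit_weighted_binomial(tab, design="treatment")
        lor = np.log((20 / 30) / (30 / 20))  # UVminus relative to UVplus
        k = fit.terms.index("treatment[UVminus]")
        assert fit.coefficients[k] == pytest.approx(lor, abs=1e-8)
        assert abs(fit.coefficients[k]) == pytest.approx(0.810930, abs=1e-6)

    def test_aggregated_equals_disaggregated_bernoulli(self, rng):
        tab = pd.DataFrame({
            "treatment": ["UVplus", "UVplus", "UVminus", "UVminus"],
            "successes": [7, 3, 9, 5], "failures": [3, 5, 1, 4]})
        rows = []
        for r in tab.itertuples():
            rows += [{"treatment": r.treatment, "successes": 1, "failures": 0}] \
                * r.successes
            rows += [{"treatment": r.treatment, "successes": 0, "failures": 1}] \
                * r.failures
        fit_a = mv.fit_weighted_binomial(tab, design="treatment")
        fit_b = mv.fit_weighted_binomial(pd.DataFrame(rows), design="treatment")
        np.testing.assert_allclose(fit_a.coefficients, fit_b.coefficients,
                                   atol=1e-10)
        np.testing.assert_allclose(fit_a.standard_errors,
                                   fit_b.standard_errors, atol=1e-10)

    def test_antisymmetric_under_label_swap(self, rng):
        tab = pd.DataFrame({"treatment": ["UVplus", "UVminus", "UVplus",
                                          "UVminus"],
                            "successes": rng.integers(1, 20, 4),
                            "failures": rng.integers(1, 20, 4)})
        swapped = tab.rename(columns={"successes": "failures",
                                      "failures": "successes"})
        fit = mv.fit_weighted_binomial(tab, design="treatment")
        fit_sw = mv.fit_weighted_binomial(swapped, design="treatment")
        np.testing.assert_allclose(fit_sw.coefficients, -fit.coefficients,
                                   atol=1e-8)

    def test_matches_reference_glm_implementation(self, rng):
        import statsmodels.api as sm
        for _ in range(10):
            n = 12
            tab = pd.DataFrame({
                "treatment": ["UVplus", "UVminus"] * (n // 2),
                "successes": rng.integers(1, 30, n),
                "failures": rng.integers(1, 30, n)})
            fit = mv.fit_weighted_binomial(tab, design="treatment")
            X = np.column_stack([np.ones(n),
                                 (tab["treatment"] == "UVminus").to_numpy(float)])
            ref = sm.GLM(tab[["successes", "failures"]].to_numpy(), X,
                         family=sm.families.Binomial()).fit(tol=1e-12,
                                                            maxiter=200)
            np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-8)
            np.testing.assert_allclose(fit.z, ref.tvalues, atol=1e-6)

    def test_treatment_by_behavior_interaction_design(self, rng):
        trials, _ = mv.generate_mate_choice_trials(
            30, 20, {"UVplus": 0.5, "UVminus": 0.7}, rng,
            courtship_events_per_male=10,
            p_comimic_courtship={"UVplus": 0.5, "UVminus": 0.5})
        stacked = pd.concat([mv.build_choice_table(trials, "approach"),
                             mv.build_choice_table(trials, "courtship")],
                            ignore_index=True)
        fit = mv.fit_weighted_binomial(stacked, design="treatment_x_behavior")
        assert "treatment[UVminus]:behavior[courtship]" in fit.terms
        z, p = mv.wald_test(fit, "treatment[UVminus]:behavior[courtship]")
        # interaction is real here: UV removal shifts approach but not courtship
        assert z < 0 and p < 0.05

    def test_separation_flagged_not_fatal(self):
        tab = pd.DataFrame({"treatment": ["UVplus", "UVminus"],
                            "successes": [10, 0], "failures": [0, 10]})
        with pytest.warns(UserWarning, match="separation"):
            fit = mv.fit_weighted_binomial(tab, design="treatment")
        assert not fit.converged

    def test_empty_table_rejected(self):
        tab = pd.DataFrame({"treatment": ["UVplus"], "successes": [0],
                            "failures": [0]})
        with pytest.raises(InsufficientDataError):
            mv.fit_weighted_binomial(tab, design="intercept_only")


class TestWaldTest:
    def test_values_from_fit_vectors(self):
        fit = mv.GLMFit(terms=("intercept", "x"),
                        coefficients=np.array([0.0, 1.96]),
                        standard_errors=np.array([1.0, 1.0]),
                        z=np.array([0.0, 1.96]),
                        p=np.array([1.0, 0.0499958]),
                        deviance=0.0, iterations=1, converged=True,
                        design="treatment")
        z, p = mv.wald_test(fit, "intercept")
        assert z == 0.0 and p == 1.0
        z, p = mv.wald_test(fit, "x")
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_unknown_term_rejected(self):
        fit = mv.GLMFit(terms=("intercept",), coefficients=np.zeros(1),
                        standard_errors=np.ones(1), z=np.zeros(1),
                        p=np.ones(1), deviance=0.0, iterations=1,
                        converged=True, design="intercept_only")
        with pytest.raises(ConfigurationError):
            mv.wald_test(fit, "treatment")


def test_wald_type_one_error_is_calibrated(rng):
    """Null rejection rate of the treatment Wald test across seeded
    simulated experiments (no true preference difference)."""
    rej = 0
    reps = 2000
    for _ in range(reps):
        trials, _ = mv.generate_mate_choice_trials(40, 20, 0.5, rng)
        tab = mv.build_choice_table(trials)
        fit = mv.fit_weighted_binomial(tab, design="treatment")
        _, p = mv.wald_test(fit, "treatment[UVminus]")
        rej += p < 0.05
    assert 0.04 <= rej / reps <= 0.065
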