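"""Synthetic spectra, ring populations, and choice-trial generators."""

import numpy as np
import pytest

import mimicvis as mv
from mimicvis.errors import ConfigurationError, ScenarioError
from mimicvis.synth import generate_training_library


class TestPatchSpectrum:
    def test_sigmoid_limits_without_variation(self, grid):
        m = mv.PatchSpectrumModel(color_class="yellow",
                                  longpass_inflection=500, longpass_slope=0.1,
                                  plateau=0.8, uv_lobe=None,
                                  individual_cv=0.0, inflection_sd_nm=0.0)
        s = mv.generate_patch_spectrum(m, np.random.default_rng(0), grid)
        lam = s.wavelengths
        assert s.values[lam == 650][0] == pytest.approx(0.8, abs=1e-3)
        assert s.values[lam == 350][0] == pytest.approx(0.0, abs=1e-3)

    def test_uv_lobe_adds_stated_amplitude(self, grid):
        base_m = mv.PatchSpectrumModel(color_class="yellow",
                                       longpass_inflection=500,
                                       longpass_slope=0.1, plateau=0.8,
                                       uv_lobe=None, individual_cv=0.0,
                                       inflection_sd_nm=0.0)
        lobe_m = mv.PatchSpectrumModel(color_class="yellow",
                                       longpass_inflection=500,
                                       longpass_slope=0.1, plateau=0.8,
                                       uv_lobe=(350, 25, 0.3),
                                       individual_cv=0.0, inflection_sd_nm=0.0)
        rng = np.random.default_rng(0)
        base = mv.generate_patch_spectrum(base_m, rng, grid)
        lobe = mv.generate_patch_spectrum(lobe_m, rng, grid)
        lam = base.wavelengths
        diff = lobe.values[lam == 350][0] - base.values[lam == 350][0]
        assert diff == pytest.approx(0.3, abs=1e-6)

    def test_same_seed_reproduces_spectrum(self, grid):
        m = mv.default_patch_model("red")
        a = mv.generate_patch_spectrum(m, np.random.default_rng(42), grid)
        b = mv.generate_patch_spectrum(m, np.random.default_rng(42), grid)
        np.testing.assert_array_equal(a.values, b.values)

    def test_excessive_reflectance_clipped_with_warning(self, grid):
        m = mv.PatchSpectrumModel(color_class="white",
                                  longpass_inflection=300,
                                  longpass_slope=0.2, plateau=1.0,
                                  uv_lobe=(350, 40, 0.9),
                                  individual_cv=0.0, inflection_sd_nm=0.0)
        with pytest.warns(UserWarning, match="clipped"):
            s = mv.generate_patch_spectrum(m, np.random.default_rng(0), grid)
        assert s.values.max() == 1.5

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigurationError):
            mv.PatchSpectrumModel(color_class="red", longpass_inflection=600,
                                  longpass_slope=0.1, plateau=1.4)
        with pytest.raises(ConfigurationError):
            mv.default_patch_model("ultraviolet-chartreuse")


class TestRingGenerator:
    def test_single_individual_scenario_rejected(self):
        with pytest.raises(ScenarioError):
            mv.RingScenario(n_a=1, n_b=10)

    def test_ground_truth_returned_with_data(self, bluetit, d65, rng):
        sc = mv.RingScenario(n_a=3, n_b=3, divergence_nm=7.0)
        meas, truth = mv.generate_ring(sc, bluetit, rng, illuminant=d65)
        assert truth["divergence_nm"] == 7.0
        assert len(meas) == 6
        model_b = truth["models"][("yellow", "melpomene")]
        model_a = truth["models"][("yellow", "erato")]
        assert model_b.longpass_inflection \
            == model_a.longpass_inflection + 7.0

    def test_zero_divergence_means_match_within_mc_error(self, bluetit, d65):
        sc = mv.RingScenario(n_a=12, n_b=12)
        rng = np.random.default_rng(5)
        meas, _ = mv.generate_ring(sc, bluetit, rng, illuminant=d65)
        means = mv.individual_mean_jnd(mv.pairwise_jnd_table(meas))
        com = means["mean_comimic_jnd"].mean()
        con = means["mean_conspecific_jnd"].mean()
        assert com == pytest.approx(con, rel=0.25)

    def test_divergence_raises_comimic_jnd_only(self, bluetit, d65):
        rng = np.random.default_rng(6)
        sc0 = mv.RingScenario(n_a=8, n_b=8, divergence_nm=0.0)
        sc1 = mv.RingScenario(n_a=8, n_b=8, divergence_nm=12.0)
        m0, _ = mv.generate_ring(sc0, bluetit, np.random.default_rng(6),
                                 illuminant=d65)
        m1, _ = mv.generate_ring(sc1, bluetit, np.random.default_rng(6),
                                 illuminant=d65)
        mm0 = mv.individual_mean_jnd(mv.pairwise_jnd_table(m0))
        mm1 = mv.individual_mean_jnd(mv.pairwise_jnd_table(m1))
        assert mm1["mean_comimic_jnd"].mean() > 2 * mm0["mean_comimic_jnd"].mean()
        assert mm1["mean_conspecific_jnd"].mean() == pytest.approx(
            mm0["mean_conspecific_jnd"].mean(), rel=0.3)

    def test_calibration_hits_jnd_targets(self, bluetit, d65):
        sc = mv.calibrate_ring_scenario(bluetit, target_comimic_jnd=6.0,
                                        target_conspecific_jnd=1.0)
        rng = np.random.default_rng(77)
        meas, _ = mv.generate_ring(sc, bluetit, rng, illuminant=d65)
        means = mv.individual_mean_jnd(mv.pairwise_jnd_table(meas))
        assert means["mean_comimic_jnd"].mean() == pytest.approx(6.0, rel=0.25)
        assert means["mean_conspecific_jnd"].mean() == pytest.approx(1.0,
                                                                     rel=0.35)


class TestTrialGenerator:
    def test_null_preference_recovers_near_zero_effect(self):
        rng = np.random.default_rng(9)
        trials, truth = mv.generate_mate_choice_trials(40, 100, 0.5, rng)
        fit = mv.fit_weighted_binomial(mv.build_choice_table(trials),
                                       design="treatment")
        k = fit.terms.index("treatment[UVminus]")
        assert abs(fit.coefficients[k]) < 0.1
        assert truth["log_odds_approach"]["UVminus"] == 0.0

    def test_effect_recovery_within_wald_interval(self):
        rng = np.random.default_rng(10)
        trials, truth = mv.generate_mate_choice_trials(
            40, 50, {"UVplus": 0.5, "UVminus": 0.65}, rng)
        fit = mv.fit_weighted_binomial(mv.build_choice_table(trials),
                                       design="treatment")
        k = fit.terms.index("treatment[UVminus]")
        true_diff = truth["log_odds_approach"]["UVminus"] \
            - truth["log_odds_approach"]["UVplus"]
        assert true_diff == pytest.approx(np.log(0.65 / 0.35), abs=1e-12)
        lo = fit.coefficients[k] - 2.6 * fit.standard_errors[k]
        hi = fit.coefficients[k] + 2.6 * fit.standard_errors[k]
        assert lo < true_diff < hi

    def test_same_seed_gives_identical_tables(self):
        a, _ = mv.generate_mate_choice_trials(
            10, 709 / 82, 0.5, np.random.default_rng(3),
            courtship_events_per_male=62 / 82)
        b, _ = mv.generate_mate_choice_trials(
            10, 709 / 82, 0.5, np.random.default_rng(3),
            courtship_events_per_male=62 / 82)
        assert a == b

    def test_reference_scale_preset_matches_aggregate_scale(self):
        trials, _ = mv.reference_scale_trials(np.random.default_rng(11))
        males = {t.male_id for t in trials}
        total_app = sum(t.approaches for t in trials)
        total_crt = sum(t.courtships for t in trials)
        assert len(males) == 41
        assert 550 <= total_app <= 880   # ~709 expected, Poisson spread
        assert 30 <= total_crt <= 100    # ~62 expected

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            mv.generate_mate_choice_trials(5, 10, 1.5,
                                           np.random.default_rng(0))


class TestTrainingLibrary:
    def test_values_bounded_and_deterministic(self, grid):
        a = generate_training_library(20, np.random.default_rng(2), grid)
        b = generate_training_library(20, np.random.default_rng(2), grid)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.values, sb.values)
            assert sa.values.min() >= 0.02 and sa.values.max() <= 1.2
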