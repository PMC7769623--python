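import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hearttap import (
    ModelParams,
    PriorSpec,
    closed_form_tap_probability,
    derive_params,
    derived_precision,
    fit_subject,
    log_likelihood,
    model_accuracy,
    transform,
    untransform,
)
from hearttap.fitting import log_likelihood_reference

from conftest import make_trials


def grid_map(trials, prior_var=0.5, resolution=0.01, penalized=True):
    """Brute-force reference MAP (or MLE) on a native-parameter grid."""
    from scipy.special import logit

    best, best_val = None, -np.inf
    grid = np.arange(resolution, 1.0, resolution)
    for ip in grid:
        for phb in grid:
            val = log_likelihood(ModelParams(ip, phb), trials)
            if penalized:
                val -= (logit(ip) ** 2 + logit(phb) ** 2) / (2 * prior_var)
            if val > best_val:
                best, best_val = (ip, phb), val
    return best


class TestTransforms:
    def test_prior_means_map_to_zero(self):
        eta = transform(ModelParams(0.5, 0.5, b0=1.0, variant="learning"))
        np.testing.assert_allclose(eta, 0.0, atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(ip=st.floats(0.01, 0.99), phb=st.floats(0.01, 0.99),
           b0=st.floats(0.05, 20.0))
    def test_round_trip_identity(self, ip, phb, b0):
        p = ModelParams(ip, phb, b0=b0, variant="learning")
        q = untransform(transform(p), "learning")
        assert q.ip_raw == pytest.approx(ip, abs=1e-12)
        assert q.p_hb == pytest.approx(phb, abs=1e-12)
        assert q.b0 == pytest.approx(b0, rel=1e-12)


class TestLogLikelihood:
    def test_chance_model_gives_n_log_half(self):
        trials = make_trials([("systole", "tap"), ("diastole", "no_tap")] * 10)
        ll = log_likelihood(ModelParams(0.5, 0.5), trials)
        assert ll == pytest.approx(20 * math.log(0.5))

    def test_four_trial_worked_case(self):
        # sys:tap, dia:no, sys:tap, dia:tap at ip=0.8, phb=0.5:
        # p_sys=0.8, p_dia=0.2 -> ln.8 + ln.8 + ln.8 + ln.2 = -2.27887
        trials = make_trials([("systole", "tap"), ("diastole", "no_tap"),
                              ("systole", "tap"), ("diastole", "tap")])
        ll = log_likelihood(ModelParams(0.8, 0.5), trials)
        assert ll == pytest.approx(3 * math.log(0.8) + math.log(0.2))
        assert ll == pytest.approx(-2.2788685663767296)

    def test_near_perfect_fit_limit(self):
        trials = make_trials([("systole", "tap"), ("diastole", "no_tap")] * 50)
        ll = log_likelihood(ModelParams(0.999, 0.5), trials)
        assert -0.2 < ll < 0.0

    def test_fast_path_matches_matrix_route(self, simulated_subject):
        _, _, _, trials = simulated_subject(ip_raw=0.7, p_hb=0.3)
        for variant, b0 in [("perception_only", 1.0), ("learning", 0.4)]:
            params = ModelParams(0.66, 0.37, b0=b0, variant=variant)
            assert log_likelihood(params, trials) == pytest.approx(
                log_likelihood_reference(params, trials), abs=1e-8
            )


class TestFitSubject:
    def test_recovers_high_precision_subject(self, simulated_subject):
        _, _, truth, trials = simulated_subject(ip_raw=0.9, p_hb=0.5)
        fit = fit_subject(trials)
        assert fit.converged
        assert fit.map_native.ip_raw == pytest.approx(0.9, abs=0.1)
        # agrees with the brute-force grid MAP to grid resolution
        g_ip, g_phb = grid_map(trials)
        assert fit.map_native.ip_raw == pytest.approx(g_ip, abs=0.02)
        assert fit.map_native.p_hb == pytest.approx(g_phb, abs=0.02)

    def test_shrinkage_toward_prior_mean(self):
        # All-no-tap data: the MLE pushes p_hb to the grid edge; the MAP
        # stays strictly between the prior mean (0.5) and the MLE.
        trials = make_trials([("systole", "no_tap"),
                              ("diastole", "no_tap")] * 20)
        fit = fit_subject(trials)
        _, mle_phb = grid_map(trials, penalized=False)
        assert mle_phb < fit.map_native.p_hb < 0.5

    def test_posterior_covariance_is_spd(self, simulated_subject):
        _, _, _, trials = simulated_subject()
        fit = fit_subject(trials)
        cov = fit.posterior_covariance
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_free_energy_below_map_log_likelihood(self, simulated_subject):
        _, _, _, trials = simulated_subject()
        fit = fit_subject(trials)
        assert fit.free_energy < fit.log_likelihood_at_map

    def test_learning_variant_fits_three_parameters(self, simulated_subject):
        _, _, _, trials = simulated_subject(ip_raw=0.85, p_hb=0.5, b0=0.25,
                                            variant="learning")
        fit = fit_subject(trials, variant="learning")
        assert fit.map_unconstrained.size == 3
        assert fit.converged

    def test_learning_penalized_on_perception_data(self, simulated_subject):
        """Fitting the learning variant to perception-only data from the
        low-prior regime loses free energy on average: the belief drift it
        must suppress costs either fit or prior plausibility."""
        diffs = []
        for seed in range(8):
            _, _, _, trials = simulated_subject(ip_raw=0.75, p_hb=0.2,
                                                seed=200 + seed)
            fp = fit_subject(trials).free_energy
            fl = fit_subject(trials, variant="learning").free_energy
            diffs.append(fl - fp)
        assert np.mean(diffs) < 0

    def test_empty_trials_rejected(self):
        from hearttap import TrialSequence

        with pytest.raises(ValueError, match="insufficient"):
            fit_subject(TrialSequence(trials=[]))


class TestModelAccuracy:
    def test_high_precision_agent_scores_high(self, simulated_subject):
        _, _, _, trials = simulated_subject(ip_raw=0.99, p_hb=0.5, seed=3)
        fit = fit_subject(trials)
        assert fit.model_accuracy > 0.95

    def test_chance_probabilities_count_as_matched(self):
        trials = make_trials([("systole", "tap"), ("diastole", "no_tap")] * 5)
        fit = fit_subject(make_trials([("systole", "tap"),
                                       ("diastole", "tap")] * 5))
        fit.map_native = ModelParams(0.5, 0.5)
        assert model_accuracy(fit, trials) == 1.0

    def test_anticorrelated_responses_score_near_zero(self, simulated_subject):
        """Flipping every response of a precise agent makes accuracy at the
        reflected parameters the mirror image."""
        from hearttap import Trial, TrialSequence

        _, _, _, trials = simulated_subject(ip_raw=0.95, p_hb=0.5, seed=4)
        flipped = TrialSequence(trials=[
            Trial(t.index, t.observation,
                  "no_tap" if t.response == "tap" else "tap",
                  t.window_start, t.window_end)
            for t in trials.trials
        ])
        fit = fit_subject(trials)
        assert model_accuracy(fit, flipped) < 0.1


class TestDerivedParams:
    @pytest.mark.parametrize("raw, ip", [(0.5, 0.0), (0.9, 0.4), (0.1, 0.4)])
    def test_fold_transform(self, raw, ip):
        assert derived_precision(raw) == pytest.approx(ip)

    def test_derive_from_fit(self, simulated_subject):
        _, _, _, trials = simulated_subject()
        fit = fit_subject(trials)
        d = derive_params(fit)
        assert d.avr == fit.map_native.ip_raw
        assert d.ip == pytest.approx(abs(d.avr - 0.5))
        assert 0.0 <= d.ip <= 0.5
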