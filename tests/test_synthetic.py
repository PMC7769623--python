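import numpy as np
import pytest

from hearttap import (
    BeatGenConfig,
    CohortScenario,
    ModelParams,
    ParamDist,
    ToneGenConfig,
    build_trial_sequence,
    closed_form_tap_probability,
    generate_beats,
    generate_cohort,
    generate_tone_schedule,
    simulate_subject,
)


class TestGenerateBeats:
    def test_deterministic_limit_is_exactly_periodic(self):
        beats = generate_beats(BeatGenConfig(mean_rate=60, ibi_sd=0.0,
                                             rsa_amplitude=0.0, duration=60))
        assert len(beats) == 60
        np.testing.assert_allclose(np.diff(beats.times), 1.0)

    def test_count_distribution_brackets_the_rate(self):
        """~70 bpm with 50 ms IBI noise: the central mass of the count
        distribution stays within 70 +/- 4 over many seeds."""
        counts = np.array([
            len(generate_beats(BeatGenConfig(mean_rate=70, ibi_sd=0.05,
                                             duration=60, seed=s)))
            for s in range(1000)
        ])
        lo, hi = np.percentile(counts, [2.5, 97.5])
        assert 66 <= lo and hi <= 74

    def test_same_seed_reproduces_times(self):
        cfg = BeatGenConfig(mean_rate=72, ibi_sd=0.04, duration=60, seed=42)
        np.testing.assert_array_equal(generate_beats(cfg).times,
                                      generate_beats(cfg).times)

    def test_count_scales_with_duration(self):
        short = len(generate_beats(BeatGenConfig(mean_rate=70, ibi_sd=0.05,
                                                 duration=60, seed=1)))
        long = len(generate_beats(BeatGenConfig(mean_rate=70, ibi_sd=0.05,
                                                duration=180, seed=1)))
        assert long == pytest.approx(3 * short, rel=0.1)

    def test_rsa_modulates_intervals(self):
        beats = generate_beats(BeatGenConfig(mean_rate=60, ibi_sd=0.0,
                                             rsa_amplitude=0.2,
                                             rsa_frequency=13,
                                             duration=60))
        ibis = np.diff(beats.times)
        assert ibis.min() < 0.9 and ibis.max() > 1.1
        assert np.all(ibis > 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BeatGenConfig(mean_rate=0)
        with pytest.raises(ValueError):
            BeatGenConfig(rsa_amplitude=1.0)


class TestToneSchedule:
    @pytest.mark.parametrize("seed", [0, 1, 7, 123])
    def test_exactly_78_tones_in_60_seconds(self, seed):
        tones = generate_tone_schedule(ToneGenConfig(seed=seed))
        assert len(tones) == 78
        assert tones.times[-1] < 60.0

    def test_degenerate_config_is_equally_spaced(self):
        cfg = ToneGenConfig(n_tones=10, jitter_fraction=0.0,
                            modulation_amplitude=0.0, trial_duration=60)
        tones = generate_tone_schedule(cfg)
        np.testing.assert_allclose(np.diff(tones.times), 6.0)

    def test_positive_gaps_across_many_seeds(self):
        min_gap = min(
            np.diff(generate_tone_schedule(ToneGenConfig(seed=s)).times).min()
            for s in range(1000)
        )
        assert min_gap > 0


class TestSimulateSubject:
    def test_extreme_precision_taps_track_systoles(self):
        beats = generate_beats(BeatGenConfig(mean_rate=70, ibi_sd=0.02,
                                             duration=600, seed=0))
        params = ModelParams(ip_raw=0.999, p_hb=0.5)
        _, _, trials = simulate_subject(params, beats, seed=1)
        obs = np.array([t.observation == "systole" for t in trials.trials])
        tap = np.array([t.response == "tap" for t in trials.trials])
        assert tap[obs].mean() > 0.99
        assert tap[~obs].mean() < 0.01

    def test_prior_dominated_limit_rarely_taps(self):
        beats = generate_beats(BeatGenConfig(mean_rate=70, ibi_sd=0.02,
                                             duration=300, seed=0))
        _, _, trials = simulate_subject(ModelParams(0.5, 1e-6), beats, seed=1)
        assert sum(t.response == "tap" for t in trials.trials) == 0

    def test_empirical_tap_rate_matches_closed_form(self):
        """Sampled responses are Bernoulli in the model's tap probability:
        empirical rates converge within 3 binomial SEs."""
        ip, phb = 0.8, 0.35
        beats = generate_beats(BeatGenConfig(mean_rate=70, ibi_sd=0.02,
                                             duration=1200, seed=2))
        _, _, trials = simulate_subject(ModelParams(ip, phb), beats, seed=3)
        for obs_name in ("systole", "diastole"):
            sel = [t for t in trials.trials if t.observation == obs_name]
            rate = np.mean([t.response == "tap" for t in sel])
            p = closed_form_tap_probability(ip, phb, obs_name)
            se = np.sqrt(p * (1 - p) / len(sel))
            assert abs(rate - p) < 3 * se

    def test_round_trip_reproduces_sampled_responses(self):
        beats = generate_beats(BeatGenConfig(mean_rate=70, ibi_sd=0.05,
                                             duration=60, seed=5))
        taps, _, trials = simulate_subject(ModelParams(0.7, 0.4), beats,
                                           seed=6)
        reseg = build_trial_sequence(beats, taps)
        assert reseg.responses == trials.responses


def uniform_cell(lo_ip, hi_ip, lo_p, hi_p):
    return {
        "ip_raw": ParamDist(dist="uniform", low=lo_ip, high=hi_ip),
        "p_hb": ParamDist(dist="uniform", low=lo_p, high=hi_p),
    }


class TestGenerateCohort:
    def scenario(self, seed=0, sd=0.03):
        dists = {}
        for group, ip_mean in [("hc", 0.07), ("pat", 0.03)]:
            for cond in ("guessing", "breath_hold"):
                dists[(group, cond)] = {
                    "ip": ParamDist(mean=ip_mean, sd=sd),
                    "p_hb": ParamDist(mean=0.3, sd=0.1),
                }
        return CohortScenario(
            groups=[("hc", 5), ("pat", 5)],
            conditions=["guessing", "breath_hold"],
            param_distributions=dists,
            beat_config=BeatGenConfig(mean_rate=70, ibi_sd=0.05, duration=60),
            seed=seed,
        )

    def test_cell_counts(self, tmp_path):
        data = generate_cohort(self.scenario(), out_dir=tmp_path)
        assert len(data.events) == 20
        assert len(data.truth) == 20
        assert len(list(tmp_path.glob("*__*.csv"))) == 20
        assert (tmp_path / "truth.csv").exists()

    def test_zero_sd_shares_parameters_within_cell(self):
        data = generate_cohort(self.scenario(sd=0.0))
        cell = data.truth.query("group == 'hc' and condition == 'guessing'")
        assert cell["ip_raw"].nunique() == 1

    def test_reactive_convention_unfolds_ip_above_half(self):
        data = generate_cohort(self.scenario())
        assert (data.truth["ip_raw"] >= 0.5).all()

    def test_master_seed_determinism(self):
        a = generate_cohort(self.scenario(seed=3))
        b = generate_cohort(self.scenario(seed=3))
        key = next(iter(a.events))
        np.testing.assert_array_equal(a.events[key]["tap"].times,
                                      b.events[key]["tap"].times)
        assert a.truth.equals(b.truth)

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            CohortScenario(groups=[], conditions=["c"],
                           param_distributions={})
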