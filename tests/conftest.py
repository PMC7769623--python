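import numpy as np
import pytest

from hearttap import (
    BeatGenConfig,
    ModelParams,
    TrialSequence,
    generate_beats,
    simulate_subject,
)


@pytest.fixture
def simulated_subject():
    """One ~140-trial simulated subject with known parameters."""

    def _make(ip_raw=0.8, p_hb=0.4, b0=1.0, variant="perception_only",
              seed=11, mean_rate=71.0, duration=60.0):
        params = ModelParams(ip_raw, p_hb, b0=b0, variant=variant)
        beats = generate_beats(
            BeatGenConfig(mean_rate=mean_rate, ibi_sd=0.05,
                          duration=duration, seed=seed)
        )
        taps, truth, trials = simulate_subject(params, beats, seed=seed + 9000)
        return beats, taps, truth, trials

    return _make


def make_trials(pattern):
    """Build a TrialSequence from (observation, response) pairs."""
    from hearttap import Trial

    trials = [
        Trial(index=i, observation=obs, response=resp,
              window_start=0.5 * i, window_end=0.5 * (i + 1))
        for i, (obs, resp) in enumerate(pattern)
    ]
    return TrialSequence(trials=trials)
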