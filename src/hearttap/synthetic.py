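"""Synthetic cohorts for the heartbeat-tapping task.

Generates the three ingredients every downstream stage needs: quasi-periodic
heartbeat series (Gaussian inter-beat variability with an optional
respiratory-sinus-arrhythmia modulation), the sinusoidally patterned
78-tone control schedule, and simulated tappers whose responses are sampled
from the perception model's posterior.  Whole cohorts draw subject-level
(IP, pHB) parameters from per-group, per-condition distributions and write
the same event CSVs the analysis reads, alongside a ground-truth table, so
parameter recovery can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import LEARNING, PERCEPTION_ONLY, ModelParams, run_trials
from .segmentation import (
    DEFAULT_PTT,
    EventSeries,
    TrialSequence,
    assign_responses,
    perceivable_beats,
    segment_trials,
    write_events_csv,
)

logger = logging.getLogger("hearttap")

#: Hard floor on sampled inter-beat intervals (seconds).
IBI_FLOOR = 1e-3


# ---------------------------------------------------------------------------
# Heartbeats
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeatGenConfig:
    """Quasi-periodic beat series parameters.

    ``mean_rate`` in beats/minute; ``ibi_sd`` the SD (seconds) of Gaussian
    inter-beat-interval noise; ``rsa_amplitude`` the fractional sinusoidal
    modulation of the IBI by respiratory sinus arrhythmia at
    ``rsa_frequency`` cycles/minute (a normal breathing rate is ~13/min).
    """

    mean_rate: float = 70.0
    ibi_sd: float = 0.05
    rsa_amplitude: float = 0.0
    rsa_frequency: float = 13.0
    duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be positive")
        if self.ibi_sd < 0:
            raise ValueError("ibi_sd must be non-negative")
        if not 0.0 <= self.rsa_amplitude < 1.0:
            raise ValueError("rsa_amplitude must be in [0, 1)")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def generate_beats(config: BeatGenConfig) -> EventSeries:
    """Simulate R-peak times over one recording window.

    Successive inter-beat intervals are the base interval 60/mean_rate,
    modulated by the RSA sinusoid evaluated at the current time, plus
    Gaussian noise; intervals are floored at 1 ms (logged if the floor ever
    binds).  The first beat falls at t = 0.
    """
    rng = np.random.default_rng(config.seed)
    base = 60.0 / config.mean_rate
    omega = 2.0 * np.pi * config.rsa_frequency / 60.0
    times = [0.0]
    floored = 0
    t = 0.0
    while True:
        ibi = base * (1.0 + config.rsa_amplitude * np.sin(omega * t))
        if config.ibi_sd > 0:
            ibi += rng.normal(0.0, config.ibi_sd)
        if ibi < IBI_FLOOR:
            ibi = IBI_FLOOR
            floored += 1
        t += ibi
        if t >= config.duration:
            break
        times.append(t)
    if floored:
        logger.warning("generate_beats: %d inter-beat intervals floored at %g s",
                       floored, IBI_FLOOR)
    return EventSeries(
        times=np.asarray(times), kind="r_peak", duration=config.duration
    )


# ---------------------------------------------------------------------------
# Tone schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToneGenConfig:
    """Auditory control-condition schedule: 78 tones over 60 s whose
    inter-onset intervals follow a sine pattern at 13 cycles/minute
    (mimicking RSA at a normal breathing rate) with ±10% multiplicative
    jitter."""

    n_tones: int = 78
    jitter_fraction: float = 0.10
    modulation_frequency: float = 13.0
    modulation_amplitude: float = 0.2
    tone_duration: float = 0.1
    trial_duration: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tones < 1:
            raise ValueError("n_tones must be at least 1")
        if not 0.0 <= self.jitter_fraction < 1.0:
            raise ValueError("jitter_fraction must be in [0, 1)")
        if not 0.0 <= self.modulation_amplitude < 1.0:
            raise ValueError("modulation_amplitude must be in [0, 1)")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")


def generate_tone_schedule(config: ToneGenConfig) -> EventSeries:
    """Generate exactly ``n_tones`` onsets fitting inside the trial.

    Base inter-onset intervals (trial_duration / n_tones) are scaled by
    (1 + a·sin(2*pi*f*t)) at the nominal onset times, jittered
    multiplicatively by a uniform ±jitter_fraction draw, and — should the
    schedule overflow the trial — rescaled uniformly (logged).  The first
    onset is at t = 0, so the count never depends on the jitter draw.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_tones
    base = config.trial_duration / n
    nominal = np.arange(n) * base
    omega = 2.0 * np.pi * config.modulation_frequency / 60.0
    intervals = base * (
        1.0 + config.modulation_amplitude * np.sin(omega * nominal)
    )
    if config.jitter_fraction > 0:
        intervals = intervals * (
            1.0 + rng.uniform(-config.jitter_fraction, config.jitter_fraction, n)
        )
    onsets = np.concatenate([[0.0], np.cumsum(intervals[:-1])])
    span = onsets[-1]
    limit = config.trial_duration - intervals[-1]
    if span > limit:
        scale = limit / span
        onsets = onsets * scale
        logger.info("generate_tone_schedule: rescaled intervals by %.4f to fit",
                    scale)
    return EventSeries(
        times=onsets, kind="tone", duration=config.trial_duration
    )


# ---------------------------------------------------------------------------
# Simulated tappers
# ---------------------------------------------------------------------------

def simulate_subject(
    params: ModelParams,
    beats: EventSeries,
    seed: int,
    ptt: float = DEFAULT_PTT,
) -> tuple[EventSeries, ModelParams, TrialSequence]:
    """Sample one subject's taps from the perception model.

    Beats (R-peaks, or an already perceivable series) are segmented into
    systole/diastole trials; per-trial tap probabilities come from the
    model's posterior; a tap/no-tap is sampled per trial and each sampled
    tap is placed uniformly inside its trial window (segmentation only ever
    uses window membership, so placement within the window is
    inconsequential).  Returns the tap series, the generating parameters and
    the simulated trial sequence (responses as sampled).
    """
    if not len(beats):
        raise ValueError("beats series is empty")
    perc = perceivable_beats(beats, ptt) if beats.kind == "r_peak" else beats
    windows = segment_trials(perc)
    observations = [w[0] for w in windows]
    rng = np.random.default_rng(seed)
    trace = run_trials(params, observations, rng=rng)
    tap_times = []
    for (obs, start, end), resp in zip(windows, trace.responses):
        if resp == "tap":
            tap_times.append(rng.uniform(start, end))
    taps = EventSeries(
        times=np.asarray(sorted(tap_times)),
        kind="tap",
        duration=beats.duration,
        subject_id=beats.subject_id,
        condition=beats.condition,
    )
    trial_seq = assign_responses(windows, taps)
    return taps, params, trial_seq


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDist:
    """Distribution of one native parameter across a (group, condition) cell.

    ``dist='normal'`` draws from N(mean, sd); ``dist='uniform'`` from
    U(low, high).  When attached to the folded precision measure the draw is
    truncated to [0, 0.5) before being unfolded to ip_raw.
    """

    dist: str = "normal"
    mean: float = 0.0
    sd: float = 0.0
    low: float = 0.0
    high: float = 0.0

    def __post_init__(self) -> None:
        if self.dist not in ("normal", "uniform"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if self.dist == "normal" and self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.dist == "uniform" and self.high < self.low:
            raise ValueError("need high >= low")

    def sample(self, rng: np.random.Generator) -> float:
        if self.dist == "normal":
            return float(rng.normal(self.mean, self.sd)) if self.sd > 0 else self.mean
        return float(rng.uniform(self.low, self.high))


#: Open-interval clip applied to sampled probabilities.
_EPS = 1e-3


@dataclass(frozen=True)
class CohortScenario:
    """Study design for a synthetic cohort.

    ``param_distributions`` maps (group, condition) to a dict with keys
    ``ip`` (folded precision, unfolded via ``ip_convention``) *or* ``ip_raw``
    (used directly), plus ``p_hb`` and optionally ``b0``.  Group-level
    summaries in the source literature report the folded precision only, so
    the folded parameterization with a reactive convention is the default
    way to express them.
    """

    groups: Sequence[tuple[str, int]]
    conditions: Sequence[str]
    param_distributions: Mapping[tuple[str, str], Mapping[str, ParamDist]]
    beat_config: BeatGenConfig = BeatGenConfig()
    ip_convention: str = "reactive"  # ip_raw = 0.5 + ip; "anticipatory" = 0.5 - ip
    variant: str = PERCEPTION_ONLY
    ptt: float = DEFAULT_PTT
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("scenario must define at least one group")
        if any(n < 1 for _, n in self.groups):
            raise ValueError("each group needs at least one subject")
        if self.ip_convention not in ("reactive", "anticipatory"):
            raise ValueError(f"unknown ip_convention {self.ip_convention!r}")


def _subject_seed(master: int, subject_id: str, condition: str) -> np.random.SeedSequence:
    # Stable per-subject-condition stream derived from the master seed.
    import zlib

    key = zlib.crc32(f"{subject_id}|{condition}".encode())
    return np.random.SeedSequence([int(master), int(key)])


def _draw_params(
    dists: Mapping[str, ParamDist],
    rng: np.random.Generator,
    convention: str,
    variant: str,
) -> ModelParams:
    if "ip_raw" in dists:
        ip_raw = float(np.clip(dists["ip_raw"].sample(rng), _EPS, 1.0 - _EPS))
    else:
        ip = float(np.clip(dists["ip"].sample(rng), 0.0, 0.5 - _EPS))
        ip_raw = 0.5 + ip if convention == "reactive" else 0.5 - ip
    p_hb = float(np.clip(dists["p_hb"].sample(rng), _EPS, 1.0 - _EPS))
    b0 = 1.0
    if "b0" in dists:
        b0 = max(dists["b0"].sample(rng), _EPS)
    return ModelParams(ip_raw=ip_raw, p_hb=p_hb, b0=b0, variant=variant)


@dataclass
class CohortData:
    """In-memory synthetic cohort: events, trials and the truth table."""

    events: dict[tuple[str, str], dict[str, EventSeries]]
    trials: dict[tuple[str, str], TrialSequence]
    truth: pd.DataFrame
    scenario: CohortScenario


def generate_cohort(scenario: CohortScenario, out_dir: str | Path | None = None
                    ) -> CohortData:
    """Simulate every subject-condition cell of a scenario.

    Per subject and condition: draw native parameters from the cell's
    distributions, simulate a beat series and the model-sampled taps, and
    (optionally) write one event CSV per cell plus a ``truth.csv`` table of
    the generating parameters under ``out_dir``.
    """
    events: dict[tuple[str, str], dict[str, EventSeries]] = {}
    trials: dict[tuple[str, str], TrialSequence] = {}
    rows = []
    for group, n_subjects in scenario.groups:
        for i in range(n_subjects):
            subject_id = f"{group}_{i:03d}"
            for condition in scenario.conditions:
                ss = _subject_seed(scenario.seed, subject_id, condition)
                rng = np.random.default_rng(ss)
                dists = scenario.param_distributions[(group, condition)]
                params = _draw_params(
                    dists, rng, scenario.ip_convention, scenario.variant
                )
                child = ss.spawn(2)
                beat_cfg = BeatGenConfig(
                    mean_rate=scenario.beat_config.mean_rate,
                    ibi_sd=scenario.beat_config.ibi_sd,
                    rsa_amplitude=scenario.beat_config.rsa_amplitude,
                    rsa_frequency=scenario.beat_config.rsa_frequency,
                    duration=scenario.beat_config.duration,
                    seed=int(child[0].generate_state(1)[0] % (2**31)),
                )
                beats = generate_beats(beat_cfg)
                beats.subject_id, beats.condition = subject_id, condition
                taps, _, trial_seq = simulate_subject(
                    params,
                    beats,
                    seed=int(child[1].generate_state(1)[0] % (2**31)),
                    ptt=scenario.ptt,
                )
                trial_seq.subject_id, trial_seq.condition = subject_id, condition
                events[(subject_id, condition)] = {"r_peak": beats, "tap": taps}
                trials[(subject_id, condition)] = trial_seq
                rows.append(
                    {
                        "subject_id": subject_id,
                        "group": group,
                        "condition": condition,
                        "ip_raw": params.ip_raw,
                        "p_hb": params.p_hb,
                        "b0": params.b0,
                    }
                )
    truth = pd.DataFrame(rows)
    data = CohortData(events=events, trials=trials, truth=truth,
                      scenario=scenario)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (subject_id, condition), series in events.items():
            write_events_csv(
                out / f"{subject_id}__{condition}.csv", series.values()
            )
        truth.to_csv(out / "truth.csv", index=False)
    return data


# ---------------------------------------------------------------------------
# Scenario I/O
# ---------------------------------------------------------------------------

def scenario_from_dict(cfg: Mapping) -> CohortScenario:
    """Build a scenario from a plain dict (YAML/JSON-shaped)."""
    dists: dict[tuple[str, str], dict[str, ParamDist]] = {}
    for cell in cfg["param_distributions"]:
        key = (cell["group"], cell["condition"])
        dists[key] = {
            name: ParamDist(**spec)
            for name, spec in cell["params"].items()
        }
    beat_cfg = BeatGenConfig(**cfg.get("beat_config", {}))
    return CohortScenario(
        groups=[tuple(g) for g in cfg["groups"]],
        conditions=list(cfg["conditions"]),
        param_distributions=dists,
        beat_config=beat_cfg,
        ip_convention=cfg.get("ip_convention", "reactive"),
        variant=cfg.get("variant", PERCEPTION_ONLY),
        ptt=cfg.get("ptt", DEFAULT_PTT),
        seed=int(cfg.get("seed", 0)),
    )


def load_scenario(path: str | Path) -> CohortScenario:
    """Load a scenario from a YAML (or JSON, a YAML subset) file."""
    import yaml

    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def recovery_scenario(
    n_subjects: int = 100,
    ip_raw_range: tuple[float, float] = (0.05, 0.95),
    p_hb_range: tuple[float, float] = (0.1, 0.9),
    mean_rate: float = 71.0,
    duration: float = 60.0,
    seed: int = 0,
    variant: str = PERCEPTION_ONLY,
    b0_range: tuple[float, float] | None = None,
) -> CohortScenario:
    """Uniform-truth scenario for parameter-recovery experiments.

    Defaults give ~71 beats per 60 s trial, i.e. ~140 trials per subject.
    """
    params: dict[str, ParamDist] = {
        "ip_raw": ParamDist(dist="uniform", low=ip_raw_range[0], high=ip_raw_range[1]),
        "p_hb": ParamDist(dist="uniform", low=p_hb_range[0], high=p_hb_range[1]),
    }
    if b0_range is not None:
        params["b0"] = ParamDist(dist="uniform", low=b0_range[0], high=b0_range[1])
    return CohortScenario(
        groups=[("sim", n_subjects)],
        conditions=["recovery"],
        param_distributions={("sim", "recovery"): params},
        beat_config=BeatGenConfig(
            mean_rate=mean_rate, ibi_sd=0.05, duration=duration, seed=0
        ),
        variant=variant,
        seed=seed,
    )
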