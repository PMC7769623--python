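"""Three-state Bayesian perception model of heartbeat tapping.

Each trial is a two-timestep partially observable Markov decision process
without actions on the world: the agent starts in a "start" state (initial
distribution D), transitions into a heartbeat or no-heartbeat state with
prior probability pHB (transition matrix B), and then observes a systole or
diastole whose reliability as evidence is the interoceptive precision IP_raw
(likelihood matrix A).  The posterior heartbeat probability is read out
directly as the probability of choosing to tap — there is no separate
response-noise parameter, since in this task such noise is not
distinguishable from IP_raw.

A learning variant places Dirichlet priors (concentration scale b0) on the
start-column of B and accumulates each trial's posterior into them, so the
prior belief in a heartbeat drifts toward the frequency with which heartbeats
were believed to be felt.  b0 acts as an inverse learning rate.

State order is (start, no_heartbeat, heartbeat); observation order is
(start, diastole, systole).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Variants of the model.
PERCEPTION_ONLY = "perception_only"
LEARNING = "learning"

#: Floor applied inside logs before the softmax; structural zeros in A and B
#: would otherwise produce -inf.  exp(-32) follows the convention of standard
#: active-inference implementations.
LOG_FLOOR = math.exp(-32.0)

OBSERVATIONS = ("start", "diastole", "systole")
STATES = ("start", "no_heartbeat", "heartbeat")
_OBS_INDEX = {name: i for i, name in enumerate(OBSERVATIONS)}


@dataclass(frozen=True)
class ModelParams:
    """Native model parameters.

    ``ip_raw`` is the raw likelihood precision (values below 0.5 encode a
    reliably *anticipatory* tapper, above 0.5 a reactive one); ``p_hb`` the
    prior transition probability into the heartbeat state; ``b0`` the scalar
    on the initial Dirichlet concentrations (learning variant only, inverse
    learning rate).
    """

    ip_raw: float
    p_hb: float
    b0: float = 1.0
    variant: str = PERCEPTION_ONLY

    def __post_init__(self) -> None:
        if not 0.0 < self.ip_raw < 1.0:
            raise ValueError(f"ip_raw must be in (0, 1), got {self.ip_raw}")
        if not 0.0 < self.p_hb < 1.0:
            raise ValueError(f"p_hb must be in (0, 1), got {self.p_hb}")
        if self.b0 <= 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        if self.variant not in (PERCEPTION_ONLY, LEARNING):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class GenerativeModel:
    """Likelihood (A), transition (B) and initial-state (D) arrays.

    Columns of A are states, rows observations; columns of B are the state at
    the first timestep, rows the state at the second.  ``b`` holds the
    Dirichlet concentrations over B for the learning variant (None
    otherwise).
    """

    A: np.ndarray
    B: np.ndarray
    D: np.ndarray
    b: np.ndarray | None = None
    params: ModelParams | None = None


def build_model(params: ModelParams) -> GenerativeModel:
    """Construct A/B/D (and initial Dirichlet counts) from native parameters."""
    ip, phb = params.ip_raw, params.p_hb
    A = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, ip, 1.0 - ip],
            [0.0, 1.0 - ip, ip],
        ]
    )
    B = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0 - phb, 1.0, 0.0],
            [phb, 0.0, 1.0],
        ]
    )
    D = np.array([1.0, 0.0, 0.0])
    b = B * params.b0 if params.variant == LEARNING else None
    return GenerativeModel(A=A, B=B, D=D, b=b, params=params)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def infer_posterior(model: GenerativeModel, observation: str) -> np.ndarray:
    """Posterior over states at the second timestep of one trial.

    Implements softmax(ln B·s_start + ln A^T·o) with the log floor.  The
    first timestep needs no numerics: D and the start observation are both
    fully precise, so the belief there is a delta on the start state.
    """
    if observation not in ("systole", "diastole"):
        raise ValueError(
            f"observation must be systole or diastole, got {observation!r}"
        )
    prior = model.B[:, 0]  # B applied to the one-hot start belief
    lik = model.A[_OBS_INDEX[observation], :]  # A^T o for one-hot o
    logits = np.log(np.maximum(prior, LOG_FLOOR)) + np.log(
        np.maximum(lik, LOG_FLOOR)
    )
    return _softmax(logits)


def tap_probability(posterior: np.ndarray) -> float:
    """P(tap): posterior heartbeat mass renormalized over the two substantive
    states, discarding the floor-epsilon mass on the start state."""
    n_hb, hb = posterior[1], posterior[2]
    total = n_hb + hb
    if total <= 0:
        return 0.0
    return float(hb / total)


def update_concentrations(b: np.ndarray, posterior: np.ndarray) -> np.ndarray:
    """Accumulate one trial's posterior into the Dirichlet counts.

    The trial contributes the outer product of the second-timestep posterior
    with the (one-hot start) first-timestep belief, so only the start column
    grows.
    """
    out = b.copy()
    out[:, 0] += posterior
    return out


def expected_transition(b: np.ndarray) -> np.ndarray:
    """Dirichlet-mean transition matrix: column-normalized concentrations."""
    sums = b.sum(axis=0)
    out = np.zeros_like(b)
    for j, s in enumerate(sums):
        if s > 0:
            out[:, j] = b[:, j] / s
    return out


@dataclass
class AgentTrace:
    """Per-trial record of one run of the model over an observation stream."""

    observations: list[str]
    posteriors: list[np.ndarray]
    tap_probabilities: list[float]
    responses: list[str] | None = None
    concentrations: list[np.ndarray] | None = None  # learning variant

    def __len__(self) -> int:
        return len(self.observations)


def run_trials(
    params: ModelParams,
    observations: Sequence[str],
    rng: np.random.Generator | None = None,
    keep_concentrations: bool = False,
) -> AgentTrace:
    """Run the model over a systole/diastole stream in temporal order.

    The perception-only variant has no carry-over between trials; the
    learning variant updates Dirichlet counts after each trial and uses their
    mean as the next trial's transition matrix.  If ``rng`` is given, a
    tap/no-tap response is sampled per trial from the tap probability
    (behavior is sampled from the posterior over states).
    """
    model = build_model(params)
    learning = params.variant == LEARNING
    b = model.b
    posts: list[np.ndarray] = []
    p_taps: list[float] = []
    responses: list[str] | None = [] if rng is not None else None
    b_snaps: list[np.ndarray] | None = [] if (learning and keep_concentrations) else None
    work = GenerativeModel(A=model.A, B=model.B, D=model.D, params=params)
    for obs in observations:
        if learning:
            work.B = expected_transition(b)
        post = infer_posterior(work, obs)
        p = tap_probability(post)
        posts.append(post)
        p_taps.append(p)
        if responses is not None:
            responses.append("tap" if rng.random() < p else "no_tap")
        if learning:
            b = update_concentrations(b, post)
            if b_snaps is not None:
                b_snaps.append(b.copy())
    return AgentTrace(
        observations=list(observations),
        posteriors=posts,
        tap_probabilities=p_taps,
        responses=responses,
        concentrations=b_snaps,
    )


def closed_form_tap_probability(ip_raw: float, p_hb: float, observation: str) -> float:
    """Two-state Bayes-ratio tap probability (analytic form, no softmax).

    For a systole: P = pHB·IP / (pHB·IP + (1−pHB)(1−IP)); the diastole case
    swaps IP for 1−IP.  Serves as an independent check of the matrix/softmax
    route (the two agree to ~1e-10; the log-floor perturbation is of order
    exp(-32)).
    """
    lik_hb = ip_raw if observation == "systole" else 1.0 - ip_raw
    lik_nhb = 1.0 - lik_hb
    num = p_hb * lik_hb
    return num / (num + (1.0 - p_hb) * lik_nhb)
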