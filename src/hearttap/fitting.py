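"""Subject-level parameter estimation: MAP with Gaussian priors and a
Laplace approximation to the log model evidence (free energy).

Parameters are estimated in an unconstrained space — logit for ip_raw and
p_hb, natural log for b0 — where the native prior means (0.5, 0.5, 1) map to
zero and the prior is an isotropic Gaussian with variance 1/2 per dimension.
The shrinkage this prior exerts deters overfitting: moving a parameter far
from its prior costs likelihood that the data must buy back.  A damped-Newton
search with central-difference derivatives maximizes the log-joint; the free
energy is the Laplace approximation

    F = ln p(y, theta_MAP) + (k/2) ln 2*pi + (1/2) ln det(Sigma),

with Sigma the inverse negative Hessian of the log-joint at the MAP.  F is
the per-subject currency for Bayesian model comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .model import (
    LEARNING,
    LOG_FLOOR,
    PERCEPTION_ONLY,
    ModelParams,
    run_trials,
)
from .segmentation import TAP, TrialSequence

logger = logging.getLogger("hearttap")

#: Likelihood clipping bound keeping log probabilities finite.
PROB_CLIP = 1e-16


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian priors in estimation space.

    Native means (ip_raw=0.5, p_hb=0.5, b0=1) all map to zero under the
    logit/log transforms, so the prior mean vector is zero; ``variance``
    (default 1/2, a deliberately tight value) applies per dimension.
    """

    ip_raw_mean: float = 0.5
    p_hb_mean: float = 0.5
    b0_mean: float = 1.0
    variance: float = 0.5

    def mean_vector(self, variant: str) -> np.ndarray:
        m = [logit(self.ip_raw_mean), logit(self.p_hb_mean)]
        if variant == LEARNING:
            m.append(math.log(self.b0_mean))
        return np.asarray(m, dtype=float)


@dataclass(frozen=True)
class FitOptions:
    max_iter: int = 128
    tol: float = 1e-4  # nats; convergence on accepted objective change
    deriv_step: float = 1e-3
    lambda_init: float = 1e-2  # Levenberg-Marquardt damping


@dataclass
class FitResult:
    """MAP fit of one subject-condition under one model variant."""

    map_native: ModelParams
    map_unconstrained: np.ndarray
    posterior_covariance: np.ndarray
    free_energy: float
    log_likelihood_at_map: float
    n_iterations: int
    converged: bool
    model_accuracy: float = float("nan")
    hessian_fallback: bool = False


@dataclass(frozen=True)
class DerivedParams:
    """Folded precision (IP), strategy (AvR = raw precision) and prior belief."""

    ip: float
    avr: float
    p_hb: float


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def transform(params: ModelParams) -> np.ndarray:
    """Native → unconstrained estimation space (logit, logit[, log])."""
    eta = [logit(params.ip_raw), logit(params.p_hb)]
    if params.variant == LEARNING:
        eta.append(math.log(params.b0))
    return np.asarray(eta, dtype=float)


def untransform(eta: np.ndarray, variant: str = PERCEPTION_ONLY) -> ModelParams:
    """Unconstrained vector → native parameters.

    Probabilities are clipped away from the exact bounds (expit saturates in
    floating point beyond |eta| ~ 37), keeping extreme search iterates inside
    the open parameter domain.
    """
    eta = np.asarray(eta, dtype=float)
    tiny = 1e-12
    b0 = float(np.clip(np.exp(eta[2]), tiny, 1e12)) if variant == LEARNING else 1.0
    return ModelParams(
        ip_raw=float(np.clip(expit(eta[0]), tiny, 1.0 - tiny)),
        p_hb=float(np.clip(expit(eta[1]), tiny, 1.0 - tiny)),
        b0=b0,
        variant=variant,
    )


def derived_precision(ip_raw) -> np.ndarray | float:
    """Folded interoceptive-precision transform IP = |IP_raw − 0.5|.

    Both ends of the raw range encode a reliable systole→tap mapping (an
    anticipatory tapper near 0, a reactive one near 1), so precision is the
    distance from the minimally precise value 0.5; range [0, 0.5].
    """
    return np.abs(np.asarray(ip_raw, dtype=float) - 0.5)


def derive_params(fit: FitResult) -> DerivedParams:
    """Interpretation-ready measures from a fit: IP, AvR, pHB."""
    raw = fit.map_native.ip_raw
    return DerivedParams(
        ip=float(derived_precision(raw)), avr=raw, p_hb=fit.map_native.p_hb
    )


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _trial_codes(trials: TrialSequence) -> tuple[np.ndarray, np.ndarray]:
    obs = np.array([t.observation == "systole" for t in trials.trials])
    resp = np.array([t.response == TAP for t in trials.trials])
    return obs, resp


def _fast_tap_prob(ip: float, phb: float, is_systole: bool) -> float:
    # Mirrors infer_posterior + tap_probability, including the log floor on
    # structural factors, without building matrices.
    lik_hb = ip if is_systole else 1.0 - ip
    lik_nhb = 1.0 - lik_hb
    num = max(phb, LOG_FLOOR) * max(lik_hb, LOG_FLOOR)
    den = num + max(1.0 - phb, LOG_FLOOR) * max(lik_nhb, LOG_FLOOR)
    return num / den


def _bernoulli_ll(p: float, n_tap: int, n_no: int) -> float:
    p = min(max(p, PROB_CLIP), 1.0 - PROB_CLIP)
    return n_tap * math.log(p) + n_no * math.log(1.0 - p)


def log_likelihood(params: ModelParams, trials: TrialSequence) -> float:
    """Sum of log Bernoulli(response | P(tap)) over trials, in nats.

    Perception-only tap probabilities depend only on the observation, so the
    sum collapses onto the four (observation, response) counts; the learning
    variant is evaluated sequentially because the Dirichlet counts carry
    over.
    """
    if not len(trials):
        logger.warning("log_likelihood of empty trial sequence; returning 0")
        return 0.0
    is_sys, is_tap = _trial_codes(trials)
    ip, phb = params.ip_raw, params.p_hb
    if params.variant == PERCEPTION_ONLY:
        p_sys = _fast_tap_prob(ip, phb, True)
        p_dia = _fast_tap_prob(ip, phb, False)
        ll = _bernoulli_ll(
            p_sys, int(np.sum(is_sys & is_tap)), int(np.sum(is_sys & ~is_tap))
        )
        ll += _bernoulli_ll(
            p_dia, int(np.sum(~is_sys & is_tap)), int(np.sum(~is_sys & ~is_tap))
        )
        return ll
    # Learning variant: the expected transition's start column is the
    # normalized concentration pair; the update adds the trial posterior.
    b_n = (1.0 - phb) * params.b0
    b_h = phb * params.b0
    ll = 0.0
    log = math.log
    for sys, tap in zip(is_sys.tolist(), is_tap.tolist()):
        prior_h = b_h / (b_n + b_h)
        p = _fast_tap_prob(ip, prior_h, sys)
        pc = min(max(p, PROB_CLIP), 1.0 - PROB_CLIP)
        ll += log(pc) if tap else log(1.0 - pc)
        b_h += p
        b_n += 1.0 - p
    return ll


def log_likelihood_reference(params: ModelParams, trials: TrialSequence) -> float:
    """Likelihood via the full matrix machinery (`run_trials`); slow route
    used to cross-check the fast evaluation."""
    trace = run_trials(params, trials.observations)
    ll = 0.0
    for t, p in zip(trials.trials, trace.tap_probabilities):
        pc = min(max(p, PROB_CLIP), 1.0 - PROB_CLIP)
        ll += math.log(pc) if t.response == TAP else math.log(1.0 - pc)
    return ll


# ---------------------------------------------------------------------------
# MAP estimation (damped Newton) and Laplace free energy
# ---------------------------------------------------------------------------

def _log_joint(eta: np.ndarray, trials: TrialSequence, variant: str,
               prior: PriorSpec) -> float:
    k = eta.size
    params = untransform(eta, variant)
    lp = -0.5 * float(np.sum((eta - prior.mean_vector(variant)) ** 2)) / prior.variance
    lp -= 0.5 * k * math.log(2.0 * math.pi * prior.variance)
    return log_likelihood(params, trials) + lp


def _gradient(f, eta: np.ndarray, h: float) -> np.ndarray:
    g = np.zeros_like(eta)
    for i in range(eta.size):
        e = np.zeros_like(eta)
        e[i] = h
        g[i] = (f(eta + e) - f(eta - e)) / (2 * h)
    return g


def _hessian(f, eta: np.ndarray, h: float) -> np.ndarray:
    k = eta.size
    H = np.zeros((k, k))
    f0 = f(eta)
    for i in range(k):
        ei = np.zeros(k)
        ei[i] = h
        H[i, i] = (f(eta + ei) - 2 * f0 + f(eta - ei)) / h**2
        for j in range(i + 1, k):
            ej = np.zeros(k)
            ej[j] = h
            H[i, j] = H[j, i] = (
                f(eta + ei + ej) - f(eta + ei - ej)
                - f(eta - ei + ej) + f(eta - ei - ej)
            ) / (4 * h**2)
    return H


def _spd_inverse(neg_hessian: np.ndarray) -> tuple[np.ndarray, bool]:
    """Invert -H, eigenvalue-clipping to SPD; fall back to the diagonal."""
    sym = 0.5 * (neg_hessian + neg_hessian.T)
    try:
        w, v = np.linalg.eigh(sym)
    except np.linalg.LinAlgError:  # pragma: no cover - pathological input
        w, v = None, None
    if w is not None and np.all(np.isfinite(w)):
        w_clipped = np.maximum(w, 1e-8)
        cov = (v / w_clipped) @ v.T
        return 0.5 * (cov + cov.T), bool(np.any(w < 1e-8))
    diag = np.maximum(np.diag(sym), 1e-8)
    return np.diag(1.0 / diag), True


def fit_subject(
    trials: TrialSequence,
    variant: str = PERCEPTION_ONLY,
    prior: PriorSpec | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """MAP-fit one subject-condition and compute the Laplace free energy.

    Damped (Levenberg-Marquardt) Newton ascent on the log-joint with
    central-difference derivatives, started at the prior mean.  Accepted
    steps never decrease the objective; convergence is declared when an
    accepted step improves it by less than ``options.tol`` nats.
    """
    if not len(trials):
        raise ValueError("insufficient beats: no trials to fit")
    prior = prior or PriorSpec()
    options = options or FitOptions()
    if variant not in (PERCEPTION_ONLY, LEARNING):
        raise ValueError(f"unknown variant {variant!r}")

    def f(eta: np.ndarray) -> float:
        return _log_joint(eta, trials, variant, prior)

    eta = prior.mean_vector(variant).copy()
    obj = f(eta)
    lam = options.lambda_init
    h = options.deriv_step
    converged = False
    n_iter = 0
    for n_iter in range(1, options.max_iter + 1):
        g = _gradient(f, eta, h)
        H = _hessian(f, eta, h)
        accepted = False
        for _ in range(12):
            try:
                step = np.linalg.solve(-H + lam * np.eye(eta.size), g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = eta + step
            cand_obj = f(cand)
            if np.isfinite(cand_obj) and cand_obj >= obj:
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            converged = True  # no ascent direction improves: at an optimum
            break
        improvement = cand_obj - obj
        eta, obj = cand, cand_obj
        lam = max(lam / 3.0, 1e-8)
        if improvement < options.tol:
            converged = True
            break
    if not converged:
        logger.warning("fit_subject: no convergence in %d iterations", n_iter)

    H_map = _hessian(f, eta, h)
    cov, fallback = _spd_inverse(-H_map)
    k = eta.size
    sign, logdet = np.linalg.slogdet(cov)
    free_energy = obj + 0.5 * k * math.log(2.0 * math.pi) + 0.5 * logdet
    params = untransform(eta, variant)
    result = FitResult(
        map_native=params,
        map_unconstrained=eta,
        posterior_covariance=cov,
        free_energy=float(free_energy),
        log_likelihood_at_map=log_likelihood(params, trials),
        n_iterations=n_iter,
        converged=converged,
        hessian_fallback=fallback,
    )
    result.model_accuracy = model_accuracy(result, trials)
    return result


def model_accuracy(fit: FitResult, trials: TrialSequence) -> float:
    """Fraction of responses matching the highest-probability action.

    A trial counts as matched when the fitted tap probability and the
    response fall on the same side of 0.5; an exactly chance-level
    probability matches either response (a chance model should not be
    penalized asymmetrically).
    """
    params = fit.map_native
    is_sys, is_tap = _trial_codes(trials)
    if params.variant == PERCEPTION_ONLY:
        p = np.where(
            is_sys,
            _fast_tap_prob(params.ip_raw, params.p_hb, True),
            _fast_tap_prob(params.ip_raw, params.p_hb, False),
        )
    else:
        trace = run_trials(params, trials.observations)
        p = np.asarray(trace.tap_probabilities)
    tie = np.isclose(p, 0.5, rtol=0.0, atol=1e-12)
    matched = tie | ((p > 0.5) & is_tap) | ((p < 0.5) & ~is_tap)
    return float(np.mean(matched))


def grid_log_evidence(
    trials: TrialSequence,
    variant: str = PERCEPTION_ONLY,
    prior: PriorSpec | None = None,
    half_width: float = 5.0,
    n_grid: int = 81,
) -> float:
    """Log evidence by 2-D trapezoid integration over estimation space.

    Independent numerical check of the Laplace free energy (perception-only
    variant: 2 parameters).  Integrates exp(log-joint) on a square grid of
    ``n_grid`` points per axis spanning ``±half_width`` around the prior
    mean.
    """
    if variant != PERCEPTION_ONLY:
        raise ValueError("grid integration implemented for the 2-parameter variant")
    prior = prior or PriorSpec()
    axis = np.linspace(-half_width, half_width, n_grid)
    lj = np.empty((n_grid, n_grid))
    for i, x in enumerate(axis):
        for j, y in enumerate(axis):
            lj[i, j] = _log_joint(np.array([x, y]), trials, variant, prior)
    m = lj.max()
    integrand = np.exp(lj - m)
    inner = np.trapezoid(integrand, axis, axis=1)
    return float(m + np.log(np.trapezoid(inner, axis)))


def fits_to_frame(
    fits: list[tuple[str, str, FitResult]]
) -> "pd.DataFrame":  # noqa: F821 - imported lazily
    """Tabulate (subject_id, condition, fit) triples as the fit-results CSV."""
    import pandas as pd

    rows = []
    for subject_id, condition, fit in fits:
        d = derive_params(fit)
        rows.append(
            {
                "subject_id": subject_id,
                "condition": condition,
                "variant": fit.map_native.variant,
                "ip_raw": fit.map_native.ip_raw,
                "ip": d.ip,
                "avr": d.avr,
                "p_hb": fit.map_native.p_hb,
                "b0": fit.map_native.b0,
                "free_energy": fit.free_energy,
                "log_likelihood": fit.log_likelihood_at_map,
                "accuracy": fit.model_accuracy,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows)
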