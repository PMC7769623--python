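"""Random-effects group Bayesian model selection.

Treats the model identity of each subject as a random effect: model
frequencies r in the population carry a Dirichlet prior, and subject-level
log evidences (Laplace free energies) update it via a variational fixed
point.  From the Dirichlet posterior we compute each model's exceedance
probability (XP, the probability it is the most frequent), the Bayes omnibus
risk (BOR, the posterior probability that all models are equally frequent),
and the protected exceedance probability PXP = BOR/K + (1-BOR)*XP, which
discounts XP by the chance that observed differences are noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, gammaln, logsumexp


@dataclass
class EvidenceMatrix:
    """Subject × model log-evidence array (nats) with model labels."""

    free_energies: np.ndarray
    models: list[str]

    def __post_init__(self) -> None:
        self.free_energies = np.asarray(self.free_energies, dtype=float)
        if self.free_energies.ndim != 2:
            raise ValueError("free_energies must be 2-D (subjects x models)")
        n, k = self.free_energies.shape
        if k < 2:
            raise ValueError("need at least 2 models")
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if len(self.models) != k:
            raise ValueError("model labels must match the number of columns")
        if not np.all(np.isfinite(self.free_energies)):
            raise ValueError("free energies must be finite")


@dataclass
class BMSResult:
    """Group-level model-selection summary."""

    models: list[str]
    alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_prob: np.ndarray
    protected_exceedance_prob: np.ndarray
    bor: float
    mc_samples: int
    seed: int

    @property
    def winner(self) -> str:
        return self.models[int(np.argmax(self.protected_exceedance_prob))]

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "alpha": self.alpha.tolist(),
            "expected_frequencies": self.expected_frequencies.tolist(),
            "exceedance_prob": self.exceedance_prob.tolist(),
            "protected_exceedance_prob": self.protected_exceedance_prob.tolist(),
            "bor": self.bor,
            "mc_samples": self.mc_samples,
            "seed": self.seed,
        }


def _vb_fixed_point(
    F: np.ndarray, prior_alpha: float, tol: float = 1e-6, max_iter: int = 10_000
) -> tuple[np.ndarray, np.ndarray, float]:
    """Variational fixed point for the Dirichlet posterior.

    Returns (alpha, subject-wise model posteriors u, variational free energy
    of the random-effects model).  Per-subject rows of F may carry arbitrary
    additive constants: the softmax removes them, and the returned free
    energy is reported relative to the same constants as the null model's,
    so comparisons are shift-invariant.
    """
    n, k = F.shape
    alpha0 = np.full(k, prior_alpha, dtype=float)
    alpha = alpha0.copy()
    u = np.full((n, k), 1.0 / k)
    for _ in range(max_iter):
        log_u = F + digamma(alpha) - digamma(alpha.sum())
        log_u = log_u - logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        new_alpha = alpha0 + u.sum(axis=0)
        if np.max(np.abs(new_alpha - alpha)) < tol:
            alpha = new_alpha
            break
        alpha = new_alpha
    # Variational bound on ln p(y | random-effects model).
    psi_diff = digamma(alpha) - digamma(alpha.sum())
    elbo = float(np.sum(u * (F + psi_diff)))
    elbo += float(
        gammaln(alpha0.sum()) - np.sum(gammaln(alpha0))
        + np.sum((alpha0 - 1.0) * psi_diff)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(u > 0, u * np.log(u), 0.0).sum()
    elbo += float(ent)
    elbo -= float(
        gammaln(alpha.sum()) - np.sum(gammaln(alpha))
        + np.sum((alpha - 1.0) * psi_diff)
    )
    return alpha, u, elbo


def group_bms(evidence: EvidenceMatrix, prior_alpha: float = 1.0) -> np.ndarray:
    """Dirichlet concentrations of the posterior over model frequencies."""
    alpha, _, _ = _vb_fixed_point(evidence.free_energies, prior_alpha)
    return alpha


def exceedance_prob(
    alpha: np.ndarray, n_samples: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities under Dirichlet(alpha)."""
    alpha = np.asarray(alpha, dtype=float)
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_samples))
    winners = np.argmax(draws, axis=1)
    counts = np.bincount(winners, minlength=alpha.size)
    return counts / counts.sum()


def protected_exceedance(
    evidence: EvidenceMatrix,
    alpha: np.ndarray,
    xp: np.ndarray,
    prior_alpha: float = 1.0,
) -> tuple[np.ndarray, float]:
    """Protected exceedance probabilities and the Bayes omnibus risk.

    The null hypothesis fixes all frequencies at 1/K; its evidence is the
    sum over subjects of logsumexp(F_n) - ln K.  BOR is the posterior
    probability of that null versus the random-effects alternative (equal
    prior odds); PXP shrinks each XP toward 1/K by the BOR.
    """
    F = evidence.free_energies
    n, k = F.shape
    f_null = float(np.sum(logsumexp(F, axis=1) - np.log(k)))
    _, _, f_alt = _vb_fixed_point(F, prior_alpha)
    # BOR = p(null | y) with equal prior odds on null vs alternative.
    bor = float(1.0 / (1.0 + np.exp(f_alt - f_null)))
    pxp = bor / k + (1.0 - bor) * np.asarray(xp, dtype=float)
    return pxp, bor


def run_bms(
    evidence: EvidenceMatrix,
    prior_alpha: float = 1.0,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Full stack: Dirichlet posterior, XP, BOR, PXP."""
    alpha = group_bms(evidence, prior_alpha)
    xp = exceedance_prob(alpha, n_samples=n_samples, seed=seed)
    pxp, bor = protected_exceedance(evidence, alpha, xp, prior_alpha)
    return BMSResult(
        models=list(evidence.models),
        alpha=alpha,
        expected_frequencies=alpha / alpha.sum(),
        exceedance_prob=xp,
        protected_exceedance_prob=pxp,
        bor=bor,
        mc_samples=int(n_samples),
        seed=int(seed),
    )


def compare_variants(
    fits: dict[str, dict[str, float]],
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Group BMS over per-subject free energies of competing variants.

    ``fits`` maps variant label -> {subject_id: free_energy}.  Subjects
    missing a free energy for any variant are dropped with a warning.
    """
    import logging

    models = sorted(fits)
    common = set.intersection(*(set(fits[m]) for m in models))
    dropped = set.union(*(set(fits[m]) for m in models)) - common
    if dropped:
        logging.getLogger("hearttap").warning(
            "compare_variants: dropping %d subject(s) with missing fits: %s",
            len(dropped), sorted(dropped),
        )
    subjects = sorted(common)
    F = np.array([[fits[m][s] for m in models] for s in subjects])
    return run_bms(
        EvidenceMatrix(free_energies=F, models=models),
        n_samples=n_samples,
        seed=seed,
    )
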