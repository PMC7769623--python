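# Methods

## Trial construction

The unit of analysis is the interval between consecutive *perceivable*
heartbeats. A beat becomes perceivable at the EKG R-wave peak plus the pulse
transit time (PTT) — the delay before the pressure wave reaches the
periphery. The default PTT is 200 ms (a standard estimate for the earlobe);
`estimate_ptt` computes a subject-specific value as the median R-wave→PPG
onset delay, pairing each R-peak with the first PPG onset within 0.5 s (a
physiological upper bound that prevents pairing across beats). If fewer than
half of the R-peaks pair, the estimate is flagged and the 200 ms default is
recommended.

Each span between consecutive perceivable beats is halved at its midpoint:
the first half is the after-beat (systole-present) window, the second half
the before-beat (diastole) window. Two beats 1 s apart therefore produce a
500 ms systole window. Windows are half-open `[start, end)`, so a tap
exactly on a boundary belongs unambiguously to the later window; n beats
yield exactly 2(n−1) contiguous windows tiling `[e₁, eₙ)`. Conventions the
segmentation adopts where several were defensible:

- time before the first perceivable beat and after the last has no defined
  systole/diastole status and yields no trials; taps falling there are
  counted in provenance but unused;
- multiple taps within one window collapse to a single tap response (each
  interval is one tap/no-tap choice); the count is retained for QC;
- beats whose shifted time falls past the end of the recording are dropped,
  not clamped;
- the PTT-shifted times are used for the window boundaries throughout, not
  only for the first shift.

## Perception model

States are (start, no-heartbeat, heartbeat); observations are (start,
diastole, systole); each trial has two timesteps. The initial distribution D
is a delta on the start state, so the first-timestep belief needs no
numerics: it is exactly that delta. At the second timestep the posterior is

    s̄ = σ( ln(B·s₁) + ln(Aᵀ·o) )

where the start-column of B is (0, 1−pHB, pHB) and the systole/diastole
block of A has IP_raw on the matched diagonal. Structural zeros in A and B
are floored at e⁻³² inside the logarithm (the convention of standard
active-inference implementations); the posterior start-state mass is then of
order e⁻⁶⁴ and is discarded by renormalizing P(tap) over the two substantive
states. The result equals the two-state Bayes ratio

    P(HB | systole) = pHB·IP_raw / (pHB·IP_raw + (1−pHB)(1−IP_raw))

to ~1e-10; the matrix/softmax route and the closed form are kept as two
independent code paths and cross-checked in the tests. The response model is
`P(tap) = P(HB)` with no extra stochasticity parameter: in this task
response noise is not separable from IP_raw, as both flatten the posterior
that behavior is sampled from.

The learning variant places Dirichlet concentrations b = B·b0 on the
transition matrix and adds each trial's posterior to the start column (the
within-trial sum of state outer products contributes exactly one term,
because the first-timestep belief is the start delta). The next trial uses
the Dirichlet mean (column-normalized b). b0 is an inverse learning rate:
b0 → ∞ recovers the perception-only model (verified to 1e-4 over 200
trials); small b0 lets the prior belief track the running average of past
posteriors. Identity columns are never updated — the update's outer product
puts mass only in the start column.

An identifiability consequence worth stating: observations strictly
alternate systole/diastole, so a perception-only model can reproduce *any*
stationary pair of systole/diastole tap rates (solve the two Bayes-ratio
equations for IP_raw and pHB). The learning variant is therefore
behaviorally distinguishable only through the early-trial transient, while
its concentration counts are small — a genuinely small-evidence problem
that shapes the model-selection experiment below.

## Parameter estimation

Parameters are estimated in an unconstrained space — logit(IP_raw),
logit(pHB), ln(b0) — where the native prior means (0.5, 0.5, 1) map to 0.
The prior is Gaussian with variance ½ per dimension in that space,
deliberately tight to deter overfitting. The likelihood is the product of
Bernoulli terms P(response | tap probability), clipped at 1e-16 for
finiteness; for the perception-only variant it collapses onto the four
(observation, response) counts, while the learning variant is evaluated
sequentially.

The MAP is found by damped Newton ascent on the log-joint: central-difference
gradient and Hessian (step 1e-3), Levenberg–Marquardt damping (λ starts at
1e-2, ×10 on rejection, ÷3 on acceptance), started at the prior mean.
Accepted steps never decrease the objective; convergence is declared when an
accepted step improves it by under 1e-4 nats (at most 128 iterations). The
posterior covariance is the inverse negative Hessian at the MAP,
symmetrized and eigenvalue-clipped to be safely positive-definite (diagonal
fallback if the eigendecomposition fails, flagged on the result). The
Laplace free energy is

    F = ln p(y, θ_MAP) + (k/2)·ln 2π + ½·ln det Σ.

Across simulated subjects F agrees with brute-force 2-D trapezoid
integration of the joint (81×81 grid over ±5 in each unconstrained
dimension) to within ~0.05 nats and rank-correlates at ρ ≈ 1.0.

Derived measures: IP = |IP_raw − 0.5| (both raw extremes encode reliable
systole tracking — anticipatory near 0, reactive near 1), AvR = IP_raw.
Model accuracy is the fraction of trials whose response lies on the same
side of 0.5 as the fitted tap probability; an exactly chance-level
probability matches either response, so a chance model is not penalized
asymmetrically.

## Group model selection

Subject-level free energies feed a random-effects scheme: model frequencies
carry a Dirichlet(1, …, 1) prior, updated by the standard variational fixed
point (subject-wise model posteriors ∝ exp(F + ψ(α_k) − ψ(Σα)), α = prior +
summed posteriors, iterated to |Δα| < 1e-6). Exceedance probabilities are
Monte-Carlo fractions of Dirichlet draws in which each model's frequency is
maximal (default 1e6 draws, seeded). The Bayes omnibus risk compares the
variational free energy of this alternative against the null in which all
frequencies equal 1/K (evidence Σₙ[logsumexp(Fₙ) − ln K]) at equal prior
odds, and the protected exceedance probability is PXP = BOR/K + (1−BOR)·XP.
All outputs are invariant to per-subject additive constants on the evidence
rows. Note that with identical evidence the BOR grows toward 1 only like
the null-vs-alternative gap (~½·ln n): it is ~0.79 at n = 20 and exceeds
0.9 only around n ≈ 200, while PXP is pinned at 1/K by symmetry at any n.

## Synthetic data

The generators emulate the statistical structure the analysis relies on,
not cardiac physiology:

- **Beats** — inter-beat intervals are Gaussian around 60/rate (default
  71 bpm, SD 50 ms, floored at 1 ms) with an optional sinusoidal
  respiratory-sinus-arrhythmia modulation (default off; 13 cycles/min when
  used). Defaults give ~66–74 beats per 60 s trial, i.e. ~140 trials, the
  range typical of resting adults on this task.
- **Tones** — exactly n_tones (default 78) onsets over 60 s; base intervals
  sinusoidally modulated (amplitude 0.2) at 13 cycles/min, then jittered
  multiplicatively by a uniform ±10% draw (the jitter distribution is not
  otherwise constrained; uniform is assumed), and rescaled uniformly if the
  schedule would overflow the trial. The count never depends on the jitter.
- **Tappers** — per-trial responses are Bernoulli draws from the model's
  tap probability; sampled taps are placed uniformly inside their window
  (segmentation uses window membership only, so placement is
  inconsequential — re-segmentation reproduces the sampled responses
  exactly, verified over 1000 seeds).
- **Cohorts** — per (group, condition) cell, parameters are drawn from
  configurable normal or uniform distributions. Group summaries in the
  literature report the folded precision only, so cells may specify IP
  (truncated to [0, 0.5)) which is unfolded as IP_raw = 0.5 + IP under the
  default reactive convention, or IP_raw directly. Sampled probabilities are
  clipped to [1e-3, 1−1e-3]. Per-subject streams derive from the master
  seed via a CRC-keyed SeedSequence, so cohorts are reproducible and
  insensitive to generation order.

What the generators do *not* emulate — real EKG morphology and artifacts,
ectopic beats, reaction-time jitter between percept and key press, motor
noise, within-trial nonstationarity of heart rate under breath-holding —
bounds what passing tests show: they certify the pipeline's statistical
machinery (segmentation, inference, estimation, selection) under the model's
own assumptions, not robustness to physiological confounds.

## Validation experiments and problem sizes

- **Parameter recovery** — 100 subjects, one 60 s trial each (~140 model
  trials), truth uniform on IP_raw ∈ (0.05, 0.95), pHB ∈ (0.1, 0.9):
  Pearson r(truth, estimate) ≥ 0.8 and |mean bias| ≤ 0.05 for both
  parameters (observed r ≈ 0.97–0.99, |bias| < 0.01). Estimates shrink
  toward 0.5, as the prior dictates; the truth ranges are centered there, so
  shrinkage cancels in the mean.
- **Variant recovery** — cohorts of 20 subjects simulated from each variant,
  both variants fitted to every subject, group BMS on the free energies.
  The generating regimes are chosen where the variants are behaviorally
  separable, mirroring the task conditions in which each variant wins on
  real cohorts: perception-only cohorts use a suppressed prior
  (IP_raw ∈ (0.6, 0.9), pHB ∈ (0.1, 0.3), the no-guessing/breath-hold-like
  regime) where the learning model's drift toward its fixed point is a
  misfit; learning cohorts use a precise signal (IP_raw ∈ (0.85, 0.95),
  pHB ∈ (0.3, 0.7), tone-like) with a fast learner (b0 = 0.25). Cohort
  parameters sit on stratified grids with coprime-stride pairing rather
  than random draws, so the cohort represents its regime at any size
  without parameter-sampling luck. With moderate precision and pHB near
  0.5 the two variants are nearly indistinguishable (PXP ≈ 0.5) — the
  expected behavior given the identifiability argument above, and the
  package reproduces it rather than hiding it.
- **Outlier screen** — iterative two-sided Grubbs at α = 0.01 (critical
  value from the t-distribution) has a per-dataset false-positive rate at
  the nominal α under a normal null (1000 replicates, binomial tolerance)
  and catches a planted 8-SD point essentially always.

## Numerical choices and degenerate inputs

- log floor e⁻³² before every softmax; likelihood clip 1e-16; probabilities
  clipped to [1e-12, 1−1e-12] when mapping unconstrained iterates back to
  native parameters (expit saturates in floating point beyond |η| ≈ 37).
- Fewer than two perceivable beats, an empty trial table, or a zero-length
  group list raise immediately with a descriptive message; an empty trial
  sequence passed to the likelihood returns 0 with a logged warning.
- Grubbs on a zero-variance sample returns no outliers; the iteration stops
  below n = 3.
- Ties: a tap exactly on a window boundary goes to the later window; a tap
  probability exactly 0.5 counts as matched for either response.

## Known limitations

- The estimation scheme is a generic damped-Newton MAP with a Laplace free
  energy; it does not reproduce any particular legacy optimizer's iteration
  schedule, only the estimator it defines.
- The learning variant updates only the transition concentrations' start
  column; likelihood (A-matrix) learning is out of scope.
- Group-level covariate analyses (mixed-effects models, Bayes-factor model
  spaces over group structures) are deliberately not part of the package;
  the fit tables are designed to be exported to standard statistical tools.
- b0 is weakly identified whenever the generating process is stationary;
  fits of the learning variant to such data return b0 near its prior, and
  model selection, not the b0 estimate, is the meaningful readout.
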