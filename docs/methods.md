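# Methods

## The task

The probabilistic reversal learning (PRL) task presents two abstract
stimuli, one on each side of the display (sides randomised independently
per trial with p = 0.5). One stimulus — the CS+ — is rewarded on 85% of
the trials on which it is chosen; the other (CS−) on 15%. After 10–15
correct responses the contingencies silently reverse. A block consists of
ten such discriminations, hence nine reversals; the cohort design is 18
controls, 18 participants with gambling disorder and 20 with cocaine use
disorder, each completing three blocks.

Two design details are not fully determined by the published description
and were resolved as follows:

* **Criterion counting.** "Correct response" is taken to mean a choice of
  the current CS+, irrespective of the (probabilistic) feedback actually
  delivered, and the 10–15 criterion counts correct responses
  *cumulatively* within a discrimination. The alternative — an unbroken
  streak that resets on any incorrect choice — makes the printed block
  structure arithmetically unreachable: even a flawless responder needs at
  least the sum of the drawn criteria (~125 trials) per block, and a
  realistic responder choosing the CS+ on ~85% of trials would need on the
  order of 400 trials per block to produce nine streak-based reversals.
  Cumulative counting lets a typical learner complete a block in roughly
  150–200 trials, which is the only reading compatible with every block
  containing ten discriminations. The streak rule remains available via
  ``TaskConfig(criterion_consecutive=True)``. Probabilistic negative
  feedback on a correct choice never affects the count in either mode.
* **Block termination.** A block ends when its tenth discrimination is
  solved; ``trials_per_block`` (default 360) is a safety budget after
  which an unfinished block is truncated rather than extended, so the
  number of trials per block is an emergent quantity, as in a
  fixed-duration scanner run. Missed ("too late") responses are not
  simulated; the model family has no omission mechanism.

## The model family

All six candidate models are stickiness-augmented Q-learning (Rescorla–
Wagner) models. The chosen stimulus's value is updated by

    Q_{t+1}(c_t) = Q_t(c_t) + α · (r_t − Q_t(c_t)),   r_t ∈ {0, 1},

with the learning rate α split into α_rew (applied when r = 1) and α_pun
(when r = 0) in the split-rate models. Choice follows a softmax over the
two on-screen options whose logit adds outcome-independent one-back
stickiness terms:

    P(left) = σ( β (Q(left) − Q(right))
                 + κ_stim (1[prev stim = left stim] − 1[prev stim = right stim])
                 + κ_side (1[prev side = left] − 1[prev side = right]) ).

Indicators are zero on the first trial of a run. The registry is

| model | learning rates | κ_stim | κ_side | free parameters |
|-------|----------------|--------|--------|-----------------|
| 1 | single α | – | – | 2 |
| 2 | single α | ✓ | – | 3 |
| 3 | single α | – | ✓ | 3 |
| 4 | single α | ✓ | ✓ | 4 |
| 5 | α_rew, α_pun | – | – | 3 |
| 6 | α_rew, α_pun | ✓ | ✓ | 5 |

Model 6 is the winning model used for simulation and regressor extraction.
Q-values are initialised at 0.5 for both stimuli at the start of each
block (uninformative midpoint), and learner state (values and one-back
history) resets at block boundaries because each block uses a fresh
stimulus pair; ``reset_between_blocks=False`` carries state across blocks
but then requires a single shared stimulus pair. With r ∈ {0, 1} and
α ∈ [0, 1] all Q-values remain in [0, 1], so β (Q_L − Q_R) is bounded by β.

## Hierarchical Bayesian estimation

Each group has its own mean and SD per free parameter on an unconstrained
scale (logit for learning rates, log for β, identity for κ); subjects are
non-centred offsets from their group distribution. Priors are weakly
informative: group means ~ Normal(0, 1), group SDs ~ half-Normal(1),
subject offsets ~ Normal(0, 1). On the natural scale the implied prior
median of β is 1 with a heavy right tail; all hyperparameters are exposed
in the configuration.

Sampling uses a No-U-Turn sampler written for this package: multinomial
trajectory sampling, dual-averaging step-size adaptation (target
acceptance 0.8), Stan-style windowed diagonal mass-matrix adaptation, a
divergence threshold of 1000 on the energy error, and a maximum tree depth
of 10. Gradients of the log-posterior are exact: Q-values depend only on
the learning rates, so forward sensitivities dQ/dα_rew and dQ/dα_pun are
propagated through the value recursion, while β, κ_stim and κ_side enter
the choice logit linearly; the kernel is compiled with numba and was
verified against central finite differences. Defaults are 4 chains of
1000 warm-up and 1000 retained iterations.

Convergence is summarised by the split-R-hat and effective sample size
(via ArviZ) of every group mean and SD on both scales, every subject-level
parameter, and every pairwise group contrast; the fit is flagged
non-converged when any R-hat ≥ 1.1. Model comparison uses PSIS-LOO
expected log predictive density with subject-wise pointwise likelihoods
(WAIC fallback), comparing raw criteria — models equiprobable a priori.

Group contrasts are computed on the natural scale: each draw of the group
mean location is transformed, then differenced, and summarised by 75% and
95% highest density intervals. The HDI of a sample is the narrowest
contiguous window containing ⌈mass·n⌉ sorted draws (ties broken toward
the lower window); it requires at least 100 draws.

## Synthetic cohorts

Because the study data cannot be shared, cohorts are simulated from the
winning model. Group-level generative defaults correspond to natural-scale
medians α_rew ≈ 0.40, α_pun ≈ 0.30, β ≈ 3, κ_stim ≈ 0.25, κ_side ≈ 0.10
with unconstrained-scale SDs of 0.5/0.5/0.4/0.3/0.3 — magnitudes typical
of stickiness-softmax fits to reversal learning in clinical cohorts. By
default all three groups share these values; group differences are
induced explicitly (e.g. lowering the gambling-group κ_stim mean by 0.4
to emulate the stimulus-stickiness deficit scenario). Every subject runs
on an independent RNG stream keyed by (master seed, subject index), so
cohorts are bit-reproducible and order-independent.

The generator emulates the study's design constants, not its nuisance
processes: there are no missed responses, no reaction times, no
within-session drift or fatigue, and subjects are exchangeable within
group. Passing recovery and calibration checks on these cohorts therefore
demonstrates that the estimation machinery is sound under the design,
not that real participants satisfy the model's assumptions.

## fMRI regressors

Expected values and prediction errors are extracted by replaying the
fitted model deterministically over each subject's observed choices with
that subject's posterior-mean parameters (standard practice in
model-based fMRI; full posterior propagation is available by transforming
each draw). Q_t(c_t) is recorded before the update; δ_t = r_t − Q_t(c_t).

The published verbal definitions of the six model-based event types are
internally inconsistent (a "punishment prediction error" cannot be
positive on rewarded trials under a signed-δ reading). The implemented
rule — expectation type from Q_t(c_t) ≥ 0.5 versus < 0.5, outcome
splitting positive versus negative — is the only scheme that yields six
mutually exclusive event types with the stated ranges: rewarded-trial
modulators δ = 1 − Q ∈ [0, 1] and punished-trial modulators δ = −Q ∈
[−1, 0]. The 0.5 threshold and its tie-break (ties count as reward
expectation) are configuration options. Event files use the FSL
three-column format with onsets from the published timing (2 s stimulus,
0.5 s feedback, 3.253 s inter-stimulus interval → 5.753 s trial spacing);
modulators are mean-centred per file by default, and a seventh
response/feedback file carries unit amplitudes.

## Behavioural measures

``prop_correct`` is the fraction of trials choosing the current CS+.
``trials_to_criterion`` averages trial counts over completed
discriminations only — those terminated by a reversal — excluding the
trailing discrimination of a truncated block. A perseverative response is
each post-reversal choice of the previously correct stimulus before the
first choice of the newly correct one. The posterior-predictive check
re-simulates the task from fitted subject parameters and flags group
means of these measures that fall outside the central 95% interval across
replicates.

## Problem sizes and numerical choices

MCMC-based checks run at deliberately reduced scale, chosen once from
pilot runs and then frozen: convergence and contrast checks use
12–16-subject cohorts; recovery pools subjects from two 12-subject
cohorts fitted with 2 chains of 400+400 iterations; the null-contrast
calibration uses eight single-block replicate cohorts. Pilot runs at
these settings gave truth-versus-posterior-mean correlations of 0.83–0.96
for all five parameters, comfortably above the 0.7 criterion, and
recovery of the stickiness-deficit contrast at the 75% (but not 95%)
level, mirroring the strength of evidence reported for the real cohort.
Tolerances on stochastic quantities are three binomial standard errors.

## Known limitations

* The exact priors, chain counts and comparison metric of the original
  analysis are unpublished; the defaults here are explicit, disclosed
  stand-ins, and LOO rather than an unknown criterion ranks the models.
* Contrasts are computed on transformed group-location draws (the group
  median on the natural scale); if the original analysis contrasted
  another functional, numerical values would differ while the
  exclusion logic is unchanged.
* The sampler is single-threaded; chains run sequentially.
* Perseveration and criterion-counting conventions follow the prior
  literature as documented above, not a published operationalisation.
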