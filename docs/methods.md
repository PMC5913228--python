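# Methods

## The task and its state space

The transreinforcer reversal-learning task pairs two conditioned stimuli
(CS 0, CS 1) with food-odor outcomes (US) that vary along two orthogonal
dimensions: identity (sweet vs savory) and intensity (high vs low; the
value dimension).  Within a block both CSs predict the *same* identity
and *opposite* intensities, so exactly four CS-US mappings ("task
states") exist.  Sessions are 84 trials in 8 contiguous blocks — four of
9 trials and four of 12, order pseudorandomized — separated by seven
covert reversals that strictly alternate between identity reversals
(iREV: identity flips, CS-value assignment kept; a DISV transition) and
value reversals (vREV: CS-value assignment swaps, identity kept; SIDV).
Two thirds of trials are forced choices; every block opens with two
forced trials, one per CS, so reversals always land on forced trials.
The randomization scheme for block order and free-trial placement is not
dictated by the design, so the generator shuffles block lengths
uniformly (preferring the balanced four-and-four length mix) and places
the extra forced trials uniformly outside the two opening positions,
all under a seeded generator.

## The reinforcement-learning model

The agent keeps a cached expected value per CS (EV_1, EV_2, initialized
at 0) and a single shared expected identity EI = P(sweet), initialized
at 0.5.  On each responded trial, with delivered value V ∈ {0, 1} and
identity I ∈ {0, 1}:

    vPE = V − EV_S            EV_S  ← EV_S  + α · vPE
    fPE = (−V + 1) − EV_NS    EV_NS ← EV_NS + α · fPE
    iPE = I − EI              EI    ← EI    + α · iPE

The fictive (counterfactual) update exploits the anti-correlated values
within a block; the single EI is updated for both CSs at once because
both predict the same identity.  Choice follows a softmax on the EVs
with slope θ = 3^c − 1, a parameterisation that reaches
near-deterministic choice at moderate c.  Free parameters: α ∈ (0, 1)
and c ≥ 0; c is bounded by a configurable `c_max` (default 5, i.e.
θ ≤ 242) because the hierarchical prior needs a bounded support.
Variants: `shared_alpha` (one α for all three updates; the reference
model), `split_alpha` (separate α for the value and fictive updates),
and `no_fpe` (no fictive update).

Likelihood: only responded free-choice trials enter (forced choices are
fully cued and carry no parameter information; a flag scores all
responded trials instead).  Missed trials contribute neither likelihood
nor updates.  Expectations carry over across a subject's three runs by
default (the associations persist across runs); a flag resets them.
Probabilities are clipped to [1e−12, 1 − 1e−12] before logs, and the
softmax is computed in log-sum-exp form.

## Parameter estimation

`fit_subject` is a bounded point estimator on the unit-scaled
parameters (α, c/c_max).  Plain maximum likelihood diverges to the
boundary (α → 1, c → c_max) whenever the realized free choices are
fully consistent with the converged values — a separation phenomenon,
not an optimizer failure — so the default objective adds a weak
symmetric Beta(1.5, 1.5) prior (MAP).  For recovery work the
`"bayes"` estimator returns the posterior mean on a 60×60 grid, which
averages over the likelihood ridge instead of picking a corner of it.
Reported NLLs are data likelihoods at the estimate, so AIC/BIC remain
likelihood-based.

`fit_hierarchical` is the reference method: unit-scaled subject
parameters are Beta(μ_k, σ_k) with μ_k ~ Normal(0.5, 1) truncated to
(0, 1) and σ_k ~ Uniform(0.01, 0.5) restricted to the valid beta moment
region — weakly informative hyperpriors matching the structural
description of the estimation scheme.  Sampling is
Metropolis-within-Gibbs: per sweep, all subjects' parameters are
proposed jointly (reflected Gaussian steps, vectorised across subjects
through a compiled multi-subject likelihood kernel), then each
hyperparameter is updated conditionally.  Defaults are 3000 retained
samples after 1000 burn-in with three chains; split-R̂ (via arviz) is
reported for every parameter and values above 1.1 are surfaced as
warnings, never dropped.

Model comparison sums per-subject point-fit NLLs over identical trial
sets; k counts subject-level parameters (2 or 3 per subject), with an
option to add the four parent-distribution parameters per subject-level
parameter; n_obs for BIC is the total number of responded free-choice
trials.

## Synthetic cohorts and planted effects

The generator reproduces the study conditions: 23 subjects × 3 runs ×
84 trials, TR 2 s, trial spacing 15 ± 2 s, with (α, c) drawn from beta
parents (α: mean 0.5, sd 0.15; c: mean 1.5, sd 0.5 — plausible for
human reversal learning and wide enough that recovery is non-trivial).
Choices come from the generative model itself.

Neural data live on a 16³ grid (keeps a full searchlight pass to
seconds per subject) with disjoint box ROIs — midbrain, OFC, amygdala,
control — inside an in-brain mask.  Three effects are planted:

* **Midbrain PE response.**  Each odor delivery adds an impulse of
  amplitude `gain_j · (0.5 + β_iPE·|iPE| + β_vPE+·vPE⁺ + ε_t)` to every
  midbrain voxel, convolved with a double-gamma HRF (peak 5 s) sampled
  on the FIR bin grid and scaled so bins 3–5 average to 1 — hence a
  noiseless FIR fit returns exactly the planted β.  `gain_j` is a
  subject gain (sd 0.25) and ε_t a trial-level amplitude fluctuation
  (sd 0.5).  ε_t matters: it is the trial-specific midbrain signal that
  the coupling analysis traces downstream.
* **State patterns.**  Each task state has a fixed multivoxel pattern:
  in OFC a shared identity component (amplitude 1) plus a small
  state-unique component (0.3); in amygdala a CS-value component plus
  the unique component.  The cross components are zero, so OFC codes
  identity only and amygdala value only — the planted analog of the
  reported dissociation.  CS-evoked responses are boxcars (cue to
  choice) convolved with the same HRF, scaled per voxel by the
  *expressed* pattern.
* **Coupling.**  The expressed pattern follows the revealed state with
  step `clip(0.2 + κ·amp_t, 0, 1)` after each US, so trials with larger
  midbrain amplitude produce larger next-trial expectation updates.
  At κ = 0 updates still happen (baseline step 0.2) but are unrelated
  to midbrain fluctuations.  Default κ = 0.25; beyond κ ≈ 0.3 the step
  saturates at its clip bound and detectability declines, so
  dose-response checks use κ ∈ {0.05, 0.1, 0.2}.

Respiration traces (10 Hz) are a slow sinusoid plus noise with
US-locked sniff bumps that are larger, later-peaking and wider for
high-intensity odors.  Gaussian noise (sd 1) is added to every in-brain
voxel.  Everything is reproducible from the config seed.

What the generator does **not** emulate: scanner drift, motion,
physiological aliasing, spatial autocorrelation of noise, hemodynamic
variability across regions, and non-compliant behavior.  Passing tests
therefore demonstrate that the analysis code recovers what it claims to
recover under its own generative assumptions — not that the effects are
detectable in real fMRI noise.

## Univariate engine

FIR designs use nine unconvolved post-onset scan bins (bin 1 at the
onset scan; onsets mapped to the nearest scan, configurable to floor).
Each parametric modulator is mean-centered per run and multiplies the
bin indicators; serial orthogonalization is deliberately not offered —
correlated modulators share variance, and VIFs are reported instead.
Event-related designs (for the pattern analyses) are HRF-convolved
boxcars.  Estimation is OLS with a pseudo-inverse fallback (flagged) on
rank deficiency; effects are the mean of a modulator's betas over bins
3–5 (6–10 s post onset), bracketing the hemodynamic peak given the ~2 s
latency to peak inhalation.

## Pattern analysis

Per run, a template GLM estimates CS-evoked patterns for the two
occurrences of each state (forced trials; free trials, odor onsets and
rating onsets get their own regressors), and a test GLM estimates one
pattern per trial.  Searchlight spheres are Euclidean balls of radius 3
voxels (123 voxels on an isotropic grid); spheres with fewer than 10
in-mask voxels are skipped and logged.  For each leave-one-run-out fold
the four templates are occurrence-averages over the two template runs
with the per-voxel mean across states removed (so templates sum to zero
per voxel); each forced test trial's pattern is Pearson-correlated with
the four templates, Fisher z-transformed (r clipped at ±(1−1e−7), since
noiseless self-correlations can hit 1), labeled SISV/SIDV/DISV/DIDV by
the relation between trial state and template state, and trial-averaged
per label at the sphere center.  Test trials are forced-choice by
default (flag to include free trials; another flag can exclude
immediate post-reversal trials).

## Coupling analyses

At an OFC voxel set, identity information is the mean template z over
the two sweet states minus the two savory states; the update is the
absolute difference between consecutive forced trials within a run (no
update across run boundaries; the run's last entry carries none).  The
trial-level GLM modulates the forced-US FIR response by the z-scored
update, with the three PE modulators as covariates and free-choice
deliveries in a separate FIR set.  The covariates are essential: both
the update trace and the PE response are reversal-locked, so without
them a κ = 0 world yields spuriously positive coupling out of shared
task structure; with them, the update beta isolates US-evoked variance
beyond the deterministic PE response.  The subject-level analog
correlates each subject's midbrain |iPE| beta with the mean
pre-to-post-iREV change in post-state-referenced identity information,
where "post" is the first forced trial strictly after the reversal
trial (the reversal trial's own CS pattern still expresses the old
expectation).  The directional control splits |iPE| by the direction of
the most recent identity reversal; trials before a run's first iREV
fall into an unmodulated set.

## Group inference

One-sample and paired t-tests and Pearson correlations on per-subject
values; voxelwise one-sample t-maps across subject contrast maps; and
within-ROI Bonferroni correction in place of random-field family-wise
control — conservative, dependency-free, and testable by null
simulation.  Behavioral reversal curves index free choices by
free-choice order (−3..−1, +1..+3 around each reversal), scoring each
plotted trial against its own block's high-intensity CS.
Repeated-measures ANOVA is not re-implemented; the tidy condition
tables it would consume are emitted instead.

## Validation design and problem sizes

The test suite validates each stage against independent oracles
(hand-arithmetic update examples, a pure-python step-by-step NLL
recursion on ≤8-trial sessions at 1e−10, closed-form t/r statistics,
linear-algebra template identities) and then round-trips the full
pipeline on planted cohorts.  Scale choices, made once:

* Parameter recovery plants α on an even grid over (0.15, 0.85) with c
  fixed at 1.5 across 23 agents × 252 trials — the standard
  one-factor-recovery design.  Under the cohort's own narrow parent
  (sd 0.15) α is only weakly identified from 84 free choices per
  subject, an identifiability property of the task, not an estimator
  defect (MAP, posterior-mean and hierarchical estimators all plateau
  around r ≈ 0.5–0.8 there).
* Hierarchical coverage uses 10 replicate cohorts of 23 subjects with
  α ~ Beta(4, 4), at 1000 retained samples / 500 burn-in / 3 chains
  (reduced from the reference settings; coverage, not precision, is the
  question).
* Model recovery uses 20 replicate cohorts of 23 slow learners
  (α ~ U(0.12, 0.4)).  Slow learning is the regime in which the
  fictive-update variants make distinguishable choice predictions;
  fast learners re-converge within the two forced openers and the
  shared vs no-fictive comparison collapses to a coin flip (per-subject
  expected NLL margin ≈ 0.02 nats) — consistent with the near-zero AIC
  margin such comparisons show in practice.
* False-positive control is checked with 200 reduced null replicates
  (8 subjects each) at both the GLM level and the pattern level,
  asserting the rejection count inside the exact central 95% binomial
  interval at the 5% test level.
* MVPA localization runs the full searchlight on 6 subjects; coupling
  detection uses 20 replicate cohorts of 6 subjects at κ = 0.25.

`scripts/acceptance.py` re-runs the entire pipeline at the full study
scale (23 subjects) and writes every headline statistic it computes.

## Known limitations

* The amplitude of the OFC SISV−SIDV difference is slightly positive
  (not exactly zero as an idealized identity-only code would give):
  the state-unique pattern component and the update lag after
  reversals both favor the exact-state template.
* The Gibbs sampler mixes adequately for coverage but split-R̂ can
  exceed 1.1 on subject-level parameters at reduced chain lengths; the
  warnings are surfaced in the fit object.
* Onset-to-scan mapping quantizes event timing to the TR grid; no
  sub-TR microtime resolution.
* BOLD noise is white; autocorrelation-aware inference (prewhitening)
  is out of scope.
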