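# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `curiolearn`.

## The task world

Hiding locations live on a normalised one-dimensional strip [0, 1].
Four pattern types are generated from Gaussians whose latent mean can
drift (reflected at the boundaries) or be resampled uniformly on [0, 1]
with a per-trial change-point probability (CPP):

| label | noise sd | drift/trial | CPP |
|---|---|---|---|
| LOW_NOISE_DRIFT | 0.03 | 0.005 | 0.01 |
| HIGH_NOISE | 0.25 | 0 | 0 |
| HIGH_CPP | 0.03 | 0 | 0.15 |
| DRIFT_CPP | 0.03 | 0.02 | 0.15 |

The numeric levels are package defaults realising the intended
qualitative contrasts (three learnable patterns, one unlearnable);
they are configurable.  `build_experiment` assigns one pattern of each
label to the four animals of each of three settings, using a
seed-indexed permutation (24 consecutive seeds enumerate all 4!
assignments for a setting), and draws each animal's home location
(`mean0`) uniformly from [0.15, 0.85] so that patterns start away from
the strip centre and there is something to learn from the first trials
on.  A setting ends when any animal has hidden 35 times or 90 trials
have been played; the last trial of a cap-ended setting is marked as a
forced transition and excluded from leave-stay observations, because a
forced exit is not a decision.

## The learner

Beliefs about one animal follow two coupled delta rules (position and
drift), with the position learning rate switching between a low and a
high value through a latent per-trial Bernoulli(φ) indicator; observed
predictions are Gaussian around the current belief with variance η.
Both updates use the pre-update state.  The belief about a newly
engaged animal is initialised at that animal's first observed location
with zero drift, and the first trial contributes the response
likelihood at that initial belief; beliefs persist when an animal is
revisited (unselected animals are frozen).  An alternative convention
(likelihood evaluated after integrating the drift term) is possible
from the equations' indexing; the implemented convention is
predict-with-current-V, then update.

Estimation pools all participants who played a given animal: the five
parameters are shared, the indicators are latent per participant-trial.
Priors: α_low, α_high ~ Uniform(0, 1) with the ordering
α_low < α_high enforced by rejection, φ ~ Beta(1, 1),
β ~ Uniform(0, 1), and Gamma(0.01, 0.01) on the precision 1/η.  The
sampler is Metropolis-within-Gibbs: logit-scale random walks for the
rates and β, a log-scale walk for η, a conjugate Beta draw for φ, and
a single-site Gibbs sweep over every zₜ with the forward pass
recomputed from the flipped trial onward (O(T) per site, T ≤ 90).
Proposal scales adapt toward ~40% acceptance during burn-in only.
Two further choices matter for mixing of the tightly coupled
(α_high, z) pair: three full update sweeps are run per stored draw,
and the likelihood is annealed (inverse temperature ramping 0.3 → 1
over the first 80% of burn-in) so chains escape secondary modes of the
indicator configuration before sampling.  Convergence is declared when
every parameter's split R-hat (arviz) is below 1.05; non-convergence
is flagged on the results object, never silent.

Parameter recovery at the package's reference conditions (20
participants × 60 trials on a HIGH_CPP pattern, truth α_low = 0.2,
α_high = 0.8, φ = 0.1, β = 0.05, η = 0.0025; 3 chains × 2000 draws,
50% burn-in) returns posterior means within ±0.02 of the rates and φ
and η within a few percent, comfortably inside the ±0.15 / factor-two
acceptance bands.

## Exploration drives

Per trial: PEₜ = |rₜ − Vₜ| (the equations' signed error is used only
inside the belief updates); LPₜ = PEₜ₋₁ − PEₜ, defined from the second
consecutive trial of an engagement (undefined rows enter regressions at
the predictor mean); novelty = −cumulative exposure within the setting
(revisits accumulate; the engagement-local count is also stored);
expected PE follows the same delta rule driven by the realised α\*ₜ,
initialised at the animal's first realised error; expected LP is the
current error minus the next trial's expected error.  Options never
played carry novelty 0, expected error 1/3 (the mean absolute error of
a uniform guess against a uniform target) and expected progress 0.
Summed LP over an engagement telescopes exactly to first-minus-last
error, and expected PE is a convex combination of the errors seen so
far — both are enforced as property tests.

Because expected LP is defined as PE − expected PE and standardisation
is affine, the two candidate leave-stay variable sets that contain
expected LP span identical design spaces and tie exactly in the AIC
comparison; the comparison's winner is unaffected.

## Synthetic cohort

Each participant has a standard-normal latent trait.  The 44-item
questionnaire uses an ordered three-category response model with fixed
per-item thresholds (spread over [−1, 1], second threshold 1.5 higher,
discrimination scale 0.7); the informant perceives the trait with
Gaussian noise (sd 0.35 self, 0.25 other — other-reports are treated
as the more reliable source).  Items partition into six domains
(8/7/8/6/7/8 items); Spearman correlation between the latent trait and
the total score is ≈ 0.9.  Both report variants are generated for
every participant; a returned-questionnaire missingness mechanism is
deliberately not simulated.

The agent plays the task with its own delta-rule learner (centre-prior
V₀ = 0.5 for unseen animals — an uninformed agent cannot start at the
true location, and this gives first engagements a genuine learning
curve), leaves with probability logistic in learning progress,
expected error and novelty (progress and expected-error weights ramp
from an early to a late value along a logistic in engagement time,
centre 6 trials, width 3), and chooses the next animal by conditional
logit over the frozen novelty / expected progress / expected error of
the three alternatives.  The default trait links plant the structure
the analyses look for: low-trait agents weight progress early and
expected error late, high-trait agents are more persistent and weight
progress late (both targeted trait-by-time interactions negative);
everyone prefers novelty; expected-progress seeking rises and
expected-error avoidance falls with the trait; and the low learning
rate rises with the trait.  Setting every slope to zero yields null
cohorts for type-I studies.  Optional mechanisms, off by default, give
the generator within-engagement learning curves when a study needs
them: memory retention (the remembered belief shrinks toward the
centre on re-engagement), a switch-disruption kick (one-time Gaussian
perturbation of the belief on re-engagement), and attentional warm-up
noise on perceived outcomes after a switch.

What the generator does *not* emulate: reaction times, response
biases, within-session fatigue other than the boredom report,
questionnaire masking, or any dependence of the boredom report on
task experience (it is drawn uniformly from {after setting 1, 2, 3,
never}).  Passing tests therefore validate the estimation and
inference machinery under a known generative process, not the
substantive human findings.

## Decision analyses

*Leave-stay.*  Binomial mixed model with random intercepts for
participant, setting, pattern type and animal, and fixed effects:
each of three drives in full factorial interaction with standardised
engagement time and the standardised trait score (16 terms).  All
predictors are z-scored globally over the analysed data.  Estimation
is maximum likelihood under the Laplace approximation, implemented
in-package (no Python package offers ML binomial GLMMs with crossed
random effects): penalized IRLS over (β, u) inside, Nelder-Mead over
the log random-effect SDs outside; the reported log-likelihood is the
Laplace approximation, AIC/BIC count fixed effects plus one variance
per factor, and deviance is −2·logLik.  Wald z p-values are used for
fixed effects.  The implementation agrees with lme4's Laplace fit to
within 0.03 on coefficients and 0.3 on logLik on test problems (a
small systematic difference remains because β is profiled inside the
penalized step here but optimised in the outer loop by lme4).
Separation or non-convergence is flagged on the result, not raised.

Wald calibration of the three-way interaction test under null cohorts
is approximately nominal but regime-dependent: measured rejection at
α = .05 is ≈ 8.5% for 20 participants × 2 settings, ≈ 4% at 24 × 2
settings (the calibration study's size), and ≈ 2% at 30 × 3 settings.

*Exploratory choice.*  McFadden conditional logit over the three
options available at each free leave (statsmodels `ConditionalLogit`;
one group per event, exactly one chosen option), attributes z-scored
over option rows; no random effects, and the trait enters through a
mean split (low = below the sample mean, ties go high) with one model
per group, mirroring the two-group design the multinomial tooling
forces.  Groups with < 50 events are flagged low-power.

*Learning performance.*  Linear mixed models of standardised PE on
time × pattern × trait, ML-fitted, compared with and without the
three-way interaction by a likelihood-ratio test with 3 degrees of
freedom (the trait × time contrasts of the three non-reference
patterns, reference = HIGH_NOISE).  Two implementation points matter:

1. Random-effects structure: a participant intercept alone is badly
   miscalibrated (null mean χ² ≈ 4.5–5, rejection 16–20%) because PE
   is autocorrelated within engagements, overdispersing
   per-participant learning-curve slopes; adding a random time slope
   per pattern within participant restores calibration (null mean χ²
   2.96–3.36, rejection 4–6% across the studied regimes).
2. The ML optimum must actually be found: generic optimizers on this
   five-component variance structure stall by whole logLik units,
   which is the same order as the test statistic.  The models are
   therefore fitted with an exact profiled-ML engine (lme4-style
   penalized-least-squares identity with β, u and the residual
   variance profiled out; Nelder-Mead over the log variance ratios
   from two deterministic starts), which matches statsmodels to 1e-3
   on structures statsmodels handles reliably.

*Power study for the learning link.*  Detecting a trait-linked
learning-speed difference with this LRT is intrinsically hard in the
simulated world: per-participant learning-curve slopes vary strongly
with pattern realisations and engagement timing, and policy-driven
leaving selects trajectories.  The dedicated study design
(`PolicyLink.learning_speed_study`) uses persistent agents with
trait-independent policies, a trait-linked switch-disruption +
repair-speed gradient, stimulus sequences yoked across participants,
full logs, the latent trait as moderator, and 140 participants; its
measured power is ≈ 0.8 per replicate, and the test asserts a majority
of rejections over 7 replicates.  At 70 participants the same design
yields ≈ 40% power — a finding worth knowing when sizing a real study
of this effect.

## Preprocessing

Participants flagged as not having understood the task are removed
entirely; for the rest, every setting strictly after the one in which
boredom was reported is discarded — before any model fitting.  The
report reconciles counts exactly (after = before − discarded) and the
reconciliation is asserted in code.

## Problem sizes used by the tests and the acceptance script

Chosen to exercise each property at meaningful scale: forward-recursion
oracle, 100 random instances; telescoping, one 20-participant cohort;
MCMC recovery and change-point attribution, 20 × 60 trials with
3 × 2000 draws; planted leave-stay recovery, 11 cohorts of n = 70;
type-I calibration, 200 null cohorts (150 in the script) of 24
participants × 2 settings; model selection, 20 cohorts (12 in the
script) of n = 35; learning-speed power, 7 replicates (5 in the
script) at n = 140.

## Known limitations

- The Laplace GLMM profiles β inside the penalized step; its Wald
  calibration is approximate and regime-dependent (measured above).
- The generator's leave policy uses nominal (fixed-scale) predictor
  units, so planted weights correspond to recovered standardized
  coefficients only up to a monotone rescaling; signs are preserved.
- The boredom report is independent of experience, so the boredom
  filter's selection effects in real data are not emulated.
- Exact marginalisation over indicator paths is exponential and not
  attempted; inference for z is single-site Gibbs, and multimodality
  is handled by burn-in annealing rather than mode-jumping moves.
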