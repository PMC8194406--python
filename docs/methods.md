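# Methods

This note documents the models implemented in `facevoice`, the defaults of
the synthetic-data generator, the numerical choices, and known limitations.

## Decision model and perceptual scales

Paired gender comparisons are modeled in a signal-detection framework.  A
stimulus is a point `(phi_V, phi_A)` on the morph lattice, `phi in [0, 1]`
running from most feminine to most masculine with equal spacing between
morph steps (the physical spacing of the morph continuum is not otherwise
defined, and the scale estimates are plotted against level index anyway).
The noiseless decision value for an ordered pair is

    delta = beta_V (g_V(phi1_V) - g_V(phi2_V))
          + beta_A (g_A(phi1_A) - g_A(phi2_A))
          + theta_cong (|g_V(phi1_V) - g_A(phi1_A)| - |g_V(phi2_V) - g_A(phi2_A)|)
          + theta_mag (g_V(phi1_V) - g_V(phi2_V)) (g_A(phi1_A) - g_A(phi2_A))

with fixed normalized shapes `g_V(phi) = phi^2` (face) and `g_A(phi) = phi`
(voice), and the response is `1{delta + eps > 0}` with `eps ~ N(0, sigma^2)`.
`sigma` is fixed at 1, which makes all weights interpretable in d' units:
`beta_V` is the d' change produced by a full-range face morph.

Conventions worth stating explicitly:

* The congruence regressor is the *difference* of the two within-stimulus
  absolute discrepancies.  This keeps the decision variable antisymmetric
  under exchange of the two stimuli, which any paired-comparison decision
  variable must be.  The magnitude regressor, a product of two differences,
  is inherently symmetric under exchange — that is a property of the model
  itself, and the test suite asserts antisymmetry only for magnitude-free
  models.
* Interaction regressors are computed from the normalized shapes `g`, not
  the beta-scaled contributions, so estimation stays linear in the
  coefficients (the fixed-curve refit workflow).

### Estimation

Fitting is probit binomial maximum likelihood on trial-difference design
matrices (`scales.encode_trials` + `scales.fit_mlcm`, backed by statsmodels
GLM/IRLS).  Identifiability of the nonparametric scales follows the standard
conjoint-measurement convention: the most feminine level of each modality is
anchored at 0 and the judgment-noise SD at 1, leaving 17 free face values,
18 free voice values (35 for the additive model), and `18*19 - 1 = 341` for
the saturated (one value per cell) model.  Estimates beyond 50 d' units are
flagged as complete/quasi-complete separation (`converged = False` with a
diagnostic) rather than raised; rank-deficient design matrices raise with
the collinear columns named.

### Mixed model

Cohorts are fitted with per-observer random slopes on the modality
regressors only (uncorrelated, diagonal covariance; richer structures are
prone to singular fits at these sample sizes):

    P(choose 1 | observer s) = Phi(x' beta + z' b_s),  b_s ~ N(0, diag(sigma_V^2, sigma_A^2))

The marginal likelihood is computed per observer by a Laplace approximation:
an inner Newton solve for the joint-density mode of `b_s` (the probit
Bernoulli log-likelihood is concave, so Newton with step halving is safe;
gradient tolerance 1e-8), then the Gaussian curvature correction
`-(1/2) log|Z'WZ + D^-1| - (1/2) log|D|`.  The outer optimization over
`(beta, log sigma)` uses L-BFGS-B with warm-started inner modes, bounds
`sigma in [1e-4, 10]`, and tolerance 1e-6; a fitted SD at or below 1e-3 sets
the `singular` flag.  A unit test cross-checks the Laplace marginal against
61-node Gauss-Hermite quadrature on a one-slope problem (agreement well
inside 0.5 log-likelihood units).

### Model ladder

`inference.model_ladder` runs, in order: judgment-direction group test,
observer-sex group test (each a 2-df fixed interaction of a centered group
code with the two modality regressors), independence vs additive (2 df: one
fixed weight plus one variance component — stated explicitly because mixed-
model df conventions vary), and additive vs each 1-df interaction.
`dAIC = Chisq - 2 df` (= AIC_nested - AIC_full), so positive values favor
the fuller model.  Boundary-corrected p-values for the variance component in
the independence/additive test are *not* applied; the plain chi-square test
is anti-conservative for that row, a documented limitation.  Predictive
accuracy scores `1` when the fitted model's preferred choice matches the
response, `1/2` on predicted ties.

## Cue-fusion account of the interactions

The fused percept is the precision-weighted average of the unimodal
estimates; the fused variance `1/(1/s_V^2 + 1/s_A^2)` never exceeds either
unimodal variance.  Two pre-fusion variance adjustments generate the
interaction signatures, with directions specified by the hypotheses and
functional forms chosen here for simplicity:

* congruence: `s_m <- s_m (1 + kappa_cong |mu_V - mu_A|)` — incongruent
  stimuli are treated as less reliable.  Inflating both unimodal variances
  raises the fused variance, which pushes single-stimulus classification
  probabilities toward chance for incongruent stimuli (the directional
  property the tests assert).
* magnitude: `s_m <- s_m / (1 + kappa_mag |mu_m - 1/2|)` — clearly gendered
  signals are encoded more precisely than near-neutral ones.

## Synthetic-data generator

The generator's defaults reproduce the study's structure: per task, 12
observers x 1,500 trials (5 sessions of 300), each observer's trial list an
independent uniform without-replacement subsample (2.57%) of the 58,311
unordered non-matching pairs of the 18 x 19 lattice, with presentation order
randomized and recorded.  Mean weights per task are chosen to reproduce the
qualitative weight pattern of the judgments: face task `beta_V = 3.5,
beta_A = 0.7` (5x face dominance), voice task `beta_V = 0.6, beta_A = 4.8`
(8x voice dominance — the ratio-of-ratios across tasks is then 40-fold),
stimulus task `beta_V = beta_A = 2.0`.  Between-observer variability is
normal and uncorrelated on `(beta_V, beta_A)` only, SD 0.5 in d' units, a
moderate individual-difference spread; interaction coefficients are shared
across observers (mirroring the fixed-effect-only treatment of the
interactions).  Observer sex and judgment direction are assigned in balanced
alternation and are *inert* in the generator, making the group-factor rows
of the ladder true nulls.

What the generator does not emulate: lapses, reaction times, session or
order effects, learning, and any true group differences.  Passing tests
therefore show that the estimators recover the parameters of this idealized
observer family at the study's sample sizes — not that real observers
satisfy the model.

## fMRI schedule and connectivity model

Each acquisition presents the 9 combinations of the reduced
feminine/neutral/masculine grid 3 times plus 8 response trials (every
combination except neutral-neutral), stimulus duration 0.5 s, fixation
intervals drawn uniformly from {5, 5.5, 6, 6.5, 7} s.  Orderings are drawn
by rejection sampling (retry cap 10,000) until no more than three successive
repetitions occur of the same stimulus, the same alternating stimulus pair,
or the same fixation duration.  Response-trial exclusions per task (neutral
face for the face task, neutral voice for the voice task, incongruent
combinations for the stimulus task) leave 30 analyzable trials of the 40 in
a five-acquisition run.

The neural model is the two-region bilinear system above with defaults
`A = [[-0.5, 0.15], [0.15, -0.5]]` s^-1 (stable self-decay, weak symmetric
cross-talk) and driving weights 0.4 (visual -> FFA, auditory -> TVA); the
modulatory effect size is 0.4 on the modulated coupling.  Integration is
fixed-step RK4 at dt = 0.1 s; because the inputs are piecewise-constant
boxcars, the RK4 update is applied through per-input-configuration step
matrices (algebraically identical to naive stepping, much faster).  BOLD is
the convolution of the neural states with a canonical double-gamma
hemodynamic response (peaks at 6 s and 16 s, undershoot ratio 1/6), plus
white observation noise (default SD 0.05, giving a peak contrast-to-noise
around 5 — typical of a good ROI eigenvariate).

Model evidence uses -BIC/2 from a nonlinear least-squares fit of the free
A/B/C entries through the forward model (free parameters: both A
off-diagonals, both driving weights, plus the B entries the candidate
permits).  This is a deliberate desk-scale surrogate for a variational
free-energy inversion of a full generative hemodynamic model; the
model-selection layer consumes any per-subject log-evidence matrix.

Random-effects Bayesian model selection implements the variational
Dirichlet update over model frequencies; exceedance probabilities are
Monte-Carlo estimates from 1e6 Dirichlet draws (symmetric cases resolve to
about +-0.005; seeded).  Family inference assigns model priors `1/|family|`
so families carry equal prior mass, and reports the posterior probability
that one family's summed frequency exceeds the other's.  Limitation: with
weakly informative evidence and *unequal* family sizes, the variational
fixed point drifts toward the larger per-model prior, so family symmetry is
only exact for equal-size partitions (the four-model spaces here are always
split 2/2); singleton families reduce to model-level exceedance.

## Problem sizes in the test suite

The test and acceptance runs choose sizes that keep every check sharp but
cheap: oracle equivalence uses 1e5 draws per pair on the 3 x 3 grid; pooled
recovery uses all 36 pairs x 50 repeats; mixed-model recovery uses 24
observers x 1,500 trials; type-I calibration runs 200 single-observer
replicates at 1,500 trials; power for `theta_cong = 0.8` is checked at the
full study scale (12 observers x 1,500 trials) over 5 replicate cohorts; the
connectivity positive control simulates 12 subjects for the four-model
space.  These are the package's own verification sizes, documented here so
they can be scaled up when more precision is wanted.
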