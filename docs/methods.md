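# Methods

This package implements, end to end and without any human data, the
computational apparatus of a referential-communication study of
*overinformativeness*: when and why speakers mention more attributes
than reference strictly requires ("the green metal bat" when "the green
bat" would do). Every stage — stimulus construction, per-participant
psychophysical calibration, trial generation, response production, and
statistical analysis — is implemented as testable code, with simulated
observers and speakers standing in for participants.

## Stimulus continua (`overinform.continua`)

Two attribute dimensions are manipulated:

* **Colour (visual).** Stimuli are points in CIELAB, interpolated
  linearly between two category endpoints. CIELAB's approximate
  perceptual uniformity makes a straight line a perceptually smooth
  gradient. The default cool continuum runs from blue
  (73.03, −19.98, 37.84) to green (87.24, −62.94, 41.00) and the warm
  one from yellow (88.29, −0.98, 69.51) to orange (68.55, 40.91, 49.37),
  each in **50 equally spaced steps** (endpoints included, 1-based
  indexing). A second, perceptually proximate blue/green pair with
  equalised lightness (73, −36.31, −13.94 / 73, −54.46, 13.65) serves
  the shape-array experiment. Rendering to sRGB uses the standard D65
  transform with out-of-gamut channels clipped (with a warning);
  display colours are cosmetic — all task logic runs on step indices.

* **Material (auditory).** An impact sound is described by its resonant
  modes, each a triple (amplitude, centre frequency, decay rate).
  Continua between two materials (wood→glass, cardboard→metal, labelled
  "wood"/"metal" to participants) interpolate the modal parameters
  linearly over **10 steps**, pairing modes in ascending-frequency
  order. Synthesis is deliberately minimal: a 1 s sum of exponentially
  damped sinusoids, `Σᵢ aᵢ e^(−dᵢt) sin(2π fᵢ t)`, peak-limited to
  [−1, 1] — the simplest generative model consistent with the named
  parameters, not a full contact-acoustics simulation. All sounds are
  normalised to a common RMS level (a `mode="peak"` flag exists because
  "volume" is ambiguous; RMS is the default reading). The four default
  material parameter sets are synthetic placeholders (the source
  recordings' modal fits are not published); no test depends on their
  values, only on the interpolation and synthesis contracts.

## Adaptive staircases (`overinform.staircase`)

Per attribute, two staircases run simultaneously from opposite ends of
the continuum with strictly interleaved trials. A response is *correct*
when it matches the label of the staircase's own starting end. Rules:

* two consecutive correct identifications advance the staircase toward
  the far end; the consecutive counter resets after every move and
  after every error;
* any incorrect identification is a *reversal* and regresses the
  staircase toward its own end;
* material staircases (10 steps) move one step in either direction;
  colour staircases (50 steps) accelerate: progressions of 5, 4, 2,
  then 1 steps and regressions of 4, 3, 2, then 1 steps, keyed to the
  number of errors so far (the progression sequence 5→4→2→1 is
  implemented verbatim, including the apparent skip of 3);
* after five reversals the participant must label the current stimulus
  correctly once more; that confirmation terminates the staircase;
* all positions clamp to the continuum; a 500-trial cap guarantees
  halting against pathological responders (hitting it fails the
  calibration).

Extraction: the **low-discriminability** stimulus is the stimulus of
the final correct identification; the **high-discriminability**
stimulus is the latest one correctly identified before any reversal at
step ≤ 2. A participant's calibration succeeds only if all four stimuli
(high/low × both categories) exist for the attribute; failures mirror
the substantial calibration-exclusion rates such staircases show when
run online, and propagate as `success=False`.

Because a 2-down/1-up rule equilibrates near the ~71%-correct point and
the terminal confirmation follows a regression, each staircase's
low-discriminability index sits systematically ~1 step toward its own
end. The two staircases bracket the boundary symmetrically, so where a
single boundary estimate is needed (the recovery checks) we use the
mean of the two indices, which cancels the offset (measured median
error: 0.4 steps on the 10-step continuum, 0.8 on the 50-step one).
Both raw indices are retained in `CalibrationResult`, and the trial
generator uses whichever matches the trial's category.

## Trial generation (`overinform.design`)

**Experiment 1 (bat factory).** Three bats per trial, each with a
colour and a material sound; timing metadata (800 ms fall, 1 s sound,
1.7 s dwell) is carried but not rendered. The *sufficient* attribute
uniquely demarcates the target (target takes one category, both
distractors the other); the *redundant* attribute is one stimulus
shared by all three. Display types set discriminability: Baseline
(both high), S-High/R-Low, S-Low/R-High. Low-discriminability contrasts
place the calibrated boundary stimulus **on the target** against the
opposite category's high-discriminability stimulus — speakers must
label the boundary stimulus when naming the target, which is what makes
mislabelling diagnostic. A session has 48 critical trials (24 per
redundant attribute, 16 per display type, 8 per cell — the published
trial total and 24/24 split are honoured; a 12/12/12 display-type split
cannot sum to 48) plus 12 fillers in which all items are identical
except that the target differs in exactly one attribute. Order is fully
randomised.

**Experiment 2 (shape arrays).** Displays of circles, squares,
pentagons and hexagons varying in one redundant attribute per
between-subject condition: stripe orientation, high-frequency colour
terms (green/blue) or low-frequency synonyms (teal/jade) over the same
proximate colour pair. Critical trials give the target a unique shape
(noun alone suffices; adjectives are always overinformative) and cross
set size (3, 6, 9, 16) with the number of distractors sharing the
target's attribute value (3: 0–1; others: 0–4), every combination
twice → 34 critical trials; 14 fillers share the target's shape with a
distractor while its attribute value is unique, so adjective + noun are
jointly required. Shapes may repeat across items (forced for set sizes
above 4).

**Expression scoring.** An expression denotes the set of items matching
every mentioned term; it *identifies* when that set is exactly the
target. Among identifying expressions, one is *overinformative* when
some proper subset of its modifiers — the noun is the head and is
always kept — still identifies the target, else *minimal*. Match sets
shrink monotonically as terms are added, so the implementation tests
single-modifier deletions; the test suite checks it against exhaustive
subset enumeration. Feedback: thumbs-down iff reference fails; shrug
for overinforming on fillers; thumbs-up otherwise. The shape task
rejects noun-less expressions before classification.

## Simulated participants (`overinform.agents`)

**Observer.** A lapse-rate logistic psychometric model over absolute
continuum position: P(far category | x) = γ/2 + (1−γ)·σ((x−b)/s).
Defaults: boundary b uniform on the middle third of the continuum;
slope s = 0.75 steps (material) and 2.0 steps (colour); lapse γ = 0.02.
Individual boundaries are sharp — people hold highly specific,
individually varying colour category boundaries, and smooth *average*
curves arise from boundary variation across observers — and these
choices make the dual staircase terminate reliably and the aggregate
curves smooth.

**Speaker.** The generative inverse of the analysis model: on each
trial the speaker emits the minimal sufficient expression and upgrades
it to the overinformative one with probability σ(x′β + uⱼ), where x is
the trial's dummy coding, β defaults to the published posterior means
(experiment 1: intercept −2.50, Material-Redundant −1.43, Baseline
−0.94, S-High/R-Low −1.09 against Colour-Redundant / S-Low/R-High
reference; experiment 2: intercept 0.97, LF-Colour −0.20, Orientation
−0.97 against HF-Colour reference), and uⱼ ~ N(0, σᵤ²) is a by-subject
intercept with σᵤ = 0.8 — a value chosen once to give subject
heterogeneity comparable to the spread of observed subject means
without degenerate cells. The speaker is always the exact generative
inverse of the analysis model it feeds: the experiment-1 speaker
carries the by-subject intercept because the experiment-1 model
estimates one, and the default experiment-2 speaker sets σᵤ = 0 because
the published experiment-2 model is a plain logistic regression
(heterogeneous experiment-2 populations can still be simulated by
passing an explicit speaker). Attribute terms are produced by sampling the
speaker's own observer at the stimulus position, so boundary (low-disc)
stimuli are mislabelled often and prototypical stimuli almost never; the
noun is never mislabelled in experiment 1. Noise channels for the
exclusion rules: a small `underinform_rate` (default 0.01) of bare-noun
responses in experiment 1, a small `noun_error_rate` (default 0.015,
matching the observed ~1.5% noun-error rate) in experiment 2, and
optional "fatigue" subjects who go underinformative wholesale (off by
default; used only by exclusion tests). These rates are placeholders
(no quantitative speaker noise rates are published for this paradigm)
and nothing besides
the exclusion machinery depends on them.

`simulate_experiment1` runs the full pipeline per subject: draw
observers, run the dual staircases, skip subjects whose calibration
fails, generate a session, sample responses. `simulate_experiment2`
skips calibration (both attributes are near-ceiling discriminable) and
samples responses across the three conditions.

What the generator does **not** emulate: real perceptual spaces
(mislabelling is purely distance-to-boundary), production latencies,
learning or fatigue dynamics within a session (other than the injected
wholesale fatigue), and any dependence of overinforming on set size or
distractor count in experiment 2 (none was observed empirically). A green
recovery test therefore establishes that the analysis recovers the
generative coefficients under the model's own assumptions — not that
those assumptions describe human speakers.

## Analysis (`overinform.analysis`, `overinform.bayes`,
`overinform.psychometric`)

**Coding.** Responses are classified against their display. A modifier
term matching *nothing* in the display is a category mislabel: it is
dropped, the trial is flagged when the named attribute was
low-discriminability, and the trial is retained if the remainder still
identifies the target (mislabelling is an inevitable aspect of low
discriminability). A mislabelled *sufficient* term instead matches the
distractors, so the expression fails and the trial is later dropped —
reproducing the asymmetry between retained mislabelled-redundant trials
and excluded non-identifiable ones. A critical-trial response is coded
overinformative iff it identifies the target and mentions the redundant
attribute.

**Exclusions.** Subjects with more than 10 underinformative
director-task trials (critical and filler alike) are removed wholesale
(strict inequality: 10 is retained, 11 excluded); remaining
non-identifiable trials are dropped individually; mislabelled
low-discriminability trials are kept. The operation is idempotent and
reports counts per reason.

**Regression.** `BayesMixedLogit` is a Bayesian logistic regression
with Normal(0, 2) priors on coefficients (the published prior),
optional by-subject random intercepts in non-centred parameterisation,
and a half-Normal(1) prior on the intercept SD (unpublished; a standard
weakly informative choice). The experiment-1 model includes by-subject
intercepts; the experiment-2 model does not — its published description
("intercept and main effects") omits them and its printed intercept SE
(0.09 at ~2000 trials) matches the fixed-effects-only information,
whereas a mixed model yields ~0.16. Sampling is Hamiltonian Monte
Carlo: diagonal mass matrix and chain initialisation from the posterior
mode (found by L-BFGS), dual-averaging step-size adaptation to 0.8
acceptance during warm-up, path lengths jittered on 8–24 leapfrog
steps; defaults 4 chains × 1000 draws after 500 warm-up. Convergence is
checked with split R-hat; any value above 1.05 raises a loud error
carrying the diagnostics. "SE" in output tables is the posterior SD;
intervals are central 95% credible intervals.

**Model comparison.** Bayes factors use the Laplace approximation to
each model's log marginal likelihood at its posterior mode (Hessian by
central differences of the analytic gradient). This is approximate by
construction — adequate for the coarse "is the interaction model
inferior?" comparison, not for precise evidence claims.

**Psychometric fits.** Maximum-likelihood logistic fits of category
probability against continuum position, same lapse-rate family as the
observer (lapse fixed at 0.02 by default; fitting it free is unstable
at staircase sample sizes). Degenerate all-same-response data are
flagged with the boundary reported at the continuum edge. Display
points can be binned (5 trials per bin for the 50-step colour
continuum). All confidence intervals are percentile bootstrap with
B = 1000 by default: trials within bins for psychometric points,
subjects for condition proportions.

## Numerical choices and degenerate inputs

* Continuum steps are computed as `a + w·(b−a)` so equal endpoints give
  bit-identical steps; endpoints are assigned exactly.
* Interpolation rejects n < 2; modal interpolation rejects unequal mode
  counts; synthesis rejects sample rates below Nyquist for the highest
  mode; normalisation rejects zero-energy input.
* Staircase updates after termination raise; extraction without any
  correct response raises a calibration failure.
* Logistic separation is handled by the proper prior (finite posterior
  means); the psychometric fit bounds degenerate boundaries at the
  continuum edges.
* HMC divergences (non-finite Hamiltonians) reject the proposal; the
  mode-based mass matrix is clipped below at 1e-3 curvature.

## Known limitations

* The modal synthesiser ignores attack transients, nonlinear damping
  and radiation filtering; RMS normalisation is not loudness
  normalisation.
* The Laplace Bayes factor can be off for strongly non-Gaussian
  posteriors (few subjects, extreme cells).
* With ~20 subjects per between-subject condition, mixed-logit fixed
  effects show a small away-from-zero shrinkage-asymmetry bias
  (~0.1 log-odds) when random intercepts are included; the
  experiment-2 default avoids this by matching the published plain
  model.
* Simulated speakers have no pragmatics: coefficients are imposed, not
  derived from utility; the package tests the measurement pipeline,
  not the theory.
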