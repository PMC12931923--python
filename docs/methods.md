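# Methods

This note documents the models, algorithms and numerical choices behind the
package, and what its synthetic-data tests do and do not establish.

## The task and its geometry

The LOCUS paradigm (Location and Colour Updating across Saccades) probes
spatial working memory across eye movements.  Each trial presents two
coloured squares in sequence (1 s each, 0.5 s inter-stimulus interval), each
inside a 9.8° × 9.8° frame centred on a fixation cross, followed by a colour
wheel cueing recall of one item's colour and location.  Four conditions
manipulate when saccades occur: no saccade, a saccade after item 1 (the
second frame appears elsewhere), a saccade after item 2 (the wheel appears
elsewhere), and two saccades.  A 160-trial session holds exactly 40 trials
per condition.

The generator enforces the design constraints: frame centres come from a
3 × 5 screen grid with 0.3° gaps (15 locations, 10.1° centre-to-centre, so
any instructed saccade exceeds the 8.5° minimum amplitude); each stimulus is
placed uniformly inside its frame by rejection sampling, at least 3.82° from
the fixation cross; the colour wheel's rotation is randomised per trial.

Event timings the data do not pin down are generator settings with fixed
defaults: wheel onset 0.5 s after item 2 offset, colour response 2 s and
location response 3 s after wheel onset, saccades executed 0.2 s after the
event that cues them.  From these the per-item timing variables follow:

* τ — time from the item's disappearance to the location response;
* t — time since the first saccade executed after the item was viewed;
* T — time since the second such saccade;
* n — number of saccades since the item's fixation (0, 1 or 2).

The condition × item mapping of n is NO_SACCADE (0, 0), SAC_AFTER_1 (1, 0),
SAC_AFTER_2 (1, 1) — both items are viewed at the same fixation and the
wheel saccade follows both — and TWO_SACCADES (2, 1).

## The seven generative models

All models treat memory decay as diffusion: variance grows linearly in
elapsed time.  Before evaluation, each trial is rigidly rotated and
translated so the origin is the fixation at which the probed item was viewed
and the target lies at angle zero; the response and the distractor get the
identical transform, so distances are preserved.

1. **Allocentric** — screen-centred coordinates (u, v), independent normals
   per axis with variance `enc + dec·τ`.
2. **Dual** — eye-centred polar coordinates: the response's radial distance
   r is normal about the target's distance with variance
   `r_enc + r_dec·τ` (deg²), and its angle is normal about the target's
   angle with variance `a_enc + a_dec·τ` (rad²).
3. **Dual (fixation decay)** — adds `fix_dec·t` to both polar variances:
   the remembered fixation point starts to decay at the first saccade after
   the stimulus.
4. **Dual (saccade update)** — adds `n·sacc_enc + sacc_dec·(t + T)` to both
   polar variances: each saccade injects an encoding error into the
   remembered saccade vector, and those memories decay for the whole time
   since each saccade was made.
5.–7. **Interference variants** of models 2–4: with probability w the
   response is drawn around the distractor (translated into the same
   reference frame, with its own τ, t, T, n), so the trial density is the
   mixture `(1 − w)·p_target + w·p_distractor`.

Adding the fixation/saccade terms to *both* the radial (deg²) and angular
(rad²) variances is a modelling convention of this package; the alternative
(scaling the angular contribution by 1/r²) would couple the two coordinates
and is not used.

Parameters are unconstrained reals κ: scales enter as `exp(κ)` (positive by
construction), the interference weight as `sigmoid(κ)`.  The prior on every
κ is N(0, 1/8), deliberately conservative: a parameter must earn its
distance from zero.

### Angular residuals

The angular residual is wrapped into (−π, π] and evaluated under a normal
density **renormalised over that interval** (a doubly truncated normal; the
correction is `−log erf(π/√(2Σ_θ))`, negligible for small angular variance).
The forward simulator draws the angular deviation by rejection within the
same interval.  This makes the trial density integrate to exactly one and
makes simulation and fitting mutually consistent at any variance — without
it, prior-sampled subjects with large angular variances produce biased
recoveries.  This is not a wrapped-normal or von Mises model: no mass is
aliased across the boundary.  The radial normal is left untruncated at
r = 0; the probability assigned to negative radii is negligible for
realistic geometries (target eccentricity ≥ 3.82°).

## Laplace inversion

Each subject × model fit maximises the log-joint (log-likelihood plus log
prior) by damped Newton ascent in the unconstrained space:

* derivatives: central finite differences of the likelihood term (step
  1e-3, balancing truncation against cancellation for these smooth,
  ≤7-dimensional objectives); the prior's gradient and Hessian are added
  analytically, so an empty dataset inverts exactly to the prior;
* damping: a Levenberg–Marquardt term λI added to the negative Hessian,
  doubled when a step fails to raise the free energy and halved on success;
* start: the prior mean (fits are deterministic); convergence when the
  free-energy gain of an accepted step drops below 1e-4 nats, at most 128
  iterations.

The posterior is Gaussian at the mode with covariance the inverse negative
Hessian (jittered to positive definite if needed), and the free energy

    F = J(mode) + (d/2)·ln 2π + ½·ln det Σ_post

approximates log model evidence; with no data F = 0 exactly, and for a
linear-Gaussian likelihood it reproduces the conjugate closed form to 1e-8.

**Known limitation.**  The session's timing design makes τ, t and t + T
nearly collinear across the eight condition × item combinations, so models
stacking two decay rates on one coordinate (fixation- and saccade-update
variants) have a curved trade-off ridge between those rates in log space.
The local Gaussian understates marginal uncertainty along that ridge:
replicate simulations show 90% credible intervals covering the generating
value only ~50% of the time for the affected decay rates (all other
parameters reach nominal-ish coverage), and their point recovery, while
well-ranked, can sit 2–4 posterior SD from the truth.  The original
inversion scheme shows the same signature (weak recovery correlations for
exactly those parameters).  The test suite asserts strict coverage only
outside the degenerate set and a sanity floor inside it.

## Model selection and recovery

Evidence is accumulated across subjects per model (fixed effects) and a
softmax over summed log evidences gives posterior model probabilities; the
Bayes factor quoted for a winner is the ratio of the top two posterior
probabilities.  The recovery analysis simulates 16 subjects per generating
model with prior-sampled parameters, refits all seven models, and softmaxes
the accumulated evidence per generating model into a column-stochastic
confusion matrix; for the saccade-update-with-interference model it also
correlates generating with recovered (posterior-mode) parameters.  The
interference weight is the best-recovered parameter (median Pearson r ≈ 0.8–0.9
across seeds at 16 subjects × 160 trials); decay rates on the collinear
clocks recover poorly, as expected from the design.

## Group inference

PEB here is a parameter-wise second-level Bayesian linear model: subject i's
posterior mode for a parameter is modelled as N((Xβ)_i, σ²_between + v_i),
with v_i the subject's first-level posterior variance (uncertain subjects
weigh less) and σ²_between estimated by restricted maximum likelihood.  The
β posterior is the generalised-least-squares Gaussian (flat prior on group
means), giving closed-form directional contrast probabilities
P(β_A − β_B > 0); contrasts above 0.95 are flagged.  Parameters are analysed
marginally; a joint analysis across parameters is not implemented.

The score regression demeans the behavioural scores (excluding subjects more
than 2 SD from the mean), z-scores each MAP regressor (centred — the model
has no intercept and the scores carry no mean — and divided by its
across-subject SD), places N(0, 1/8) priors on the coefficients plus a
log-noise-variance hyperparameter with a wider N(0, 1) prior, inverts with
the same Laplace machinery, and reports
`100·(1 − var(residuals)/var(scores))` using posterior-mean predictions.

## Gaze compliance

Preprocessing masks blinks: zero-pupil samples, plus samples whose pupil
rate of change exceeds the trace's 99.5th percentile within ±50 ms of a
closure.  Fixations are maximal runs within 2.5° of a target lasting
≥ 150 ms, evaluated in 1 s post-onset epochs.  Saccade detection median-
filters positions (5 samples), differentiates over a ±5 ms central span
(adjacent-sample differencing at 1000 Hz would turn 0.5° jitter into
hundreds of deg/s of velocity noise), finds runs above 150°/s longer than
10 ms, merges runs separated by < 20 ms, and keeps events whose net
displacement — measured between median positions in 15 ms flanking windows —
exceeds 9.2°.

Per-condition compliance rules: no-saccade trials require fixation at the
cross during both item epochs and no large saccade in any epoch; saccade
conditions require fixations on both items plus the instructed saccade(s) in
their windows and no forbidden saccade after wheel onset.  Fully masked
epochs give an *indeterminate* verdict, distinct from failure.  Behavioural
summaries use compliant trials only: Euclidean location error, shortest-arc
colour error in [0, π], and the saccade cost — mean two-saccade location
error minus mean error when the single saccade followed the unprobed item.

## What the synthetic data do and do not show

The generator reproduces the session structure, geometry, timing skeleton
and, by construction, the exact generative densities of the models, so
closed-loop tests establish internal correctness: balanced designs, exact
normalisation, calibrated recovery, detectable group effects, and a
compliance classifier that is perfect on clean traces and ≥ 95% accurate at
0.5° jitter.  They do not emulate real oculomotor dynamics (main-sequence
velocity profiles, corrective saccades, drift), real response-time
distributions (latencies are fixed constants), or any model misspecification
— real observers are not draws from any of these seven densities.  Passing
tests therefore validate the pipeline, not the psychology.

## Problem sizes

Default study-scale settings: 160 trials/session, 16 recovery subjects per
model, prior variance 1/8 everywhere.  The test suite uses 24 replicates for
coverage checks, five replicate draws per model for the 2000-trial recovery
bound, 20 subjects per group for the PEB dissociation, and 80-trial sessions
for classifier accuracy; the reproduction script uses 100 sessions for the
geometry minima, 10⁵ stimulus placements, and seven 16-subject batches for
the interference-recovery median.
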