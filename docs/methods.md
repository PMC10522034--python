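# Methods

This note documents the model, the choices made where the design was
genuinely open, the synthetic study conditions, and the limitations of
what the test suite can show.

## Model structure

Each trial has three time points: reach initiation (t0), midpoint crossing
(tMP) and endpoint (tEP). The motor output is the sum of a feedforward
command fixed at t0 and a feedback command that is zero at t0 and corrects
a gain-scaled fraction of the midpoint cursor error. Hand angles are in
degrees, counter-clockwise positive; the imposed rotation r(n) is stored
as a positive number (cursor displaced counter-clockwise of the hand), and
the cursor error at any event is the hand angle plus r(n), with the target
at 0°.

Between trials three latent variables update:

* the feedback gain `x_fb`, from endpoint error only, never modulated by
  uncertainty;
* a slow feedforward state, from both the midpoint error and the endpoint
  error corrected for the issued feedback command (`δ_EP − y_fb`, which is
  algebraically identical to `δ_MP`), never modulated by uncertainty;
* a fast feedforward state whose update carries the uncertainty scaling
  vector ν (one entry per level L, M, H, ∞; γ weights midpoint against
  endpoint events) at one of five loci — the error term, the retention
  term, the bias term, a memoryless state-level aim, or an additive output
  aim driven by the previous trial's levels.

Two structural facts follow from the equations and matter for
interpretation:

1. **The state-aim and output-aim two-state models are algebraically
   identical** on every trial after the first: both add
   `[γν(mp,n−1) + (1−γ)ν(ep,n−1)]·λ` to the planned output on top of the
   same slow state. BIC ties between them are expected, and the model
   comparison treats differences below 2 BIC units as equivalent.
2. **The printed update adds +αδ with δ = y + r**, which drives the state
   *with* the error; the fixed point of the unperturbed-target recursion is
   `(αr+λ)/(1−α−β)` rather than the compensatory −r. The equations are
   implemented exactly as written; any sign flip for plotting-style
   "adaptation extent" is a reporting choice left to the analysis layer.

### Event semantics

Baseline trials (continuous veridical feedback) and washout trials (no
feedback) have no discrete feedback event: the feedback command and all
error-driven terms are zero there, leaving pure retention/bias dynamics —
this produces the geometric washout decay. Their scaling-factor index is
the ∞ entry (the least informative level), which matters only for the
retention-, bias- and aim-scaling factors. Adaptation trials at the
no-feedback level ∞ are treated literally: the latent error scaled by the
fitted ν_∞/η_∞ enters the updates (the table of bounds treats these as
free parameters); the switch `zero_error_on_inf` zeroes those terms
instead, as a sensitivity probe of this ambiguity. In the midpoint-only
design (Experiment 1), endpoint-indexed factors are pinned to the ∞ entry
and γ is confounded with the ν amplitudes; γ is interpretable only in the
crossed design (Experiment 3).

### Parameter bounds

The per-family bounds table fixes the slow-state bias at zero, bounds
rates and retentions on [0, 1], the fast bias on (−10, 10) (non-negative
variants: (0, 10)), the feedback-gain retention on (−10, 10), the initial
feedback gain on (−2, 2), ν_ff on (0, 1), and the feedback scaling ν_fb on
(0, 1) for error/retention families, (−1, 1) for bias (with the ∞ entry
(0, 1) in the non-negative variant), and (−20, 20) ((0, 20) non-negative)
for the aim families. For the aim families the λ of the aim term is
bounded (0, 1) in the one- and two-state variants and (0, 10) in the
non-negative variant; the source table places this λ inconsistently
(absent from the fast-bias row, present in the slow-bias row for the
two-state variant and in the fast-bias row for the non-negative one), and
this reading is the one that keeps every variant non-degenerate. The free
parameter count k (15 for one-state scaling families and two-state aim
families, 17 for two-state scaling families, 13 for one-state aim) is the
number of bound entries with lower < upper.

Note the (0, 1) aim-λ bound caps the plain aim models' stratification
below one degree; the non-negative variant (λ up to 10) is the one that
can reach the multi-degree stratification real datasets show.

## Fitting

The objective is the sum of squared midpoint plus endpoint hand-angle
residuals over the fitted trials; by default adaptation + washout
(washout identifies retention), baseline excluded, all three selectable.
R² pools both series about their common mean, and n in the BIC is the
number of residuals (two per fitted trial), with k from the bounds table.

The global search is differential evolution inside the bounds, vectorised
over the population (the session recursion is evaluated for all candidates
at once; a numba kernel accelerates it, with a pure-numpy reference path
kept under test). scipy's built-in polish is replaced by an explicit
L-BFGS-B refinement of the best few population members whose gradient is a
batched central difference through the same vectorised engine — this is
roughly 30× cheaper per gradient than serial finite differences and
markedly improves convergence on the 15–17-dimensional landscapes.
Defaults: maxiter 600, population multiplier 8, two restarts, ten polished
candidates; a fit of one 300-trial session takes a few seconds. Latent
states are clipped at ±1e8 so that candidates in the divergent region of
the bound box (|β_fb| > 1 is inside it) keep a finite, ordered objective.

Parameters of the same model are not all identifiable in every design: in
the midpoint-only experiment the aim families identify only the per-level
products λ(γν_i + (1−γ)ν_∞), and the recovery study therefore scores
those products, the slow-state retention and rate, not raw ν entries.

## Synthetic study conditions

The generator runs a chosen generative model over a seeded schedule
(20 baseline + 180 adaptation + 100 washout trials; rotations i.i.d.
Gaussian mean 12°, SD 4°; four uncertainty conditions × 45 trials,
interleaved by a seeded permutation of a balanced label vector, shared
across the cohort — the trial-matched design). Motor execution noise
(default SD 1°) is injected into the plan *before* the midpoint error is
computed, so the feedback controller and the learning rules react to the
executed movement, as a real participant's noise enters the loop;
observation noise (default 0) is added to the recorded angles last.

Per-family default parameters are fixed study conditions chosen once on
three a-priori grounds: the closed trial-to-trial loop must be
contractive (the literal +αδ update is anti-compensatory, so carelessly
large rates diverge), simulated hand angles must stay in a plausible range
(tens of degrees over 300 trials), and the family's uncertainty modulation
must have the few-degree magnitude that the stratification in real
datasets shows, so that a recovery study is informative. The noise
magnitude is a free parameter of the test suite, not a claim about data.

What the generator does **not** emulate: reaction/movement times and
timeouts, trial repetition, continuous within-trial trajectories (the
model lives at three time points), non-Gaussian or temporally correlated
motor noise, and participant heterogeneity beyond what a user-supplied
parameter distribution injects. Passing tests therefore show that the
pipeline recovers what it assumes, not that any family describes human
behaviour.

## Model comparison and statistics

Models are ranked per participant by ascending BIC, ties broken by fewer
parameters then name and flagged. Cohort comparisons are paired t-tests
on per-participant (mean) BIC with Bonferroni correction and Hedges g — an
all-pairs Bonferroni scheme is used where a reference-based post-hoc would
need a designated reference model.

The identifiability study fits all five two-state families to cohorts
generated by each family. Because the per-level feedback scaling η is free
in every family, level-specific effects can be partially absorbed by any
model, and on bias-generated data the error-scaling fit ties the
generating family exactly at the optimum. The study's criterion is
therefore the one appropriate to overlapping families: the generating
family must attain the best mean BIC, or tie within 2 BIC units, in a
majority of the generating-family cohorts.

The regression layer fits group-averaged OLS with backward-difference
coding of the ordinal uncertainty factor (fitted contrasts equal
adjacent-level mean differences on balanced data; columns are centred).
Feedforward responses (IMV and its trial-to-trial change) use
previous-trial predictors and lose the first adaptation trial; IMV adds
ln(trial number) to straighten the adaptation envelope. Feedback
integration (endpoint hand angle minus IMV) uses current-trial predictors.
The midpoint error predictor is the *displayed* (pre-correction) cursor
error IMV + r; the endpoint error is the final cursor error. Relative
importance is the LMG decomposition (sequential R² averaged over all
predictor orderings), computed exactly by subset enumeration; shares are
non-negative, sum to the model R², and split symmetric contributions of
exactly collinear predictors equally. The washout analysis takes mean IMV
(the plotted quantity) over the last 10 adaptation trials grouped by the
previous trial's uncertainty type, minus the first 3 washout trials, then
repeated-measures ANOVA (generalized eta squared) and Bonferroni paired
t-tests with Hedges g.

## Kinematics

Onset is the first sample exceeding 5% of peak speed after leaving the
0.5 cm-diameter start region; offset the first sample below 5% of peak
speed after 9.5 cm of radial travel; speeds are central finite differences
with no smoothing, as specified. The IMV reads the instantaneous velocity
direction at onset by default, with a chord option (displacement over the
first k samples) for noisy recordings — per-sample white noise at 200 Hz
swamps an unsmoothed derivative, so the noise-robustness fixture uses a
smooth 0.05 cm positional wobble and the measured round-trip bounds are
3° (IMV, chord reading) and 1° (endpoint angle); noiseless round-trip
error on the fixture family is below 0.5° across ±20°.

## Problem sizes and known limitations

The test suite and the acceptance script run on reduced problem sizes
chosen as sufficient for their statistical purpose: identifiability uses
cohorts of 2 (tests) or 5 (acceptance script) participants with a
moderate optimizer budget; recovery uses one participant per noise level
with a larger budget; regression-signature cohorts use 20 participants,
the standard per-experiment sample size. Differential evolution is
stochastic: with reduced budgets, fits of near-equivalent families can
rank-invert, which is why equivalence bands, majorities and seeded runs
are part of the acceptance criteria rather than strict argmax checks.
One-state aim variants have no λ of their own in the source bounds table
and are given the two-state (0, 1) bounds; without that choice they
degenerate to pure feedback models.
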