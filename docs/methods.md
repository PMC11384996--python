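# Methods

## The diffusion model

A trial is modelled as a Wiener process `dx = mu dt + sigma dW` starting at
0 between absorbing boundaries at +B ("present" response) and −B ("absent"),
with the observed RT equal to the crossing time plus a non-decision time t0.
The geometry is deliberately minimal: symmetric boundaries (no starting-point
bias), no across-trial variability in drift or t0, no collapsing boundaries.
Only three structural parameters (mu, B, t0) are estimated; sigma = 1 fixes
the evidence scale, since only mu/sigma and B/sigma are identified.

Closed forms used throughout: the upper-boundary absorption probability
`1 / (1 + exp(-2 mu B / sigma^2))` and the mean decision time
`(B/mu) tanh(mu B / sigma^2)` (limit `B^2/sigma^2` at mu = 0, taken when
|mu B / sigma^2| < 1e-8).

### First-passage-time density

The defective density at either boundary is evaluated by the standard pair
of series expansions for symmetric start (relative position 1/2): the
small-time expansion over image charges and the large-time sine series.  For
each evaluation point the number of terms each series needs for an absolute
truncation error of 1e-10 (on the standardized scale) is computed from the
usual accuracy bounds, and the cheaper adequate series is used.  The
densities satisfy, and the tests assert, three identities: the upper density
integrates to the choice probability (quadrature tolerance 1e-4),
upper/lower densities swap under drift reflection (1e-10), and total mass
accounts for non-absorption by the deadline (1e-3).

### Simulation

Trajectories are simulated by Euler–Maruyama with increments
`mu dt + sigma sqrt(dt) N(0,1)`.  The bare scheme has an O(sqrt(dt))
absorption bias (paths can cross and return between grid points), which at
dt = 1 ms is already visible against the analytic density at n = 1e5.  A
Brownian-bridge crossing test is therefore applied inside every step: an
interior transition from x0 to x1 is absorbed at +B with probability
`exp(-2 (B - x0)(B - x1) / (sigma^2 dt))` (similarly at −B), which removes
the leading-order bias.  Crossing times are assigned at the step midpoint.
With this correction, simulated choice fractions and mean RTs agree with the
closed forms within Monte-Carlo error and the Kolmogorov–Smirnov distance to
the analytic RT distribution is about 0.003 at n = 1e5, dt = 1 ms.  Defaults:
dt = 1 ms for validation-grade runs, 5 ms for bulk experiment synthesis.
Paths still unabsorbed at the 7 s deadline are non-responses.

### Robust likelihood and fitting

Each trial's likelihood is a mixture
`(1 - lambda) f_wfpt(rt | boundary) + lambda / (2 (t_max - t0))`:
a uniform contaminant over the response window and a fair boundary coin.
The floor (default lambda = 0.02, configurable or fittable) keeps the
likelihood finite for outlier RTs — including responses faster than t0 —
which would otherwise have zero density.  Non-responses are excluded from
the likelihood rather than treated as censored, matching the RT-analysis
filter that drops timeout trials.

Fitting minimizes the summed negative log-likelihood with differential
evolution (rand/1/bin, population 15 per free parameter, crossover 0.7,
mutation factor drawn from [0.5, 1), tolerance 1e-6, seeded, with a final
local polish).  A global population method is used because the likelihood
surface in (mu, B, t0) has a sharp ridge along t0 near the fastest observed
RT where gradient methods stall.  Recovery at n = 5,000 trials returns each
parameter within a few percent of truth.

## The condition mapping

Design cells {MSS, VSS, context, target} share one coefficient vector:

* drift `mu = mu0 / (1 + gamma ln MSS) + delta [context]`.  The
  multiplicative-inverse-in-log form is the default because mean decision
  time is approximately B/mu, so a drift falling like 1/ln MSS yields the
  observed logarithmic RT growth in memory set size; a plain inverse form
  `mu0 / (1 + gamma (MSS - 1))` is available behind `drift_form` for
  comparison.  The context offset delta is additive and unconstrained in
  sign (fitted from data; a negative value means context slows evidence
  accumulation and raises RT intercepts).
* boundary `B = a0 + a1 VSS`: more display items demand more evidence
  before commitment, giving the linear RT growth in visual set size.
* t0 constant across cells.

On target-absent trials the stimulus-driven drift component is mirrored
(points toward the "absent" boundary) while the context offset keeps acting
against the correct response; the extended model additionally frees
(a0_ta, a1_ta, t0_ta).  Whether context should also enter target-absent
drift differently is not settled; the mirror rule is the simplest choice
that leaves the target-present fit untouched.

The joint fit pools all answered target-present trials (both response
types — correct responses at +B, misses at −B; the defective two-boundary
likelihood needs both choices to be consistent), maps each trial's cell to
its parameters, and optimizes the shared coefficients exactly as above.  A
vectorized likelihood path evaluates all trials in one series-expansion call
and is verified in the tests to equal the per-cell sum to 1e-9.

Default coefficients (mu0 = 2.0, gamma = 0.8, delta = −0.4, a0 = 0.8,
a1 = 0.15, t0 = 0.35 s, lambda = 0.02) are the calibration used for the
synthetic experiment: they put mean RTs in the 1–2.5 s range, produce an
empirical visual-search slope of roughly 0.18 s/item and a clearly
logarithmic memory-search curve, and keep timeout rates near 1%.  Recovery
of all six coefficients from a full synthetic experiment is within ±15%
(3-seed average).

## The synthetic experiment

`generate_experiment` emulates the online study design: 110 participants ×
112 trials; the 16 {MSS, VSS} pairs from {1, 2, 4, 8}² appear 7 times each;
the four {context, target} combinations are balanced within pair up to ±1
with the shortfall rotating across pairs, so context and target are each
present on exactly half the trials.  One stimulus (image) identifier is
bound to each of the 112 design slots and shared by all participants — as
in the real experiment, where everyone answers the same images — and each
participant sees them in an independently randomized order.

Participant heterogeneity enters as a Gaussian shift on t0 (floored at
0.05 s), the simplest mechanism that yields a clean random intercept on RT.
Its spread (default 0.53 s) was set by `calibrate_participant_sd`, which
bisects on the spread until the fitted intraclass correlation of
`RT ~ VSS * Context + (1 | participant)` reaches 0.15; at 110 participants
the realized ICC fluctuates by a few hundredths across seeds.  Optional
stimulus outliers (a constant RT shift on one stimulus) support end-to-end
screening tests.

What the generator does **not** emulate: accuracy is whatever the diffusion
produces.  In particular, because the boundary rises with VSS, simulated
accuracy *increases* with visual set size, whereas human accuracy typically
declines; the accuracy-model tests therefore use a direct logistic
generator.  There is also no scene-semantics structure, no sequential
effects, and no per-stimulus variability beyond the injected outliers.
Passing pipeline tests on this data demonstrates correctness of the
estimators and filters under the stated generative assumptions, not
fidelity to every feature of human data.

The change-detection generator draws true capacity K per participant from
N(2.31, 0.82²) truncated at 0 and emits responses from the whole-display
guessing model (probe in memory with probability min(1, K/N); otherwise
guess "change" at rate 0.1): exactly the model inverted by Cowan's
K = N (H − FA), so the estimator is unbiased by construction.  The go/no-go
generator draws d′ ~ N(2.5, 0.5²) and criterion c ~ N(−0.23, 0.58²) and
emits responses with hit rate Φ(d′/2 − c) and false-alarm rate Φ(−d′/2 − c).
The c population values mirror liberal responding; d′ values reflect an easy
colour discrimination.

## Statistical battery

Per-participant curves are fitted on cell means (mean RT per set-size level,
the other set size fixed at 4), by ordinary least squares on the level and
on its natural log; slopes, intercepts, R² and Gaussian AIC are aggregated
as mean ± SEM across participants.  Natural logs are used everywhere — the
base only rescales log-form slopes.

The Gaussian random-intercept model is fitted by maximum likelihood with the
variance ratio theta = sigma_b²/sigma_e² profiled: given theta, GLS
coefficients and the residual variance are closed-form (Woodbury identity
per group), leaving a one-dimensional bounded search over theta in [0, 100].
ML rather than REML is used so likelihood-ratio tests across fixed-effect
structures are valid; AIC counts all fixed effects plus the two variance
parameters; fixed-effect CIs and p-values are Wald/normal (the degrees-of-
freedom correction question is sidestepped and the output labels the
method).  The implementation agrees with statsmodels' MixedLM (ML) to
1e-4 in log-likelihood on test data, and the null-true likelihood-ratio
test rejects at 4–5% at nominal 5%.

The accuracy companion is a random-intercept logistic model whose per-group
marginal likelihood is integrated by adaptive Gauss–Hermite quadrature
(21 nodes recentred and rescaled at each group's posterior mode, found by
Newton iteration); with zero group variance it reproduces plain logistic
regression to 1e-4.  Complete separation is detected as runaway
coefficients and raised as an error.

## Screening and filtering rules

RT analysis keeps answered, correct trials; timeouts (7 s) are removed;
sub-200 ms responses are deliberately retained.  Participants are excluded
when their raw-data accuracy (timeouts counted as not correct) falls more
than 3 SDs below the participant mean; with zero SD nobody is excluded.
Stimulus screening runs a one-way ANOVA of RT on stimulus id within each
{context, MSS, VSS, target} cell, on correct-trial RTs (the same data the
analyses use); if F > 20 with p < 0.05, Tukey's HSD at alpha = 0.05 flags
deviant stimuli and the one whose mean RT differs most from the mean of the
remaining stimuli is discarded — at most one per cell to preserve design
balance.  With exactly two stimuli the deviation criterion is symmetric, so
ties break toward the slower stimulus (screening hunts abnormally slow
images).  Every filter appends a provenance record (rule, counts removed),
serialized as a JSON sidecar next to each written CSV.

## Problem sizes and numerical choices in the test suite

Simulation-based checks use 1e5 paths at dt = 1 ms for density/closed-form
agreement, 5,000 trials for single-model recovery (3 seeds), and full
110-participant experiments for mapping recovery (3 seeds, averaged).
Calibration suites run 500 null replicates at 12 participants × 24 trials
(type-I error) and 20 replicates at 30 × 56 (AIC form selection and
fixed-effect coverage, with generator inputs 1.23 s intercept, 0.49 s
context effect, 0.12 s/item, ICC 0.15).  Differential evolution caps at
250 generations for the joint fit (it converges earlier by tolerance).

## Known limitations

* The model is fitted to pooled data; there is no hierarchical
  per-participant DDM, so participant variability is only captured by the
  synthetic generator, not by the fitted model.
* Non-responses are dropped, not censored, slightly biasing fits for
  parameter regimes with substantial deadline mass.
* The deviation rule for stimulus discard and the target-absent drift
  mirror are operational choices where the procedure is described only
  qualitatively in the literature; both are isolated behind small functions
  and easy to swap.
* Accuracy generated by the diffusion rises with VSS (see above), so the
  synthetic data reproduce the RT signatures but not the accuracy-by-VSS
  decline of human observers.
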