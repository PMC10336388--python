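# Methods

`shoalspect` analyses cooperative predator inspection in shoals of small
fish (the motivating system is Trinidadian guppies, *Poecilia reticulata*)
filmed from above in a 1.5 m x 1.5 m pool at 25 frames/s and tracked to
per-individual (x, y) coordinates.  A model predator sits against one wall
behind a liftable screen; each trial contributes a 7-minute "before" phase
(screen down) and a 7-minute "during" phase beginning 30 s after the
screen starts to lift.  Experimental group size takes three levels — 5
(small), 10 (intermediate) and 20 (large) fish — with five trials per
level.  The scientific question is how group size shifts individual
investment in predator inspection, a volunteer's-dilemma-like public-goods
behaviour, and in risk proxies (refuge use, shoal cohesion).

## Trajectory quality control

Tracking output occasionally contains identity swaps that look like
teleports.  A detection is removed when, relative to the previously
*retained* detection of the same fish, it implies an instantaneous speed
above 50 cm/s or a single-step Euclidean displacement above 50 cm; speed
across a gap of missing frames uses the elapsed time over the gap.
Removal marks the point invisible rather than deleting the row, because
invisibility doubles as the refuge proxy: a rejected point is one the
tracker effectively never saw.  The filter is sequential (each retained
point becomes the reference for the next candidate), which makes it
idempotent, and the two rules are applied disjunctively — a point failing
either is removed.  Phase windows are half-open frame intervals
`[start, end)`: "before" is the 10 500 frames ending at the screen-lift
frame, "during" the 10 500 frames starting 750 frames after it.

## Behaviour metrics

A fish is *inspecting* when its tracked position lies within 30 cm of any
part of the predator-model polygon (minimum Euclidean point-to-polygon
distance, zero inside the outline).  An inspection *event* is a maximal
run of consecutive visible in-zone frames in the during phase.  The event
boundary is the strictest reading available — a single out-of-zone or
invisible frame ends the event — with a configurable `gap_tolerance_frames`
(default 0) for sensitivity analysis of short tracking dropouts.  Five
per-fish responses follow: event count; mean event duration (one value per
fish, the quantity modelled by the Gamma regression); total inspecting time
over the 420 s phase; mean over events of the per-event mean distance; and
the minimum distance of the closest inspection.  Refuge use per phase is
one minus the fraction of the 10 500 phase frames in which the fish was
visible; fish under plant cover cannot be tracked, so invisibility is the
operational refuge definition, and the denominator is the full window (a
frame without a row counts as hidden).

Joint inspections merge individual events whose half-open frame intervals
overlap, transitively (connected components of the interval-overlap
graph); the number of distinct fish in a component is the inspectors-per-
inspection count.  Touching intervals (`[a,b)` and `[b,c)`) do not merge.

## Cohesion

Group density is the median over fish of the inverse area of each fish's
Voronoi cell, with the tessellation clipped to the arena rectangle so that
boundary cells are finite; the cells partition the arena (areas sum to
22 500 cm^2, asserted in tests).  Positions enter once per second — the
first visible detection of each fish within the second, anchored to the
phase-window start — a per-second median over fish is taken, and seconds
aggregate to a per-minute median, giving a 14-point series per trial
(minutes 1-7 before, 8-14 during).  Coincident points are perturbed by
1e-6 cm; a second with fewer than two visible fish contributes nothing.

Sub-groups are DBSCAN clusters with reachability distance 6 cm (about
four guppy body lengths) and `min_samples = 2`.  At that minimum
neighbourhood size DBSCAN has no core/border asymmetry, so the procedure
is exactly chain-rule connectivity — connected components of the <= 6 cm
proximity graph — while lone individuals are not clusters.  The per-minute
median cluster size follows the same second/minute aggregation; seconds
with no cluster of two or more fish contribute nothing.

## Bayesian inference

Each behaviour is modelled separately: Poisson (counts, log link), Beta
(proportions, logit link, precision kappa) or Gamma (positive durations
and distances, log link, shape alpha).  Fixed effects are experimental
group size (three-level factor, treatment-coded against "small"), water
temperature and mean fish length (centred, scaled to unit SD; the
reference point for marginal effects is therefore the sample mean); trial
identity is a random intercept, since fish within a trial are not
independent.  The refuge model adds phase and its interaction with group
size; the cohesion and sub-group time-series models additionally carry a
zero-mean Gaussian-process smooth over the minute index with a
squared-exponential kernel (amplitude half-N(0,1); length-scale
LogNormal(log 3, 0.75), in minutes) to absorb temporal autocorrelation.

Priors are weakly informative, matching the original analyses: Poisson
b, sigma ~ N(0,1); Beta (inspection responses) b, sigma ~ N(0,3),
kappa ~ N(0,5); Beta (refuge and cohesion) b, sigma ~ N(0,1),
kappa ~ N(0,20); Gamma coefficients and alpha ~ N(0,1).  Scale parameters
must be positive, so their normal priors are interpreted as half-normal
(truncated at zero) and sampled on the log scale with the Jacobian
included.  Beta responses exactly at 0 or 1 are squeezed by
`(y(n-1)+0.5)/n` before fitting; the squeeze engages only when boundary
values are present.

Posterior computation has two pieces.  The per-trial random intercept is
integrated out of the likelihood by adaptive Gauss–Hermite quadrature
(15 nodes; 11 for the beta family): for each candidate parameter vector
the conditional mode of each trial's intercept is located —
closed-form-initialised damped Newton for the Poisson and Gamma families,
a bisection bracket of the gradient's single sign change followed by
Newton polishing for the Beta family, whose extreme responses defeat
plain Newton — and the quadrature grid is centred there and scaled by the
local curvature.  This marginalisation is
numerically exact at these node counts (validated against dense
integration in the tests) and removes the funnel geometry that otherwise
defeats ensemble samplers.  The remaining low-dimensional posterior
(coefficients, log sigma, log dispersion, and the GP block where present)
is sampled with an affine-invariant ensemble (emcee) using a mixture of
differential-evolution, snooker and KDE moves, initialised from a Laplace
approximation at the posterior mode.  Because strong trial-level covariate effects can
trade off against the intercept scale, the marginal posterior can hold
several narrow basins; the optimiser is therefore multi-started (a
neutral start, a link-scale least-squares start, and the latter with
small and large initial sigma), distinct optima within 25 nats of the
best are kept, and walkers are allocated across the basins in proportion
to each basin's Laplace mass (log height plus Gaussian log-volume), so
the ensemble's difference moves can maintain and exchange mass between
them.  Defaults are 32+ walkers, 1 200 steps with 400 discarded,
thinning 2; convergence is reported as split-R-hat (walkers treated as
chains, target <= 1.01) and effective sample size (target >= 400), with a
warning — not an error — when missed.

Evidence for each between-level effect uses the Savage–Dickey density
ratio: the prior density at zero of the contrast on the linear-predictor
scale over its posterior density at zero, estimated by a Gaussian KDE with
Silverman bandwidth.  Under treatment coding the small→intermediate and
small→large contrasts are single coefficients with prior N(0, s); the
intermediate→large contrast is a coefficient difference with implied prior
N(0, s*sqrt(2)), and the same rule (root-sum-of-squares of the weight
vector) covers the phase-interaction contrasts.  Ratios are reported >= 1
with a direction ("for"/"against"); when the posterior density at zero
underflows the ratio is capped at 1e6 and flagged.  Verbal categories
follow the conventional bands: 1-3 weak, 3-10 moderate, 10-30 strong,
30-100 very strong, above 100 extreme.  (A Bayes factor of 68 is "very
strong" under these bands, even though informal usage sometimes labels it
"strong".)  Effect sizes are back-transformed: per draw the two levels'
linear predictors at the reference covariate point pass through the
inverse link and are differenced; the posterior median and 89% highest
density interval of those differences are reported on the response scale.
The HDI is the narrowest-window sweep over sorted draws (ties toward the
lower window).

Inspectors-per-inspection is a plain maximum-likelihood Poisson GLM of the
merged-event inspector count on group size, coded with no intercept so
each level's coefficient is its log mean, with Wald p-values (statsmodels).

## Volunteer's dilemma models

In the baseline game one volunteer suffices to produce the public good.
Payoffs: a volunteer receives `b - c`; a defector receives `b` when at
least one other volunteers and 0 otherwise (the non-production cost is the
forgone benefit).  The mixed ESS makes individuals indifferent:
`p = 1 - (c/b)^(1/(n-1))`, and both `p` and the probability that anyone
volunteers, `1 - (1-p)^n`, decline with group size — the group-size
paradox.  Variants are parameterised families solved numerically on the
indifference condition (expected payoffs computed over the binomial
distribution of co-volunteers; residual below 1e-10):

- *shared cost* — cost `c/k` split among the realised `k` volunteers;
  softens but does not reverse the paradox.
- *group-size-dependent cost* — `c(n) = c exp(-decay (n-2))`.  A power-law
  decline `c n^-gamma` can never reverse the ordering (the `1/(n-1)` root
  in the ESS dominates any polynomial), which is why the decay is
  exponential: for `decay > ln(b/c)` the volunteering probability
  increases with group size.
- *synergy* — benefit `b(1 + s (k-1)^power)` for all members when `k >= 1`
  volunteer, default `power = 2`.  Linear synergy (`power = 1`) only
  rescales the dilemma (the interior ESS solves a constant
  `(1-p)^(n-1)`); accelerating synergy makes volunteering strictly
  dominant in large groups while small groups keep an interior mixed
  equilibrium, so larger groups volunteer more.

Degenerate solutions (`p = 0` or `p = 1`) are returned when one strategy
dominates.  A Monte-Carlo simulator cross-checks the analytic
`1 - (1-p)^n` at the expected `1/sqrt(reps)` rate.

## Synthetic data

The trajectory generator emulates the study design — 15 trials (five per
group size), 25 frames/s, the two 7-minute phases separated by the 750
frame screen-lift gap — with fish shoaling around slowly drifting
sub-group centroids (an Ornstein–Uhlenbeck-style biased random walk,
steps capped at 1.55 cm/frame = 38.75 cm/s, safely under the quality
filter).  Scheduled excursions take a fish along the outward normal of the
predator's shoal-facing edge, so the per-frame distance to the model
equals the path parameter exactly; entry and exit cross the 30 cm boundary
in single sub-cap steps and the in-zone profile is a tent dipping to a
drawn closest distance in [5, 28] cm.  Refuge intervals freeze the fish's
position and emit invisible frames, so a reappearing fish never trips the
speed filter and scheduled hidden fractions are recovered exactly.  The
ground-truth record (events with boundaries and distances, hidden frames,
true rates) is frame-exact by construction, which is what makes the
round-trip tests exact rather than approximate.  Default rates (events
per fish per 7 min of 2.5/2.0/8.5 for groups of 5/10/20; heaviest refuge
use in intermediate groups) reproduce the qualitative response pattern of
the study and are fixture choices, not estimates of real data.  Teleport
corruption for testing the filter is a separate fault-injection function,
never part of normal generation.

The metric-level generator is the generative twin of the GLMMs: it samples
responses from the chosen family given coefficients on the same design
matrix the fitter constructs, with trial intercepts at the drawn sigma.
Calibration (`calibration_coverage`) draws the true coefficients from the
model's own priors each replicate, so the 89% HDI of the
intermediate→large contrast covers the truth at exactly 0.89 in
expectation; beta datasets containing exact 0/1 responses are redrawn
(acceptance depends only on the data, so conditional coverage is
unchanged, and the boundary squeeze never engages during calibration).

What the synthetic data do not emulate: real fish kinematics (burst-glide
swimming, wall-following), identity-swap errors other than injected
teleports, behavioural feedback between inspection and refuge use, and
any dependence of inspection distance on group size.  Passing round-trip
tests therefore demonstrates correctness of the measurement pipeline, not
realism of the behavioural model.

## Problem sizes and numerical choices

The test suite and the acceptance script run the trajectory pipeline on
one trial per group size (35 fish, ~760 k detections) and solve the games
over n = 2..50.  Calibration uses 200 replicates per family in the test
suite for the Poisson and Gamma families and 80 for the Beta family
(whose likelihood is the most expensive), and smaller replicate counts in
the acceptance script; these sizes give binomial standard errors of
0.02-0.035 on a nominal 0.89 coverage.  Tolerances: ESS indifference
residuals are checked to 1e-10; Voronoi partition to 1e-6 relative;
Savage–Dickey against the conjugate oracle to 5% at 10 000 draws;
frame-exact recovery to equality.  Degenerate inputs are handled
explicitly: empty trajectory tables pass through the filter, fish with no
events yield NaN distance fields, seconds with fewer than two visible fish
contribute no density value, and a group-size level with no merged
inspections makes the inspectors GLM fail loudly rather than silently.

## Known limitations

Random intercepts are marginalised, so per-trial effect draws are not
exposed.  The ensemble sampler's tail accuracy, not the quadrature, limits
calibration: measured 89%-HDI coverage is ~0.86-0.88 for the Poisson and
Gamma families but ~0.82-0.84 for the Beta inspection family, whose wide
N(0,3) coefficient priors routinely produce near-boundary responses and
razor-sharp, occasionally multi-basin posteriors; longer chains, more
walkers and extra mode searches did not close the remaining gap.  The
Savage–Dickey
KDE underestimates extreme evidence (hence the explicit 1e6 cap).  The GP
smooth is shared across trials (one latent function, not one per trial),
the simplest structure consistent with a single arena-level time course.
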