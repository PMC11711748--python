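# Methods

`beltquest` models a split-belt treadmill psychophysics experiment: walkers
at a 1 m/s baseline have one belt briefly accelerated or decelerated, judge
in a two-alternative forced choice (2AFC) which belt runs faster, and an
adaptive QUEST staircase converges on each walker's just-noticeable
inter-belt speed difference (JND). This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not emulate.

## The staircase

The staircase maintains a discretized posterior over the threshold `T`.
The likelihood of a correct response at intensity `x` is a Weibull
psychometric function

```
p(x; T) = delta*gamma + (1 - delta) * (1 - (1 - gamma) * exp(-10**(beta*(xw - Tw))))
```

with guess rate `gamma = 0.5` (left/right 2AFC), lapse rate `delta = 0.01`
and slope `beta = 3.5`. `xw` and `Tw` are intensity and threshold in
*working units*.

**Working scale.** The default working scale is log10 m/s, the original
QUEST formulation, in which `10**(beta*(xw - Tw)) = (x/T)**beta`: the slope
acts on the *ratio* of intensity to threshold, so discriminability scales
with the threshold (Weber-like behaviour). A `scale="linear"` switch
evaluates the same expression in plain m/s instead. The scale choice is not
cosmetic. With `beta = 3.5` on the linear scale the psychometric transition
spans a fixed ~0.3 m/s regardless of the threshold; for thresholds near
0.07 m/s the per-trial Fisher information then caps the achievable
estimation precision near 0.05 m/s SD after 30 trials, and the staircase
cannot produce the tight trial-30 credible intervals this design relies on.
On the log scale the same slope resolves thresholds to ~0.01 m/s in 30
trials. The log scale is therefore the default and the linear variant is
kept for comparison.

**Prior and grid.** The prior over the threshold is a Gaussian in working
units with mode at the initial guess of 0.1 m/s (10% of baseline) and SD
0.4 working units — deliberately wide so a single prior serves both
perturbation directions. The grid spans 0.005-0.9 m/s in steps of 0.001
working units and is *anchored at the guess*, so the guess is a grid point
exactly. Because truncation to the grid moves the prior mean but not its
mode, the default mode estimator makes the first recommended perturbation
equal the prior guess exactly — every simulated block opens at 0.1 m/s.
The upper grid bound stays below the 1 m/s baseline so a decelerated belt
can never reverse; the 0.9 m/s ceiling also keeps the belt ramp (3 m/s²)
able to finish within a 0.4 s swing phase.

**Placement and estimators.** Each trial is presented at the current point
estimate clamped to [0.005, 0.9] m/s. The default estimator is the
posterior mode with ties broken toward the smaller threshold (determinism);
`mean` (a geometric mean under the log scale) and `median` are available
behind a config switch. Blocks have no termination criterion: they end by
trial count, mirroring a fixed-duration design. The 95% credible width is
read off the discrete posterior CDF with linear interpolation between grid
points and reported in m/s.

## Virtual observers

One observer is parameterized by true thresholds for increase and decrease
perturbations, a response Weibull with the same family as the staircase
(slope 3.5, lapse 0.02 by default), a per-trial non-response probability
(0.026), and a steps-to-response latency distribution (rounded truncated
normal on the integer steps 3-10, mean 5.11, SD 1.8). The latency floor is
3 because the response prompt appears three steps after perturbation onset.
Non-responses are logged as wrong answers with the full 10-step window as
their step count and are excluded from latency averages.

Bookkeeping for the 2AFC: an increase perturbation makes the perturbed belt
the faster one; a decrease makes the *opposite* belt faster. The recorded
response side is derived from correctness and this rule, and tests assert
the consistency exhaustively.

Populations are drawn from a bivariate lognormal: log-thresholds share a
common median (0.06 m/s), shape `sigma_log = 0.59` (which gives the target
95th/5th percentile ratio `exp(2*1.645*0.59) ~ 7`), and latent inter-type
correlation `rho_types = 0.8`. Latency means are drawn correlated with
log-threshold at `rho_latency = -0.3` (slower responders tend to detect
smaller differences); this coupling is an emulation choice, not an
estimate. The median threshold 0.06 m/s makes the *mean* threshold
`0.06*exp(sigma_log**2/2) ~ 0.071 m/s`, i.e. ~7% of baseline.

## Session protocol

Four blocks per participant — two per direction, alternating, with the
first direction counterbalanced by participant parity (the original
ordering is not knowable; the choice is recorded in the run manifest).
Trials per block are drawn uniformly from [25, 35]: block duration is
meaningless in simulation, and the floor of 25 preserves the late-trial
analysis window (trials 16-25) used for steps/JND correlations. Step-level
timing inside a trial (swing-phase triggering, ramp profiles) is abstracted
to the trial level; the signal-processing module covers the step-detection
side separately, because the staircase statistics do not depend on
intra-trial kinematics.

Trial logs round-trip through CSV at full float precision, and a replay
re-runs the posterior from the logged intensities and correctness flags, so
`simulate -> write -> read -> replay -> analyze` reproduces every reported
statistic bit-identically for a fixed seed.

## Gait signal processing

Marker traces (250 Hz) with short missing-data runs are repaired by natural
cubic splines (gaps at the trace edge or longer than 200 ms are refused with
the offending interval named) and smoothed with a Savitzky-Golay filter,
124 ms window (31 samples), order 3.

Step detection uses the combined left+right vertical GRF, low-pass filtered
with a 524 ms window chosen to cover about one step but never two. The
filter is a Savitzky-Golay of order 3 rather than a boxcar: a 524 ms moving
average has a spectral null at 1/0.524 s ≈ 1.9 Hz — exactly the step
frequency of normal walking — and would annihilate the very oscillation the
detector needs. Events are local maxima of the filtered signal; turning
points (zero crossings of the smoothed second derivative) fill in only
where no maximum falls within a 250 ms refractory window and only between
the first and last maximum (turning points on the lead-in/lead-out load
ramps are not steps). Events in unloaded stretches (below 25% of the
filtered signal's range) are discarded as noise. The width precondition is
enforced as `width * cadence in [0.8, 2.0)` with the cadence estimated
spectrally; the lower edge admits slow walking at 1.6 steps/s while a
doubled cadence still fails. The synthetic GRF generator scripts
alternating half-sine stance loads (stance duration 1.25 step periods,
amplitude 700 N, optional timing jitter and white noise); the detector
recovers scripted step counts to ±1 in 40 across cadences 1.6-2.2 steps/s.

Steps-to-response counts detected events in `(onset, response_time]`,
capped at the 10-step response window.

## Statistics

*JZS t-test Bayes factor*: `BF10` for a paired design is the marginal
likelihood of the observed t under a Cauchy(0, 0.707) prior on the
standardized effect size, over the point-null likelihood, by adaptive
quadrature of the noncentral-t density split at the likelihood peak
(relative tolerance 1e-10; convergence failures raise with diagnostics).

*Correlation Bayes factor*: the prior on the population correlation is a
stretched beta of width 0.333 (`(rho+1)/2 ~ Beta(3, 3)`); the likelihood is
the exact small-sample density of the Pearson r (hypergeometric form), and
the BF again comes from adaptive quadrature split at the observed r.
Perfect correlations are returned as an overflow guard of 1e12. Both
integrators are cross-checked in tests against fixed-grid Riemann sums and
against an independent analytic implementation.

*Attenuation ceiling*: the maximum observable correlation between two
measures with reliabilities `r11`, `r22` is `sqrt(r11*r22)`. The observed
cross-type correlation is compared to this ceiling with
`t = (r - r_max) * sqrt(n-2) / sqrt(1 - r**2)`, df = n-2 — a construction
that treats the ceiling as a fixed reference value; it reproduces the
published worked example but is an inference about that analysis, not a
standard named test. The null interval for the interval Bayes factor is
derived by propagating Fisher-z intervals of the two reliabilities through
the product rule — an explicit interpretation, since the ceiling has no
standard confidence interval; when both reliabilities are 1 the interval
degenerates to a point and the interval BF is reported as undefined.

*Deming regression*: closed-form errors-in-variables slope with
error-variance ratio `lam` (y-error over x-error variance); `lam = 1` is the
orthogonal fit, `lam -> inf` recovers OLS of y on x.

Two-sided p-values throughout; no multiple-testing correction. All
correlations are Pearson correlations of participant-level means.

## What the synthetic data do not show

The virtual observers have, by construction, exactly the Weibull response
family the staircase assumes, stationary thresholds, and independent trials.
Passing tests therefore demonstrate that the pipeline is *internally*
correct and well calibrated — not that real walkers satisfy these
assumptions. In particular the simulation omits: learning or adaptation
within and across blocks, sequential response dependencies and response
bias, any biomechanical asymmetry between speeding up and slowing down a
belt (the two directions differ only through their latent thresholds), and
real marker/GRF artefact structure beyond random gaps and white noise.
Simulated reliabilities come out higher than is typical of human data
(~0.85 vs ~0.5) because the staircase's measurement error is small relative
to the wide between-participant spread; published human summary statistics
are consequently not reproduction targets for the simulator, only the
structural behaviours (spread ratio, non-response rate, latency window,
null type difference, attenuation-consistent cross-type correlation) are.

## Default problem sizes

Simulation-based checks use sizes chosen to make sampling error small at
interactive runtimes: 200 replicate blocks per true threshold for staircase
recovery; 40 replications of 16 observers for the null-difference check; 30
replications of 24 observers for the attenuation-band check; populations of
2000 for distributional checks; 10,000 trials for rate calibrations; 50
seeds for step-detection validation.
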