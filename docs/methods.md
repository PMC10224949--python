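# Methods

## Task structure and conditions

Each condition presents a set of cylinders (radius 3.5 cm). The standard
set has heights 5–9 cm with family weights 300, 400, 600, 700 g and an
800 g outlier at 7 cm; the sigmoidal ("nonlinear") variants replace the
family weights with 300, 320, 680, 700 g; the small-family variant keeps
only the 6/7/8 cm objects (400, 800, 600 g). Sessions are 100 trials
(103 in Frequent Outlier), organized in blocks containing one trial per
family object plus, after the outlier's introduction, one outlier trial
(three in Frequent Outlier). Sequential conditions present only family
objects for the first 40 trials; the Concurrent conditions interleave all
five objects from trial 1.

Block structures not fully determined by those counts were fixed as
follows: Small Family keeps the 40-trial family-only pre-phase (20 blocks
of 2) followed by 20 blocks of 3; Frequent Outlier uses 10 pre-blocks of 4
plus 9 post-blocks of 7 (4 family + 3 outlier), the only integer
decomposition giving 103 trials at a 3:4 outlier:family ratio.

Schedules are randomized within block by rejection sampling of
permutations until the boundary constraint holds (the last object of block
*t* never opens block *t*+1); within-block repeats can only involve the
outlier and only in Frequent Outlier, where they are permitted. Schedules
are deterministic functions of an integer seed, which is recorded in the
output.

### Analysis windows

Three windows drive the analysis, generalized from the standard design by
a uniform block rule:

- **Family-regression window**: every block after the first
  outlier-containing block (standard: blocks 12–22; Frequent Outlier:
  12–19; Small Family: 22–40; Concurrent: 11–20, i.e. the second half).
- **Outlier window**: all outlier trials strictly after the very first
  outlier presentation (Concurrent: outlier trials after block 10).
- **Participant-screening window**: first outlier block onward
  (block 11 in the standard design).

For non-standard block structures these three windows are stated slightly
differently in the source descriptions ("block 11 onwards", "blocks
12–22", "after the very first presentation"); the block rule above applies
each literally where it is defined and extends it by block position
elsewhere. An alternative for Small Family — matching the standard
condition's post-introduction *trial* count — would start the window
mid-block; we prefer whole blocks and note that the two choices differ
only in whether the window's first partial block is included.

## Trial physics

Units: k = 100 N/m, c = 3 N·s/m, masses in kg internally, g = 9.81 m/s².
This convention puts equilibrium lengths mg/k for the 300–800 g objects at
2.94–7.85 cm, commensurate with the 2.5 cm and 6 cm error scales in the
feedback functions; k and c are configurable if a different convention is
wanted. On release the object starts at rest with the spring at the set
length L; its offset relaxes to e = L − mg/k through the closed-form
damped-oscillator solution. All task objects are underdamped at the
default parameters (ζ ranges 0.17–0.27); the critically damped and
overdamped branches are implemented for completeness and verified against
a numerical integrator. Scores are rounded half-away-from-zero to the
nearest integer. The speeded rule applies after trial 12: responses slower
than 2.25 s lose 100 points and trigger a timeout of 6 s + 2 s per prior
violation.

## Synthetic-participant model

The generative model is plumbing: the minimal structure that reproduces
the qualitative pattern the metric is designed to measure, so the pipeline
can be validated by parameter recovery. It is not fit to, and should not
be mistaken for, real behavior.

Each participant has a linear internal category line (the least-squares
fit of true equilibrium length on height over the family — exactly the
true family line for linear families, the best linear approximation for
the sigmoidal ones). Responses:

- **Family trials**: the response converges exponentially (rate
  `learning_rate`, default 0.15/trial) from the family-mean length to the
  category line; convergence is treated as complete once the outlier phase
  begins (the residual transient at that point is < 0.3% of the initial
  bias at the default rate, and clamping it makes the zero-noise pipeline
  an exact identity on the latent encoding strength).
- **Outlier trials**: a convex mixture
  `latent_ce/100 · line(h_outlier) + (1 − latent_ce/100) · true length`.
- **Category update**: the error actually experienced on an outlier trial
  (true equilibrium of the presented mass minus the response — i.e. only
  error unexplained by the participant's own plan) scales the category
  line multiplicatively with gain `category_update_gain` (default 0.01),
  raising slope and intercept together. This mimics the observed upward
  drift of the family regression after the outlier appears and makes the
  pre/post slope shift positive on average. The default is kept small so
  the drift biases recovered encoding strength by under ~3 points at the
  default noise; larger gains trade recovery accuracy for stronger drift.
- **Noise**: Gaussian motor noise on every response (default SD 0.5 cm,
  chosen so that per-participant metric noise is of the order of the
  between-participant spread implied by the published standard errors);
  uniform ±150 g weight perturbations in Added Noise are applied to the
  presented mass before feedback; response times are log-normal (median
  2.33 s, or 1.42 s for speeded cohorts).

What the model omits: trial-by-trial error-driven learning on family
trials, perceptual color effects (color schemes are metadata), explicit
strategies, heavy-tailed motor noise, and any response-time dependence of
accuracy. Passing recovery tests therefore shows that the measurement
pipeline is faithful to a known ground truth of this form — not that real
behavior follows the model.

## Exclusion and the encoding metric

Trial exclusion: per participant × family object, responses beyond 4
scaled MADs (MAD × 1.4826, the normal-consistency constant) of the cell
median are flagged in a single pass; outlier-object trials are never
flagged; cells with fewer than 3 trials are exempt (degenerate MAD) and
logged. Participant exclusion (applied after trial exclusion): mean
family response over the screening window beyond 5 scaled MADs of the
cohort median. With zero motor noise the MAD is degenerate (0), so
exclusion should be disabled for exact-identity checks.

The metric: fit OLS of family response on height over the regression
window; CE% = 100·(1 − (mean outlier response − regression value at the
outlier height) / (true outlier length − true family line at the outlier
height)). For the symmetric standard design with balanced counts, the
regression value at the outlier height equals the mean family response
(the OLS line passes through the mean point); the package checks this
identity to 1e-9 cm and skips it for asymmetric or unbalanced windows.
Bootstrapped SEMs are the SD of resampled cohort means (seeded).

## Bayes engine

Likelihood: Student-t on the observed mean difference, scale = the
standard error of the difference under unequal variances, df by
Welch–Satterthwaite. Null: point at zero. Alternative: half-normal on the
hypothesized half-line, σ = range / z₀.₉₉₅ with range equal to the
reference mean (decrease) or 100 − reference mean (increase), so 99% of
the prior mass covers the theoretically possible effect; z₀.₉₉₅ is
evaluated at full double precision. B10 is the prior-averaged marginal
over the point likelihood, computed by adaptive quadrature on the prior's
finite effective support [0, 13.5σ] (mass beyond < 1e-40) with the
likelihood peak passed as a breakpoint and relative tolerance 1e-10;
non-convergence raises with diagnostics. Combined comparisons center each
condition-reference pair on its reference mean, pool, and use
σ = √((σ₁² + σ₂²)/2). Evidential labels follow the standard
anecdotal/moderate/strong/very strong/extreme bands at 3/10/30/100 with
reciprocal bands for the null.

The power simulator draws both groups from normal outcome distributions
and counts threshold crossings (B10 > 3, or < 1/3 under a true null). It
evaluates B10 with a vectorized fixed-grid quadrature (64 Gauss–Legendre
panels × 4 nodes over [0, 8σ]), which agrees with the adaptive engine to
better than 1e-5 relative across the summary-statistic ranges that arise
and keeps 10,000-replicate runs to a few seconds. The pilot groups that
motivated the published design (means 84% and 47%) have unpublished SDs,
so SDs are explicit scenario inputs; the analysis script reports a
25–35-point sensitivity band (SD 30 is consistent with the ~10-point
standard errors of the published comparisons at n = 20).

## Problem sizes and numerical choices

Tests and drivers use 20-participant cohorts, 1,000–2,000 power
replicates (10,000 available via `reps`), 1,000–2,000 bootstrap
resamples, and 1,000 seeded schedules per condition for constraint
checking. All randomness flows through `numpy` `SeedSequence` spawning,
so every table, report, and estimate is reproducible from a single
integer seed. Exact-identity assertions use 1e-9 tolerances (float
arithmetic over ~100-trial aggregations); oracle comparisons for the
physics use 1e-6 cm against an RK integrator at 1e-11 relative tolerance.

## Known limitations

- The published per-condition encoding means cannot be reproduced without
  the deposited participant data; the synthetic cohorts target the same
  means but have a chosen, not estimated, between-participant spread, so
  synthetic Bayes factors are more extreme than the published ones.
- The published design power (0.80 at n = 20) is not exactly recoverable
  (unpublished pilot SDs); the power module verifies structural
  properties and reports sensitivity bands instead.
- The "block 11 onwards" screening window and the Small Family window
  generalization are package choices where the source descriptions only
  cover the standard block structure.
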