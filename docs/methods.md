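# Methods

`vocalphen` converts confidence-scored species labels from an AI acoustic
classifier (e.g. BirdNET run over consecutive, non-overlapping 3-s windows)
into population-level vocal-phenology curves and standardized phenometrics.
This note records the statistical model, the numerical choices, what the
synthetic generator does and does not emulate, and the known limitations.

## Pipeline overview

1. **Calibration.** For each species, a manually reviewed sample of clips
   (binary true/false against confidence score CS) is drawn over two score
   ranges — broad (0.1–1.0) and high (0.95–1.0) — and fed to a logistic
   model `logit pr(TP) = b0 + b1·CS`. The retention threshold is the closed
   form `CS* = (logit(t) − b0)/b1` at target precision `t` (default 0.95),
   clamped to [0, 1]. Solutions above 1 are "unattainable" (nothing
   retained); solutions below the run's score floor legitimately retain
   everything. Labels with `CS < CS*` are discarded.
2. **Call density.** Retained labels become a daily binomial success rate
   per species × site × day: labels ÷ analyzed 3-s segments. Duplicate
   labels within one segment collapse to one, because the segment is the
   Bernoulli trial. Zero-label days inside a deployment window are explicit
   rows; days outside deployment are structurally missing, never zeros.
3. **Eligibility gate.** A species × stratum cell is modeled only when ≥ 5
   distinct sites hold at least one retained label.
4. **Hierarchical smooth.** Per cell, a binomial GAM of ordinal day with
   site random intercepts (below).
5. **Phenometrics.** Peaks, half-rises, half-declines and the phenoperiod
   are extracted from the population-level daily curve.
6. **Group summaries.** Means of onset/peak/duration by migratory strategy ×
   elevation stratum, and per-species Mid-minus-Low peak lags.

## The hierarchical smooth

Per species × stratum, with `k_sd` labels out of `n_sd` segments at site `s`
on day `d`:

    k_sd ~ Binomial(n_sd, p_sd),    logit p_sd = a + f(d) + b_s,
    b_s ~ N(0, sigma^2)

`f` is a low-rank penalized cubic B-spline of day — rank `k = 7` by default,
open uniform knots over the observed day range, second-order difference
(curvature) penalty, sum-to-zero constraint absorbed by a null-space
reparameterization (so the smooth contributes `k − 1` columns next to the
intercept). The penalty null space contains linear coefficient trends, the
standard property of curvature penalties; an exact thin-plate basis is not
required because the phenometrics depend on the smooth's shape class, not
the basis family.

Random intercepts are the usual GAM formulation of a Gaussian random effect:
a ridge-penalized indicator block with common precision `1/sigma^2`,
estimated jointly with the smooth. Fitting is penalized IRLS (Newton with
step halving on the penalized log-likelihood). The two variance-type
parameters `(lambda, sigma)` are selected on a log-spaced grid by the
Laplace-approximate restricted likelihood

    V(lambda, sigma) = l_p(theta_hat) + 1/2 log|S_lambda|_+ − 1/2 log|H + S_lambda|,

maximized over `lambda ∈ 10^{−2..6}` (9 points) and
`sigma ∈ 10^{−1.3..0.7}` (5 points). The grid is deliberately coarse: the
restricted likelihood is flat near its optimum and the resulting curves are
insensitive at the resolution phenometrics use (whole days). A test
cross-checks the fitted population curve against mgcv's
`gam(cbind(k, n−k) ~ s(day, k=7, bs="tp") + s(site, bs="re"), REML)` on a
common simulated cell; the two agree to < 0.01 on the probability scale.

**Population curve convention.** Predictions set the site offset to zero
(the median site), one curve per cell, matching the single-curve-per-species
presentation this workflow supports. Predictions are clipped to the observed
day range — no phenometric is extracted from extrapolation.

**Deviance explained** is `1 − D_model / D_null`, with the null deviance
from the intercept-only binomial fit (`p̄ = Σk/Σn`), and defined as 0 when
all observed rates are identical.

## Phenometric rules

All rules operate on the integer-day grid of the predicted curve, with
`r = 0.30` as the relative-height cut:

- **Qualifying peak** — interior local maximum (`p[i] > p[i−1]` and
  `p[i] ≥ p[i+1]`; plateaus take their first day) with `p ≥ r · max(p)`.
  "Within at least 30% of the seasonal maximum" is read as
  `p ≥ 0.30 · max(p)`; the alternative reading (≥ 70% of max) is rejected
  as inconsistent with how boundary-active species behave at season start.
- **Half-rise / half-decline** — first crossing of the midpoint between a
  local minimum and the adjacent peak, linearly interpolated between grid
  days and floored to a whole date (the outputs are calendar dates). The
  window edges serve as local minima when no interior minimum exists; an
  edge that sits above the cut and falls away from it also anchors a
  crossing, so a curve already declining on day one still gets a period end.
- **Phenoperiod** — first half-rise to last half-decline. If the curve is
  within the cut at the window start (end), the first (last) modeled day is
  used instead and flagged as a boundary. A curve with no qualifying peak
  and no crossing at all (e.g. flat) has no detectable phenoperiod, even
  though the boundary test is vacuously true for it — otherwise any flat
  curve would claim a full-window phenoperiod. Declines that never re-cross
  before the window end produce no half-decline; the boundary rule then
  governs the period end.
- **Group means** include boundary-flagged starts at their boundary dates
  (the summary reports how many cells are boundary-flagged so truncation is
  visible). The cross-stratum lag averages `peak_Mid − peak_Low` over
  species detected in both strata.

## The synthetic generator

`synthetic.simulate_study` emulates the full data-generating process the
pipeline assumes: two elevation strata (Low < 650 m, Mid 650–1350 m) with 30
recorder sites each by default; deployment windows of 42 ± 14 days (clamped
at ≥ 7) placed uniformly in a 120-day season (ordinal days 91–210); 2800
analyzed 3-s segments per site-day (the 140-min morning schedule); Gaussian
site intercepts on the logit scale (SD 0.5); classifier recall 0.5 per truly
vocal segment; false labels at 0.002 per segment; true-positive scores
Beta(8, 2) and false-positive scores Beta(2, 8), so pr(TP) rises
monotonically with score; and an optional linear day drift of the TP score
mean to reproduce seasonally declining precision. Validation sets are drawn
by the calibration module's own two-range sampler with outcomes set by each
label's true origin. Where the source study reports no usable magnitude
(per-day label rates, score distributions), defaults are order-of-magnitude
choices a field ecoacoustician would recognize, fixed once.

**Truth curves live in the model's function class.** Species are specified
as a baseline logit plus Gaussian bumps `(peak_day, amplitude, width)`, and
the sketch is then projected (least squares on the season grid) onto the
same rank-7 spline space the estimator uses; the projected curve is the
ground truth, and truth phenometrics are the phenometrics module applied to
it. Rationale: an a-priori approximation study showed that raw Gaussian-bump
curves — particularly bimodal ones — are not representable at rank 7, and
the basis-approximation bias alone (up to ~8 days on duration) would
dominate any end-to-end comparison. Rendering truth into the smooth class
makes recovery tests measure what they are meant to measure: estimation
error from sampling noise, staggered deployments, site heterogeneity,
imperfect recall and score-dependent false positives. The corollary is that
these tests do *not* measure basis misspecification: for real data whose
seasonal structure is finer than the chosen rank, `k` must be raised.

The ready-made community (`make_paper_like_community`) holds six species
spanning the four migratory strategies: an early, long-vocal resident that
is already within 30% of its seasonal maximum on day 1 (boundary-flagged
start), a bimodal resident with a second bump 48 days after the first, a
short-distance migrant, two late/brief long-distance migrants, and a
late-peaking irruptive. Every Mid-stratum curve lags its Low counterpart by
17 days.

What the generator does **not** emulate: spatial autocorrelation beyond
independent site intercepts, weather/masking effects on detectability,
within-day (diel) structure, recall varying over season, and vocal-class
composition. Passing recovery tests therefore says nothing about those
failure modes in field data.

## The calibration recovery study

The threshold-recovery experiment (50 replicate species, n = 200 reviewed
clips each) draws outcomes from precision curves logistic in the score —
the model class the calibration stage fits — so the true threshold is
defined in closed form. Slopes are drawn from 15–30 per unit score, the
local log-odds slope implied by the generator's Beta score mixture at
mid-range scores (`d logit pr(TP)/ds ≈ 6/(s(1−s))` for the default shape
parameters), with true thresholds spread over 0.4–0.9. The review sample
weights the broad range 150/50 rather than 100/100: a Cramér–Rao analysis
of the two-range design shows the information about a mid-range threshold
comes almost entirely from the broad range, and with a 100/100 split the
information bound alone sits at the size of the acceptable error. The
package default for field use remains an even split, and both quotas are
configurable. Under these conditions the mean absolute threshold error is
≈ 0.026.

Separation handling: with a single score covariate, (quasi-)complete
separation is detected exactly — no score overlap between outcome classes —
and flagged without a finite MLE; thresholds then come from a grid scan of
the empirical precision-at-threshold curve. Note that this empirical scan is
biased low under the two-range design (the oversampled high range dilutes
aggregate precision), which is why exact separation detection, rather than a
parameter-magnitude heuristic, matters.

## Numerical choices and degenerate inputs

- Score enters the calibration model untransformed; the closed-form
  threshold requires a monotone link in CS.
- AIC is `−2 loglik + 2k`; model-comparison ties break toward the
  score-only model (parsimony).
- All-positive validation outcomes give threshold 0 ("all-true");
  all-negative give "unattainable". Cells with fewer distinct days than the
  basis rank reduce the rank with a warning; non-converged smooths are
  flagged and excluded downstream.
- Retention-report fractions are rounded half-up to 2 decimals, matching
  how such tables are printed.
- Everything is deterministic given inputs and seeds; pipeline reruns are
  byte-identical.

## Problem sizes used by the test and acceptance runs

The end-to-end study uses the six-species community at 30 sites per stratum,
a 120-day season and 2800 segments/day (≈ 0.5 M labels), which fits a
12-cell HGAM batch in a few seconds. The power studies use 100 replicates of
n = 200 validation draws; the oracle-equivalence sweep uses 500 random
piecewise-linear curves. These sizes were chosen so each study's Monte-Carlo
error is well below the tolerance it checks.

## Known limitations

- At data-sparse season edges (few deployments covering the first or last
  days) the smooth is weakly constrained and can wiggle upward, occasionally
  flipping a boundary flag or appending a spurious edge half-rise; mgcv
  shows the same behavior on the same cells. Group summaries are robust to
  this; single-cell phenoperiod endpoints near the window edge are the least
  reliable outputs.
- Phenoperiod endpoints are reported without uncertainty; the workflow
  estimates relative vocal activity, not abundance, and recall is not
  estimated.
- The 30%-of-maximum rule and the half-crossing definitions are conventions;
  all are parameterized (`rel_height`, target precision, `k`, gate size) so
  sensitivity analyses are one loop away.
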