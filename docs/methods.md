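# Methods

## Model

The simulator implements a change-of-mind drift-diffusion agent for
two-stage delay-foraging tasks.  Per trial: an offer delay is drawn
uniformly from the integers 1–30 s; the agent draws an initial
willingness-to-wait `W0 = W_T + N(0, σ_W)` around its preference threshold
`W_T` (18 s by default) and accepts iff `W0 ≥ offer` (weak inequality), or
unconditionally under the accept-all policy.  Having accepted, `W` drifts on
a discrete 1 s grid, `W(t+1) = W(t) + N(0, σ_N)`, and the agent quits the
first second at which `W(t) < T_WZ(t)` (strict inequality).  Quit checks run
at `t = 1 … offer−1`; at `t = offer` the reward is delivered, and in the
original variant the bound is 0 there anyway, so no check is performed at
the reward instant.  In the original variant `T_WZ(t) = offer − t`.

Assumptions worth stating: trials are independent (no learning, satiety, or
session time budget); time is integer seconds throughout (real-valued input
times are floored with a warning); there is a single reward site per
simulated session, since the agent's threshold is site-independent.

One wording conflict in the model's description had to be resolved: the
acceptance rule is sometimes written as `W0 ≥ W_T`, which would make
acceptance independent of the offer (constant 0.5) and destroy the
psychometric accept curve that the σ_W calibration fits.  We use
`W0 ≥ offer`, the only rule consistent with the closed-form accept rate
`Φ((W_T − offer)/σ_W)` and with a bound that starts at the offer and reaches
zero at reward.  Likewise `T_WZ(0) = offer` (not `W0`), the only start value
for which a −1 s/s slope reaches 0 at the countdown's end.

### Variants

* `twz_slope` ∈ {−1, 0, +1}: expanding (original), flat, or ascending
  (anti-sunk-cost) bound.  The bound is never floored at zero — the
  ascending bound grows without limit.
* `twz_init` ∈ {offer, zero, offer_at_dt_end}: where the bound starts.
  `zero` gives a flat bound at 0 (quits then require `W < 0`; at baseline
  parameters ≈ 3.5 % of accepted trials, concentrated at long offers, versus
  ≈ 51 % with the flat bound at the offer).  `offer_at_dt_end` holds the
  bound at the offer until an imposed decision time ends (reset model 1).
* `upper_bound = non_increasing` clips positive drift draws to zero
  (`W(t) ≤ W(t−1)`).
* `decision_time_s = DT > 0` forbids quitting for `t ≤ DT` and resets W to
  W0 at `t = DT`; drift during the decision time is discarded, and offers
  no longer than DT are earned automatically.

## Measures

**p(Earn) matrix.** Every accepted trial with offer `D` and stop time `τ`
(the quit time, or `D` if earned) passes through states `(s, D−s)` for
`s = 0 … τ−1` and contributes an earn/not-earn to each; the state from
which a quitter left is its last contribution.  Cells visited fewer than
`min_count` times are undefined (NaN), never zero-filled.  The default is
1 for simulation-scale data and 5 for small behavioral sessions; sign tests
on bound variants use 10, because a single stray trial surviving deep into
a rarely accepted long offer can contribute ±15 probability points to a
10⁵-trial bubble at extreme σ_W.

**Sunk-cost bubble.** `B(s) = Σ_r [p(s,r) − p(0,r)]` over every `r` defined
in both rows (no further range restriction — an open choice, recorded here),
and `bubble_total = Σ_{s≥1} B(s)`, in summed probability points.

**Baseline slope.** Unweighted OLS of `p(0,r)` on `r`.  All least-squares
fits in the package are unweighted OLS, matching the "linear fit" the
measures are defined by.

**Attrition bias.** Each accepted trial contributes its W0 once per second
in the wait zone (`s = 0 … τ−1`, the actual scatter points rather than a
binned histogram); the measure is the OLS slope of W0 on `s`, computed by
exact sufficient statistics and therefore order-invariant.

**Threshold.** Grid MLE over integer thresholds 0–30 with a fixed lapse
(default 0.05; offers ≤ T accepted with probability 1 − lapse, else lapse).
Ties break to the midpoint of the maximizing set; all-accept/all-skip data
return the boundary with a degeneracy flag.  A jointly fit lapse is not
implemented because the measure, as defined, is a step-function likelihood
scan.

**Probit tangent and σ_W.** A two-parameter ML probit of accept on offer;
the tangent is the analytic derivative magnitude `|b₁|·φ(0)` at the 50 %
point.  For data generated by the model the tangent is `φ(0)/σ_W`, so the
hyperbolic calibration `σ_W = a + b/x` has the ideal limit `a = 0`,
`b = φ(0) ≈ 0.3989`, and the simulated protocol (10 replicates × 10⁵ trials
per σ_W in {0.25 … 20} at σ_N = 3) lands within half a percent of it with
adjusted R² ≈ 0.9997.  Note that measuring the "tangent" instead as a 1 s
finite difference of the fitted curve would bias the fit toward a negative
intercept (≈ −0.07 to −0.26 depending on the difference scheme, by closed
form); we use the analytic derivative.

**Rank tests.** The value-conditioned comparison of Δp(Earn) between
negative- and positive-value cells is a two-sample Wilcoxon rank-sum
(Mann-Whitney) test; the mesh-comparison offsets use the one-sample signed
rank test against zero.  The two are distinct tests and are named in the
output; for ≤ 8 observations per group the rank-sum p agrees with
exhaustive permutation enumeration (verified in the tests).

**Latency to accrual.** The smallest `s ≥ 1` with
`B(s) > κ · max_s B(s)` and `B(s+1)` also above (two-bin persistence),
κ = 0.10 by default.  The detection constant is an operational choice —
only the 15 s outlier cutoff is externally given.

## Campaigns

* **Parameter sweep:** one experiment per cell of
  σ_W ∈ {0, 0.25, 0.5, 1, 3, 5, 8, 10, 20} × σ_N ∈ {0, 2, 3, 5}; the four
  regressions (attrition, baseline, bubble on σ_W + σ_N; bubble on
  attrition) use one measure per cell, giving 33 residual df on the full
  grid.  Per-predictor F is the squared t statistic.
* **Calibration:** as above; perfectly separated replicates (possible at
  the smallest σ_W) are dropped with a count.
* **Reset experiment:** accept-all agents, DT on the integer grid 0–10 s
  (the grid is a package choice), 10⁵ trials per DT; model 1 uses
  `offer_at_dt_end`, model 2 the original bound start.  Both produce
  near-perfect quadratic fits of total sensitivity vs DT; the models are
  discriminated by curvature — model 1 is nearly linear (quadratic
  coefficient ≈ +0.05, at the edge of resolution), model 2 strongly
  decelerating (≈ +1.25).
* **Mesh comparison:** subjects are matched to the mesh cell whose σ_W is
  nearest their fitted σ_W, then (among ties) nearest in z-scored
  (baseline slope, bubble) space; signed subject-minus-mesh offsets are
  tested against zero.  The matching rule (σ_W first, standardized 2-D
  distance second) is recorded in every output because the procedure it
  operationalizes is ambiguous.

## Synthetic generator

The hazard generator emulates the statistical structure the measures assume
without sharing any drift-diffusion machinery: four sites with individual
thresholds (defaults 12/16/20/24 s, spanning the offer range as the four
flavors/galleries do), a symmetric-lapse probit accept rule
(`lapse + (1−2·lapse)·Φ((threshold−offer)/accept_noise)`, defaults 0.02 and
5 s), and a per-second logistic quit hazard
`h(t) = logistic(logit(h₀) + c_rem·(offer−t) + c_spent·t)` with defaults
h₀ = 0.06, c_rem = +0.08 (quitting more likely far from reward),
c_spent = −0.15 (a mild escalation of commitment).  Defaults were chosen
once to give task-realistic accept (~60 %) and quit (~15–30 %) rates and a
clearly signed bubble.  p(Earn | s, D) is exactly
`Π_{t=s+1}^{D−1} (1 − h(t))`, an analytic oracle for the entire
measurement chain.

What it does not emulate: session-level time budgets and satiety, reward-
flavor preference dynamics, learning, and cross-trial dependence.  Passing
its recovery tests therefore shows the measures read out the generating
structure correctly — not that real subjects satisfy that structure.

## Numerical and reproducibility choices

One root seed spawns three named substreams (offers, W0, drift noise); the
noise matrix is drawn in row-major trial order, so growing `n_trials`
extends the table without reshuffling earlier trials, and the chunked
executor (2¹⁷ trials per block, for memory) draws an identical sequence at
any chunk size.  Campaign seeds derive deterministically from
(root, cell index, replicate) and stay below 2³¹.  Probit fits that face
perfect separation are flagged (tangent = ∞) rather than fit; rank tests on
all-zero differences are reported as degenerate rather than forced to a
p-value.

Problem sizes: tests run 2×10⁴–10⁵ trials per experiment; the acceptance
script runs the calibration and reset campaigns at 10⁵ trials per
experiment and the sweep at 10⁶ per cell.  The sweep regressions' F
statistics are stable to within ±5 % between 10⁵ and 10⁶ trials per cell.

## Known limitations

* Blocking upward drift (the non-increasing-W variants) erodes the
  surviving willingness toward the bound, so those variants produce
  *negative* bubbles here (≈ −10 for the original bound, ≈ −72 with the
  flat bound) rather than the near-zero sensitivity sometimes ascribed to
  the flat-bound-plus-monotone-drift combination; no reading of that
  variant consistent with its stated mechanism yields |bubble| ≈ 0.
* The sweep-regression F statistics depend on unpublished details of how
  the per-cell summary measures are computed; alternative summaries
  (count-guarded, range-capped, cell-mean, count-weighted bubbles) move
  them by less than a factor of two, and the qualitative structure —
  attrition driven by σ_W with negligible σ_N, baseline and bubble driven
  by σ_N, bubble peaking at high σ_N and mid σ_W, and bubble neither
  implied nor precluded by attrition — is robust to all of them.
* σ_N has no behavioral estimator here (only σ_W is identified, through
  the accept curve); fitting σ_N to individuals is out of scope.
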