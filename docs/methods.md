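# Methods

This note records the model, the numerical choices and the limits of what
the test suite demonstrates.

## Unit of analysis and data model

The unit is the **ward-day**: the multiset of measurement clock times in
one ward on one calendar day, as decimal hours on the linear scale
[0, 24). Times come from bedside meters logged to the minute, so exact
ties are expected and tolerated everywhere. A 00:xx measurement belongs to
its calendar date; no circular wrapping is applied — a bedtime component
may in principle place small mass past midnight, and timings near 0 h are
modelled as-is on the linear scale. Panels are complete ward × day grids;
days without measurements are kept with n = 0 so they can be counted and
propagate as *missing* (never as p = 1) through every stage. Duplicate
records (same patient, same minute) are kept: with ward-level marginal
distributions as the target there is no defensible deduplication rule.

## Uniformity testing

The non-adherence null is Uniform(0, 24). The one-sample KS statistic
`D = sup |F_n(y) − y/24|` is computed with exact finite-sample p-values up
to n = 150 and the asymptotic Kolmogorov limit above (configurable); the
method used is reported in every result. α = 0.05 throughout,
configurable once and shared by all stages. No multiple-testing
correction is applied across ward-days — the day-level p-values are a
surveillance signal, not confirmatory inference. Minute-resolution ties
violate the continuity assumption of the two-sample asymptotic p-value;
a pooled-resampling bootstrap p-value (default B = 1000) is available and
labelled when used. The default remains asymptotic.

## Power by empirical-CDF inversion

Each observed day defines its own alternative: its empirical CDF with
knots (y_(k), k/n), duplicates collapsed to the maximal F (a point mass),
linearly interpolated, and anchored on the left at (y_(1), 0). The anchor
is required because the inversion searches for the interval with
F(t1) < u ≤ F(t2), which is undefined below the smallest observation; the
consequence is that simulated support equals [min, max] of the observed
day. Draws map u through the piecewise-linear inverse (a single linear
interpolation in u, identical to the interval formula). Power is the
rejection fraction over B iterations (default 5000; tests use 300–2000),
computed by comparing each replicate's D against the exact critical value
`kstwo.isf(α, n)` — equivalent to thresholding the p-value, since the
survival function is strictly decreasing in D.

Two properties deserve emphasis. First, a day with fewer than two
distinct values has a degenerate CDF; its power is undefined and the day
is reported missing. Second, self-sampled power is *conditional on the
observed day*: a finite day drawn from Uniform(0, 24) embeds its own
sampling deviation in the interpolated CDF, so its self-sampled power
exceeds α on average (≈ 0.3 at n = 80) and approaches α only for days
lying close to the uniform quantiles. This is not an artifact — it is the
mechanism by which observed structure translates into power — but it
means day-level power must not be read as a type-I error rate. The
type-I rate of the *test itself* is checked separately (2,000 uniform
days of n = 80 reject at 3.5–6.5 %).

A ward is **adequately powered** when its mean *or* median daily power
is ≥ 0.90 (the disjunction is deliberate and matches the stated rule).
Pooled two-day windows (day i−1 ∪ day i, labelled by the current day)
trade the assumption of a stable care process across consecutive days for
roughly doubled sample size.

Seeding: one master seed; each (ward, day) gets the substream
`SeedSequence([master, crc32(ward_id), day_index])`, so results are
independent of evaluation order and safely parallelizable.

## Ranking and the meta-regression

Wards are ranked by the proportion of computable days with p < α,
ties broken by median p; missing days are excluded from both keys and a
ward with no computable days ranks last with a warning. The
meta-regression fits OLS of −log10(p) on z(D), z(n) and their product.
Standardization uses the sample SD (n − 1 denominator) over all included
ward-days. Exact-zero p-values (possible under the bootstrap) are floored
at 1e-300 before the log, with a warning. Reported intervals are
classical OLS 95 % CIs, labelled as such. The marginal effect of one
predictor at a fixed value of the other is β_main + β_interaction × other;
an increase Δ of −log10(p) is reported as a 100·(1 − 10^−Δ) % p-value
reduction, rounded to one decimal only at the reporting layer.

## Concomitant-variable mixture

Model: K normal components with day-constant (μ_k, σ_k²) and day-varying
mixing probabilities through a multinomial logit on day indicators
(component 1 as reference, α_1 ≡ 0). Because the day-indicator design is
saturated, the logit M-step is closed-form — π_k on day d is the mean
responsibility of component k among day d's observations — which the test
suite verifies against a numerically maximized multinomial logit on small
instances. Days with zero observations contribute no indicator column and
have no defined π.

Numerical choices: variance floor σ² ≥ 1e-4 h² (tied minute data can
otherwise drive a component to a spike); relative log-likelihood tolerance
1e-6; max 500 iterations; the log-likelihood is asserted non-decreasing
(tolerance 1e-8 relative) at every step. Multi-start: the first start
places means at the ((k − 0.5)/K)-quantiles of the pooled timings, the
remaining starts draw Dirichlet(1) responsibilities and take one M-step;
default 5 starts, best final log-likelihood wins. A start whose minimum
component weight collapses below 1e-6·n is abandoned; all-starts failure
is fatal with diagnostics. Components are relabelled in increasing order
of mean after fitting, which makes summaries invariant to the arbitrary
EM labelling.

Selection: `ICL = −2 logL + ν log n + 2·entropy` with
`ν = 2K + (K − 1)·D` free parameters and
`entropy = −Σ_ij Σ_k ẑ_ijk log ẑ_ijk`; BIC is emitted alongside for
comparison. The ICL is stated as this package's definition (equivalent to
BIC exactly when classification is hard). Default search range K = 1..8;
the acceptance runs use K = 1..6, which brackets the generator's
five-component truth with margin on both sides.

Summaries: components with SD < 1 h (threshold configurable) are
*narrow*; when exactly four are narrow they map, in time order, to the
breakfast/lunch/dinner/bedtime slots, otherwise they are reported
unassigned with a flag. Wide components are background. Cross-ward tables
report median (min, max) of means and SDs per slot; probabilities are
day-averaged within ward before summarizing; wide components are pooled
into a single background column. Interval plots draw mean ± 1.96 SD per
component against the 8/12/18/22 h reference lines; where an interval
crosses its mealtime is reported as endpoints, with judgement left to the
reader — no crossing cut-off is imposed.

## Transition surveillance

For each consecutive-day window: flag a **transition** when the 2S-KS
p-value is significant and exactly one of the two 1S-KS p-values is;
direction is *to adherence* when the current day is the significant one.
Windows where both days are significantly non-uniform yet differ
significantly from each other are reported in a separate `shape_change`
category rather than dropped. Any window touching a missing p-value is
`unevaluable` and never flagged. Because the rule is built from α-level
tests, stray flags occur at roughly the α rate even under stable regimes;
the engineered-scenario tests therefore construct the non-adherent day as
the exact uniform quantiles (so its own test behaves deterministically)
and verify flags appear at exactly the engineered boundaries.

## Synthetic-data generator

The generator emulates adherent-ward structure with component means
7.23/11.38/17.18/21.94 h, SDs 0.28/0.34/0.25/0.26 h and a wide background
(mean 11.22 h, SD 5.94 h) — the published cross-ward median estimates.
The published probabilities (0.22/0.18/0.22/0.20, background 0.12) are
medians across wards and sum to 0.94, so they are renormalized onto the
simplex. Daily counts are discrete-uniform on [59, 103], the reported
range of median daily counts among adequately powered wards. Draws
outside [0, 24) are resampled, not clipped, avoiding boundary spikes at
the cost of slightly truncating the background component. Scenarios:
`adherent`, `uniform`, `mixed` (half the wards uniform), and an
engineered regime switch on a chosen day. An optional AR(1) perturbation
of the component logits exercises the day-varying mixture; by default π
is constant over days.

What the generator does **not** emulate: within-patient correlation of
successive timings, fasting/insulin-infusion monitoring cycles beyond the
single wide background, day-of-week structure, admission/discharge
census changes, and missing-data mechanisms other than empty days.
Passing tests therefore demonstrate correctness of the machinery under
the model's own assumptions, not robustness to these real-data features.

## Problem sizes used in the checks

Simulation-based checks run at study scale where that is cheap (61-day
wards at ~80 measurements/day for the mixture; 2,000 ward-days for the
type-I rate; 200 replicates of 671 ward-days for the meta-regression
coverage) and at reduced iteration counts for the power engine
(B = 300–2000 in tests versus the 5000 default), sizes at which the
Monte-Carlo error is already far below the asserted tolerances. The
meta-regression replication draws its noise SD from the published
R² (97.2 %): residual variance = signal variance × 0.028/0.972. Coverage
is asserted per coefficient (each 95 % CI covers its truth in ≥ 90 % of
replicates); the joint coverage of three ~independent 95 % intervals is
bounded near 0.857 and is reported, not asserted.

## Known limitations

- The asymptotic 2S-KS p-value is anticonservative under heavy ties; the
  bootstrap option mitigates but costs B two-sample tests per window.
- The mixture likelihood is multimodal; multi-start EM reduces but cannot
  eliminate the risk of a local optimum, and the saturated day-indicator
  logit spends (K − 1) parameters per day, so very sparse days estimate
  their π poorly.
- Ward specialty is plotting metadata only; no hierarchical pooling
  across wards is attempted.
- The pipeline assesses *timing* only: BG values, hypo-/hyperglycaemia
  and patient-level linkage are out of scope by design.
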