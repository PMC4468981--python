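# Methods

This note documents the models, the synthetic-data generator, the numerical
choices behind the Bayes-factor machinery, and the limits of what the test
suite demonstrates.

## Experimental designs

Four designs cross search type (singleton / conjunction) with difficulty.
Each session: 10 practice trials, then alternating 200-trial Neutral and
Bias blocks, starting and ending Neutral (7 blocks for `exp1a`/`exp2b`, 5
for `exp1b`/`exp2a`). Neutral blocks hold exactly 100 trials per color;
Bias blocks exactly 160 bias-color / 40 other-color trials. Set-size
designs (`exp2a`: 11/21 items, `exp2b`: 6/9) counterbalance set size
against color within block. Breaks every 125 trials; a break landing on a
block boundary is shifted one trial later so transitions stay
inconspicuous. Neutral blocks following a Bias block are partitioned into
sub-blocks I/II/III of 67/67/66 trials (largest-first is this package's
convention; only "66 or 67" is constrained by the procedure).

Sequence balance is achieved by constrained shuffling with rejection (up to
10,000 shuffles per block) rather than deterministic construction, so the
residual sequence randomness that short-term models feed on is preserved.
The accepted criterion is a repetition/switch imbalance of at most 5% of
classifiable trials per neutral block. Repetition labels use the
immediately preceding trial in presentation order (priming operates on what
was seen, not on what survives later exclusion). Response sides are 50/50
per block and independent of color — the procedure does not state whether
they were crossed with color, so independence is assumed.

## Episodic retrieval model

A deliberately standard instance-model instantiation (the drifting-context
variety used throughout the associative-memory literature), with every
constant exposed:

* context: `context_dim = 200` binary elements; each resamples uniformly
  with probability `drift_rate = 0.05` per trial, giving expected overlap
  `0.5 + 0.5*(1 - drift_rate)**k` with a snapshot `k` trials old;
* encoding: one trace per trial (color tag, context snapshot,
  `encode_strength = 1`);
* retrieval: deterministic expected activation
  `sum(strength * overlap * feature_weight)` with weights 1.0 (matching
  color) / 0.0 (non-matching);
* RT link: `rt_base - rt_gain * log(1 + activation)` with
  `rt_base = 600 ms`, `rt_gain = 30 ms`. The logarithm keeps RTs bounded
  and monotone in activation; only ordinal and persistence predictions are
  interpreted, so the link is a documented free choice rather than a fitted
  claim.

Retrieval is not sampled: the quantity of interest is expected
facilitation, and trial-level retrieval noise would only add variance that
the run-level Monte-Carlo already provides (one simulated run = one
synthetic observer). The implementation tracks per-trace context-match
counts incrementally — only elements that actually flip update the counts —
which is exactly equivalent to recomputing overlaps from stored snapshots
(tested) and makes 500-run simulations cheap.

Because traces accumulate without decay of number, a bias block leaves a
permanent 4:1 trace-count advantage; once context overlap has equilibrated
near 0.5 the advantage survives indefinitely, producing the persistent
sub-block-III color difference. Frequency monotonicity, recency, and exact
color-swap antisymmetry are tested properties.

## Feature-weighting model

The descriptive short-term account: facilitation
`sum_i A_i * exp(-lag/tau_i)` summed over past same-color trials, with at
most two exponential components; `RT = rt_base - facilitation`. Defaults
`A = 25 ms`, `tau = 2.5` trials, single component — a half-life of about
1.7 trials, consistent with benefits vanishing over roughly 5–8 trials.
Whether the original descriptive model used one or two components is not
determinable from the main text, so the component count is configuration.
The kernel is history-linear (exact) and equilibrates after any
composition change within `ceil(tau * ln(A/eps))` trials, which is why it
predicts a null sub-block-III difference.

## Synthetic behavior generator

The generator is the generative mirror of the analysis models. Per trial:

```
RT = grand_mean + participant_intercept - block_learning*(block-1)
     + C * [ apriori_offset   * (+-1/2 by color)
           + short_term       * (+-1/2 by repetition/switch)
           + long_term        * (+-1/2 by color, post-bias neutral only)
           + set_size_effect  * (+-1/2 by set size)
           + response_rep     * (+-1/2 by response repetition) ]
     + lognormal noise (zero mean, SD residual_sd, log-scale shape 0.4)
```

with `correct ~ Bernoulli(1 - error_rate)`; error trials draw RTs from the
same distribution (they are excluded downstream regardless). Each preset's
effect sizes, cohort size, error rate and awareness-score distribution are
the corresponding experiment's published values, with published null
findings encoded as true zeros (`long_term = 0` for both singleton-search
presets). Grand means, participant/residual SDs and block-learning slopes
are not published quantities; they are fixed at values typical for the two
task families (650–1250 ms means, ~100–180 ms participant SD, ~110–320 ms
residual SD, 12–35 ms learning per block) and are part of the preset, not
fitted.

**Calibration of the z-to-ms conversion.** Effects are specified in
standardized (zRT) units but injected in ms. Two systematic factors link
the scales: (i) injected effects themselves add variance to the z-scoring
cell (each balanced two-level effect of size `e*C` ms adds `(e*C)^2/4`);
(ii) the 2.5 SD outlier rule trims the long right tail of the lognormal
noise, shrinking the included-trial SD (factor `s_t ≈ 0.853` at shape 0.4)
more than it shrinks a small between-condition mean separation (factor
`slope ≈ 0.924`). The conversion factor therefore solves

```
C^2 * (slope^2 - sum_i e_i^2 / 4) = s_t^2 * residual_sd^2
```

with `slope` and `s_t` computed once by quadrature over the standardized
lognormal density. Validated at 120-participant scale, analysis-side
recovery is unbiased to about 1.5% (the small residue comes from the
outlier window being estimated on trials pooled across blocks, where the
learning trend widens it slightly). The lognormal shape 0.4 puts ~2.4% of
trials beyond the outlier bound, matching the 2–3% rates the exclusion
report should show.

What the generator does **not** emulate: participant-level heterogeneity of
priming effects (fixed slopes; random intercepts only), speed–accuracy
trade-offs, within-block practice beyond the linear block term, and any
sequential RT autocorrelation. Passing recovery tests therefore shows the
analysis chain is consistent with its own generative assumptions at the
published effect sizes and sample sizes — not that real data satisfy those
assumptions.

## Preprocessing

Order of operations (each per participant): practice removal, post-break
removal, error removal, then outlier removal with bounds `mean +- 2.5 SD`
computed over the participant's surviving neutral-block trials (the source
text does not fix this order or the outlier reference set; both choices are
documented here and in the API docstrings). Only neutral-block trials enter
analysis. z-scoring is per participant x block (the finest grain at which
the later correction is defined; cells with fewer than two trials raise an
explicit error). Color correction subtracts each participant's first-block
per-color deviation from the cell mean, in all blocks; it zeroes the
first-block color difference exactly and is idempotent. Quantile bins sort
by raw RT (ties broken by trial index), remainder trials to the earliest
bins. Within-subject interval half-widths use participant-mean centering,
the `sqrt(J/(J-1))` bias correction and a `t(0.975, n-1)` quantile.

A consequence of using inclusive group statistics for the 3 SD
participant-exclusion rule: a lone deviant among `n` participants can be at
most `(n-1)/sqrt(n)` group SDs out, so the rule cannot fire below n = 11.
At the actual cohort sizes (25–41) this is immaterial.

## Bayes-factor machinery

Linear mixed model `y = mu*1 + X*theta + eps` on standardized RTs, with
sum-to-zero-projected indicator blocks per term (interactions are products
of projected main-effect codings), `theta_t ~ N(0, sigma^2 g_t I)` per
term, `g_t ~ InverseGamma(1/2, r_t^2/2)` (i.e. scaled-Cauchy priors on
standardized effects) with `r = 0.5` for fixed terms and `r = 1.0` for the
participant factor, and Jeffreys `1/sigma^2` on `(mu, sigma^2)`.

Conditional on g the marginal likelihood is closed-form; the determinant
and quadratic forms are evaluated in p x p space via the Woodbury identity
from precomputed `X'X`, `X'y`, `X'1`, so each evaluation is O(p^3) with p
around 30–50. The low-dimensional g integral uses importance sampling: the
integrand's mode in log-g space is found by Nelder–Mead, a finite-difference
Laplace covariance (inflated 1.4x) defines a multivariate-t (df 7)
proposal, and the Monte-Carlo SE of each log marginal is reported. All
model comparisons share the intercept-only null, making log BFs exactly
transitive. Degenerate designs (aliased terms) are rejected with the
offending rank deficit named. BFs larger than e^20 are meaningful only in
log space; "BF > 1000" claims are asserted as `log_bf > log(1000)`.

Effect posteriors resample g from the importance draws, then draw
`sigma^2 | g, y` (inverse-gamma) and `(mu, theta) | sigma^2, g, y`
(Gaussian) exactly, grouping repeated g values to share factorizations.
Reported contrasts are differences of condition-level effects (switch minus
repetition, other minus bias, high minus low set size), positive when the
expected facilitation holds, in zRT units — the same scale the analysis
models operate on.

The one-sample t-test BF integrates the noncentral-t likelihood against a
Cauchy(0, sqrt(2)/2) prior on the standardized effect (truncated for the
one-sided version); the regression BF uses the JZS R^2 formula with
`r = sqrt(2)/4`, integrated in log-g space for stability near R^2 = 1. Both
are 1-D quadratures; the test suite checks the t-test against the
independent g-space representation and the ANOVA machinery against dense
n x n quadrature on toy problems.

The sequential rule recomputes the model set after each participant batch
and stops when one of M2/M3/M4 beats M1 with BF > 10 *and* the winning
model attributes the long-term effect to the bias color (posterior target
contrast positive), or when M1 beats all alternatives at the same
threshold; an exhausted stream is inconclusive.

Prior scales are the defaults of the default-prior ANOVA literature; the
source analyses cite that literature without printing scale values, so the
defaults are an explicit assumption here, exposed in `PriorScales`.

Accuracy analyses reuse the same machinery on participant x condition
proportions (linear on proportions — the original implementation detail is
unstated; trial-level binomial models are out of scope).

## Problem sizes and reproducibility

Headline runs use the published cohort sizes (31/26/41/25 participants,
1000–1400 trials each) with 10^4 posterior samples per fit; model-contrast
simulations use 500 runs per model; the test suite uses reduced versions
(25–100 runs, 10^3–2*10^4 importance samples) chosen to keep the full
suite in the minutes range while leaving every Monte-Carlo tolerance
enforced through the reported SEs. Every entry point takes a seed;
per-stage streams are spawned from `numpy.random.SeedSequence` so cohort
generation, trial sequences and posterior sampling are independently
reproducible. Deterministic stages rerun bit-for-bit; stochastic stages
rerun within their reported Monte-Carlo error.

## Known limitations

* The episodic model is this package's instantiation of the instance-based
  account; the original simulation's exact equations (e.g. whether
  distractor or response features were encoded) are in online-only
  supplementary material and are not claimed to be reproduced. Only the
  qualitative persistence prediction is treated as anchored.
* Parameter recovery at a single cohort has irreducible estimator spread
  (~0.02–0.035 zRT at the published sample sizes, the first-block color
  correction contributing about half for the long-term contrast), so
  single-seed recovered values scatter around the preset truth with that SD.
* The mixed models assume exchangeable trials within participant; the
  generator honors this, real RT series do not (autocorrelation, fatigue).
* Accuracy models on proportions ignore binomial heteroscedasticity.
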