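# searchprime

Generative models, synthetic cohorts and default-prior Bayes-factor analysis
for **long- and short-term intertrial priming in visual search**.

## The scientific problem

When the target color of a visual search repeats from one trial to the next,
responses are faster — *intertrial priming*. Two families of accounts explain
it:

* **Feature weighting** — processing a target transiently raises the
  attentional weight of its features; the benefit decays within ~5–8 trials.
* **Episodic retrieval** — every trial is stored as a memory trace bound to a
  slowly drifting temporal context; retrieval of color-matching traces
  facilitates the current trial.

The accounts disagree about what happens after a *bias block* in which one
color is the target on 80% of trials. Instance-based memory accumulates more
traces for the frequent color, so an episodic model predicts a **long-term
priming** advantage for the biased color that persists throughout a
subsequent 200-trial neutral (50/50) block. A pure decay kernel predicts
**no difference** between colors once the bias is gone. This package
implements both models, the four experimental designs that test the
prediction (singleton vs. conjunction search, easy vs. hard), a synthetic
behavior generator whose presets encode the published effect sizes as
generative ground truth, the RT preprocessing chain, and the Bayesian
model-comparison machinery.

## Models and analysis in brief

* **Episodic model** (`searchprime.sam`): binary context vector of dimension
  `d`, each element resampling with probability `rho` per trial, so overlap
  with a snapshot taken `k` trials ago decays as `0.5 + 0.5*(1-rho)**k`.
  Activation for a color is `sum(strength * overlap * feature_weight)` over
  stored traces; `RT = rt_base - rt_gain * log(1 + activation)`.
* **Feature-weighting model** (`searchprime.stf`): facilitation kernel
  `sum_i A_i * exp(-lag/tau_i)` over same-color trials (one or two
  components); `RT = rt_base - facilitation`.
* **Preprocessing** (`searchprime.preprocess`): exclude participants
  (>15% errors, mean RT >3 group SD), trials (post-break, errors, RT outliers
  beyond 2.5 SD), z-score RT per participant x block
  (`zRT = (RT - M)/SD`), and subtract each participant's first-block
  per-color zRT deviation from all blocks (color correction).
* **Inference** (`searchprime.bayes`): JZS default-prior Bayes factors for
  the mixed model set M1 (repetition type), M2 (+ target type), M3
  (+ target x sub-block), M4 (both), each with a participant random factor;
  Cauchy prior scales r = 0.5 (fixed) / 1.0 (random); marginal likelihoods by
  closed form conditional on the variance-scale parameters g and adaptive
  importance sampling over g, with Monte-Carlo SEs reported. One-sided
  t-test and regression BFs by direct quadrature; sequential BF > 10
  stopping rule with a sign check on the long-term contrast.

## Worked example

Contrast the two models' predictions on the 5-block conjunction-search
design (neutral–bias–neutral–bias–neutral):

```bash
searchprime contrast --experiment exp1b --runs 100 --seed 1 --out contrast.json
```

prints

```
sam: sub-block III color difference 13.48 ms (SE 0.11)
stf: sub-block III color difference 0.32 ms (SE 0.37)
```

The statistic is the mean RT difference (other minus biased color) in the
final third of post-bias neutral blocks. The episodic model keeps a ~13 ms
advantage for the previously biased color 130+ trials after the bias ended;
the decay-kernel model is indistinguishable from zero — the dissociation
the experimental designs were built to test.

A full synthetic-cohort analysis (generation, preprocessing, model
comparison, effect posteriors, awareness tests):

```bash
searchprime analyze --experiment exp1b --seed 11 --generator-seed 2 \
    --samples 10000 --out results.json
```

reports `best model: M2` — the model with a persistent target-type (long-term
priming) effect — with posterior contrasts near the preset's injected values
(repetition 0.176, target 0.219 zRT units on this cohort, against injected
0.20 and 0.16) and a one-sided t-test BF
strongly supporting above-zero bias awareness that nevertheless does not
predict the effect (regression BF favoring the null).

Library use mirrors the CLI:

```python
from searchprime import behavior, preprocess, bayes

cohort, awareness = behavior.generate_cohort(behavior.get_preset("exp1b"), seed=2)
corrected, report = preprocess.preprocess_cohort(cohort)
data = bayes.analysis_table(corrected)
models = bayes.model_set("exp1b")
bf = bayes.anova_bf(data, models["M2"], models["M1"], seed=11)
post = bayes.effect_posterior(data, models["M2"], "target", seed=11)
```

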