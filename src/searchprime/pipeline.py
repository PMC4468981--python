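"""End-to-end runs: the two-model prediction contrast and the full
synthetic-cohort analysis bundle.

Every output dictionary records the configuration and seeds that produced
it, so deterministic stages rerun bit-for-bit and Monte-Carlo stages rerun
statistically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import bayes, behavior, preprocess, sam, stf
from .design import BIAS, ExperimentDesign, build_design, generate_trial_sequence
from .sam import SamParams
from .stf import KernelParams

__all__ = ["RunConfig", "run_model_contrast", "run_full_analysis",
           "persistence_statistic", "simulate_model_runs", "recover_effects"]


@dataclass
class RunConfig:
    experiment_id: str = "exp1b"
    seed_design: int = 1
    seed_generator: int = 2
    seed_mcmc: int = 11
    n_runs: int = 500  # model-contrast simulation runs
    n_samples: int = bayes.DEFAULT_SAMPLES  # importance/MCMC samples
    preset_overrides: dict = field(default_factory=dict)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stamp(self) -> dict:
        return {"config": asdict(self), "config_hash": self.digest()}


def simulate_model_runs(model: str, design: ExperimentDesign, n_runs: int,
                        seed, sam_params: SamParams | None = None,
                        stf_params: KernelParams | None = None) -> pd.DataFrame:
    """Simulate ``n_runs`` synthetic observers of one model on fresh
    sequences; returns a long table (run, trial, block, target_type,
    sub_block, rt)."""
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    frames = []
    for run, child in enumerate(root.spawn(n_runs)):
        seq_ss, model_ss = child.spawn(2)
        plans = generate_trial_sequence(design, seq_ss)
        if model == "sam":
            rts = sam.simulate_session(plans, sam_params or SamParams(), model_ss)
        elif model == "stf":
            rts = stf.simulate_session(plans, stf_params or KernelParams(), model_ss)
        else:
            raise ValueError(f"unknown model {model!r}")
        frames.append(pd.DataFrame({
            "run": run,
            "trial": [t.trial_index for t in plans],
            "block": [t.block_index for t in plans],
            "target_type": [t.target_type for t in plans],
            "sub_block": [t.sub_block for t in plans],
            "practice": [t.practice for t in plans],
            "rt": rts,
        }))
    return pd.concat(frames, ignore_index=True)


def persistence_statistic(runs: pd.DataFrame) -> dict:
    """Sub-block-III color difference (other minus bias RT, ms): the
    long-term persistence statistic, with its SE over runs."""
    sub3 = runs[runs["sub_block"] == "III"]
    per_run = (sub3.groupby(["run", "target_type"])["rt"].mean().unstack())
    diff = per_run["other_color"] - per_run[BIAS]
    return {"mean": float(diff.mean()),
            "se": float(diff.std(ddof=1) / np.sqrt(len(diff))),
            "n_runs": int(len(diff))}


def run_model_contrast(config: RunConfig,
                       sam_params: SamParams | None = None,
                       stf_params: KernelParams | None = None) -> dict:
    """Contrast the episodic-retrieval and feature-weighting predictions on
    identical designs: per-block per-color mean facilitation plus the
    persistence statistic for each model."""
    design = build_design(config.experiment_id)
    out = {"experiment": config.experiment_id, **config.stamp(), "models": {}}
    for tag, model in enumerate(("sam", "stf")):
        runs = simulate_model_runs(model, design, config.n_runs,
                                   np.random.SeedSequence([config.seed_design, tag]),
                                   sam_params, stf_params)
        session = runs[~runs["practice"]]
        table = (session.groupby(["block", "target_type"])["rt"]
                 .mean().unstack().round(3))
        out["models"][model] = {
            "block_color_means": table.to_dict(),
            "persistence": persistence_statistic(session),
        }
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Generate a cohort, preprocess it, and run the complete analysis:
    model comparison, effect posteriors, awareness tests, quantile-bin
    regression, and (for set-size designs) search slopes."""
    exp = config.experiment_id
    preset = behavior.get_preset(exp, **config.preset_overrides)
    design = build_design(exp)
    cohort, awareness = behavior.generate_cohort(preset, config.seed_generator,
                                                 design=design)
    corrected, report = preprocess.preprocess_cohort(cohort)
    sub = bayes.analysis_table(corrected)
    models = bayes.model_set(exp)
    seeds = np.random.SeedSequence(config.seed_mcmc).spawn(12)

    lm = {}
    for i, name in enumerate(["Mnull", "M1", "M2", "M3", "M4"]):
        lm[name], se, _ = bayes.log_marginal(sub, models[name],
                                             n_samples=config.n_samples,
                                             seed=seeds[i])
    bf_table = {f"{a},{b}": float(lm[a] - lm[b])
                for a in lm for b in lm if a != b}
    best = max(["M1", "M2", "M3", "M4"], key=lm.get)

    posts = {}
    for contrast in ("repetition", "target"):
        posts[contrast] = asdict(bayes.effect_posterior(
            sub, models["M2"], contrast, n_samples=config.n_samples,
            seed=seeds[5]))
    if exp in ("exp2a", "exp2b"):
        posts["set_size"] = asdict(bayes.effect_posterior(
            sub, models["M2"], "set_size", n_samples=config.n_samples,
            seed=seeds[6]))

    # awareness: one-sided t-test on the scores; regression of the realized
    # long-term effect on the scores
    ttest = bayes.ttest_bf_onesided(awareness["score"])
    effect_by_p = (sub.groupby(["participant", "target_type"])["zrt_corrected"]
                   .mean().unstack())
    lt_effect = (effect_by_p["other_color"] - effect_by_p[BIAS])
    merged = awareness.set_index("participant").join(lt_effect.rename("effect"))
    reg = bayes.regression_bf(merged["score"], merged["effect"])

    # RT-quantile analysis of the long-term effect
    bins = pd.concat([preprocess.quantile_bins(grp)
                      for _, grp in sub.groupby("participant")],
                     ignore_index=True)
    bin_means = bins.groupby("bin_index").agg(mean_rt=("mean_rt", "mean"),
                                              effect=("effect", "mean"))
    qreg = bayes.regression_bf(bin_means["mean_rt"], bin_means["effect"]) \
        if len(bin_means) >= 4 else None

    bundle = {
        "experiment": exp, **config.stamp(),
        "exclusions": report,
        "log_marginals": {k: float(v) for k, v in lm.items()},
        "bf_table": bf_table,
        "best_model": best,
        "posteriors": posts,
        "awareness_ttest": ttest,
        "awareness_regression": {"log_bf": reg.log_bf},
        "quantile_regression": ({"log_bf": qreg.log_bf} if qreg else None),
    }
    if design.set_sizes:
        slopes = {int(p): preprocess.search_slope(grp)
                  for p, grp in cohort[~cohort["practice"]].groupby("participant")}
        bundle["search_slopes_ms_per_item"] = {
            "mean": float(np.mean(list(slopes.values()))),
            "n_serial": int(sum(v >= 10.0 for v in slopes.values())),
        }
    return bundle


#: recovery plan: experiment, generator/mcmc seed tags, model fitted, and the
#: contrasts whose posterior means are compared against the preset truth
_RECOVERY_PLAN = (
    ("exp1b", 2, 11, "M2", (("target", "exp1b_long_term"),
                            ("repetition", "exp1b_short_term"))),
    ("exp1a", 3, 12, "M1", (("repetition", "exp1a_short_term"),)),
    ("exp2b", 4, 13, "M2", (("set_size", "exp2b_set_size"),)),
)


def recover_effects(seed: int = 1, n_samples: int = bayes.DEFAULT_SAMPLES) -> dict:
    """Parameter-recovery runs: generate each experiment's preset cohort,
    preprocess it, fit the standard model, and report the posterior means of
    the injected contrasts (standardized zRT units).

    ``seed`` drives every stage; per-stage streams are spawned from
    ``SeedSequence([seed, stage_tag])`` so cohorts and samplers are
    independent but fully reproducible.
    """
    out = {}
    for exp, gen_tag, mcmc_tag, model_name, contrasts in _RECOVERY_PLAN:
        preset = behavior.get_preset(exp)
        cohort, _ = behavior.generate_cohort(
            preset, np.random.SeedSequence([seed, gen_tag]))
        corrected, _ = preprocess.preprocess_cohort(cohort)
        sub = bayes.analysis_table(corrected)
        models = bayes.model_set(exp)
        n_p = int(sub["participant"].nunique())
        for i, (contrast, name) in enumerate(contrasts):
            post = bayes.effect_posterior(
                sub, models[model_name], contrast, n_samples=n_samples,
                seed=np.random.SeedSequence([seed, mcmc_tag, i]))
            out[name] = {"value": float(post.mean), "n": n_p,
                         "ci_low": float(post.ci_low),
                         "ci_high": float(post.ci_high)}
    return out
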