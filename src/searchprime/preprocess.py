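"""RT preprocessing: exclusion rules, per-block standardization, first-block
color correction, and the derived summaries used by the analyses.

Pipeline order (each step applied per participant):

1. participant exclusion — error rate over 15% of all non-practice trials,
   then mean RT more than 3 group SDs from the group mean (group statistics
   computed after the error-rate step);
2. trial exclusion — practice trials, trials immediately following a break,
   error trials, then RT outliers more than 2.5 SD from the participant's
   mean (mean/SD over neutral-block trials surviving the earlier steps;
   only neutral-block trials enter the analyses);
3. z-standardization of RT within each participant x block cell;
4. color correction — each participant's first (neutral) block provides the
   a-priori per-color deviation of zRT from the cell mean, which is
   subtracted from that color's zRTs in *all* blocks, so any color
   difference surviving in later blocks is attributable to the bias
   manipulation.

All functions operate on the tidy trial tables produced by
:mod:`searchprime.behavior` and return copies; nothing mutates its input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .design import BIAS, OTHER

__all__ = [
    "exclude_participants", "exclude_trials", "zscore_per_block",
    "color_correct", "inverse_z_for_plot", "quantile_bins", "search_slope",
    "cousineau_morey_ci", "preprocess_cohort", "PreprocessError",
]

ERROR_RATE_CUTOFF = 0.15
GROUP_RT_SD_CUTOFF = 3.0
OUTLIER_SD_CUTOFF = 2.5


class PreprocessError(RuntimeError):
    pass


def exclude_participants(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop participants by error rate, then by deviant mean RT.

    Returns the kept cohort and a report dict listing removals with reasons.
    """
    if cohort["participant"].nunique() < 2:
        raise PreprocessError("need at least 2 participants")
    data = cohort[~cohort["practice"]]
    removals = []

    err = 1.0 - data.groupby("participant")["correct"].mean()
    bad_err = err[err > ERROR_RATE_CUTOFF].index.tolist()
    for p in bad_err:
        removals.append({"participant": int(p), "reason": "error_rate",
                         "value": float(err[p])})

    data = data[~data["participant"].isin(bad_err)]
    means = data.groupby("participant")["rt"].mean()
    z = (means - means.mean()) / means.std(ddof=1)
    bad_rt = z[z.abs() > GROUP_RT_SD_CUTOFF].index.tolist()
    for p in bad_rt:
        removals.append({"participant": int(p), "reason": "mean_rt",
                         "value": float(z[p])})

    bad = set(bad_err) | set(bad_rt)
    kept = cohort[~cohort["participant"].isin(bad)].copy()
    if kept.empty:
        raise PreprocessError("all participants removed")
    report = {"removed": removals,
              "n_removed": len(bad),
              "n_kept": int(kept["participant"].nunique())}
    return kept, report


def exclude_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Flag excluded trials of a single participant (or a whole cohort).

    Exclusion order: practice -> post-break -> errors -> outliers.  Outlier
    bounds use each participant's mean/SD of *neutral-block* trials that
    survived the earlier steps.  Bias-block trials are flagged with the same
    rules but only neutral-block trials enter analysis downstream.
    """
    out = trials.copy()
    out["excluded"] = False
    out["exclusion_reason"] = ""

    def flag(mask, reason):
        new = mask & ~out["excluded"]
        out.loc[new, "excluded"] = True
        out.loc[new, "exclusion_reason"] = reason

    flag(out["practice"].astype(bool), "practice")
    flag(out["post_break"].astype(bool), "post_break")
    flag(~out["correct"].astype(bool), "error")

    for p, grp in out.groupby("participant"):
        base = grp[~grp["excluded"] & (grp["block_kind"] == "neutral")]
        if len(base) < 2:
            continue
        m, sd = base["rt"].mean(), base["rt"].std(ddof=1)
        lo, hi = m - OUTLIER_SD_CUTOFF * sd, m + OUTLIER_SD_CUTOFF * sd
        outlier = (~grp["excluded"]) & ((grp["rt"] < lo) | (grp["rt"] > hi))
        out.loc[outlier[outlier].index, "excluded"] = True
        out.loc[outlier[outlier].index, "exclusion_reason"] = "outlier"
    return out


def zscore_per_block(trials: pd.DataFrame) -> pd.DataFrame:
    """zRT = (RT - M) / SD within each participant x block cell.

    Operates on included trials only; a cell with fewer than 2 included
    trials is an error (its SD is undefined).
    """
    data = trials[~trials["excluded"]].copy()
    stats_ = data.groupby(["participant", "block"])["rt"].agg(["mean", "std", "count"])
    bad = stats_[stats_["count"] < 2]
    if len(bad):
        p, b = bad.index[0]
        raise PreprocessError(
            f"participant {p}, block {b}: fewer than 2 included trials")
    g = data.groupby(["participant", "block"])["rt"]
    data["zrt"] = (data["rt"] - g.transform("mean")) / g.transform(lambda s: s.std(ddof=1))
    return data


def color_correct(zscored: pd.DataFrame, first_block: int = 1) -> pd.DataFrame:
    """Subtract each participant's first-block per-color zRT deviation.

    After correction the participant's first-block color difference is zero
    by construction; the correction is idempotent.
    """
    out = zscored.copy()
    out["zrt_corrected"] = out["zrt"].astype(float)
    for p, grp in out.groupby("participant"):
        fb = grp[grp["block"] == first_block]
        if fb.empty:
            raise PreprocessError(f"participant {p}: first block missing")
        cell_mean = fb["zrt"].mean()
        for color in (BIAS, OTHER):
            sel = fb[fb["target_type"] == color]
            if sel.empty:
                raise PreprocessError(
                    f"participant {p}: color {color} absent from first block")
            d = sel["zrt"].mean() - cell_mean
            idx = grp[grp["target_type"] == color].index
            out.loc[idx, "zrt_corrected"] = out.loc[idx, "zrt_corrected"] - d
    return out


def inverse_z_for_plot(corrected: pd.DataFrame,
                       column: str = "zrt_corrected") -> pd.Series:
    """Map standardized values back to ms via each block's mean and SD."""
    g = corrected.groupby(["participant", "block"])["rt"]
    mean = g.transform("mean")
    sd = g.transform(lambda s: s.std(ddof=1))
    return corrected[column] * sd + mean


def quantile_bins(trials: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Split one participant's post-bias neutral trials into ``k`` RT bins.

    Trials are sorted by raw RT (ties broken by trial index) and partitioned
    into near-equal consecutive groups, remainder to the earliest bins.
    Returns one row per bin: mean RT and the bias-minus-other corrected-zRT
    effect (other minus bias, positive = bias color faster).
    """
    if len(trials) < k:
        raise PreprocessError(f"need at least {k} trials for {k} bins")
    srt = trials.sort_values(["rt", "trial"], kind="mergesort")
    n = len(srt)
    base, rem = divmod(n, k)
    sizes = [base + (1 if i < rem else 0) for i in range(k)]
    rows, start = [], 0
    for i, size in enumerate(sizes):
        binned = srt.iloc[start:start + size]
        start += size
        is_bias = binned["target_type"] == BIAS
        effect = (binned.loc[~is_bias, "zrt_corrected"].mean()
                  - binned.loc[is_bias, "zrt_corrected"].mean())
        rows.append({
            "participant": binned["participant"].iloc[0],
            "bin_index": i + 1,
            "mean_rt": float(binned["rt"].mean()),
            "effect": float(effect),
        })
    return pd.DataFrame(rows)


def search_slope(trials: pd.DataFrame) -> float:
    """Search slope in ms per display item for one participant."""
    sizes = sorted(pd.unique(trials["set_size"].dropna()))
    if len(sizes) != 2:
        raise PreprocessError("search slope needs exactly two set sizes")
    lo, hi = sizes
    m = trials.groupby("set_size")["rt"].mean()
    return float((m[hi] - m[lo]) / (hi - lo))


def cousineau_morey_ci(cell_means: pd.DataFrame, confidence: float = 0.95
                       ) -> pd.Series:
    """95% within-subject CI half-widths per condition.

    ``cell_means`` is a participants x conditions table of condition means.
    Participant means are removed, the grand mean restored, per-condition
    SEs computed, and the Morey bias correction ``sqrt(J/(J-1))`` applied
    with a t(0.975, n-1) quantile.
    """
    n, j = cell_means.shape
    if n < 2 or j < 2:
        raise PreprocessError("need >= 2 participants and >= 2 conditions")
    centered = cell_means.sub(cell_means.mean(axis=1), axis=0) + cell_means.values.mean()
    se = centered.std(ddof=1) / np.sqrt(n)
    correction = np.sqrt(j / (j - 1))
    tq = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
    return se * correction * tq


def preprocess_cohort(cohort: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Full pipeline: participant exclusion, trial exclusion, z-scoring
    (neutral blocks), color correction.  Returns the analysis-ready table of
    included neutral-block trials and an exclusion report."""
    kept, report = exclude_participants(cohort)
    flagged = exclude_trials(kept)
    neutral = flagged[flagged["block_kind"] == "neutral"].copy()
    non_practice = flagged[~flagged["practice"]]
    report["trial_exclusions"] = (
        non_practice[non_practice["block_kind"] == "neutral"]
        .groupby("exclusion_reason").size().drop(labels="", errors="ignore")
        .to_dict())
    report["pct_neutral_excluded"] = float(
        100.0 * neutral["excluded"].mean())
    z = zscore_per_block(neutral)
    corrected = color_correct(z)
    return corrected, report
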