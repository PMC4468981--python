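"""Synthetic per-participant behavior: RT and accuracy tables plus
bias-awareness scores, with the exact effect structure the analysis models
assume.

The generator is the generative mirror of the analysis: it injects, on the
millisecond scale, participant random intercepts, a linear per-block
learning trend, an innate per-participant color offset, a short-term
repetition benefit, a long-term bias-color benefit confined to post-bias
neutral blocks, a set-size cost (where the design has one), a response-
repetition benefit, right-skewed lognormal residual noise, and Bernoulli
errors.  Effects are specified in standardized (zRT) units, as the analysis
reports them; the preset for each experiment encodes that experiment's
published posterior effect sizes as generative ground truth (with the null
findings encoded as true zeros), so analysis-side estimates can be tested
for parameter recovery.

z-to-ms conversion
------------------
Per-block z-scoring divides by the realized within-block SD of *included*
trials, which (a) includes the variance the injected effects themselves add
and (b) excludes the outlier-trimmed tail of the noise.  A z-effect ``e``
is therefore injected as ``e * C`` ms with ``C`` calibrated against both —
see :func:`z_to_ms_factor` — so the analysis recovers ``e`` in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .design import (BIAS, REP, ExperimentDesign, build_design,
                     generate_trial_sequence, trials_to_frame)

__all__ = ["GeneratorPreset", "PRESETS", "get_preset", "generate_participant",
           "generate_cohort", "z_to_ms_factor"]

#: shape (sigma) of the lognormal residual on the log scale; fixed so that
#: roughly 2-3% of trials exceed the 2.5 SD outlier bound, as observed
LOGNORMAL_SHAPE = 0.4


@dataclass(frozen=True)
class GeneratorPreset:
    """Full parameter vector of the synthetic RT model for one experiment."""

    experiment_id: str
    n_participants: int
    grand_mean_rt: float  # ms
    participant_sd: float = 100.0  # ms, random intercept SD
    residual_sd: float = 150.0  # ms, SD of the lognormal trial noise
    block_learning: float = 12.0  # ms RT decrement per block
    apriori_color_offset_sd: float = 0.10  # z-units, per-participant innate offset
    short_term_effect: float = 0.0  # z, repetition vs switch
    long_term_effect: float = 0.0  # z, bias vs other in post-bias neutral blocks
    set_size_effect: float = 0.0  # z, low vs high distractor count
    response_rep_effect: float = 0.0  # z
    error_rate: float = 0.03
    awareness_mean: float = 0.0  # on [-1, 1]
    awareness_sd: float = 0.1

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.participant_sd <= 0 or self.residual_sd <= 0:
            raise ValueError("SDs must be positive")


#: one preset per experiment; effect sizes and cohort sizes are the
#: published values for that experiment (zeros encode published null results)
PRESETS: dict[str, GeneratorPreset] = {
    "exp1a": GeneratorPreset(
        experiment_id="exp1a", n_participants=31, grand_mean_rt=650.0,
        residual_sd=110.0, short_term_effect=0.44, long_term_effect=0.0,
        response_rep_effect=0.0, error_rate=0.043,
        awareness_mean=0.09, awareness_sd=0.15,
    ),
    "exp1b": GeneratorPreset(
        experiment_id="exp1b", n_participants=26, grand_mean_rt=1250.0,
        residual_sd=320.0, participant_sd=180.0, block_learning=35.0,
        short_term_effect=0.20, long_term_effect=0.16,
        response_rep_effect=0.056, error_rate=0.029,
        awareness_mean=0.12, awareness_sd=0.10,
    ),
    "exp2a": GeneratorPreset(
        experiment_id="exp2a", n_participants=41, grand_mean_rt=1100.0,
        residual_sd=300.0, participant_sd=160.0, block_learning=30.0,
        short_term_effect=0.30, long_term_effect=0.0, set_size_effect=0.13,
        response_rep_effect=0.05, error_rate=0.046,
        awareness_mean=0.03, awareness_sd=0.18,
    ),
    "exp2b": GeneratorPreset(
        experiment_id="exp2b", n_participants=25, grand_mean_rt=1050.0,
        residual_sd=280.0, participant_sd=150.0, block_learning=28.0,
        short_term_effect=0.31, long_term_effect=0.09, set_size_effect=0.37,
        response_rep_effect=0.10, error_rate=0.033,
        awareness_mean=0.14, awareness_sd=0.11,
    ),
}


def get_preset(experiment_id: str, **overrides) -> GeneratorPreset:
    preset = PRESETS[experiment_id]
    return replace(preset, **overrides) if overrides else preset


def _trimmed_noise_response(shape: float = LOGNORMAL_SHAPE,
                            cut: float = 2.5) -> tuple[float, float]:
    """Response of the trimmed noise distribution to a small mean shift.

    The analysis discards trials beyond ``cut`` SDs of the cell mean, which
    (a) shrinks a small between-condition mean separation by a factor
    ``slope`` (the long right tail of the slower condition is cut harder)
    and (b) shrinks the within-cell noise SD by a factor ``s_t``.  Both are
    computed by quadrature over the standardized lognormal noise density.
    """
    z = np.linspace(-9.0, 9.0, 8001)
    w = np.exp(-z ** 2 / 2.0)
    w /= w.sum()
    m1 = np.exp(shape ** 2 / 2.0)
    s1 = np.sqrt((np.exp(shape ** 2) - 1.0) * np.exp(shape ** 2))
    x = (np.exp(shape * z) - m1) / s1  # mean 0, SD 1

    def trimmed_mean(mu):
        keep = np.abs(x + mu) < cut
        return float(np.sum((x[keep] + mu) * w[keep]) / np.sum(w[keep]))

    h = 0.05
    slope = (trimmed_mean(h) - trimmed_mean(-h)) / (2.0 * h)
    keep = np.abs(x) < cut
    wk = w[keep] / np.sum(w[keep])
    mt = np.sum(x[keep] * wk)
    s_t = float(np.sqrt(np.sum((x[keep] - mt) ** 2 * wk)))
    return slope, s_t


_TRIM_SLOPE, _TRIM_SD = _trimmed_noise_response()


def z_to_ms_factor(preset: GeneratorPreset) -> float:
    """Milliseconds per z-unit, from the preset's residual structure.

    Chosen so that the *analysis-side* standardized contrast — computed on
    included trials after outlier trimming and per-block z-scoring —
    recovers the preset z effect in expectation:

        e * C * slope = sqrt(s_t**2 * residual_sd**2 + C**2 * sum(e_i**2)/4)
                        * e

    where ``slope``/``s_t`` are the trimmed-noise response factors and each
    balanced two-level effect contributes ``(e_i*C)**2 / 4`` of (untrimmed)
    variance to the z-scoring cell.
    """
    e2 = (preset.short_term_effect ** 2 + preset.long_term_effect ** 2
          + preset.set_size_effect ** 2 + preset.response_rep_effect ** 2
          + preset.apriori_color_offset_sd ** 2)
    denom = _TRIM_SLOPE ** 2 - e2 / 4.0
    if denom <= 0:
        raise ValueError("effect variance too large for calibrated conversion")
    return preset.residual_sd * _TRIM_SD / np.sqrt(denom)


def _lognormal_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Zero-mean, right-skewed noise with SD ``sd`` ms."""
    s = LOGNORMAL_SHAPE
    raw = np.exp(s * rng.standard_normal(n))
    m1 = np.exp(s ** 2 / 2.0)
    s1 = np.sqrt((np.exp(s ** 2) - 1.0) * np.exp(s ** 2))
    return sd * (raw - m1) / s1


def generate_participant(design: ExperimentDesign, preset: GeneratorPreset,
                         participant_id: int, seed) -> pd.DataFrame:
    """Simulate one participant's session as a trial table.

    ``seed`` may be anything :func:`numpy.random.default_rng` accepts; the
    trial sequence and the behavioral noise use independent child streams so
    the sequence depends only on (seed,).
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    seq_ss, beh_ss = ss.spawn(2)
    trials = generate_trial_sequence(design, seq_ss)
    rng = np.random.default_rng(beh_ss)

    df = trials_to_frame(trials, design, participant=participant_id)
    n = len(df)
    C = z_to_ms_factor(preset)
    intercept = rng.normal(0.0, preset.participant_sd)
    apriori = rng.normal(0.0, preset.apriori_color_offset_sd)  # z-units

    block = df["block"].to_numpy()
    bias = (df["target_type"] == BIAS).to_numpy()
    rep = (df["repetition_type"] == REP).to_numpy()
    rep_def = (df["repetition_type"] != "undefined").to_numpy()
    rrep = (df["response_repetition"] == REP).to_numpy()
    rrep_def = (df["response_repetition"] != "undefined").to_numpy()

    post_bias_neutral = _post_bias_neutral_mask(df, design)

    signed = lambda flag: np.where(flag, -0.5, 0.5)  # flagged level is faster
    rt = (preset.grand_mean_rt + intercept
          - preset.block_learning * np.maximum(block - 1, 0)
          + C * apriori * signed(~bias)  # sign: apriori>0 -> bias color faster
          + C * preset.short_term_effect * np.where(rep_def, signed(rep), 0.0)
          + C * preset.long_term_effect * np.where(post_bias_neutral, signed(bias), 0.0)
          + C * preset.response_rep_effect * np.where(rrep_def, signed(rrep), 0.0))
    if preset.set_size_effect and design.set_sizes:
        low = (df["set_size"] == min(design.set_sizes)).to_numpy()
        rt = rt + C * preset.set_size_effect * signed(low)
    rt = rt + _lognormal_noise(rng, n, preset.residual_sd)

    df["rt"] = np.maximum(rt, 1.0)  # RTs are strictly positive
    df["correct"] = rng.random(n) >= preset.error_rate
    df["excluded"] = False
    df["exclusion_reason"] = ""
    return df


def _post_bias_neutral_mask(df: pd.DataFrame, design: ExperimentDesign) -> np.ndarray:
    kinds = {b.index: b.kind for b in design.blocks}
    post = set()
    prev_kind = None
    for b in design.blocks:
        if b.kind == "neutral" and prev_kind == "bias":
            post.add(b.index)
        prev_kind = b.kind
    return df["block"].isin(post).to_numpy() & (df["block_kind"] == "neutral").to_numpy()


def generate_cohort(preset: GeneratorPreset, seed,
                    design: ExperimentDesign | None = None,
                    n_participants: int | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full cohort.

    Returns
    -------
    trials : DataFrame
        Concatenated trial tables over all participants.
    awareness : DataFrame
        One row per participant with a bias-awareness score on [-1, 1],
        drawn from a truncated normal and — by construction — uncorrelated
        with the participant's realized priming effect.
    """
    design = design or build_design(preset.experiment_id)
    n_p = n_participants or preset.n_participants
    root = (seed if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(seed))
    children = root.spawn(n_p + 1)
    tables = [generate_participant(design, preset, pid, child)
              for pid, child in enumerate(children[:n_p])]
    rng = np.random.default_rng(children[-1])
    a, b = ((-1.0 - preset.awareness_mean) / preset.awareness_sd,
            (1.0 - preset.awareness_mean) / preset.awareness_sd)
    scores = stats.truncnorm.rvs(a, b, loc=preset.awareness_mean,
                                 scale=preset.awareness_sd, size=n_p,
                                 random_state=rng)
    awareness = pd.DataFrame({"participant": np.arange(n_p), "score": scores})
    return pd.concat(tables, ignore_index=True), awareness
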