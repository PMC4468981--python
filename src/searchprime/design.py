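"""Experimental designs and balanced trial-sequence generation.

Four designs are supported, crossing search type with difficulty:

==========  =================  ======  =========  ==============
id          task               blocks  set sizes  participants
==========  =================  ======  =========  ==============
``exp1a``   singleton, easy       7       --           31
``exp1b``   conjunction, hard     5       --           26
``exp2a``   singleton, hard       5     11 / 21        41
``exp2b``   conjunction, easy     7      6 / 9         25
==========  =================  ======  =========  ==============

Every design alternates 200-trial Neutral and Bias blocks, starting and
ending with a Neutral block.  In Neutral blocks the two target colors are
exactly balanced; in Bias blocks one color (the "bias color") is the target
on exactly 80% of trials.  Sessions begin with 10 practice trials, and a
short participant break occurs every 125 trials, shifted so that it never
coincides with a block transition.  Neutral blocks that follow a Bias block
are partitioned into three consecutive sub-blocks (I, II, III) used to probe
the decay of long-term priming.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BlockSpec",
    "ExperimentDesign",
    "TrialPlan",
    "EXPERIMENT_IDS",
    "build_design",
    "generate_trial_sequence",
    "assign_sub_blocks",
    "trials_to_frame",
    "DesignError",
    "BalanceError",
]

EXPERIMENT_IDS = ("exp1a", "exp1b", "exp2a", "exp2b")

#: target-color labels used throughout the package
BIAS, OTHER = "bias_color", "other_color"
REP, SWITCH, UNDEF = "repetition", "switch", "undefined"

#: proportion of bias-color targets in a Bias block
BIAS_PROPORTION = 0.8
#: tolerated repetition/switch imbalance per block, as a fraction of
#: classifiable trials
REP_BALANCE_TOL = 0.05
#: maximum constrained-shuffle attempts before giving up on a block
MAX_SHUFFLES = 10_000


class DesignError(ValueError):
    """Unknown experiment id or invalid design configuration."""


class BalanceError(RuntimeError):
    """Raised when a balanced sequence cannot be found by rejection."""

    def __init__(self, block_index: int, attempts: int):
        self.block_index = block_index
        self.attempts = attempts
        super().__init__(
            f"block {block_index}: no repetition/switch-balanced order found "
            f"after {attempts} shuffles"
        )


@dataclass(frozen=True)
class BlockSpec:
    """One block of the session."""

    index: int  # 1-based
    kind: str  # "neutral" | "bias"
    n_trials: int = 200
    bias_proportion: float = 0.5
    set_sizes: tuple[int, ...] = ()

    def __post_init__(self):
        if self.n_trials <= 0:
            raise DesignError("n_trials must be positive")
        if self.bias_proportion not in (0.5, BIAS_PROPORTION):
            raise DesignError("bias_proportion must be 0.5 or 0.8")
        n_bias = self.bias_proportion * self.n_trials
        if abs(n_bias - round(n_bias)) > 1e-9:
            raise DesignError("bias_proportion * n_trials must be an integer")


@dataclass(frozen=True)
class ExperimentDesign:
    experiment_id: str
    blocks: tuple[BlockSpec, ...]
    n_practice: int = 10
    break_interval: int = 125
    bias_color_label: str = "red"
    set_sizes: tuple[int, ...] = ()

    @property
    def n_trials(self) -> int:
        """Non-practice trials in the session."""
        return sum(b.n_trials for b in self.blocks)

    def __post_init__(self):
        kinds = [b.kind for b in self.blocks]
        expect = ["neutral" if i % 2 == 0 else "bias" for i in range(len(kinds))]
        if kinds != expect or kinds[-1] != "neutral":
            raise DesignError("blocks must alternate neutral/bias, neutral first and last")


@dataclass
class TrialPlan:
    """One planned trial (no behavior attached yet)."""

    trial_index: int  # 0-based within session, practice included
    block_index: int  # 1-based; 0 for practice trials
    target_type: str  # BIAS | OTHER
    repetition_type: str  # REP | SWITCH | UNDEF
    response_side: str  # "up" | "down"
    response_repetition: str
    set_size: int | None = None
    post_break: bool = False
    sub_block: str | None = None  # "I" | "II" | "III"
    practice: bool = False


def build_design(experiment_id: str, bias_color_label: str = "red") -> ExperimentDesign:
    """Return the preset design for one of the four experiments.

    Parameters
    ----------
    experiment_id
        One of ``exp1a``, ``exp1b``, ``exp2a``, ``exp2b``.
    bias_color_label
        Which physical color plays the bias role (counterbalanced across
        participants in the original procedure; a label only, analysis is
        color-role based).
    """
    presets = {
        "exp1a": (7, ()),
        "exp1b": (5, ()),
        "exp2a": (5, (11, 21)),
        "exp2b": (7, (6, 9)),
    }
    try:
        n_blocks, set_sizes = presets[experiment_id]
    except KeyError:
        raise DesignError(
            f"unknown experiment_id {experiment_id!r}; expected one of {EXPERIMENT_IDS}"
        ) from None
    blocks = tuple(
        BlockSpec(
            index=i + 1,
            kind="neutral" if i % 2 == 0 else "bias",
            n_trials=200,
            bias_proportion=0.5 if i % 2 == 0 else BIAS_PROPORTION,
            set_sizes=set_sizes,
        )
        for i in range(n_blocks)
    )
    return ExperimentDesign(
        experiment_id=experiment_id,
        blocks=blocks,
        bias_color_label=bias_color_label,
        set_sizes=set_sizes,
    )


def _balanced_halves(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random 0/1 array of length n with counts split as evenly as possible."""
    arr = np.zeros(n, dtype=int)
    arr[: n // 2] = 1
    if n % 2:
        arr[n // 2] = rng.integers(2)
    rng.shuffle(arr)
    return arr


def _block_colors(block: BlockSpec, prev_color: str | None,
                  rng: np.random.Generator) -> list[str]:
    """Color sequence for one block with exact counts and, for neutral
    blocks, repetition/switch balance by constrained shuffling."""
    n = block.n_trials
    n_bias = round(block.bias_proportion * n)
    colors = np.array([BIAS] * n_bias + [OTHER] * (n - n_bias))
    if block.kind != "neutral":
        rng.shuffle(colors)
        return list(colors)
    # neutral: reject shuffles until |#rep - #switch| <= 5% of classifiable
    for attempt in range(MAX_SHUFFLES):
        rng.shuffle(colors)
        if prev_color is None:
            reps = colors[1:] == colors[:-1]
            n_class = n - 1
        else:
            prev = np.concatenate(([prev_color], colors[:-1]))
            reps = colors == prev
            n_class = n
        imbalance = abs(int(reps.sum()) - (n_class - int(reps.sum())))
        if imbalance <= REP_BALANCE_TOL * n_class:
            return list(colors)
    raise BalanceError(block.index, MAX_SHUFFLES)


def _assign_set_sizes(colors: list[str], set_sizes: tuple[int, ...],
                      rng: np.random.Generator) -> list[int]:
    """Counterbalance set size against target color within the block."""
    out = np.zeros(len(colors), dtype=int)
    colors_arr = np.array(colors)
    for color in (BIAS, OTHER):
        idx = np.flatnonzero(colors_arr == color)
        labels = _balanced_halves(len(idx), rng)
        out[idx] = np.array(set_sizes)[labels]
    return list(out)


def _break_positions(design: ExperimentDesign) -> set[int]:
    """Non-practice trial ordinals (1-based) after which a break occurs.

    Breaks fall every ``break_interval`` trials; a break that would land on a
    block boundary is shifted one trial later so block transitions stay
    inconspicuous.
    """
    boundaries = set(np.cumsum([b.n_trials for b in design.blocks])[:-1].tolist())
    positions = set()
    pos = design.break_interval
    while pos < design.n_trials:
        shifted = pos + 1 if pos in boundaries else pos
        positions.add(shifted)
        pos += design.break_interval
    return positions


def sub_block_sizes(n: int) -> tuple[int, int, int]:
    """Partition ``n`` trials into three consecutive parts, largest first.

    A 200-trial block yields (67, 67, 66)."""
    base, rem = divmod(n, 3)
    return tuple(base + (1 if i < rem else 0) for i in range(3))


def assign_sub_blocks(block_trials: list[TrialPlan]) -> list[TrialPlan]:
    """Label a post-bias neutral block's trials with sub-blocks I/II/III."""
    sizes = sub_block_sizes(len(block_trials))
    labels = ["I"] * sizes[0] + ["II"] * sizes[1] + ["III"] * sizes[2]
    return [replace_sub(t, lab) for t, lab in zip(block_trials, labels)]


def replace_sub(trial: TrialPlan, label: str) -> TrialPlan:
    trial.sub_block = label
    return trial


def generate_trial_sequence(design: ExperimentDesign, seed) -> list[TrialPlan]:
    """Emit the full, balanced trial sequence for one session.

    Guarantees (exact, for every seed):

    * per bias block exactly ``0.8 * n`` bias-color targets;
    * per neutral block exactly ``n/2`` of each color and a
      repetition/switch imbalance of at most 5% of classifiable trials;
    * response sides 50/50 per block, independent of color;
    * set size (where present) counterbalanced against color within block;
    * breaks every 125 trials, never on a block boundary;
    * sub-block labels I/II/III on neutral blocks that follow a bias block.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialPlan] = []

    # practice: random colors, excluded from all bookkeeping
    for i in range(design.n_practice):
        color = BIAS if rng.integers(2) else OTHER
        side = "up" if rng.integers(2) else "down"
        trials.append(TrialPlan(
            trial_index=i, block_index=0, target_type=color,
            repetition_type=UNDEF, response_side=side,
            response_repetition=UNDEF,
            set_size=int(rng.choice(design.set_sizes)) if design.set_sizes else None,
            practice=True,
        ))

    breaks = _break_positions(design)
    prev_color: str | None = None
    prev_side: str | None = None
    ordinal = 0  # 1-based non-practice counter
    for bi, block in enumerate(design.blocks):
        colors = _block_colors(block, prev_color, rng)
        sides = ["up" if s else "down" for s in _balanced_halves(block.n_trials, rng)]
        sizes = (_assign_set_sizes(colors, block.set_sizes, rng)
                 if block.set_sizes else [None] * block.n_trials)
        block_trials = []
        for color, side, size in zip(colors, sides, sizes):
            ordinal += 1
            rep = UNDEF if prev_color is None else (REP if color == prev_color else SWITCH)
            rrep = UNDEF if prev_side is None else (REP if side == prev_side else SWITCH)
            block_trials.append(TrialPlan(
                trial_index=design.n_practice + ordinal - 1,
                block_index=block.index,
                target_type=color,
                repetition_type=rep,
                response_side=side,
                response_repetition=rrep,
                set_size=size,
                post_break=(ordinal - 1) in breaks,  # trial following a break
                practice=False,
            ))
            prev_color, prev_side = color, side
        follows_bias = bi > 0 and design.blocks[bi - 1].kind == "bias"
        if block.kind == "neutral" and follows_bias:
            block_trials = assign_sub_blocks(block_trials)
        trials.extend(block_trials)
    return trials


#: CSV column order for serialized sequences
TRIAL_COLUMNS = [
    "participant", "trial", "block", "block_kind", "target_type",
    "repetition_type", "response_side", "response_repetition",
    "set_size", "post_break", "sub_block", "practice",
]


def trials_to_frame(trials: list[TrialPlan], design: ExperimentDesign,
                    participant: int = 0) -> pd.DataFrame:
    """Tabulate a trial sequence (one row per trial, fixed column order)."""
    kind = {b.index: b.kind for b in design.blocks}
    kind[0] = "practice"
    df = pd.DataFrame({
        "participant": participant,
        "trial": [t.trial_index for t in trials],
        "block": [t.block_index for t in trials],
        "block_kind": [kind[t.block_index] for t in trials],
        "target_type": [t.target_type for t in trials],
        "repetition_type": [t.repetition_type for t in trials],
        "response_side": [t.response_side for t in trials],
        "response_repetition": [t.response_repetition for t in trials],
        "set_size": [t.set_size for t in trials],
        "post_break": [t.post_break for t in trials],
        "sub_block": [t.sub_block for t in trials],
        "practice": [t.practice for t in trials],
    })
    return df[TRIAL_COLUMNS]
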