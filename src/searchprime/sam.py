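"""Instance-based episodic retrieval model of intertrial priming.

The model follows the classic Search-of-Associative-Memory (SAM) family of
instance models with a randomly drifting binary context (Mensink–Raaijmakers
style):

1. every search trial lays down one episodic trace binding the target color
   to a snapshot of the current temporal context;
2. at retrieval, each stored trace is activated in proportion to
   ``strength x context_overlap x feature_weight``; the summed activation of
   color-matching traces facilitates the current trial;
3. the context is a vector of binary elements, each of which resamples
   uniformly with probability ``drift_rate`` per trial, so that the expected
   overlap with a snapshot taken ``k`` trials ago decays geometrically as
   ``0.5 + 0.5 * (1 - drift_rate)**k``.

Because traces are never removed, a block in which one color dominates
leaves a permanent excess of traces for that color; the model therefore
predicts *long-term* priming that persists after the bias is gone, on top of
recency-driven short-term repetition priming.

Retrieval here is deterministic expected activation (not sampled recall),
mapped to RT through a bounded logarithmic link
``RT = rt_base - rt_gain * log(1 + activation)``.  Only ordinal and
persistence predictions are interpreted; the link and all constants are
exposed in :class:`SamParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import BIAS, TrialPlan

__all__ = [
    "SamParams",
    "SamState",
    "init_state",
    "drift_context",
    "encode_trial",
    "retrieval_activation",
    "simulate_session",
]


@dataclass(frozen=True)
class SamParams:
    """Parameters of the episodic retrieval simulator.

    Defaults are this package's documented instantiation; the qualitative
    predictions (short-term recency priming, persistent long-term bias
    advantage) are robust to them.
    """

    context_dim: int = 200  # number of binary context elements
    drift_rate: float = 0.05  # per-trial resampling probability per element
    encode_strength: float = 1.0  # strength increment at study
    strength_same_feature: float = 1.0  # weight of color-matching traces
    strength_diff_feature: float = 0.0  # weight of non-matching traces
    rt_base: float = 600.0  # ms
    rt_gain: float = 30.0  # ms per unit log-activation

    def __post_init__(self):
        if not 0.0 <= self.drift_rate <= 1.0:
            raise ValueError("drift_rate must lie in [0, 1]")
        if self.strength_diff_feature > self.strength_same_feature:
            raise ValueError("strength_diff_feature must not exceed strength_same_feature")
        if self.context_dim < 1:
            raise ValueError("context_dim must be >= 1")


class SamState:
    """Growing store of episodic traces plus the current drifting context.

    ``snapshots`` rows are context snapshots at encoding time; ``match``
    caches, for each trace, the number of context elements currently agreeing
    with its snapshot, and is updated incrementally as the context drifts.
    """

    __slots__ = ("context", "snapshots", "colors", "strengths", "match",
                 "n_traces", "trial_counter")

    def __init__(self, context: np.ndarray, capacity: int = 64):
        self.context = context  # int8 {0,1}
        d = context.shape[0]
        self.snapshots = np.empty((capacity, d), dtype=np.int8)
        self.colors = np.empty(capacity, dtype=np.int8)  # 1 = BIAS, 0 = OTHER
        self.strengths = np.empty(capacity, dtype=np.float64)
        self.match = np.empty(capacity, dtype=np.int64)
        self.n_traces = 0
        self.trial_counter = 0

    def _grow(self):
        for name in ("snapshots", "colors", "strengths", "match"):
            arr = getattr(self, name)
            new = np.empty((arr.shape[0] * 2, *arr.shape[1:]), dtype=arr.dtype)
            new[: arr.shape[0]] = arr
            setattr(self, name, new)

    def overlaps(self) -> np.ndarray:
        """Fractional context overlap of each stored trace, in [0, 1]."""
        return self.match[: self.n_traces] / self.context.shape[0]


def init_state(params: SamParams, rng: np.random.Generator) -> SamState:
    """Fresh state with a random initial context."""
    context = rng.integers(0, 2, size=params.context_dim, dtype=np.int8)
    return SamState(context)


def drift_context(state: SamState, params: SamParams,
                  rng: np.random.Generator) -> SamState:
    """Resample each context element with probability ``drift_rate``.

    Resampled elements draw uniformly from {0, 1} (so half of them keep
    their value).  Trace match counts are updated only for elements that
    actually flipped.
    """
    d = params.context_dim
    mask = rng.random(d) < params.drift_rate
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return state
    new_vals = rng.integers(0, 2, size=idx.size, dtype=np.int8)
    flipped = idx[new_vals != state.context[idx]]
    if flipped.size and state.n_traces:
        n = state.n_traces
        # a flip turns each former agreement into disagreement and vice versa
        agree = state.snapshots[:n, flipped] == state.context[flipped]
        state.match[:n] -= 2 * agree.sum(axis=1) - flipped.size
    state.context[idx] = new_vals
    return state


def encode_trial(state: SamState, target_color: str, params: SamParams) -> SamState:
    """Store one trace binding the target color to the current context."""
    if state.n_traces == state.snapshots.shape[0]:
        state._grow()
    i = state.n_traces
    state.snapshots[i] = state.context
    state.colors[i] = 1 if target_color == BIAS else 0
    state.strengths[i] = params.encode_strength
    state.match[i] = params.context_dim  # snapshot == context at encoding
    state.n_traces += 1
    state.trial_counter += 1
    return state


def retrieval_activation(state: SamState, target_color: str,
                         params: SamParams) -> float:
    """Summed activation ``strength x overlap x feature_weight`` over traces."""
    n = state.n_traces
    if n == 0:
        return 0.0
    same = state.colors[:n] == (1 if target_color == BIAS else 0)
    weights = np.where(same, params.strength_same_feature,
                       params.strength_diff_feature)
    return float(np.dot(state.strengths[:n] * weights, state.overlaps()))


def simulate_session(trial_plans: list[TrialPlan], params: SamParams,
                     seed) -> np.ndarray:
    """Predicted RT for every trial of a session.

    Per trial: drift the context, compute the retrieval activation for the
    trial's target color, map it to RT, then encode the trial.  Practice
    trials are simulated like any other (they prime subsequent trials) and
    their RTs are returned in place.
    """
    rng = np.random.default_rng(seed)
    state = init_state(params, rng)
    n = len(trial_plans)
    state.snapshots = np.empty((max(n, 1), params.context_dim), dtype=np.int8)
    state.colors = np.empty(max(n, 1), dtype=np.int8)
    state.strengths = np.empty(max(n, 1), dtype=np.float64)
    state.match = np.empty(max(n, 1), dtype=np.int64)
    rts = np.empty(n)
    for i, trial in enumerate(trial_plans):
        drift_context(state, params, rng)
        act = retrieval_activation(state, trial.target_type, params)
        rts[i] = params.rt_base - params.rt_gain * np.log1p(act)
        encode_trial(state, trial.target_type, params)
    if not np.all(np.isfinite(rts)):
        raise ValueError("non-finite RT produced; check SamParams")
    return rts
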