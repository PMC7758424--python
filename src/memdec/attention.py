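"""Stochastic spatial attention with top-down feedback from the accumulators.

At each step, attention may shift to location i with probability

    p_i = eps * (s_i + phi * g_i**n) / sum_j (s_j + phi * g_j**n)

where s is bottom-up salience (0/1 object presence here), g the ReLU output
of the accumulators, phi the top-down gain and n a contrast exponent
(default 2).  The probabilities sum to eps, the base rate of attentional
shifts; with probability 1 - eps attention stays put.  A draw that lands on
the currently attended location counts as a dwell continuation, not a
re-fixation.  Once the decision layer fires, attention locks onto the chosen
object and no longer moves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateSceneError, ScenarioError

__all__ = ["AttentionConfig", "AttentionState", "switch_probabilities", "maybe_shift", "lock"]


@dataclass
class AttentionConfig:
    epsilon: float = 0.05  # base rate of attentional shifts per step
    phi: float = 0.0       # top-down feedback gain
    n: float = 2.0         # contrast exponent

    def __post_init__(self):
        if not 0.0 <= self.epsilon <= 1.0:
            raise ScenarioError("epsilon must be in [0, 1]")
        if self.phi < 0:
            raise ScenarioError("phi must be >= 0")


@dataclass
class AttentionState:
    current: int
    locked: bool = False


def switch_probabilities(
    s: np.ndarray, g: np.ndarray, cfg: AttentionConfig
) -> np.ndarray:
    """Per-location shift probabilities; sums to epsilon."""
    s = np.asarray(s, dtype=float)
    g = np.asarray(g, dtype=float)
    if s.shape != g.shape:
        raise ScenarioError(f"salience {s.shape} and feedback {g.shape} lengths differ")
    if (s < 0).any() or (g < 0).any():
        raise ScenarioError("salience and feedback must be elementwise >= 0")
    w = s + cfg.phi * g**cfg.n
    tot = w.sum()
    if tot <= 0.0:
        raise DegenerateSceneError("no salience or feedback anywhere: attention undefined")
    return cfg.epsilon * w / tot


def maybe_shift(
    state: AttentionState, p: np.ndarray, rng: np.random.Generator
) -> AttentionState:
    """Sample one attentional event: move to location i w.p. p_i, else stay."""
    if state.locked:
        return state
    u = rng.random()
    acc = 0.0
    for i, pi in enumerate(p):
        acc += pi
        if u < acc:
            return AttentionState(current=i, locked=False)
    return state


def lock(state: AttentionState, winner: int) -> AttentionState:
    """Lock attention onto the chosen object; only a trial reset unlocks."""
    return AttentionState(current=winner, locked=True)
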