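"""Spatially-indexed leaky competing accumulators and the decision layer.

One accumulator per location integrates the value signal while its location
is attended:

    dx_i/dt = -lam*x_i + alpha*I_i - beta*sum_{j!=i} I_j
              + gamma*f(x_i) - delta*sum_{j!=i} f(x_j) + N(sigma)

with I_i = V when i is the attended location and 0 otherwise, and f = ReLU.
All four gains are stored nonnegative; the inhibitory pathways (forward
inhibition beta, feedback inhibition delta) act through an inhibitory
inter-node and therefore enter with a minus sign.  Noise is independent
Gaussian per accumulator per step, scaled by sqrt(dt).

The decision layer is winner-takes-all with a fixed threshold (default 1):
it reacts only once an accumulator crosses threshold, and ties are broken
uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalError, ScenarioError

__all__ = ["AccumulatorBank", "DecisionLayer", "acc_step", "check_decision", "reset_bank"]


@dataclass
class AccumulatorBank:
    n: int = 2
    alpha: float = 1.0    # forward excitation
    beta: float = 0.0     # forward inhibition (via inhibitory inter-node)
    gamma: float = 0.0    # feedback excitation
    delta: float = 0.0    # feedback inhibition (via inhibitory inter-node)
    leak: float = 0.0     # decay constant lam
    sigma: float = 0.0    # noise scale
    dt: float = 1.0
    clamp_state: bool = False   # optionally keep x itself >= 0
    x: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.n < 1:
            raise ScenarioError("need at least one accumulator")
        for name in ("alpha", "beta", "gamma", "delta", "leak", "sigma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ScenarioError(f"accumulator gain {name} must be finite and >= 0")
        if self.dt <= 0:
            raise ScenarioError("accumulator dt must be > 0")
        if self.x is None:
            self.x = np.zeros(self.n)
        else:
            self.x = np.asarray(self.x, dtype=float)
            if self.x.shape != (self.n,):
                raise ScenarioError(f"accumulator state shape {self.x.shape} != ({self.n},)")

    def output(self) -> np.ndarray:
        """ReLU output f(x) of the accumulators (also the attention feedback g)."""
        return np.maximum(self.x, 0.0)


@dataclass
class DecisionLayer:
    threshold: float = 1.0

    def __post_init__(self):
        if self.threshold <= 0:
            raise ScenarioError("decision threshold must be > 0")


def acc_step(
    bank: AccumulatorBank,
    V: float,
    selected: int,
    rng: np.random.Generator | None = None,
) -> AccumulatorBank:
    """Advance the bank one Euler step with value V gated to ``selected``."""
    if not 0 <= selected < bank.n:
        raise ScenarioError(f"selected location {selected} out of range 0..{bank.n - 1}")
    x = bank.x
    # forward terms: I_selected = V, others 0; inhibition sums the *other* inputs
    dx = -bank.leak * x
    dx[selected] += bank.alpha * V
    if bank.beta != 0.0:
        dx -= bank.beta * V
        dx[selected] += bank.beta * V     # no self-inhibition from own input
    if bank.gamma != 0.0 or bank.delta != 0.0:
        fx = np.maximum(x, 0.0)
        if bank.gamma != 0.0:
            dx += bank.gamma * fx
        if bank.delta != 0.0:
            dx -= bank.delta * (fx.sum() - fx)
    x = x + bank.dt * dx
    if bank.sigma > 0.0:
        if rng is None:
            raise ScenarioError("sigma > 0 requires an rng")
        x = x + bank.sigma * np.sqrt(bank.dt) * rng.standard_normal(bank.n)
    if bank.clamp_state:
        np.maximum(x, 0.0, out=x)
    if not np.isfinite(x).all():
        raise NumericalError("accumulator state became non-finite")
    bank.x = x
    return bank


def check_decision(
    bank: AccumulatorBank,
    layer: DecisionLayer,
    rng: np.random.Generator | None = None,
) -> int | None:
    """Winner location once an accumulator reaches threshold; None before that.

    The winner is the largest supra-threshold accumulator; exact ties are
    broken uniformly at random (seeded via ``rng``).
    """
    x = bank.x
    top = x.max()
    if top < layer.threshold:
        return None
    above = x >= layer.threshold
    tied = np.flatnonzero(above & (x == top))
    if tied.size == 1:
        return int(tied[0])
    if rng is None:
        return int(tied[0])
    return int(tied[rng.integers(tied.size)])


def reset_bank(bank: AccumulatorBank) -> AccumulatorBank:
    """Zero all accumulator states (the decision layer does this after a choice)."""
    bank.x = np.zeros(bank.n)
    return bank
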