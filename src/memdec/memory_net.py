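"""Recurrent memory network: fast attractors, depression-driven latching,
and delayed episodic transitions.

The state x of the network evolves by explicit Euler integration of

    dx_i/dt = -leak * x_i + I_i + sum_j (1 - d_ji) w_ji f(x_j(t - tau_ji))

with a single delay per connection set: semantic (auto- and
hetero-associative) weights act with latency ``tau_fast``, episodic
hetero-associative weights with latency ``tau_slow``.  The activation f is a
saturating piecewise-linear function clip(x, 0, 1), so the readout
m = f(x) is a graded binary-like pattern.  Per-connection synaptic
depression d_ji grows with the signal flowing through the connection and
recovers on its own timescale; it is what limits the time the state stays at
an attractor and drives latching transitions between semantically associated
attractors.

The leak term is optional (default 0): the raw dynamics have no intrinsic
decay, and with orthogonal patterns a saturating f keeps the readout bounded
regardless.  Scenario presets enable a small leak so that a collapsed
attractor actually releases its nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import NumericalError, ScenarioError

__all__ = [
    "MemoryConfig",
    "AssociationSet",
    "MemoryState",
    "encode_attractors",
    "encode_episodic_chain",
    "add_association",
    "init_state",
    "step",
    "readout",
    "reset",
    "pattern_visits",
]


def pwl_saturation(x: np.ndarray) -> np.ndarray:
    """Bounded nondecreasing activation with f(0)=0: clip(x, 0, 1)."""
    return np.clip(x, 0.0, 1.0)


@dataclass
class MemoryConfig:
    dt: float = 1.0
    tau_fast: int = 1       # latency of semantic connections, in steps
    tau_slow: int = 25      # latency of episodic connections, in steps
    depression_gain: float = 0.0
    depression_recovery: float = 0.0
    leak: float = 0.0
    input_gain: float = 1.0
    noise: float = 0.0      # optional additive noise on x, default off
    activation: Callable[[np.ndarray], np.ndarray] = pwl_saturation

    def __post_init__(self):
        if self.dt <= 0:
            raise ScenarioError("memory dt must be > 0")
        if self.tau_fast < 1 or self.tau_slow < 1:
            raise ScenarioError("delays must be >= 1 step")
        for name in ("depression_gain", "depression_recovery", "leak", "noise"):
            if getattr(self, name) < 0:
                raise ScenarioError(f"memory {name} must be >= 0")


@dataclass
class AssociationSet:
    """Pre-learned weights: fast semantic, slow episodic, plus the stored patterns."""

    semantic_weights: np.ndarray   # (N, N), W[i, j] = w_ji (j presynaptic)
    episodic_weights: np.ndarray   # (N, N), same convention
    stored_patterns: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.semantic_weights = np.asarray(self.semantic_weights, dtype=float)
        self.episodic_weights = np.asarray(self.episodic_weights, dtype=float)
        ws, we = self.semantic_weights, self.episodic_weights
        if ws.ndim != 2 or ws.shape[0] != ws.shape[1]:
            raise ScenarioError(f"semantic_weights must be square, got {ws.shape}")
        if we.shape != ws.shape:
            raise ScenarioError(
                f"episodic_weights shape {we.shape} != semantic {ws.shape}"
            )
        if not (np.isfinite(ws).all() and np.isfinite(we).all()):
            raise ScenarioError("association weights must be finite")

    @property
    def n(self) -> int:
        return self.semantic_weights.shape[0]

    @property
    def has_episodic(self) -> bool:
        if not hasattr(self, "_has_episodic"):
            self._has_episodic = bool(self.episodic_weights.any())
        return self._has_episodic


@dataclass
class MemoryState:
    """Activation x, per-connection depression, and the delay ring buffer.

    ``hist[t % depth]`` holds f(x) after step t; the buffer is deep enough for
    the slowest connection latency.
    """

    x: np.ndarray
    d_sem: np.ndarray
    d_epi: np.ndarray
    hist: np.ndarray       # (depth, N) ring buffer of past readouts
    t: int = 0             # steps taken since last full init
    depressed: bool = False  # True once any d_ji has become nonzero

    @property
    def depth(self) -> int:
        return self.hist.shape[0]


def init_state(n: int, cfg: MemoryConfig) -> MemoryState:
    depth = max(cfg.tau_fast, cfg.tau_slow) + 1
    return MemoryState(
        x=np.zeros(n),
        d_sem=np.zeros((n, n)),
        d_epi=np.zeros((n, n)),
        hist=np.zeros((depth, n)),
    )


def _check_patterns(patterns) -> list[np.ndarray]:
    pats = [np.asarray(p, dtype=float) for p in patterns]
    if pats:
        n = pats[0].shape[0]
        for p in pats:
            if p.ndim != 1 or p.shape[0] != n:
                raise ScenarioError("patterns must all be 1-d vectors of the same length")
    return pats


def encode_attractors(patterns, strength: float = 1.0, n: int | None = None) -> np.ndarray:
    """Auto-associative weights making each pattern a fixed point of the fast dynamics.

    Hebbian outer products, normalized per pattern so a fully-active pattern
    drives each of its own nodes with total input ``strength``.
    """
    pats = _check_patterns(patterns)
    if not pats:
        if n is None:
            raise ScenarioError("encode_attractors needs patterns or an explicit size n")
        return np.zeros((n, n))
    size = pats[0].shape[0]
    w = np.zeros((size, size))
    for p in pats:
        w += strength / p.sum() * np.outer(p, p)
    return w


def add_association(w: np.ndarray, src: np.ndarray, dst: np.ndarray, strength: float) -> np.ndarray:
    """Add a hetero-association src -> dst (in place) with per-node drive ``strength``."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    w += strength / src.sum() * np.outer(dst, src)
    return w


def encode_episodic_chain(sequence, strength: float = 1.0) -> np.ndarray:
    """Delayed hetero-associative weights replaying a stored sequence.

    Connection from each pattern to its successor; with the network running,
    initializing at pattern k activates pattern k+1 about tau_slow steps later.
    """
    pats = _check_patterns(sequence)
    if len(pats) < 2:
        raise ScenarioError("an episodic chain needs at least 2 patterns")
    n = pats[0].shape[0]
    w = np.zeros((n, n))
    for a, b in zip(pats[:-1], pats[1:]):
        add_association(w, a, b, strength)
    return w


def step(
    state: MemoryState,
    inp: np.ndarray,
    assoc: AssociationSet,
    cfg: MemoryConfig,
    rng: np.random.Generator | None = None,
) -> MemoryState:
    """Advance the memory network one Euler step (in place) and return it."""
    n = assoc.n
    if state.x.shape[0] != n or inp.shape[0] != n:
        raise ScenarioError(
            f"dimension mismatch: state {state.x.shape[0]}, input {inp.shape[0]}, weights {n}"
        )
    f = cfg.activation
    depth = state.depth
    # hist[t % depth] is f(x) after step t; before any step the buffer holds f(x0).
    f_fast = state.hist[(state.t - cfg.tau_fast) % depth]

    if state.depressed:
        rec = ((1.0 - state.d_sem) * assoc.semantic_weights) @ f_fast
        if assoc.has_episodic:
            f_slow = state.hist[(state.t - cfg.tau_slow) % depth]
            rec += ((1.0 - state.d_epi) * assoc.episodic_weights) @ f_slow
    else:
        rec = assoc.semantic_weights @ f_fast
        if assoc.has_episodic:
            f_slow = state.hist[(state.t - cfg.tau_slow) % depth]
            rec += assoc.episodic_weights @ f_slow

    dx = inp + rec
    if cfg.leak > 0:
        dx = dx - cfg.leak * state.x
    state.x = state.x + cfg.dt * dx
    if cfg.noise > 0:
        if rng is None:
            raise ScenarioError("memory noise > 0 requires an rng")
        state.x = state.x + cfg.noise * np.sqrt(cfg.dt) * rng.standard_normal(n)

    # NaN/inf propagate through the sum, so one reduction checks the vector
    if not np.isfinite(state.x.sum()):
        bad = np.flatnonzero(~np.isfinite(state.x))
        raise NumericalError(
            f"memory state non-finite at step {state.t} (nodes {bad.tolist()[:5]})",
            step=state.t,
        )

    if cfg.depression_gain > 0 or cfg.depression_recovery > 0:
        g, r = cfg.depression_gain, cfg.depression_recovery
        f_slow = state.hist[(state.t - cfg.tau_slow) % depth]
        for d, w, fpre in (
            (state.d_sem, assoc.semantic_weights, f_fast),
            (state.d_epi, assoc.episodic_weights, f_slow),
        ):
            d += cfg.dt * (g * w * fpre[None, :] * (1.0 - d) - r * d)
            np.clip(d, 0.0, 1.0, out=d)
        if g > 0:
            state.depressed = True

    state.t += 1
    state.hist[state.t % depth] = f(state.x)
    return state


def readout(state: MemoryState, cfg: MemoryConfig) -> np.ndarray:
    """Memory output m = f(x), sent to the value component."""
    return cfg.activation(state.x)


def reset(state: MemoryState) -> MemoryState:
    """Clear activations and delay history; depression persists (it recovers
    on its own timescale, not at attention shifts)."""
    state.x = np.zeros_like(state.x)
    state.hist[:] = 0.0
    state.t = 0
    return state


def pattern_visits(
    trace: np.ndarray, patterns, threshold: float = 0.8
) -> list[int]:
    """Order in which stored patterns first become active in a readout trace.

    A pattern counts as visited at the first step where its mean activation
    over its own support exceeds ``threshold``.  Returns pattern indices in
    visit order.
    """
    pats = _check_patterns(patterns)
    first = []
    for k, p in enumerate(pats):
        supp = p > 0
        act = trace[:, supp].mean(axis=1)
        hit = np.flatnonzero(act > threshold)
        if hit.size:
            first.append((hit[0], k))
    first.sort()
    return [k for _, k in first]
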