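"""Per-step simulation loop, seeded trials, parameter sweeps and summaries.

A trial runs the full perception-memory-value-accumulation-attention loop
until one accumulator crosses the decision threshold (the choice, with the
step count as reaction time) or ``max_steps`` elapse (a timeout, reported
separately).  Trials are seeded independently by offset from a base seed so
any single trial can be reproduced in isolation.

There is deliberately no discount parameter anywhere in the configuration:
preference for temporally proximal rewards emerges from the episodic replay
latency interacting with the accumulators and attention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from . import attention as att
from . import memory_net as mem
from .accumulators import AccumulatorBank, DecisionLayer, acc_step, check_decision, reset_bank
from .errors import ScenarioError
from .scene import Scene, salience_vector, sample_attribute
from .valuation import ValueMap

__all__ = [
    "Scenario",
    "TrialResult",
    "ExperimentSummary",
    "BreakpointResult",
    "run_trial",
    "run_trials",
    "sweep",
    "sweep_frame",
    "discounting_breakpoint",
]


@dataclass
class Scenario:
    """Everything needed to run trials: world, memories, values, dynamics."""

    scene: Scene
    associations: mem.AssociationSet
    value_map: ValueMap
    memory_cfg: mem.MemoryConfig
    bank: AccumulatorBank
    attention_cfg: att.AttentionConfig
    decision: DecisionLayer = field(default_factory=DecisionLayer)
    max_steps: int = 10_000
    dwell_attr: int = 20
    seed: int = 0
    spec: dict[str, Any] | None = None   # make_scenario kwargs, enables rebuilds

    def __post_init__(self):
        n = self.scene.feature_dim
        if self.associations.n != n:
            raise ScenarioError(
                f"association matrices are {self.associations.n}x{self.associations.n} "
                f"but the scene's feature_dim is {n}"
            )
        if self.value_map.v.shape[0] != n:
            raise ScenarioError(
                f"value map length {self.value_map.v.shape[0]} != feature_dim {n}"
            )
        if self.bank.n != self.scene.n_locations:
            raise ScenarioError(
                f"bank has {self.bank.n} accumulators for {self.scene.n_locations} locations"
            )
        if self.max_steps < 1:
            raise ScenarioError("max_steps must be >= 1")
        if self.dwell_attr < 1:
            raise ScenarioError("dwell_attr must be >= 1")


@dataclass
class TrialResult:
    choice: int | None           # winning location, None on timeout
    rt: int | None               # steps to threshold, None on timeout
    dwell: np.ndarray            # attended steps per location
    n_steps: int
    traces: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        if (self.choice is None) != (self.rt is None):
            raise ScenarioError("timeout must have both choice and rt as None")


def run_trial(
    scenario: Scenario,
    seed: int | None = None,
    record_traces: bool = False,
) -> TrialResult:
    """Run one seeded trial of the full architecture."""
    sc = scenario
    rng = np.random.default_rng(sc.seed if seed is None else seed)
    n_loc = sc.scene.n_locations
    obj_at = [sc.scene.object_at(i) for i in range(n_loc)]
    s = salience_vector(sc.scene)
    mcfg, acfg = sc.memory_cfg, sc.attention_cfg
    input_gain = mcfg.input_gain
    vmap = sc.value_map

    bank = replace(sc.bank, x=np.zeros(sc.bank.n))
    state = mem.init_state(sc.scene.feature_dim, mcfg)

    # initial fixation: salience-weighted random object
    a = att.AttentionState(current=int(rng.choice(n_loc, p=s / s.sum())))
    attr = sample_attribute(obj_at[a.current], rng)
    inp = input_gain * attr.features
    steps_on_attr = 0
    dwell = np.zeros(n_loc)

    # attention probabilities are constant when there is no top-down feedback
    p_static = None
    if acfg.phi == 0.0:
        p_static = att.switch_probabilities(s, np.zeros(n_loc), acfg)

    occupied = s > 0
    traces: dict[str, list] | None = None
    if record_traces:
        traces = {"memory": [], "value": [], "accumulators": [], "attended": []}

    choice = rt = None
    for t in range(sc.max_steps):
        # --- spatial attention -------------------------------------------
        if p_static is not None:
            p = p_static
        else:
            p = att.switch_probabilities(s, bank.output(), acfg)
            p = np.where(occupied, p, 0.0)  # attention only targets objects
        new_a = att.maybe_shift(a, p, rng)
        if new_a.current != a.current:
            a = new_a
            mem.reset(state)
            attr = sample_attribute(obj_at[a.current], rng)
            inp = input_gain * attr.features
            steps_on_attr = 0
        else:
            steps_on_attr += 1
            if steps_on_attr >= sc.dwell_attr:
                steps_on_attr = 0
                new_attr = sample_attribute(obj_at[a.current], rng)
                if new_attr.id != attr.id:
                    attr = new_attr
                    inp = input_gain * attr.features
                    mem.reset(state)

        # --- memory -> value -> accumulation -----------------------------
        mem.step(state, inp, sc.associations, mcfg,
                 rng if mcfg.noise > 0 else None)
        # the ring buffer's newest row is exactly readout(state) = f(x)
        m = state.hist[state.t % state.depth]
        V = float(vmap.v @ m)
        acc_step(bank, V, a.current, rng)
        dwell[a.current] += 1

        if record_traces:
            traces["memory"].append(m.copy())
            traces["value"].append(V)
            traces["accumulators"].append(bank.x.copy())
            traces["attended"].append(a.current)

        winner = check_decision(bank, sc.decision, rng)
        if winner is not None:
            choice, rt = winner, t + 1
            a = att.lock(a, winner)
            reset_bank(bank)
            break

    out_traces = None
    if record_traces:
        out_traces = {
            "memory": np.asarray(traces["memory"]),
            "value": np.asarray(traces["value"]),
            "accumulators": np.asarray(traces["accumulators"]),
            "attended": np.asarray(traces["attended"]),
        }
    return TrialResult(
        choice=choice,
        rt=rt,
        dwell=dwell,
        n_steps=rt if rt is not None else sc.max_steps,
        traces=out_traces,
    )


@dataclass
class ExperimentSummary:
    """Aggregate of a batch of trials: choice probabilities and RT statistics.

    Choice probabilities are over decided trials and sum to 1; timeouts are
    counted separately.  ``rts`` keeps the full per-alternative RT samples so
    distributions (histograms, skew, IQR) can be computed downstream.
    """

    n_trials: int
    n_timeouts: int
    counts: np.ndarray                 # decided choices per location
    choice_prob: np.ndarray            # counts / decided
    rts: dict[int, np.ndarray]         # location -> RT samples (steps)
    mean_rt: np.ndarray                # per location, NaN if never chosen
    median_rt: np.ndarray
    dwell_share_chosen: float          # mean fraction of dwell on the chosen object
    params: dict[str, Any] = field(default_factory=dict)
    base_seed: int | None = None

    @property
    def labels(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(len(self.counts))]

    def summary(self) -> pd.DataFrame:
        """One row per alternative."""
        rows = []
        for i in range(len(self.counts)):
            rows.append(
                {
                    "alternative": self.labels[i],
                    "location": i,
                    **self.params,
                    "n_chosen": int(self.counts[i]),
                    "choice_prob": self.choice_prob[i],
                    "mean_rt": self.mean_rt[i],
                    "median_rt": self.median_rt[i],
                }
            )
        return pd.DataFrame(rows)

    @property
    def overall_mean_rt(self) -> float:
        all_rts = np.concatenate([v for v in self.rts.values()]) if self.rts else np.array([])
        return float(all_rts.mean()) if all_rts.size else float("nan")


def summarize(results: list[TrialResult], n_locations: int,
              params: dict | None = None, base_seed: int | None = None) -> ExperimentSummary:
    counts = np.zeros(n_locations)
    rts: dict[int, list[int]] = {i: [] for i in range(n_locations)}
    timeouts = 0
    shares = []
    for r in results:
        if r.choice is None:
            timeouts += 1
            continue
        counts[r.choice] += 1
        rts[r.choice].append(r.rt)
        tot = r.dwell.sum()
        if tot > 0:
            shares.append(r.dwell[r.choice] / tot)
    decided = counts.sum()
    prob = counts / decided if decided else np.full(n_locations, np.nan)
    rt_arrays = {i: np.asarray(v) for i, v in rts.items()}
    mean_rt = np.array([v.mean() if v.size else np.nan for v in rt_arrays.values()])
    median_rt = np.array([np.median(v) if v.size else np.nan for v in rt_arrays.values()])
    return ExperimentSummary(
        n_trials=len(results),
        n_timeouts=timeouts,
        counts=counts,
        choice_prob=prob,
        rts=rt_arrays,
        mean_rt=mean_rt,
        median_rt=median_rt,
        dwell_share_chosen=float(np.mean(shares)) if shares else float("nan"),
        params=dict(params or {}),
        base_seed=base_seed,
    )


def run_trials(scenario: Scenario, n: int, base_seed: int | None = None,
               params: dict | None = None) -> ExperimentSummary:
    """Run n independent trials seeded base_seed .. base_seed+n-1."""
    if n < 1:
        raise ScenarioError("need n >= 1 trials")
    base = scenario.seed if base_seed is None else base_seed
    results = [run_trial(scenario, seed=base + i) for i in range(n)]
    return summarize(results, scenario.scene.n_locations, params, base)


# --- parameter sweeps -----------------------------------------------------

_PARAM_OWNERS = {
    "sigma": "bank", "alpha": "bank", "beta": "bank", "gamma": "bank",
    "delta": "bank", "acc_leak": ("bank", "leak"),
    "epsilon": "attention_cfg", "phi": "attention_cfg", "n_contrast": ("attention_cfg", "n"),
    "tau_fast": "memory_cfg", "tau_slow": "memory_cfg",
    "depression_gain": "memory_cfg", "depression_recovery": "memory_cfg",
    "memory_leak": ("memory_cfg", "leak"), "input_gain": "memory_cfg",
    "threshold": "decision",
    "max_steps": None, "dwell_attr": None,
}


def rebuild(scenario: Scenario, **overrides) -> Scenario:
    """Re-run the scenario generator with some arguments overridden."""
    from .scene import make_scenario

    if scenario.spec is None:
        raise ScenarioError("scenario has no generator spec; cannot rebuild")
    kwargs = dict(scenario.spec)
    kwargs.update(overrides)
    return make_scenario(**kwargs)


def with_param(scenario: Scenario, name: str, value) -> Scenario:
    """Return a copy of the scenario with one exposed parameter changed."""
    if name == "chain_length":
        if scenario.spec is None:
            raise ScenarioError("chain_length sweeps need a generator-built scenario")
        chains = list(scenario.spec.get("chain_lengths") or
                      [0] * scenario.spec["n_objects"])
        idx = [i for i, c in enumerate(chains) if c > 0] or [len(chains) - 1]
        for i in idx:
            chains[i] = int(value)
        return rebuild(scenario, chain_lengths=chains)
    if name in ("max_steps", "dwell_attr"):
        return replace(scenario, **{name: value})
    if name not in _PARAM_OWNERS:
        raise ScenarioError(
            f"unknown sweep parameter {name!r}; known: {sorted(_PARAM_OWNERS)} + ['chain_length']"
        )
    owner = _PARAM_OWNERS[name]
    attr_name = name
    if isinstance(owner, tuple):
        owner, attr_name = owner
    sub = replace(getattr(scenario, owner), **{attr_name: value})
    if owner == "bank":
        sub = replace(sub, x=np.zeros(sub.n))
    new = replace(scenario, **{owner: sub})
    if scenario.spec is not None:
        # keep the generator spec in sync so later rebuilds preserve the change
        spec_key = {"bank": "acc_cfg", "memory_cfg": "memory_cfg",
                    "attention_cfg": "attention_cfg", "decision": "threshold"}[owner]
        new.spec = dict(scenario.spec)
        new.spec[spec_key] = sub.threshold if owner == "decision" else sub
    return new


def sweep(scenario: Scenario, name: str, values, n: int,
          base_seed: int | None = None) -> list[ExperimentSummary]:
    """One ExperimentSummary per value, all other parameters held fixed."""
    base = scenario.seed if base_seed is None else base_seed
    out = []
    for k, v in enumerate(values):
        sc = with_param(scenario, name, v)
        out.append(run_trials(sc, n, base_seed=base + k * n, params={name: v}))
    return out


def sweep_frame(summaries: list[ExperimentSummary]) -> pd.DataFrame:
    """Tidy table: one row per swept value x alternative."""
    return pd.concat([s.summary() for s in summaries], ignore_index=True)


# --- implicit discounting -------------------------------------------------

@dataclass
class BreakpointResult:
    crossing: int | None               # smallest k with P(delayed) < 0.5
    ci: tuple[float, float] | None     # bootstrap 95% CI on the crossing
    chain_lengths: np.ndarray
    p_delayed: np.ndarray
    summaries: list[ExperimentSummary]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chain_length": self.chain_lengths, "p_delayed": self.p_delayed}
        )


def _crossing(p: np.ndarray) -> int | None:
    below = np.flatnonzero(p < 0.5)
    return int(below[0]) if below.size else None


def discounting_breakpoint(
    scenario: Scenario,
    value_immediate: float,
    value_delayed: float,
    max_chain: int = 9,
    n: int = 1000,
    base_seed: int | None = None,
    n_boot: int = 500,
) -> BreakpointResult:
    """Chain length at which preference for the delayed larger reward crosses 0.5.

    Object at location 0 carries ``value_delayed`` behind k = 0..max_chain
    episodic transitions; the object at location 1 carries ``value_immediate``
    directly.  Implicit discounting makes the delayed option lose for large k
    even though no discount factor exists in the model.
    """
    if not value_immediate < value_delayed:
        raise ScenarioError("need value_immediate < value_delayed")
    if scenario.spec is None:
        raise ScenarioError("discounting_breakpoint needs a generator-built scenario")
    base = scenario.seed if base_seed is None else base_seed
    ks = np.arange(max_chain + 1)
    summaries = []
    counts_del = np.zeros(len(ks), dtype=int)
    counts_dec = np.zeros(len(ks), dtype=int)
    for k in ks:
        sc = rebuild(
            scenario,
            value_spec=[value_delayed, value_immediate],
            chain_lengths=[int(k), 0],
        )
        s = run_trials(sc, n, base_seed=base + int(k) * n,
                       params={"chain_length": int(k)})
        summaries.append(s)
        counts_del[k] = int(s.counts[0])
        counts_dec[k] = int(s.counts.sum())
    p_delayed = np.where(counts_dec > 0, counts_del / np.maximum(counts_dec, 1), np.nan)
    crossing = _crossing(p_delayed)

    ci = None
    if n_boot > 0:
        brng = np.random.default_rng(base)
        xs = []
        for _ in range(n_boot):
            pb = brng.binomial(counts_dec, np.nan_to_num(p_delayed)) / np.maximum(counts_dec, 1)
            c = _crossing(pb)
            xs.append(max_chain + 1 if c is None else c)
        lo, hi = np.percentile(xs, [2.5, 97.5])
        ci = (float(lo), float(hi))
    return BreakpointResult(
        crossing=crossing, ci=ci, chain_lengths=ks, p_delayed=p_delayed,
        summaries=summaries,
    )
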