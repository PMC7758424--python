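"""The stimulus world: objects at spatial locations, each a set of attributes.

An object is a bag of attributes; attending an object means stochastically
processing one of its attributes at a time, each of which emits a fixed binary
feature vector into the memory network.  Locations double as handles for the
accumulators (deictic coding): accumulator *i* collects evidence for the object
at location *i*.

This module also hosts :func:`make_scenario`, the programmatic scenario
generator used by the presets and the test suite.  Feature patterns for
distinct attributes are laid out as orthogonal one-hot blocks by default so
that attractor encoding is exact; a block ``overlap`` is exposed for
semantic-similarity setups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CapacityError, ScenarioError

__all__ = [
    "Attribute",
    "SceneObject",
    "Scene",
    "sample_attribute",
    "salience_vector",
    "make_scenario",
]


@dataclass(frozen=True)
class Attribute:
    """A perceivable attribute emitting a binary feature vector when attended."""

    id: str
    features: np.ndarray  # binary, length F

    def __post_init__(self):
        feats = np.asarray(self.features, dtype=float)
        if feats.ndim != 1:
            raise ScenarioError(f"attribute {self.id!r}: features must be a 1-d vector")
        if not np.isin(feats, (0.0, 1.0)).all():
            raise ScenarioError(f"attribute {self.id!r}: features must be binary (0/1)")
        object.__setattr__(self, "features", feats)


@dataclass
class SceneObject:
    """An object at a spatial location with at least one attribute."""

    id: str
    location: int
    attributes: list[Attribute]
    salience: float = 1.0

    def __post_init__(self):
        if self.location < 0:
            raise ScenarioError(f"object {self.id!r}: location must be >= 0")
        if not self.attributes:
            raise ScenarioError(f"object {self.id!r}: needs at least one attribute")
        if self.salience < 0:
            raise ScenarioError(f"object {self.id!r}: salience must be >= 0")
        ids = [a.id for a in self.attributes]
        if len(set(ids)) != len(ids):
            raise ScenarioError(f"object {self.id!r}: duplicate attribute ids {ids}")


@dataclass
class Scene:
    """A set of objects with mutually distinct locations and a fixed feature size."""

    objects: list[SceneObject]
    feature_dim: int

    def __post_init__(self):
        if not self.objects:
            raise ScenarioError("scene needs at least one object")
        locs = [o.location for o in self.objects]
        if len(set(locs)) != len(locs):
            raise ScenarioError(f"scene: duplicate object locations {locs}")
        for o in self.objects:
            for a in o.attributes:
                if a.features.shape[0] != self.feature_dim:
                    raise ScenarioError(
                        f"attribute {a.id!r} of object {o.id!r} has feature length "
                        f"{a.features.shape[0]}, expected {self.feature_dim}"
                    )

    @property
    def n_locations(self) -> int:
        return max(o.location for o in self.objects) + 1

    def object_at(self, location: int) -> SceneObject | None:
        for o in self.objects:
            if o.location == location:
                return o
        return None


def sample_attribute(obj: SceneObject, rng: np.random.Generator) -> Attribute:
    """Pick one attribute of ``obj`` uniformly at random."""
    if not obj.attributes:
        raise ScenarioError(f"object {obj.id!r} has no attributes")
    return obj.attributes[rng.integers(len(obj.attributes))]


def salience_vector(scene: Scene) -> np.ndarray:
    """Bottom-up salience per location; 0 at empty locations."""
    s = np.zeros(scene.n_locations)
    for o in scene.objects:
        s[o.location] = o.salience
    return s


def _as_value_lists(value_spec, n_objects: int, attrs_per_object: int) -> list[list[float]]:
    """Normalize a value spec into one list of per-attribute values per object."""
    if len(value_spec) != n_objects:
        raise ScenarioError(
            f"value_spec has {len(value_spec)} entries for {n_objects} objects"
        )
    out = []
    for i, v in enumerate(value_spec):
        vals = [float(v)] if np.isscalar(v) else [float(x) for x in v]
        if len(vals) != attrs_per_object:
            raise ScenarioError(
                f"value_spec[{i}] has {len(vals)} values for {attrs_per_object} attributes"
            )
        out.append(vals)
    return out


def make_scenario(
    n_objects: int,
    attrs_per_object: int,
    feature_dim: int | None,
    value_spec,
    chain_lengths=None,
    rng: np.random.Generator | None = None,
    *,
    block_size: int = 1,
    overlap: int = 0,
    saliences=None,
    attractor_strength: float = 0.4,
    episodic_strength: float = 0.5,
    memory_cfg=None,
    acc_cfg=None,
    attention_cfg=None,
    threshold: float = 1.0,
    max_steps: int = 10_000,
    dwell_attr: int = 20,
    seed: int = 0,
):
    """Build a complete runnable Scenario with orthogonal block patterns.

    ``value_spec`` gives, per object, a scalar (one attribute) or a list of
    per-attribute values.  ``chain_lengths`` gives, per object, the number of
    episodic transitions between the object's first attribute and the memory
    state that carries its value; 0 means the attribute pattern itself is
    valued.  Value mass is spread over the elements of the valued pattern so
    that the linear readout at the settled attractor equals the stated value.

    ``feature_dim=None`` auto-sizes the feature space to exactly host the
    requested orthogonal patterns (useful for chain-length sweeps, where the
    number of patterns varies).
    """
    from .engine import Scenario
    from .memory_net import AssociationSet, MemoryConfig, encode_attractors, encode_episodic_chain
    from .accumulators import AccumulatorBank, DecisionLayer
    from .attention import AttentionConfig
    from .valuation import ValueMap

    if n_objects < 1 or attrs_per_object < 1 or (feature_dim is not None and feature_dim < 1):
        raise ScenarioError("n_objects, attrs_per_object and feature_dim must all be >= 1")
    chain_lengths = list(chain_lengths) if chain_lengths is not None else [0] * n_objects
    if len(chain_lengths) != n_objects:
        raise ScenarioError(
            f"chain_lengths has {len(chain_lengths)} entries for {n_objects} objects"
        )
    if any(c < 0 for c in chain_lengths):
        raise ScenarioError("chain_lengths must be >= 0")
    values = _as_value_lists(value_spec, n_objects, attrs_per_object)
    if saliences is None:
        saliences = [1.0] * n_objects

    n_patterns = n_objects * attrs_per_object + sum(chain_lengths)
    if overlap >= block_size:
        raise ScenarioError(f"overlap ({overlap}) must be smaller than block_size ({block_size})")
    stride = block_size - overlap
    needed = block_size + (n_patterns - 1) * stride
    if feature_dim is None:
        feature_dim = needed
    if needed > feature_dim:
        raise CapacityError(
            f"feature_dim={feature_dim} too small for {n_patterns} patterns of "
            f"block_size={block_size} with overlap={overlap} (need {needed})"
        )

    cursor = 0

    def next_pattern() -> np.ndarray:
        nonlocal cursor
        p = np.zeros(feature_dim)
        p[cursor : cursor + block_size] = 1.0
        cursor += stride
        return p

    names = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    objects: list[SceneObject] = []
    patterns: dict[str, np.ndarray] = {}
    chains: list[list[str]] = []
    v = np.zeros(feature_dim)

    for i in range(n_objects):
        oid = names[i] if i < len(names) else f"O{i}"
        attrs = []
        for j in range(attrs_per_object):
            pname = f"{oid}{j}"
            pat = next_pattern()
            patterns[pname] = pat
            attrs.append(Attribute(id=pname, features=pat))
            if not (j == 0 and chain_lengths[i] > 0):
                v += values[i][j] / pat.sum() * pat
        if chain_lengths[i] > 0:
            chain = [f"{oid}0"]
            for k in range(chain_lengths[i]):
                cname = f"{oid}0.ep{k + 1}"
                cpat = next_pattern()
                patterns[cname] = cpat
                chain.append(cname)
            terminal = patterns[chain[-1]]
            v += values[i][0] / terminal.sum() * terminal
            chains.append(chain)
        objects.append(SceneObject(id=oid, location=i, attributes=attrs, salience=saliences[i]))

    scene = Scene(objects=objects, feature_dim=feature_dim)
    w_sem = encode_attractors(list(patterns.values()), strength=attractor_strength)
    w_epi = np.zeros((feature_dim, feature_dim))
    for chain in chains:
        w_epi += encode_episodic_chain(
            [patterns[n] for n in chain], strength=episodic_strength
        )
    assoc = AssociationSet(
        semantic_weights=w_sem, episodic_weights=w_epi, stored_patterns=dict(patterns)
    )
    spec = dict(
        n_objects=n_objects,
        attrs_per_object=attrs_per_object,
        feature_dim=None,  # auto-resize on rebuilds (e.g. chain-length sweeps)
        value_spec=value_spec,
        chain_lengths=chain_lengths,
        block_size=block_size,
        overlap=overlap,
        saliences=saliences,
        attractor_strength=attractor_strength,
        episodic_strength=episodic_strength,
        memory_cfg=memory_cfg,
        acc_cfg=acc_cfg,
        attention_cfg=attention_cfg,
        threshold=threshold,
        max_steps=max_steps,
        dwell_attr=dwell_attr,
        seed=seed,
    )
    return Scenario(
        scene=scene,
        associations=assoc,
        value_map=ValueMap(v=v),
        memory_cfg=memory_cfg if memory_cfg is not None else MemoryConfig(),
        bank=acc_cfg if acc_cfg is not None else AccumulatorBank(n=scene.n_locations),
        attention_cfg=attention_cfg if attention_cfg is not None else AttentionConfig(),
        decision=DecisionLayer(threshold=threshold),
        max_steps=max_steps,
        dwell_attr=dwell_attr,
        seed=seed,
        spec=spec,
    )
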