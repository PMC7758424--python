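"""Bundled scenario presets, named after the experiments they reproduce.

The printed quantities — option values (0.4/0.6, 0.2/0.8, 0.2/0.3 mirrored,
0.9/1.0), decision threshold 1 and contrast exponent n=2 — define the
scenarios; every dynamical gain (integration, leak, noise, attention base
rate, episodic latency) is this repository's own calibration, chosen to
reproduce the qualitative trends at desk-scale trial counts.
"""

from __future__ import annotations

from .accumulators import AccumulatorBank
from .attention import AttentionConfig
from .memory_net import MemoryConfig
from .scene import make_scenario

__all__ = ["get_preset", "list_presets", "PRESETS"]


def _base_memory(**kw) -> MemoryConfig:
    cfg = dict(leak=0.2, input_gain=0.5, tau_fast=1, tau_slow=25)
    cfg.update(kw)
    return MemoryConfig(**cfg)


def _base_bank(**kw) -> AccumulatorBank:
    cfg = dict(n=2, alpha=0.015, leak=0.004, sigma=0.02)
    cfg.update(kw)
    return AccumulatorBank(**cfg)


def _two_object(value_a, value_b, *, attrs=1, chains=(0, 0), sigma=0.02,
                phi=0.0, epsilon=0.5, tau_slow=25, input_gain=0.5,
                episodic_strength=0.5, max_steps=10_000, **kw):
    return make_scenario(
        n_objects=2,
        attrs_per_object=attrs,
        feature_dim=None,
        value_spec=[value_a, value_b],
        chain_lengths=list(chains),
        episodic_strength=episodic_strength,
        memory_cfg=_base_memory(tau_slow=tau_slow, input_gain=input_gain),
        acc_cfg=_base_bank(sigma=sigma, **kw),
        attention_cfg=AttentionConfig(epsilon=epsilon, phi=phi, n=2.0),
        max_steps=max_steps,
    )


def fig5a():
    """Two one-attribute objects, values 0.4 (A) and 0.6 (B)."""
    return _two_object(0.4, 0.6)


def fig5b():
    """Two one-attribute objects, values 0.2 (A) and 0.8 (B)."""
    return _two_object(0.2, 0.8)


def fig7():
    """Symmetric multi-attribute choice: A={0.2, 0.3}, B={0.3, 0.2}.

    Forward gain is doubled relative to the one-attribute scenarios so the
    mean per-dwell value (0.25 instead of 0.5) drives the accumulators at
    the same operating point.
    """
    return _two_object([0.2, 0.3], [0.3, 0.2], attrs=2, alpha=0.03)


def fig9a():
    """Implicit discounting, equal goals: A's value 1 sits behind an episodic
    chain (sweep ``chain_length``), B's value 1 is immediate."""
    return _two_object(1.0, 1.0, chains=(3, 0), sigma=0.005, alpha=0.004,
                       leak=0.002, epsilon=0.08, tau_slow=2, input_gain=1.0,
                       episodic_strength=1.0, max_steps=20_000)


def fig9b():
    """Delayed larger reward 1.0 (A, behind the chain) vs immediate 0.9 (B)."""
    return _two_object(1.0, 0.9, chains=(2, 0), sigma=0.005, alpha=0.004,
                       leak=0.002, epsilon=0.08, tau_slow=2, input_gain=1.0,
                       episodic_strength=1.0, max_steps=20_000)


def fig10():
    """Top-down attention feedback: values 0.4/0.6, phi swept upward from 0."""
    return _two_object(0.4, 0.6, phi=200.0)


PRESETS = {
    "fig5a": fig5a,
    "fig5b": fig5b,
    "fig7": fig7,
    "fig9a": fig9a,
    "fig9b": fig9b,
    "fig10": fig10,
}


def list_presets() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str):
    """Build a bundled scenario by name."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {list_presets()}") from None
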