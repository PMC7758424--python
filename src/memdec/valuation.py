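"""Linear value readout: V = v · m.

Each element of the memory state carries a fixed scalar value; the value of
the current memory readout m = f(x) is their inner product.  This is the only
channel through which memory content reaches the accumulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ScenarioError

__all__ = ["ValueMap", "evaluate"]


@dataclass
class ValueMap:
    v: np.ndarray

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if self.v.ndim != 1:
            raise ScenarioError("value map must be a 1-d vector")
        if not np.isfinite(self.v).all():
            raise ScenarioError("value map entries must be finite")


def evaluate(m: np.ndarray, vm: ValueMap) -> float:
    """Scalar value of a memory readout."""
    m = np.asarray(m, dtype=float)
    if m.shape != vm.v.shape:
        raise ScenarioError(
            f"memory readout length {m.shape} does not match value map {vm.v.shape}"
        )
    return float(vm.v @ m)
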