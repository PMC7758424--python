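"""Exception types shared across the package."""


class ScenarioError(ValueError):
    """A scenario, config or argument violates a structural constraint."""


class CapacityError(ScenarioError):
    """The feature dimensionality cannot host the requested orthogonal patterns."""


class DegenerateSceneError(ScenarioError):
    """Attention cannot be allocated: every salience and feedback term is zero."""


class NumericalError(FloatingPointError):
    """A simulated state became non-finite; carries context about where."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step
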