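"""Exception types shared across the package."""


class InvalidParameterError(ValueError):
    """A model parameter violates its domain (e.g. non-positive spread)."""


class InfeasibleTestError(ValueError):
    """A test's nominal posterior width is wider than the prior it would update.

    A toxicity test can only narrow uncertainty; asking it to widen the prior
    has no Bayesian interpretation and is rejected rather than clamped.
    """


class ConfigError(ValueError):
    """A scenario configuration failed validation."""
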